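"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates a cytokine-exposure transcriptome study on a focal
bacterial genome: a 130-genome presence/absence panel in which planted
operons share identical phylogenetic profiles, negative-binomial RNA-seq
counts with condition effects planted coherently within transcription
units, strand-specific 5'-end coverage with read pileups at each unit's
true TSS, and a random functional-category map — together with the ground
truth needed for recovery evaluation.

Genes are laid left-to-right on a single contig as transcription units
(operons of 2-6 genes and monocistronic genes, each unit on a random
strand).  Every generator is a pure function of its config (which carries
the seed): reruns are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as opio
from .io import CategoryMap, CountMatrix, GeneFeature, ProfileMatrix, StrandCoverage

#: Minimum gap between consecutive transcription units.  Upstream TSS
#: offsets are at most 100 nt per unit, so a 210 nt floor keeps two units'
#: TSSs more than the caller's 5 nt cluster width apart: the planted truth
#: stays unambiguous at single-nucleotide resolution.
MIN_UNIT_GAP = 210

#: Margin kept free at both contig edges (room for upstream TSSs).
CONTIG_MARGIN = 200

COG_LETTERS = list("JKLDVTMNUOCGEFHIPQ")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror a desk-scale version of the emulated study: a panel of
    130 genomes, ~300 genes of mean length 1 kb, 40 operons of 2-6 genes,
    three replicates per condition, NB dispersion 0.1, 30% of transcription
    units carrying a |log2FC| = 2 condition effect, and dRNA-seq-like
    5'-end coverage with ~50 reads per true TSS over a 0.1 reads/nt
    background.
    """

    n_genomes: int = 130
    n_genes: int = 300
    n_operons: int = 40
    operon_size_range: tuple[int, int] = (2, 6)
    mean_gene_length: int = 1000
    operon_intergenic_gap: int = 50
    non_operon_gap_mean: int = 300
    profile_presence_prob: float = 0.7
    profile_noise: float = 0.0  # per-bit flip probability (non-focal columns)
    n_replicates: int = 3
    nb_dispersion: float = 0.1  # phi; 0 degenerates to Poisson
    frac_de: float = 0.3  # fraction of transcription units with an effect
    planted_log2fc_magnitude: float = 2.0
    count_mean_log_mu: float = 5.0  # natural-log scale of mean expression
    count_log_sd: float = 1.0
    tss_rate: float = 50.0  # Poisson mean reads per true TSS
    tss_jitter_sd: float = 1.0  # nt
    background_rate: float = 0.1  # 5'-end reads per position per strand
    contig_length: int | None = None  # None: sized to fit the layout
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("profile_presence_prob", "profile_noise", "frac_de"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for name in ("n_genomes", "n_genes", "n_operons", "n_replicates",
                     "mean_gene_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.operon_size_range
        if not 2 <= lo <= hi:
            raise ValueError("operon sizes must be >= 2 and ordered")


@dataclass
class GroundTruth:
    """Planted structure: operons, per-gene effects and true TSS positions."""

    gene_ids: list[str]
    true_operons: list[list[str]]  # ordered gene_id lists, disjoint
    true_de: dict[str, float]  # planted log2FC, 0 for null genes
    true_tss: list[tuple[int, str, str]] = field(default_factory=list)
    # (1-based position, strand, leader gene_id)


FOCAL_GENOME = "FOCAL"


def genome_panel(config: SimConfig) -> list[str]:
    """Ordered genome IDs; the focal genome is first."""
    return [FOCAL_GENOME] + [f"PANEL{i:03d}" for i in range(1, config.n_genomes)]


def _unit_plan(config: SimConfig, rng: np.random.Generator) -> list[int]:
    """Sizes of transcription units in layout order (1 = monocistronic)."""
    lo, hi = config.operon_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_operons)
    n_operon_genes = int(sizes.sum())
    if n_operon_genes > config.n_genes:
        raise ValueError(
            f"{config.n_operons} operons need {n_operon_genes} genes but "
            f"n_genes={config.n_genes}"
        )
    units = list(sizes) + [1] * (config.n_genes - n_operon_genes)
    rng.shuffle(units)
    return units


def simulate_pangenome(
    config: SimConfig,
) -> tuple[list[GeneFeature], ProfileMatrix, dict[str, str], GroundTruth]:
    """Lay out genes on one contig and draw their phylogenetic profiles.

    Operon members get identical presence/absence patterns across the panel
    (before noise), sit contiguously on one strand, and are closer than the
    operon span criterion by construction.  Monocistronic genes draw
    independent Bernoulli patterns.  Profile noise flips each non-focal bit
    independently; the focal-genome column stays 1 (the gene is annotated
    there by construction).  Condition effects are planted per unit with
    probability ``frac_de`` and random sign, so DE signs are coherent
    within operons.
    """
    rng = np.random.default_rng([config.seed, 0])
    units = _unit_plan(config, rng)

    genes: list[GeneFeature] = []
    true_operons: list[list[str]] = []
    true_de: dict[str, float] = {}
    unit_members: list[list[str]] = []
    pos = CONTIG_MARGIN + 1
    gene_no = 0
    lo_len = config.mean_gene_length // 2
    hi_len = config.mean_gene_length + config.mean_gene_length // 2
    for size in units:
        strand = "+" if rng.random() < 0.5 else "-"
        members: list[str] = []
        for k in range(size):
            if k > 0:
                pos += int(rng.integers(1, config.operon_intergenic_gap + 1))
            gene_no += 1
            length = int(rng.integers(lo_len, hi_len + 1))
            gid = f"g{gene_no:04d}"
            genes.append(
                GeneFeature(
                    gene_id=gid, contig="contig1", start=pos,
                    end=pos + length - 1, strand=strand,
                )
            )
            members.append(gid)
            pos += length
        extra = rng.exponential(max(config.non_operon_gap_mean - MIN_UNIT_GAP, 1))
        pos += MIN_UNIT_GAP + int(extra)
        if size >= 2:
            true_operons.append(members)
        unit_members.append(members)
        # operon-coherent condition effect, one draw per transcription unit
        if rng.random() < config.frac_de:
            lfc = config.planted_log2fc_magnitude * (
                1.0 if rng.random() < 0.5 else -1.0
            )
        else:
            lfc = 0.0
        for gid in members:
            true_de[gid] = lfc

    contig_length = (
        config.contig_length
        if config.contig_length is not None
        else genes[-1].end + CONTIG_MARGIN
    )
    if genes[-1].end + CONTIG_MARGIN > contig_length:
        raise ValueError(
            f"genes span {genes[-1].end + CONTIG_MARGIN} nt but contig_length="
            f"{contig_length}; use a larger contig"
        )

    panel = genome_panel(config)
    bits = np.zeros((config.n_genes, config.n_genomes), dtype=np.uint8)
    row = 0
    for members in unit_members:
        pattern = np.ones(config.n_genomes, dtype=np.uint8)
        pattern[1:] = rng.random(config.n_genomes - 1) < config.profile_presence_prob
        for _ in members:
            bits[row] = pattern
            row += 1
    if config.profile_noise > 0:
        flips = rng.random(bits.shape) < config.profile_noise
        flips[:, 0] = False  # focal column stays 1
        bits = np.where(flips, 1 - bits, bits)

    gene_ids = [g.gene_id for g in genes]
    gene_to_og = {gid: f"OG{i + 1:07d}" for i, gid in enumerate(gene_ids)}
    profiles = ProfileMatrix(row_ids=gene_ids, genome_ids=panel, bits=bits)
    truth = GroundTruth(
        gene_ids=gene_ids, true_operons=true_operons, true_de=true_de
    )
    return genes, profiles, gene_to_og, truth


def simulate_counts(truth: GroundTruth, config: SimConfig) -> CountMatrix:
    """NB gene x sample counts with the planted condition effects.

    count ~ NB(mean = s_j * mu_g * 2^(log2FC_g * [treated]), dispersion phi)
    with mu_g ~ LogNormal(count_mean_log_mu, count_log_sd) and library scale
    factors s_j ~ Uniform(0.8, 1.2); phi = 0 gives Poisson counts.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes = truth.gene_ids
    mu = rng.lognormal(config.count_mean_log_mu, config.count_log_sd, len(genes))
    samples = [f"control_{r + 1}" for r in range(config.n_replicates)] + [
        f"treated_{r + 1}" for r in range(config.n_replicates)
    ]
    condition_of = {
        s: ("control" if s.startswith("control") else "treated") for s in samples
    }
    s_j = rng.uniform(0.8, 1.2, len(samples))
    lfc = np.array([truth.true_de[g] for g in genes])
    counts = np.empty((len(genes), len(samples)), dtype=np.int64)
    phi = config.nb_dispersion
    for j, sample in enumerate(samples):
        m = s_j[j] * mu
        if condition_of[sample] == "treated":
            m = m * np.exp2(lfc)
        if phi == 0:
            counts[:, j] = rng.poisson(m)
        else:
            r = 1.0 / phi
            counts[:, j] = rng.negative_binomial(r, r / (r + m))
    return CountMatrix(
        gene_ids=list(genes), sample_ids=samples, counts=counts,
        condition_of=condition_of,
    )


def _units_of(
    features: list[GeneFeature], truth: GroundTruth
) -> list[list[GeneFeature]]:
    """Transcription units in layout order: operons plus monocistronic genes."""
    by_id = {g.gene_id: g for g in features}
    in_operon = {g for op in truth.true_operons for g in op}
    units: list[list[GeneFeature]] = []
    op_iter = {op[0]: op for op in truth.true_operons}
    for g in features:
        if g.gene_id in op_iter:
            units.append([by_id[x] for x in op_iter[g.gene_id]])
        elif g.gene_id not in in_operon:
            units.append([g])
    return units


def simulate_tss_coverage(
    features: list[GeneFeature],
    truth: GroundTruth,
    config: SimConfig,
) -> tuple[StrandCoverage, StrandCoverage, list[tuple[int, str, str]]]:
    """5'-end coverage with one true TSS per transcription unit.

    The TSS sits Uniform[20, 100] nt upstream (transcription-direction) of
    the unit's leader gene; Poisson(tss_rate) reads land there with
    Normal(0, tss_jitter_sd) positional jitter, over a Poisson background
    of ``background_rate`` reads per position on each strand.  Fills
    ``truth.true_tss`` and also returns it.
    """
    rng = np.random.default_rng([config.seed, 2])
    contig_length = (
        config.contig_length
        if config.contig_length is not None
        else max(g.end for g in features) + CONTIG_MARGIN
    )
    cov = {
        "+": rng.poisson(config.background_rate, contig_length).astype(np.int64),
        "-": rng.poisson(config.background_rate, contig_length).astype(np.int64),
    }
    true_tss: list[tuple[int, str, str]] = []
    for unit in _units_of(features, truth):
        if unit[0].strand == "+":
            leader = min(unit, key=lambda g: g.start)
            tss_pos = leader.start - int(rng.integers(20, 101))
        else:
            leader = max(unit, key=lambda g: g.end)
            tss_pos = leader.end + int(rng.integers(20, 101))
        tss_pos = min(max(tss_pos, 1), contig_length)
        n_reads = rng.poisson(config.tss_rate)
        offsets = np.rint(rng.normal(0.0, config.tss_jitter_sd, n_reads))
        positions = np.clip(tss_pos + offsets.astype(int), 1, contig_length)
        np.add.at(cov[unit[0].strand], positions - 1, 1)
        true_tss.append((tss_pos, unit[0].strand, leader.gene_id))
    truth.true_tss = true_tss
    contig = features[0].contig if features else "contig1"
    return (
        StrandCoverage(contig=contig, strand="+", values=cov["+"]),
        StrandCoverage(contig=contig, strand="-", values=cov["-"]),
        true_tss,
    )


def simulate_categories(
    gene_ids: list[str], config: SimConfig
) -> CategoryMap:
    """Random COG-letter assignments; each gene carries one or two letters."""
    rng = np.random.default_rng([config.seed, 3])
    assignments: set[tuple[str, str]] = set()
    for gid in gene_ids:
        k = 1 + int(rng.random() < 0.2)
        for cat in rng.choice(COG_LETTERS, size=k, replace=False):
            assignments.add((gid, str(cat)))
    return CategoryMap(assignments=assignments, category_kind="COG")


@dataclass
class Dataset:
    """A complete simulated input set plus its ground truth."""

    config: SimConfig
    features: list[GeneFeature]
    profiles: ProfileMatrix  # per-gene profiles
    gene_to_og: dict[str, str]
    counts: CountMatrix
    coverage_plus: StrandCoverage
    coverage_minus: StrandCoverage
    categories: CategoryMap
    truth: GroundTruth

    @property
    def og_profiles(self) -> ProfileMatrix:
        """The profile matrix keyed by orthogroup ID instead of gene ID
        (what :func:`operonpp.pipeline.run_pipeline` consumes)."""
        return ProfileMatrix(
            row_ids=[self.gene_to_og[g] for g in self.profiles.row_ids],
            genome_ids=list(self.profiles.genome_ids),
            bits=self.profiles.bits.copy(),
        )


def simulate_dataset(config: SimConfig) -> Dataset:
    """Run all generators under one config; the one-stop entry point."""
    features, profiles, gene_to_og, truth = simulate_pangenome(config)
    counts = simulate_counts(truth, config)
    cov_plus, cov_minus, _ = simulate_tss_coverage(features, truth, config)
    categories = simulate_categories(truth.gene_ids, config)
    return Dataset(
        config=config, features=features, profiles=profiles,
        gene_to_og=gene_to_og, counts=counts, coverage_plus=cov_plus,
        coverage_minus=cov_minus, categories=categories, truth=truth,
    )


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the five pipeline input files plus the ground truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff3": out / "annotation.gff3",
        "counts": out / "counts.tsv",
        "orthogroups": out / "orthogroups.tsv",
        "bedgraph_plus": out / "five_prime_plus.bedgraph",
        "bedgraph_minus": out / "five_prime_minus.bedgraph",
        "categories": out / "categories.tsv",
        "truth": out / "truth.json",
    }
    opio.write_gff3(dataset.features, paths["gff3"])
    opio.write_count_matrix(dataset.counts, paths["counts"])
    panel = list(dataset.profiles.genome_ids)
    og_members: dict[str, dict[str, list[str]]] = {}
    for i, gid in enumerate(dataset.profiles.row_ids):
        og = dataset.gene_to_og[gid]
        members: dict[str, list[str]] = {FOCAL_GENOME: [gid]}
        for j, genome in enumerate(panel[1:], start=1):
            if dataset.profiles.bits[i, j]:
                members[genome] = [f"{og}_{genome}"]
        og_members[og] = members
    opio.write_orthogroups(paths["orthogroups"], og_members, panel)
    opio.write_bedgraph(dataset.coverage_plus, paths["bedgraph_plus"])
    opio.write_bedgraph(dataset.coverage_minus, paths["bedgraph_minus"])
    opio.write_category_map(dataset.categories, paths["categories"])
    opio.write_truth_json(dataset.truth, paths["truth"])
    return paths
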