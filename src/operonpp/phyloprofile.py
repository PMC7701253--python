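"""Phylogenetic-profile construction and operon prediction.

A phylogenetic profile is a binary vector recording presence (1) or absence
(0) of a gene's orthogroup across an ordered panel of genomes.  Genes that
were gained and lost together — in particular co-operonic genes — have
similar profiles, quantified here by Jaccard distance.

Putative operons are maximal runs of genes that jointly satisfy four
criteria: (a) same contig and strand, (b) consecutive start-to-start
distance within a span cutoff (default 10,000 nt), (c) consecutive profile
Jaccard distance below a threshold (default 0.001), and (d) the same sign
of differential expression.  On a panel of G <= 1000 genomes the smallest
nonzero Jaccard distance between binary vectors is 1/|union| >= 1/G > 0.001,
so the default distance rule is equivalent to requiring identical profiles —
which also makes "all pairwise" and "consecutive pairs" readings coincide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .diffexpr import DERecord
from .io import GeneFeature, ProfileMatrix

logger = logging.getLogger(__name__)

DEFAULT_MAX_DISTANCE = 0.001
DEFAULT_MAX_SPAN_NT = 10_000


@dataclass
class OperonPrediction:
    """An ordered same-strand run of genes predicted to be one operon."""

    operon_id: str
    gene_ids: list[str]  # genomic order, length >= 2
    strand: str
    span: tuple[int, int]  # (min start, max end) over members
    de_sign: str  # "up" or "down", shared by all members
    max_pair_distance: float  # max consecutive-pair Jaccard distance
    tss_validated: bool | None = None
    leader_tss: list[int] = field(default_factory=list)
    violating_tss: list[int] = field(default_factory=list)


def jaccard_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - |u AND v| / |u OR v| for binary vectors; 0 if both are all-zero."""
    u = np.asarray(u, dtype=bool)
    v = np.asarray(v, dtype=bool)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    union = np.logical_or(u, v).sum()
    if union == 0:
        return 0.0
    return 1.0 - np.logical_and(u, v).sum() / union


def pairwise_distances(profiles: ProfileMatrix) -> np.ndarray:
    """Symmetric Jaccard distance matrix over all profile rows."""
    if len(profiles.row_ids) < 2:
        raise ValueError("need at least 2 profile rows")
    return squareform(pdist(profiles.bits.astype(bool), metric="jaccard"))


def build_gene_profiles(
    og_profiles: ProfileMatrix,
    gene_to_og: dict[str, str],
    genes: list[GeneFeature],
    focal_genome_index: int = 0,
) -> ProfileMatrix:
    """Per-gene profiles: each gene inherits its orthogroup's row.

    A gene with no orthogroup assignment gets a singleton profile (1 only in
    the focal genome) and is flagged; on any real panel such a profile can
    only match another focal-only profile, so unassigned genes cannot link
    to panel-supported genes.
    """
    og_index = {og: i for i, og in enumerate(og_profiles.row_ids)}
    g = len(og_profiles.genome_ids)
    bits = np.zeros((len(genes), g), dtype=np.uint8)
    flagged: set[str] = set()
    for i, gene in enumerate(genes):
        og = gene_to_og.get(gene.gene_id)
        if og is not None and og in og_index:
            bits[i] = og_profiles.bits[og_index[og]]
        else:
            bits[i, focal_genome_index] = 1
            flagged.add(gene.gene_id)
    return ProfileMatrix(
        row_ids=[gene.gene_id for gene in genes],
        genome_ids=list(og_profiles.genome_ids),
        bits=bits,
        flagged=flagged,
    )


def predict_operons(
    genes: list[GeneFeature],
    gene_profiles: ProfileMatrix,
    de_records: list[DERecord],
    max_distance: float = DEFAULT_MAX_DISTANCE,
    max_span_nt: int = DEFAULT_MAX_SPAN_NT,
    require_sign: bool = True,
    skip_ineligible: bool = False,
) -> list[OperonPrediction]:
    """Group genes into putative operons under the four criteria.

    Genes are scanned in genomic (contig, start) order.  Consecutive
    eligible genes are linked when they share contig, strand and DE sign,
    lie within ``max_span_nt`` (start-to-start) and their profiles are
    within ``max_distance`` Jaccard distance; maximal linked runs of two or
    more genes become predictions, so each gene joins at most one operon.

    When ``require_sign`` is true only genes labelled up or down are
    eligible.  By default an ineligible gene sitting between two eligible
    ones breaks the chain (genes of an operon are expected to respond
    together); ``skip_ineligible=True`` instead links across it, pairing
    with the restriction of planted operons to their DE-called members.
    """
    order = sorted(range(len(genes)), key=lambda i: (genes[i].contig, genes[i].start))
    if order != list(range(len(genes))):
        logger.warning("gene features were not sorted; sorting by (contig, start)")
    sign_of = {r.gene_id: r.sign for r in de_records}
    prof_row = {rid: i for i, rid in enumerate(gene_profiles.row_ids)}

    def eligible(gene: GeneFeature) -> bool:
        if gene.gene_id not in prof_row:
            return False
        if require_sign:
            return sign_of.get(gene.gene_id, "ns") in ("up", "down")
        return True

    def linkable(a: GeneFeature, b: GeneFeature) -> float | None:
        """Jaccard distance if the pair satisfies all criteria, else None."""
        if a.contig != b.contig or a.strand != b.strand:
            return None
        if abs(b.start - a.start) > max_span_nt:
            return None
        if require_sign and sign_of.get(a.gene_id) != sign_of.get(b.gene_id):
            return None
        d = jaccard_distance(
            gene_profiles.bits[prof_row[a.gene_id]],
            gene_profiles.bits[prof_row[b.gene_id]],
        )
        return d if d < max_distance else None

    operons: list[OperonPrediction] = []
    run: list[GeneFeature] = []
    run_dists: list[float] = []

    def flush() -> None:
        nonlocal run, run_dists
        if len(run) >= 2:
            sign = sign_of.get(run[0].gene_id, "ns")
            operons.append(
                OperonPrediction(
                    operon_id=f"OP{len(operons) + 1:04d}",
                    gene_ids=[g.gene_id for g in run],
                    strand=run[0].strand,
                    span=(min(g.start for g in run), max(g.end for g in run)),
                    de_sign=sign if require_sign else "na",
                    max_pair_distance=max(run_dists),
                )
            )
        run, run_dists = [], []

    for i in order:
        gene = genes[i]
        if not eligible(gene):
            if not skip_ineligible:
                flush()
            continue
        if run:
            d = linkable(run[-1], gene)
            if d is None:
                flush()
        if run:
            run.append(gene)
            run_dists.append(d)
        else:
            run = [gene]
            run_dists = []
    flush()
    return operons


def audit_operons(
    operons: list[OperonPrediction],
    genes: list[GeneFeature],
    gene_profiles: ProfileMatrix,
    de_records: list[DERecord],
    max_distance: float = DEFAULT_MAX_DISTANCE,
    max_span_nt: int = DEFAULT_MAX_SPAN_NT,
) -> list[str]:
    """Post-hoc check that no prediction violates any of the four criteria.

    Returns a list of human-readable violations (empty when all pass).
    """
    by_id = {g.gene_id: g for g in genes}
    sign_of = {r.gene_id: r.sign for r in de_records}
    prof_row = {rid: i for i, rid in enumerate(gene_profiles.row_ids)}
    problems: list[str] = []
    seen: dict[str, str] = {}
    for op in operons:
        members = [by_id[g] for g in op.gene_ids]
        if len(members) < 2:
            problems.append(f"{op.operon_id}: fewer than 2 genes")
        if len({m.strand for m in members}) != 1:
            problems.append(f"{op.operon_id}: mixed strands")
        if len({sign_of.get(m.gene_id, 'ns') for m in members}) != 1:
            problems.append(f"{op.operon_id}: mixed DE signs")
        for a, b in zip(members, members[1:]):
            if abs(b.start - a.start) > max_span_nt:
                problems.append(f"{op.operon_id}: {a.gene_id}-{b.gene_id} too far")
            d = jaccard_distance(
                gene_profiles.bits[prof_row[a.gene_id]],
                gene_profiles.bits[prof_row[b.gene_id]],
            )
            if d >= max_distance:
                problems.append(
                    f"{op.operon_id}: {a.gene_id}-{b.gene_id} distance {d:.4g}"
                )
        for m in members:
            if m.gene_id in seen:
                problems.append(
                    f"{m.gene_id} in both {seen[m.gene_id]} and {op.operon_id}"
                )
            seen[m.gene_id] = op.operon_id
    return problems


def operon_recovery(
    predicted: list[OperonPrediction],
    true_operons: list[list[str]],
    de_records: list[DERecord],
    split_at_missing: bool = True,
) -> tuple[float, float]:
    """Precision and recall of predictions against planted operons.

    Planted operons are restricted to members actually labelled up or down
    (a gene the DE stage missed cannot appear in any prediction).  With
    ``split_at_missing`` a planted operon is additionally split at each
    non-DE member, matching the default chaining rule; restricted fragments
    shorter than two genes are dropped.  Operons compare as ordered tuples.
    """
    called = {r.gene_id for r in de_records if r.sign in ("up", "down")}
    target: set[tuple[str, ...]] = set()
    for op in true_operons:
        if split_at_missing:
            frag: list[str] = []
            for g in op:
                if g in called:
                    frag.append(g)
                else:
                    if len(frag) >= 2:
                        target.add(tuple(frag))
                    frag = []
            if len(frag) >= 2:
                target.add(tuple(frag))
        else:
            frag = [g for g in op if g in called]
            if len(frag) >= 2:
                target.add(tuple(frag))
    pred = {tuple(op.gene_ids) for op in predicted}
    if not pred and not target:
        return 1.0, 1.0
    tp = len(pred & target)
    precision = tp / len(pred) if pred else 1.0
    recall = tp / len(target) if target else 1.0
    return precision, recall
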