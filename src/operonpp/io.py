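"""Readers and writers for every external format the pipeline touches.

All coordinates are held 1-based inclusive internally (the GFF3 convention);
BED and bedGraph, which are 0-based half-open, are converted at the boundary.
Downstream modules consume only the domain types defined here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFeature:
    """A gene's coordinates, strand and identifiers on the focal genome.

    ``start``/``end`` are 1-based inclusive with ``end >= start``; ``strand``
    is ``+`` or ``-``.  Strand is a hard criterion of the operon procedure,
    so unstranded features are rejected at parse time rather than guessed.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"{self.gene_id}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def tx_start(self) -> int:
        """Transcription-direction start: GFF3 start on +, GFF3 end on -."""
        return self.start if self.strand == "+" else self.end


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample counts with a condition map."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (genes, samples), integer
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match gene/sample lists")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.sample_ids if s not in self.condition_of]
        if missing:
            raise ValueError(f"samples without a condition: {missing}")
        conds = {self.condition_of[s] for s in self.sample_ids}
        if len(conds) != 2:
            raise ValueError(f"exactly two conditions required, got {sorted(conds)}")

    @property
    def conditions(self) -> list[str]:
        return sorted({self.condition_of[s] for s in self.sample_ids})

    def samples_of(self, condition: str) -> list[int]:
        """Column indices of the samples in ``condition``."""
        return [
            j for j, s in enumerate(self.sample_ids)
            if self.condition_of[s] == condition
        ]


@dataclass
class StrandCoverage:
    """Dense per-position 5'-end read counts for one strand of one contig.

    ``values[i]`` is the number of read 5' ends whose first transcribed base
    maps at 1-based position ``i + 1``; the vector spans the whole contig.
    """

    contig: str
    strand: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")

    def __getitem__(self, pos1: int) -> int:
        return int(self.values[pos1 - 1])


@dataclass
class CategoryMap:
    """Gene -> functional-category assignments (COG letters or KEGG pathways).

    A gene may carry multiple categories.
    """

    assignments: set[tuple[str, str]]
    category_kind: str = "COG"

    def categories_of(self, gene_id: str) -> set[str]:
        return {c for g, c in self.assignments if g == gene_id}

    def genes_of(self, category_id: str) -> set[str]:
        return {g for g, c in self.assignments if c == category_id}

    @property
    def category_ids(self) -> list[str]:
        return sorted({c for _, c in self.assignments})


@dataclass
class ProfileMatrix:
    """Binary presence/absence vectors over an ordered genome panel."""

    row_ids: list[str]
    genome_ids: list[str]
    bits: np.ndarray  # shape (rows, genomes), values in {0, 1}
    flagged: set[str] = field(default_factory=set)  # rows with no orthogroup

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape != (
            len(self.row_ids), len(self.genome_ids)
        ):
            raise ValueError("bits shape does not match row/genome lists")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("profile entries must be 0 or 1")
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise ValueError("genome_ids must be unique")

    def row(self, row_id: str) -> np.ndarray:
        return self.bits[self.row_ids.index(row_id)]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_gff3(
    path: str | Path,
    feature_types: set[str] = frozenset({"gene", "CDS"}),
) -> list[GeneFeature]:
    """Read gene features from a GFF3 file.

    ``gene_id`` is taken from the ``ID`` attribute, falling back to
    ``locus_tag``.  Records whose type is not in ``feature_types`` are
    skipped.  Malformed lines, unstranded retained features and duplicate
    gene IDs raise :class:`ParseError`.
    """
    features: list[GeneFeature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ParseError(
                    f"{path}:{lineno}: malformed GFF3 line: expected 9 "
                    f"tab-separated columns"
                )
            try:
                rec = feature_from_line(line)
            except Exception as exc:
                raise ParseError(f"{path}:{lineno}: malformed GFF3 line: {exc}")
            if rec.featuretype not in feature_types:
                continue
            gene_id = (
                rec.attributes.get("ID", [None])[0]
                or rec.attributes.get("locus_tag", [None])[0]
            )
            if gene_id is None:
                raise ParseError(
                    f"{path}:{lineno}: feature has neither ID nor locus_tag"
                )
            if rec.strand not in ("+", "-"):
                raise ParseError(
                    f"{path}:{lineno}: gene {gene_id} has strand "
                    f"{rec.strand!r}; unstranded genes cannot enter operon logic"
                )
            if gene_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene_id {gene_id}")
            seen.add(gene_id)
            product = rec.attributes.get("product", [""])[0]
            features.append(
                GeneFeature(
                    gene_id=gene_id,
                    contig=rec.seqid,
                    start=rec.start,
                    end=rec.end,
                    strand=rec.strand,
                    product=product,
                )
            )
    return features


def write_gff3(features: list[GeneFeature], path: str | Path) -> None:
    """Write features as GFF3 ``gene`` records (round-trips with read_gff3)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.gene_id}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                f"{f.contig}\toperonpp\tgene\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def read_orthogroups(
    path: str | Path, genome_ids: list[str]
) -> tuple[ProfileMatrix, dict[str, str]]:
    """Read an orthogroup membership table into binary profiles.

    The table is tab-separated with the orthogroup ID in the first column and
    one column per genome holding comma-space-separated gene IDs (possibly
    empty).  Profile columns follow ``genome_ids`` order; extra genomes in
    the table are ignored (panels are routinely subset), but a requested
    genome missing from the header is an error.  Gene IDs from ALL genome
    columns are mapped to their orthogroup; a gene in two orthogroups is an
    error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    header = list(df.columns[1:])
    missing = [g for g in genome_ids if g not in header]
    if missing:
        raise ParseError(f"genomes missing from orthogroup table: {missing}")
    og_ids = list(df.iloc[:, 0])
    bits = np.zeros((len(og_ids), len(genome_ids)), dtype=np.uint8)
    gene_to_og: dict[str, str] = {}
    for i, og in enumerate(og_ids):
        for g in header:
            cell = df.iloc[i][g].strip()
            if not cell:
                continue
            if g in genome_ids:
                bits[i, genome_ids.index(g)] = 1
            for gene in (x.strip() for x in cell.split(",")):
                if not gene:
                    continue
                if gene in gene_to_og and gene_to_og[gene] != og:
                    raise ParseError(
                        f"gene {gene} appears in orthogroups "
                        f"{gene_to_og[gene]} and {og}"
                    )
                gene_to_og[gene] = og
    return ProfileMatrix(og_ids, list(genome_ids), bits), gene_to_og


def write_orthogroups(
    path: str | Path,
    og_members: dict[str, dict[str, list[str]]],
    genome_ids: list[str],
) -> None:
    """Write an orthogroup table (og -> genome -> gene list) as TSV."""
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(genome_ids) + "\n")
        for og in sorted(og_members):
            cells = [", ".join(og_members[og].get(g, [])) for g in genome_ids]
            fh.write(og + "\t" + "\t".join(cells) + "\n")


def read_count_matrix(
    path: str | Path, condition_map: dict[str, str]
) -> CountMatrix:
    """Read a gene x sample TSV of raw counts (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for sample in df.columns:
        if sample not in condition_map:
            raise ParseError(f"sample {sample} has no condition assigned")
        col = df[sample]
        if not np.issubdtype(col.dtype, np.number):
            bad = col[pd.to_numeric(col, errors="coerce").isna()].index[0]
            raise ParseError(f"non-numeric count at gene {bad}, sample {sample}")
        frac = col != np.floor(col)
        if frac.any():
            raise ParseError(
                f"non-integer count at gene {col[frac].index[0]}, sample {sample}"
            )
        if (col < 0).any():
            raise ParseError(
                f"negative count at gene {col[col < 0].index[0]}, sample {sample}"
            )
    return CountMatrix(
        gene_ids=list(df.index),
        sample_ids=list(df.columns),
        counts=df.to_numpy(dtype=np.int64),
        condition_of={s: condition_map[s] for s in df.columns},
    )


def write_count_matrix(counts: CountMatrix, path: str | Path) -> None:
    pd.DataFrame(
        counts.counts, index=pd.Index(counts.gene_ids, name="gene_id"),
        columns=counts.sample_ids,
    ).to_csv(path, sep="\t")


def _read_bedgraph(
    path: str | Path, contig_length: int, strand: str
) -> StrandCoverage:
    values = np.zeros(contig_length, dtype=np.int64)
    covered = np.zeros(contig_length, dtype=bool)
    contig = "contig"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            contig, s, e, v = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if e > contig_length:
                raise ParseError(
                    f"{path}:{lineno}: interval end {e} exceeds contig "
                    f"length {contig_length}"
                )
            if s < 0 or e <= s:
                raise ParseError(f"{path}:{lineno}: invalid interval [{s}, {e})")
            if covered[s:e].any():
                raise ParseError(f"{path}:{lineno}: overlapping intervals")
            covered[s:e] = True
            # bedGraph [s, e) with value v covers 1-based positions s+1..e
            values[s:e] = int(v)
    return StrandCoverage(contig=contig, strand=strand, values=values)


def read_strand_coverage(
    path_plus: str | Path, path_minus: str | Path, contig_length: int
) -> tuple[StrandCoverage, StrandCoverage]:
    """Read per-strand 5'-end coverage from two bedGraph files."""
    return (
        _read_bedgraph(path_plus, contig_length, "+"),
        _read_bedgraph(path_minus, contig_length, "-"),
    )


def write_bedgraph(cov: StrandCoverage, path: str | Path) -> None:
    """Write dense coverage as run-length-encoded bedGraph (zeros omitted)."""
    v = cov.values
    with open(path, "w") as fh:
        boundaries = np.flatnonzero(np.diff(v) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(v)]))
        for s, e in zip(starts, ends):
            if v[s] != 0:
                fh.write(f"{cov.contig}\t{s}\t{e}\t{int(v[s])}\n")


def read_category_map(path: str | Path, category_kind: str = "COG") -> CategoryMap:
    """Read a two-column gene_id / category_id TSV (header optional)."""
    assignments: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or (lineno == 1 and line.lower().startswith("gene")):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[1]:
                raise ParseError(f"{path}:{lineno}: expected gene_id<TAB>category")
            assignments.add((parts[0], parts[1]))
    return CategoryMap(assignments=assignments, category_kind=category_kind)


def write_category_map(cmap: CategoryMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcategory_id\n")
        for gene, cat in sorted(cmap.assignments):
            fh.write(f"{gene}\t{cat}\n")


_MINUS_VARIANTS = str.maketrans({"−": "-", "–": "-"})


def read_fold_change_table(path: str | Path) -> pd.DataFrame:
    """Read a published gene / annotation / log2FC table.

    Printed tables in the literature frequently use the decimal comma and
    typographic minus signs; both are accepted alongside ``.`` and ``-``.
    Returns a DataFrame with columns gene_id, annotation, log2fc.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = ["gene_id", "annotation", "log2fc"]

    def _num(x: str) -> float:
        return float(x.translate(_MINUS_VARIANTS).replace(",", "."))

    df["log2fc"] = df["log2fc"].map(_num)
    return df


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

def write_results(operons, tss, de_table, out_dir: str | Path) -> dict[str, Path]:
    """Write operon TSV, TSS BED6 and DE TSV into ``out_dir``.

    Returns the paths written.  Empty inputs produce headers-only files
    (BED has no header, so an empty TSS list gives an empty file).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "operons": out / "operons.tsv",
        "tss": out / "tss.bed",
        "de": out / "differential_expression.tsv",
    }
    write_operon_table(operons, paths["operons"])
    write_tss_bed(tss, paths["tss"])
    write_de_table(de_table, paths["de"])
    return paths


def write_operon_table(operons, path: str | Path) -> None:
    cols = (
        "operon_id\tgene_ids\tstrand\tspan_start\tspan_end\tde_sign\t"
        "max_pairwise_jaccard\ttss_validated\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for op in operons:
            validated = "" if op.tss_validated is None else str(op.tss_validated)
            fh.write(
                f"{op.operon_id}\t{','.join(op.gene_ids)}\t{op.strand}\t"
                f"{op.span[0]}\t{op.span[1]}\t{op.de_sign}\t"
                f"{op.max_pair_distance:.6g}\t{validated}\n"
            )


def write_tss_bed(tss, path: str | Path) -> None:
    """Write TSS records as BED6 (0-based half-open; name=id, score=count)."""
    with open(path, "w") as fh:
        for i, t in enumerate(tss, start=1):
            fh.write(
                f"{t.contig}\t{t.position - 1}\t{t.position}\tTSS{i:04d}\t"
                f"{t.read_count}\t{t.strand}\n"
            )


def read_tss_bed(path: str | Path) -> list[tuple[str, int, str, int]]:
    """Read a TSS BED6 back as (contig, 1-based position, strand, count)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            contig, s, e, _name, score, strand = line.split("\t")
            out.append((contig, int(s) + 1, strand.strip(), int(score)))
    return out


def write_de_table(de_table, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tmean_cpm\tlog2fc\tpvalue\tqvalue\tsign\n")
        for r in de_table:
            fh.write(
                f"{r.gene_id}\t{r.mean_cpm:.6g}\t{r.log2fc:.6g}\t"
                f"{r.pvalue:.6g}\t{r.qvalue:.6g}\t{r.sign}\n"
            )


def read_de_table(path: str | Path):
    """Read a DE TSV written by :func:`write_de_table` back into records."""
    from .diffexpr import DERecord

    df = pd.read_csv(path, sep="\t")
    return [
        DERecord(
            gene_id=str(r.gene_id), mean_cpm=r.mean_cpm, log2fc=r.log2fc,
            pvalue=r.pvalue, qvalue=r.qvalue, sign=r.sign,
        )
        for r in df.itertuples()
    ]


def write_truth_json(truth, path: str | Path) -> None:
    """Serialise simulation ground truth for recovery evaluation."""
    payload = {
        "gene_ids": truth.gene_ids,
        "true_operons": truth.true_operons,
        "true_de": truth.true_de,
        "true_tss": [
            {"position": p, "strand": s, "leader_gene": g}
            for p, s, g in truth.true_tss
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth_json(path: str | Path):
    from .simulate import GroundTruth

    with open(path) as fh:
        d = json.load(fh)
    return GroundTruth(
        gene_ids=d["gene_ids"],
        true_operons=[list(op) for op in d["true_operons"]],
        true_de={g: float(v) for g, v in d["true_de"].items()},
        true_tss=[
            (t["position"], t["strand"], t["leader_gene"]) for t in d["true_tss"]
        ],
    )
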