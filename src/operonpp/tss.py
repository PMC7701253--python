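"""Single-nucleotide TSS calling from 5'-end coverage, and operon validation.

In a 5'-enriched (dRNA-seq-like) library the first transcribed base of each
transcript produces a sharp pileup of read 5' ends.  A position is called a
candidate TSS when its 5'-end count clears an absolute floor AND a local
enrichment factor over the surrounding background; nearby candidates
(sequencing jitter spreads a true TSS over a few nt) are merged, keeping
the strongest position.

Called TSSs are classified against the annotation (primary / internal /
antisense / orphan) and primary TSSs are used to validate predicted
operons: a genuine operon is transcribed from a single promoter at its
leader gene, so it should carry a primary TSS there and none at internal
members.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import GeneFeature, StrandCoverage
from .phyloprofile import OperonPrediction

DEFAULT_MIN_COUNT = 10
DEFAULT_ENRICHMENT = 5.0
DEFAULT_BG_WINDOW = 100
DEFAULT_CLUSTER_WIDTH = 5
DEFAULT_UPSTREAM_WINDOW = 300
DEFAULT_DOWNSTREAM_LEEWAY = 50
BACKGROUND_FLOOR = 0.1  # avoids division by zero in empty neighbourhoods


@dataclass
class TSSRecord:
    contig: str
    position: int  # 1-based
    strand: str
    read_count: int
    enrichment: float
    tss_class: str = "unclassified"  # primary | internal | antisense | orphan
    assigned_gene: str | None = None


def _local_background(
    values: np.ndarray, idx: int, bg_window: int, exclude: int = 2
) -> float:
    """Mean coverage within +/- bg_window of idx, excluding +/- exclude nt."""
    lo = max(0, idx - bg_window)
    hi = min(len(values), idx + bg_window + 1)
    window = values[lo:hi].astype(float)
    elo = max(0, idx - exclude - lo)
    ehi = min(len(window), idx + exclude + 1 - lo)
    mask = np.ones(len(window), dtype=bool)
    mask[elo:ehi] = False
    if not mask.any():
        return BACKGROUND_FLOOR
    return max(float(window[mask].mean()), BACKGROUND_FLOOR)


def call_tss(
    coverage: StrandCoverage,
    min_count: int = DEFAULT_MIN_COUNT,
    enrichment_factor: float = DEFAULT_ENRICHMENT,
    bg_window: int = DEFAULT_BG_WINDOW,
    cluster_width: int = DEFAULT_CLUSTER_WIDTH,
) -> list[TSSRecord]:
    """Call TSS positions from one strand's 5'-end coverage.

    Candidates must satisfy value >= min_count and value >=
    enrichment_factor x local background (background floored at 0.1).
    Candidates within ``cluster_width`` nt of each other merge into one
    record at the position of maximal count (ties resolve to the smallest
    coordinate).
    """
    v = coverage.values
    candidates = []
    for idx in np.flatnonzero(v >= min_count):
        bg = _local_background(v, int(idx), bg_window)
        if v[idx] >= enrichment_factor * bg:
            candidates.append((int(idx), int(v[idx]), v[idx] / bg))
    records: list[TSSRecord] = []
    cluster: list[tuple[int, int, float]] = []

    def flush() -> None:
        if not cluster:
            return
        best = max(cluster, key=lambda c: (c[1], -c[0]))
        records.append(
            TSSRecord(
                contig=coverage.contig,
                position=best[0] + 1,
                strand=coverage.strand,
                read_count=best[1],
                enrichment=float(best[2]),
            )
        )

    for cand in candidates:
        if cluster and cand[0] - cluster[-1][0] > cluster_width:
            flush()
            cluster = []
        cluster.append(cand)
    flush()
    return records


def classify_tss(
    tss_list: list[TSSRecord],
    genes: list[GeneFeature],
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
    downstream_leeway: int = DEFAULT_DOWNSTREAM_LEEWAY,
) -> list[TSSRecord]:
    """Label each TSS as primary, internal, antisense or orphan.

    The gene "start" is strand-aware (transcription direction): the GFF3
    start for + genes, the GFF3 end for - genes, with the upstream window
    extending to larger coordinates on the - strand.  A TSS eligible as
    primary for several genes is assigned to the nearest start.
    """
    out = []
    for t in tss_list:
        primary_hits: list[tuple[int, str]] = []
        internal_hit = None
        antisense_hit = None
        for g in genes:
            if g.contig != t.contig:
                continue
            inside = g.start <= t.position <= g.end
            if g.strand == t.strand:
                s = g.tx_start
                if g.strand == "+":
                    in_window = s - upstream_window <= t.position <= s + downstream_leeway
                else:
                    in_window = s - downstream_leeway <= t.position <= s + upstream_window
                if in_window:
                    primary_hits.append((abs(t.position - s), g.gene_id))
                elif inside:
                    internal_hit = g.gene_id
            elif inside:
                antisense_hit = g.gene_id
        if primary_hits:
            _, gene_id = min(primary_hits)
            out.append(replace(t, tss_class="primary", assigned_gene=gene_id))
        elif internal_hit is not None:
            out.append(replace(t, tss_class="internal", assigned_gene=internal_hit))
        elif antisense_hit is not None:
            out.append(replace(t, tss_class="antisense", assigned_gene=antisense_hit))
        else:
            out.append(replace(t, tss_class="orphan", assigned_gene=None))
    return out


@dataclass
class ValidationReport:
    n_operons: int
    n_validated: int
    n_tss_in_operons: int  # primary TSSs assigned to any operon member
    rows: list[dict]


def validate_operons(
    operons: list[OperonPrediction],
    tss_list: list[TSSRecord],
    leader_only: bool = False,
) -> tuple[list[OperonPrediction], ValidationReport]:
    """Set ``tss_validated`` on each operon from classified TSSs.

    An operon validates when at least one primary TSS is assigned to its
    leader gene (5'-most in transcription direction) and — unless
    ``leader_only`` — no primary TSS is assigned to a downstream member.
    """
    primary = [t for t in tss_list if t.tss_class == "primary"]
    by_gene: dict[str, list[int]] = {}
    for t in primary:
        by_gene.setdefault(t.assigned_gene, []).append(t.position)
    validated: list[OperonPrediction] = []
    rows = []
    n_tss_in_operons = 0
    for op in operons:
        leader = op.gene_ids[0] if op.strand == "+" else op.gene_ids[-1]
        downstream = [g for g in op.gene_ids if g != leader]
        leader_tss = sorted(by_gene.get(leader, []))
        violating = sorted(
            pos for g in downstream for pos in by_gene.get(g, [])
        )
        ok = bool(leader_tss) and (leader_only or not violating)
        validated.append(
            replace(op, tss_validated=ok, leader_tss=leader_tss,
                    violating_tss=violating)
        )
        n_tss_in_operons += len(leader_tss) + len(violating)
        rows.append(
            {
                "operon_id": op.operon_id,
                "leader_gene": leader,
                "leader_tss": leader_tss,
                "violating_tss": violating,
                "validated": ok,
            }
        )
    report = ValidationReport(
        n_operons=len(operons),
        n_validated=sum(op.tss_validated for op in validated),
        n_tss_in_operons=n_tss_in_operons,
        rows=rows,
    )
    return validated, report


def tss_recovery(
    called: list[TSSRecord],
    true_tss: list[tuple[int, str, str]],
    tolerance: int = 2,
) -> tuple[float, float]:
    """Precision and recall of called TSSs against truth, within a tolerance.

    Each true TSS may be matched by at most one call and vice versa;
    matching is greedy by distance.
    """
    matched_true: set[int] = set()
    matched_call: set[int] = set()
    pairs = sorted(
        (abs(c.position - pos), i, j)
        for j, c in enumerate(called)
        for i, (pos, strand, _g) in enumerate(true_tss)
        if strand == c.strand and abs(c.position - pos) <= tolerance
    )
    for _d, i, j in pairs:
        if i not in matched_true and j not in matched_call:
            matched_true.add(i)
            matched_call.add(j)
    precision = len(matched_call) / len(called) if called else 1.0
    recall = len(matched_true) / len(true_tss) if true_tss else 1.0
    return precision, recall
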