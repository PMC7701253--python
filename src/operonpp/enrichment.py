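"""Functional-category tabulation and hypergeometric over-representation.

DEGs are tabulated per COG letter or KEGG pathway within the analyzed
universe (the genes passing the expression filter).  Each category gets
up/down counts, a signed delta = n_up - n_down, and a one-sided
hypergeometric over-representation p-value with BH correction across
categories.  Counts render in the conventional "k/n" form (DEGs over
category genes).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

from .diffexpr import DERecord, bh_adjust
from .io import CategoryMap


@dataclass
class EnrichmentRecord:
    category_id: str
    n_category: int  # category genes in the analyzed universe
    n_up: int
    n_down: int
    delta: int  # n_up - n_down
    p_over: float
    qvalue: float

    @property
    def ratio_label(self) -> str:
        """Conventional 'DEGs/category size' rendering, e.g. '4/7'."""
        return f"{self.n_up + self.n_down}/{self.n_category}"


def tabulate_categories(
    de_records: list[DERecord],
    category_map: CategoryMap,
    universe: set[str],
) -> dict[str, tuple[int, int, int, int]]:
    """Per-category (n_category, n_up, n_down, delta), universe-restricted.

    Genes carrying several categories count in each; category genes absent
    from the universe are ignored.
    """
    sign_of = {r.gene_id: r.sign for r in de_records}
    table: dict[str, tuple[int, int, int, int]] = {}
    for cat in category_map.category_ids:
        members = category_map.genes_of(cat) & universe
        n_up = sum(1 for g in members if sign_of.get(g) == "up")
        n_down = sum(1 for g in members if sign_of.get(g) == "down")
        table[cat] = (len(members), n_up, n_down, n_up - n_down)
    return table


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k].

    X counts category genes among n draws without replacement from a
    universe of N genes containing K category genes.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent arguments N={N}, K={K}, n={n}, k={k}")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    de_records: list[DERecord],
    category_map: CategoryMap,
    universe: set[str],
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Over-representation of DEGs per category, BH-corrected, delta-sorted."""
    if not universe:
        raise ValueError("empty gene universe")
    table = tabulate_categories(de_records, category_map, universe)
    n_deg = sum(
        1 for r in de_records
        if r.sign in ("up", "down") and r.gene_id in universe
    )
    pvals = {}
    for cat, (n_cat, n_up, n_down, _delta) in table.items():
        k = min(n_up + n_down, n_cat, n_deg)
        pvals[cat] = hypergeom_upper(len(universe), n_cat, n_deg, k)
    qvals = bh_adjust(pvals)
    records = [
        EnrichmentRecord(
            category_id=cat, n_category=n_cat, n_up=n_up, n_down=n_down,
            delta=delta, p_over=pvals[cat], qvalue=qvals[cat],
        )
        for cat, (n_cat, n_up, n_down, delta) in table.items()
    ]
    records.sort(key=lambda r: (-r.delta, r.category_id))
    return records


def write_enrichment_table(records: list[EnrichmentRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "category_id\tn_category\tn_up\tn_down\tdelta\tratio\t"
            "p_over\tqvalue\n"
        )
        for r in records:
            fh.write(
                f"{r.category_id}\t{r.n_category}\t{r.n_up}\t{r.n_down}\t"
                f"{r.delta}\t{r.ratio_label}\t{r.p_over:.6g}\t{r.qvalue:.6g}\n"
            )
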