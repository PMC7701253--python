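"""End-to-end orchestration: counts -> DEGs -> operons -> TSS -> enrichment."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import diffexpr, enrichment, io as opio, phyloprofile, tss
from .io import CategoryMap, CountMatrix, GeneFeature, ProfileMatrix, StrandCoverage


@dataclass
class Thresholds:
    """Every tunable cutoff of the pipeline, with the defaults documented
    on each stage; loadable from a TOML table of the same key names."""

    alpha: float = diffexpr.DEFAULT_ALPHA
    fc_cut: float = diffexpr.DEFAULT_FC_CUT
    cpm_min: float = diffexpr.DEFAULT_CPM_MIN
    pseudocount: float = diffexpr.DEFAULT_PSEUDOCOUNT
    use_qvalue: bool = True
    max_distance: float = phyloprofile.DEFAULT_MAX_DISTANCE
    max_span_nt: int = phyloprofile.DEFAULT_MAX_SPAN_NT
    require_sign: bool = True
    skip_ineligible: bool = False
    min_count: int = tss.DEFAULT_MIN_COUNT
    enrichment_factor: float = tss.DEFAULT_ENRICHMENT
    bg_window: int = tss.DEFAULT_BG_WINDOW
    cluster_width: int = tss.DEFAULT_CLUSTER_WIDTH
    upstream_window: int = tss.DEFAULT_UPSTREAM_WINDOW
    downstream_leeway: int = tss.DEFAULT_DOWNSTREAM_LEEWAY
    leader_only: bool = False

    @classmethod
    def from_toml(cls, path: str | Path) -> "Thresholds":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


@dataclass
class PipelineResult:
    de_records: list[diffexpr.DERecord]
    universe: set[str]
    gene_profiles: ProfileMatrix
    operons: list[phyloprofile.OperonPrediction]
    tss_records: list[tss.TSSRecord]
    validation: tss.ValidationReport
    enrichment: list[enrichment.EnrichmentRecord] = field(default_factory=list)


def run_pipeline(
    features: list[GeneFeature],
    counts: CountMatrix,
    og_profiles: ProfileMatrix,
    gene_to_og: dict[str, str],
    coverage_plus: StrandCoverage,
    coverage_minus: StrandCoverage,
    categories: CategoryMap | None = None,
    thresholds: Thresholds | None = None,
    treated: str = "treated",
    control: str = "control",
) -> PipelineResult:
    """Run every analysis stage on in-memory domain objects."""
    th = thresholds or Thresholds()
    de_records = diffexpr.run_differential_expression(
        counts, treated=treated, control=control, alpha=th.alpha,
        fc_cut=th.fc_cut, cpm_min=th.cpm_min, pseudocount=th.pseudocount,
        use_qvalue=th.use_qvalue,
    )
    universe = {r.gene_id for r in de_records}
    gene_profiles = phyloprofile.build_gene_profiles(
        og_profiles, gene_to_og, features
    )
    operons = phyloprofile.predict_operons(
        features, gene_profiles, de_records, max_distance=th.max_distance,
        max_span_nt=th.max_span_nt, require_sign=th.require_sign,
        skip_ineligible=th.skip_ineligible,
    )
    tss_records: list[tss.TSSRecord] = []
    for cov in (coverage_plus, coverage_minus):
        tss_records.extend(
            tss.call_tss(
                cov, min_count=th.min_count,
                enrichment_factor=th.enrichment_factor,
                bg_window=th.bg_window, cluster_width=th.cluster_width,
            )
        )
    tss_records = tss.classify_tss(
        tss_records, features, upstream_window=th.upstream_window,
        downstream_leeway=th.downstream_leeway,
    )
    operons, validation = tss.validate_operons(
        operons, tss_records, leader_only=th.leader_only
    )
    enr: list[enrichment.EnrichmentRecord] = []
    if categories is not None and universe:
        enr = enrichment.enrich(de_records, categories, universe, alpha=th.alpha)
    return PipelineResult(
        de_records=de_records, universe=universe, gene_profiles=gene_profiles,
        operons=operons, tss_records=tss_records, validation=validation,
        enrichment=enr,
    )


def write_pipeline_outputs(result: PipelineResult, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = opio.write_results(
        result.operons, result.tss_records, result.de_records, out
    )
    if result.enrichment:
        paths["enrichment"] = out / "enrichment.tsv"
        enrichment.write_enrichment_table(result.enrichment, paths["enrichment"])
    return paths
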