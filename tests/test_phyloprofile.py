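import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from operonpp.diffexpr import DERecord
from operonpp.io import GeneFeature, ProfileMatrix
from operonpp.phyloprofile import (
    audit_operons,
    build_gene_profiles,
    jaccard_distance,
    operon_recovery,
    pairwise_distances,
    predict_operons,
)


def _profiles(rows, row_ids=None, genome_ids=None):
    rows = np.asarray(rows, dtype=np.uint8)
    return ProfileMatrix(
        row_ids=row_ids or [f"r{i}" for i in range(rows.shape[0])],
        genome_ids=genome_ids or [f"G{j}" for j in range(rows.shape[1])],
        bits=rows,
    )


def _gene(gid, start, end, strand="+"):
    return GeneFeature(gid, "contig1", start, end, strand)


def _de(gid, sign, lfc=2.0):
    return DERecord(gid, 100.0, lfc if sign == "up" else -lfc, 1e-6, 1e-5, sign)


class TestJaccardDistance:
    def test_identical_nonzero_vectors(self):
        u = np.array([1, 0, 1, 1])
        assert jaccard_distance(u, u) == 0.0

    def test_disjoint_nonzero_vectors(self):
        assert jaccard_distance([1, 1, 0, 0], [0, 0, 1, 1]) == 1.0

    def test_set_enumeration_example(self):
        # intersection {1,2}, union {0,1,2,3}: d = 1 - 2/4
        assert jaccard_distance([1, 1, 1, 0], [0, 1, 1, 1]) == pytest.approx(0.5)

    def test_all_zero_pair_defined_as_zero(self):
        assert jaccard_distance([0, 0, 0], [0, 0, 0]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            jaccard_distance([1, 0], [1, 0, 1])

    @settings(deadline=None, max_examples=400)
    @given(
        st.integers(min_value=1, max_value=30).flatmap(
            lambda n: st.tuples(
                *[st.lists(st.integers(0, 1), min_size=n, max_size=n)] * 3
            )
        )
    )
    def test_metric_axioms(self, uvw):
        u, v, w = (np.array(x) for x in uvw)
        duv = jaccard_distance(u, v)
        assert jaccard_distance(u, u) == 0.0
        assert duv == jaccard_distance(v, u)
        assert 0.0 <= duv <= 1.0
        assert duv <= jaccard_distance(u, w) + jaccard_distance(w, v) + 1e-12


class TestPairwiseDistances:
    def test_identical_rows_give_zero_matrix(self):
        prof = _profiles([[1, 0, 1]] * 3)
        assert (pairwise_distances(prof) == 0).all()

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(2)
        prof = _profiles(rng.integers(0, 2, size=(12, 9)))
        d = pairwise_distances(prof)
        for i in range(12):
            for j in range(12):
                assert d[i, j] == pytest.approx(
                    jaccard_distance(prof.bits[i], prof.bits[j]), abs=1e-12
                )

    def test_hand_enumerated_three_rows(self):
        prof = _profiles([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]])
        d = pairwise_distances(prof)
        assert d[0, 1] == 0.0
        assert d[0, 2] == 1.0 and d[1, 2] == 1.0
        assert (d == d.T).all() and (np.diag(d) == 0).all()


class TestBuildGeneProfiles:
    def test_gene_inherits_orthogroup_row(self):
        og = _profiles([[1, 1, 0]], row_ids=["OG1"])
        genes = [_gene("a", 100, 200)]
        gp = build_gene_profiles(og, {"a": "OG1"}, genes)
        assert gp.bits.tolist() == [[1, 1, 0]]
        assert gp.flagged == set()

    def test_unmapped_gene_gets_flagged_singleton(self):
        og = _profiles([[1, 1, 0]], row_ids=["OG1"])
        genes = [_gene("orphan", 100, 200)]
        gp = build_gene_profiles(og, {}, genes)
        assert gp.bits.tolist() == [[1, 0, 0]]
        assert gp.flagged == {"orphan"}

    def test_same_orthogroup_genes_share_rows(self):
        og = _profiles([[1, 0, 1]], row_ids=["OG1"])
        genes = [_gene("a", 100, 200), _gene("b", 300, 400)]
        gp = build_gene_profiles(og, {"a": "OG1", "b": "OG1"}, genes)
        assert (gp.bits[0] == gp.bits[1]).all()


class TestPredictOperons:
    def _setup(self, strand_b="+", sign_b="up", profile_b=None, start_b=400):
        genes = [_gene("a", 200, 350), _gene("b", start_b, start_b + 150, strand_b)]
        rows = [[1, 1, 0, 1], profile_b or [1, 1, 0, 1]]
        gp = _profiles(rows, row_ids=["a", "b"])
        de = [_de("a", "up"), _de("b", sign_b)]
        return genes, gp, de

    def test_all_criteria_met_links_pair(self):
        genes, gp, de = self._setup()
        ops = predict_operons(genes, gp, de)
        assert len(ops) == 1 and ops[0].gene_ids == ["a", "b"]
        assert ops[0].de_sign == "up"
        assert ops[0].span == (200, 550)

    def test_opposite_strand_breaks_link(self):
        genes, gp, de = self._setup(strand_b="-")
        assert predict_operons(genes, gp, de) == []

    def test_opposite_sign_breaks_link(self):
        genes, gp, de = self._setup(sign_b="down")
        assert predict_operons(genes, gp, de) == []

    def test_span_cutoff_breaks_link(self):
        genes, gp, de = self._setup(start_b=10_300)
        assert predict_operons(genes, gp, de) == []

    def test_single_genome_difference_on_130_panel_not_linked(self):
        """One differing genome gives d >= 1/130 > 0.001."""
        row_a = [1] * 130
        row_b = [1] * 129 + [0]
        genes = [_gene("a", 200, 350), _gene("b", 400, 550)]
        gp = _profiles([row_a, row_b], row_ids=["a", "b"])
        de = [_de("a", "up"), _de("b", "up")]
        assert predict_operons(genes, gp, de) == []
        d = jaccard_distance(row_a, row_b)
        assert d == pytest.approx(1 / 130) and d > 0.001

    def test_intervening_ineligible_gene_breaks_chain_by_default(self):
        genes = [
            _gene("a", 200, 350), _gene("m", 400, 550), _gene("b", 600, 750)
        ]
        gp = _profiles([[1, 1]] * 3, row_ids=["a", "m", "b"])
        de = [_de("a", "up"), DERecord("m", 5.0, 0.0, 0.9, 0.9, "ns"), _de("b", "up")]
        assert predict_operons(genes, gp, de) == []
        skip = predict_operons(genes, gp, de, skip_ineligible=True)
        assert [op.gene_ids for op in skip] == [["a", "b"]]

    def test_unsorted_input_is_sorted_with_warning(self, caplog):
        genes, gp, de = self._setup()
        with caplog.at_level("WARNING"):
            ops = predict_operons(list(reversed(genes)), gp, de)
        assert ops and ops[0].gene_ids == ["a", "b"]
        assert any("not sorted" in r.message for r in caplog.records)


class TestOnSimulatedPanel:
    def test_threshold_equals_exact_equality_on_default_panel(
        self, default_dataset, default_result
    ):
        """d < 0.001 iff identical vectors on a 130-genome panel, so operon
        calls are unchanged when the threshold is replaced by equality."""
        prof = default_dataset.profiles
        d = pairwise_distances(prof)
        close = d < 0.001
        for i in np.argwhere(close.sum(axis=1) > 1)[:, 0]:
            for j in np.flatnonzero(close[i]):
                assert (prof.bits[i] == prof.bits[j]).all()
        ops_exact = predict_operons(
            default_dataset.features, default_result.gene_profiles,
            default_result.de_records, max_distance=1e-12,
        )
        assert [o.gene_ids for o in default_result.operons] == [
            o.gene_ids for o in ops_exact
        ]

    def test_noise_free_recovery_is_exact(self, default_dataset, default_result):
        precision, recall = operon_recovery(
            default_result.operons, default_dataset.truth.true_operons,
            default_result.de_records,
        )
        assert precision == 1.0 and recall == 1.0

    def test_predictions_pass_posthoc_audit(self, default_dataset, default_result):
        problems = audit_operons(
            default_result.operons, default_dataset.features,
            default_result.gene_profiles, default_result.de_records,
        )
        assert problems == []

    def test_recall_non_increasing_in_profile_noise(self):
        from operonpp.pipeline import run_pipeline
        from operonpp.simulate import SimConfig, simulate_dataset

        mean_recall = []
        for eps in (0.0, 0.005, 0.02, 0.05):
            recalls = []
            for seed in range(10):
                ds = simulate_dataset(SimConfig(seed=seed, profile_noise=eps))
                res = run_pipeline(
                    ds.features, ds.counts, ds.og_profiles, ds.gene_to_og,
                    ds.coverage_plus, ds.coverage_minus,
                )
                _p, r = operon_recovery(
                    res.operons, ds.truth.true_operons, res.de_records
                )
                recalls.append(r)
            mean_recall.append(np.mean(recalls))
        assert all(a >= b for a, b in zip(mean_recall, mean_recall[1:]))
        assert mean_recall[0] == 1.0
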