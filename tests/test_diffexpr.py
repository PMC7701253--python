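import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from operonpp.diffexpr import (
    DERecord,
    bh_adjust,
    call_degs,
    compute_cpm,
    exact_count_test,
    filter_expressed,
    log2_fold_change,
    run_differential_expression,
)
from operonpp.io import CountMatrix
from operonpp.simulate import GroundTruth, SimConfig, simulate_counts


def _matrix(counts, conditions=("control", "control", "treated", "treated")):
    counts = np.asarray(counts)
    samples = [f"s{j}" for j in range(counts.shape[1])]
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(counts.shape[0])],
        sample_ids=samples,
        counts=counts,
        condition_of=dict(zip(samples, conditions)),
    )


def bh_oracle(p):
    """Direct evaluation of q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    q_sorted = [
        min(1.0, min(ps[j] * m / (j + 1) for j in range(i, m)))
        for i in range(m)
    ]
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestCpm:
    def test_count_over_libsize_times_million(self):
        cm = _matrix([[10, 10], [990, 990]], conditions=("control", "treated"))
        cpm = compute_cpm(cm)
        assert cpm[0, 0] == pytest.approx(10_000)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        cm = _matrix(rng.integers(0, 500, size=(30, 4)))
        cpm = compute_cpm(cm)
        assert cpm.sum(axis=0) == pytest.approx([1e6] * 4, rel=1e-9)

    def test_all_zero_gene_stays_zero(self):
        cm = _matrix([[0, 0, 0, 0], [5, 5, 5, 5]])
        assert (compute_cpm(cm)[0] == 0).all()

    def test_zero_library_size_names_sample(self):
        cm = _matrix([[0, 1, 1, 1]])
        with pytest.raises(ValueError, match="s0"):
            compute_cpm(cm)


class TestFilterExpressed:
    @pytest.mark.parametrize(
        "cpm_row, threshold, kept",
        [
            ((2, 2, 0, 0), 1.0, True),  # mean exactly at the threshold
            ((0, 0, 0, 0), 1.0, False),
            ((0, 0, 0, 0), 0.0, True),
        ],
    )
    def test_mean_cpm_rule(self, cpm_row, threshold, kept):
        cpm = np.array([cpm_row], dtype=float)
        retained = filter_expressed(cpm, ["g0"], threshold)
        assert ("g0" in retained) is kept


class TestLog2FoldChange:
    def test_ratio_of_means(self):
        cm = _matrix([[10, 10, 40, 40]])
        cpm = np.array([[10.0, 10.0, 40.0, 40.0]])
        lfc = log2_fold_change(cpm, cm, "treated", "control", pseudocount=0)
        assert lfc["g0"] == pytest.approx(2.0)

    def test_identical_means_give_zero(self):
        cm = _matrix([[7, 7, 7, 7]])
        cpm = np.full((1, 4), 7.0)
        assert log2_fold_change(cpm, cm, "treated", "control")["g0"] == 0.0

    def test_antisymmetric_under_condition_swap(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 200, size=(20, 4))
        cm = _matrix(counts)
        cpm = compute_cpm(cm)
        fwd = log2_fold_change(cpm, cm, "treated", "control")
        rev = log2_fold_change(cpm, cm, "control", "treated")
        for g in fwd:
            assert fwd[g] == pytest.approx(-rev[g])


class TestExactCountTest:
    def test_all_zero_gene_has_p_one(self):
        cm = _matrix([[0, 0, 0, 0], [10, 10, 10, 10]])
        assert exact_count_test(cm, "treated", "control")["g0"] == 1.0

    def test_one_sided_extreme_closed_form(self):
        # equal pooled library sizes; one gene with all 10 counts treated:
        # p = 2 * (1/2)^10
        counts = np.array([[0, 0, 5, 5], [500, 500, 495, 495]])
        cm = _matrix(counts)
        p = exact_count_test(cm, "treated", "control")["g0"]
        assert p == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_symmetric_center_capped_at_one(self):
        counts = np.array([[5, 0, 5, 0], [500, 500, 500, 500]])
        cm = _matrix(counts)
        assert exact_count_test(cm, "treated", "control")["g0"] == 1.0

    def test_null_calibration_poisson(self):
        """Poisson null, 2000 genes, 3 vs 3: p < 0.05 near nominal rate."""
        gene_ids = [f"g{i:05d}" for i in range(2000)]
        truth = GroundTruth(
            gene_ids=gene_ids, true_operons=[],
            true_de={g: 0.0 for g in gene_ids},
        )
        cfg = SimConfig(n_genes=2000, nb_dispersion=0.0, seed=11)
        cm = simulate_counts(truth, cfg)
        p = np.array(list(exact_count_test(cm, "treated", "control").values()))
        assert 0.035 <= (p < 0.05).mean() <= 0.065


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        q = bh_adjust({"a": 0.01, "b": 0.02, "c": 0.03})
        assert [q["a"], q["b"], q["c"]] == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust({"a": 0.2})["a"] == pytest.approx(0.2)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust({"a": 1.5})

    @settings(deadline=None, max_examples=100)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_matches_min_over_suffix_oracle(self, pvals):
        q = bh_adjust({f"g{i}": p for i, p in enumerate(pvals)})
        expected = bh_oracle(np.array(pvals))
        got = np.array([q[f"g{i}"] for i in range(len(pvals))])
        assert got == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=40)
    )
    def test_monotone_in_p(self, pvals):
        q = bh_adjust({f"g{i}": p for i, p in enumerate(pvals)})
        pairs = sorted(zip(pvals, [q[f"g{i}"] for i in range(len(pvals))]))
        qs = [b for _a, b in pairs]
        assert all(x <= y + 1e-12 for x, y in zip(qs, qs[1:]))


class TestCallDegs:
    def _rec(self, lfc, q):
        return DERecord("g", 10.0, lfc, q, q)

    @pytest.mark.parametrize(
        "lfc, q, sign",
        [
            (3.0, 0.01, "up"),
            (-3.0, 0.01, "down"),
            (0.5, 0.04, "ns"),   # below the fold-change cut
            (3.0, 0.051, "ns"),  # above alpha
        ],
    )
    def test_sign_labels(self, lfc, q, sign):
        assert call_degs([self._rec(lfc, q)])[0].sign == sign

    def test_published_table_fold_change_filter(self, fold_change_table_path):
        """All 25 genes in the shipped table pass |log2FC| >= 2: 16 up, 9 down."""
        from operonpp.io import read_fold_change_table

        df = read_fold_change_table(fold_change_table_path)
        retained = df[df["log2fc"].abs() >= 2]
        assert len(retained) == 25
        assert (retained["log2fc"] > 0).sum() == 16
        assert (retained["log2fc"] < 0).sum() == 9


class TestPower:
    def test_planted_effects_recovered_with_correct_sign(self):
        """Genes with a planted 4-fold effect and >= 100 mean counts are
        recovered with the right sign in >= 95% of cases."""
        rng = np.random.default_rng(100)
        cfg = SimConfig(n_genes=1000, seed=0)
        gids = [f"g{i}" for i in range(1000)]
        lfc = {
            g: (float(rng.choice([2.0, -2.0])) if rng.random() < 0.1 else 0.0)
            for g in gids
        }
        truth = GroundTruth(gene_ids=gids, true_operons=[], true_de=lfc)
        cm = simulate_counts(truth, cfg)
        control_mean = dict(zip(gids, cm.counts[:, :3].mean(axis=1)))
        recs = {r.gene_id: r for r in run_differential_expression(cm)}
        planted = [g for g in gids if lfc[g] != 0 and control_mean[g] >= 100]
        correct = sum(
            1 for g in planted
            if g in recs and recs[g].sign == ("up" if lfc[g] > 0 else "down")
        )
        assert correct / len(planted) >= 0.95

    def test_qvalue_never_below_pvalue(self, default_result):
        for r in default_result.de_records:
            assert r.qvalue >= r.pvalue - 1e-12
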