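import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from avmpanel.differential import (
    annotation_enrichment,
    anova_by_tissue,
    atrial_ventricular_test,
    bh_adjust,
    direction_summary,
    enrichment_table,
    variance_filter,
)
from conftest import make_annotation, make_dataset


def brute_force_bh(p):
    """Literal step-up definition: q(i) = min_{j>=i} p(j)*m/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        q[idx] = min(
            min(p[order[j - 1]] * m / j for j in range(rank_i, m + 1)), 1.0
        )
    return q


class TestVarianceFilter:
    def test_ratios_and_threshold_hand_example(self):
        # per-probe sigma 0.10, 0.20, 0.05 -> ratios 0.5, 1.0, 0.25
        base = np.array([-1.0, 1.0]) / np.sqrt(2)  # sd exactly 1 (ddof=1)
        beta = {
            "s1": 0.5 + np.array([0.10, 0.20, 0.05]) * base[0],
            "s2": 0.5 + np.array([0.10, 0.20, 0.05]) * base[1],
        }
        ds = make_dataset(beta, ["a", "b", "c"])
        kept, ratio = variance_filter(ds, threshold=0.4)
        assert list(kept) == ["a", "b"]
        assert ratio.round(6).tolist() == [0.5, 1.0, 0.25]

    def test_constant_probe_always_excluded(self):
        ds = make_dataset({"s1": [0.5, 0.1], "s2": [0.5, 0.9]}, ["const", "var"])
        kept, _ = variance_filter(ds, threshold=0.0)
        assert list(kept) == ["var"]

    def test_single_varying_probe_is_its_own_maximum(self):
        ds = make_dataset({"s1": [0.1], "s2": [0.9]}, ["p"])
        kept, ratio = variance_filter(ds, threshold=0.4)
        assert list(kept) == ["p"] and ratio["p"] == 1.0

    def test_all_constant_is_an_error(self):
        ds = make_dataset({"s1": [0.5], "s2": [0.5]}, ["p"])
        with pytest.raises(ValueError, match="no variance"):
            variance_filter(ds)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.04], [0.03, 0.03, 0.04]),
            ([0.5], [0.5]),
            ([1e-8, 0.9], [2e-8, 0.9]),
        ],
    )
    def test_step_up_hand_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60)
    )
    def test_matches_brute_force_step_up(self, p):
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), rtol=1e-12)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=40)
    )
    def test_q_monotone_in_p(self, p):
        q = bh_adjust(p)
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= np.asarray(p) - 1e-15).all()


def _tissue_dataset(groups: dict[str, list[list[float]]]):
    """groups: tissue -> per-sample beta columns."""
    beta, tissues = {}, {}
    i = 0
    for tissue, cols in groups.items():
        for col in cols:
            sid = f"s{i}"
            beta[sid] = col
            tissues[sid] = tissue
            i += 1
    n = len(next(iter(beta.values())))
    return make_dataset(beta, [f"p{k}" for k in range(n)], tissues=tissues)


class TestAnova:
    def test_hand_decomposition_f_16(self):
        ds = _tissue_dataset(
            {"IAS": [[0.1], [0.2]], "LA": [[0.3], [0.4]], "LV": [[0.5], [0.6]]}
        )
        res = anova_by_tissue(ds)
        assert res.loc["p0", "F"] == pytest.approx(16.0)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(3)
        ds = _tissue_dataset(
            {
                "IAS": [list(rng.random(5)) for _ in range(4)],
                "LA": [list(rng.random(5)) for _ in range(3)],
                "LV": [list(rng.random(5)) for _ in range(3)],
            }
        )
        from scipy.stats import f_oneway

        res = anova_by_tissue(ds)
        tissues = ds.samples.set_index("sample_id")["tissue"]
        for probe in ds.probe_ids:
            args = [
                ds.beta.loc[probe, tissues.index[tissues == t]].to_numpy()
                for t in tissues.unique()
            ]
            F, p = f_oneway(*args)
            assert res.loc[probe, "F"] == pytest.approx(F)
            assert res.loc[probe, "p"] == pytest.approx(p)

    def test_degenerate_all_equal_gives_f0_p1(self):
        ds = _tissue_dataset(
            {t: [[0.4], [0.4]] for t in ["IAS", "LA", "RA", "LV", "RV"]}
        )
        res = anova_by_tissue(ds)
        assert res.loc["p0", "F"] == 0.0 and res.loc["p0", "p"] == 1.0

    def test_degenerate_separated_groups_give_p0(self):
        ds = _tissue_dataset({"IAS": [[0.2], [0.2]], "LV": [[0.8], [0.8]]})
        res = anova_by_tissue(ds)
        assert res.loc["p0", "p"] == 0.0 and np.isinf(res.loc["p0", "F"])


class TestAtrialVentricularTest:
    def _two_group(self, atrial, ventricular):
        groups = {"IAS": [[v] for v in atrial], "LV": [[v] for v in ventricular]}
        return _tissue_dataset(groups)

    def test_student_hand_computation(self):
        ds = self._two_group([0.8, 0.9], [0.2, 0.3])
        res = atrial_ventricular_test(ds, method="student")
        row = res.loc["p0"]
        assert row["delta_beta_signed"] == pytest.approx(0.6)
        assert row["direction"] == "atrial_hyper"
        assert row["statistic"] == pytest.approx(8.485, abs=5e-4)

    def test_identical_groups_give_t0_p1_direction_none(self):
        ds = self._two_group([0.5, 0.5], [0.5, 0.5])
        row = atrial_ventricular_test(ds).loc["p0"]
        assert row["statistic"] == 0.0 and row["p"] == 1.0
        assert row["delta_beta_signed"] == 0.0 and row["direction"] == "none"

    def test_zero_variance_distinct_means_p0(self):
        ds = self._two_group([0.9, 0.9], [0.1, 0.1])
        row = atrial_ventricular_test(ds).loc["p0"]
        assert row["p"] == 0.0
        assert row["delta_beta_signed"] == pytest.approx(0.8)
        assert bool(row["significant"])

    def test_student_equals_welch_for_balanced_equal_variance(self):
        ds = self._two_group([0.2, 0.4, 0.6], [0.5, 0.7, 0.9])
        s = atrial_ventricular_test(ds, method="student").loc["p0"]
        w = atrial_ventricular_test(ds, method="welch").loc["p0"]
        assert s["statistic"] == pytest.approx(w["statistic"], rel=1e-12)
        assert s["p"] == pytest.approx(w["p"], rel=1e-12)

    def test_small_chamber_class_is_an_error(self):
        groups = {"IAS": [[0.1], [0.2]], "LV": [[0.5]]}
        ds = _tissue_dataset(groups)
        with pytest.raises(ValueError, match=">= 2 samples"):
            atrial_ventricular_test(ds)


class TestDirectionSummary:
    def test_printed_direction_split_rounds_to_74(self):
        res = pd.DataFrame(
            {"delta_beta_signed": [-0.4] * 124 + [0.4] * 44}
        )
        out = direction_summary(res, significant_only=False)
        assert out["n_ventricular_hyper"] == 124
        assert out["pct_ventricular_hyper"] == 74
        assert out["pct_atrial_hyper"] == 26

    def test_all_null_table(self):
        res = pd.DataFrame({"delta_beta_signed": [0.0, 0.0]})
        out = direction_summary(res, significant_only=False)
        assert out["pct_ventricular_hyper"] == 0
        assert out["pct_atrial_hyper"] == 0

    def test_one_of_three_rounds_to_33(self):
        res = pd.DataFrame({"delta_beta_signed": [-0.3, 0.2, 0.1]})
        out = direction_summary(res, significant_only=False)
        assert out["pct_ventricular_hyper"] == 33

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            direction_summary(pd.DataFrame({"delta_beta_signed": []}))


def _flagged_annotation(n_flagged_hits, n_hits, n_flagged_bg, n_bg):
    rows = []
    hits, bg = [], []
    for i in range(n_hits):
        pid = f"hit{i}"
        rows.append({"probe_id": pid, "enhancer": i < n_flagged_hits})
        hits.append(pid)
    for i in range(n_bg):
        pid = f"bg{i}"
        rows.append({"probe_id": pid, "enhancer": i < n_flagged_bg})
        bg.append(pid)
    return make_annotation(rows), hits, bg


class TestEnrichment:
    def test_odds_ratio_hand_example(self):
        ann, hits, bg = _flagged_annotation(8, 10, 10, 100)
        res = annotation_enrichment(hits, bg, ann, "enhancer")
        assert (res.a, res.b, res.c, res.d) == (8, 2, 10, 90)
        assert res.odds_ratio == pytest.approx(36.0)
        assert res.fraction_hits == pytest.approx(0.8)

    def test_no_enrichment_gives_or_1(self):
        ann, hits, bg = _flagged_annotation(1, 2, 5, 10)
        res = annotation_enrichment(hits, bg, ann, "enhancer")
        assert res.odds_ratio == pytest.approx(1.0)
        assert not res.continuity_corrected

    def test_zero_cell_triggers_continuity_correction(self):
        ann, hits, bg = _flagged_annotation(0, 5, 10, 100)
        res = annotation_enrichment(hits, bg, ann, "enhancer")
        assert res.continuity_corrected
        assert res.odds_ratio == pytest.approx(
            (0.5 * 90.5) / (5.5 * 10.5)
        )

    def test_overlapping_sets_rejected(self):
        ann, hits, bg = _flagged_annotation(1, 3, 1, 3)
        with pytest.raises(ValueError, match="overlap"):
            annotation_enrichment(hits, hits[:1] + bg, ann, "enhancer")

    def test_enrichment_table_adjusts_across_flags(self):
        ann, hits, bg = _flagged_annotation(8, 10, 10, 100)
        table = enrichment_table(hits, bg, ann, ["enhancer", "dhs"])
        assert set(table.index) == {"enhancer", "dhs"}
        assert (table["q"] >= table["p"] - 1e-15).all()
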