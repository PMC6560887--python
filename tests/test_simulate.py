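import numpy as np
import pandas as pd
import pytest
from scipy import stats

from avmpanel.simulate import (
    SimulationConfig,
    generate_annotation,
    simulate_hipsc,
    simulate_pyro,
    simulate_tissue_cohort,
)


def binomial_99_bounds(n, p):
    lo, hi = stats.binom.interval(0.99, n, p)
    return lo, hi


class TestGenerateAnnotation:
    def test_same_seed_is_byte_identical(self):
        cfg = SimulationConfig(n_probes=500, n_true_loci=10, seed=42)
        a1, t1 = generate_annotation(cfg)
        a2, t2 = generate_annotation(cfg)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_no_sex_probes_when_fraction_zero(self):
        cfg = SimulationConfig(n_probes=500, n_true_loci=10, frac_sex_probes=0.0,
                               seed=1)
        ann, _ = generate_annotation(cfg)
        assert not ann["chrom"].isin(["X", "Y"]).any()

    def test_enhancer_enrichment_among_planted_loci(self):
        cfg = SimulationConfig(
            n_probes=1000, n_true_loci=20, enhancer_base_rate=0.2,
            enhancer_enrichment=3.0, seed=2,
        )
        ann, truth = generate_annotation(cfg)
        flagged = int(ann.loc[truth["is_true"], "enhancer"].sum())
        lo, hi = binomial_99_bounds(20, 0.6)
        assert lo <= flagged <= hi

    def test_qc_flags_never_on_planted_loci(self):
        cfg = SimulationConfig(n_probes=2000, n_true_loci=100, seed=3)
        ann, truth = generate_annotation(cfg)
        planted = ann.loc[truth["is_true"]]
        assert not planted["chrom"].isin(["X", "Y"]).any()
        assert not (planted["snp_at_cpg_maf"] > 0.05).any()
        assert not (planted["snp_within_3bp_maf"] > 0.05).any()
        assert not planted["cross_reactive"].any()

    def test_planted_gene_structure_exercises_panel_rules(self):
        cfg = SimulationConfig(n_probes=500, n_true_loci=10, seed=4)
        ann, truth = generate_annotation(cfg)
        planted = ann.loc[truth["is_true"]]
        genes = [g[0] for g in planted["genes"]]
        assert len(genes) != len(set(genes))  # >= 2 planted loci share a gene
        assert any(r == ["TSS1500"] for r in planted["gene_regions"])

    def test_direction_fraction_within_binomial_bounds(self):
        cfg = SimulationConfig(n_probes=2000, n_true_loci=200,
                               frac_vent_hyper=0.74, seed=5)
        _, truth = generate_annotation(cfg)
        n_neg = int((truth["delta_signed"] < 0).sum())
        lo, hi = binomial_99_bounds(200, 0.74)
        assert lo <= n_neg <= hi

    def test_config_invariants_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_probes=10, n_true_loci=20)
        with pytest.raises(ValueError):
            SimulationConfig(delta_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            SimulationConfig(frac_vent_hyper=1.5)


class TestTissueCohort:
    def test_zero_noise_samples_equal_group_means(self):
        cfg = SimulationConfig(n_probes=300, n_true_loci=10, noise_sd=0.0,
                               low_lcr_sample=False, detection_fail_rate=0.0,
                               seed=6)
        ann, truth = generate_annotation(cfg)
        ds = simulate_tissue_cohort(cfg, ann, truth)
        classes = ds.chamber_classes()
        a = ds.beta[classes.index[classes == "atrial"]]
        v = ds.beta[classes.index[classes == "ventricular"]]
        np.testing.assert_array_equal(
            a.to_numpy(), np.tile(truth["mean_atrial"].to_numpy()[:, None],
                                  (1, a.shape[1]))
        )
        delta_emp = a.mean(axis=1) - v.mean(axis=1)
        np.testing.assert_allclose(delta_emp, truth["delta_signed"]
                                   + truth["mean_atrial"] * 0, atol=1e-12)

    def test_default_noise_recovers_planted_deltas_within_se_bound(self):
        cfg = SimulationConfig(n_probes=2000, n_true_loci=100, seed=7)
        ann, truth = generate_annotation(cfg)
        ds = simulate_tissue_cohort(cfg, ann, truth)
        classes = ds.chamber_classes()
        a = ds.beta[classes.index[classes == "atrial"]]
        v = ds.beta[classes.index[classes == "ventricular"]]
        planted = truth.index[truth["is_true"]]
        err = (
            a.loc[planted].mean(axis=1) - v.loc[planted].mean(axis=1)
            - truth.loc[planted, "delta_signed"]
        )
        se = cfg.noise_sd * np.sqrt(1 / 44 + 1 / 5)
        # ~2 se per locus for most loci, a generous 5-se cap overall
        assert (err.abs() < 0.05).mean() >= 0.9
        assert err.abs().max() < 5 * se

    def test_cohort_composition_and_replicates(self):
        cfg = SimulationConfig(n_probes=200, n_true_loci=5, seed=8)
        ann, truth = generate_annotation(cfg)
        ds = simulate_tissue_cohort(cfg, ann, truth)
        sheet = ds.samples
        # 44 atrial + 5 ventricular patients; P001 triplicated, P045
        # duplicated, plus one low-LCR extra
        assert ds.n_samples == 44 + 5 + 2 + 1 + 1
        # pre-averaging rows: 35 IAS patients, P001 (IAS) appears as 3
        # replicates, plus the low-LCR extra
        assert (sheet["tissue"] == "IAS").sum() == 35 + 2 + 1
        assert (sheet["replicate_group"] == "P001_avg").sum() == 3
        assert (sheet["replicate_group"] == "P045_avg").sum() == 2
        tissue_counts = sheet.loc[
            sheet["chamber_class"] == "ventricular", "tissue"
        ].value_counts()
        # P045 (LV) appears twice; after averaging this is 3 LV + 2 RV
        assert tissue_counts["LV"] == 4 and tissue_counts["RV"] == 2
        from avmpanel.qc import average_replicates

        avg = average_replicates(ds)
        counts = avg.samples["chamber_class"].value_counts()
        assert counts["atrial"] == 45  # 44 + the low-LCR extra
        assert counts["ventricular"] == 5

    def test_detection_failures_at_configured_rate(self):
        cfg = SimulationConfig(n_probes=5000, n_true_loci=10,
                               detection_fail_rate=0.01, low_lcr_sample=False,
                               seed=9)
        ann, truth = generate_annotation(cfg)
        ds = simulate_tissue_cohort(cfg, ann, truth)
        rate = (ds.detection_p.to_numpy() >= 0.01).mean()
        assert rate == pytest.approx(0.01, rel=0.3)

    def test_beta_range_respected_after_truncation(self):
        cfg = SimulationConfig(n_probes=500, n_true_loci=10, noise_sd=0.4,
                               seed=10)
        ann, truth = generate_annotation(cfg)
        ds = simulate_tissue_cohort(cfg, ann, truth)
        b = ds.beta.to_numpy()
        assert (b >= 0).all() and (b <= 1).all()


@pytest.fixture(scope="module")
def cohort():
    cfg = SimulationConfig(n_probes=100, n_true_loci=5,
                           low_lcr_sample=False, seed=11)
    ann, truth = generate_annotation(cfg)
    return simulate_tissue_cohort(cfg, ann, truth), truth


@pytest.fixture(scope="module")
def truth():
    cfg = SimulationConfig(n_probes=300, n_true_loci=20, seed=12)
    _, t = generate_annotation(cfg)
    return t


class TestSimulatePyro:

    def test_identity_transform(self, cohort):
        ds, _ = cohort
        locus = ds.probe_ids[0]
        assays = simulate_pyro(ds, [locus], bias=(1.0, 0.0), noise_sd_pct=0.0)
        sid = ds.sample_ids[0]
        assert assays[0].measurements[sid] == pytest.approx(
            100.0 * ds.beta.loc[locus, sid]
        )

    def test_affine_arithmetic(self, cohort):
        ds, _ = cohort
        beta = ds.beta.copy()
        beta.iloc[0, :] = 1.0
        ds2 = type(ds)(beta=beta, detection_p=ds.detection_p,
                       samples=ds.samples,
                       array_total_probes=ds.array_total_probes)
        assays = simulate_pyro(ds2, [ds.probe_ids[0]], bias=(0.9, 5.0),
                               noise_sd_pct=0.0)
        assert all(
            v == pytest.approx(95.0) for v in assays[0].measurements.values()
        )

    def test_controls_through_same_bias(self, cohort):
        ds, _ = cohort
        assays = simulate_pyro(ds, [ds.probe_ids[0]], bias=(0.9, 5.0),
                               noise_sd_pct=0.0)
        assert assays[0].methylated_control == pytest.approx(0.9 * 80 + 5)
        assert assays[0].unmethylated_control == pytest.approx(0.9 * 3 + 5)

    def test_unknown_locus_rejected(self, cohort):
        ds, _ = cohort
        with pytest.raises(ValueError, match="unknown locus"):
            simulate_pyro(ds, ["cg_not_there"])


class TestSimulateHipsc:

    def _panel(self, truth, k=8):
        return list(truth.index[truth["is_true"]][:k])

    def _group_delta(self, ds):
        classes = ds.chamber_classes()
        a = ds.beta[classes.index[classes == "atrial"]]
        v = ds.beta[classes.index[classes == "ventricular"]]
        return a.mean(axis=1) - v.mean(axis=1)

    def test_full_attenuation_reproduces_tissue_differences(self, truth):
        panel = self._panel(truth)
        ds = simulate_hipsc(truth, panel, attenuation=1.0, noise_sd=0.0)
        np.testing.assert_allclose(
            self._group_delta(ds), truth.loc[panel, "delta_signed"], atol=1e-12
        )

    def test_half_attenuation_halves_difference(self, truth):
        panel = self._panel(truth)
        ds = simulate_hipsc(truth, panel, attenuation=0.5, noise_sd=0.0)
        np.testing.assert_allclose(
            self._group_delta(ds), 0.5 * truth.loc[panel, "delta_signed"],
            atol=1e-12,
        )

    def test_inverse_locus_flips_sign(self, truth):
        panel = self._panel(truth)
        ds = simulate_hipsc(
            truth, panel, attenuation=1.0, inverse_loci=[panel[0]], noise_sd=0.0
        )
        delta = self._group_delta(ds)
        expected = truth.loc[panel, "delta_signed"].copy()
        expected.iloc[0] *= -1
        np.testing.assert_allclose(delta, expected, atol=1e-12)

    def test_inverse_locus_must_be_in_panel(self, truth):
        panel = self._panel(truth)
        with pytest.raises(ValueError, match="not in panel"):
            simulate_hipsc(truth, panel, inverse_loci=["cg00000999"])

    def test_cell_lines_globally_low_or_high(self, truth):
        panel = self._panel(truth)
        ds = simulate_hipsc(truth, panel, noise_sd=0.0)
        cl = ds.samples[ds.samples["cohort"] == "cellline"]["sample_id"]
        assert len(cl) == 2
        means = ds.beta[list(cl)].mean()
        assert means.min() == pytest.approx(0.1)
        assert means.max() == pytest.approx(0.78)
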