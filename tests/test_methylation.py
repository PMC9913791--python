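"""Unit and property tests for QC, imputation, CIMP, EpiTOC and Δβ calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from epidac import (BetaMatrix, ProbeAnnotation, apply_probe_qc, call_dm,
                    cimp_percentage, classify_cimp, correlate_age_vs_cimp,
                    epitoc_age, impute_missing_knn)
from epidac.methylation import CimpCall, EpitocAge
from .conftest import toy_beta_frame


def make_annotation(probe_ids, cimp=(), epitoc=(), blacklist=None):
    blacklist = blacklist or {}
    probes = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(len(probe_ids)) * 100,
        "end": np.arange(len(probe_ids)) * 100 + 2,
        "in_cimp_panel": [p in set(cimp) for p in probe_ids],
        "in_epitoc_panel": [p in set(epitoc) for p in probe_ids],
        "blacklist_reason": [blacklist.get(p, "none") for p in probe_ids],
    }, index=pd.Index(probe_ids, name="probe_id"))
    return ProbeAnnotation(probes=probes)


class TestProbeQC:
    def test_detection_above_cutoff_masked_exact_cutoff_kept(self):
        beta = toy_beta_frame([[0.5, 0.6], [0.7, 0.8]])
        detp = toy_beta_frame([[0.06, 0.05], [0.01, 0.01]])
        bm = BetaMatrix(beta, detp)
        ann = make_annotation(list(beta.index))
        out = apply_probe_qc(bm, ann, detection_alpha=0.05)
        assert np.isnan(out.beta.iloc[0, 0])        # 0.06 > 0.05 -> missing
        assert out.beta.iloc[0, 1] == 0.6           # exactly 0.05 -> retained
        assert out.qc_log["n_entries_masked_detection"] == 1

    def test_blacklisted_probes_dropped(self):
        ids = [f"cg{i}" for i in range(100)]
        beta = toy_beta_frame(np.full((100, 2), 0.5), probes=ids)
        bm = BetaMatrix(beta)
        ann = make_annotation(ids, blacklist={ids[i]: "multimapping" for i in range(10)})
        out = apply_probe_qc(bm, ann)
        assert len(out.beta) == 90
        assert out.qc_log["n_probes_dropped_blacklist"] == 10

    def test_qc_is_idempotent(self):
        rng = np.random.default_rng(0)
        ids = [f"cg{i}" for i in range(50)]
        beta = toy_beta_frame(rng.random((50, 4)), probes=ids)
        detp = toy_beta_frame(rng.random((50, 4)) * 0.2, probes=ids)
        bm = BetaMatrix(beta, detp)
        ann = make_annotation(ids, blacklist={ids[0]: "meqtl"})
        once = apply_probe_qc(bm, ann)
        twice = apply_probe_qc(once, ann)
        pd.testing.assert_frame_equal(once.beta, twice.beta)

    def test_disjoint_probe_sets_error(self):
        bm = BetaMatrix(toy_beta_frame([[0.5]], probes=["cgA"]))
        ann = make_annotation(["cgB"])
        with pytest.raises(ValueError, match="no overlap"):
            apply_probe_qc(bm, ann)


class TestImputation:
    def test_no_missing_is_identity(self):
        beta = toy_beta_frame(np.full((15, 3), 0.4))
        out = impute_missing_knn(BetaMatrix(beta), k=2)
        pd.testing.assert_frame_equal(out.beta, beta)

    def test_hand_computed_two_neighbour_mean(self):
        # probe p0 missing in s0; its two nearest probes by the other
        # samples carry 0.2 and 0.4 there -> imputed 0.3
        beta = toy_beta_frame([
            [np.nan, 0.50, 0.50],
            [0.20, 0.50, 0.50],
            [0.40, 0.51, 0.49],
            [0.90, 0.90, 0.90],
            [0.95, 0.95, 0.95],
        ], probes=list("abcde"))
        out = impute_missing_knn(BetaMatrix(beta), k=2)
        assert out.beta.loc["a", "s0"] == pytest.approx(0.3, abs=1e-12)

    def test_output_stays_in_unit_interval(self):
        rng = np.random.default_rng(1)
        vals = rng.random((30, 5))
        vals[rng.random((30, 5)) < 0.1] = np.nan
        vals[0, :3] = np.nan
        out = impute_missing_knn(BetaMatrix(toy_beta_frame(vals)), k=3)
        assert not out.beta.isna().any().any()
        assert out.beta.min().min() >= 0 and out.beta.max().max() <= 1

    def test_probe_missing_everywhere_errors_with_name(self):
        vals = np.full((10, 3), 0.5)
        vals[2, :] = np.nan
        with pytest.raises(ValueError, match="cg002"):
            impute_missing_knn(BetaMatrix(toy_beta_frame(vals)), k=2)

    def test_too_few_complete_probes_errors(self):
        vals = np.full((4, 3), 0.5)
        vals[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            impute_missing_knn(BetaMatrix(toy_beta_frame(vals)), k=5)


class TestCimp:
    def test_saturated_and_empty_extremes(self):
        ids = [f"cg{i}" for i in range(10)]
        ann = make_annotation(ids, cimp=ids)
        high = BetaMatrix(toy_beta_frame(np.full((10, 1), 0.9), probes=ids))
        call = cimp_percentage(high, ann, "s0", methylated_cutoff=0.3)
        assert call.cimp_percent == 100.0 and call.cimp_class == "CIMP_plus"
        low = BetaMatrix(toy_beta_frame(np.zeros((10, 1)), probes=ids))
        call = cimp_percentage(low, ann, "s0")
        assert call.cimp_percent == 0.0 and call.cimp_class == "CIMP_minus"

    @pytest.mark.parametrize("percent,expected", [
        (43.3, "CIMP_plus"),     # intermediate percentages still classify CIMP+
        (40.0, "CIMP_minus"),    # the cut is strictly > 40
        (40.0001, "CIMP_plus"),
        (0.0, "CIMP_minus"),
    ])
    def test_classification_boundary(self, percent, expected):
        assert classify_cimp(percent) == expected

    def test_order_invariance(self, small_cohort):
        cohort = small_cohort
        sample = cohort.samples.index[0]
        base = cimp_percentage(cohort.beta, cohort.annotation, sample)
        shuffled = BetaMatrix(cohort.beta.beta.sample(frac=1, random_state=0),
                              cohort.beta.detection_p.sample(frac=1, random_state=0))
        again = cimp_percentage(shuffled, cohort.annotation, sample)
        assert base.cimp_percent == pytest.approx(again.cimp_percent)


class TestEpitoc:
    def test_arithmetic_mean(self):
        ids = list("abc")
        ann = make_annotation(ids, epitoc=ids)
        bm = BetaMatrix(toy_beta_frame([[0.2], [0.4], [0.6]], probes=ids))
        assert epitoc_age(bm, ann, "s0").age == pytest.approx(0.4)
        zero = BetaMatrix(toy_beta_frame([[0.0], [0.0], [0.0]], probes=ids))
        assert epitoc_age(zero, ann, "s0").age == 0.0

    def test_missing_values_rejected(self):
        ids = list("abc")
        ann = make_annotation(ids, epitoc=ids)
        bm = BetaMatrix(toy_beta_frame([[0.2], [np.nan], [0.6]], probes=ids))
        with pytest.raises(ValueError, match="impute"):
            epitoc_age(bm, ann, "s0")

    def test_treatment_reduces_mitotic_age_in_every_model(self, default_analysis):
        """Genome-wide hypomethylation shows up as a lower mitotic age in
        the treated arm of each model."""
        cohort = default_analysis["cohort"]
        bi = default_analysis["beta_imputed"]
        ann = cohort.annotation
        for model in cohort.config.model_names:
            va = np.mean([epitoc_age(bi, ann, s).age
                          for s in cohort.samples_for(model=model, arm="vehicle")])
            ta = np.mean([epitoc_age(bi, ann, s).age
                          for s in cohort.samples_for(model=model, arm="DAC")])
            assert ta < va


class TestDeltaBeta:
    def _bm(self, values):
        return BetaMatrix(toy_beta_frame(values))

    def test_group_mean_difference_and_direction(self):
        t = self._bm([[0.3, 0.3]])
        v = self._bm([[0.6, 0.6]])
        dm = call_dm(t, v)
        assert dm["delta_beta"].iloc[0] == pytest.approx(-0.3)
        assert bool(dm["is_dm"].iloc[0]) and dm["direction"].iloc[0] == "hypo"

    @pytest.mark.parametrize("delta,expected", [
        (0.2, False), (-0.2, False), (0.2000001, True), (-0.2000001, True), (0.25, True),
    ])
    def test_strict_threshold_boundary(self, delta, expected):
        t = self._bm([[0.5 + delta]])
        v = self._bm([[0.5]])
        dm = call_dm(t, v)
        assert bool(dm["is_dm"].iloc[0]) is expected
        if expected:
            assert dm["direction"].iloc[0] == ("hyper" if delta > 0 else "hypo")

    def test_arm_swap_negates_delta(self, small_cohort):
        cohort = small_cohort
        t = cohort.beta.select_samples(cohort.samples_for(arm="DAC"))
        v = cohort.beta.select_samples(cohort.samples_for(arm="vehicle"))
        fwd = call_dm(t, v)
        rev = call_dm(v, t)
        assert np.allclose(fwd["delta_beta"], -rev["delta_beta"].loc[fwd.index])

    def test_probe_without_data_excluded_and_logged(self):
        t = BetaMatrix(toy_beta_frame([[np.nan, np.nan], [0.5, 0.5]]))
        v = BetaMatrix(toy_beta_frame([[0.4, 0.4], [0.4, 0.4]]))
        dm = call_dm(t, v)
        assert len(dm) == 1
        assert dm.attrs["n_excluded_no_data"] == 1

    def test_mismatched_probe_sets_rejected(self):
        t = BetaMatrix(toy_beta_frame([[0.5]], probes=["cgA"]))
        v = BetaMatrix(toy_beta_frame([[0.5]], probes=["cgB"]))
        with pytest.raises(ValueError, match="probe set"):
            call_dm(t, v)


class TestAgeCimpCorrelation:
    def test_collinear_pairs(self):
        up = [(EpitocAge("a", 0.1, 3), CimpCall("a", 10, "CIMP_minus", 3)),
              (EpitocAge("b", 0.2, 3), CimpCall("b", 20, "CIMP_minus", 3)),
              (EpitocAge("c", 0.3, 3), CimpCall("c", 30, "CIMP_minus", 3))]
        assert correlate_age_vs_cimp(up) == pytest.approx(1.0)
        down = [(0.1, 30), (0.2, 20), (0.3, 10)]
        assert correlate_age_vs_cimp(down) == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate_age_vs_cimp([(0.1, 10), (0.1, 20), (0.1, 30)])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="at least 3"):
            correlate_age_vs_cimp([(0.1, 10), (0.2, 20)])

    def test_generator_couples_age_and_cimp(self, default_analysis):
        """Models with higher CIMP probability carry globally higher
        methylation, so mitotic age and CIMP% correlate positively."""
        cohort = default_analysis["cohort"]
        bi = default_analysis["beta_imputed"]
        bq = default_analysis["beta_qc"]
        ann = cohort.annotation
        pairs = []
        for model in cohort.config.model_names:
            samples = cohort.samples_for(model=model, arm="vehicle")
            age = np.mean([epitoc_age(bi, ann, s).age for s in samples])
            pct = np.mean([cimp_percentage(bq, ann, s).cimp_percent for s in samples])
            pairs.append((age, pct))
        assert correlate_age_vs_cimp(pairs) > 0


@given(st.lists(st.floats(0, 1), min_size=2, max_size=8),
       st.lists(st.floats(0, 1), min_size=2, max_size=8))
def test_delta_beta_antisymmetry_property(t_vals, v_vals):
    t = BetaMatrix(toy_beta_frame([t_vals]))
    v = BetaMatrix(toy_beta_frame([v_vals]))
    fwd = call_dm(t, v)
    rev = call_dm(v, t)
    assert fwd["delta_beta"].iloc[0] == pytest.approx(-rev["delta_beta"].iloc[0])
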