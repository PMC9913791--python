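"""Size factors, BH adjustment, the NB Wald test and the signature rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from epidac import bh_adjust, de_test, derive_signature, size_factors


def nb_matrix(rng, n_genes, n_samples, disp=0.05, libs=None, mu=None):
    mu = mu if mu is not None else rng.lognormal(4, 1.2, n_genes)
    libs = libs if libs is not None else np.ones(n_samples)
    m = mu[:, None] * np.asarray(libs)[None, :]
    y = rng.negative_binomial(1 / disp, 1 / (1 + disp * m))
    return pd.DataFrame(y, index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"s{j}" for j in range(n_samples)])


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        assert np.allclose(size_factors(cm), [1.0, 1.0])

    def test_doubled_library_doubles_factor_ratio(self):
        cm = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]})
        sf = size_factors(cm)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_recovers_known_library_sizes(self):
        rng = np.random.default_rng(2)
        libs = np.array([0.5, 0.5, 1.0, 1.0, 2.0, 2.0])
        cm = nb_matrix(rng, 2000, 6, disp=0.02, libs=libs)
        sf = size_factors(cm)
        ratio = sf.to_numpy() / libs
        assert np.all(np.abs(ratio / ratio.mean() - 1) < 0.05)

    def test_no_common_gene_errors(self):
        cm = pd.DataFrame({"a": [5, 0], "b": [0, 5]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(cm)


class TestBHAdjust:
    def test_hand_computed_stepup(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged_and_all_ones(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjustment_never_decreases_p(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)


class TestDETest:
    def test_constant_gene_has_zero_lfc_and_p_one(self):
        cm = pd.DataFrame([[50] * 8, [10, 12, 9, 11, 10, 12, 9, 11]],
                          index=["flat", "noise"],
                          columns=[f"s{j}" for j in range(8)])
        de = de_test(cm, ["A"] * 4 + ["B"] * 4)
        assert de.loc["flat", "log2fc"] == pytest.approx(0.0, abs=1e-6)
        assert de.loc["flat", "p"] == pytest.approx(1.0, abs=1e-6)

    def test_label_swap_negates_lfc_keeps_p(self):
        rng = np.random.default_rng(4)
        cm = nb_matrix(rng, 300, 8)
        fwd = de_test(cm, ["A"] * 4 + ["B"] * 4, levels=("A", "B"))
        rev = de_test(cm, ["A"] * 4 + ["B"] * 4, levels=("B", "A"))
        assert np.allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-6)
        assert np.allclose(fwd["p"], rev["p"], atol=1e-8)

    def test_doubled_counts_recover_unit_lfc(self):
        # a minority of genes doubled in the second group (a global doubling
        # would be indistinguishable from a library-size shift)
        rng = np.random.default_rng(5)
        mu = np.full(400, 200.0)
        cm = nb_matrix(rng, 400, 8, disp=0.01, mu=mu)
        cm.iloc[:50, 4:] = nb_matrix(rng, 50, 4, disp=0.01,
                                     mu=np.full(50, 400.0)).to_numpy()
        de = de_test(cm, ["A"] * 4 + ["B"] * 4, levels=("A", "B"))
        assert abs(de["log2fc"].iloc[:50].mean() - 1.0) < 0.3
        assert np.all(np.abs(de["log2fc"].iloc[:50] - 1.0) < 0.5)

    def test_identical_arms_lfc_centred_at_zero(self):
        rng = np.random.default_rng(6)
        cm = nb_matrix(rng, 1000, 8)
        de = de_test(cm, ["A"] * 4 + ["B"] * 4)
        assert abs(de["log2fc"].mean()) < 0.05

    def test_small_group_rejected(self):
        cm = pd.DataFrame([[5, 6, 7]], index=["g"], columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="at least 2"):
            de_test(cm, ["A", "B", "B"])

    def test_all_zero_genes_excluded_and_logged(self):
        rng = np.random.default_rng(7)
        cm = nb_matrix(rng, 50, 6)
        cm.iloc[0] = 0
        de = de_test(cm, ["A"] * 3 + ["B"] * 3)
        assert "g0" not in de.index
        assert de.attrs["n_excluded_all_zero"] == 1

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(8)
        powers = []
        for lfc in (0.5, 1.0, 2.0):
            mu = np.full(300, 100.0)
            cm = nb_matrix(rng, 300, 8, disp=0.05, mu=mu)
            cm.iloc[:60, 4:] = nb_matrix(rng, 60, 4, disp=0.05,
                                         mu=np.full(60, 100.0 * 2 ** lfc)).to_numpy()
            de = de_test(cm, ["A"] * 4 + ["B"] * 4, levels=("A", "B"))
            powers.append(de["is_de"].iloc[:60].mean())
        assert powers[0] < powers[1] < powers[2]

    def test_de_set_nested_across_fdr_levels(self):
        rng = np.random.default_rng(9)
        cm = nb_matrix(rng, 500, 8)
        cm.iloc[:40, 4:] *= 4
        de = de_test(cm, ["A"] * 4 + ["B"] * 4)
        at_05 = set(de.index[de["padj"] < 0.05])
        at_10 = set(de.index[de["padj"] < 0.10])
        assert at_05 <= at_10
        assert np.all(de["padj"] >= de["p"] - 1e-12)

    def test_agrees_with_independent_nb_implementation(self):
        """Cross-check fold-change estimates against pydeseq2 on a small
        simulated dataset; the two NB fits should agree closely."""
        import warnings
        rng = np.random.default_rng(10)
        mu = rng.lognormal(5, 1.0, 120)
        cm = nb_matrix(rng, 120, 8, disp=0.05, mu=mu)
        cm.iloc[:20, 4:] = nb_matrix(rng, 20, 4, disp=0.05,
                                     mu=mu[:20] * 4).to_numpy()
        de = de_test(cm, ["A"] * 4 + ["B"] * 4, levels=("A", "B"))
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats
        meta = pd.DataFrame({"condition": ["A"] * 4 + ["B"] * 4},
                            index=cm.columns)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(counts=cm.T, metadata=meta,
                               design="~condition", quiet=True)
            dds.deseq2()
            res = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
            res.summary()
        ref = res.results_df["log2FoldChange"].reindex(de.index)
        r = np.corrcoef(de["log2fc"], ref)[0, 1]
        assert r > 0.95
        assert (de["log2fc"] - ref).abs().median() < 0.2


class TestSignature:
    def _de(self, n_passing, n_failing=30, seed=0):
        rng = np.random.default_rng(seed)
        lfc = np.concatenate([rng.uniform(1.2, 3, n_passing),
                              rng.uniform(0, 0.9, n_failing)])
        padj = np.concatenate([rng.uniform(0, 0.04, n_passing),
                               rng.uniform(0.1, 1, n_failing)])
        return pd.DataFrame({"log2fc": lfc, "padj": padj},
                            index=[f"g{i:03d}" for i in range(n_passing + n_failing)])

    def test_truncated_to_seventy(self):
        sig = derive_signature(self._de(100))
        assert len(sig) == 70
        assert (sig["log2fc"].abs() > 1).all() and (sig["padj"] < 0.05).all()

    def test_fewer_passing_returned_in_full(self):
        assert len(derive_signature(self._de(12))) == 12

    def test_padj_ties_broken_by_larger_fold_change(self):
        de = pd.DataFrame({"log2fc": [1.5, -2.5, 3.0], "padj": [0.01, 0.01, 0.001]},
                          index=["a", "b", "c"])
        sig = derive_signature(de, max_genes=2)
        assert list(sig.index) == ["c", "b"]
        assert list(sig["side"]) == ["up_in_sensitive", "down_in_sensitive"]

    def test_empty_signature_warns(self):
        de = pd.DataFrame({"log2fc": [0.2], "padj": [0.9]}, index=["a"])
        with pytest.warns(UserWarning, match="empty"):
            sig = derive_signature(de)
        assert len(sig) == 0

    def test_default_cohort_yields_full_signature(self, default_analysis):
        sig = derive_signature(default_analysis["de"]["baseline"])
        assert len(sig) == 70


class TestSubgroupPattern:
    def test_sensitive_subgroup_has_more_de_at_similar_dm(self, default_analysis):
        """More treatment-responsive genes in the sensitive models, with
        comparable methylation effects in both subgroups."""
        de_s = default_analysis["de"]["subgroup_sensitive"]
        de_l = default_analysis["de"]["subgroup_less_sensitive"]
        dm_s = default_analysis["dm"]["subgroup_sensitive"]
        dm_l = default_analysis["dm"]["subgroup_less_sensitive"]
        assert de_s["is_de"].sum() > de_l["is_de"].sum()
        ratio = dm_s["is_dm"].sum() / dm_l["is_dm"].sum()
        assert 2 / 3 < ratio < 3 / 2
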