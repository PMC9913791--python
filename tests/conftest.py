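"""Shared fixtures: a small cohort for unit tests and the default cohort
(full study conditions) with its downstream analysis results, computed once
per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from epidac import (CohortConfig, apply_probe_qc, call_dm, de_test,
                    generate_cohort, impute_missing_knn, size_factors,
                    summarize_gene_methylation)

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("suite")

SMALL_FIELDS = dict(
    n_probes=2_000, n_genes=500, cimp_panel_size=200, epitoc_panel_size=60,
    n_bins=400, replicates_per_arm=3, n_responsive_genes_sensitive=80,
    n_responsive_genes_less=25, n_myc_targets=25, n_baseline_signature_genes=40,
    random_set_size=25,
)


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(seed=11, **SMALL_FIELDS)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """Full study conditions (EPIC-scale down-sample, 5 models, 4 reps)."""
    return generate_cohort(CohortConfig(seed=20260920 % 2**16))


@pytest.fixture(scope="session")
def default_analysis(default_cohort):
    """QC, imputation, per-model and per-subgroup DM/DE, baseline DE."""
    cohort = default_cohort
    cfg = cohort.config
    ann = cohort.annotation
    bq = apply_probe_qc(cohort.beta, ann)
    bi = impute_missing_knn(bq, 10)
    sf = size_factors(cohort.counts)

    dm, de = {}, {}
    groups = [(m, dict(model=m)) for m in cfg.model_names]
    groups += [(f"subgroup_{s}", dict(subgroup=s))
               for s in ("sensitive", "less_sensitive")]
    for name, sel in groups:
        treated = cohort.samples_for(arm="DAC", **sel)
        vehicle = cohort.samples_for(arm="vehicle", **sel)
        dm[name] = call_dm(bq.select_samples(treated), bq.select_samples(vehicle))
        samples = vehicle + treated
        de[name] = de_test(cohort.counts[samples],
                           cohort.samples.loc[samples, "arm"],
                           levels=("vehicle", "DAC"), sf=sf.loc[samples])

    v_less = cohort.samples_for(subgroup="less_sensitive", arm="vehicle")
    v_sens = cohort.samples_for(subgroup="sensitive", arm="vehicle")
    samples = v_less + v_sens
    de["baseline"] = de_test(cohort.counts[samples],
                             cohort.samples.loc[samples, "subgroup"],
                             levels=("less_sensitive", "sensitive"),
                             sf=sf.loc[samples])

    joint_up = {}
    for m in cfg.model_names:
        gm = summarize_gene_methylation(dm[m], ann)
        hypo = set(gm.index[gm["n_hypo"] > 0]) & set(de[m].index)
        sig = de[m][de[m]["padj"] < 0.05]
        joint_up[m] = hypo & set(sig.index[sig["log2fc"] > 0])

    return {"cohort": cohort, "beta_qc": bq, "beta_imputed": bi, "sf": sf,
            "dm": dm, "de": de, "joint_up": joint_up}


def toy_beta_frame(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i:03d}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=probes, columns=samples)
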