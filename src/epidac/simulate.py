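"""Seeded synthetic PDX cohort generator.

Emulates, at desk scale, the structure of a hypomethylating-agent PDX study:
five models in vehicle and treated arms with 3-4 replicates per arm,
EPIC-like beta values from a two-component Beta mixture, global treatment
hypomethylation that spares a fixed CIMP panel, negative-binomial RNA counts
with more treatment-responsive genes in the sensitive subgroup, four
per-sample A/B compartment tracks over a toy genome of contiguous 50 kb
bins, exponential survival times with arm-specific scales, and counting-bead
flow-cytometry tables. Truth tables (which probes shifted, which genes
respond, true compartment labels) are always produced alongside the data so
that every downstream stage can be tested for recovery.

All randomness flows from the single config seed through named substreams,
so identical seed + config gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import BLACKLIST_REASONS, REGION_CLASSES, ProbeAnnotation
from .methylation import BetaMatrix

ARMS = ("vehicle", "DAC")
SURVIVAL_ARMS = ("vehicle", "DAC_1cycle", "DAC_2cycle")

# printed CIMP methylation percentages of the five PDX models, reused as the
# per-model probability that a CIMP-panel probe is methylated
DEFAULT_CIMP_PROBS = (0.894, 0.433, 0.952, 0.897, 0.530)

_STREAMS = {"annotation": 0, "beta": 1, "counts": 2, "compartments": 3, "outcomes": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults are the emulation targets: a down-sampled EPIC-scale probe set,
    the 1099-CpG CIMP panel, five models split into a more sensitive
    (first three) and less sensitive (last two) subgroup, a global treated-arm
    hypomethylation of -0.25 on 60% of non-CIMP probes with the CIMP panel
    spared, 82% of probes / 74% of genes in open (A) chromatin, and four
    compartment samples at 50 kb resolution.
    """

    # scale
    n_probes: int = 20_000
    n_genes: int = 3_000
    cimp_panel_size: int = 1_099
    epitoc_panel_size: int = 200
    n_models: int = 5
    replicates_per_arm: int = 4
    # methylation model
    model_cimp_probs: tuple = DEFAULT_CIMP_PROBS
    n_sensitive_models: int = 3
    global_hypo_effect: float = -0.25
    affected_probe_fraction: float = 0.6
    cimp_spare: bool = True
    methylated_mean: float = 0.8
    unmethylated_mean: float = 0.1
    beta_noise_sd: float = 0.05
    detection_fail_rate: float = 0.01
    blacklist_fraction: float = 0.05
    # annotation / toy genome
    gene_link_prob: float = 0.8
    second_link_prob: float = 0.05
    bin_size: int = 50_000
    n_bins: int = 2_000
    open_fraction_probes: float = 0.82
    open_fraction_genes: float = 0.74
    # expression model
    nb_dispersion: float = 0.05
    log_mean_mu: float = 4.0
    log_mean_sd: float = 1.2
    responsive_min_base_mean: float = 30.0
    n_responsive_genes_sensitive: int = 300
    n_responsive_genes_less: int = 60
    responsive_up_fraction: float = 0.8
    core_lfc_range: tuple = (2.0, 3.0)
    extra_lfc_range: tuple = (1.0, 3.0)
    n_myc_targets: int = 50
    myc_lfc_range: tuple = (-1.5, -0.5)
    n_baseline_signature_genes: int = 120
    baseline_lfc_range: tuple = (1.5, 3.0)
    n_random_gene_sets: int = 10
    random_set_size: int = 50
    # compartments
    n_compartment_samples: int = 4
    compartment_concordance: float = 0.9
    # outcomes
    mice_per_arm: int = 5
    survival_scale_vehicle: float = 25.0
    survival_scale_dac1: float = 40.0
    survival_scale_dac2: float = 55.0
    sensitive_survival_multiplier: float = 1.8
    censor_prob: float = 0.05
    flow_baseline_cells_per_ul: float = 500.0
    vehicle_growth: float = 4.0
    sensitive_treated_growth: float = 0.5
    less_treated_growth: float = 1.8
    bead_volume_ul: float = 50.0
    cell_volume_ul: float = 30.0
    bead_concentration_per_ul: float = 1.0
    mean_bead_count: float = 2_500.0
    # seed (mandatory for any generation)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {"n_probes": self.n_probes, "n_genes": self.n_genes,
                  "n_models": self.n_models, "replicates_per_arm": self.replicates_per_arm,
                  "n_bins": self.n_bins, "bin_size": self.bin_size,
                  "mice_per_arm": self.mice_per_arm,
                  "n_compartment_samples": self.n_compartment_samples}
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.cimp_panel_size < 0 or self.epitoc_panel_size < 0:
            raise ValueError("panel sizes must be non-negative")
        if self.cimp_panel_size + self.epitoc_panel_size > self.n_probes:
            raise ValueError("cimp_panel_size + epitoc_panel_size must not exceed n_probes")
        fractions = {
            "affected_probe_fraction": self.affected_probe_fraction,
            "detection_fail_rate": self.detection_fail_rate,
            "blacklist_fraction": self.blacklist_fraction,
            "gene_link_prob": self.gene_link_prob,
            "second_link_prob": self.second_link_prob,
            "open_fraction_probes": self.open_fraction_probes,
            "open_fraction_genes": self.open_fraction_genes,
            "responsive_up_fraction": self.responsive_up_fraction,
            "compartment_concordance": self.compartment_concordance,
            "censor_prob": self.censor_prob,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if len(self.model_cimp_probs) < self.n_models:
            raise ValueError("model_cimp_probs must provide one probability per model")
        if not 0 < self.n_sensitive_models < self.n_models:
            raise ValueError("n_sensitive_models must split the models into two subgroups")
        if self.n_responsive_genes_sensitive < self.n_responsive_genes_less:
            raise ValueError("sensitive models must have at least as many responsive genes")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.replicates_per_arm not in (3, 4):
            raise ValueError("replicates_per_arm must be 3 or 4 (triplicates or quadruplets)")

    @property
    def model_names(self) -> list[str]:
        return [f"PDX{i + 1}" for i in range(self.n_models)]

    @property
    def sensitive_models(self) -> list[str]:
        return self.model_names[: self.n_sensitive_models]

    @property
    def less_sensitive_models(self) -> list[str]:
        return self.model_names[self.n_sensitive_models:]

    def subgroup_of(self, model: str) -> str:
        return "sensitive" if model in self.sensitive_models else "less_sensitive"

    def to_dict(self) -> dict:
        return asdict(self)


def _non_cimp_meth_prob(cimp_prob: float) -> float:
    # couples genome-wide methylation propensity to the CIMP probability so
    # that mitotic age and CIMP percentage co-vary across models
    return 0.35 + 0.3 * cimp_prob


def generate_probe_annotation(config: CohortConfig) -> ProbeAnnotation:
    """Probe manifest on a toy genome of contiguous fixed-width bins.

    Probes land in open (A) bins with probability ``open_fraction_probes``;
    gene TSSs are uniform over bins, so the open gene fraction follows the
    bin composition (``open_fraction_genes``). CIMP and EpiTOC panels are
    disjoint random probe subsets; a blacklist marks a configurable fraction.
    The true bin labels and the gene table ride along as attributes
    (``annotation.bins``, ``annotation.genes``).
    """
    rng = _rng(config.seed, "annotation")
    n_bins, width = config.n_bins, config.bin_size
    bin_open = rng.random(n_bins) < config.open_fraction_genes
    bins = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n_bins, dtype=np.int64) * width,
        "end": (np.arange(n_bins, dtype=np.int64) + 1) * width,
        "label": np.where(bin_open, "A", "B"),
    })

    open_bins = np.flatnonzero(bin_open)
    closed_bins = np.flatnonzero(~bin_open)
    if len(open_bins) == 0 or len(closed_bins) == 0:
        raise ValueError("toy genome needs both open and closed bins; adjust n_bins")
    in_open = rng.random(config.n_probes) < config.open_fraction_probes
    probe_bins = np.where(in_open,
                          rng.choice(open_bins, size=config.n_probes),
                          rng.choice(closed_bins, size=config.n_probes))
    pos = probe_bins * width + rng.integers(0, width, size=config.n_probes)
    probe_ids = [f"cg{i:08d}" for i in range(config.n_probes)]

    # disjoint panels, then blacklist drawn from probes outside both panels
    order = rng.permutation(config.n_probes)
    cimp_idx = order[: config.cimp_panel_size]
    epitoc_idx = order[config.cimp_panel_size: config.cimp_panel_size + config.epitoc_panel_size]
    in_cimp = np.zeros(config.n_probes, dtype=bool)
    in_cimp[cimp_idx] = True
    in_epitoc = np.zeros(config.n_probes, dtype=bool)
    in_epitoc[epitoc_idx] = True
    blacklist = np.array(["none"] * config.n_probes, dtype=object)
    eligible = order[config.cimp_panel_size + config.epitoc_panel_size:]
    n_black = int(round(config.blacklist_fraction * config.n_probes))
    n_black = min(n_black, len(eligible))
    chosen = eligible[:n_black]
    blacklist[chosen] = rng.choice(BLACKLIST_REASONS[1:], size=n_black)

    probes = pd.DataFrame({
        "chrom": "chr1",
        "start": pos,
        "end": pos + 2,  # CpG dinucleotide, 0-based half-open
        "in_cimp_panel": in_cimp,
        "in_epitoc_panel": in_epitoc,
        "blacklist_reason": blacklist,
    }, index=pd.Index(probe_ids, name="probe_id"))

    gene_bins = rng.integers(0, n_bins, size=config.n_genes)
    tss = gene_bins * width + rng.integers(0, width, size=config.n_genes)
    length = rng.integers(2_000, 20_000, size=config.n_genes)
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    genes = pd.DataFrame({
        "chrom": "chr1",
        "start": tss,
        "end": tss + length,
        "tss": tss,
    }, index=pd.Index(gene_ids, name="gene_id"))

    linked = rng.random(config.n_probes) < config.gene_link_prob
    link_gene = rng.integers(0, config.n_genes, size=config.n_probes)
    link_region = rng.choice(REGION_CLASSES, size=config.n_probes, p=[0.5, 0.35, 0.15])
    rows = [(probe_ids[i], gene_ids[link_gene[i]], link_region[i])
            for i in np.flatnonzero(linked)]
    second = rng.random(config.n_probes) < config.second_link_prob
    second_gene = rng.integers(0, config.n_genes, size=config.n_probes)
    second_region = rng.choice(REGION_CLASSES, size=config.n_probes, p=[0.5, 0.35, 0.15])
    for i in np.flatnonzero(linked & second):
        if second_gene[i] != link_gene[i]:
            rows.append((probe_ids[i], gene_ids[second_gene[i]], second_region[i]))
    links = pd.DataFrame(rows, columns=["probe_id", "gene_id", "region_class"])

    ann = ProbeAnnotation(probes=probes, links=links, genes=genes)
    ann.bins = bins  # true compartment labels of the toy genome
    return ann


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    nu = mean * (1 - mean) / sd ** 2 - 1
    if nu <= 0:
        raise ValueError("beta_noise_sd too large for the component means")
    return mean * nu, (1 - mean) * nu


def sample_sheet(config: CohortConfig) -> pd.DataFrame:
    """One row per profiling sample: model x arm x replicate."""
    rows = []
    for model in config.model_names:
        for arm in ARMS:
            for rep in range(1, config.replicates_per_arm + 1):
                rows.append({
                    "sample_id": f"{model}_{arm}_r{rep}",
                    "model": model,
                    "arm": arm,
                    "replicate": rep,
                    "subgroup": config.subgroup_of(model),
                })
    return pd.DataFrame(rows).set_index("sample_id")


def generate_beta_cohort(config: CohortConfig, annotation: ProbeAnnotation
                         ) -> tuple[BetaMatrix, pd.DataFrame, dict]:
    """Beta matrix for every model x arm x replicate, plus truth tables.

    Vehicle betas come from a two-component Beta mixture (methylated probes
    concentrated near 0.8, unmethylated near 0.1). Whether a non-CIMP probe
    is methylated in a model thresholds a shared per-probe uniform draw by
    the model's methylation propensity, so probe states are nested across
    models; CIMP-panel probes are methylated with the model's CIMP
    probability. Treated arms shift the affected probes by
    ``global_hypo_effect`` (truncated to [0, 1]), sparing the CIMP panel when
    ``cimp_spare``. A small fraction of detection p-values comes out > 0.05.

    Returns (beta matrix, sample sheet, truth dict with ``probes`` and
    ``methylated_state``).
    """
    rng = _rng(config.seed, "beta")
    sheet = sample_sheet(config)
    probe_ids = annotation.probes.index
    n = len(probe_ids)
    is_cimp = annotation.probes["in_cimp_panel"].to_numpy(bool)

    u = rng.random(n)  # shared methylation-propensity draw, nested across models
    eligible = ~is_cimp if config.cimp_spare else np.ones(n, bool)
    affected = np.zeros(n, bool)
    pool = np.flatnonzero(eligible)
    n_aff = int(round(config.affected_probe_fraction * len(pool)))
    affected[rng.choice(pool, size=n_aff, replace=False)] = True

    a_m, b_m = _beta_params(config.methylated_mean, config.beta_noise_sd)
    a_u, b_u = _beta_params(config.unmethylated_mean, config.beta_noise_sd)

    state = {}
    for mi, model in enumerate(config.model_names):
        p_cimp = config.model_cimp_probs[mi]
        meth = u < _non_cimp_meth_prob(p_cimp)
        meth[is_cimp] = rng.random(is_cimp.sum()) < p_cimp
        state[model] = meth

    beta_cols, detp_cols = {}, {}
    for sid, row in sheet.iterrows():
        meth = state[row["model"]]
        draws = np.where(meth, rng.beta(a_m, b_m, size=n), rng.beta(a_u, b_u, size=n))
        if row["arm"] == "DAC":
            draws = np.clip(draws + config.global_hypo_effect * affected, 0.0, 1.0)
        beta_cols[sid] = draws
        detp = rng.uniform(0.0, 0.04, size=n)
        fail = rng.random(n) < config.detection_fail_rate
        detp[fail] = rng.uniform(0.051, 1.0, size=int(fail.sum()))
        detp_cols[sid] = detp

    beta = pd.DataFrame(beta_cols, index=probe_ids)
    detp = pd.DataFrame(detp_cols, index=probe_ids)
    truth_probes = pd.DataFrame({
        "is_affected": affected,
        "methylation_propensity": u,
        "in_cimp_panel": is_cimp,
    }, index=probe_ids)
    meth_state = pd.DataFrame(state, index=probe_ids)
    truth = {"probes": truth_probes, "methylated_state": meth_state}
    return BetaMatrix(beta, detp), sheet, truth


def _genes_with_qualifying_probes(annotation: ProbeAnnotation, truth: dict,
                                  models: list[str], min_probes: int) -> pd.Index:
    """Genes linked to >= min_probes affected probes methylated in all ``models``."""
    probes = truth["probes"]
    state = truth["methylated_state"][models]
    qualifying = probes["is_affected"] & state.all(axis=1)
    links = annotation.links
    q = links[links["probe_id"].map(qualifying).fillna(False)]
    counts = q.groupby("gene_id")["probe_id"].nunique()
    return pd.Index(sorted(counts.index[counts >= min_probes]))


def generate_counts(config: CohortConfig, annotation: ProbeAnnotation,
                    dm_truth: dict) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Negative-binomial count matrix for every sample, plus expression truth.

    Less-sensitive models respond on a core set of genes linked to affected,
    everywhere-methylated probes; sensitive models respond on the core plus
    extra genes (so the sensitive subgroup has more responsive genes at
    similar methylation effects). A designated MYC-target set is
    downregulated in treated arms of every model, and a baseline
    subgroup-difference block (present in both arms of sensitive models)
    carries the sensitivity signature. Also returns the gene-set collection
    used for enrichment testing.
    """
    rng = _rng(config.seed, "counts")
    sheet = sample_sheet(config)
    gene_ids = annotation.genes.index
    n_genes = len(gene_ids)

    base_mean = rng.lognormal(config.log_mean_mu, config.log_mean_sd, size=n_genes)
    lib = rng.uniform(0.7, 1.3, size=len(sheet))

    core_pool = _genes_with_qualifying_probes(
        annotation, dm_truth, config.model_names, min_probes=2)
    sens_pool = _genes_with_qualifying_probes(
        annotation, dm_truth, config.sensitive_models, min_probes=1)

    n_core = config.n_responsive_genes_less
    if len(core_pool) < n_core:
        raise ValueError("not enough genes linked to affected methylated probes "
                         "for the core responsive set; increase n_probes or links")
    core = pd.Index(rng.choice(core_pool, size=n_core, replace=False))
    extra_pool = sens_pool.difference(core)
    n_extra = config.n_responsive_genes_sensitive - n_core
    if len(extra_pool) < n_extra:
        raise ValueError("not enough genes for the sensitive-only responsive set")
    extra = pd.Index(rng.choice(extra_pool, size=n_extra, replace=False))

    taken = set(core) | set(extra)
    remaining = [g for g in gene_ids if g not in taken]
    rng.shuffle(remaining)
    myc = pd.Index(remaining[: config.n_myc_targets])
    baseline = pd.Index(remaining[config.n_myc_targets:
                                  config.n_myc_targets + config.n_baseline_signature_genes])

    # responsive / signature genes need to be expressed for recovery to be
    # power-limited rather than count-limited
    floor = config.responsive_min_base_mean
    bm = pd.Series(base_mean, index=gene_ids)
    for idx in (core, extra, baseline):
        bm.loc[idx] = np.maximum(bm.loc[idx], floor)

    def _signed_lfc(k: int, lo: float, hi: float) -> np.ndarray:
        mag = rng.uniform(lo, hi, size=k)
        sign = np.where(rng.random(k) < config.responsive_up_fraction, 1.0, -1.0)
        return mag * sign

    core_lfc = pd.Series(_signed_lfc(len(core), *config.core_lfc_range), index=core)
    extra_lfc = pd.Series(_signed_lfc(len(extra), *config.extra_lfc_range), index=extra)
    myc_lfc = pd.Series(rng.uniform(config.myc_lfc_range[0], config.myc_lfc_range[1],
                                    size=len(myc)), index=myc)
    base_sign = np.where(np.arange(len(baseline)) % 2 == 0, 1.0, -1.0)
    baseline_lfc = pd.Series(
        rng.uniform(config.baseline_lfc_range[0], config.baseline_lfc_range[1],
                    size=len(baseline)) * base_sign, index=baseline)

    treatment_lfc = {}
    for model in config.model_names:
        lfc = pd.Series(0.0, index=gene_ids)
        lfc.loc[core] = core_lfc
        if model in config.sensitive_models:
            lfc.loc[extra] = extra_lfc
        lfc.loc[myc] = myc_lfc
        treatment_lfc[model] = lfc

    counts = {}
    disp = config.nb_dispersion
    for si, (sid, row) in enumerate(sheet.iterrows()):
        mu = bm.to_numpy() * lib[si]
        if row["arm"] == "DAC":
            mu = mu * 2.0 ** treatment_lfc[row["model"]].to_numpy()
        if row["subgroup"] == "sensitive":
            mu = mu * 2.0 ** baseline_lfc.reindex(gene_ids).fillna(0.0).to_numpy()
        if np.any(mu <= 0):
            raise ValueError("non-positive NB mean")
        counts[sid] = rng.negative_binomial(1.0 / disp, 1.0 / (1.0 + disp * mu))
    count_df = pd.DataFrame(counts, index=gene_ids)

    responsive_rows = []
    for model in config.model_names:
        lfc = treatment_lfc[model]
        for g in lfc.index[lfc != 0]:
            kind = ("myc_target" if g in myc
                    else "core" if g in core else "sensitive_extra")
            responsive_rows.append({"model": model, "gene_id": g,
                                    "log2fc": lfc.loc[g], "kind": kind})
    truth = {
        "responsive": pd.DataFrame(responsive_rows),
        "genes": pd.DataFrame({
            "base_mean": bm,
            "is_core_responsive": bm.index.isin(core),
            "is_sensitive_extra": bm.index.isin(extra),
            "is_myc_target": bm.index.isin(myc),
            "baseline_log2fc": baseline_lfc.reindex(gene_ids).fillna(0.0),
        }),
    }

    gene_sets = {"MYC_TARGETS": list(myc)}
    others = [g for g in gene_ids if g not in set(myc)]
    for i in range(config.n_random_gene_sets):
        gene_sets[f"RANDOM_{i:02d}"] = list(
            rng.choice(others, size=config.random_set_size, replace=False))
    truth["gene_sets"] = gene_sets
    return count_df, sheet, truth


def generate_compartments_and_outcomes(config: CohortConfig,
                                       annotation: ProbeAnnotation) -> dict:
    """Per-sample A/B tracks, survival table and flow-cytometry table.

    Each of the ``n_compartment_samples`` tracks reproduces the true bin
    label with probability ``compartment_concordance``. Survival times are
    exponential with arm-specific scales (treated arms longer-lived, the
    sensitive subgroup more so). The flow table provides bead and cell event
    counts per mouse and day from which absolute counts can be reconstructed.
    """
    rng = _rng(config.seed, "compartments")
    bins = annotation.bins
    truth_labels = bins["label"].to_numpy()
    tracks = []
    for _ in range(config.n_compartment_samples):
        flip = rng.random(len(bins)) >= config.compartment_concordance
        labels = np.where(flip, np.where(truth_labels == "A", "B", "A"), truth_labels)
        t = bins[["chrom", "start", "end"]].copy()
        t["label"] = labels
        tracks.append(t)

    orng = _rng(config.seed, "outcomes")
    scales = {"vehicle": config.survival_scale_vehicle,
              "DAC_1cycle": config.survival_scale_dac1,
              "DAC_2cycle": config.survival_scale_dac2}
    surv_rows = []
    for model in config.model_names:
        mult = (config.sensitive_survival_multiplier
                if model in config.sensitive_models else 1.0)
        for arm in SURVIVAL_ARMS:
            scale = scales[arm] * (mult if arm != "vehicle" else 1.0)
            times = orng.exponential(scale, size=config.mice_per_arm)
            times = np.maximum(times, 0.5)
            censored = orng.random(config.mice_per_arm) < config.censor_prob
            for t, c in zip(times, censored):
                surv_rows.append({"model": model, "arm": arm,
                                  "time_days": round(float(t), 2),
                                  "event": 0 if c else 1})
    survival = pd.DataFrame(surv_rows)

    flow_rows = []
    for model in config.model_names:
        sensitive = model in config.sensitive_models
        growth = {"vehicle": config.vehicle_growth,
                  "DAC": (config.sensitive_treated_growth if sensitive
                          else config.less_treated_growth)}
        for arm in ARMS:
            day1 = orng.lognormal(np.log(config.flow_baseline_cells_per_ul), 0.2,
                                  size=config.mice_per_arm)
            for mouse in range(config.mice_per_arm):
                for day in (1, 5):
                    conc = day1[mouse] if day == 1 else (
                        day1[mouse] * growth[arm] * orng.lognormal(0.0, 0.1))
                    bead_count = max(int(orng.poisson(config.mean_bead_count)), 1)
                    # invert the published bead formula so the intended
                    # concentration is recovered exactly by the readout stage
                    hcd45 = int(round(conc * bead_count * config.cell_volume_ul
                                      * config.bead_concentration_per_ul
                                      / config.bead_volume_ul))
                    depleted = arm == "DAC" and day == 5
                    mcd45 = int(orng.poisson(800.0 * (0.25 if depleted else 1.0)))
                    flow_rows.append({
                        "model": model, "arm": arm, "day": day, "mouse": mouse + 1,
                        "hcd45_count": hcd45, "mcd45_count": mcd45,
                        "bead_count": bead_count,
                        "bead_volume_ul": config.bead_volume_ul,
                        "cell_volume_ul": config.cell_volume_ul,
                        "bead_concentration_per_ul": config.bead_concentration_per_ul,
                    })
    flow = pd.DataFrame(flow_rows)
    return {"tracks": tracks, "consensus_truth": bins.copy(),
            "survival": survival, "flow": flow}


@dataclass
class SyntheticCohort:
    """Everything one seeded generator run produces."""

    config: CohortConfig
    annotation: ProbeAnnotation
    beta: BetaMatrix
    samples: pd.DataFrame
    counts: pd.DataFrame
    beta_truth: dict = field(default_factory=dict)
    counts_truth: dict = field(default_factory=dict)
    gene_sets: Mapping[str, list] = field(default_factory=dict)
    tracks: list = field(default_factory=list)
    consensus_truth: pd.DataFrame | None = None
    survival: pd.DataFrame | None = None
    flow: pd.DataFrame | None = None

    def samples_for(self, model: str | None = None, arm: str | None = None,
                    subgroup: str | None = None) -> list[str]:
        sel = pd.Series(True, index=self.samples.index)
        if model is not None:
            sel &= self.samples["model"] == model
        if arm is not None:
            sel &= self.samples["arm"] == arm
        if subgroup is not None:
            sel &= self.samples["subgroup"] == subgroup
        return list(self.samples.index[sel])


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Run the full generator: annotation, betas, counts, compartments, outcomes."""
    ann = generate_probe_annotation(config)
    beta, sheet, beta_truth = generate_beta_cohort(config, ann)
    counts, _, counts_truth = generate_counts(config, ann, beta_truth)
    comp = generate_compartments_and_outcomes(config, ann)
    return SyntheticCohort(
        config=config, annotation=ann, beta=beta, samples=sheet, counts=counts,
        beta_truth=beta_truth, counts_truth=counts_truth,
        gene_sets=counts_truth["gene_sets"], tracks=comp["tracks"],
        consensus_truth=comp["consensus_truth"], survival=comp["survival"],
        flow=comp["flow"],
    )
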