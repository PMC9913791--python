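"""End-to-end pipeline: generate/load -> QC -> CIMP/EpiTOC -> DM -> DE ->
GSEA -> integration -> compartments -> enrichment -> readouts -> signature.

A run is driven by a :class:`RunConfig` (single key-value YAML file), writes
every stage output under one directory, and records a machine-readable
manifest with per-stage outputs, wall times and SHA-256 checksums. Reruns
with the same config and seed reproduce the checksums of all outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as eio
from .compartments import (assign_features, consensus_compartments,
                           open_chromatin_enrichment)
from .expression import de_test, derive_signature, size_factors
from .gsea import preranked_gsea
from .integration import (build_integration_table, concordance_table,
                          summarize_gene_methylation)
from .methylation import (apply_probe_qc, call_dm, cimp_percentage,
                          epitoc_age, impute_missing_knn)
from .readouts import logrank_test, normalized_tumor_growth, significance_band
from .simulate import ARMS, CohortConfig, SyntheticCohort, generate_cohort


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Thresholds, inputs and bookkeeping for one pipeline run.

    Either ``synthetic`` holds a :class:`CohortConfig` (inputs are generated)
    or ``inputs`` maps the named input files (``beta``, ``detection_p``,
    ``annotation``, ``genes``, ``counts``, ``sample_sheet``, ``tracks`` (list),
    ``survival``, ``flow``, ``gene_sets``).
    """

    outdir: str = "epidac_run"
    seed: int = 0
    synthetic: CohortConfig | None = None
    inputs: dict = field(default_factory=dict)
    detection_alpha: float = 0.05
    delta_beta: float = 0.2
    padj: float = 0.05
    cimp_percent_cutoff: float = 40.0
    methylated_beta: float = 0.3
    signature_fc: float = 1.0
    signature_n: int = 70
    knn_k: int = 10
    gsea_n_perm: int = 500

    def __post_init__(self) -> None:
        if not 0 <= self.detection_alpha <= 1:
            raise ValueError("detection_alpha must lie in [0, 1]")
        if not 0 < self.delta_beta < 1:
            raise ValueError("delta_beta must lie in (0, 1)")
        if not 0 < self.padj <= 1:
            raise ValueError("padj must lie in (0, 1]")
        if not 0 <= self.cimp_percent_cutoff <= 100:
            raise ValueError("cimp_percent_cutoff must lie in [0, 100]")
        if not 0 <= self.methylated_beta <= 1:
            raise ValueError("methylated_beta must lie in [0, 1]")
        if self.signature_n < 1 or self.knn_k < 1 or self.gsea_n_perm < 1:
            raise ValueError("signature_n, knn_k and gsea_n_perm must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if synth is not None:
            cfg.synthetic = CohortConfig(**synth)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        if self.synthetic is not None:
            raw["synthetic"] = self.synthetic.to_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def _load_inputs(cfg: RunConfig) -> SyntheticCohort:
    inputs = cfg.inputs
    for required in ("beta", "annotation", "counts", "sample_sheet"):
        if required not in inputs:
            raise PipelineError(
                f"stage 'load': missing input '{required}' and no synthetic spec present")
    ann = eio.read_annotation(inputs["annotation"], inputs.get("genes"))
    beta = eio.read_beta(inputs["beta"], inputs.get("detection_p"))
    counts = eio.read_matrix(inputs["counts"])
    sheet = pd.read_csv(inputs["sample_sheet"], index_col=0)
    tracks = [eio.read_track(p) for p in inputs.get("tracks", [])]
    survival = pd.read_csv(inputs["survival"]) if "survival" in inputs else None
    flow = pd.read_csv(inputs["flow"]) if "flow" in inputs else None
    gene_sets = eio.read_gmt(inputs["gene_sets"]) if "gene_sets" in inputs else {}
    config = cfg.synthetic or CohortConfig(seed=cfg.seed)
    return SyntheticCohort(config=config, annotation=ann, beta=beta, samples=sheet,
                           counts=counts, gene_sets=gene_sets, tracks=tracks,
                           survival=survival, flow=flow)


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> list[Path]:
    """Write every generated input (and truth table) as plain text."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(path: Path):
        written.append(path)
        return path

    eio.write_beta(cohort.beta, _w(d / "beta.tsv"), _w(d / "detection_p.tsv"))
    eio.write_annotation(cohort.annotation, _w(d / "probe_annotation.tsv"),
                         _w(d / "genes.tsv"))
    eio.write_matrix(cohort.counts, _w(d / "counts.tsv"))
    cohort.samples.to_csv(_w(d / "sample_sheet.csv"))
    for i, t in enumerate(cohort.tracks):
        eio.write_track(t, _w(d / f"compartments_sample{i + 1}.tsv"))
    if cohort.survival is not None:
        cohort.survival.to_csv(_w(d / "survival.csv"), index=False)
    if cohort.flow is not None:
        cohort.flow.to_csv(_w(d / "flow.csv"), index=False)
    if cohort.gene_sets:
        eio.write_gmt(cohort.gene_sets, _w(d / "gene_sets.gmt"))
    truth_dir = d / "truth"
    truth_dir.mkdir(exist_ok=True)
    for name, table in {**cohort.beta_truth,
                        **{k: v for k, v in cohort.counts_truth.items()
                           if isinstance(v, pd.DataFrame)}}.items():
        table.to_csv(_w(truth_dir / f"{name}.tsv"), sep="\t",
                     float_format=eio.FLOAT_FORMAT)
    if cohort.consensus_truth is not None:
        eio.write_track(cohort.consensus_truth, _w(truth_dir / "consensus_truth.tsv"))
    return written


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in dependency order; returns the run manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": [], "checksums": {}}
    outputs: list[Path] = []

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                produced = fn() or []
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - deliberate stage wrapping
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            produced = [Path(p) for p in produced]
            outputs.extend(produced)
            manifest["stages"].append({
                "name": name,
                "outputs": [str(p.relative_to(out)) for p in produced],
                "seconds": round(time.perf_counter() - t0, 3),
            })
        return deco

    cfg.to_yaml(out / "config.yaml")
    outputs.append(out / "config.yaml")

    state: dict = {}

    @stage("inputs")
    def _inputs():
        if cfg.synthetic is not None:
            synth = cfg.synthetic
            if synth.seed != cfg.seed:
                synth = CohortConfig(**{**synth.to_dict(), "seed": cfg.seed})
            state["cohort"] = generate_cohort(synth)
            return write_cohort(state["cohort"], out / "inputs")
        state["cohort"] = _load_inputs(cfg)
        return []

    cohort: SyntheticCohort = state["cohort"]
    res = out / "results"
    res.mkdir(exist_ok=True)
    models = sorted(cohort.samples["model"].unique())
    subgroups = sorted(cohort.samples["subgroup"].unique())

    @stage("qc")
    def _qc():
        state["beta_qc"] = apply_probe_qc(cohort.beta, cohort.annotation,
                                          cfg.detection_alpha)
        path = res / "qc_log.json"
        with open(path, "w") as fh:
            json.dump(state["beta_qc"].qc_log, fh, indent=2, sort_keys=True)
        return [path]

    @stage("impute")
    def _impute():
        state["beta_imputed"] = impute_missing_knn(state["beta_qc"], cfg.knn_k)
        return []

    @stage("cimp")
    def _cimp():
        rows = []
        for sid, meta in cohort.samples.iterrows():
            call = cimp_percentage(state["beta_qc"], cohort.annotation, sid,
                                   cfg.methylated_beta, cfg.cimp_percent_cutoff)
            rows.append({"sample_id": sid, "model": meta["model"], "arm": meta["arm"],
                         "cimp_percent": call.cimp_percent, "cimp_class": call.cimp_class})
        calls = pd.DataFrame(rows).set_index("sample_id")
        path = res / "cimp_calls.csv"
        calls.to_csv(path, float_format=eio.FLOAT_FORMAT)
        state["cimp"] = calls
        return [path]

    @stage("epitoc")
    def _epitoc():
        rows = []
        for sid, meta in cohort.samples.iterrows():
            age = epitoc_age(state["beta_imputed"], cohort.annotation, sid)
            rows.append({"sample_id": sid, "model": meta["model"], "arm": meta["arm"],
                         "epitoc_age": age.age})
        ages = pd.DataFrame(rows).set_index("sample_id")
        path = res / "epitoc_age.csv"
        ages.to_csv(path, float_format=eio.FLOAT_FORMAT)
        state["epitoc"] = ages
        return [path]

    @stage("dm")
    def _dm():
        paths = []
        state["dm"] = {}
        groups = [(m, cohort.samples["model"] == m) for m in models]
        groups += [(f"subgroup_{s}", cohort.samples["subgroup"] == s) for s in subgroups]
        for name, sel in groups:
            treated = cohort.samples.index[sel & (cohort.samples["arm"] == ARMS[1])]
            vehicle = cohort.samples.index[sel & (cohort.samples["arm"] == ARMS[0])]
            dm = call_dm(state["beta_qc"].select_samples(treated),
                         state["beta_qc"].select_samples(vehicle), cfg.delta_beta)
            state["dm"][name] = dm
            p = res / f"dm_{name}.tsv"
            dm.to_csv(p, sep="\t", float_format=eio.FLOAT_FORMAT)
            paths.append(p)
        return paths

    @stage("de")
    def _de():
        paths = []
        state["de"] = {}
        sf_all = size_factors(cohort.counts)
        comparisons = [(m, cohort.samples["model"] == m, "arm", ARMS) for m in models]
        comparisons += [(f"subgroup_{s}", cohort.samples["subgroup"] == s, "arm", ARMS)
                        for s in subgroups]
        if len(subgroups) == 2:
            comparisons.append(("baseline", cohort.samples["arm"] == ARMS[0],
                                "subgroup", ("less_sensitive", "sensitive")))
        for name, sel, col, levels in comparisons:
            samples = cohort.samples.index[sel]
            de = de_test(cohort.counts[list(samples)],
                         cohort.samples.loc[samples, col], levels=levels,
                         sf=sf_all.loc[list(samples)], padj_cutoff=cfg.padj)
            state["de"][name] = de
            p = res / f"de_{name}.tsv"
            de.to_csv(p, sep="\t", float_format=eio.FLOAT_FORMAT)
            paths.append(p)
        return paths

    @stage("gsea")
    def _gsea():
        if not cohort.gene_sets:
            return []
        paths = []
        state["gsea"] = {}
        for name in models:
            ranking = state["de"][name]["stat"]
            result = preranked_gsea(ranking, cohort.gene_sets,
                                    n_perm=cfg.gsea_n_perm, seed=cfg.seed)
            state["gsea"][name] = result
            p = res / f"gsea_{name}.tsv"
            result.to_csv(p, sep="\t", float_format=eio.FLOAT_FORMAT)
            paths.append(p)
        return paths

    @stage("integrate")
    def _integrate():
        paths = []
        rows, joint_up, joint_down = {}, {}, {}
        for name in models + [f"subgroup_{s}" for s in subgroups]:
            gm = summarize_gene_methylation(state["dm"][name], cohort.annotation)
            de = state["de"][name]
            rows[name] = build_integration_table(gm, de, dm=state["dm"][name],
                                                 p_cutoff=cfg.padj)
            if name in models:
                hypo = set(gm.index[gm["n_hypo"] > 0]) & set(de.index)
                sig = de[de["padj"] < cfg.padj]
                joint_up[name] = hypo & set(sig.index[sig["log2fc"] > 0])
                joint_down[name] = hypo & set(sig.index[sig["log2fc"] < 0])
        table = pd.DataFrame(rows).T
        table.index.name = "model"
        per_model = table.loc[models]
        p1 = res / "integration_models.csv"
        per_model.to_csv(p1)
        p2 = res / "integration_subgroups.csv"
        table.loc[[f"subgroup_{s}" for s in subgroups]].to_csv(p2)
        paths += [p1, p2]
        for direction, sets in (("hypo_up", joint_up), ("hypo_down", joint_down)):
            for k in (len(models), len(models) - 1):
                tab = concordance_table(sets, k=max(k, 1))
                p = res / f"concordant_{direction}_k{k}.tsv"
                tab.to_csv(p, sep="\t")
                paths.append(p)
        state["integration"] = table
        return paths

    @stage("compartments")
    def _compartments():
        if not cohort.tracks:
            return []
        consensus = consensus_compartments(cohort.tracks)
        state["consensus"] = consensus
        probes = cohort.annotation.probes.loc[state["beta_qc"].beta.index]
        probe_feat = pd.DataFrame({"chrom": probes["chrom"], "pos": probes["start"]})
        state["probe_labels"] = assign_features(probe_feat, consensus)
        genes = cohort.annotation.genes
        gene_feat = pd.DataFrame({"chrom": genes["chrom"], "pos": genes["tss"]})
        state["gene_labels"] = assign_features(gene_feat, consensus)
        p1 = res / "consensus_compartments.tsv"
        eio.write_track(consensus, p1)
        p2 = res / "feature_compartments.tsv"
        labels = pd.concat([
            state["probe_labels"].rename("label").to_frame().assign(feature="probe"),
            state["gene_labels"].rename("label").to_frame().assign(feature="gene"),
        ])
        labels.index.name = "feature_id"
        labels.to_csv(p2, sep="\t")
        return [p1, p2]

    @stage("enrich")
    def _enrich():
        if "consensus" not in state:
            return []
        rows = []
        bg_probes = state["probe_labels"]
        bg_genes = state["gene_labels"]
        for s in subgroups:
            dm = state["dm"][f"subgroup_{s}"]
            dm_ids = dm.index[dm["is_dm"]]
            et = open_chromatin_enrichment(bg_probes.loc[bg_probes.index.intersection(dm_ids)],
                                           bg_probes)
            rows.append({"feature": "dm_cpg", "subgroup": s, **et.report()})
            de = state["de"][f"subgroup_{s}"]
            deg = de.index[de["is_de"]]
            et = open_chromatin_enrichment(bg_genes.loc[bg_genes.index.intersection(deg)],
                                           bg_genes)
            rows.append({"feature": "deg", "subgroup": s, **et.report()})
        table = pd.DataFrame(rows)
        state["enrichment"] = table
        p = res / "enrichment_table.csv"
        table.to_csv(p, index=False)
        return [p]

    @stage("flow")
    def _flow():
        if cohort.flow is None:
            return []
        rows = []
        for model in models:
            f = cohort.flow[cohort.flow["model"] == model]
            ratio = normalized_tumor_growth(f[f["arm"] == ARMS[1]],
                                            f[f["arm"] == ARMS[0]])
            rows.append({"model": model, "normalized_growth_ratio": ratio})
        table = pd.DataFrame(rows).set_index("model")
        state["growth"] = table
        p = res / "growth_ratios.csv"
        table.to_csv(p, float_format=eio.FLOAT_FORMAT)
        return [p]

    @stage("survival")
    def _survival():
        if cohort.survival is None:
            return []
        rows = []
        surv = cohort.survival
        arms = sorted(surv["arm"].unique())
        for model in sorted(surv["model"].unique()):
            sm = surv[surv["model"] == model]
            for i, a in enumerate(arms):
                for b in arms[i + 1:]:
                    ga = sm[sm["arm"] == a]
                    gb = sm[sm["arm"] == b]
                    stat, p = logrank_test(ga["time_days"], ga["event"],
                                           gb["time_days"], gb["event"])
                    rows.append({"model": model, "arm_a": a, "arm_b": b,
                                 "statistic": stat, "p": p,
                                 "band": significance_band(p)})
        table = pd.DataFrame(rows)
        state["logrank"] = table
        p = res / "survival_logrank.csv"
        table.to_csv(p, index=False, float_format=eio.FLOAT_FORMAT)
        return [p]

    @stage("signature")
    def _signature():
        if "baseline" not in state.get("de", {}):
            return []
        sig = derive_signature(state["de"]["baseline"], cfg.signature_fc,
                               cfg.padj, cfg.signature_n)
        state["signature"] = sig
        p = res / "sensitivity_signature.tsv"
        sig.to_csv(p, sep="\t", float_format=eio.FLOAT_FORMAT)
        return [p]

    for path in outputs:
        manifest["checksums"][str(path.relative_to(out))] = eio.sha256_of(path)
    manifest["checksums"] = dict(sorted(manifest["checksums"].items()))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    state["manifest"] = manifest
    run_pipeline.last_state = state  # convenient handle for interactive use
    return manifest
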