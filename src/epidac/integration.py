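"""Gene-level integration of differential methylation with expression.

A gene is hypomethylated when at least one hypomethylated differentially
methylated probe links to it (probes linking several genes contribute to each
of them). The integration table counts, per model or subgroup, differentially
methylated genes and CpGs by direction, differentially expressed genes by
direction, and their joint sets; cross-model concordance intersects the joint
gene sets across models at a minimum-support threshold k.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .annotation import REGION_CLASSES, ProbeAnnotation


def summarize_gene_methylation(dm: pd.DataFrame, ann: ProbeAnnotation) -> pd.DataFrame:
    """Per-gene tallies of differentially methylated probes by region class.

    ``dm`` is the probe-level Δβ call table (index probe id, columns
    ``delta_beta``, ``is_dm``, ``direction``). Only DM probes contribute;
    genes with no DM probe are absent from the output. DM probes missing from
    the annotation are skipped and counted in ``result.attrs``.

    Returns a DataFrame indexed by gene id with one count column per region
    class (``n_dm_gene_body`` etc.), ``n_hypo``, ``n_hyper`` and
    ``net_direction`` in {hypo, hyper, mixed}.
    """
    dm_probes = dm[dm["is_dm"]]
    n_unannotated = int((~dm_probes.index.isin(ann.links["probe_id"])).sum())
    merged = ann.links.merge(
        dm_probes[["direction"]], left_on="probe_id", right_index=True, how="inner"
    )
    if merged.empty:
        out = pd.DataFrame(columns=[f"n_dm_{rc}" for rc in REGION_CLASSES]
                           + ["n_hypo", "n_hyper", "net_direction"])
        out.attrs["n_dm_probes_unannotated"] = n_unannotated
        return out

    by_region = (merged.groupby(["gene_id", "region_class"]).size()
                 .unstack(fill_value=0).reindex(columns=list(REGION_CLASSES), fill_value=0))
    by_region.columns = [f"n_dm_{rc}" for rc in by_region.columns]
    by_dir = (merged.groupby(["gene_id", "direction"]).size()
              .unstack(fill_value=0).reindex(columns=["hypo", "hyper"], fill_value=0))
    out = by_region.join(by_dir.rename(columns={"hypo": "n_hypo", "hyper": "n_hyper"}))
    out["net_direction"] = "mixed"
    out.loc[(out["n_hypo"] > 0) & (out["n_hyper"] == 0), "net_direction"] = "hypo"
    out.loc[(out["n_hyper"] > 0) & (out["n_hypo"] == 0), "net_direction"] = "hyper"
    out.index.name = "gene_id"
    out.attrs["n_dm_probes_unannotated"] = n_unannotated
    return out


def build_integration_table(gene_methylation: pd.DataFrame, de: pd.DataFrame,
                            dm: pd.DataFrame | None = None,
                            use_raw_p: bool = False,
                            p_cutoff: float = 0.05) -> dict:
    """One row of the per-model integration table.

    ``gene_methylation`` comes from :func:`summarize_gene_methylation`; ``de``
    is the gene-level DE table. Joint counts (hypomethylated and up/down) are
    computed over genes present in the expression data; methylation-only
    counts keep every annotated gene. ``dm`` (probe-level calls) adds the DM
    CpG counts when provided. By default differential expression means
    padj < cutoff; ``use_raw_p`` switches the join to the raw p-value, which
    is how pan-model concordance lists are usually drawn.
    """
    hypo_genes = set(gene_methylation.index[gene_methylation["n_hypo"] > 0])
    hyper_genes = set(gene_methylation.index[gene_methylation["n_hyper"] > 0])
    p_col = "p" if use_raw_p else "padj"
    sig = de[de[p_col] < p_cutoff]
    up = set(sig.index[sig["log2fc"] > 0])
    down = set(sig.index[sig["log2fc"] < 0])
    expressed = set(de.index)
    row = {
        "n_hypo_genes": len(hypo_genes),
        "n_hyper_genes": len(hyper_genes),
        "n_up_genes": len(up),
        "n_down_genes": len(down),
        "n_hypo_and_up": len(hypo_genes & expressed & up),
        "n_hypo_and_down": len(hypo_genes & expressed & down),
    }
    if dm is not None:
        dm_sig = dm[dm["is_dm"]]
        row["n_dm_cpgs_hypo"] = int((dm_sig["direction"] == "hypo").sum())
        row["n_dm_cpgs_hyper"] = int((dm_sig["direction"] == "hyper").sum())
    return row


def cross_model_concordance(model_gene_sets: Mapping[str, set] | Sequence[set],
                            k: int) -> set:
    """Genes supported by at least k of the per-model gene sets."""
    if isinstance(model_gene_sets, Mapping):
        sets = list(model_gene_sets.values())
    else:
        sets = list(model_gene_sets)
    n = len(sets)
    if n < 1:
        raise ValueError("need at least one model")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of models ({n})")
    if k < 1:
        raise ValueError("k must be at least 1")
    support: dict = {}
    for s in sets:
        for g in s:
            support[g] = support.get(g, 0) + 1
    return {g for g, c in support.items() if c >= k}


def concordance_table(model_gene_sets: Mapping[str, set], k: int) -> pd.DataFrame:
    """Concordant genes with their per-model support count (support >= k)."""
    support: dict = {}
    for s in model_gene_sets.values():
        for g in s:
            support[g] = support.get(g, 0) + 1
    rows = [{"gene_id": g, "n_models": c} for g, c in support.items() if c >= k]
    out = pd.DataFrame(rows, columns=["gene_id", "n_models"])
    if len(out):
        out = out.sort_values(["n_models", "gene_id"], ascending=[False, True])
        out = out.set_index("gene_id")
    return out
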