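"""Probe annotation manifest: coordinates, gene links, panels and blacklist.

The manifest mirrors what a methylation-array annotation provides once it has
been matched to an expression annotation: per-probe coordinates (0-based,
half-open), zero or more gene links with a regulatory region class, membership
in the fixed CIMP and EpiTOC CpG panels, and a blacklist reason for probes
that standard array QC removes (multimapping probes, probes with a SNP within
5 bp of the interrogated cytosine, meQTL probes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

REGION_CLASSES = ("gene_body", "promoter", "enhancer")
BLACKLIST_REASONS = ("none", "multimapping", "snp_within_5bp", "meqtl")

PROBE_COLUMNS = ["chrom", "start", "end", "in_cimp_panel", "in_epitoc_panel", "blacklist_reason"]
LINK_COLUMNS = ["probe_id", "gene_id", "region_class"]


@dataclass
class ProbeAnnotation:
    """Per-probe annotation plus a long-format probe-to-gene link table.

    Parameters
    ----------
    probes
        Indexed by probe id; columns ``chrom``, ``start``, ``end``,
        ``in_cimp_panel``, ``in_epitoc_panel``, ``blacklist_reason``.
    links
        Long table with columns ``probe_id``, ``gene_id``, ``region_class``;
        a probe may link to zero, one or several genes (many-to-many).
    genes
        Optional gene coordinate table indexed by gene id with columns
        ``chrom``, ``start``, ``end``, ``tss``.
    """

    probes: pd.DataFrame
    links: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=LINK_COLUMNS))
    genes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in PROBE_COLUMNS if c not in self.probes.columns]
        if missing:
            raise ValueError(f"probe table is missing columns: {missing}")
        if not self.probes.index.is_unique:
            raise ValueError("probe ids must be unique")
        if (self.probes["start"] >= self.probes["end"]).any():
            raise ValueError("probe intervals must satisfy start < end")
        bad = set(self.probes["blacklist_reason"]) - set(BLACKLIST_REASONS)
        if bad:
            raise ValueError(f"unknown blacklist reasons: {sorted(bad)}")
        if len(self.links):
            bad = set(self.links["region_class"]) - set(REGION_CLASSES)
            if bad:
                raise ValueError(f"unknown region classes: {sorted(bad)}")
        both = self.probes["in_cimp_panel"].astype(bool) & self.probes["in_epitoc_panel"].astype(bool)
        if both.any():
            raise ValueError("CIMP and EpiTOC panels must be disjoint")

    @property
    def cimp_probes(self) -> pd.Index:
        return self.probes.index[self.probes["in_cimp_panel"].astype(bool)]

    @property
    def epitoc_probes(self) -> pd.Index:
        return self.probes.index[self.probes["in_epitoc_panel"].astype(bool)]

    @property
    def blacklisted_probes(self) -> pd.Index:
        return self.probes.index[self.probes["blacklist_reason"] != "none"]

    def __len__(self) -> int:
        return len(self.probes)
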