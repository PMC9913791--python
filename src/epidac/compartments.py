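"""Consensus A/B chromatin compartments and open-chromatin enrichment.

Per-sample compartment tracks label fixed-width genomic bins A (active/open)
or B (inactive/closed). The consensus track keeps a label only where every
sample agrees; discordant bins become ``ambiguous`` and are not used further.
Features (CpG probes, genes) are assigned the label of the bin containing
their anchor point; features in ambiguous bins or outside the track are
excluded. Enrichment of a feature set in open chromatin is summarised by a
relative risk: the proportion of the feature set in A divided by the
proportion of the background-minus-feature set in A.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["chrom", "start", "end", "label"]
SAMPLE_LABELS = ("A", "B")
AMBIGUOUS = "ambiguous"
EXCLUDED = "excluded"


def _check_track(track: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRACK_COLUMNS if c not in track.columns]
    if missing:
        raise ValueError(f"track is missing columns: {missing}")
    return track.reset_index(drop=True)


def consensus_compartments(tracks: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Unanimity consensus over per-sample A/B tracks.

    All tracks must share an identical bin grid (no resampling is attempted).
    A bin is A iff every sample calls A, B iff every sample calls B, and
    ``ambiguous`` otherwise. With a single track this is the identity.
    """
    if len(tracks) == 0:
        raise ValueError("need at least one track")
    tracks = [_check_track(t) for t in tracks]
    grid = tracks[0][["chrom", "start", "end"]]
    for t in tracks[1:]:
        if len(t) != len(grid) or not t[["chrom", "start", "end"]].equals(grid):
            raise ValueError("per-sample tracks have different bin grids")
    labels = np.stack([t["label"].to_numpy() for t in tracks])
    bad = set(labels.ravel()) - set(SAMPLE_LABELS)
    if bad:
        raise ValueError(f"per-sample labels must be A or B, found {sorted(bad)}")
    all_a = (labels == "A").all(axis=0)
    all_b = (labels == "B").all(axis=0)
    out = grid.copy()
    out["label"] = np.where(all_a, "A", np.where(all_b, "B", AMBIGUOUS))
    return out


def assign_features(features: pd.DataFrame, consensus: pd.DataFrame,
                    pos_column: str = "pos") -> pd.Series:
    """Label features by the consensus bin containing their anchor point.

    ``features`` needs columns ``chrom`` and ``pos_column`` (the anchor
    coordinate: a probe position or a gene TSS). Features in ambiguous bins,
    outside any bin, or on chromosomes absent from the track are ``excluded``.
    """
    for col in ("chrom", pos_column):
        if col not in features.columns:
            raise ValueError(f"features table is missing column {col!r}")
    pos = features[pos_column]
    if pos.isna().any() or (pos < 0).any():
        raise ValueError("feature anchor positions must be non-negative and defined")
    consensus = _check_track(consensus)
    result = pd.Series(EXCLUDED, index=features.index, dtype=object, name="compartment")
    for chrom, bins in consensus.groupby("chrom", sort=False):
        bins = bins.sort_values("start")
        starts = bins["start"].to_numpy()
        ends = bins["end"].to_numpy()
        labels = bins["label"].to_numpy()
        sel = features["chrom"] == chrom
        if not sel.any():
            continue
        p = features.loc[sel, pos_column].to_numpy()
        idx = np.searchsorted(starts, p, side="right") - 1
        inside = (idx >= 0) & (p < ends[np.clip(idx, 0, len(ends) - 1)])
        lab = np.where(inside, labels[np.clip(idx, 0, len(labels) - 1)], EXCLUDED)
        lab = np.where(lab == AMBIGUOUS, EXCLUDED, lab)
        result.loc[sel] = lab
    return result


def relative_risk(n_open_feature, n_closed_feature,
                  n_open_background, n_closed_background):
    """Open-chromatin relative risk from the four 2x2 cell counts.

    proportion open within the feature set divided by the proportion open
    within the background after removing the feature set. Accepts scalars or
    numpy arrays; undefined ratios come back as NaN.
    """
    of = np.asarray(n_open_feature, dtype=float)
    cf = np.asarray(n_closed_feature, dtype=float)
    eo = np.asarray(n_open_background, dtype=float) - of
    ec = np.asarray(n_closed_background, dtype=float) - cf
    with np.errstate(divide="ignore", invalid="ignore"):
        p_feat = of / (of + cf)
        p_rest = eo / (eo + ec)
        rr = p_feat / p_rest
    return rr if rr.shape else float(rr)


@dataclass(frozen=True)
class EnrichmentTable:
    """2x2 open/closed x feature/background counts with derived statistics.

    Background counts include the feature set; the relative risk compares the
    feature's open proportion with the open proportion of the background
    after excluding the feature.
    """

    n_open_feature: int
    n_closed_feature: int
    n_open_background: int
    n_closed_background: int

    def __post_init__(self) -> None:
        cells = (self.n_open_feature, self.n_closed_feature,
                 self.n_open_background, self.n_closed_background)
        if any(c < 0 for c in cells):
            raise ValueError("cell counts must be non-negative")
        if (self.n_open_feature > self.n_open_background
                or self.n_closed_feature > self.n_closed_background):
            raise ValueError("feature counts exceed background counts; "
                             "the feature set must be a subset of the background")

    @property
    def p_open_feature(self) -> float:
        denom = self.n_open_feature + self.n_closed_feature
        return self.n_open_feature / denom if denom else float("nan")

    @property
    def p_open_background_excl(self) -> float:
        eo = self.n_open_background - self.n_open_feature
        ec = self.n_closed_background - self.n_closed_feature
        return eo / (eo + ec) if (eo + ec) else float("nan")

    @property
    def relative_risk(self) -> float:
        rr = relative_risk(self.n_open_feature, self.n_closed_feature,
                           self.n_open_background, self.n_closed_background)
        return float(rr)

    @property
    def is_defined(self) -> bool:
        return bool(np.isfinite(self.relative_risk))

    def report(self, ndigits: int = 2) -> dict:
        """Rounded summary for tabular reporting; full precision stays internal."""
        return {
            "n_open_feature": self.n_open_feature,
            "n_closed_feature": self.n_closed_feature,
            "n_open_background": self.n_open_background,
            "n_closed_background": self.n_closed_background,
            "p_open_feature": round(self.p_open_feature, ndigits),
            "p_open_background_excl": round(self.p_open_background_excl, ndigits),
            "relative_risk": round(self.relative_risk, ndigits),
        }


def open_chromatin_enrichment(feature_labels: pd.Series,
                              background_labels: pd.Series) -> EnrichmentTable:
    """Build the enrichment table from per-feature compartment labels.

    Both series map feature id -> label in {A, B, excluded}; excluded
    features are ignored. The feature index must be a subset of the
    background index.
    """
    if not feature_labels.index.isin(background_labels.index).all():
        raise ValueError("feature set must be a subset of the background set")
    f = feature_labels[feature_labels.isin(SAMPLE_LABELS)]
    b = background_labels[background_labels.isin(SAMPLE_LABELS)]
    return EnrichmentTable(
        n_open_feature=int((f == "A").sum()),
        n_closed_feature=int((f == "B").sum()),
        n_open_background=int((b == "A").sum()),
        n_closed_background=int((b == "B").sum()),
    )
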