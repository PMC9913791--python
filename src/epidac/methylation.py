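"""Methylation-array profiling on beta-value matrices.

Covers the array side of the analysis: detection-p masking and blacklist
removal, probe-space K-nearest-neighbour imputation, CIMP methylation
percentage and classification, the EpiTOC mitotic-age proxy (mean beta over a
fixed CpG panel), and the Δβ differential-methylation rule (a CpG is
differentially methylated when the absolute difference of group-mean betas
between treated and vehicle arms exceeds a strict threshold, 0.2 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import KNNImputer

from .annotation import ProbeAnnotation

#: default detection p-value above which an entry is treated as missing
DETECTION_ALPHA = 0.05
#: default |Δβ| threshold (strict) for calling a probe differentially methylated
DELTA_BETA_THRESHOLD = 0.2
#: default beta value at or above which a CIMP-panel probe counts as methylated
METHYLATED_BETA_CUTOFF = 0.3
#: CIMP percentage (strictly) above which a sample is CIMP+
CIMP_PERCENT_CUTOFF = 40.0


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with detection p-values.

    Missing entries are encoded as NaN in ``beta``; ``detection_p`` keeps the
    per-entry detection p-values used by QC. ``qc_log`` accumulates counts of
    dropped probes and masked entries across processing steps.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    qc_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.detection_p is None:
            self.detection_p = pd.DataFrame(
                0.0, index=self.beta.index, columns=self.beta.columns
            )
        if self.detection_p.shape != self.beta.shape:
            raise ValueError("beta and detection_p shapes differ")
        if not (self.beta.index.equals(self.detection_p.index)
                and self.beta.columns.equals(self.detection_p.columns)):
            raise ValueError("beta and detection_p must share probe ids and sample ids")
        if not self.beta.index.is_unique:
            raise ValueError("probe ids must be unique")
        if not self.beta.columns.is_unique:
            raise ValueError("sample ids must be unique")
        vals = self.beta.to_numpy(float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                raise ValueError("beta values must lie in [0, 1] where not missing")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.beta.isna()

    def select_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.beta.columns]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return BetaMatrix(self.beta[samples].copy(), self.detection_p[samples].copy(),
                          dict(self.qc_log))


@dataclass(frozen=True)
class CimpCall:
    sample_or_model_id: str
    cimp_percent: float
    cimp_class: str  # "CIMP_plus" | "CIMP_minus"
    n_probes_evaluated: int


@dataclass(frozen=True)
class EpitocAge:
    sample_id: str
    age: float
    n_probes: int


def apply_probe_qc(bm: BetaMatrix, ann: ProbeAnnotation,
                   detection_alpha: float = DETECTION_ALPHA) -> BetaMatrix:
    """Mask failed detections and drop blacklisted probes.

    Entries with detection p-value strictly greater than ``detection_alpha``
    become missing (an entry at exactly the cutoff is retained). Probes with a
    non-``none`` blacklist reason, and probes absent from the annotation, are
    dropped entirely. Idempotent: a second application is a no-op.
    """
    common = bm.beta.index.intersection(ann.probes.index)
    if len(common) == 0:
        raise ValueError("no overlap between beta-matrix probes and annotation probes")
    n_unannotated = len(bm.beta.index) - len(common)
    reasons = ann.probes.loc[common, "blacklist_reason"]
    keep = common[reasons == "none"]
    n_blacklisted = len(common) - len(keep)

    beta = bm.beta.loc[keep]
    detp = bm.detection_p.loc[keep]
    masked = beta.where(detp <= detection_alpha)
    n_masked = int((masked.isna() & beta.notna()).to_numpy().sum())

    log = dict(bm.qc_log)
    log.update({
        "detection_alpha": detection_alpha,
        "n_probes_in": int(len(bm.beta.index)),
        "n_probes_dropped_unannotated": int(n_unannotated),
        "n_probes_dropped_blacklist": int(n_blacklisted),
        "n_entries_masked_detection": int(n_masked) + int(log.get("n_entries_masked_detection", 0)),
        "n_probes_out": int(len(keep)),
    })
    return BetaMatrix(masked, detp.copy(), log)


def impute_missing_knn(bm: BetaMatrix, k: int = 10) -> BetaMatrix:
    """Impute missing betas from the k nearest probes.

    Distance between probes is the (NaN-aware) Euclidean distance over the
    samples where both probes have values; each missing entry becomes the mean
    of the k nearest probes with a value in that sample. Output is complete and
    clipped to [0, 1].
    """
    all_missing = bm.beta.index[bm.beta.isna().all(axis=1)]
    if len(all_missing):
        raise ValueError(
            f"probe(s) missing in all samples cannot be imputed: {list(all_missing[:5])}"
        )
    n_complete = int(bm.beta.notna().all(axis=1).sum())
    if n_complete < k + 1:
        raise ValueError(
            f"need at least k+1={k + 1} probes with complete data, found {n_complete}"
        )
    n_missing = int(bm.beta.isna().to_numpy().sum())
    if n_missing == 0:
        return BetaMatrix(bm.beta.copy(), bm.detection_p.copy(), dict(bm.qc_log))
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(bm.beta.to_numpy(float))
    filled = np.clip(filled, 0.0, 1.0)
    beta = pd.DataFrame(filled, index=bm.beta.index, columns=bm.beta.columns)
    log = dict(bm.qc_log)
    log.update({"knn_k": k, "n_entries_imputed": n_missing})
    return BetaMatrix(beta, bm.detection_p.copy(), log)


def cimp_percentage(bm: BetaMatrix, ann: ProbeAnnotation, sample: str,
                    methylated_cutoff: float = METHYLATED_BETA_CUTOFF,
                    percent_cutoff: float = CIMP_PERCENT_CUTOFF) -> CimpCall:
    """CIMP methylation percentage and classification for one sample.

    The percentage is 100 x (#CIMP-panel probes with beta >= cutoff) /
    (#CIMP-panel probes with a value); the sample is CIMP+ iff the percentage
    is strictly greater than ``percent_cutoff`` (default 40).
    """
    panel = ann.cimp_probes.intersection(bm.beta.index)
    values = bm.beta.loc[panel, sample].dropna()
    if len(values) == 0:
        raise ValueError("CIMP panel is empty after QC; percentage undefined")
    percent = 100.0 * float((values >= methylated_cutoff).mean())
    cls = "CIMP_plus" if percent > percent_cutoff else "CIMP_minus"
    return CimpCall(sample, percent, cls, len(values))


def classify_cimp(percent: float, percent_cutoff: float = CIMP_PERCENT_CUTOFF) -> str:
    """Classify a CIMP methylation percentage (CIMP+ iff strictly > cutoff)."""
    return "CIMP_plus" if percent > percent_cutoff else "CIMP_minus"


def epitoc_age(bm: BetaMatrix, ann: ProbeAnnotation, sample: str) -> EpitocAge:
    """Mitotic-age proxy: arithmetic mean beta over the EpiTOC panel probes.

    Requires a complete (imputed) matrix over the panel — imputation is a
    stated precondition, so residual missing values raise.
    """
    panel = ann.epitoc_probes.intersection(bm.beta.index)
    if len(panel) == 0:
        raise ValueError("EpiTOC panel is empty; age undefined")
    values = bm.beta.loc[panel, sample]
    if values.isna().any():
        raise ValueError(
            "missing values in EpiTOC panel; impute before computing mitotic age"
        )
    return EpitocAge(sample, float(values.mean()), len(values))


def call_dm(treated: BetaMatrix, vehicle: BetaMatrix,
            threshold: float = DELTA_BETA_THRESHOLD) -> pd.DataFrame:
    """Δβ differential-methylation calls between treated and vehicle arms.

    Δβ is the available-case mean over treated samples minus the mean over
    vehicle samples. A probe is differentially methylated iff |Δβ| is strictly
    greater than ``threshold``; direction is ``hypo`` for negative Δβ. Probes
    with no value in either arm are excluded (count in ``result.attrs``).

    Returns a DataFrame indexed by probe id with columns ``delta_beta``,
    ``is_dm`` and ``direction``.
    """
    if set(treated.beta.index) != set(vehicle.beta.index):
        raise ValueError("treated and vehicle arms must share the same probe set")
    if treated.beta.shape[1] < 1 or vehicle.beta.shape[1] < 1:
        raise ValueError("each arm needs at least one sample")
    v = vehicle.beta.loc[treated.beta.index]
    t_mean = treated.beta.mean(axis=1)
    v_mean = v.mean(axis=1)
    delta = t_mean - v_mean
    ok = delta.notna()
    delta = delta[ok]
    out = pd.DataFrame({
        "delta_beta": delta,
        "is_dm": delta.abs() > threshold,
        "direction": np.where(delta < 0, "hypo", "hyper"),
    })
    out.attrs["n_excluded_no_data"] = int((~ok).sum())
    out.attrs["threshold"] = threshold
    return out


def correlate_age_vs_cimp(pairs: Iterable[tuple]) -> float:
    """Pearson correlation between EpiTOC age and CIMP methylation percentage.

    ``pairs`` is an iterable of (EpitocAge, CimpCall) or plain
    (age, percent) tuples; needs at least 3 pairs and nonzero variance in both
    coordinates.
    """
    ages, percents = [], []
    for a, c in pairs:
        ages.append(a.age if isinstance(a, EpitocAge) else float(a))
        percents.append(c.cimp_percent if isinstance(c, CimpCall) else float(c))
    if len(ages) < 3:
        raise ValueError("need at least 3 (age, CIMP%) pairs")
    if np.ptp(ages) == 0 or np.ptp(percents) == 0:
        raise ValueError("correlation undefined: zero variance in age or CIMP%")
    r, _ = stats.pearsonr(ages, percents)
    return float(r)
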