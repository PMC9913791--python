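"""Pre-clinical readouts: bead-corrected counts, tumor growth, survival.

Flow-cytometry counting beads added to a fixed blood volume convert gated
hCD45+ event counts into absolute cells per microliter, correcting for the
leukocyte depletion the treatment induces. Tumor growth is summarised as the
day-5/day-1 ratio of mean absolute counts, normalised between treated and
vehicle arms. Survival is compared with the Kaplan-Meier product-limit
estimator and the log-rank (Mantel-Cox) test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

FLOW_COLUMNS = ["model", "arm", "day", "hcd45_count", "mcd45_count", "bead_count",
                "bead_volume_ul", "cell_volume_ul", "bead_concentration_per_ul"]


def absolute_cell_count(cell_count: float, bead_count: float,
                        bead_volume_ul: float, cell_volume_ul: float,
                        bead_concentration_per_ul: float,
                        formula: str = "as_published") -> float:
    """Absolute cells per microliter from counting-bead flow data.

    ``as_published`` follows the study's printed expression exactly:
    (cell_count x bead_volume) / (bead_count x cell_volume x concentration).
    ``standard`` is the conventional bead-counting form in which the bead
    concentration multiplies rather than divides:
    (cell_count / bead_count) x (bead_volume x concentration) / cell_volume.
    Both are offered because the printed form's units do not reduce to
    cells/uL in the usual way; neither is asserted as the intended one.
    """
    if bead_count <= 0:
        raise ValueError("bead_count must be positive (zero signals staining failure)")
    if bead_volume_ul <= 0 or cell_volume_ul <= 0 or bead_concentration_per_ul <= 0:
        raise ValueError("volumes and bead concentration must be positive")
    if formula == "as_published":
        return (cell_count * bead_volume_ul) / (
            bead_count * cell_volume_ul * bead_concentration_per_ul
        )
    if formula == "standard":
        return (cell_count * bead_volume_ul * bead_concentration_per_ul) / (
            bead_count * cell_volume_ul
        )
    raise ValueError(f"unknown formula {formula!r}")


def _mean_absolute_count(records: pd.DataFrame, formula: str) -> float:
    counts = [
        absolute_cell_count(r.hcd45_count, r.bead_count, r.bead_volume_ul,
                            r.cell_volume_ul, r.bead_concentration_per_ul,
                            formula=formula)
        for r in records.itertuples()
    ]
    return float(np.mean(counts))


def normalized_tumor_growth(treated: pd.DataFrame, vehicle: pd.DataFrame,
                            day_start: int = 1, day_end: int = 5,
                            formula: str = "as_published") -> float:
    """Treated-to-vehicle ratio of day-end/day-start tumor growth.

    Both inputs are flow tables (schema ``FLOW_COLUMNS``) for one arm each;
    growth per arm is mean absolute hCD45+ count on ``day_end`` divided by the
    mean on ``day_start``, on bead-corrected counts.
    """
    ratios = []
    for arm in (treated, vehicle):
        start = arm[arm["day"] == day_start]
        end = arm[arm["day"] == day_end]
        if start.empty or end.empty:
            raise ValueError(f"missing day-{day_start} or day-{day_end} records")
        denom = _mean_absolute_count(start, formula)
        if denom <= 0:
            raise ValueError("day-start mean absolute count must be positive")
        ratios.append(_mean_absolute_count(end, formula) / denom)
    return ratios[0] / ratios[1]


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival curve.

    Returns a step function as a DataFrame with columns ``time`` and
    ``survival``, starting at (0, 1). Censored records (event=0) reduce the
    risk set without forcing a step.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one record")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    out = sf.reset_index()
    out.columns = ["time", "survival"]
    return out


def logrank_statistic(time_a, event_a, time_b, event_b) -> float:
    """Log-rank (Mantel-Cox) chi-square statistic with 1 df.

    Sums observed-minus-expected events in arm A over the pooled distinct
    event times, with the usual hypergeometric variance.
    """
    ta = np.asarray(time_a, float); ea = np.asarray(event_a, int)
    tb = np.asarray(time_b, float); eb = np.asarray(event_b, int)
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    group = np.concatenate([np.zeros(len(ta), int), np.ones(len(tb), int)])
    if events.sum() == 0:
        raise ValueError("need at least one event")
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & (group == 0)).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return float(o_minus_e ** 2 / var)


def logrank_test(time_a, event_a, time_b, event_b,
                 p_method: str = "chi2", n_perm: int = 10000,
                 seed: int | None = None) -> tuple[float, float]:
    """Log-rank test between two arms; returns (statistic, two-sided p).

    ``p_method='chi2'`` uses the 1-df chi-square reference (the conventional
    Mantel-Cox p). ``p_method='permutation'`` estimates the p-value by
    randomly reassigning arm labels ``n_perm`` times, which is preferable at
    very small arm sizes where the chi-square approximation is rough.
    """
    ta = np.asarray(time_a, float); ea = np.asarray(event_a, int)
    tb = np.asarray(time_b, float); eb = np.asarray(event_b, int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both arms must be non-empty")
    stat = logrank_statistic(ta, ea, tb, eb)
    if p_method == "chi2":
        return stat, float(stats.chi2.sf(stat, df=1))
    if p_method == "permutation":
        rng = np.random.default_rng(seed)
        times = np.concatenate([ta, tb])
        events = np.concatenate([ea, eb])
        n_a = len(ta)
        exceed = 0
        for _ in range(n_perm):
            idx = rng.permutation(len(times))
            a = idx[:n_a]
            b = idx[n_a:]
            s = logrank_statistic(times[a], events[a], times[b], events[b])
            # small tolerance keeps exact ties (common at these arm sizes)
            # on the exceedance side regardless of summation order
            if s >= stat - 1e-12:
                exceed += 1
        return stat, (exceed + 1) / (n_perm + 1)
    raise ValueError(f"unknown p_method {p_method!r}")


def significance_band(p: float) -> str:
    """Prism-style significance band: ns, *, ** or ***."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
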