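"""Strength-of-preference analysis of two-choice playback sessions.

A focal fish swims in a tank with playback electrodes at both ends (physical
sections A and E).  Zone B is the preference zone next to A, zone D the one
next to E, and zone C is neutral.  Because the side carrying each stimulus
is interchanged between playback intervals, zone times are first mapped onto
stimulus identity ("side-unswapping") and then summed; the strength of
preference for stimulus 1 is

    SOP = (t_B - t_D) / (t_B + t_D)

with t_B / t_D the total time next to stimulus 1 / stimulus 2.  SOP ranges
from -1 (complete avoidance) to +1 (complete preference).  Responsiveness is
the total time spent outside the neutral zone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multicomp import pairwise_tukeyhsd
import statsmodels.formula.api as smf

__all__ = [
    "ZoneInterval",
    "PreferenceSession",
    "SOPResult",
    "compute_sop",
    "preference_test",
    "condition_comparison",
    "responsiveness_comparison",
    "read_sessions",
    "write_sessions",
    "sop_table",
]

CONDITIONS = ("I", "II", "III", "IV", "V")

#: Seconds of slack allowed when checking that zone times fit the interval.
_TIME_TOLERANCE_S = 1.0


@dataclass
class ZoneInterval:
    """Zone occupancy of one playback interval, in the physical tank frame."""

    side_of_stimulus1: str            # 'A' or 'E': which end carried stimulus 1
    t_zone_b_s: float
    t_zone_c_s: float
    t_zone_d_s: float
    length_s: float = 120.0

    def __post_init__(self) -> None:
        if self.side_of_stimulus1 not in ("A", "E"):
            raise ValueError("side_of_stimulus1 must be 'A' or 'E'")
        times = (self.t_zone_b_s, self.t_zone_c_s, self.t_zone_d_s)
        if any(t < 0 for t in times):
            raise ValueError("zone times must be non-negative")
        if sum(times) > self.length_s + _TIME_TOLERANCE_S:
            raise ValueError(
                f"zone times sum to {sum(times):.1f} s, exceeding the "
                f"{self.length_s:.0f}-s interval"
            )

    def stimulus_times(self) -> tuple[float, float]:
        """(time near stimulus 1, time near stimulus 2) after side-unswapping."""
        if self.side_of_stimulus1 == "A":
            return self.t_zone_b_s, self.t_zone_d_s
        return self.t_zone_d_s, self.t_zone_b_s


@dataclass
class PreferenceSession:
    """All playback intervals of one focal fish in one condition."""

    focal_id: str
    condition: str
    intervals: list[ZoneInterval]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("session has no playback intervals")


@dataclass
class SOPResult:
    sop: float                  # NaN when undefined
    t_b_total: float            # total seconds near stimulus 1
    t_d_total: float            # total seconds near stimulus 2
    responsiveness: float       # seconds outside the neutral zone
    defined: bool


def compute_sop(session: PreferenceSession) -> SOPResult:
    """Session-level SOP over summed, side-unswapped zone times.

    When the fish never enters either preference zone the index is
    undefined; the result is flagged and should be excluded from group
    tests.
    """
    tb = td = 0.0
    for interval in session.intervals:
        t1, t2 = interval.stimulus_times()
        tb += t1
        td += t2
    responsiveness = tb + td
    if responsiveness == 0:
        return SOPResult(float("nan"), tb, td, 0.0, defined=False)
    return SOPResult((tb - td) / (tb + td), tb, td, responsiveness, defined=True)


def preference_test(sops: Sequence[float]) -> dict:
    """One-sample t-test of SOP values against the no-preference value 0."""
    values = np.asarray([s for s in sops if not math.isnan(s)], dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 defined SOP values")
    if values.std(ddof=1) == 0:
        return {
            "mean_sop": float(values.mean()),
            "statistic": float("nan"),
            "pvalue": float("nan"),
            "n": int(values.size),
            "degenerate": True,
        }
    statistic, pvalue = stats.ttest_1samp(values, 0.0)
    return {
        "mean_sop": float(values.mean()),
        "statistic": float(statistic),
        "pvalue": float(pvalue),
        "n": int(values.size),
        "degenerate": False,
    }


def _sop_transform(sop: np.ndarray, transform: str) -> np.ndarray:
    """Variance-stabilizing transform of SOP values in [-1, 1]."""
    if transform == "arcsin":
        return np.arcsin(sop)
    if transform == "arcsin_sqrt":
        return np.arcsin(np.sqrt((sop + 1.0) / 2.0))
    raise ValueError(f"unknown SOP transform {transform!r}")


def _rm_anova(long: pd.DataFrame, depvar: str) -> dict:
    """Repeated-measures ANOVA of ``depvar`` across conditions.

    Uses the classical within-subject ANOVA when every fish was tested in
    every condition; with missing cells it falls back to a mixed model with
    a random intercept per fish (Wald test on the condition terms) and
    emits a warning.
    """
    counts = long.groupby("focal_id")["condition"].nunique()
    n_cond = long["condition"].nunique()
    complete = bool((counts == n_cond).all()) and not long.duplicated(
        ["focal_id", "condition"]
    ).any()
    if complete:
        fit = AnovaRM(long, depvar=depvar, subject="focal_id", within=["condition"]).fit()
        row = fit.anova_table.iloc[0]
        return {
            "method": "repeated_measures_anova",
            "statistic": float(row["F Value"]),
            "pvalue": float(row["Pr > F"]),
            "df": (float(row["Num DF"]), float(row["Den DF"])),
        }
    warnings.warn(
        "unbalanced or incomplete sessions; fitting a mixed model on available cases",
        stacklevel=3,
    )
    model = smf.mixedlm(f"{depvar} ~ C(condition)", long, groups=long["focal_id"])
    fit = model.fit(reml=False)
    terms = [name for name in fit.params.index if name.startswith("C(condition)")]
    wald = fit.wald_test(" = ".join(terms) + " = 0" if len(terms) > 1 else terms[0] + " = 0",
                         scalar=True)
    return {
        "method": "mixed_model_wald",
        "statistic": float(wald.statistic),
        "pvalue": float(wald.pvalue),
        "df": None,
    }


def condition_comparison(
    sessions: Sequence[PreferenceSession],
    transform: str = "arcsin",
    tukey_alpha: float = 0.05,
) -> dict:
    """Compare SOP across playback conditions within the same focal fish.

    SOP values are arcsine-transformed (``transform="arcsin_sqrt"`` maps
    (SOP+1)/2 through arcsin-of-square-root instead), the omnibus test is a
    repeated-measures ANOVA with fish as the repeated factor, and Tukey's
    HSD provides the pairwise comparisons.  Sessions with undefined SOP are
    dropped.
    """
    rows = []
    for s in sessions:
        res = compute_sop(s)
        if res.defined:
            rows.append({"focal_id": s.focal_id, "condition": s.condition, "sop": res.sop})
    long = pd.DataFrame(rows)
    if long.empty or long["condition"].nunique() < 2:
        raise ValueError("need sessions from at least 2 conditions")
    long["sop_t"] = _sop_transform(long["sop"].to_numpy(), transform)
    omnibus = _rm_anova(long, "sop_t")
    tukey = pairwise_tukeyhsd(long["sop_t"], long["condition"], alpha=tukey_alpha)
    tukey_frame = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return {
        "omnibus": omnibus,
        "tukey": tukey_frame,
        "transform": transform,
        "n_sessions": int(len(long)),
        "condition_means": long.groupby("condition")["sop"].mean().to_dict(),
    }


def responsiveness_comparison(
    sessions: Sequence[PreferenceSession],
    transform: str = "sqrt",
) -> dict:
    """Compare time outside the neutral zone across conditions.

    Durations are square-root transformed by default (the conventional
    variance stabilizer for time data); ``transform="square"`` applies a
    literal square instead.  Zero times pass through either transform.
    """
    rows = []
    for s in sessions:
        res = compute_sop(s)
        rows.append(
            {"focal_id": s.focal_id, "condition": s.condition, "resp": res.responsiveness}
        )
    long = pd.DataFrame(rows)
    if long.empty or long["condition"].nunique() < 2:
        raise ValueError("need sessions from at least 2 conditions")
    if transform == "sqrt":
        long["resp_t"] = np.sqrt(long["resp"])
    elif transform == "square":
        long["resp_t"] = long["resp"] ** 2
    else:
        raise ValueError(f"unknown responsiveness transform {transform!r}")
    omnibus = _rm_anova(long, "resp_t")
    return {
        "omnibus": omnibus,
        "transform": transform,
        "n_sessions": int(len(long)),
        "condition_means": long.groupby("condition")["resp"].mean().to_dict(),
    }


# ---------------------------------------------------------------------------
# session log I/O

_COLUMNS = [
    "focal_id",
    "condition",
    "interval_index",
    "side_of_stimulus1",
    "t_zoneB_s",
    "t_zoneC_s",
    "t_zoneD_s",
]


def read_sessions(path) -> list[PreferenceSession]:
    """Read per-interval zone-occupancy logs from CSV."""
    frame = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"session log is missing columns {missing}")
    sessions = []
    for (focal_id, condition), grp in frame.groupby(["focal_id", "condition"], sort=False):
        grp = grp.sort_values("interval_index")
        intervals = [
            ZoneInterval(
                side_of_stimulus1=str(row.side_of_stimulus1),
                t_zone_b_s=float(row.t_zoneB_s),
                t_zone_c_s=float(row.t_zoneC_s),
                t_zone_d_s=float(row.t_zoneD_s),
            )
            for row in grp.itertuples()
        ]
        sessions.append(PreferenceSession(str(focal_id), str(condition), intervals))
    return sessions


def write_sessions(sessions: Sequence[PreferenceSession], path) -> None:
    rows = []
    for s in sessions:
        for i, iv in enumerate(s.intervals):
            rows.append(
                {
                    "focal_id": s.focal_id,
                    "condition": s.condition,
                    "interval_index": i,
                    "side_of_stimulus1": iv.side_of_stimulus1,
                    "t_zoneB_s": iv.t_zone_b_s,
                    "t_zoneC_s": iv.t_zone_c_s,
                    "t_zoneD_s": iv.t_zone_d_s,
                }
            )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def sop_table(sessions: Sequence[PreferenceSession]) -> pd.DataFrame:
    """Per-session SOP summary table."""
    rows = []
    for s in sessions:
        res = compute_sop(s)
        rows.append(
            {
                "focal_id": s.focal_id,
                "condition": s.condition,
                "sop": res.sop,
                "t_b_total_s": res.t_b_total,
                "t_d_total_s": res.t_d_total,
                "responsiveness_s": res.responsiveness,
                "defined": res.defined,
            }
        )
    return pd.DataFrame(rows)
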