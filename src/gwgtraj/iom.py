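"""WHO pre-pregnancy BMI categories and IOM 2009 gestational weight-gain compliance.

The 2009 Institute of Medicine guidelines recommend a total gestational weight
gain (GWG) range per WHO pre-pregnancy BMI (ppBMI) category:

=============  ===============  =================
category       ppBMI (kg/m^2)   total gain (kg)
=============  ===============  =================
underweight    < 18.5           12.5 - 18
normal         18.5 - 24.9      11.5 - 16
overweight     25 - 29.9        7 - 11.5
obese          >= 30            5 - 9
=============  ===============  =================

Compliance is assessed before term by projecting the recommended *total* window
back to the gestational age of a mid-pregnancy weighing.  Two projection modes
are provided:

``interpolation`` (default)
    Each bound is linearly interpolated between a first-trimester anchor of
    0.5-2 kg at 13 completed weeks and the total window at 40 weeks, so the
    window at 40 weeks is exactly the recommended total range.
``rate``
    Each bound grows from the first-trimester anchor at the IOM second/third
    trimester weekly rate for the category.

A woman whose observed gain at the visit falls below / within / above the
projected window is labelled L / N / H for that trimester (bounds inclusive,
i.e. a gain exactly on a bound counts as within the guidelines).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BMICategory",
    "IOMWindow",
    "GainClassification",
    "TransitionTable",
    "ExclusionError",
    "IOM_WINDOWS",
    "who_category",
    "projected_window",
    "classify_gain",
    "classify_cohort",
    "transition_table",
    "gdm_from_glucose",
]

# Trimester boundaries in completed weeks: T1 <= 13, T2 = 14-27, T3 >= 28.
T2_RANGE = (14, 27)
T3_START = 28

#: Gestational-age range over which a window can be projected (weeks).
GA_MIN, GA_MAX = 13.0, 42.0

_ANCHOR_WEEK = 13.0  # end of first trimester
_TERM_WEEK = 40.0


class BMICategory(str, enum.Enum):
    """WHO ppBMI category."""

    UNDERWEIGHT = "underweight"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESE = "obese"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Ordered categories, lightest first.
CATEGORY_ORDER: tuple[BMICategory, ...] = (
    BMICategory.UNDERWEIGHT,
    BMICategory.NORMAL,
    BMICategory.OVERWEIGHT,
    BMICategory.OBESE,
)

# Half-open ppBMI intervals [lo, hi) per category.
_BMI_BOUNDS = {
    BMICategory.UNDERWEIGHT: (0.0, 18.5),
    BMICategory.NORMAL: (18.5, 25.0),
    BMICategory.OVERWEIGHT: (25.0, 30.0),
    BMICategory.OBESE: (30.0, math.inf),
}


@dataclass(frozen=True)
class IOMWindow:
    """Recommended gain bounds for one ppBMI category.

    ``total_lo``/``total_hi`` are the recommended total gain at term (kg),
    ``t1_lo``/``t1_hi`` the first-trimester anchor (kg at 13 weeks), and
    ``rate_lo``/``rate_hi`` the recommended weekly gain rates for the second
    and third trimesters (kg/week).
    """

    category: BMICategory
    total_lo: float
    total_hi: float
    t1_lo: float = 0.5
    t1_hi: float = 2.0
    rate_lo: float = 0.0
    rate_hi: float = 0.0

    def __post_init__(self) -> None:
        if not self.total_lo < self.total_hi:
            raise ValueError("total_lo must be < total_hi")


IOM_WINDOWS: dict[BMICategory, IOMWindow] = {
    BMICategory.UNDERWEIGHT: IOMWindow(
        BMICategory.UNDERWEIGHT, 12.5, 18.0, rate_lo=0.44, rate_hi=0.58
    ),
    BMICategory.NORMAL: IOMWindow(
        BMICategory.NORMAL, 11.5, 16.0, rate_lo=0.35, rate_hi=0.50
    ),
    BMICategory.OVERWEIGHT: IOMWindow(
        BMICategory.OVERWEIGHT, 7.0, 11.5, rate_lo=0.23, rate_hi=0.33
    ),
    BMICategory.OBESE: IOMWindow(
        BMICategory.OBESE, 5.0, 9.0, rate_lo=0.17, rate_hi=0.27
    ),
}


class ExclusionError(ValueError):
    """A record lacks the data needed for classification.

    Mirrors the cohort flow-chart exclusions (no ppBMI / no weight in the
    requested trimester): callers catch this and report the woman in the
    exclusion accounting rather than in any analysis table.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def who_category(ppbmi: float) -> BMICategory:
    """Classify a pre-pregnancy BMI (kg/m^2) into its WHO category.

    Boundaries follow the WHO convention: 18.5 -> normal, 25 -> overweight,
    30 -> obese.
    """
    if not np.isfinite(ppbmi) or ppbmi <= 0:
        raise ValueError(f"ppbmi must be positive and finite, got {ppbmi!r}")
    for cat in CATEGORY_ORDER:
        lo, hi = _BMI_BOUNDS[cat]
        if lo <= ppbmi < hi:
            return cat
    raise AssertionError("unreachable")  # pragma: no cover


def who_category_vector(ppbmi: np.ndarray) -> np.ndarray:
    """Vectorised :func:`who_category`; returns an object array of categories."""
    ppbmi = np.asarray(ppbmi, dtype=float)
    edges = [18.5, 25.0, 30.0]
    idx = np.searchsorted(edges, ppbmi, side="right")
    out = np.array(CATEGORY_ORDER, dtype=object)[idx]
    bad = ~np.isfinite(ppbmi) | (ppbmi <= 0)
    if bad.any():
        raise ValueError("ppbmi must be positive and finite for all subjects")
    return out


def projected_window(
    category: BMICategory, ga_weeks: float, mode: str = "interpolation"
) -> tuple[float, float]:
    """Project the IOM gain window (kg) for ``category`` to ``ga_weeks``.

    In ``interpolation`` mode each bound moves linearly from the 13-week
    anchor to the printed total window at 40 weeks (and keeps that slope up
    to 42 weeks); in ``rate`` mode it grows at the IOM weekly rate.
    """
    if not (GA_MIN <= ga_weeks <= GA_MAX):
        raise ValueError(f"ga_weeks must be in [{GA_MIN}, {GA_MAX}], got {ga_weeks}")
    w = IOM_WINDOWS[BMICategory(category)]
    dt = ga_weeks - _ANCHOR_WEEK
    if mode == "interpolation":
        span = _TERM_WEEK - _ANCHOR_WEEK
        lo = w.t1_lo + (w.total_lo - w.t1_lo) * dt / span
        hi = w.t1_hi + (w.total_hi - w.t1_hi) * dt / span
    elif mode == "rate":
        lo = w.t1_lo + w.rate_lo * dt
        hi = w.t1_hi + w.rate_hi * dt
    else:
        raise ValueError(f"unknown projection mode {mode!r}")
    return lo, hi


@dataclass(frozen=True)
class GainClassification:
    """Low/Normal/High label of an observed gain against the projected window."""

    trimester: str  # "T2" or "T3"
    label: str  # "L", "N" or "H"
    observed_gain: float
    ga_weeks: float
    window_at_ga: tuple[float, float]
    mode: str = "interpolation"


def _label(gain: float, lo: float, hi: float) -> str:
    # Bounds inclusive: a gain exactly on a bound is within guidelines.
    if gain < lo:
        return "L"
    if gain > hi:
        return "H"
    return "N"


def classify_gain(record, trimester: str, mode: str = "interpolation") -> GainClassification:
    """Classify one woman's weight gain in ``trimester`` ("T2" or "T3").

    ``record`` needs ``pre_pregnancy_weight``, ``ppbmi`` and a ``visits``
    sequence of ``(gestational_age_weeks, weight_kg)`` pairs; attribute or
    mapping access both work.  If several visits fall in the trimester the
    latest is used (closest to the projection horizon).

    Raises
    ------
    ExclusionError
        If the pre-pregnancy weight, ppBMI or a visit in the trimester is
        missing — the record should be counted as excluded.
    """

    def get(name):
        if isinstance(record, Mapping):
            return record.get(name)
        return getattr(record, name, None)

    prepreg = get("pre_pregnancy_weight")
    ppbmi = get("ppbmi")
    visits = get("visits")
    if prepreg is None or not np.isfinite(prepreg):
        raise ExclusionError("missing pre-pregnancy weight")
    if ppbmi is None or not np.isfinite(ppbmi):
        raise ExclusionError("missing ppBMI")
    if trimester == "T2":
        in_tri = lambda ga: T2_RANGE[0] <= ga <= T2_RANGE[1]
    elif trimester == "T3":
        in_tri = lambda ga: ga >= T3_START
    else:
        raise ValueError(f"trimester must be 'T2' or 'T3', got {trimester!r}")
    candidates = [
        (ga, wt)
        for ga, wt in (visits or [])
        if np.isfinite(ga) and np.isfinite(wt) and in_tri(ga)
    ]
    if not candidates:
        raise ExclusionError(f"no weight measurement in {trimester}")
    ga, wt = max(candidates, key=lambda v: v[0])
    gain = wt - prepreg
    lo, hi = projected_window(who_category(ppbmi), ga, mode=mode)
    return GainClassification(trimester, _label(gain, lo, hi), gain, ga, (lo, hi), mode)


def classify_cohort(cohort: pd.DataFrame, mode: str = "interpolation") -> pd.DataFrame:
    """Classify every woman of a wide cohort table for T2 and T3.

    Expects the canonical wide schema (``id``, ``pre_pregnancy_weight``,
    ``ppbmi``, ``ga_t2``, ``wt_t2``, ``ga_t3``, ``wt_t3``).  Returns a frame
    indexed like ``cohort`` with columns ``category``, ``t2_label``,
    ``t3_label`` (NaN where unclassifiable), per-trimester gains and windows,
    and ``exclusion`` (empty string when the woman is fully classifiable).
    """
    out = pd.DataFrame(index=cohort.index)
    ppbmi = cohort["ppbmi"].to_numpy(dtype=float)
    prepreg = cohort["pre_pregnancy_weight"].to_numpy(dtype=float)
    ok_base = np.isfinite(ppbmi) & (ppbmi > 0) & np.isfinite(prepreg)
    cat = np.empty(len(cohort), dtype=object)
    cat[ok_base] = who_category_vector(ppbmi[ok_base])
    cat[~ok_base] = None
    out["category"] = [c.value if c is not None else None for c in cat]
    reasons = np.where(ok_base, "", "missing ppBMI or pre-pregnancy weight")

    for tri, ga_col, wt_col in (("t2", "ga_t2", "wt_t2"), ("t3", "ga_t3", "wt_t3")):
        ga = cohort[ga_col].to_numpy(dtype=float)
        wt = cohort[wt_col].to_numpy(dtype=float)
        if tri == "t2":
            in_tri = (ga >= T2_RANGE[0]) & (ga <= T2_RANGE[1])
        else:
            in_tri = ga >= T3_START
        ok = ok_base & np.isfinite(ga) & np.isfinite(wt) & in_tri
        gain = np.where(ok, wt - prepreg, np.nan)
        lo = np.full(len(cohort), np.nan)
        hi = np.full(len(cohort), np.nan)
        for c in CATEGORY_ORDER:
            sel = ok & (cat == c)
            if sel.any():
                lo_c, hi_c = zip(*(projected_window(c, g, mode=mode) for g in ga[sel]))
                lo[sel] = lo_c
                hi[sel] = hi_c
        label = np.where(
            ok,
            np.where(gain < lo, "L", np.where(gain > hi, "H", "N")),
            None,
        )
        out[f"{tri}_gain"] = gain
        out[f"{tri}_ga"] = np.where(ok, ga, np.nan)
        out[f"{tri}_lo"] = lo
        out[f"{tri}_hi"] = hi
        out[f"{tri}_label"] = label
        miss = ok_base & ~ok
        reasons = np.where(
            miss,
            np.where(
                reasons == "",
                f"no weight measurement in {tri.upper()}",
                reasons + f"; no weight measurement in {tri.upper()}",
            ),
            reasons,
        )
    out["exclusion"] = reasons
    out["mode"] = mode
    return out


LABELS = ("L", "N", "H")


@dataclass
class TransitionTable:
    """T2 -> T3 compliance transitions with the normalisation strata.

    ``counts`` is the 3x3 L/N/H table (rows = T2, columns = T3).  ``strata``
    splits the T2H row into women who stayed above guidelines (T3H) versus
    those who came back within or below them (T3N or T3L), and the T2N row
    into women who stayed within/below versus those who moved above, each
    with its share of the row total and of the full cohort.
    """

    counts: pd.DataFrame
    n: int
    strata: dict = field(default_factory=dict)

    def cell(self, t2: str, t3: str) -> int:
        return int(self.counts.loc[t2, t3])


def transition_table(
    labels_t2: Iterable[str], labels_t3: Iterable[str]
) -> TransitionTable:
    """Cross-tabulate per-woman T2 and T3 labels and derive the strata shares."""
    t2 = np.asarray(list(labels_t2), dtype=object)
    t3 = np.asarray(list(labels_t3), dtype=object)
    if t2.shape != t3.shape:
        raise ValueError("labels_t2 and labels_t3 must have equal length")
    counts = pd.DataFrame(0, index=list(LABELS), columns=list(LABELS), dtype=int)
    for a in LABELS:
        for b in LABELS:
            counts.loc[a, b] = int(np.sum((t2 == a) & (t3 == b)))
    n = int(counts.to_numpy().sum())

    def _stratum(row: str, stay: str) -> dict:
        row_total = int(counts.loc[row].sum())
        stay_n = int(counts.loc[row, stay])
        move_n = row_total - stay_n
        pct = lambda num, den: 100.0 * num / den if den else float("nan")
        return {
            "row_total": row_total,
            "stayed": {"n": stay_n, "pct_of_row": pct(stay_n, row_total),
                       "pct_of_total": pct(stay_n, n)},
            "changed": {"n": move_n, "pct_of_row": pct(move_n, row_total),
                        "pct_of_total": pct(move_n, n)},
        }

    strata = {
        # T2H: stayed above (T3H) vs normalised (T3N or T3L)
        "T2H": _stratum("H", "H"),
        # T2N: moved above (T3H) vs stayed within/below
        "T2N": {
            "row_total": int(counts.loc["N"].sum()),
            "stayed": {
                "n": int(counts.loc["N", "N"] + counts.loc["N", "L"]),
                "pct_of_row": (
                    100.0 * (counts.loc["N", "N"] + counts.loc["N", "L"])
                    / counts.loc["N"].sum()
                    if counts.loc["N"].sum()
                    else float("nan")
                ),
            },
            "changed": {
                "n": int(counts.loc["N", "H"]),
                "pct_of_row": (
                    100.0 * counts.loc["N", "H"] / counts.loc["N"].sum()
                    if counts.loc["N"].sum()
                    else float("nan")
                ),
            },
        },
    }
    return TransitionTable(counts=counts, n=n, strata=strata)


# 50 g glucose challenge test (GCT) / 75 g OGTT decision rule.
GCT_POSITIVE = 10.3  # mmol/L, GDM regardless of OGTT
GCT_OGTT_ZONE = (7.8, 10.2)  # mmol/L, OGTT required
OGTT_THRESHOLDS = (5.3, 10.6, 9.0)  # mmol/L at 0, 1 and 2 h


def gdm_from_glucose(
    gct: float, ogtt: Sequence[float] | None = None
) -> bool | None:
    """Gestational-diabetes decision from screening glucose values.

    GDM is positive if the 50 g challenge result is >= 10.3 mmol/L, or if the
    challenge falls in the 7.8-10.2 mmol/L zone and any 75 g OGTT value at
    0/1/2 h meets its 5.3/10.6/9.0 mmol/L threshold.  A challenge in the OGTT
    zone without OGTT values is indeterminate and returns ``None`` (never a
    negative diagnosis).
    """
    if gct is None or not np.isfinite(gct) or gct < 0:
        raise ValueError(f"invalid GCT value {gct!r}")
    if gct >= GCT_POSITIVE:
        return True
    if gct >= GCT_OGTT_ZONE[0]:  # 7.8 <= gct < 10.3: confirmation zone
        if ogtt is None:
            return None
        if len(ogtt) != 3:
            raise ValueError("ogtt must provide (fasting, 1 h, 2 h) values")
        return any(v >= thr for v, thr in zip(ogtt, OGTT_THRESHOLDS))
    return False
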