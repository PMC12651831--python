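"""F-18 decay arithmetic, treatment windows and sequential target ordering.

A PET-linac refuses delivery once the target's activity concentration decays
below 5 kBq/mL, so every target carries a *treatment window*: the time from
the reference measurement until AC crosses the floor.  With one radiation
source, multiple targets are treated sequentially, which turns scheduling
into single-machine scheduling with deadlines — solved optimally (for
feasibility) by earliest-deadline-first ordering.  Counter-intuitively, a
large low-uptake target can have a *shorter* window than a small hot one and
should then be treated first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AC_MIN_KBQ_ML = 5.0


@dataclass(frozen=True)
class Radionuclide:
    name: str
    halflife_min: float

    def __post_init__(self) -> None:
        if self.halflife_min <= 0:
            raise ValueError("halflife must be positive")


#: fluorine-18, the PET radionuclide in FDG
F18 = Radionuclide("F-18", 109.8)


@dataclass
class TreatmentTarget:
    """A deliverable target: reference AC and expected delivery duration."""

    id: str
    ac0_kbq_ml: float
    delivery_min: float = 25.0
    window_min: float | None = None

    def __post_init__(self) -> None:
        if self.ac0_kbq_ml <= 0:
            raise ValueError("ac0 must be positive")
        if self.delivery_min <= 0:
            raise ValueError("delivery duration must be positive")


def treatment_window(
    ac0: float,
    ac_min: float = AC_MIN_KBQ_ML,
    halflife_min: float = F18.halflife_min,
) -> float:
    """Minutes until exponential decay takes ``ac0`` below ``ac_min``.

    Zero when the target is already at or below the floor; otherwise
    ``(halflife / ln 2) * ln(ac0 / ac_min)``.
    """
    if ac0 <= 0 or ac_min <= 0:
        raise ValueError("activity concentrations must be positive")
    if halflife_min <= 0:
        raise ValueError("halflife must be positive")
    if ac0 <= ac_min:
        return 0.0
    return halflife_min / math.log(2.0) * math.log(ac0 / ac_min)


# ---------------------------------------------------------------------------
# AC-vs-SUVmax model and the treatment-window table
# ---------------------------------------------------------------------------

@dataclass
class LinearACModel:
    """Per-size linear fits of planning AC against measured SUVmax.

    ``coeffs`` maps sphere diameter (mm) to ``(slope, intercept, suv_hi)``
    where ``suv_hi`` is the largest SUVmax observed for that size.  The
    linear response is trusted up to ``extrapolation_factor * suv_hi``;
    beyond that the prediction is withheld (None) rather than extrapolated —
    sub-centimetre targets never reach high SUVmax in the measured data, so
    their high-uptake cells are unknowable.
    """

    coeffs: Mapping[float, tuple[float, float, float]]
    extrapolation_factor: float = 1.3

    def predict(self, size_mm: float, suvmax: float) -> float | None:
        if size_mm not in self.coeffs:
            raise KeyError(f"no AC model for size {size_mm} mm")
        slope, intercept, suv_hi = self.coeffs[size_mm]
        if suvmax > self.extrapolation_factor * suv_hi + 1e-9:
            return None
        return slope * suvmax + intercept


def fit_ac_model(rows: pd.DataFrame | Iterable[Mapping]) -> LinearACModel:
    """Least-squares AC-vs-SUVmax line per target size.

    ``rows`` needs columns/keys ``size_mm``, ``suvmax`` and ``ac_kbq_ml`` —
    typically the per-configuration output of the phantom study.
    """
    df = pd.DataFrame(rows)
    coeffs = {}
    for size, grp in df.groupby("size_mm"):
        if len(grp) < 2:
            raise ValueError(f"need >= 2 observations per size, got {len(grp)} for {size}")
        slope, intercept = np.polyfit(grp["suvmax"], grp["ac_kbq_ml"], 1)
        coeffs[float(size)] = (float(slope), float(intercept), float(grp["suvmax"].max()))
    return LinearACModel(coeffs)


DEFAULT_SUV_BINS = ((5, 7), (8, 12), (13, 17), (18, 22), (23, 27), (28, 32))


def window_table(
    ac_model: LinearACModel,
    sizes_mm: Sequence[float] = (8, 9, 11, 13, 16, 20),
    suv_bins: Sequence[tuple[float, float]] = DEFAULT_SUV_BINS,
    ac_min: float = AC_MIN_KBQ_ML,
    halflife_min: float = F18.halflife_min,
    rounding_h: float = 0.5,
) -> pd.DataFrame:
    """Maximum treatment window (hours) per size and SUVmax bin.

    Each cell evaluates the AC model at the bin midpoint and rounds the decay
    window *down* to the nearest ``rounding_h`` hours (a delivery slot must
    fit entirely inside the window).  Cells where the model predicts
    AC <= floor, or where the bin lies outside the model's measured SUVmax
    domain, are NaN (not available).
    """
    index = [f"{lo}-{hi}" for lo, hi in suv_bins]
    table = pd.DataFrame(index=index, columns=[f"{s} mm" for s in sizes_mm], dtype=float)
    for (lo, hi), label in zip(suv_bins, index):
        mid = (lo + hi) / 2.0
        for s in sizes_mm:
            ac = ac_model.predict(s, mid)
            if ac is None or ac <= ac_min:
                table.loc[label, f"{s} mm"] = np.nan
                continue
            minutes = treatment_window(ac, ac_min, halflife_min)
            hours = math.floor(minutes / 60.0 / rounding_h) * rounding_h
            table.loc[label, f"{s} mm"] = hours
    return table


# ---------------------------------------------------------------------------
# sequential multi-target scheduling
# ---------------------------------------------------------------------------

def _windows(targets: Sequence[TreatmentTarget], ac_min, halflife_min) -> list[float]:
    return [
        t.window_min
        if t.window_min is not None
        else treatment_window(t.ac0_kbq_ml, ac_min, halflife_min)
        for t in targets
    ]


def sequence_targets(
    targets: Sequence[TreatmentTarget],
    ac_min: float = AC_MIN_KBQ_ML,
    halflife_min: float = F18.halflife_min,
    setup_min: float = 0.0,
) -> tuple[list[str], bool, list[dict]]:
    """Earliest-deadline-first ordering with a feasibility verdict.

    The schedule is feasible when every prefix of deliveries finishes inside
    the window of its last target; EDF is feasibility-optimal for this
    problem, so an infeasible EDF order means no order is feasible.
    Returns ``(ordered ids, feasible, timeline)`` where the timeline lists
    start/end times and the AC remaining at each start.
    """
    if not targets:
        raise ValueError("need at least one target")
    wins = _windows(targets, ac_min, halflife_min)
    order = sorted(range(len(targets)), key=lambda i: (wins[i], targets[i].id))
    t = 0.0
    feasible = True
    timeline = []
    for k, i in enumerate(order):
        if k > 0:
            t += setup_min
        start, end = t, t + targets[i].delivery_min
        ok = end <= wins[i]
        feasible &= ok
        timeline.append(
            {
                "id": targets[i].id,
                "start_min": start,
                "end_min": end,
                "window_min": wins[i],
                "ac_at_start_kbq_ml": targets[i].ac0_kbq_ml
                * 2.0 ** (-start / halflife_min),
                "within_window": ok,
            }
        )
        t = end
    return [targets[i].id for i in order], feasible, timeline


def feasible_by_exhaustion(
    targets: Sequence[TreatmentTarget],
    ac_min: float = AC_MIN_KBQ_ML,
    halflife_min: float = F18.halflife_min,
    setup_min: float = 0.0,
) -> bool:
    """Brute-force feasibility over all permutations (small n only)."""
    if len(targets) > 8:
        raise ValueError("exhaustive check is limited to n <= 8")
    wins = _windows(targets, ac_min, halflife_min)
    for perm in permutations(range(len(targets))):
        t = 0.0
        ok = True
        for k, i in enumerate(perm):
            if k > 0:
                t += setup_min
            t += targets[i].delivery_min
            if t > wins[i]:
                ok = False
                break
        if ok:
            return True
    return False
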