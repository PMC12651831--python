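"""Volume x SUVmax eligibility scoring, confusion statistics and bootstrap.

The deliverability of a small PET-avid target on a PET-linac is governed by
its total detectable signal, which scales with the product of activity
concentration (reflected by SUVmax) and volume.  The screening criterion is

    ``volume_cc * SUVmax > 11``   (strict),

with an equivalent diameter form ``d_cm**3 * SUVmax > 21`` for spherical
lesions (21 = 11 * 6 / pi, rounded).  This module scores lesion records
against such criteria, evaluates them against planning outcomes as confusion
matrices, finds accuracy-optimal thresholds on a candidate grid, and
quantifies threshold uncertainty with a non-parametric bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

#: candidate thresholds used for optimisation: 100 points on [4, 35]
DEFAULT_THRESHOLD_GRID = np.linspace(4.0, 35.0, 100)

CSV_COLUMNS = ["id", "volume_cc", "suvmax", "ac_kbq_ml", "nts", "planned_ok"]


@dataclass
class LesionRecord:
    """One lesion: PET-avid volume, SUVmax and the planning outcome label."""

    id: str
    volume_cc: float
    suvmax: float
    ac_kbq_ml: float | None = None
    nts: float | None = None
    planned_ok: bool | None = None

    def __post_init__(self) -> None:
        if self.volume_cc <= 0:
            raise ValueError("volume_cc must be positive")
        if self.suvmax <= 0:
            raise ValueError("suvmax must be positive")


@dataclass
class Criterion:
    """Eligibility rule: ``form`` selects the score, threshold is strict.

    Forms: ``product`` (volume_cc * SUVmax, default threshold 11),
    ``diameter`` (d_cm**3 * SUVmax, default threshold 21) and ``suvmax``
    (the conventional SUVmax-only rule, default threshold 6).
    """

    form: str = "product"
    threshold: float | None = None

    _DEFAULTS = {"product": 11.0, "diameter": 21.0, "suvmax": 6.0}

    def __post_init__(self) -> None:
        if self.form not in self._DEFAULTS:
            raise ValueError(f"unknown criterion form: {self.form}")
        if self.threshold is None:
            self.threshold = self._DEFAULTS[self.form]
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    def score(self, record: LesionRecord) -> float:
        if self.form == "product":
            return product_score(record.volume_cc, record.suvmax)
        if self.form == "diameter":
            return diameter_score(diameter_from_volume(record.volume_cc), record.suvmax)
        return record.suvmax


@dataclass
class ConfusionStats:
    """Counts and proportions of a binary screening rule vs planning outcome.

    Positive class = planning succeeded.  Zero-denominator proportions are
    reported as None, not 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float | None = field(init=False)
    sensitivity: float | None = field(init=False)
    specificity: float | None = field(init=False)

    def __post_init__(self) -> None:
        total = self.tp + self.fp + self.tn + self.fn
        self.accuracy = (self.tp + self.tn) / total if total else None
        pos = self.tp + self.fn
        self.sensitivity = self.tp / pos if pos else None
        neg = self.tn + self.fp
        self.specificity = self.tn / neg if neg else None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


@dataclass
class BootstrapResult:
    """Distribution of accuracy-optimal thresholds over bootstrap resamples."""

    n_boot: int
    grid: np.ndarray
    optimal_per_sample: np.ndarray
    mean: float
    ci95: tuple[float, float]
    tie_rule: str
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "n_boot": self.n_boot,
            "grid_min": float(self.grid.min()),
            "grid_max": float(self.grid.max()),
            "grid_size": int(self.grid.size),
            "mean": self.mean,
            "ci95": list(self.ci95),
            "tie_rule": self.tie_rule,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def product_score(volume_cc: float, suvmax: float) -> float:
    """Volume (cc) times SUVmax."""
    if volume_cc <= 0 or suvmax <= 0:
        raise ValueError("volume_cc and suvmax must be positive")
    return volume_cc * suvmax


def eligible(score: float, criterion: Criterion) -> bool:
    """Strict comparison against the criterion threshold."""
    return score > criterion.threshold


def diameter_score(d_cm: float, suvmax: float) -> float:
    """Cubed maximum diameter (cm) times SUVmax."""
    if d_cm <= 0 or suvmax <= 0:
        raise ValueError("d_cm and suvmax must be positive")
    return d_cm**3 * suvmax


def convert_threshold(volume_threshold: float) -> tuple[float, int]:
    """Translate a Volume x SUVmax threshold to the d**3 x SUVmax form.

    For a sphere V = (pi/6) d**3, so d**3 * SUVmax = (6/pi) * V * SUVmax.
    Returns the raw converted value and its integer rounding.
    """
    raw = volume_threshold * 6.0 / math.pi
    return raw, round(raw)


def diameter_from_volume(volume_cc: float) -> float:
    """Diameter in cm of a sphere of the given volume in cc."""
    if volume_cc <= 0:
        raise ValueError("volume_cc must be positive")
    return (6.0 * volume_cc / math.pi) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(records: Sequence[LesionRecord], criterion: Criterion) -> ConfusionStats:
    """Confusion matrix of criterion eligibility vs the planning outcome."""
    records = list(records)
    if not records:
        raise ValueError("no records to evaluate")
    if any(r.planned_ok is None for r in records):
        raise ValueError("every record needs a planned_ok label")
    tp = fp = tn = fn = 0
    for r in records:
        pred = eligible(criterion.score(r), criterion)
        if r.planned_ok:
            tp, fn = (tp + 1, fn) if pred else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if pred else (fp, tn + 1)
    return ConfusionStats(tp=tp, fp=fp, tn=tn, fn=fn)


def _accuracy_matrix(products: np.ndarray, ok: np.ndarray, grid: np.ndarray) -> np.ndarray:
    preds = products[:, None] > grid[None, :]
    return (preds == ok[:, None]).mean(axis=0)


def optimal_threshold(
    records: Sequence[LesionRecord],
    grid: np.ndarray | None = None,
    tie_rule: str = "lowest",
    rng: np.random.Generator | None = None,
) -> float:
    """Grid threshold maximising the accuracy of ``product > t``.

    Ties are resolved by taking the lowest tied threshold (clinical-utility
    convention) or a uniformly random tied threshold (``tie_rule='random'``,
    the more conservative estimate of threshold uncertainty).
    """
    grid = DEFAULT_THRESHOLD_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("threshold grid must be sorted")
    products = np.array([product_score(r.volume_cc, r.suvmax) for r in records])
    ok = np.array([bool(r.planned_ok) for r in records])
    acc = _accuracy_matrix(products, ok, grid)
    best = acc.max()
    ties = np.flatnonzero(acc == best)
    if tie_rule == "lowest":
        return float(grid[ties[0]])
    if tie_rule == "random":
        rng = rng or np.random.default_rng()
        return float(grid[rng.choice(ties)])
    raise ValueError(f"unknown tie_rule: {tie_rule}")


def bootstrap_threshold(
    records: Sequence[LesionRecord],
    n_boot: int = 1000,
    grid: np.ndarray | None = None,
    seed: int | None = None,
    tie_rule: str = "lowest",
    exclude_ids: Iterable[str] | None = None,
) -> BootstrapResult:
    """Bootstrap distribution of the accuracy-optimal product threshold.

    ``n_boot`` resamples with replacement at the cohort size; per sample the
    optimal threshold on the candidate grid is retained; the 95% CI is the
    empirical 2.5th/97.5th percentile interval.  ``exclude_ids`` drops known
    outlier lesions (for example elevated-background-shell failures) before
    resampling.
    """
    grid = DEFAULT_THRESHOLD_GRID if grid is None else np.asarray(grid, dtype=float)
    if exclude_ids is not None:
        excl = set(exclude_ids)
        records = [r for r in records if r.id not in excl]
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 records to bootstrap")
    products = np.array([product_score(r.volume_cc, r.suvmax) for r in records])
    ok = np.array([bool(r.planned_ok) for r in records])
    n = len(records)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    preds = products[idx][:, :, None] > grid[None, None, :]
    acc = (preds == ok[idx][:, :, None]).mean(axis=1)  # (n_boot, n_grid)
    if tie_rule == "lowest":
        opt = grid[np.argmax(acc, axis=1)]
    elif tie_rule == "random":
        best = acc.max(axis=1, keepdims=True)
        # random tie-break: perturb tied entries by random keys
        keys = rng.random(acc.shape)
        keys[acc < best] = -1.0
        opt = grid[np.argmax(keys, axis=1)]
    else:
        raise ValueError(f"unknown tie_rule: {tie_rule}")
    lo, hi = np.percentile(opt, [2.5, 97.5])
    return BootstrapResult(
        n_boot=n_boot,
        grid=grid,
        optimal_per_sample=opt,
        mean=float(opt.mean()),
        ci95=(float(lo), float(hi)),
        tie_rule=tie_rule,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# record I/O
# ---------------------------------------------------------------------------

def records_to_csv(records: Sequence[LesionRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "id": r.id,
                "volume_cc": r.volume_cc,
                "suvmax": r.suvmax,
                "ac_kbq_ml": r.ac_kbq_ml,
                "nts": r.nts,
                "planned_ok": r.planned_ok,
            }
            for r in records
        ],
        columns=CSV_COLUMNS,
    )
    df.to_csv(path, index=False)


def records_from_csv(path) -> list[LesionRecord]:
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"lesion table is missing column(s): {', '.join(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            LesionRecord(
                id=str(row["id"]),
                volume_cc=float(row["volume_cc"]),
                suvmax=float(row["suvmax"]),
                ac_kbq_ml=None if pd.isna(row["ac_kbq_ml"]) else float(row["ac_kbq_ml"]),
                nts=None if pd.isna(row["nts"]) else float(row["nts"]),
                planned_ok=None if pd.isna(row["planned_ok"]) else bool(row["planned_ok"]),
            )
        )
    return records
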