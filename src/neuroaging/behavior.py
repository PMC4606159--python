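"""Behavioral endpoints: avoidance learning, freezing, startle, Barnes, open field.

Implements the scalar endpoints of a mouse sensorimotor/learning battery:

* two-way active avoidance — per-block outcome percentages (blocks of 20
  trials) and the learning slope, an ordinary least-squares fit of the
  percentage of avoidance per block of 5 trials against block index;
* fear conditioning — freezing as the percentage of 0.5 s observation
  intervals whose motion index stays below threshold (default 20 artificial
  units) throughout, plus shock reactivity from 2 s motion bins around the
  unconditioned stimulus;
* acoustic startle — trial amplitude as the mean of 65 one-ms accelerometer
  readings and the per-animal amplitude/intensity regression slope;
* Barnes maze probe — exploration-bout preference for the target hole over
  the 19 nontarget holes;
* open-field locomotion — percentage of infrared beam breaks in the arena
  center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Phase",
    "MotionTrace",
    "BlockSummary",
    "SlopeResult",
    "BeamBreakRecord",
    "MOTION_THRESHOLD",
    "block_percentages",
    "avoidance_slope",
    "freezing_percent",
    "shock_reactivity",
    "startle_slope",
    "barnes_probe_profile",
    "percent_center",
]

OUTCOMES = ("avoid", "escape", "failure")

#: Default freezing motion threshold in the tracker's artificial units.
MOTION_THRESHOLD = 20.0


@dataclass(frozen=True)
class Phase:
    """A named, contiguous span of a session (baseline, CS, UCS, post...)."""

    name: str
    start: float
    end: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"phase {self.name}: end must exceed start")


@dataclass(frozen=True)
class MotionTrace:
    """Motion-index values on a contiguous observation-interval grid.

    ``values`` holds one motion index per observation interval (``interval``
    seconds wide, default grid 0.5 s); interval k spans
    [k*interval, (k+1)*interval).  ``phases`` annotate session epochs.
    """

    values: np.ndarray
    interval: float = 0.5
    phases: tuple[Phase, ...] = ()
    motion_threshold: float = MOTION_THRESHOLD

    def __post_init__(self):
        if self.motion_threshold <= 0:
            raise ValueError("motion_threshold must be positive")
        object.__setattr__(self, "values", np.asarray(self.values, float))

    @property
    def duration(self) -> float:
        return len(self.values) * self.interval

    def phase_slice(self, name: str) -> np.ndarray:
        """Values of the intervals lying wholly inside the named phase."""
        for ph in self.phases:
            if ph.name == name:
                starts = np.arange(len(self.values)) * self.interval
                sel = (starts >= ph.start - 1e-9) & (starts + self.interval <= ph.end + 1e-9)
                return self.values[sel]
        raise KeyError(f"unknown phase {name!r}; have {[p.name for p in self.phases]}")


# ---------------------------------------------------------------------------
# active avoidance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlockSummary:
    """Outcome percentages for one block of consecutive trials."""

    block: int
    block_size: int
    pct_avoid: float
    pct_escape: float
    pct_failure: float
    partial: bool = False


@dataclass(frozen=True)
class SlopeResult:
    """An ordinary least-squares fit of an endpoint against an ordinal axis."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


def _check_trials(trials: pd.DataFrame):
    if len(trials) == 0:
        raise ValueError("empty trial table")
    bad = set(trials["outcome"]) - set(OUTCOMES)
    if bad:
        raise ValueError(f"unknown outcomes: {bad}")


def block_percentages(trials: pd.DataFrame, block_size: int = 20) -> list[BlockSummary]:
    """Outcome percentages per block of ``block_size`` consecutive trials.

    Outcomes are exhaustive and exclusive, so the three percentages sum to
    exactly 100 in every block (the failure percentage is computed as the
    complement, which keeps closure exact in floating point).  A final
    partial block, if the trial count is not divisible, is returned with
    ``partial=True``.
    """
    _check_trials(trials)
    out = []
    outcomes = trials["outcome"].to_numpy()
    for b, lo in enumerate(range(0, len(outcomes), block_size), start=1):
        chunk = outcomes[lo: lo + block_size]
        n = len(chunk)
        pa = 100.0 * np.count_nonzero(chunk == "avoid") / n
        pe = 100.0 * np.count_nonzero(chunk == "escape") / n
        # complement of the rounded sum: pa + pe + pf == 100 exactly in
        # floating point for any block size, including partial blocks
        pf = 100.0 - (pa + pe)
        out.append(BlockSummary(b, n, pa, pe, pf, partial=n < block_size))
    return out


def avoidance_slope(trials: pd.DataFrame, block_size: int = 5) -> SlopeResult:
    """Learning slope: OLS of % avoidance per block of 5 on block index.

    Blocks are indexed 1..k (a 100-trial session gives 20 blocks of 5); the
    slope is in percent avoidance per block.  Partial final blocks are
    excluded from the fit.
    """
    blocks = [b for b in block_percentages(trials, block_size) if not b.partial]
    if len(blocks) < 2:
        raise ValueError("need at least 2 complete blocks for a slope")
    x = np.array([b.block for b in blocks], float)
    y = np.array([b.pct_avoid for b in blocks])
    fit = sps.linregress(x, y)
    r2 = fit.rvalue**2 if np.ptp(y) > 0 else 1.0  # exact fit of constant data
    return SlopeResult(float(fit.slope), float(fit.intercept), float(r2), len(blocks))


# ---------------------------------------------------------------------------
# fear conditioning
# ---------------------------------------------------------------------------


def freezing_percent(trace: MotionTrace, phase: str | None = None) -> float:
    """Percentage of observation intervals spent freezing.

    An interval registers freezing iff its motion index stays below the
    motion threshold throughout the interval; the result is
    100 * frozen / total over the intervals of ``phase`` (or the whole trace).
    """
    values = trace.values if phase is None else trace.phase_slice(phase)
    if values.size == 0:
        raise ValueError(f"phase {phase!r} contains no complete interval")
    frozen = values < trace.motion_threshold
    return 100.0 * np.count_nonzero(frozen) / frozen.size


def shock_reactivity(trace: MotionTrace, ucs_times: list[float],
                     bin_width: float = 2.0, n_baseline_bins: int = 5) -> tuple[float, float]:
    """Pre-shock baseline vs during-shock motion, averaged across trials.

    For each unconditioned-stimulus onset, the motion index is collapsed to
    ``bin_width``-second bins aligned to the onset; the baseline is the mean
    of the ``n_baseline_bins`` bins immediately preceding it, the response
    the mean during the shock bin.  Values are averaged across the shock
    trials (two, in a standard training session).
    """
    if not ucs_times:
        raise ValueError("no UCS onsets annotated")
    per_bin = int(round(bin_width / trace.interval))
    if per_bin < 1:
        raise ValueError("bin_width below the observation interval")
    pres, durs = [], []
    for t0 in ucs_times:
        i0 = int(round(t0 / trace.interval))
        lo = i0 - n_baseline_bins * per_bin
        hi = i0 + per_bin
        if lo < 0 or hi > len(trace.values):
            raise ValueError(f"UCS at {t0} s lacks {n_baseline_bins} baseline bins in record")
        base = trace.values[lo:i0].reshape(n_baseline_bins, per_bin).mean(axis=1)
        pres.append(base.mean())
        durs.append(trace.values[i0:hi].mean())
    return float(np.mean(pres)), float(np.mean(durs))


# ---------------------------------------------------------------------------
# acoustic startle
# ---------------------------------------------------------------------------


def startle_slope(table: pd.DataFrame) -> SlopeResult:
    """OLS slope of startle amplitude on stimulus intensity (dB above background).

    NOSTIM (no-stimulus) trials never enter the fit.  Amplitude is the mean
    of the 65 per-ms readings; if reading columns ``r0``..``r64`` are present
    the amplitude is recomputed from them, otherwise the stored ``amplitude``
    column is used.
    """
    active = table.loc[~table["nostim"].astype(bool)]
    if len(active) == 0:
        raise ValueError("no active (stimulus) trials")
    if active["intensity_db"].nunique() < 2:
        raise ValueError("need >= 2 distinct stimulus intensities")
    rcols = [f"r{j}" for j in range(65)]
    if set(rcols).issubset(table.columns):
        amp = active[rcols].to_numpy().mean(axis=1)
    else:
        amp = active["amplitude"].to_numpy()
    fit = sps.linregress(active["intensity_db"].to_numpy(float), amp)
    r2 = fit.rvalue**2 if np.ptp(amp) > 0 else 1.0
    return SlopeResult(float(fit.slope), float(fit.intercept), float(r2), len(active))


# ---------------------------------------------------------------------------
# Barnes maze and open field
# ---------------------------------------------------------------------------


def barnes_probe_profile(bouts: pd.Series | dict) -> tuple[float, float, float]:
    """Target-hole preference from probe-trial exploration bouts.

    ``bouts`` maps hole positions -10..+9 relative to the target (target = 0)
    to bout counts over the 20 maze holes.  Returns (target bouts, mean
    bouts over the 19 nontarget holes, their difference).
    """
    s = pd.Series(bouts, dtype=float)
    expected = set(range(-10, 10))
    if set(int(k) for k in s.index) != expected:
        missing = sorted(expected - set(int(k) for k in s.index))
        raise ValueError(f"need all 20 holes -10..9; missing {missing}")
    if (s < 0).any():
        raise ValueError("bout counts must be >= 0")
    s.index = s.index.astype(int)
    target = float(s.loc[0])
    nontarget = float(s.drop(0).mean())
    return target, nontarget, target - nontarget


@dataclass(frozen=True)
class BeamBreakRecord:
    """Open-field beam-break counts for one session."""

    total: int
    center: int
    rearing: int = 0
    duration_min: float = 15.0

    def __post_init__(self):
        if self.center > self.total:
            raise ValueError("center beam breaks cannot exceed total")
        if min(self.total, self.center, self.rearing) < 0:
            raise ValueError("counts must be >= 0")


def percent_center(rec: BeamBreakRecord) -> float:
    """Percentage of beam breaks recorded in the arena center.

    Undefined (NaN) for a session with no beam breaks at all.
    """
    if rec.total == 0:
        return float("nan")
    return 100.0 * rec.center / rec.total
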