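"""Field-potential analysis: fEPSP slopes, I-O curves, paired-pulse ratio, LTP.

Extracellular CA1 field EPSPs evoked by Schaffer-collateral stimulation are
reduced to their initial slope — a linear fit over the 20-80% span of the
negative-going rising phase, after blanking the stimulus artifact.  On top of
that single measure the module builds input-output curves (slope vs
logarithmically increasing stimulation intensity), paired-pulse ratio curves
over the doubling ISI ladder 25 -> 1600 ms, and baseline-normalized LTP time
courses around theta-burst stimulation (5 pulses at 100 Hz, 10 bursts at
200 ms intervals per bout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "StimEvent",
    "Sweep",
    "SlopeConfig",
    "EPSPMeasure",
    "PPR_ISIS_MS",
    "measure_slope",
    "io_curve",
    "ppr",
    "ltp_timecourse",
    "tbs_protocol",
]

#: Paired-pulse interstimulus-interval ladder (ms), doubling 25 -> 1600.
PPR_ISIS_MS = (25, 50, 100, 200, 400, 800, 1600)


@dataclass(frozen=True)
class StimEvent:
    """One stimulus annotation: onset time (s), intensity (mA), pulse index."""

    time: float
    intensity: float = 0.1
    pulse: int = 0


@dataclass(frozen=True)
class Sweep:
    """A uniformly sampled voltage record with stimulus annotations."""

    time: np.ndarray
    voltage: np.ndarray
    sampling_rate: float
    stims: tuple[StimEvent, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "time", np.asarray(self.time, float))
        object.__setattr__(self, "voltage", np.asarray(self.voltage, float))
        if self.time.shape != self.voltage.shape:
            raise ValueError("time and voltage must have equal length")
        for s in self.stims:
            if not self.time[0] <= s.time <= self.time[-1]:
                raise ValueError(f"stimulus at {s.time} s outside the record")


@dataclass(frozen=True)
class SlopeConfig:
    """Slope-measurement parameters.

    ``blank_ms``: dead time after the stimulus excluded from analysis
    (artifact blanking).  ``fit_start_ms``: earliest fit time after the
    stimulus, which also keeps any fiber volley out of the window.
    ``rise_lo``/``rise_hi``: fractional span of the rising phase fitted
    (default 20-80%).  ``search_ms``: how far past the stimulus to look for
    the fEPSP peak.  ``min_amplitude_mv``: deflections smaller than this are
    reported as null measures (no detectable response).  ``detrend``:
    subtract a line fitted to the 2 ms pre-stimulus baseline, which removes
    the decaying tail of a preceding response (essential for the second
    pulse of short-ISI pairs).  ``smooth_samples``: boxcar width used only to
    localize the peak and the 20/80% crossings, so sample noise cannot
    scramble the fit window; the fit itself runs on the unsmoothed trace.
    """

    blank_ms: float = 1.0
    fit_start_ms: float = 1.5
    rise_lo: float = 0.2
    rise_hi: float = 0.8
    search_ms: float = 30.0
    min_amplitude_mv: float = 0.02
    detrend: bool = True
    smooth_samples: int = 5


@dataclass(frozen=True)
class EPSPMeasure:
    """An initial-slope measurement for one pulse.

    ``slope`` is the magnitude of the negative-going rise in mV/ms (NaN when
    flagged null); ``window`` the fitted (start, end) in seconds.
    """

    slope: float
    window: tuple[float, float]
    r_squared: float
    ok: bool = True


def _null_measure() -> EPSPMeasure:
    return EPSPMeasure(float("nan"), (float("nan"), float("nan")), float("nan"), ok=False)


def measure_slope(sweep: Sweep, pulse: int = 0, config: SlopeConfig | None = None) -> EPSPMeasure:
    """Initial fEPSP slope for the given pulse of a sweep.

    The baseline is the mean voltage over the 2 ms preceding the stimulus;
    the response window runs from the stimulus (plus ``fit_start_ms``) to the
    next stimulus or ``search_ms``.  The most negative deflection defines the
    peak; a least-squares line through the samples between the 20% and 80%
    amplitude crossings of the falling (negative-going) phase gives the
    slope, reported as a positive magnitude in mV/ms.  Deflections below
    ``min_amplitude_mv`` yield a flagged null measure.
    """
    cfg = config or SlopeConfig()
    stim = next((s for s in sweep.stims if s.pulse == pulse), None)
    if stim is None:
        raise ValueError(f"no stimulus annotated with pulse index {pulse}")
    fs = sweep.sampling_rate
    i_stim = int(round((stim.time - sweep.time[0]) * fs))

    i_base0 = max(0, i_stim - int(round(0.002 * fs)))
    t_base = sweep.time[i_base0:i_stim]
    v_base = sweep.voltage[i_base0:i_stim]
    if t_base.size == 0:
        t_base, v_base = sweep.time[:1], sweep.voltage[:1]
    if cfg.detrend and t_base.size > 3:
        trend_coef = np.polyfit(t_base, v_base, 1)
    else:
        trend_coef = np.array([0.0, v_base.mean()])

    later = [s.time for s in sweep.stims if s.time > stim.time]
    t_end = min(stim.time + cfg.search_ms / 1000.0, later[0] if later else np.inf,
                sweep.time[-1])
    i_lo = i_stim + int(round(cfg.fit_start_ms / 1000.0 * fs))
    i_hi = int(round((t_end - sweep.time[0]) * fs))
    if i_hi - i_lo < int(0.002 * fs):
        raise ValueError("post-artifact analysis region shorter than 2 ms")

    t_win = sweep.time[i_lo:i_hi]
    defl = np.polyval(trend_coef, t_win) - sweep.voltage[i_lo:i_hi]  # + for negative-going
    smooth = ndi.uniform_filter1d(defl, max(1, cfg.smooth_samples))
    i_peak = int(np.argmax(smooth))
    amp = smooth[i_peak]
    if amp < cfg.min_amplitude_mv:
        return _null_measure()

    lo_level, hi_level = cfg.rise_lo * amp, cfg.rise_hi * amp

    def _crossing(level: float) -> float:
        # last crossing of `level` before the peak, sub-sample interpolated
        j = i_peak
        while j > 0 and smooth[j] > level:
            j -= 1
        if smooth[j] > level:  # never dropped below: window starts at the edge
            return float(t_win[j])
        frac = float(np.clip((level - smooth[j]) / (smooth[j + 1] - smooth[j]), 0.0, 1.0))
        return float(t_win[j] + frac * (t_win[j + 1] - t_win[j]))

    t20, t80 = _crossing(lo_level), _crossing(hi_level)
    if not t80 > t20:
        return _null_measure()
    # least-squares line over the 20-80% span of the (detrended) deflection;
    # fitting on a dense interpolated grid removes the sample-discretization
    # of the window endpoints (the underlying rise is smooth, so linear
    # interpolation at >= 10 kHz sampling contributes negligible error)
    tf = np.linspace(t20, t80, 200)
    vf = np.interp(tf, t_win, defl)
    A = np.vstack([tf, np.ones_like(tf)]).T
    coef, res, *_ = np.linalg.lstsq(A, vf, rcond=None)
    ss_tot = float(((vf - vf.mean()) ** 2).sum())
    r2 = 1.0 - float(res[0]) / ss_tot if res.size and ss_tot > 0 else 1.0
    slope_mv_ms = abs(coef[0]) / 1000.0  # mV/s -> mV/ms
    return EPSPMeasure(float(slope_mv_ms), (t20, t80), r2)


def io_curve(sweeps_by_intensity: dict[float, list[Sweep]],
             config: SlopeConfig | None = None) -> pd.DataFrame:
    """Input-output curve: mean initial slope per stimulation intensity.

    Returns a table of (intensity, mean slope, n sweeps, n null) sorted by
    ascending intensity; intensities whose sweeps all yield null measures
    are kept with NaN slope and flagged by the counts.
    """
    rows = []
    for inten in sorted(sweeps_by_intensity):
        measures = [measure_slope(s, 0, config) for s in sweeps_by_intensity[inten]]
        good = [m.slope for m in measures if m.ok]
        rows.append({
            "intensity": inten,
            "mean_slope_mv_ms": float(np.mean(good)) if good else np.nan,
            "n_sweeps": len(measures),
            "n_null": len(measures) - len(good),
        })
    return pd.DataFrame(rows, columns=["intensity", "mean_slope_mv_ms", "n_sweeps", "n_null"])


def average_sweeps(sweeps: list[Sweep]) -> Sweep:
    """Point-wise average of replicate sweeps sharing one time base.

    Standard replicate averaging before slope measurement; all sweeps must
    have the same length, sampling rate, and stimulus annotations.
    """
    first = sweeps[0]
    for s in sweeps[1:]:
        if s.voltage.shape != first.voltage.shape or s.sampling_rate != first.sampling_rate:
            raise ValueError("replicate sweeps must share one time base")
        if s.stims != first.stims:
            raise ValueError("replicate sweeps must share stimulus annotations")
    v = np.mean([s.voltage for s in sweeps], axis=0)
    return Sweep(time=first.time, voltage=v, sampling_rate=first.sampling_rate,
                 stims=first.stims)


def ppr(sweeps_by_isi: dict[float, Sweep | list[Sweep]],
        config: SlopeConfig | None = None) -> pd.DataFrame:
    """Paired-pulse ratio curve over the ISI ladder.

    For each ISI (ms) the entry is one two-pulse sweep or a list of
    replicate sweeps (averaged point-wise before measurement); the ratio is
    the second pulse's slope divided by the first's (p2/p1).  A null first
    pulse leaves the ratio undefined (NaN, flagged).
    """
    rows = []
    for isi in sorted(sweeps_by_isi):
        entry = sweeps_by_isi[isi]
        sweep = average_sweeps(list(entry)) if isinstance(entry, (list, tuple)) else entry
        m1 = measure_slope(sweep, 0, config)
        m2 = measure_slope(sweep, 1, config)
        ok = m1.ok and m2.ok and m1.slope > 0
        rows.append({
            "isi_ms": isi,
            "slope1_mv_ms": m1.slope,
            "slope2_mv_ms": m2.slope,
            "ppr": m2.slope / m1.slope if ok else np.nan,
            "ok": ok,
        })
    return pd.DataFrame(rows, columns=["isi_ms", "slope1_mv_ms", "slope2_mv_ms", "ppr", "ok"])


def ltp_timecourse(
    times_min: np.ndarray,
    slopes: np.ndarray,
    baseline_window: tuple[float, float],
    tbs_times_min: list[float],
    epoch_min: float = 20.0,
    summary_min: float = 5.0,
    drift_limit: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame, bool]:
    """Baseline-normalized LTP time course with per-epoch summaries.

    ``slopes`` are per-sweep initial slopes at ``times_min`` (minutes).  All
    values are divided by the baseline-window mean and scaled to percent, so
    the baseline mean is 100% by construction.  Each induction event in
    ``tbs_times_min`` opens a 20 min epoch; the epoch summary is the mean
    over its final ``summary_min`` minutes.  The boolean flag reports
    baseline drift: true when the first- and second-half baseline means
    differ by more than ``drift_limit`` of their overall mean.

    Returns (time course table, epoch summary table, drift_flag).
    """
    t = np.asarray(times_min, float)
    y = np.asarray(slopes, float)
    b0, b1 = baseline_window
    if b1 - b0 < 10.0:
        raise ValueError("baseline window must span at least 10 min")
    base = y[(t >= b0) & (t < b1)]
    if base.size == 0:
        raise ValueError("no sweeps in the baseline window")
    norm = 100.0 * y / base.mean()

    tb = t[(t >= b0) & (t < b1)]
    half = tb[0] + (tb[-1] - tb[0]) / 2.0
    m1 = base[tb < half].mean() if (tb < half).any() else base.mean()
    m2 = base[tb >= half].mean() if (tb >= half).any() else base.mean()
    drift = abs(m2 - m1) / base.mean() > drift_limit

    course = pd.DataFrame({"time_min": t, "norm_slope_pct": norm})
    rows = [{
        "epoch": "baseline",
        "start_min": b0, "end_min": b1,
        "mean_pct": float(norm[(t >= b0) & (t < b1)].mean()),
    }]
    for k, t_tbs in enumerate(sorted(tbs_times_min), start=1):
        end = t_tbs + epoch_min
        lo = end - summary_min
        sel = (t >= lo) & (t < end)
        rows.append({
            "epoch": f"post-{k}",
            "start_min": lo, "end_min": end,
            "mean_pct": float(norm[sel].mean()) if sel.any() else np.nan,
        })
    return course, pd.DataFrame(rows), bool(drift)


def tbs_protocol(n_bouts: int = 1, pulses_per_burst: int = 5, burst_hz: float = 100.0,
                 n_bursts: int = 10, burst_interval_s: float = 0.2,
                 bout_interval_s: float = 20.0) -> np.ndarray:
    """Pulse times (s) of a theta-burst stimulation protocol.

    Each bout is 10 bursts at 200 ms onset intervals, each burst 5 pulses at
    100 Hz (10 ms spacing) — 50 pulses per bout; successive bouts start
    ``bout_interval_s`` apart.
    """
    if n_bouts < 1:
        raise ValueError("n_bouts must be >= 1")
    pulse = np.arange(pulses_per_burst) / burst_hz
    burst = np.arange(n_bursts) * burst_interval_s
    bout = np.arange(n_bouts) * bout_interval_s
    times = (bout[:, None, None] + burst[None, :, None] + pulse[None, None, :]).ravel()
    return np.sort(times)
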