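"""Ground-truthed synthetic inputs for every pipeline stage.

Three families of raw data feed the quantification pipeline: stained-section
images, behavioral session tables, and field-potential sweeps.  None of them
can ship with the package, so this module rasterizes stained-section phantoms
(dark DAB-like ellipses on a light background), draws stochastic shuttle-box /
startle / freezing sessions from known generative parameters, and synthesizes
fEPSP sweeps whose initial slopes are set by construction.  Every generator is
bit-reproducible under a fixed seed and returns the ground truth alongside the
data, so downstream estimators can be tested for exact or convergent recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ihc import SectionImage
from .behavior import MotionTrace, Phase

__all__ = [
    "EllipseObject",
    "SectionPhantomSpec",
    "AASessionSpec",
    "StartleSessionSpec",
    "MotionTraceSpec",
    "EphysSweepSpec",
    "generate_section",
    "generate_aa_session",
    "generate_startle_session",
    "generate_motion_trace",
    "generate_sweep",
]

# ---------------------------------------------------------------------------
# stained-section phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EllipseObject:
    """A single stained object: an ellipse in pixel coordinates.

    ``center`` is (row, col) in pixels, ``semi_axes`` (a, b) in pixels,
    ``orientation`` in radians (rotation of the a-axis from the row axis),
    ``intensity`` the stain level in [0, 255] (darker than background), and
    ``label`` either ``"cluster"`` (GFAP/CD68-like blob) or ``"nucleus"``
    (c-Fos-like small round object).
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation: float = 0.0
    intensity: float = 80.0
    label: str = "cluster"

    @property
    def area_px(self) -> float:
        a, b = self.semi_axes
        return math.pi * a * b

    @property
    def perimeter_px(self) -> float:
        # Ramanujan's second approximation; exact for circles.
        a, b = self.semi_axes
        h = ((a - b) / (a + b)) ** 2
        return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


@dataclass(frozen=True)
class SectionPhantomSpec:
    """Parameters of one synthetic stained section.

    The phantom emulates a DAB-stained bright-field image: a light, noisy
    background with dark elliptical stained objects.  ``pixel_size`` is the
    calibration in micrometres per pixel.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.5
    background_level: float = 200.0
    objects: tuple[EllipseObject, ...] = ()
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not (0 <= self.background_level <= 255):
            raise ValueError("background_level must be in [0, 255]")
        for i, obj in enumerate(self.objects):
            if obj.intensity >= self.background_level:
                raise ValueError(
                    f"object {i}: stain intensity {obj.intensity} must be darker "
                    f"than background {self.background_level}"
                )
            if min(obj.semi_axes) <= 0:
                raise ValueError(f"object {i}: semi-axes must be positive")


def _ellipse_coverage(shape, obj: EllipseObject, supersample: int = 4) -> tuple[slice, slice, np.ndarray]:
    """Sub-pixel area coverage of one ellipse over its bounding box.

    Each pixel is split into ``supersample**2`` sub-samples; coverage is the
    fraction of sub-sample centers falling inside the ellipse.  As resolution
    grows the integrated coverage approaches the analytic area, which is what
    makes convergence tests against the closed-form geometry meaningful.
    """
    cr, cc = obj.center
    ext = max(obj.semi_axes) + 1.0
    r0, r1 = int(math.floor(cr - ext)), int(math.ceil(cr + ext)) + 1
    c0, c1 = int(math.floor(cc - ext)), int(math.ceil(cc + ext)) + 1
    if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
        raise ValueError(
            f"object at {obj.center} with semi-axes {obj.semi_axes} extends "
            f"beyond the {shape} image bounds"
        )
    s = supersample
    off = (np.arange(s) + 0.5) / s - 0.5
    rows = np.arange(r0, r1)[:, None] + off[None, :]   # (nr, s)
    cols = np.arange(c0, c1)[:, None] + off[None, :]
    dr = (rows - cr).reshape(-1, s, 1, 1)
    dc = (cols - cc).reshape(1, 1, -1, s)
    ct, st = math.cos(obj.orientation), math.sin(obj.orientation)
    a, b = obj.semi_axes
    u = (dr * ct + dc * st) / a
    v = (-dr * st + dc * ct) / b
    inside = (u * u + v * v) <= 1.0
    cov = inside.mean(axis=(1, 3))
    return slice(r0, r1), slice(c0, c1), cov


def generate_section(spec: SectionPhantomSpec, stain: str = "GFAP") -> tuple[SectionImage, pd.DataFrame]:
    """Rasterize a stained-section phantom and return it with its ground truth.

    Returns a calibrated :class:`~neuroaging.ihc.SectionImage` (8-bit range,
    dark objects on a light background) and a ground-truth table with one row
    per spec object: analytic ``area_um2`` (pi*a*b), ``perimeter_um``
    (Ramanujan approximation), centroid in micrometres, and the class label.
    Identical spec and seed reproduce the identical image bit-for-bit.
    """
    rng = np.random.default_rng(spec.seed)
    img = np.full(spec.image_shape, float(spec.background_level))
    for obj in spec.objects:
        rs, cs, cov = _ellipse_coverage(spec.image_shape, obj)
        tile = img[rs, cs]
        img[rs, cs] = tile * (1.0 - cov) + obj.intensity * cov
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=spec.image_shape)
    img = np.clip(img, 0.0, 255.0)

    ps = spec.pixel_size
    truth = pd.DataFrame(
        {
            "area_um2": [o.area_px * ps**2 for o in spec.objects],
            "perimeter_um": [o.perimeter_px * ps for o in spec.objects],
            "centroid_row_um": [o.center[0] * ps for o in spec.objects],
            "centroid_col_um": [o.center[1] * ps for o in spec.objects],
            "label": [o.label for o in spec.objects],
        }
    )
    return SectionImage(intensity=img, pixel_size=ps, stain=stain), truth


def nonoverlapping_objects(
    n: int,
    image_shape: tuple[int, int],
    radius_range: tuple[float, float],
    rng: np.random.Generator,
    intensity: float = 80.0,
    label: str = "cluster",
    max_tries: int = 10000,
) -> tuple[EllipseObject, ...]:
    """Place ``n`` non-overlapping ellipses by rejection sampling.

    Helper for recovery tests: objects are guaranteed disjoint (center
    distance > sum of max semi-axes + 2 px) and fully inside the image.
    """
    placed: list[EllipseObject] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(f"could not place {n} disjoint objects in {image_shape}")
        a = rng.uniform(*radius_range)
        b = rng.uniform(*radius_range)
        ext = max(a, b) + 2.0
        cr = rng.uniform(ext, image_shape[0] - ext)
        cc = rng.uniform(ext, image_shape[1] - ext)
        ok = all(
            math.hypot(cr - o.center[0], cc - o.center[1])
            > ext + max(o.semi_axes) + 2.0
            for o in placed
        )
        if ok:
            theta = rng.uniform(0, math.pi)
            placed.append(EllipseObject((cr, cc), (a, b), theta, intensity, label))
    return tuple(placed)


# ---------------------------------------------------------------------------
# behavioral sessions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AASessionSpec:
    """One two-way active-avoidance session with a known learning curve.

    The per-trial probability of a successful avoidance interpolates from
    ``p_avoid_start`` to ``p_avoid_end`` over the session (linearly or along a
    logistic curve), emulating within-session learning.  Trials that are not
    avoided become escape failures with probability ``p_failure`` and escapes
    otherwise.  ITIs are uniform on ``iti_range`` (default 25-55 s, mean 40 s,
    the protocol's range).
    """

    n_trials: int = 100
    p_avoid_start: float = 0.05
    p_avoid_end: float = 0.75
    learning_shape: str = "linear"
    p_failure: float = 0.05
    iti_range: tuple[float, float] = (25.0, 55.0)
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_avoid_start, self.p_avoid_end, self.p_failure):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not self.iti_range[0] < self.iti_range[1]:
            raise ValueError("iti_range must be (low, high) with low < high")
        if self.learning_shape not in ("linear", "logistic"):
            raise ValueError("learning_shape must be 'linear' or 'logistic'")

    def p_avoid(self) -> np.ndarray:
        """Per-trial avoidance probabilities (the generative learning curve)."""
        x = np.linspace(0.0, 1.0, self.n_trials)
        if self.learning_shape == "linear":
            f = x
        else:
            z = 1.0 / (1.0 + np.exp(-10.0 * (x - 0.5)))
            f = (z - z[0]) / (z[-1] - z[0])
        return self.p_avoid_start + (self.p_avoid_end - self.p_avoid_start) * f


def generate_aa_session(spec: AASessionSpec) -> pd.DataFrame:
    """Simulate an avoidance session as a trial table.

    Columns: ``trial`` (1..N), ``outcome`` in {avoid, escape, failure},
    ``latency_s`` (avoid: U(0,5) from cue onset; escape: cue + 5 s + U(0,2);
    failure: NaN), ``iti_s`` ~ U(iti_range).  Exactly one outcome per trial.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.p_avoid()
    u = rng.random(spec.n_trials)
    avoided = u < p
    fail_draw = rng.random(spec.n_trials) < spec.p_failure
    outcome = np.where(avoided, "avoid", np.where(fail_draw, "failure", "escape"))
    lat_avoid = rng.uniform(0.0, 5.0, spec.n_trials)
    lat_escape = 5.0 + rng.uniform(0.0, 2.0, spec.n_trials)
    latency = np.where(avoided, lat_avoid, np.where(fail_draw, np.nan, lat_escape))
    iti = rng.uniform(*spec.iti_range, spec.n_trials)
    return pd.DataFrame(
        {
            "trial": np.arange(1, spec.n_trials + 1),
            "outcome": outcome,
            "latency_s": latency,
            "iti_s": iti,
        }
    )


#: dB-above-background levels of the default startle session (incl. 0 dB).
STARTLE_LEVELS = (0, 4, 8, 12, 16, 20, 24, 28, 35, 42, 49, 55)


@dataclass(frozen=True)
class StartleSessionSpec:
    """An acoustic-startle session with a known amplitude/intensity slope.

    Trial amplitudes follow ``max(0, intercept + true_slope*dB + noise)``;
    each trial carries 65 one-millisecond accelerometer readings whose
    arithmetic mean equals the trial amplitude (the session's amplitude
    definition).  ``n_nostim`` no-stimulus trials measure cage displacement
    only.  ITIs are uniform on ``iti_range`` (default 8-22 s, mean 15 s).
    """

    intensities: tuple[float, ...] = STARTLE_LEVELS
    n_per_level: int = 8
    true_slope: float = 2.0
    intercept: float = 5.0
    noise_sd: float = 4.0
    n_nostim: int = 8
    iti_range: tuple[float, float] = (8.0, 22.0)
    seed: int = 0

    def __post_init__(self):
        if any(i < 0 for i in self.intensities):
            raise ValueError("intensities must be >= 0 dB above background")
        if self.n_per_level <= 0:
            raise ValueError("n_per_level must be positive")
        if not self.iti_range[0] < self.iti_range[1]:
            raise ValueError("iti_range must be (low, high) with low < high")


def _reading_profile() -> np.ndarray:
    # Half-sine startle envelope over 65 ms, normalized to unit mean so the
    # 65-reading average reproduces the trial amplitude exactly.
    w = np.sin(np.linspace(0.0, np.pi, 65))
    return w / w.mean()


def generate_startle_session(spec: StartleSessionSpec) -> pd.DataFrame:
    """Simulate a startle session as a wide trial table.

    Columns: ``trial``, ``intensity_db``, ``nostim`` (bool), ``amplitude``
    and ``r0``..``r64`` (the 65 per-ms readings).  Active trials are presented
    in pseudorandom order with NOSTIM trials interspersed; ``iti_s`` is drawn
    for active trials only (NaN on NOSTIM, which do not enter the ITI).
    """
    rng = np.random.default_rng(spec.seed)
    levels = np.repeat(spec.intensities, spec.n_per_level).astype(float)
    nostim = np.concatenate([np.zeros(levels.size, bool), np.ones(spec.n_nostim, bool)])
    db = np.concatenate([levels, np.zeros(spec.n_nostim)])
    order = rng.permutation(db.size)
    db, nostim = db[order], nostim[order]

    amp = spec.intercept + spec.true_slope * db + rng.normal(0.0, spec.noise_sd, db.size)
    amp = np.where(nostim, np.abs(rng.normal(0.0, spec.noise_sd, db.size)), amp)
    amp = np.maximum(amp, 0.0)

    profile = _reading_profile()
    readings = amp[:, None] * profile[None, :]
    iti = np.where(nostim, np.nan, rng.uniform(*spec.iti_range, db.size))

    table = pd.DataFrame({"trial": np.arange(1, db.size + 1), "intensity_db": db,
                          "nostim": nostim, "amplitude": amp, "iti_s": iti})
    for j in range(65):
        table[f"r{j}"] = readings[:, j]
    return table


@dataclass(frozen=True)
class MotionTraceSpec:
    """A fear-conditioning motion-index trace with known freeze bouts.

    The motion index is emitted once per observation interval (0.5 s grid by
    default).  Intervals fully inside a freeze bout read ``frozen_level``
    (below the 20-unit motion threshold), all others ``moving_level``, plus
    Gaussian noise.  Bouts must not overlap.
    """

    duration: float = 60.0
    interval: float = 0.5
    freeze_bouts: tuple[tuple[float, float], ...] = ()
    moving_level: float = 120.0
    frozen_level: float = 5.0
    noise_sd: float = 1.0
    phases: tuple[Phase, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not self.frozen_level < 20.0 < self.moving_level:
            raise ValueError("need frozen_level < 20 < moving_level")
        if self.duration <= 0 or self.interval <= 0:
            raise ValueError("duration and interval must be positive")
        bouts = sorted(self.freeze_bouts)
        for (s0, e0), (s1, e1) in zip(bouts, bouts[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping freeze bouts: ({s0},{e0}) and ({s1},{e1})")
        for s, e in bouts:
            if s < 0 or e > self.duration or s >= e:
                raise ValueError(f"bout ({s},{e}) outside trace duration {self.duration}")


def generate_motion_trace(spec: MotionTraceSpec) -> MotionTrace:
    """Simulate a motion-index trace on the observation-interval grid."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration / spec.interval))
    starts = np.arange(n) * spec.interval
    ends = starts + spec.interval
    frozen = np.zeros(n, bool)
    for s, e in spec.freeze_bouts:
        # only intervals wholly inside a bout are motionless throughout
        frozen |= (starts >= s - 1e-9) & (ends <= e + 1e-9)
    values = np.where(frozen, spec.frozen_level, spec.moving_level).astype(float)
    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, n)
    values = np.maximum(values, 0.0)
    phases = spec.phases or (Phase("all", 0.0, spec.duration),)
    return MotionTrace(values=values, interval=spec.interval, phases=tuple(phases))


# ---------------------------------------------------------------------------
# field-potential sweeps
# ---------------------------------------------------------------------------

_TAU_RISE_MS = 1.0
_TAU_DECAY_MS = 8.0


def _unit_epsp(t_ms: np.ndarray) -> np.ndarray:
    """Difference-of-exponentials fEPSP kernel, peak-normalized to 1."""
    tr, td = _TAU_RISE_MS, _TAU_DECAY_MS
    t_peak = math.log(td / tr) * tr * td / (td - tr)
    tp = np.maximum(t_ms, 0.0)  # zero before onset (avoids exp overflow)
    w = np.where(t_ms >= 0, np.exp(-tp / td) - np.exp(-tp / tr), 0.0)
    peak = math.exp(-t_peak / td) - math.exp(-t_peak / tr)
    return w / peak


def _unit_rise_slope() -> float:
    """Least-squares 20-80% rise slope of the unit kernel (1/ms).

    Evaluated on a 1 MHz grid, so it is the generator's own high-resolution
    definition of "initial slope", independent of any analyzer code.
    """
    t = np.arange(0.0, 6.0, 0.001)
    w = _unit_epsp(t)
    i_peak = int(np.argmax(w))
    rise = w[: i_peak + 1]
    lo = int(np.searchsorted(rise, 0.2))
    hi = int(np.searchsorted(rise, 0.8))
    x = t[lo:hi]
    y = rise[lo:hi]
    return float(np.polyfit(x, y, 1)[0])


_UNIT_SLOPE = _unit_rise_slope()


@dataclass(frozen=True)
class EphysSweepSpec:
    """A synthetic extracellular sweep with constructed fEPSP slopes.

    Each stimulus produces a brief biphasic artifact followed (after a 2 ms
    synaptic delay) by a negative-going fEPSP whose 20-80% rising-phase slope
    equals ``true_initial_slope * ppr_profile[pulse]`` (in mV/ms, magnitude).
    """

    sampling_rate: float = 20000.0
    stim_times: tuple[float, ...] = (0.05,)
    true_initial_slope: float = 0.2
    ppr_profile: tuple[float, ...] = (1.0,)
    artifact_amplitude: float = 2.0
    noise_sd: float = 0.0
    duration: float | None = None
    epsp_delay_ms: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate < 10000.0:
            raise ValueError("sampling_rate must be >= 10 kHz")
        if list(self.stim_times) != sorted(set(self.stim_times)):
            raise ValueError("stim_times must be strictly increasing")
        if len(self.ppr_profile) != len(self.stim_times):
            raise ValueError("ppr_profile must give one scale per stimulus")


def generate_sweep(spec: EphysSweepSpec, stim_intensity: float = 0.1):
    """Synthesize one sweep; returns a :class:`~neuroaging.ephys.Sweep`.

    The fEPSP amplitude is calibrated so that the least-squares slope of the
    20-80% rising phase equals the requested slope for each pulse.
    """
    from .ephys import Sweep, StimEvent

    fs = spec.sampling_rate
    dur = spec.duration if spec.duration is not None else spec.stim_times[-1] + 0.1
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    v = np.zeros(n)
    rng = np.random.default_rng(spec.seed)

    for k, st in enumerate(spec.stim_times):
        # biphasic stimulus artifact: 0.2 ms up, 0.2 ms down
        up = (t >= st) & (t < st + 0.0002)
        dn = (t >= st + 0.0002) & (t < st + 0.0004)
        v[up] += spec.artifact_amplitude
        v[dn] -= spec.artifact_amplitude
        onset = st + spec.epsp_delay_ms / 1000.0
        t_ms = (t - onset) * 1000.0
        target = spec.true_initial_slope * spec.ppr_profile[k]
        amp = target / _UNIT_SLOPE  # mV peak so the rise slope is `target`
        v -= amp * _unit_epsp(t_ms)

    if spec.noise_sd > 0:
        v += rng.normal(0.0, spec.noise_sd, n)

    stims = tuple(
        StimEvent(time=st, intensity=stim_intensity, pulse=k)
        for k, st in enumerate(spec.stim_times)
    )
    return Sweep(time=t, voltage=v, sampling_rate=fs, stims=stims)
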