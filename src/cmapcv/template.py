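"""Single motor unit potential (sMUP) templates.

The compound muscle action potential (CMAP) is synthesized by latency-shifting
and summing one unit waveform — the sMUP — across an axon population.  This
module provides that unit waveform: a synthetic biphasic generator, a CSV
loader for externally digitized recordings, natural cubic-spline smoothing,
and gating/resampling onto the simulation grid.

Grid convention
---------------
Templates live on a uniform 0.1 ms grid covering the half-open interval
[0, 15.0) ms — 150 samples at t = 0.0, 0.1, ..., 14.9 ms.  Amplitudes are
forced to exactly 0 mV before 3.5 ms and from 12.1 ms onward (the gate
window), so that stimulus artifact and baseline noise never enter the
superposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

DT_MS = 0.1
#: Half-open grid [0, 15.0) ms -> 150 samples.
N_SAMPLES = 150
GATE_WINDOW_MS = (3.5, 12.1)


def grid_times() -> np.ndarray:
    """The template time grid in ms: 0.0, 0.1, ..., 14.9."""
    return np.arange(N_SAMPLES) * DT_MS


@dataclass(frozen=True)
class SMUPTemplate:
    """A single motor unit potential sampled on the 0.1 ms grid.

    Attributes
    ----------
    sample_times : array of ms, shape (150,), uniform 0.1 ms spacing.
    amplitudes : array of mV, shape (150,); exactly zero outside the gate.
    gate_window : (start_ms, stop_ms); samples with t < start or t >= stop
        are zero.
    """

    sample_times: np.ndarray
    amplitudes: np.ndarray
    gate_window: tuple[float, float] = field(default=GATE_WINDOW_MS)

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if t.shape != (N_SAMPLES,) or a.shape != (N_SAMPLES,):
            raise ValueError(
                f"template requires {N_SAMPLES} samples, got "
                f"{t.shape} times / {a.shape} amplitudes"
            )
        dt = np.diff(t)
        if not np.allclose(dt, DT_MS, rtol=0, atol=1e-9):
            raise ValueError("sample times must be uniform at 0.1 ms")
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "amplitudes", a)

    @property
    def peak_amplitude(self) -> float:
        """max |amplitude| in mV."""
        return float(np.max(np.abs(self.amplitudes)))

    def gated(self) -> "SMUPTemplate":
        """Return a copy with amplitudes zeroed outside the gate window."""
        lo, hi = self.gate_window
        amps = np.where(
            (self.sample_times >= lo) & (self.sample_times < hi),
            self.amplitudes,
            0.0,
        )
        return SMUPTemplate(self.sample_times, amps, self.gate_window)

    def to_csv(self, path) -> None:
        """Write (time_ms, amplitude_mv) rows with a header."""
        arr = np.column_stack([self.sample_times, self.amplitudes])
        np.savetxt(path, arr, delimiter=",", header="time_ms,amplitude_mv",
                   comments="", fmt="%.6f")


def smooth_spline(times, amplitudes, query_times) -> np.ndarray:
    """Natural cubic spline through (times, amplitudes), evaluated at
    ``query_times``.

    Exact at the knots; second derivative zero at both ends; no
    extrapolation (queries outside the knot range raise).
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(amplitudes, dtype=float)
    q = np.asarray(query_times, dtype=float)
    if t.ndim != 1 or t.size < 4:
        raise ValueError("need at least 4 knots for cubic spline smoothing")
    if t.shape != a.shape:
        raise ValueError("times and amplitudes must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knot times must be strictly increasing")
    if q.size and (q.min() < t[0] - 1e-12 or q.max() > t[-1] + 1e-12):
        raise ValueError(
            f"query times must lie within [{t[0]}, {t[-1]}] ms (no extrapolation)"
        )
    spline = CubicSpline(t, a, bc_type="natural")
    return spline(np.clip(q, t[0], t[-1]))


def synthetic_smup(
    peak_amplitude_mv: float = 0.1,
    onset_ms: float = 4.0,
    seed: int = 0,
) -> SMUPTemplate:
    """Generate a smooth biphasic surrogate sMUP.

    The waveform is a negative-then-positive pair of Gaussian lobes (surface
    EMG convention: initial negative deflection), gated to the template
    window.  The shape (lobe delays, widths and the positive/negative ratio)
    is drawn deterministically from ``seed`` and then linearly scaled so
    that max |amplitude| equals ``peak_amplitude_mv`` — doubling the peak
    doubles every sample.

    Parameters
    ----------
    peak_amplitude_mv : magnitude of the dominant (negative) peak, mV; > 0.
    onset_ms : approximate take-off latency, must lie inside the gate window.
    seed : controls the small jitter of the lobe geometry.
    """
    if peak_amplitude_mv <= 0:
        raise ValueError("peak amplitude must be positive")
    lo, hi = GATE_WINDOW_MS
    if not (lo <= onset_ms <= hi):
        raise ValueError(f"onset must lie inside the gate window [{lo}, {hi}] ms")

    rng = np.random.default_rng(seed)
    # Lobe geometry: jitter around physiologic-looking defaults so different
    # seeds give slightly different morphologies.
    neg_delay = 1.0 + 0.2 * rng.random()     # ms from onset to negative peak
    neg_width = 0.55 + 0.15 * rng.random()   # ms (Gaussian sigma)
    pos_delay = neg_delay + 1.8 + 0.5 * rng.random()
    pos_width = 1.0 + 0.3 * rng.random()
    pos_ratio = 0.45 + 0.15 * rng.random()   # positive lobe is smaller

    t = grid_times()
    shape = (
        -np.exp(-0.5 * ((t - (onset_ms + neg_delay)) / neg_width) ** 2)
        + pos_ratio
        * np.exp(-0.5 * ((t - (onset_ms + pos_delay)) / pos_width) ** 2)
    )
    shape *= peak_amplitude_mv / np.max(np.abs(shape))
    return SMUPTemplate(t, shape).gated()


def load_smup(path) -> SMUPTemplate:
    """Load a digitized sMUP from a two-column CSV (time_ms, amplitude_mv).

    The points are smoothed with a natural cubic spline, resampled onto the
    0.1 ms grid over [0, 15.0) ms, and gated to zero outside the gate
    window.  Grid points outside the time span of the file are set to 0 mV.

    An optional single header line is allowed.  Non-numeric rows and
    non-monotone times raise a parse error naming the offending line.
    """
    times: list[float] = []
    amps: list[float] = []
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    if lines:
        first = lines[0].strip().split(",")
        try:
            float(first[0])
        except (ValueError, IndexError):
            start = 1  # header
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        row = raw.strip()
        if not row:
            continue
        parts = row.split(",")
        if len(parts) < 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {row!r}")
        try:
            t, a = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric value in {row!r}") from exc
        if times and t <= times[-1]:
            raise ValueError(f"{path}: line {lineno}: times must be strictly increasing")
        times.append(t)
        amps.append(a)
    if not times:
        raise ValueError(f"{path}: no data rows")

    grid = grid_times()
    inside = (grid >= times[0]) & (grid <= times[-1])
    values = np.zeros(N_SAMPLES)
    if len(times) >= 4:
        values[inside] = smooth_spline(times, amps, grid[inside])
    else:
        # too few points for a cubic spline: fall back to linear interpolation
        values[inside] = np.interp(grid[inside], times, amps)
    return SMUPTemplate(grid, values).gated()
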