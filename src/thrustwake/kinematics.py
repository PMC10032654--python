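"""Midline kinematics of undulatory swimmers.

Implements the analysis chain applied to digitised ventral-video
midlines: spline resampling of sparse marker sets, tail-beat frequency
from tail-tip excursion peaks, joint angles between equal-arclength body
segments, intersegmental phase lags by circular cross-correlation, the
body-wave wavelength, the PCA-based amplitude envelope, and the
foil--fish phase difference used to quantify wake synchronisation.

Conventions
-----------
* The body is divided into ``N`` equal-arclength segments; ``N - 1``
  joint angles exist between them.  The intersegmental phase lag
  ``delta_phi_i`` is the circular cross-correlation delay between the
  angle signals of consecutive joints, as a fraction of the cycle
  duration ``T`` times ``2 pi``.
* The overall phase lag ``delta_Phi`` sums the lags along the whole
  body.  Only ``N - 2`` adjacent-joint lags are measurable; the sum is
  completed to full body coverage by extrapolating the mean adjacent lag
  at the ends (see :func:`phase_lags` ``mode``).  The body wavelength in
  body lengths is ``lambda = 2 pi / delta_Phi``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, find_peaks, savgol_filter

from .foil import TrajectorySeries

__all__ = [
    "MidlineTrack",
    "JointAngleSeries",
    "PhaseLagResult",
    "AmplitudeProfile",
    "resample_midline",
    "tailbeat_frequency",
    "joint_angles",
    "phase_lags",
    "amplitude_profile",
    "principal_frame",
    "phase_difference",
    "gap_distance",
    "unwrap_phases",
    "circular_cross_correlation",
]


@dataclass
class MidlineTrack:
    """Time-ordered snout-to-tail midline coordinates.

    Attributes
    ----------
    times : (n_frames,) array of seconds, uniformly sampled.
    xy : (n_frames, n_markers, 2) array of marker coordinates in metres,
        ordered snout (index 0) to tail tip (index -1).
    body_length : float, snout-to-tail arclength in metres.
    fps : float, frame rate in Hz.
    """

    times: np.ndarray
    xy: np.ndarray
    body_length: float
    fps: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 3 or self.xy.shape[2] != 2:
            raise ValueError("xy must have shape (n_frames, n_markers, 2)")
        if self.xy.shape[1] < 2:
            raise ValueError("a midline needs at least 2 markers")
        if self.times.shape[0] != self.xy.shape[0]:
            raise ValueError("times and xy disagree on the number of frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not self.body_length > 0:
            raise ValueError("body_length must be positive")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def n_markers(self) -> int:
        return self.xy.shape[1]

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def translated(self, offset) -> "MidlineTrack":
        return MidlineTrack(self.times.copy(), self.xy + np.asarray(offset, dtype=float),
                            self.body_length, self.fps)

    def rotated(self, angle: float, about=(0.0, 0.0)) -> "MidlineTrack":
        c, s = math.cos(angle), math.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        about = np.asarray(about, dtype=float)
        xy = (self.xy - about) @ rot.T + about
        return MidlineTrack(self.times.copy(), xy, self.body_length, self.fps)


@dataclass
class JointAngleSeries:
    """Signed joint angles between consecutive body segments per frame."""

    angles: np.ndarray  # (n_frames, N-1), radians
    n_segments: int
    times: np.ndarray
    fps: float
    cycle_duration: float | None = None

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.shape[1] != self.n_segments - 1:
            raise ValueError("expected N-1 joint angles for N segments")


@dataclass
class PhaseLagResult:
    """Intersegmental phase lags and derived body-wave wavelength."""

    delta_phi: np.ndarray  # radians per joint pair (incl. extrapolated end lags)
    overall: float  # delta_Phi, radians
    wavelength: float  # body lengths, 2 pi / delta_Phi

    def __post_init__(self) -> None:
        self.delta_phi = np.asarray(self.delta_phi, dtype=float)


@dataclass
class AmplitudeProfile:
    """Lateral amplitude (half range of lateral displacement) along the body."""

    s: np.ndarray  # arclength fraction of body length, one value per station
    amplitude: np.ndarray  # metres
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))
    forward: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))
    lateral: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0]))


# ---------------------------------------------------------------------------
# resampling


def _equal_arclength_stations(points: np.ndarray, n_out: int) -> np.ndarray:
    """Resample one frame's markers with an interpolating cubic spline.

    The spline is parametrised by cumulative chord length and evaluated
    densely; stations are then placed at equal arclength along it.
    """
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    if np.any(seg <= 0):
        raise ValueError("coincident consecutive markers")
    spline = CubicSpline(t, points, axis=0)
    dense_t = np.linspace(0.0, t[-1], max(20 * n_out, 400))
    dense = spline(dense_t)
    dseg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(dseg)])
    targets = np.linspace(0.0, arc[-1], n_out)
    station_t = np.interp(targets, arc, dense_t)
    return spline(station_t)


def resample_midline(raw: MidlineTrack, n_out: int = 51,
                     keyframe_stride: int = 6) -> MidlineTrack:
    """Spline-resample a sparse marker track to equal-arclength stations.

    Every ``keyframe_stride``-th frame is treated as a keyframe through
    which an interpolating cubic spline is fitted and resampled at
    ``n_out`` equal-arclength stations; the intermediate frames are
    filled by linear interpolation of station coordinates between the
    bracketing keyframes, mirroring a digitisation workflow in which
    midlines are annotated on every sixth video frame.
    """
    if raw.n_markers < 2:
        raise ValueError("need at least 2 markers to resample")
    if n_out < raw.n_markers:
        raise ValueError("n_out must be at least the raw marker count")
    if keyframe_stride < 1:
        raise ValueError("keyframe_stride must be >= 1")

    nf = raw.n_frames
    keys = list(range(0, nf, keyframe_stride))
    if keys[-1] != nf - 1:
        keys.append(nf - 1)

    stations = np.empty((nf, n_out, 2))
    key_stations = {k: _equal_arclength_stations(raw.xy[k], n_out) for k in keys}
    for a, b in zip(keys[:-1], keys[1:]):
        sa, sb = key_stations[a], key_stations[b]
        for f in range(a, b + 1):
            w = 0.0 if b == a else (f - a) / (b - a)
            stations[f] = (1.0 - w) * sa + w * sb
    stations[keys[-1]] = key_stations[keys[-1]]
    return MidlineTrack(raw.times.copy(), stations, raw.body_length, raw.fps)


# ---------------------------------------------------------------------------
# principal frame, amplitude, frequency


def principal_frame(track: MidlineTrack):
    """Forward/lateral axes of a trial from PCA of the pooled point cloud.

    The first principal component of all tracked midline points is the
    forward direction, the second the lateral direction.  The lateral
    axis sign is chosen so the first tail-tip excursion is positive.
    """
    pts = track.xy.reshape(-1, 2)
    origin = pts.mean(axis=0)
    cov = np.cov((pts - origin).T)
    evals, evecs = np.linalg.eigh(cov)
    forward = evecs[:, np.argmax(evals)]
    lateral = np.array([-forward[1], forward[0]])
    # Deterministic sign conventions: forward points from mean snout to
    # mean tail station, lateral so the first tail-tip excursion is > 0.
    axis_dir = track.xy[:, -1].mean(axis=0) - track.xy[:, 0].mean(axis=0)
    if axis_dir @ forward < 0:
        forward = -forward
        lateral = -lateral
    tail_lat = (track.xy[:, -1] - origin) @ lateral
    peaks, _ = find_peaks(np.abs(tail_lat))
    pick = peaks[0] if peaks.size else int(np.argmax(np.abs(tail_lat)))
    if tail_lat[pick] < 0:
        lateral = -lateral
    return origin, forward, lateral


def amplitude_profile(track: MidlineTrack) -> AmplitudeProfile:
    """Per-station lateral amplitude: half the range of lateral displacement.

    Heading is removed by projecting on the trial's principal axes, so
    the profile is invariant under rigid rotation of the track.
    """
    if track.n_frames < 3:
        raise ValueError("need at least 3 frames to estimate amplitudes")
    origin, forward, lateral = principal_frame(track)
    lat = (track.xy - origin) @ lateral  # (n_frames, n_markers)
    amp = 0.5 * (lat.max(axis=0) - lat.min(axis=0))
    seg = np.linalg.norm(np.diff(track.xy, axis=1), axis=2)  # (nf, nm-1)
    arc = np.concatenate([np.zeros((track.n_frames, 1)), np.cumsum(seg, axis=1)], axis=1)
    s = (arc / arc[:, -1:]).mean(axis=0)
    return AmplitudeProfile(s, amp, origin, forward, lateral)


def _lowpass(sig: np.ndarray, fs: float, cutoff: float, axis: int = 0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass (no phase distortion)."""
    cutoff = min(cutoff, 0.45 * fs)
    b, a = butter(4, cutoff / (fs / 2.0))
    return filtfilt(b, a, sig, axis=axis)


def _bandpass(sig: np.ndarray, fs: float, lo: float, hi: float,
              axis: int = 0) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth band-pass."""
    hi = min(hi, 0.45 * fs)
    b, a = butter(2, [lo / (fs / 2.0), hi / (fs / 2.0)], btype="band")
    return filtfilt(b, a, sig, axis=axis)


def _dominant_frequency(sig: np.ndarray, fs: float) -> float:
    """Frequency of the largest non-DC spectral peak (Hann window)."""
    sig = sig - sig.mean()
    spec = np.abs(np.fft.rfft(sig * np.hanning(sig.size)))
    freqs = np.fft.rfftfreq(sig.size, 1.0 / fs)
    spec[0] = 0.0
    return float(freqs[int(np.argmax(spec))])


def _refine_peak(y: np.ndarray, k: int) -> float:
    """Parabolic sub-sample refinement of a discrete peak location."""
    if k <= 0 or k >= y.size - 1:
        return float(k)
    denom = y[k - 1] - 2.0 * y[k] + y[k + 1]
    if denom == 0:
        return float(k)
    return k + 0.5 * (y[k - 1] - y[k + 1]) / denom


def tailbeat_frequency(track: MidlineTrack, n_cycles: int = 3) -> float:
    """Tail-beat frequency from same-sign tail-tip excursion maxima.

    The lateral tail-tip displacement (heading removed via the principal
    frame) is scanned for positive-going maxima with a minimum
    prominence of 10% of the signal half-range; the frequency is the
    inverse of the mean period over the final ``n_cycles`` complete
    cycles.
    """
    origin, forward, lateral = principal_frame(track)
    tail = (track.xy[:, -1] - origin) @ lateral
    half_range = 0.5 * (tail.max() - tail.min())
    if half_range <= 0:
        raise ValueError("tail tip does not oscillate; no peaks found")
    # Tracking noise would spawn spurious maxima: low-pass (zero phase) at
    # three times the dominant frequency before scanning for peaks.
    f0 = _dominant_frequency(tail, track.fps)
    if f0 > 0:
        tail = _lowpass(tail, track.fps, 3.0 * f0)
        half_range = 0.5 * (tail.max() - tail.min())
        if half_range <= 0:
            raise ValueError("tail tip does not oscillate; no peaks found")
    peaks, _ = find_peaks(tail, prominence=0.1 * half_range)
    if peaks.size < n_cycles + 1:
        raise ValueError(
            f"found {peaks.size} tail-tip maxima; need {n_cycles + 1} for "
            f"{n_cycles} consecutive cycles"
        )
    use = peaks[-(n_cycles + 1):]
    times = np.array([_refine_peak(tail, k) for k in use]) / track.fps
    periods = np.diff(times)
    return float(1.0 / periods.mean())


# ---------------------------------------------------------------------------
# joint angles and phase lags


def _stations_at(points: np.ndarray, n_stations: int) -> np.ndarray:
    """Equal-arclength stations along a station polyline (linear interp)."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], n_stations)
    x = np.interp(targets, arc, points[:, 0])
    y = np.interp(targets, arc, points[:, 1])
    return np.column_stack([x, y])


def joint_angles(track: MidlineTrack, N: int = 20) -> JointAngleSeries:
    """Signed angles between consecutive equal-arclength body segments.

    The body is divided into ``N`` equal-arclength segments per frame;
    the joint angle ``phi_i`` is the signed angle between segment
    vectors ``i`` and ``i + 1`` (``i = 1..N-1``).  Angles are relative,
    hence invariant under rigid motion of the body.
    """
    if track.n_markers < N + 1:
        raise ValueError(
            f"track has {track.n_markers} stations; joint angles with N={N} "
            f"segments need at least N+1 — resample the midline first"
        )
    nf = track.n_frames
    angles = np.empty((nf, N - 1))
    for f in range(nf):
        raw_seg = np.linalg.norm(np.diff(track.xy[f], axis=0), axis=1)
        if np.any(raw_seg <= 0):
            raise ValueError(f"degenerate zero-length segment in frame {f}")
        pts = _stations_at(track.xy[f], N + 1)
        vec = np.diff(pts, axis=0)
        norms = np.linalg.norm(vec, axis=1)
        if np.any(norms <= 0):
            raise ValueError(f"degenerate zero-length segment in frame {f}")
        cross = vec[:-1, 0] * vec[1:, 1] - vec[:-1, 1] * vec[1:, 0]
        dot = np.einsum("ij,ij->i", vec[:-1], vec[1:])
        angles[f] = np.arctan2(cross, dot)
    return JointAngleSeries(angles, N, track.times.copy(), track.fps)


def circular_cross_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """c[k] = sum_t a[t] * b[(t + k) mod n] for two equal-length signals."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("signals must be 1-D and of equal length")
    return np.real(np.fft.ifft(np.conj(np.fft.fft(a)) * np.fft.fft(b)))


def _xcorr_delay(a: np.ndarray, b: np.ndarray, max_lag: int) -> float:
    """Delay (in samples) of b relative to a at the circular xcorr peak.

    The lag search is restricted to ``[0, max_lag)`` and the discrete
    peak is refined with a parabolic fit through its neighbours; a tie
    resolves to the smallest lag (first maximum).
    """
    a = a - a.mean()
    b = b - b.mean()
    if np.allclose(a, 0) or np.allclose(b, 0):
        raise ValueError("zero-variance signal; cross-correlation undefined")
    c = circular_cross_correlation(a, b)
    n = c.size
    k = int(np.argmax(c[:max_lag]))
    y = np.array([c[(k - 1) % n], c[k], c[(k + 1) % n]])
    denom = y[0] - 2.0 * y[1] + y[2]
    delta = 0.0 if denom == 0 else 0.5 * (y[0] - y[2]) / denom
    return max(k + delta, 0.0)


def _integer_cycles_slice(n_samples: int, T: float, fs: float, min_cycles: int = 3):
    n_cyc = int(math.floor((n_samples / fs) / T))
    if n_cyc < min_cycles:
        raise ValueError(
            f"signal covers {n_cyc} full cycles; need at least {min_cycles}"
        )
    n = int(round(n_cyc * T * fs))
    return slice(n_samples - n, n_samples)


def phase_lags(angles: JointAngleSeries, T: float | None = None,
               mode: Literal["full", "endpoint", "plain"] = "full",
               spatial_window: int | None = None) -> PhaseLagResult:
    """Intersegmental phase lags, overall phase lag and wavelength.

    For each adjacent joint pair the delay of the posterior joint-angle
    signal relative to the anterior one is found at the maximum of their
    circular cross-correlation over an integer number of cycles, with
    the lag restricted to ``[0, T/2)`` and parabolic sub-frame
    refinement; ``delta_phi_i = lag / T * 2 pi``.

    ``mode`` controls how the sum over the ``N - 2`` measurable
    adjacent-joint lags is completed to the overall body phase lag:

    * ``"full"`` (default): one mean adjacent lag is appended at each
      body end, so the sum spans all ``N`` segments and a pure traveling
      wave of wavelength ``lam`` body lengths yields
      ``delta_Phi = 2 pi / lam``.
    * ``"endpoint"``: a single mean lag is appended.
    * ``"plain"``: the bare ``N - 2``-term sum.

    The wavelength is ``2 pi / delta_Phi`` in body lengths.

    Each angle signal is band-pass filtered (zero phase) around the
    cycle frequency before correlating, which leaves the lag of a
    traveling wave untouched while suppressing tracking noise outside
    the tail-beat band.  ``spatial_window`` additionally applies an odd-
    width Savitzky-Golay smoother along the body — recommended for noisy
    digitised midlines, at the price of some edge distortion for waves
    much shorter than the body.
    """
    if T is None:
        T = angles.cycle_duration
    if T is None or not T > 0:
        raise ValueError("cycle duration T must be known (run tailbeat_frequency)")
    fs = angles.fps
    sl = _integer_cycles_slice(angles.angles.shape[0], T, fs)
    sig = angles.angles
    if spatial_window is not None:
        if spatial_window % 2 == 0 or spatial_window < 3:
            raise ValueError("spatial_window must be an odd width >= 3")
        sig = savgol_filter(sig, min(spatial_window, sig.shape[1]), 2, axis=1)
    sig = _bandpass(sig, fs, 0.6 / T, 3.0 / T, axis=0)[sl]
    max_lag = max(int(math.floor(T * fs / 2.0)), 1)
    n_pairs = sig.shape[1] - 1
    lags = np.empty(n_pairs)
    for i in range(n_pairs):
        lags[i] = _xcorr_delay(sig[:, i], sig[:, i + 1], max_lag)
    delta = lags / fs / T * 2.0 * math.pi
    mean_lag = delta.mean()
    if mode == "full":
        delta_all = np.concatenate([[mean_lag], delta, [mean_lag]])
    elif mode == "endpoint":
        delta_all = np.concatenate([delta, [mean_lag]])
    elif mode == "plain":
        delta_all = delta
    else:
        raise ValueError(f"unknown mode {mode!r}")
    overall = float(delta_all.sum())
    wavelength = 2.0 * math.pi / overall if overall > 0 else math.inf
    return PhaseLagResult(delta_all, overall, wavelength)


# ---------------------------------------------------------------------------
# foil--fish phase difference and spacing


def phase_difference(foil_te: TrajectorySeries, fish_te: TrajectorySeries,
                     T: float) -> float:
    """Phase by which the fish trailing edge lags the foil trailing edge.

    Both lateral-displacement series are resampled onto the coarser
    common time base over their overlapping window, cropped to an
    integer number of cycles, and circularly cross-correlated; the
    result is ``lag / T * 2 pi`` in ``[0, 2 pi)``.
    """
    t0 = max(foil_te.times[0], fish_te.times[0])
    t1 = min(foil_te.times[-1], fish_te.times[-1])
    if t1 - t0 < 3.0 * T:
        raise ValueError("series overlap covers fewer than 3 shared cycles")
    dt = max(foil_te.dt, fish_te.dt)
    fs = 1.0 / dt
    n = int(math.floor((t1 - t0) / dt)) + 1
    times = t0 + np.arange(n) * dt
    a = np.interp(times, foil_te.times, foil_te.values)
    b = np.interp(times, fish_te.times, fish_te.values)
    sl = _integer_cycles_slice(n, T, fs)
    max_lag = max(int(math.floor(T * fs)), 1)
    lag = _xcorr_delay(a[sl], b[sl], max_lag)
    return float((lag / fs / T * 2.0 * math.pi) % (2.0 * math.pi))


def unwrap_phases(distances: Sequence[float], phases: Sequence[float]):
    """Unwrap phase-difference samples ordered by increasing distance."""
    d = np.asarray(distances, dtype=float)
    p = np.asarray(phases, dtype=float)
    order = np.argsort(d)
    unwrapped = np.unwrap(p[order])
    return d[order], unwrapped


def gap_distance(foil_te_pos, fish_snout) -> float:
    """Euclidean distance between mean foil trailing edge and mean snout.

    Accepts single points or ``(n, 2)`` windows of positions, which are
    averaged before taking the distance.
    """
    a = np.asarray(foil_te_pos, dtype=float)
    b = np.asarray(fish_snout, dtype=float)
    if a.ndim == 2:
        a = a.mean(axis=0)
    if b.ndim == 2:
        b = b.mean(axis=0)
    return float(np.linalg.norm(a - b))
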