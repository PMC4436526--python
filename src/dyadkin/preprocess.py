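"""The five-step cleaning pipeline for raw tracker recordings.

Order is fixed: (1) despike each channel on its double-differenced
(acceleration) series; (2) zero-phase low-pass Butterworth filtering;
(3) 13 degree in-plane rotation of the actor's positions in the video
condition, correcting the angled game board; (4) a 111 ms backward shift
of the imitator's channels in the video condition, compensating the
camera-to-projection latency; (5) trial segmentation from the index
fingertip's displacement away from the start marker.  Each step is
independently callable; :func:`preprocess_recording` applies 1-4 with the
role/feedback gating, and :func:`segment_trials` performs step 5.

Orientation channels (azimuth/elevation/roll) are unwrapped to a
continuous representation before any differencing, are despiked and
filtered like positions, but are never rotated (the rotation acts on x
and y only).
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np

from .config import PreprocessConfig
from .core import (
    CHANNELS,
    ORIENTATION_DOFS,
    TRACKERS,
    Feedback,
    Recording,
    Role,
    TrialWindow,
)
from scipy import signal

log = logging.getLogger(__name__)


def despike(
    series: np.ndarray, sd_threshold: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Remove single-sample electromagnetic artifacts, single pass.

    Acceleration is the twice-applied first difference of the series.
    Samples whose acceleration deviates more than ``sd_threshold`` SDs
    from the acceleration mean are spike candidates; because one bad
    sample splashes across three acceleration values, adjacent candidates
    are coalesced and the sample with the largest deviation is flagged.
    Each flagged sample and its immediate neighbours are replaced by
    linear interpolation between the samples two positions either side.

    Returns ``(cleaned, flagged_indices)``.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 7:
        raise ValueError("despike requires at least 7 samples")
    acc = np.diff(x, n=2)  # acc[j] is centred on original sample j + 1
    dev = np.abs(acc - acc.mean())
    sd = acc.std()
    if sd == 0:
        return x.copy(), np.array([], dtype=int)
    candidates = np.flatnonzero(dev > sd_threshold * sd) + 1  # original index

    flagged: list[int] = []
    i = 0
    while i < len(candidates):
        j = i
        while j + 1 < len(candidates) and candidates[j + 1] - candidates[j] <= 2:
            j += 1
        group = candidates[i : j + 1]
        flagged.append(int(group[np.argmax(dev[group - 1])]))
        i = j + 1
    flagged_arr = np.array(flagged, dtype=int)

    cleaned = x.copy()
    for f in flagged_arr:
        lo, hi = max(f - 2, 0), min(f + 2, n - 1)
        span = hi - lo
        for k in range(max(f - 1, 0), min(f + 1, n - 1) + 1):
            w = (k - lo) / span
            cleaned[k] = (1 - w) * x[lo] + w * x[hi]
    if len(flagged_arr) > 0.10 * n:
        warnings.warn(
            f"despike flagged {len(flagged_arr)}/{n} samples; series likely corrupt",
            stacklevel=2,
        )
    return cleaned, flagged_arr


def lowpass_filter(
    series: np.ndarray, cutoff_hz: float, order: int, fs: float
) -> np.ndarray:
    """Zero-phase (forward-backward) low-pass Butterworth filter.

    Applied twice (once per direction), the amplitude response at the
    cutoff is 0.5 rather than the single-pass 1/sqrt(2).  Edge effects are
    handled by odd-reflection padding of length ``3 * (order + 1)``.
    """
    x = np.asarray(series, dtype=float)
    if cutoff_hz >= fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    padlen = 3 * (order + 1)
    if len(x) <= padlen:
        raise ValueError(f"series too short to filter (need > {padlen} samples)")
    b, a = signal.butter(order, cutoff_hz, fs=fs)
    return signal.filtfilt(b, a, x, padlen=padlen)


def rotate_xy(
    x: np.ndarray, y: np.ndarray, angle_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """In-plane rotation, samplewise:

    ``x' = x cos(a) - y sin(a)``, ``y' = y cos(a) + x sin(a)``.

    With ``a = 13`` this is the correction applied to the actor's position
    data in the video condition, undoing the board's 13 degree tilt.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return x * c - y * s, y * c + x * s


def shift_latency(rec: Recording, latency_s: float) -> Recording:
    """Advance all channels by ``round(latency_s * fs)`` samples.

    Compensates the video-presentation latency for the imitator in the
    video condition (111 ms at 240 Hz -> 27 samples).  The vacated tail is
    filled by repeating the final sample; length is unchanged.  The
    operation itself is role-agnostic; the caller gates it.
    """
    if latency_s < 0:
        raise ValueError("latency must be non-negative")
    k = int(round(latency_s * rec.sample_rate))
    n = rec.n_samples
    if k >= n:
        raise ValueError("latency shift exceeds the recording length")
    if k == 0:
        return rec.copy()
    out = rec.copy()
    arr = out.data.to_numpy()
    arr[: n - k] = arr[k:]
    arr[n - k :] = arr[n - k - 1]
    out.data.iloc[:, :] = arr
    return out


def unwrap_orientation(rec: Recording) -> Recording:
    """Unwrap orientation channels (degrees) to a continuous form."""
    out = rec.copy()
    for tracker in TRACKERS:
        for dof in ORIENTATION_DOFS:
            col = f"{tracker}_{dof}"
            out.data[col] = np.unwrap(out.data[col].to_numpy(), period=360.0)
    return out


def segment_trials(rec: Recording, cfg: PreprocessConfig | None = None) -> list[TrialWindow]:
    """Detect action trials from the index fingertip displacement.

    Maximal runs where the fingertip's 3D distance from the start marker
    exceeds ``trial_min_displacement_mm`` for longer than
    ``trial_min_duration_s`` become trial windows; shorter excursions are
    false starts and are discarded.  At most the first ``max_trials``
    windows are kept.  Segmentation runs on the actor; the same windows
    are applied to the paired imitator, whose movements are cue-locked to
    the actor's.
    """
    cfg = cfg or PreprocessConfig()
    index = rec.position("index")
    disp = np.linalg.norm(index - rec.start_point[None, :], axis=1)
    mask = disp > cfg.trial_min_displacement_mm
    min_len = int(cfg.trial_min_duration_s * rec.sample_rate)
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    windows = [
        TrialWindow(int(s), int(e))
        for s, e in zip(edges[::2], edges[1::2])
        if (e - s) > min_len
    ]
    if not windows:
        raise ValueError(
            f"no trials found for {rec.person_id} "
            f"({rec.feedback.value}/{rec.difficulty.value})"
        )
    if len(windows) > cfg.max_trials:
        log.info("found %d windows; keeping the first %d", len(windows), cfg.max_trials)
        windows = windows[: cfg.max_trials]
    return windows


def preprocess_recording(
    rec: Recording, cfg: PreprocessConfig | None = None
) -> tuple[Recording, dict[str, int]]:
    """Apply cleaning steps 1-4 with role/feedback gating.

    Despiking and filtering apply to every channel (orientations after
    unwrapping); the 13 degree rotation applies to the actor's x/y
    positions in the video condition only; the latency shift applies to
    the imitator in the video condition only.  Returns the cleaned
    recording and a per-channel spike-count report.
    """
    cfg = (cfg or PreprocessConfig()).validate(rec.sample_rate)
    out = unwrap_orientation(rec)
    flags: dict[str, int] = {}
    for col in CHANNELS:
        cleaned, idx = despike(out.data[col].to_numpy(), cfg.spike_sd_threshold)
        flags[col] = int(len(idx))
        out.data[col] = lowpass_filter(
            cleaned, cfg.filter_cutoff_hz, cfg.filter_order, rec.sample_rate
        )
    if rec.role == Role.actor and rec.feedback == Feedback.video:
        for tracker in TRACKERS:
            xs, ys = f"{tracker}_x", f"{tracker}_y"
            x, y = rotate_xy(
                out.data[xs].to_numpy(), out.data[ys].to_numpy(), cfg.rotation_deg
            )
            out.data[xs], out.data[ys] = x, y
        sx, sy = rotate_xy(
            out.start_point[:1], out.start_point[1:2], cfg.rotation_deg
        )
        out.start_point = np.array([sx[0], sy[0], out.start_point[2]])
    if rec.role == Role.imitator and rec.feedback == Feedback.video:
        out = shift_latency(out, cfg.video_latency_s)
    return out, flags
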