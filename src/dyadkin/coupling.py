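"""Lag-scanned cross-correlation between actor and imitator series.

For each lag l in [-L, +L] samples, the Pearson correlation is computed
between ``a[t]`` and ``b[t + l]`` over their overlap of ``n - |l|``
samples, using that segment's own means and variances (no zero padding,
no global normalization).  Sign convention: a POSITIVE lag means the
imitator's signal follows the actor's.  Per trial, the lag maximizing
|r| and the r there summarize coupling; trials are averaged to one value
per condition, and the exploratory all-pairs analysis produces 42x42
mean-r and mean-lag surface maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core import CHANNELS, Recording, TrialWindow

log = logging.getLogger(__name__)


@dataclass
class LagCurve:
    """Correlation as a function of lag (samples)."""

    lags: np.ndarray      # sample offsets, -L..+L
    r: np.ndarray         # Pearson r per lag; NaN where undefined
    n_overlap: np.ndarray
    sample_rate: float

    @property
    def lags_s(self) -> np.ndarray:
        return self.lags / self.sample_rate


@dataclass
class CouplingResult:
    r_abs_max: float
    lag_at_max_s: float
    signed_r_at_max: float


def xcorr_lagscan(
    a: np.ndarray,
    b: np.ndarray,
    max_lag: int,
    min_overlap_frac: float = 0.5,
    sample_rate: float = 240.0,
) -> LagCurve:
    """Pearson correlation of ``a[t]`` with ``b[t + l]`` for each lag l.

    Lags whose overlap falls below ``min_overlap_frac * n`` samples, or
    whose overlap has zero variance in either series, are NaN.  Uses
    FFT-accelerated sliding sums; both series are pre-centred on their
    global means (which leaves Pearson r unchanged) to keep the raw-sum
    formula numerically accurate.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n = len(a)
    if len(b) != n:
        raise ValueError("series must have equal length")
    if n <= 2:
        raise ValueError("series too short")
    if not (0 < max_lag < n):
        raise ValueError("max_lag must be in (0, n)")

    a = a - a.mean()
    b = b - b.mean()
    lags = np.arange(-max_lag, max_lag + 1)
    m = (n - np.abs(lags)).astype(float)

    # cross[l] = sum_t a[t] * b[t + l]
    full = signal.correlate(b, a, mode="full", method="auto")
    cross = full[(n - 1) - max_lag : (n - 1) + max_lag + 1]

    ca = np.concatenate([[0.0], np.cumsum(a)])
    cb = np.concatenate([[0.0], np.cumsum(b)])
    ca2 = np.concatenate([[0.0], np.cumsum(a * a)])
    cb2 = np.concatenate([[0.0], np.cumsum(b * b)])

    pos = lags >= 0
    # Overlap of a: [0, n-l) for l >= 0, [-l, n) for l < 0; of b the mirror.
    sa = np.where(pos, ca[np.clip(n - lags, 0, n)], ca[n] - ca[np.clip(-lags, 0, n)])
    sb = np.where(pos, cb[n] - cb[np.clip(lags, 0, n)], cb[np.clip(n + lags, 0, n)])
    sa2 = np.where(pos, ca2[np.clip(n - lags, 0, n)], ca2[n] - ca2[np.clip(-lags, 0, n)])
    sb2 = np.where(pos, cb2[n] - cb2[np.clip(lags, 0, n)], cb2[np.clip(n + lags, 0, n)])

    var_a = m * sa2 - sa**2
    var_b = m * sb2 - sb**2
    num = m * cross - sa * sb
    scale_a = np.maximum(ca2[n], 1e-300)
    scale_b = np.maximum(cb2[n], 1e-300)
    ok = (var_a > 1e-12 * m * scale_a / n) & (var_b > 1e-12 * m * scale_b / n)
    ok &= m >= min_overlap_frac * n
    r = np.full(lags.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        r[ok] = num[ok] / np.sqrt(var_a[ok] * var_b[ok])
    r = np.clip(r, -1.0, 1.0, out=r)
    if not np.isfinite(r).any():
        raise ValueError("correlation undefined at every lag")
    return LagCurve(lags, r, m.astype(int), sample_rate)


def abs_max(curve: LagCurve) -> CouplingResult:
    """Lag of the absolute-maximum correlation.

    Ties in |r| are broken toward the smallest |lag|, then toward the
    negative lag.
    """
    absr = np.abs(curve.r)
    if not np.isfinite(absr).any():
        raise ValueError("curve has no defined lag")
    mx = np.nanmax(absr)
    cand = np.flatnonzero(absr == mx)
    order = sorted(cand, key=lambda i: (abs(int(curve.lags[i])), int(curve.lags[i])))
    i = order[0]
    return CouplingResult(
        r_abs_max=float(mx),
        lag_at_max_s=float(curve.lags[i] / curve.sample_rate),
        signed_r_at_max=float(curve.r[i]),
    )


@dataclass
class TrialCoupling:
    per_trial: list[CouplingResult | None]
    mean_r_abs: float
    mean_lag_s: float

    @property
    def r_abs(self) -> np.ndarray:
        return np.array(
            [t.r_abs_max if t is not None else np.nan for t in self.per_trial]
        )

    @property
    def lag_s(self) -> np.ndarray:
        return np.array(
            [t.lag_at_max_s if t is not None else np.nan for t in self.per_trial]
        )


def trial_coupling(
    actor_dv: np.ndarray,
    imitator_dv: np.ndarray,
    windows: list[TrialWindow],
    sample_rate: float,
    max_lag_s: float = 5.0,
    min_overlap_frac: float = 0.5,
    exclude_trials: set[int] | None = None,
) -> TrialCoupling:
    """Per-trial lag scan + absolute maximum, averaged across trials.

    ``actor_dv`` / ``imitator_dv`` are full-session derived-variable
    series; each window is scanned independently.  Trials listed in
    ``exclude_trials`` (0-based) or yielding an undefined curve are
    skipped before averaging.
    """
    if not windows:
        raise ValueError("need at least one trial window")
    exclude = exclude_trials or set()
    results: list[CouplingResult | None] = []
    for i, w in enumerate(windows):
        if i in exclude:
            results.append(None)
            continue
        a = np.asarray(actor_dv[w.start : w.end], dtype=float)
        b = np.asarray(imitator_dv[w.start : w.end], dtype=float)
        max_lag = min(int(round(max_lag_s * sample_rate)), w.n_samples - 1)
        try:
            curve = xcorr_lagscan(a, b, max_lag, min_overlap_frac, sample_rate)
            results.append(abs_max(curve))
        except ValueError as exc:
            log.info("trial %d excluded from coupling mean: %s", i, exc)
            results.append(None)
    valid = [t for t in results if t is not None]
    if not valid:
        raise ValueError("no trial produced a defined coupling result")
    return TrialCoupling(
        per_trial=results,
        mean_r_abs=float(np.mean([t.r_abs_max for t in valid])),
        mean_lag_s=float(np.mean([t.lag_at_max_s for t in valid])),
    )


@dataclass
class SurfaceMaps:
    """42x42 exploratory maps, actor channels on rows, imitator on columns."""

    r_map: pd.DataFrame
    lag_map: pd.DataFrame


def surface_maps(
    actor: Recording,
    imitator: Recording,
    windows: list[TrialWindow],
    max_lag_s: float = 5.0,
    min_overlap_frac: float = 0.5,
) -> SurfaceMaps:
    """Mean absolute-maximum r and its lag for every ordered channel pair."""
    r_map = pd.DataFrame(
        np.nan, index=list(CHANNELS), columns=list(CHANNELS), dtype=float
    )
    lag_map = r_map.copy()
    a_cols = {c: actor.channel(c) for c in CHANNELS}
    b_cols = {c: imitator.channel(c) for c in CHANNELS}
    for ca in CHANNELS:
        for cb in CHANNELS:
            try:
                tc = trial_coupling(
                    a_cols[ca], b_cols[cb], windows, actor.sample_rate,
                    max_lag_s, min_overlap_frac,
                )
            except ValueError:
                continue
            r_map.loc[ca, cb] = tc.mean_r_abs
            lag_map.loc[ca, cb] = tc.mean_lag_s
    return SurfaceMaps(r_map=r_map, lag_map=lag_map)
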