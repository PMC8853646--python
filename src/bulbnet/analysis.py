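"""LFP spectral analysis, windowed firing rates, correlations and curve fits.

The local field potential is the inverse-distance-weighted sum of synaptic
currents (a point-source approximation with extracellular conductivity
sigma = 1/300 1/(Ohm cm)); its spectrum is estimated by Welch's method
after low-pass filtering and discarding the initial transient.  Odor
decorrelation is quantified through per-window Pearson correlations of MC
firing-rate vectors.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize, signal

__all__ = [
    "lfp_point_source",
    "lfp_spectrum",
    "windowed_rates",
    "window_starts",
    "correlation_timecourse",
    "summary_correlation",
    "fit_stretched_exp",
]

#: uV produced by 1 pA at 1 um distance, sigma = 1/300 1/(Ohm cm)
UV_PER_PA_UM = 1e-12 / (4.0 * math.pi * (1.0 / 300.0) * 1e-4) * 1e6


def lfp_point_source(currents, positions, electrode, min_distance: float = 1.0):
    """phi(t) in uV from per-synapse current traces (pA).

    ``currents``: array (n_synapses, n_steps); ``positions``: (n_synapses, 3)
    in um; ``electrode``: 3-point in um.  Distances are clamped to
    ``min_distance`` to avoid the point-source singularity.
    """
    currents = np.atleast_2d(np.asarray(currents, dtype=float))
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    e = np.asarray(electrode, dtype=float)
    d = np.linalg.norm(positions - e[None, :], axis=1)
    w = UV_PER_PA_UM / np.maximum(d, min_distance)
    return w @ currents


def lfp_spectrum(
    trace,
    dt: float = 0.1,
    cutoff_hz: float = 200.0,
    discard_ms: float = 200.0,
    window_ms: float = 400.0,
):
    """Welch power spectrum of an LFP trace.

    6th-order low-pass Butterworth at ``cutoff_hz``, linear detrend, drop
    the first ``discard_ms``, then Welch with ``window_ms`` segments at 50%
    overlap.  Returns (frequencies Hz, power).
    """
    trace = np.asarray(trace, dtype=float)
    fs = 1000.0 / dt  # Hz
    n_discard = int(round(discard_ms / dt))
    nperseg = int(round(window_ms / dt))
    if trace.size < n_discard + nperseg:
        raise ValueError(
            f"trace too short: need >= {discard_ms + window_ms} ms of signal"
        )
    sos = signal.butter(6, cutoff_hz, btype="low", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, trace)
    filtered = signal.detrend(filtered)
    filtered = filtered[n_discard:]
    freqs, power = signal.welch(
        filtered, fs=fs, nperseg=nperseg, noverlap=nperseg // 2
    )
    return freqs, power


def window_starts(duration: float, window: float, overlap: float = 0.5) -> np.ndarray:
    """Start times (ms) of sliding windows covering [0, duration]."""
    step = window * (1.0 - overlap)
    if step <= 0:
        raise ValueError("overlap must be < 1")
    starts = np.arange(0.0, duration - window + 1e-9, step)
    return starts


def windowed_rates(
    spikes,
    n_cells: int,
    duration: float,
    window: float,
    overlap: float = 0.5,
    cell_subset=None,
) -> np.ndarray:
    """Firing-rate matrix (cells x windows, Hz) from a (cell_id, t_ms) event list."""
    if window <= 0:
        raise ValueError("window must be positive")
    spikes = np.asarray(spikes, dtype=float).reshape(-1, 2)
    starts = window_starts(duration, window, overlap)
    if cell_subset is None:
        cell_subset = np.arange(n_cells)
    cell_subset = np.asarray(cell_subset, dtype=int)
    index = -np.ones(n_cells, dtype=int)
    index[cell_subset] = np.arange(len(cell_subset))
    rates = np.zeros((len(cell_subset), len(starts)))
    if spikes.size == 0:
        return rates
    ids = spikes[:, 0].astype(int)
    ts = spikes[:, 1]
    for wi, t0 in enumerate(starts):
        in_win = (ts >= t0) & (ts < t0 + window)
        if not in_win.any():
            continue
        sel = ids[in_win]
        rows = index[sel]
        valid = rows >= 0
        counts = np.bincount(rows[valid], minlength=len(cell_subset))
        rates[:, wi] = counts * 1000.0 / window
    return rates


def correlation_timecourse(rates_a, rates_b) -> np.ndarray:
    """Per-window Pearson correlation over the cell dimension.

    Windows where either vector has zero variance yield NaN (excluded from
    downstream summaries rather than scored 0).
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rate matrices must have matching shapes")
    out = np.full(a.shape[1], np.nan)
    for w in range(a.shape[1]):
        x, y = a[:, w], b[:, w]
        sx, sy = x.std(), y.std()
        if sx == 0.0 or sy == 0.0:
            continue
        out[w] = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return out


def summary_correlation(
    corr: np.ndarray,
    window: float,
    overlap: float,
    duration: float,
    skip_ms: float | None = None,
    sniff_hz: float = 6.0,
) -> float:
    """Mean per-window correlation after the first sniff (NaN windows skipped)."""
    if skip_ms is None:
        skip_ms = 1000.0 / sniff_hz
    starts = window_starts(duration, window, overlap)
    keep = starts >= skip_ms
    vals = np.asarray(corr)[keep]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def fit_stretched_exp(x, y, p0=None) -> tuple[float, float, float]:
    """Least-squares fit of a * exp(-b * x**n); returns (a, b, n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    good = np.isfinite(x) & np.isfinite(y)
    x, y = x[good], y[good]
    if x.size < 4:
        raise ValueError("need at least 4 points for the stretched-exponential fit")

    def model(x, a, b, n):
        return a * np.exp(-b * np.power(np.maximum(x, 1e-12), n))

    if p0 is None:
        a0 = max(y.max(), 1e-9)
        # crude initial decay scale from the half point
        xr = x[y < a0 / 2.0]
        x_half = xr.min() if xr.size else (x.max() if x.max() > 0 else 1.0)
        p0 = (a0, math.log(2.0) / max(x_half, 1e-6), 1.0)
    try:
        popt, _ = optimize.curve_fit(
            model,
            x,
            y,
            p0=p0,
            maxfev=20000,
            bounds=([0.0, 0.0, 0.05], [np.inf, np.inf, 10.0]),
        )
    except RuntimeError as err:
        resid = y - model(x, *p0)
        raise RuntimeError(
            f"stretched-exponential fit failed; initial residual norm "
            f"{np.linalg.norm(resid):.3g}"
        ) from err
    return tuple(float(v) for v in popt)
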