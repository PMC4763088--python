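"""Sliding-window EMG feature extraction.

Each analysis window yields, per channel, the four Hudgins time-domain
features — mean absolute value (MAV), zero crossings (ZC), slope-sign
changes (SSC) and waveform length (WL) — followed by the six coefficients of
a fitted autoregressive (AR) model, i.e. 10 features per channel.  Windows
are *trailing* (causal): a window is timestamped at its trailing edge and
spans the preceding ``window_ms`` milliseconds; consecutive windows advance
by the frame increment (25 ms by default).

Conventions
-----------
* ZC counts sample pairs whose signs differ or where exactly one sample is
  zero (a sampled sine that touches zero at an endpoint still counts that
  crossing), subject to the ``zc_threshold`` amplitude dead-band.
* SSC counts interior samples that are a strict local extremum, with both
  neighbouring slopes at least ``ssc_threshold`` in magnitude.
* AR coefficients follow the positive convention
  ``x_t = a_1 x_{t-1} + ... + a_p x_{t-p} + e_t``; a zero-variance window
  returns all-zero coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.linalg import solve_toeplitz

FEATURES_PER_CHANNEL = 10
_AR_NUGGET = 1e-9  # relative ridge on the zero-lag autocovariance
_ZERO_VAR = 1e-20


@dataclass
class FeatureConfig:
    """Windowing and feature-extraction parameters.

    Parameters
    ----------
    window_ms
        Analysis window length L in milliseconds (= samples at 1000 Hz).
    increment_ms
        Frame increment between consecutive windows (default 25 ms).
    ar_order
        Autoregressive model order (default 6).
    zc_threshold, ssc_threshold
        Amplitude dead-bands for the zero-crossing and slope-sign-change
        counts, in signal units (default 0).
    ar_method
        ``"yule_walker"`` (autocorrelation/Levinson, deterministic, default)
        or ``"burg"``.
    """

    window_ms: int
    increment_ms: int = 25
    ar_order: int = 6
    zc_threshold: float = 0.0
    ssc_threshold: float = 0.0
    ar_method: str = "yule_walker"

    def __post_init__(self) -> None:
        if not self.increment_ms > 0:
            raise ValueError("increment_ms must be positive")
        if self.window_ms < self.increment_ms:
            raise ValueError("window_ms must be >= increment_ms")
        if self.ar_order < 1:
            raise ValueError("ar_order must be >= 1")
        if self.zc_threshold < 0 or self.ssc_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if self.ar_method not in ("yule_walker", "burg"):
            raise ValueError(f"unknown ar_method {self.ar_method!r}")


@dataclass
class FeatureVector:
    """Features for one analysis window: 10 per channel, channel-major order."""

    values: np.ndarray
    window_end_ms: float
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


def window_count(duration_ms: int, window_ms: int, increment_ms: int) -> int:
    """Number of trailing windows fitting a recording: floor((T-L)/D) + 1, or 0."""
    if duration_ms < window_ms:
        return 0
    return (duration_ms - window_ms) // increment_ms + 1


def window_label(labels: np.ndarray) -> str:
    """Modal per-sample label; ties break toward the earlier-occurring class."""
    labels = np.asarray(labels)
    if labels[0] == labels[-1] and len(set(labels[:: max(1, len(labels) // 8)])) == 1:
        # cheap fast path; verify to stay exact
        uniq = np.unique(labels)
        if len(uniq) == 1:
            return str(uniq[0])
    values, first_idx, counts = np.unique(labels, return_index=True, return_counts=True)
    best = counts.max()
    tied = first_idx[counts == best]
    return str(labels[tied.min()])


def slide_windows(recording, config: FeatureConfig):
    """Trailing windows of a recording at the configured increment.

    Returns a list of ``(window_matrix, window_end_ms, label)`` where the
    window matrix has exactly ``window_ms`` rows.  A recording shorter than
    one window yields an empty list and a warning.
    """
    T = recording.n_samples
    L = config.window_ms
    if T < L:
        warnings.warn(
            f"recording of {T} ms is shorter than one {L} ms window; no windows emitted",
            stacklevel=2,
        )
        return []
    out = []
    for start in range(0, T - L + 1, config.increment_ms):
        end = start + L
        out.append((recording.samples[start:end], float(end), window_label(recording.labels[start:end])))
    return out


# ---------------------------------------------------------------------------
# Time-domain features


def td_features(window_channel, zc_threshold: float = 0.0, ssc_threshold: float = 0.0):
    """Hudgins time-domain features (MAV, ZC, SSC, WL) for one channel window."""
    x = np.asarray(window_channel, dtype=float)
    if x.size == 0:
        raise ValueError("window is empty")
    mav = float(np.mean(np.abs(x)))
    wl = float(np.sum(np.abs(np.diff(x)))) if x.size > 1 else 0.0
    zc = int(_zc_count(x[None, :, None], zc_threshold)[0, 0])
    ssc = int(_ssc_count(x[None, :, None], ssc_threshold)[0, 0])
    return mav, zc, ssc, wl


def _zc_count(w: np.ndarray, threshold: float) -> np.ndarray:
    # w: (m, L, C)
    s = np.sign(w)
    a, b = s[:, :-1], s[:, 1:]
    step = np.abs(w[:, 1:] - w[:, :-1])
    crossed = (a * b <= 0) & ~((a == 0) & (b == 0)) & (step >= threshold)
    return crossed.sum(axis=1)


def _ssc_count(w: np.ndarray, threshold: float) -> np.ndarray:
    if w.shape[1] < 3:
        return np.zeros((w.shape[0], w.shape[2]), dtype=int)
    d1 = w[:, 1:-1] - w[:, :-2]
    d2 = w[:, 1:-1] - w[:, 2:]
    turned = (d1 * d2 > 0) & (np.minimum(np.abs(d1), np.abs(d2)) >= threshold)
    return turned.sum(axis=1)


# ---------------------------------------------------------------------------
# Autoregressive features


def ar_coefficients(window_channel, order: int, method: str = "yule_walker") -> np.ndarray:
    """Coefficients of an all-pole AR model fitted to one channel window.

    Uses the autocorrelation (Yule-Walker) method solved by Levinson
    recursion, or Burg's method when requested.  Zero-variance input returns
    all zeros by convention.

    Raises
    ------
    ValueError
        If the window has ``order`` samples or fewer.
    """
    x = np.asarray(window_channel, dtype=float)
    if x.size <= order:
        raise ValueError(f"window of {x.size} samples is too short for AR order {order}")
    x = x - x.mean()
    if method == "burg":
        return _burg(x, order)
    n = x.size
    r = np.array([x[: n - k] @ x[k:] for k in range(order + 1)]) / n
    if r[0] <= _ZERO_VAR:
        return np.zeros(order)
    c = r[:order].copy()
    c[0] *= 1.0 + _AR_NUGGET
    try:
        return solve_toeplitz((c, c), r[1 : order + 1])
    except np.linalg.LinAlgError:
        from scipy.linalg import toeplitz

        T = toeplitz(c)
        return np.linalg.lstsq(T, r[1 : order + 1], rcond=None)[0]


def _burg(x: np.ndarray, order: int) -> np.ndarray:
    """Burg lattice recursion; returns positive-convention AR coefficients."""
    f = x.copy()
    b = x.copy()
    a = np.zeros(order)
    dk = f @ f + b @ b
    kk = np.zeros(order)
    aa = np.array([1.0])
    for m in range(order):
        num = -2.0 * (f[m + 1 :] @ b[m:-1])
        den = f[m + 1 :] @ f[m + 1 :] + b[m:-1] @ b[m:-1]
        k = 0.0 if den <= _ZERO_VAR else num / den
        kk[m] = k
        new_f = f[m + 1 :] + k * b[m:-1]
        new_b = b[m:-1] + k * f[m + 1 :]
        f[m + 1 :] = new_f
        b[m + 1 :] = new_b
        aa = np.concatenate([aa, [0.0]]) + k * np.concatenate([[0.0], aa[::-1]])
    # aa holds the monic polynomial [1, c1..cp]; positive convention negates
    a = -aa[1:]
    return a


def _ar_batch(w: np.ndarray, order: int) -> np.ndarray:
    """Yule-Walker AR fits for a stack of windows.

    ``w`` has shape ``(m, L, C)``; returns ``(m, C, order)``.  Solves the
    same Toeplitz systems as :func:`ar_coefficients` in a single batched
    call.
    """
    m, L, C = w.shape
    xm = w - w.mean(axis=1, keepdims=True)
    r = np.empty((m, C, order + 1))
    for k in range(order + 1):
        r[:, :, k] = np.einsum("mlc,mlc->mc", xm[:, : L - k], xm[:, k:]) / L
    r = r.reshape(m * C, order + 1)
    valid = r[:, 0] > _ZERO_VAR
    idx = np.abs(np.subtract.outer(np.arange(order), np.arange(order)))
    c = r[:, :order].copy()
    c[:, 0] *= 1.0 + _AR_NUGGET
    T = c[:, idx]
    rhs = r[:, 1 : order + 1].copy()
    T[~valid] = np.eye(order)
    rhs[~valid] = 0.0
    try:
        a = np.linalg.solve(T, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        a = np.empty_like(rhs)
        for i in range(T.shape[0]):
            try:
                a[i] = np.linalg.solve(T[i], rhs[i])
            except np.linalg.LinAlgError:
                a[i] = np.linalg.lstsq(T[i], rhs[i], rcond=None)[0]
    return a.reshape(m, C, order)


# ---------------------------------------------------------------------------
# Window -> feature vector


def _feature_block(w: np.ndarray, config: FeatureConfig) -> np.ndarray:
    """Features for a stack of windows ``(m, L, C)`` -> ``(m, C*10)``."""
    m, L, C = w.shape
    mav = np.mean(np.abs(w), axis=1)
    wl = np.sum(np.abs(np.diff(w, axis=1)), axis=1)
    zc = _zc_count(w, config.zc_threshold).astype(float)
    ssc = _ssc_count(w, config.ssc_threshold).astype(float)
    if config.ar_method == "burg":
        ar = np.empty((m, C, config.ar_order))
        for i in range(m):
            for c in range(C):
                ar[i, c] = ar_coefficients(w[i, :, c], config.ar_order, method="burg")
    else:
        ar = _ar_batch(w, config.ar_order)
    block = np.concatenate(
        [mav[..., None], zc[..., None], ssc[..., None], wl[..., None], ar], axis=2
    )  # (m, C, 10)
    return block.reshape(m, C * (4 + config.ar_order))


def extract_features(window, config: FeatureConfig, window_end_ms: float = 0.0,
                     label: str | None = None) -> FeatureVector:
    """Feature vector for one multichannel window (rows = time, cols = channels).

    Per-channel blocks are concatenated in channel order:
    ``[MAV, ZC, SSC, WL, a1..a6]`` per channel.

    Raises
    ------
    ValueError
        If the window is too short for the AR order, or contains non-finite
        samples (the offending channel is named).
    """
    w = np.asarray(window, dtype=float)
    if w.ndim == 1:
        w = w[:, None]
    if w.shape[0] <= config.ar_order:
        raise ValueError(
            f"window of {w.shape[0]} rows too short for AR order {config.ar_order}"
        )
    finite = np.isfinite(w).all(axis=0)
    if not finite.all():
        bad = np.flatnonzero(~finite)
        raise ValueError(f"non-finite samples in channel(s) {bad.tolist()}")
    values = _feature_block(w[None], config)[0]
    return FeatureVector(values=values, window_end_ms=window_end_ms, label=label)


def sliding_window_features(recording, config: FeatureConfig, *,
                            end_min_ms: float | None = None,
                            end_max_ms: float | None = None):
    """Vectorised feature extraction over all trailing windows of a recording.

    Parameters
    ----------
    end_min_ms, end_max_ms
        Optional inclusive bounds on the window trailing-edge timestamp,
        used to restrict extraction to the transient (onset) or steady-state
        region of a trial.

    Returns
    -------
    X : ndarray ``(n_windows, n_channels*10)``
    end_ms : ndarray of trailing-edge timestamps
    labels : ndarray of per-window modal labels
    """
    T = recording.n_samples
    L = config.window_ms
    ends = np.arange(L, T + 1, config.increment_ms, dtype=float)
    if end_min_ms is not None:
        ends = ends[ends >= end_min_ms]
    if end_max_ms is not None:
        ends = ends[ends <= end_max_ms]
    nch = recording.n_channels
    if ends.size == 0:
        return (np.empty((0, nch * FEATURES_PER_CHANNEL)), ends, np.empty(0, dtype=object))
    samples = np.asarray(recording.samples, dtype=float)
    view = sliding_window_view(samples, L, axis=0)  # (T-L+1, C, L)
    starts = (ends - L).astype(int)
    w = view[starts].transpose(0, 2, 1)  # (m, L, C)
    X = _feature_block(w, config)
    labs = np.array([window_label(recording.labels[s : s + L]) for s in starts])
    return X, ends, labs


def mav_columns(n_channels: int) -> np.ndarray:
    """Indices of the per-channel MAV entries within a feature vector."""
    return np.arange(n_channels) * FEATURES_PER_CHANNEL
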