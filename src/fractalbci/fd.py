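"""Fractal-dimension estimators for short physiological time series.

Two estimators are provided:

* the Grassberger–Procaccia correlation dimension (GPFD), obtained from a
  delay-coordinate phase-space reconstruction by fitting the slope of
  ``log C(r)`` against ``log r`` over a scaling region and iterating the
  embedding dimension ``M`` until the slope saturates, and
* the Higuchi fractal dimension (HFD), a time-domain estimator based on the
  mean curve length ``L(k)`` computed at interval sizes ``k = 1..kmax``.

The correlation integral ``C(r)`` is the fraction of unordered pairs of
reconstructed vectors whose Euclidean distance is strictly below ``r``
(Heaviside convention ``H(0) = 0``).  For a one-dimensional signal the HFD
lies between 1 (smooth deterministic curve) and 2 (uncorrelated noise), and
for fractional Brownian motion with Hurst exponent ``H`` it approaches
``2 - H``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist

__all__ = [
    "EpochTooShortError",
    "DegenerateSignalError",
    "RadiusSpec",
    "DelayEmbedding",
    "CorrelationCurve",
    "GPFDResult",
    "HFDResult",
    "delay_embed",
    "correlation_integral",
    "correlation_dimension",
    "gpfd",
    "higuchi_curve_length",
    "hfd",
    "hfd_batch",
]


class EpochTooShortError(ValueError):
    """The signal is too short for the requested (tau, M) embedding."""


class DegenerateSignalError(ValueError):
    """The signal carries no usable structure (constant / zero diameter)."""


@dataclass(frozen=True)
class RadiusSpec:
    """How the radius grid for the correlation-integral fit is built.

    By default 24 log-spaced radii between the 5th and 50th percentiles of
    the pairwise-distance distribution are used: the lower bound avoids the
    noise-dominated small-``r`` tail, the upper bound the saturated plateau
    where ``C(r) -> 1``.  An explicit grid overrides the percentile rule.
    """

    n_radii: int = 24
    low_percentile: float = 5.0
    high_percentile: float = 50.0
    radii: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.radii is None:
            if self.n_radii < 5:
                raise ValueError("at least 5 radii are required for the fit")
            if not 0.0 <= self.low_percentile < self.high_percentile <= 100.0:
                raise ValueError("percentile bounds must satisfy 0 <= low < high <= 100")
        else:
            r = np.asarray(self.radii, dtype=float)
            if r.ndim != 1 or r.size < 2 or np.any(r <= 0) or np.any(np.diff(r) <= 0):
                raise ValueError("explicit radii must be a positive increasing 1-D grid")
            object.__setattr__(self, "radii", r)


@dataclass(frozen=True)
class DelayEmbedding:
    """Delay-coordinate reconstruction: row i is ``[x(i), x(i+tau), ...]``."""

    vectors: np.ndarray
    tau: int
    M: int

    @property
    def Np(self) -> int:
        """Number of reconstructed vectors, ``N - (M-1)*tau``."""
        return self.vectors.shape[0]


@dataclass(frozen=True)
class CorrelationCurve:
    """Correlation integral on a radius grid plus the scaling-region fit."""

    radii: np.ndarray
    values: np.ndarray
    fit_range: Tuple[int, int]
    slope: float
    fit_r2: float


@dataclass(frozen=True)
class GPFDResult:
    """Saturation-based correlation-dimension estimate.

    ``fd`` is the correlation dimension d_c at the stopping embedding
    dimension ``M_final``; ``dc_trajectory`` records every (M, d_c(M)) pair
    visited.  ``saturated`` is False when the M cap (or embedding
    feasibility) stopped the iteration before |d_c(M) - d_c(M-1)| < epsilon.
    """

    fd: float
    M_final: int
    dc_trajectory: Tuple[Tuple[int, float], ...]
    saturated: bool
    epsilon: float
    tau: int


@dataclass(frozen=True)
class HFDResult:
    """Higuchi estimate: slope of log L(k) against log(1/k)."""

    fd: float
    k_values: np.ndarray
    lengths: np.ndarray
    fit_r2: float
    kmax: int


# ---------------------------------------------------------------------------
# delay embedding and correlation integral
# ---------------------------------------------------------------------------

def delay_embed(x: Sequence[float], tau: int, M: int) -> DelayEmbedding:
    """Reconstruct M-dimensional delay vectors with delay ``tau`` (samples).

    Returns exactly ``N - (M-1)*tau`` vectors; raises
    :class:`EpochTooShortError` when fewer than 2 would remain.
    """
    x = np.asarray(x, dtype=float).ravel()
    tau = int(tau)
    M = int(M)
    if tau < 1:
        raise ValueError("tau must be a positive integer (samples)")
    if M < 1:
        raise ValueError("embedding dimension M must be >= 1")
    n_vec = x.size - (M - 1) * tau
    if n_vec < 2:
        raise EpochTooShortError(f"epoch too short for (tau={tau}, M={M})")
    idx = np.arange(n_vec)[:, None] + tau * np.arange(M)[None, :]
    return DelayEmbedding(vectors=x[idx], tau=tau, M=M)


def correlation_integral(emb: DelayEmbedding, r: float) -> float:
    """Fraction of unordered vector pairs with Euclidean distance < r.

    The Heaviside convention is strict (``H(0) = 0``): a pair at distance
    exactly ``r`` is excluded.  Normalizing by the number of unordered pairs
    keeps the value in [0, 1].
    """
    if r <= 0:
        raise ValueError("invalid radius: r must be > 0")
    if emb.Np < 2:
        raise EpochTooShortError("need at least 2 reconstructed vectors")
    d = pdist(emb.vectors)
    return float(np.count_nonzero(d < r)) / d.size


def _sq_pair_dists(x: np.ndarray, tau: int, M: int,
                   max_vectors: Optional[int] = None) -> np.ndarray:
    """Condensed squared pairwise distances of the (tau, M) embedding.

    Shared by :func:`correlation_dimension` and :func:`gpfd` so both produce
    bitwise-identical distances for the same arguments.  With
    ``max_vectors`` set, an evenly strided deterministic subsample of the
    reconstructed vectors is used; the correlation integral estimated from
    the subsample is unbiased, at slightly higher variance.
    """
    n_vec = x.size - (M - 1) * tau
    rows = np.arange(n_vec)
    if max_vectors is not None and n_vec > max_vectors:
        rows = np.unique(np.linspace(0, n_vec - 1, max_vectors).round().astype(int))
    idx = rows[:, None] + tau * np.arange(M)[None, :]
    return pdist(x[idx], "sqeuclidean")


def _curve_from_sq_distances(d2: np.ndarray, spec: RadiusSpec) -> CorrelationCurve:
    """Build C(r) on the radius grid and fit the scaling-region slope.

    ``d2`` is the condensed vector of squared pairwise distances.
    """
    if spec.radii is not None:
        radii = np.asarray(spec.radii, dtype=float)
    else:
        positive = d2[d2 > 0]
        if positive.size == 0:
            raise DegenerateSignalError("zero-diameter attractor")
        lo2, hi2 = np.percentile(d2, [spec.low_percentile, spec.high_percentile])
        if lo2 <= 0:
            lo2 = positive.min()
        if hi2 <= lo2:
            raise ValueError("radius grid collapsed (distances too concentrated)")
        radii = np.geomspace(np.sqrt(lo2), np.sqrt(hi2), spec.n_radii)

    # strict `d < r` via right-open histogram bins on squared distances;
    # single-precision counting pass (the bin contents, not the fit, see it)
    edges64 = np.concatenate(
        ([0.0], radii * radii, [max(d2.max(), radii[-1] ** 2) * 2.0 + 1.0]))
    edges = edges64.astype(np.float32)
    if np.all(np.diff(edges) > 0):
        counts, _ = np.histogram(d2.astype(np.float32), bins=edges)
    else:  # grid too narrow for single precision
        counts, _ = np.histogram(d2, bins=edges64)
    values = np.cumsum(counts)[: radii.size] / d2.size

    mask = values > 0
    if not mask.any():
        raise ValueError("fewer than 5 radii with nonzero C(r)")
    if np.all(values[mask] == values[mask][0]):
        # flat curve, e.g. C(r) = 1 everywhere on an explicit grid
        slope, fit_r2 = 0.0, 1.0
    else:
        if mask.sum() < 5:
            raise ValueError("fewer than 5 radii with nonzero C(r)")
        lx = np.log(radii[mask])
        ly = np.log(values[mask])
        lx -= lx.mean()
        ly -= ly.mean()
        sxx = lx @ lx
        syy = ly @ ly
        sxy = lx @ ly
        slope = float(sxy / sxx)
        fit_r2 = float(sxy * sxy / (sxx * syy)) if syy > 0 else 1.0
    idx = np.flatnonzero(mask)
    fit_range = (int(idx[0]), int(idx[-1])) if idx.size else (0, 0)
    return CorrelationCurve(radii=radii, values=values, fit_range=fit_range,
                            slope=slope, fit_r2=fit_r2)


def correlation_dimension(x: Sequence[float], tau: int, M: int,
                          radius_spec: RadiusSpec = RadiusSpec(),
                          max_vectors: Optional[int] = None) -> CorrelationCurve:
    """Correlation dimension d_c at a fixed embedding dimension M.

    The slope of ``log C(r)`` versus ``log r`` is estimated by linear least
    squares over the configured radius grid (radii with ``C(r) = 0`` are
    dropped from the fit).
    """
    x = np.asarray(x, dtype=float).ravel()
    tau, M = int(tau), int(M)
    if tau < 1 or M < 1:
        raise ValueError("tau and M must be positive integers")
    if x.size - (M - 1) * tau < 2:
        raise EpochTooShortError(f"epoch too short for (tau={tau}, M={M})")
    d2 = _sq_pair_dists(x, tau, M, max_vectors)
    return _curve_from_sq_distances(d2, radius_spec)


def gpfd(x: Sequence[float], tau: int = 50, epsilon: float = 1e-3,
         M_max: int = 50, radius_spec: RadiusSpec = RadiusSpec(),
         max_vectors: Optional[int] = None) -> GPFDResult:
    """Saturation-based Grassberger–Procaccia fractal dimension.

    d_c is computed at M = 2, then M is incremented and d_c recomputed until
    ``|d_c(M) - d_c(M-1)| < epsilon`` (saturation) or M reaches ``M_max`` /
    the embedding becomes infeasible, in which case the result is flagged
    (``saturated=False``) rather than raising.  ``fd`` is d_c at stopping.

    Defaults ``tau=50``, ``epsilon=1e-3`` suit 3-s epochs sampled at 500 Hz;
    for EEG-like signals saturation is typically reached for M in the tens.
    """
    x = np.asarray(x, dtype=float).ravel()
    if np.ptp(x) == 0:
        raise DegenerateSignalError("constant signal: GPFD undefined")
    if tau < 1:
        raise ValueError("tau must be a positive integer")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if M_max < 2:
        raise ValueError("M_max must be at least 2")

    trajectory: list[Tuple[int, float]] = []
    saturated = False
    prev_dc = np.nan
    for M in range(2, M_max + 1):
        if x.size - (M - 1) * tau < 2:
            break
        try:
            curve = _curve_from_sq_distances(
                _sq_pair_dists(x, tau, M, max_vectors), radius_spec)
        except (DegenerateSignalError, ValueError):
            break
        trajectory.append((M, curve.slope))
        if len(trajectory) >= 2 and abs(curve.slope - prev_dc) < epsilon:
            saturated = True
            break
        prev_dc = curve.slope

    if not trajectory:
        raise EpochTooShortError(f"epoch too short for (tau={tau}, M=2)")
    M_final, fd = trajectory[-1]
    return GPFDResult(fd=float(fd), M_final=M_final,
                      dc_trajectory=tuple(trajectory), saturated=saturated,
                      epsilon=float(epsilon), tau=int(tau))


# ---------------------------------------------------------------------------
# Higuchi
# ---------------------------------------------------------------------------

def higuchi_curve_length(y: Sequence[float], m: int, k: int) -> float:
    """Normalized length L_m(k) of the subsampled curve starting at m.

    1-based ``m`` in 1..k; the sum of absolute lag-k differences along
    ``y(m), y(m+k), ...`` is normalized by ``(N-1)/(n*k)`` with
    ``n = int((N-m)/k)`` and scaled by the leading ``1/k``.
    """
    y = np.asarray(y, dtype=float).ravel()
    N = y.size
    k = int(k)
    m = int(m)
    if k >= N:
        raise ValueError("interval exceeds signal")
    if not 1 <= m <= k:
        raise ValueError("start index m must lie in 1..k")
    n = (N - m) // k
    if n < 1:
        raise ValueError(f"no complete interval for (m={m}, k={k})")
    idx = m - 1 + k * np.arange(n + 1)
    total = np.abs(np.diff(y[idx])).sum()
    return float(total * (N - 1) / (n * k) / k)


def _higuchi_lengths_batch(Y: np.ndarray, kmax: int) -> np.ndarray:
    """Mean curve lengths L(k), k = 1..kmax, for each row of ``Y``.

    Vectorized over the batch: for each k the lag-k absolute differences are
    computed once and the k start offsets are strided slices of that array.
    """
    B, N = Y.shape
    L = np.empty((B, kmax))
    for k in range(1, kmax + 1):
        d = np.abs(Y[:, k:] - Y[:, :-k])  # all lag-k increments at once
        n_chunks = -((N - k) // -k)
        pad = n_chunks * k - (N - k)
        if pad:
            d = np.pad(d, ((0, 0), (0, pad)))
        # column sums per start offset m: residue-class sums of the lag-k diffs
        offset_sums = d.reshape(B, n_chunks, k).sum(axis=1)
        m = np.arange(1, k + 1)
        n_mk = (N - m) // k
        factors = (N - 1) / (n_mk * k) / k  # Eq-level normalization per m
        L[:, k - 1] = offset_sums @ factors / k
    return L


def hfd(y: Sequence[float], kmax: int = 100) -> HFDResult:
    """Higuchi fractal dimension of a one-dimensional signal.

    ``L(k)`` is the average of the k curve lengths L_m(k); the FD is the
    least-squares slope of ``log L(k)`` against ``log(1/k)``.  Raises
    :class:`DegenerateSignalError` for constant input (zero curve length).
    """
    y = np.asarray(y, dtype=float).ravel()
    N = y.size
    kmax = int(kmax)
    if kmax < 2:
        raise ValueError("kmax must be at least 2")
    if kmax >= N / 2:
        raise ValueError("kmax must be below N/2")
    if np.ptp(y) == 0:
        raise DegenerateSignalError("zero curve length, FD undefined")
    L = _higuchi_lengths_batch(y[None, :], kmax)[0]
    k_values = np.arange(1, kmax + 1)
    fit = stats.linregress(np.log(1.0 / k_values), np.log(L))
    return HFDResult(fd=float(fit.slope), k_values=k_values, lengths=L,
                     fit_r2=float(fit.rvalue ** 2), kmax=kmax)


def hfd_batch(Y: np.ndarray, kmax: int = 100) -> np.ndarray:
    """Higuchi FD for each row of a 2-D array (fast path for many epochs)."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("expected a 2-D array (signals x samples)")
    if np.any(np.ptp(Y, axis=1) == 0):
        raise DegenerateSignalError("zero curve length, FD undefined")
    L = _higuchi_lengths_batch(Y, kmax)
    logk = np.log(1.0 / np.arange(1, kmax + 1))
    logk = logk - logk.mean()
    logL = np.log(L)
    slopes = (logL - logL.mean(axis=1, keepdims=True)) @ logk / (logk @ logk)
    return slopes
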