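"""Comparison feature extractors: band power, AR coefficients, CSP.

These are the baseline features the fractal-dimension estimators are
compared against: sub-band power in the mu/beta range, autoregressive
model coefficients fit by least squares, and common spatial patterns
(CSP) log-variance features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import linalg, signal as sps
from scipy.integrate import simpson

logger = logging.getLogger(__name__)

__all__ = [
    "BandDefinition",
    "CSPModel",
    "ARModel",
    "MU_BAND",
    "BETA_BAND",
    "SUBBANDS",
    "band_power",
    "ar_coefficients",
    "ar_features",
    "csp_fit",
    "csp_features",
]


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band in Hz with a human-readable name."""

    low: float
    high: float
    name: str = ""

    def validate(self, fs: float) -> None:
        if not 0 < self.low < self.high < fs / 2:
            raise ValueError(
                f"invalid band {self.low}-{self.high} Hz for fs={fs} Hz")


MU_BAND = BandDefinition(8.0, 13.0, "mu")
BETA_BAND = BandDefinition(13.0, 30.0, "beta")
#: The five mu/beta sub-bands used for band-power comparisons.
SUBBANDS: Tuple[BandDefinition, ...] = tuple(
    BandDefinition(lo, lo + 4.0, f"{int(lo)}-{int(lo) + 4}Hz")
    for lo in (8.0, 12.0, 16.0, 20.0, 24.0)
)


def _band_filter(x: np.ndarray, band: BandDefinition, fs: float,
                 order: int = 3) -> np.ndarray:
    sos = sps.butter(order, [band.low, band.high], btype="bandpass", fs=fs,
                     output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def band_power(epoch: np.ndarray, band: BandDefinition, fs: float,
               method: str = "butter", log: bool = False) -> np.ndarray:
    """Per-channel power of an epoch within a frequency band.

    ``method='butter'`` (default) is the mean squared amplitude of the
    zero-phase order-3 Butterworth band-passed signal; ``method='welch'``
    integrates the Welch periodogram over the band instead.  A unit
    sinusoid inside the band yields approximately A^2/2 = 0.5.
    """
    band.validate(fs)
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if method == "butter":
        power = np.mean(_band_filter(epoch, band, fs) ** 2, axis=-1)
    elif method == "welch":
        nperseg = min(epoch.shape[-1], int(2 * fs))
        f, psd = sps.welch(epoch, fs=fs, nperseg=nperseg, axis=-1)
        mask = (f >= band.low) & (f <= band.high)
        power = simpson(psd[..., mask], x=f[mask], axis=-1)
    else:
        raise ValueError(f"unknown band-power method: {method!r}")
    return np.log(power) if log else power


def ar_coefficients(x: Sequence[float], order: int) -> np.ndarray:
    """Autoregressive coefficients by ordinary least squares.

    Fits ``x[t] = a_1 x[t-1] + ... + a_d x[t-d] + e[t]`` on the lagged
    regressors (covariance method, no intercept) and returns ``a``.
    A near-singular design (e.g. a constant signal) is flagged with a
    warning and the minimum-norm solution returned.
    """
    x = np.asarray(x, dtype=float).ravel()
    order = int(order)
    if order < 1:
        raise ValueError("AR order must be >= 1")
    if x.size <= 10 * order:
        raise ValueError(f"need more than {10 * order} samples for order {order}")
    design = np.column_stack([x[order - i - 1:x.size - i - 1] for i in range(order)])
    target = x[order:]
    coef, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < order:
        warnings.warn("degenerate AR fit: rank-deficient lag design",
                      RuntimeWarning, stacklevel=2)
    return coef


def ar_features(epoch: np.ndarray, order: int) -> np.ndarray:
    """Concatenated per-channel AR coefficients (length n_channels * order)."""
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    return np.concatenate([ar_coefficients(ch, order) for ch in epoch])


@dataclass(frozen=True)
class ARModel:
    """AR(d) coefficients per channel; feature dimension n_channels * d."""

    order: int
    coefficients: np.ndarray  # (n_channels, order)

    @property
    def feature_vector(self) -> np.ndarray:
        return self.coefficients.ravel()


@dataclass(frozen=True)
class CSPModel:
    """Common-spatial-pattern transform ``EN = W E``.

    Rows of W are spatial filters ordered by descending generalized
    eigenvalue (variance ratio of class A against the composite
    covariance); the discriminative feature vector takes the first p and
    last p projected rows.
    """

    W: np.ndarray  # (n_channels, n_channels)
    eigenvalues: np.ndarray
    p: int
    band: Optional[BandDefinition]
    class_labels: Tuple[int, int]
    fs: Optional[float] = None

    @property
    def n_channels(self) -> int:
        return self.W.shape[1]


def _mean_spatial_covariance(epochs: np.ndarray) -> np.ndarray:
    covs = []
    for e in epochs:
        c = e @ e.T
        tr = np.trace(c)
        if tr <= 0:
            raise ValueError("epoch with zero power; cannot normalize covariance")
        covs.append(c / tr)
    return np.mean(covs, axis=0)


def csp_fit(epochs_a: np.ndarray, epochs_b: np.ndarray,
            band: Optional[BandDefinition] = None, fs: Optional[float] = None,
            p: int = 2, class_labels: Tuple[int, int] = (0, 1),
            shrinkage: float = 1e-9) -> CSPModel:
    """Fit a CSP transform from two classes of (trials, channels, samples).

    Per-trial covariances are trace-normalized and averaged per class; W
    solves the generalized eigenproblem of class-A covariance against the
    composite covariance.  Requires at least two channels and two epochs
    per class.  A rank-deficient composite covariance triggers diagonal
    shrinkage (logged).
    """
    epochs_a = np.asarray(epochs_a, dtype=float)
    epochs_b = np.asarray(epochs_b, dtype=float)
    if epochs_a.ndim != 3 or epochs_b.ndim != 3:
        raise ValueError("epoch collections must be (trials, channels, samples)")
    n_ch = epochs_a.shape[1]
    if n_ch < 2:
        raise ValueError("at least two channels are required for CSP")
    if epochs_a.shape[0] < 2 or epochs_b.shape[0] < 2:
        raise ValueError("need at least 2 epochs per class")
    if not 1 <= p <= n_ch // 2:
        raise ValueError("invalid p: require 1 <= p <= n_channels/2")
    if band is not None:
        if fs is None:
            raise ValueError("fs is required when a band is given")
        band.validate(fs)
        epochs_a = _band_filter(epochs_a, band, fs)
        epochs_b = _band_filter(epochs_b, band, fs)

    cov_a = _mean_spatial_covariance(epochs_a)
    cov_b = _mean_spatial_covariance(epochs_b)
    composite = cov_a + cov_b
    if np.linalg.matrix_rank(composite) < n_ch:
        logger.warning("rank-deficient composite covariance; applying shrinkage")
        composite = composite + shrinkage * np.trace(composite) / n_ch * np.eye(n_ch)
    eigvals, eigvecs = linalg.eigh(cov_a, composite)
    order = np.argsort(eigvals)[::-1]
    W = eigvecs[:, order].T
    return CSPModel(W=W, eigenvalues=eigvals[order], p=int(p), band=band,
                    class_labels=tuple(class_labels), fs=fs)


def csp_features(epoch: np.ndarray, model: CSPModel,
                 normalize: bool = True) -> np.ndarray:
    """2p log-variance features of the CSP-projected epoch.

    Variances of the first p and last p projected rows; with ``normalize``
    they are divided by their sum before the log, making the features
    invariant to epoch-wide amplitude scaling.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if epoch.shape[0] != model.n_channels:
        raise ValueError("epoch channel count does not match the CSP model")
    if model.band is not None:
        epoch = _band_filter(epoch, model.band, model.fs)
    p = model.p
    projected = model.W @ epoch
    rows = np.r_[projected[:p], projected[-p:]]
    var = rows.var(axis=-1)
    if np.any(var <= 0):
        raise ValueError("zero projected power: log-variance undefined")
    if normalize:
        var = var / var.sum()
    return np.log(var)
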