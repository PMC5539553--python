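"""Synthetic reference signals and two-class EEG-like sessions.

The session generator does not attempt a physiological forward model of
cortical EEG.  It targets the statistical property the fractal-dimension
features exploit: class-dependent signal complexity, planted as a Hurst
shift of a fractional-Brownian-motion backbone on a subset of channels,
optionally combined with a class-dependent band-limited oscillation
(emulating ERD/ERS-style band-power effects) plus white measurement noise.

Reference signals (line, sinusoid, white noise, fBm, Lorenz) carry their
analytically or empirically established dimensions and serve as the
validation battery for the estimators: HFD of fBm with Hurst exponent H
approaches 2 - H, and the Lorenz attractor has correlation dimension close
to 2.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .io import EpochSet, MONTAGE_30

__all__ = [
    "SessionSpec",
    "ReferenceSignal",
    "gen_fgn",
    "gen_fbm",
    "lorenz_trajectory",
    "gen_reference",
    "gen_session",
    "collection_session_seconds",
]

#: Classical Lorenz parameters and integration constants.
LORENZ_SIGMA, LORENZ_RHO, LORENZ_BETA = 10.0, 28.0, 8.0 / 3.0
LORENZ_DT = 0.01
LORENZ_TRANSIENT = 10_000


@dataclass(frozen=True)
class SessionSpec:
    """Parameters of a two-class (imagery vs. resting) synthetic session.

    Defaults mirror the recording structure of a 30-channel, 500 Hz montage
    with 3-s epochs and 40 epochs per class.  ``baseline_hurst`` sets the
    resting-state complexity (H = 0.3 gives HFD around 1.7, in the range
    observed for raw EEG); imagery epochs on the informative channels are
    shifted by ``hurst_shift`` (a positive shift smooths the signal and
    lowers its FD, the direction seen in imagery-vs-resting recordings).
    """

    n_channels: int = 30
    fs: float = 500.0
    epoch_seconds: float = 3.0
    epochs_per_class: int = 40
    informative_channels: Tuple[Union[int, str], ...] = ("C4", "CP4", "P4")
    baseline_hurst: float = 0.3
    hurst_shift: float = 0.2
    band_effect: Optional[Tuple[Tuple[float, float], float]] = None
    band_amplitude: float = 1.0
    noise_sd: float = 0.1
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_seconds))

    def informative_indices(self, channel_names: Sequence[str]) -> Tuple[int, ...]:
        idx = []
        for ch in self.informative_channels:
            if isinstance(ch, str):
                if ch not in channel_names:
                    raise ValueError(f"informative channel {ch!r} not in montage")
                idx.append(list(channel_names).index(ch))
            else:
                if not 0 <= int(ch) < self.n_channels:
                    raise ValueError(f"informative channel index {ch} out of range")
                idx.append(int(ch))
        return tuple(sorted(set(idx)))

    def validate(self) -> None:
        if self.n_channels < 1 or self.epochs_per_class < 1:
            raise ValueError("n_channels and epochs_per_class must be positive")
        H0, dH = self.baseline_hurst, self.hurst_shift
        if not (0 < H0 < 1 and 0 < H0 + dH < 1):
            raise ValueError("require 0 < H0 and 0 < H0 + dH < 1")
        if self.band_effect is not None:
            (low, high), ratio = self.band_effect
            if not 0 < low < high < self.fs / 2:
                raise ValueError("band effect outside (0, fs/2)")
            if ratio <= 0:
                raise ValueError("band-power ratio must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ReferenceSignal:
    """A signal of known (analytic or established) fractal dimension."""

    kind: str
    samples: np.ndarray
    true_dimension: Optional[float]
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# fractional Brownian motion (circulant embedding, exact covariance)
# ---------------------------------------------------------------------------

def _fgn_eigenvalues(n: int, H: float) -> np.ndarray:
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * (np.abs(k + 1) ** (2 * H) - 2 * k ** (2 * H)
                   + np.abs(k - 1) ** (2 * H))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    # tiny negative eigenvalues are FFT round-off; the fGn circulant is PSD
    lam[lam < 0] = 0.0
    return lam


def gen_fgn(n: int, H: float, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Exact-covariance fractional Gaussian noise, shape (size, n).

    Circulant embedding of the fGn autocovariance (Dietrich–Newsam): the
    real part of the FFT of spectrally weighted complex Gaussians has the
    target covariance exactly.
    """
    if not 0 < H < 1:
        raise ValueError("Hurst exponent H must lie in (0, 1)")
    lam = _fgn_eigenvalues(n, H)
    m = lam.size
    z = rng.standard_normal((size, m)) + 1j * rng.standard_normal((size, m))
    y = np.fft.fft(np.sqrt(lam) * z, axis=1) / np.sqrt(m)
    return y.real[:, :n]


def gen_fbm(N: int, H: float, seed: Union[int, np.random.Generator] = 0) -> np.ndarray:
    """Fractional Brownian motion of length N with Hurst exponent H."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.cumsum(gen_fgn(N, H, rng, size=1)[0])


# ---------------------------------------------------------------------------
# Lorenz system (fixed-step RK4)
# ---------------------------------------------------------------------------

def _lorenz_rhs(s: np.ndarray) -> np.ndarray:
    x, y, z = s
    return np.array([LORENZ_SIGMA * (y - x),
                     x * (LORENZ_RHO - z) - y,
                     x * y - LORENZ_BETA * z])


def lorenz_trajectory(N: int, dt: float = LORENZ_DT,
                      transient: int = LORENZ_TRANSIENT,
                      initial: Sequence[float] = (1.0, 1.0, 1.0)) -> np.ndarray:
    """N states of the Lorenz system after discarding the transient.

    Fixed-step fourth-order Runge–Kutta at the classical parameter values
    (sigma=10, rho=28, beta=8/3); returns an (N, 3) array on the attractor.
    """
    s = np.asarray(initial, dtype=float)
    out = np.empty((N, 3))
    for i in range(transient + N):
        k1 = _lorenz_rhs(s)
        k2 = _lorenz_rhs(s + 0.5 * dt * k1)
        k3 = _lorenz_rhs(s + 0.5 * dt * k2)
        k4 = _lorenz_rhs(s + dt * k3)
        s = s + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if i >= transient:
            out[i - transient] = s
    return out


# ---------------------------------------------------------------------------
# reference battery and sessions
# ---------------------------------------------------------------------------

def gen_reference(kind: str, N: int, seed: int = 0, **params) -> ReferenceSignal:
    """A reference signal of length N with its known dimension recorded.

    Kinds: ``line`` (FD 1), ``sine`` (limit cycle, dimension 1),
    ``white_noise`` (Higuchi FD 2), ``fbm`` (Higuchi FD 2 - H, requires
    ``H=``) and ``lorenz`` (x-component; correlation dimension ~2.05).
    """
    rng = np.random.default_rng(seed)
    if kind == "line":
        slope = params.get("slope", 1.0)
        return ReferenceSignal(kind, slope * np.arange(N, dtype=float), 1.0,
                               {"slope": slope})
    if kind == "sine":
        cycles = params.get("cycles", 10.0)
        phase = params.get("phase", 0.0)
        t = np.arange(N) / N
        return ReferenceSignal(kind, np.sin(2 * np.pi * cycles * t + phase), 1.0,
                               {"cycles": cycles})
    if kind == "white_noise":
        return ReferenceSignal(kind, rng.standard_normal(N), 2.0, {})
    if kind == "fbm":
        H = params["H"]
        return ReferenceSignal(kind, gen_fbm(N, H, rng), 2.0 - H, {"H": H})
    if kind == "lorenz":
        initial = np.array([1.0, 1.0, 1.0]) + 1e-3 * rng.standard_normal(3)
        traj = lorenz_trajectory(N, initial=initial)
        return ReferenceSignal(kind, traj[:, 0], 2.05, {"initial": tuple(initial)})
    raise ValueError(f"unsupported reference kind: {kind!r}")


def _standardize_epochs(block: np.ndarray) -> np.ndarray:
    mu = block.mean(axis=-1, keepdims=True)
    sd = block.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return (block - mu) / sd


def gen_session(spec: SessionSpec) -> EpochSet:
    """Generate a labelled two-class session per the spec; fully seeded.

    Each epoch/channel is an independent unit-variance fBm backbone with a
    class-dependent Hurst exponent on the informative channels, an optional
    class-dependent band-limited sinusoid, and additive white noise.  Labels:
    0 = resting (first ``epochs_per_class`` trials), 1 = imagery.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_ep, n_ch, n_s = spec.epochs_per_class, spec.n_channels, spec.n_samples
    if n_ch <= len(MONTAGE_30):
        names = list(MONTAGE_30[:n_ch])
    else:
        names = list(MONTAGE_30) + [f"EX{i}" for i in range(n_ch - len(MONTAGE_30))]
    informative = spec.informative_indices(names)

    data = np.empty((2 * n_ep, n_ch, n_s))
    H0, H1 = spec.baseline_hurst, spec.baseline_hurst + spec.hurst_shift
    # resting epochs: baseline Hurst everywhere
    data[:n_ep] = _standardize_epochs(
        np.cumsum(gen_fgn(n_s, H0, rng, size=n_ep * n_ch), axis=1)
    ).reshape(n_ep, n_ch, n_s)
    # imagery epochs: shifted Hurst on informative channels only
    imagery = _standardize_epochs(
        np.cumsum(gen_fgn(n_s, H0, rng, size=n_ep * n_ch), axis=1)
    ).reshape(n_ep, n_ch, n_s)
    if informative and spec.hurst_shift != 0:
        shifted = _standardize_epochs(
            np.cumsum(gen_fgn(n_s, H1, rng, size=n_ep * len(informative)), axis=1)
        ).reshape(n_ep, len(informative), n_s)
        imagery[:, list(informative), :] = shifted
    data[n_ep:] = imagery

    if spec.band_effect is not None:
        (low, high), ratio = spec.band_effect
        freq = 0.5 * (low + high)
        t = np.arange(n_s) / spec.fs
        phases = rng.uniform(0, 2 * np.pi, size=(2 * n_ep, n_ch, 1))
        amp = np.full((2 * n_ep, n_ch, 1), spec.band_amplitude)
        amp[n_ep:, list(informative), :] *= ratio
        data += amp * np.sin(2 * np.pi * freq * t[None, None, :] + phases)

    if spec.noise_sd > 0:
        data += spec.noise_sd * rng.standard_normal(data.shape)

    labels = np.r_[np.zeros(n_ep, dtype=int), np.ones(n_ep, dtype=int)]
    return EpochSet(data=data, fs=spec.fs, channel_names=names, labels=labels,
                    task="imagery-vs-resting")


def collection_session_seconds(trial_seconds: float = 8.0, trials_per_run: int = 40,
                               n_runs: int = 3, break_seconds: float = 120.0,
                               n_breaks: int = 2) -> float:
    """Wall-clock length of the motor-imagery collection protocol.

    Three 40-trial runs of 8-s trials separated by two 2-min breaks come to
    1200 s (20 min).
    """
    return trial_seconds * trials_per_run * n_runs + break_seconds * n_breaks
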