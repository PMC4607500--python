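"""Multichannel MRI noise simulation and magnitude noise distributions.

Each of the ``n`` receiver coils sees the true signal weighted by its
sensitivity map plus complex Gaussian noise; the real and imaginary
noise vectors are drawn independently with the compound-symmetric
inter-coil covariance ``sigma^2 [(1-rho) I + rho 11^T]``.  Two magnitude
combinations are supported:

* SoS  — root sum of squares, ``sqrt(sum_k |S_k|^2)``; its magnitude noise
  follows a noncentral chi (nc-chi) law of order n.
* SMF  — spatial matched filter, ``|sum_k S_k C_k|``; with normalized
  maps (``sum_k C_k^2 = 1``) and uncorrelated coils the result is Rician.

The Rician density is the nc-chi density at n = 1.  Non-integer orders
are accepted so that effective parameters (n_eff, sigma_eff^2) fitted to
correlated-coil data can be used directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, ive

__all__ = [
    "CoilConfig",
    "NoiseModel",
    "rician_pdf",
    "ncchi_pdf",
    "make_sensitivity_maps",
    "simulate_coil_signals",
    "combine_sos",
    "combine_smf",
    "contaminate",
]


@dataclass(frozen=True)
class CoilConfig:
    """Coil count, per-coil sensitivity maps, noise SD and inter-coil correlation."""

    n: int
    sensitivity_maps: np.ndarray    # (n, X, Y, Z), jointly normalized
    sigma: float
    rho: float = 0.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("need at least one coil")
        maps = np.asarray(self.sensitivity_maps, dtype=float)
        if maps.shape[0] != self.n:
            raise ValueError("one sensitivity map required per coil")
        sq = np.sum(maps**2, axis=0)
        if np.any(np.abs(sq - 1.0) > 1e-6):
            raise ValueError("sensitivity maps must satisfy sum_k C_k^2 = 1")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        object.__setattr__(self, "sensitivity_maps", maps)


@dataclass(frozen=True)
class NoiseModel:
    """Magnitude noise family with (possibly effective) order and variance."""

    family: str                     # gaussian | rician | ncchi
    n_coils: float = 1.0
    sigma2: float | np.ndarray | None = None

    def __post_init__(self):
        if self.family not in ("gaussian", "rician", "ncchi"):
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.family == "rician" and self.n_coils != 1.0:
            raise ValueError("the Rician family has order n = 1")
        if self.family == "ncchi" and self.n_coils < 1.0:
            raise ValueError("nc-chi order must be >= 1")
        if self.sigma2 is not None and np.any(np.asarray(self.sigma2) <= 0):
            raise ValueError("sigma2 must be positive where defined")


def ncchi_pdf(s, sbar, sigma2, n) -> np.ndarray:
    """Noncentral chi density of the combined magnitude signal.

    ``p(S) = (Sbar/sigma^2) (S/Sbar)^n exp(-(S^2+Sbar^2)/(2 sigma^2))
    I_{n-1}(S Sbar / sigma^2)`` for S >= 0, with the analytic central-chi
    limit substituted where ``Sbar -> 0``.  Evaluated in log space with
    the exponentially scaled Bessel function, so it is stable at any SNR.
    """
    n = float(n)
    if n < 1.0:
        raise ValueError("order n must be >= 1")
    s = np.asarray(s, dtype=float)
    sbar = np.asarray(sbar, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0):
        raise ValueError("sigma2 must be positive")
    if np.any(sbar < 0):
        raise ValueError("the true magnitude Sbar must be non-negative")

    scalar = np.ndim(s) == 0 and np.ndim(sbar) == 0 and np.ndim(sigma2) == 0
    s, sbar, sigma2 = np.atleast_1d(*np.broadcast_arrays(s, sbar, sigma2))
    out = np.zeros(s.shape, dtype=float)
    pos = s > 0

    with np.errstate(divide="ignore", invalid="ignore"):
        z = s * sbar / sigma2
        central = z < 1e-12
        gen = pos & ~central
        # general branch: log p = log Sbar - log sigma2 + n log(S/Sbar)
        #                  - (S-Sbar)^2/(2 sigma2) + z + log ive(n-1, z)
        logp = (
            np.log(np.where(gen, sbar, 1.0))
            - np.log(sigma2)
            + n * (np.log(np.where(pos, s, 1.0)) - np.log(np.where(gen, sbar, 1.0)))
            - (s - sbar) ** 2 / (2.0 * sigma2)
            + np.log(np.maximum(ive(n - 1.0, z), 1e-300))
        )
        out[gen] = np.exp(logp[gen])
        # central-chi limit (2n degrees of freedom)
        cen = pos & central
        logc = (
            (2.0 * n - 1.0) * np.log(np.where(pos, s, 1.0))
            - s**2 / (2.0 * sigma2)
            - (n - 1.0) * np.log(2.0)
            - n * np.log(sigma2)
            - gammaln(n)
        )
        out[cen] = np.exp(logc[cen])
    return float(out[0]) if scalar else out


def rician_pdf(s, sbar, sigma2) -> np.ndarray:
    """Rician magnitude density — the nc-chi density at order n = 1."""
    return ncchi_pdf(s, sbar, sigma2, n=1.0)


def make_sensitivity_maps(n: int, shape) -> np.ndarray:
    """Smooth per-coil sensitivity maps with ``sum_k C_k^2 = 1`` voxelwise.

    Each coil contributes one broad Gaussian lobe centered on an equally
    spaced point of the volume perimeter (in-plane circle); joint
    normalization enforces the unit sum-of-squares constraint.  A single
    coil yields a uniform map.
    """
    if n < 1:
        raise ValueError("need at least one coil")
    shape = tuple(int(d) for d in shape)
    if len(shape) != 3:
        raise ValueError("shape must be 3-D")
    if n == 1:
        return np.ones((1,) + shape)
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    radius = 0.6 * max(shape)
    width = 0.6 * max(shape)
    x, y, z = np.meshgrid(*[np.arange(d, dtype=float) for d in shape], indexing="ij")
    maps = np.empty((n,) + shape)
    for k in range(n):
        phi = 2.0 * np.pi * k / n
        ck = center + radius * np.array([np.cos(phi), np.sin(phi), 0.0])
        d2 = (x - ck[0]) ** 2 + (y - ck[1]) ** 2 + (z - ck[2]) ** 2
        maps[k] = np.exp(-d2 / (2.0 * width**2))
    maps /= np.sqrt(np.sum(maps**2, axis=0, keepdims=True))
    return maps


def _coil_cholesky(n: int, sigma: float, rho: float) -> np.ndarray:
    cov = sigma**2 * ((1.0 - rho) * np.eye(n) + rho * np.ones((n, n)))
    return np.linalg.cholesky(cov)


def simulate_coil_signals(true_signal, config: CoilConfig, seed=None) -> np.ndarray:
    """Per-coil complex signals ``S_k = S C_k + e_k^R + i e_k^I``.

    Real and imaginary noise vectors are independent draws across coils
    with the compound-symmetric covariance; output is bit-reproducible
    for a fixed seed (or ``numpy.random.Generator``).
    """
    true = np.asarray(true_signal, dtype=float)
    maps = config.sensitivity_maps
    vol_shape = maps.shape[1:]
    if true.shape[: len(vol_shape)] != vol_shape:
        raise ValueError(
            f"signal spatial shape {true.shape} does not match sensitivity "
            f"maps {vol_shape}"
        )
    extra = true.shape[len(vol_shape):]
    c = maps.reshape(maps.shape[:1] + vol_shape + (1,) * len(extra))
    clean = true[None, ...] * c
    if config.sigma == 0:
        return clean.astype(complex)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chol = _coil_cholesky(config.n, config.sigma, config.rho)
    size = int(np.prod(true.shape))
    e_r = (chol @ rng.standard_normal((config.n, size))).reshape(clean.shape)
    e_i = (chol @ rng.standard_normal((config.n, size))).reshape(clean.shape)
    return clean + e_r + 1j * e_i


def combine_sos(coil_signals) -> np.ndarray:
    """Root sum-of-squares magnitude combination."""
    coil_signals = np.asarray(coil_signals)
    return np.sqrt(np.sum(np.abs(coil_signals) ** 2, axis=0))


def combine_smf(coil_signals, sensitivity_maps) -> np.ndarray:
    """Spatial-matched-filter magnitude combination ``|sum_k S_k C_k|``."""
    coil_signals = np.asarray(coil_signals)
    maps = np.asarray(sensitivity_maps, dtype=float)
    extra = coil_signals.ndim - maps.ndim
    c = maps.reshape(maps.shape + (1,) * extra)
    return np.abs(np.sum(coil_signals * c, axis=0))


def contaminate(
    true_4d,
    snr: float,
    combiner: str = "smf",
    n_coils: int = 8,
    rho: float = 0.05,
    seed=None,
    s0: float = 1.0,
    sensitivity_maps: np.ndarray | None = None,
):
    """Contaminate a noiseless 4-D volume with multichannel magnitude noise.

    The per-coil noise SD is ``sigma = S0 / SNR``.  The same seed produces
    identical complex noise realizations for both combiners, so SoS and
    SMF outputs form matched pairs.  Returns ``(noisy, provenance)`` where
    provenance records seed, sigma, rho, coil count and combiner.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if combiner not in ("sos", "smf"):
        raise ValueError("combiner must be 'sos' or 'smf'")
    true = np.asarray(true_4d, dtype=float)
    if true.ndim != 4:
        raise ValueError("expected a 4-D (X, Y, Z, N) volume")
    sigma = s0 / snr
    if sensitivity_maps is None:
        sensitivity_maps = make_sensitivity_maps(n_coils, true.shape[:3])
    config = CoilConfig(n=n_coils, sensitivity_maps=sensitivity_maps,
                        sigma=sigma, rho=rho)
    coils = simulate_coil_signals(true, config, seed=seed)
    if combiner == "sos":
        noisy = combine_sos(coils)
    else:
        noisy = combine_smf(coils, sensitivity_maps)
    provenance = {
        "seed": None if isinstance(seed, np.random.Generator) else seed,
        "snr": float(snr),
        "sigma": float(sigma),
        "rho": float(rho),
        "n_coils": int(n_coils),
        "combiner": combiner,
    }
    return noisy, provenance
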