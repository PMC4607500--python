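"""Synthetic fiber phantoms with per-voxel ground truth.

Three families mirror the evaluation design of the solvers:

* ``crossing_angle_phantom`` — two straight bundles crossing at a
  prescribed angle (1..90 degrees), equal fractions in the crossing.
* ``volume_fraction_phantom`` — the 70-degree crossing with the
  non-dominant bundle fraction swept from 0.10 to 0.50.
* ``challenge_like_phantom`` — a procedurally generated field with
  straight, curved (kissing/crossing) and branching bundles plus a
  CSF-like isotropic region; WM signals use the same tensor mixture as
  the other families rather than a restricted intra-axonal model.

Signals are noiseless multi-tensor evaluations on a single-shell scheme
(70 directions at b = 3000 s/mm^2 plus one b = 0 by default); noise is
added separately by :mod:`rumbasd.noise`.  Every phantom stores a truth
field that reproduces the signal exactly through the generative model.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

from .kernel import (
    AcquisitionScheme,
    DiffusivityProfile,
    fiber_tensor,
    make_sphere_grid,
)
from .metrics import GroundTruthVoxel

__all__ = [
    "PhantomSpec",
    "PhantomVolume",
    "TruthField",
    "default_scheme",
    "crossing_angle_phantom",
    "volume_fraction_phantom",
    "challenge_like_phantom",
    "enumerate_phantom_suite",
]

DEFAULT_SHAPE = (50, 50, 50)
MAX_TRUE_FIBERS = 4


@functools.lru_cache(maxsize=4)
def default_scheme(n_dirs: int = 70, bval: float = 3000.0) -> AcquisitionScheme:
    """Single-shell scheme: one b = 0 plus ``n_dirs`` repulsion-spread directions."""
    grid = make_sphere_grid(2 * n_dirs)
    dirs = grid.vertices[: n_dirs]
    bvals = np.concatenate([[0.0], np.full(n_dirs, float(bval))])
    bvecs = np.vstack([np.zeros(3), dirs])
    return AcquisitionScheme(bvals=bvals, bvecs=bvecs)


@dataclass
class TruthField:
    """Array-backed ground truth: padded directions/fractions per voxel."""

    directions: np.ndarray          # (X, Y, Z, MAX_TRUE_FIBERS, 3), NaN padded
    fractions: np.ndarray           # (X, Y, Z, MAX_TRUE_FIBERS)
    count: np.ndarray               # (X, Y, Z) int
    f_gm: np.ndarray                # (X, Y, Z)
    f_csf: np.ndarray               # (X, Y, Z)

    @classmethod
    def empty(cls, shape) -> "TruthField":
        return cls(
            directions=np.full(tuple(shape) + (MAX_TRUE_FIBERS, 3), np.nan),
            fractions=np.zeros(tuple(shape) + (MAX_TRUE_FIBERS,)),
            count=np.zeros(shape, dtype=int),
            f_gm=np.zeros(shape),
            f_csf=np.zeros(shape),
        )

    def set_voxel(self, index, dirs, fracs, f_gm=0.0, f_csf=0.0) -> None:
        k = len(fracs)
        self.count[index] = k
        self.directions[index][:k] = dirs
        self.fractions[index][:k] = fracs
        self.f_gm[index] = f_gm
        self.f_csf[index] = f_csf

    def voxel(self, index) -> GroundTruthVoxel:
        k = int(self.count[index])
        return GroundTruthVoxel(
            fiber_dirs=self.directions[index][:k],
            fractions=self.fractions[index][:k],
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom of the evaluation suite."""

    family: str                     # crossing_angle | volume_fraction | challenge_like
    shape: tuple = DEFAULT_SHAPE
    angle: float | None = None
    minor_fraction: float | None = None

    def __post_init__(self):
        if self.family not in ("crossing_angle", "volume_fraction", "challenge_like"):
            raise ValueError(f"unknown phantom family {self.family!r}")
        if self.family == "crossing_angle":
            if self.angle is None or not (1 <= self.angle <= 90):
                raise ValueError("crossing angle must lie in [1, 90] degrees")
        if self.family == "volume_fraction":
            m = self.minor_fraction
            if m is None or not (0.1 - 1e-9 <= m <= 0.5 + 1e-9):
                raise ValueError("minor fraction must lie in [0.1, 0.5]")

    def build(self, scheme=None, profile=None) -> "PhantomVolume":
        if self.family == "crossing_angle":
            return crossing_angle_phantom(self.angle, self.shape, scheme, profile)
        if self.family == "volume_fraction":
            return volume_fraction_phantom(self.minor_fraction, self.shape, scheme, profile)
        return challenge_like_phantom(self.shape, scheme, profile)


@dataclass
class PhantomVolume:
    """Noiseless 4-D signal, ground-truth field and generation metadata."""

    signal: np.ndarray              # (X, Y, Z, N)
    truth: TruthField
    scheme: AcquisitionScheme
    profile: DiffusivityProfile
    metadata: dict = field(default_factory=dict)


def _mixture_signal(scheme, profile, dirs, fracs, f_gm=0.0, f_csf=0.0):
    """Vectorized multi-tensor signal for one compartment configuration."""
    b = scheme.bvals
    g = scheme.bvecs
    sig = np.zeros(scheme.n_measurements)
    for d, fr in zip(dirs, fracs):
        tensor = fiber_tensor(np.asarray(d, dtype=float), profile)
        sig += fr * np.exp(-b * np.einsum("ni,ij,nj->n", g, tensor, g))
    sig += f_gm * np.exp(-b * profile.d_gm)
    sig += f_csf * np.exp(-b * profile.d_csf)
    return profile.s0 * sig


def _two_bundle_phantom(angle_deg, fractions, shape, scheme, profile):
    """Two straight slabs whose overlap is the crossing region.

    Bundle directions lie in the x-y plane at +/- angle/2 about x.
    Bundle 1 occupies the middle band in y, bundle 2 the middle band in
    z; voxels outside both slabs are CSF-like isotropic background.
    """
    scheme = scheme or default_scheme()
    profile = profile or DiffusivityProfile()
    shape = tuple(int(d) for d in shape)
    half = np.radians(angle_deg) / 2.0
    d1 = np.array([np.cos(half), np.sin(half), 0.0])
    d2 = np.array([np.cos(half), -np.sin(half), 0.0])
    f1, f2 = fractions

    sig_cross = _mixture_signal(scheme, profile, [d1, d2], [f1, f2])
    sig_b1 = _mixture_signal(scheme, profile, [d1], [1.0])
    sig_b2 = _mixture_signal(scheme, profile, [d2], [1.0])
    sig_bg = _mixture_signal(scheme, profile, [], [], f_csf=1.0)

    y = np.arange(shape[1])
    z = np.arange(shape[2])
    t1 = max(1, shape[1] // 6)
    t2 = max(1, shape[2] // 6)
    band_y = np.abs(y - (shape[1] - 1) / 2.0) <= t1
    band_z = np.abs(z - (shape[2] - 1) / 2.0) <= t2
    in1 = np.zeros(shape, dtype=bool)
    in2 = np.zeros(shape, dtype=bool)
    in1[:, band_y, :] = True
    in2[:, :, band_z] = True
    cross = in1 & in2
    only1 = in1 & ~in2
    only2 = in2 & ~in1
    bg = ~(in1 | in2)

    signal = np.empty(shape + (scheme.n_measurements,))
    signal[cross] = sig_cross
    signal[only1] = sig_b1
    signal[only2] = sig_b2
    signal[bg] = sig_bg

    truth = TruthField.empty(shape)
    for idx in zip(*np.nonzero(cross)):
        truth.set_voxel(idx, [d1, d2], [f1, f2])
    for idx in zip(*np.nonzero(only1)):
        truth.set_voxel(idx, [d1], [1.0])
    for idx in zip(*np.nonzero(only2)):
        truth.set_voxel(idx, [d2], [1.0])
    truth.f_csf[bg] = 1.0

    return PhantomVolume(
        signal=signal,
        truth=truth,
        scheme=scheme,
        profile=profile,
        metadata={
            "angle_deg": float(angle_deg),
            "fractions": (float(f1), float(f2)),
            "shape": shape,
            "crossing_voxels": int(cross.sum()),
        },
    )


def crossing_angle_phantom(angle_deg, shape=DEFAULT_SHAPE, scheme=None, profile=None):
    """Two equal bundles (f1 = f2 = 0.5 in the crossing) at the given angle."""
    if not (1 <= angle_deg <= 90):
        raise ValueError("angle must lie in [1, 90] degrees")
    vol = _two_bundle_phantom(angle_deg, (0.5, 0.5), shape, scheme, profile)
    vol.metadata["family"] = "crossing_angle"
    return vol


def volume_fraction_phantom(minor_fraction, shape=DEFAULT_SHAPE, scheme=None, profile=None):
    """70-degree crossing with fractions (1 - minor, minor) in the crossing."""
    if not (0.1 - 1e-9 <= minor_fraction <= 0.5 + 1e-9):
        raise ValueError("minor fraction must lie in [0.1, 0.5]")
    vol = _two_bundle_phantom(
        70.0, (1.0 - minor_fraction, minor_fraction), shape, scheme, profile
    )
    vol.metadata["family"] = "volume_fraction"
    vol.metadata["minor_fraction"] = float(minor_fraction)
    return vol


def challenge_like_phantom(shape=DEFAULT_SHAPE, scheme=None, profile=None):
    """Curved, branching and crossing bundles with an isotropic CSF region.

    Three bundles: a straight x-aligned slab, a quarter-circle arc in the
    x-y plane crossing it (tangent directions vary along the arc), and a
    diagonal branch leaving the straight bundle.  A spherical CSF-like
    region sits in one corner; remaining voxels are GM-like isotropic.
    """
    scheme = scheme or default_scheme()
    profile = profile or DiffusivityProfile(d_gm=0.2e-3, d_csf=1.7e-3)
    shape = tuple(int(d) for d in shape)
    nx, ny, nz = shape
    x, y, z = np.meshgrid(*[np.arange(d, dtype=float) for d in shape], indexing="ij")

    t = max(1.0, min(shape) / 6.0)
    # bundle A: straight along x, central band in (y, z)
    in_a = (np.abs(y - (ny - 1) / 2.0) <= t) & (np.abs(z - (nz - 1) / 2.0) <= t)
    dir_a = np.array([1.0, 0.0, 0.0])

    # bundle B: quarter arc of radius r centered at the (x=0, y=0) edge,
    # in-plane; tangent varies with position
    r_arc = 0.75 * min(nx, ny)
    rad = np.sqrt(x**2 + y**2)
    in_b = (np.abs(rad - r_arc) <= t) & (np.abs(z - (nz - 1) / 2.0) <= t)

    # bundle C: diagonal branch from the volume center towards +y +z corner
    u = np.array([2.0, 1.0, 1.0])
    u = u / np.linalg.norm(u)
    cx = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0])
    px, py, pz = x - cx[0], y - cx[1], z - cx[2]
    proj = px * u[0] + py * u[1] + pz * u[2]
    perp2 = (px - proj * u[0]) ** 2 + (py - proj * u[1]) ** 2 + (pz - proj * u[2]) ** 2
    in_c = (perp2 <= t**2) & (proj >= 0)

    # CSF ball in a corner
    ccsf = np.array([0.15 * nx, 0.8 * ny, 0.8 * nz])
    in_csf = (x - ccsf[0]) ** 2 + (y - ccsf[1]) ** 2 + (z - ccsf[2]) ** 2 <= (
        0.12 * min(shape)
    ) ** 2 * 4.0

    signal = np.empty(shape + (scheme.n_measurements,))
    truth = TruthField.empty(shape)

    sig_gm = _mixture_signal(scheme, profile, [], [], f_gm=1.0)
    sig_csf = _mixture_signal(scheme, profile, [], [], f_csf=1.0)
    signal[...] = sig_gm
    truth.f_gm[...] = 1.0

    cache: dict = {}
    wm_any = in_a | in_b | in_c
    for idx in zip(*np.nonzero(wm_any)):
        dirs = []
        if in_a[idx]:
            dirs.append(dir_a)
        if in_b[idx]:
            # tangent of the circular arc at this voxel
            tx, ty = -y[idx], x[idx]
            norm = np.hypot(tx, ty)
            if norm > 0:
                dirs.append(np.array([tx / norm, ty / norm, 0.0]))
        if in_c[idx]:
            dirs.append(u)
        k = len(dirs)
        fracs = [1.0 / k] * k
        key = tuple(np.round(np.concatenate(dirs), 6)) + (k,)
        if key not in cache:
            cache[key] = _mixture_signal(scheme, profile, dirs, fracs)
        signal[idx] = cache[key]
        truth.set_voxel(idx, dirs, fracs)
        truth.f_gm[idx] = 0.0

    csf_only = in_csf & ~wm_any
    signal[csf_only] = sig_csf
    truth.f_gm[csf_only] = 0.0
    truth.f_csf[csf_only] = 1.0

    return PhantomVolume(
        signal=signal,
        truth=truth,
        scheme=scheme,
        profile=profile,
        metadata={"family": "challenge_like", "shape": shape},
    )


def enumerate_phantom_suite(shape=DEFAULT_SHAPE):
    """The full evaluation suite: 90 crossing-angle specs (1..90 degrees),
    41 volume-fraction specs (0.10..0.50 in 0.01 steps) and one
    challenge-like phantom — 132 in total."""
    specs = [
        PhantomSpec(family="crossing_angle", shape=tuple(shape), angle=float(a))
        for a in range(1, 91)
    ]
    specs += [
        PhantomSpec(
            family="volume_fraction",
            shape=tuple(shape),
            minor_fraction=round(0.1 + 0.01 * i, 2),
        )
        for i in range(41)
    ]
    specs.append(PhantomSpec(family="challenge_like", shape=tuple(shape)))
    return specs
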