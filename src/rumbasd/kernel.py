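"""Generative multi-tensor signal model and the deconvolution dictionary.

The measured single-shell diffusion signal in a voxel is modelled as a
mixture of anisotropic white-matter (WM) compartments plus two isotropic
terms (grey matter and CSF)::

    S_i = S0 * ( sum_j f_j exp(-b_i v_i^T D_j v_i)
                 + f_GM exp(-b_i D_GM) + f_CSF exp(-b_i D_CSF) )

where each WM compartment carries an axially symmetric diffusion tensor
D_j = R_j A R_j^T rotated so its principal axis lies along the j-th fiber
orientation.  Sampling all fiber orientations on a dense antipodally
symmetric sphere grid turns the model into a linear dictionary
``S = H f`` whose columns are single-fiber responses; the non-negative
coefficient vector ``f`` is the fiber orientation distribution function
(fODF) evaluated on the grid.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

__all__ = [
    "AcquisitionScheme",
    "DiffusivityProfile",
    "SphereGrid",
    "KernelDictionary",
    "single_fiber_signal",
    "multi_tensor_signal",
    "make_sphere_grid",
    "build_dictionary",
]

_UNIT_TOL = 1e-6


def _as_unit(v, name="vector", tol=_UNIT_TOL):
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    norm = np.linalg.norm(v)
    if abs(norm - 1.0) > tol:
        raise ValueError(f"{name} must have unit norm (|v| = {norm:.8f})")
    return v / norm


@dataclass(frozen=True)
class AcquisitionScheme:
    """Diffusion sampling scheme: b-values (s/mm^2) and unit gradient directions.

    Gradient columns with b = 0 are conventionally stored as zero vectors
    and are exempt from the unit-norm requirement.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (N, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"bvals has {bvals.shape[0]} entries but bvecs has "
                f"{bvecs.shape[0]} rows"
            )
        if bvals.shape[0] < 1:
            raise ValueError("scheme must contain at least one measurement")
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        norms = np.linalg.norm(bvecs, axis=1)
        dwi = bvals > 0
        if np.any(np.abs(norms[dwi] - 1.0) > _UNIT_TOL):
            bad = int(np.argmax(np.abs(norms - 1.0) * dwi))
            raise ValueError(
                f"bvec {bad} has norm {norms[bad]:.8f}; diffusion-weighted "
                "directions must be unit vectors"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_measurements(self) -> int:
        return int(self.bvals.shape[0])

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @classmethod
    def from_fsl(cls, bvals_path, bvecs_path) -> "AcquisitionScheme":
        """Read an FSL-style gradient table (single-row bvals, 3xN bvecs)."""
        bvals = np.loadtxt(bvals_path).ravel()
        bvecs = np.loadtxt(bvecs_path)
        if bvecs.ndim == 1:
            bvecs = bvecs.reshape(3, -1)
        if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
            bvecs = bvecs.T
        elif bvecs.shape == (3, 3):
            # ambiguous 3x3: FSL convention is 3 rows x N columns
            bvecs = bvecs.T
        return cls(bvals=bvals, bvecs=bvecs)

    def to_fsl(self, bvals_path, bvecs_path) -> None:
        np.savetxt(bvals_path, self.bvals[None, :], fmt="%.6g")
        np.savetxt(bvecs_path, self.bvecs.T, fmt="%.8f")


@dataclass(frozen=True)
class DiffusivityProfile:
    """Tensor diffusivities (mm^2/s) and base amplitude of the signal model.

    Defaults are the single-shell evaluation setting: a sharp WM response
    with lambda1 = 1.7e-3, lambda2 = lambda3 = 0.3e-3, and isotropic
    compartments at 0.1e-3 (GM-like) and 2.5e-3 (CSF-like).
    """

    lambda1: float = 1.7e-3
    lambda2: float = 0.3e-3
    lambda3: float = 0.3e-3
    d_gm: float = 0.1e-3
    d_csf: float = 2.5e-3
    s0: float = 1.0

    def __post_init__(self):
        if not (self.lambda1 >= self.lambda2 >= self.lambda3 > 0):
            raise ValueError(
                "diffusivities must satisfy lambda1 >= lambda2 >= lambda3 > 0"
            )
        if self.d_gm <= 0 or self.d_csf <= 0:
            raise ValueError("isotropic diffusivities must be positive")
        if self.s0 <= 0:
            raise ValueError("S0 must be positive")


@dataclass(frozen=True)
class SphereGrid:
    """Dense antipodally symmetric direction set with triangulation adjacency."""

    vertices: np.ndarray            # (M, 3) unit vectors
    antipode_index: np.ndarray      # (M,) index of the antipodal vertex
    neighbors: tuple                # tuple of M int arrays from the convex hull
    metadata: dict = field(default_factory=dict, compare=False)

    @property
    def m(self) -> int:
        return int(self.vertices.shape[0])

    def neighbor_angles_deg(self) -> np.ndarray:
        """Angular separation (degrees) of every triangulation edge."""
        angles = []
        for i, nb in enumerate(self.neighbors):
            for j in nb:
                if j > i:
                    c = np.clip(self.vertices[i] @ self.vertices[j], -1.0, 1.0)
                    angles.append(np.degrees(np.arccos(c)))
        return np.asarray(angles)


def rotation_to(direction: np.ndarray) -> np.ndarray:
    """Minimal (Rodrigues) rotation taking the x-axis onto ``direction``.

    When the target is anti-parallel to x the rotation axis degenerates;
    a fixed fallback (180 degrees about z) is used for determinism.
    """
    d = np.asarray(direction, dtype=float)
    x = np.array([1.0, 0.0, 0.0])
    c = float(np.clip(x @ d, -1.0, 1.0))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([-1.0, -1.0, 1.0])
    axis = np.cross(x, d)
    axis /= np.linalg.norm(axis)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    s = np.sqrt(1.0 - c * c)
    return np.eye(3) + s * k + (1.0 - c) * (k @ k)


def fiber_tensor(direction: np.ndarray, profile: DiffusivityProfile) -> np.ndarray:
    """3x3 diffusion tensor with principal axis along ``direction``."""
    r = rotation_to(direction)
    a = np.diag([profile.lambda1, profile.lambda2, profile.lambda3])
    return r @ a @ r.T


def single_fiber_signal(fiber_dir, bval, gvec, profile: DiffusivityProfile) -> float:
    """Noiseless signal of one coherent fiber population.

    Returns ``S0 * exp(-b g^T D g)`` where D is the profile's tensor
    rotated onto ``fiber_dir``.  Invariant to a sign flip of either
    vector.  A zero gradient vector is accepted when b = 0.
    """
    bval = float(bval)
    if bval < 0:
        raise ValueError("bval must be non-negative")
    d = _as_unit(fiber_dir, "fiber_dir")
    if bval == 0:
        return float(profile.s0)
    g = _as_unit(gvec, "gvec")
    tensor = fiber_tensor(d, profile)
    return float(profile.s0 * np.exp(-bval * (g @ tensor @ g)))


def multi_tensor_signal(
    fibers,
    fractions,
    scheme: AcquisitionScheme,
    profile: DiffusivityProfile,
    f_gm: float = 0.0,
    f_csf: float = 0.0,
) -> np.ndarray:
    """Noiseless mixture signal over a whole acquisition scheme.

    ``fractions`` are the WM compartment fractions (one per fiber);
    together with ``f_gm`` and ``f_csf`` they must sum to 1.
    """
    fractions = np.asarray(fractions, dtype=float)
    if len(fibers) != fractions.shape[0]:
        raise ValueError("one fraction required per fiber")
    if np.any(fractions < 0) or f_gm < 0 or f_csf < 0:
        raise ValueError("fractions must be non-negative")
    total = float(fractions.sum() + f_gm + f_csf)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1 (got {total:.12f})")

    b = scheme.bvals
    g = scheme.bvecs
    signal = np.zeros(scheme.n_measurements)
    for frac, fib in zip(fractions, fibers):
        tensor = fiber_tensor(_as_unit(fib, "fiber"), profile)
        quad = np.einsum("ni,ij,nj->n", g, tensor, g)
        signal += frac * np.exp(-b * quad)
    signal += f_gm * np.exp(-b * profile.d_gm)
    signal += f_csf * np.exp(-b * profile.d_csf)
    return profile.s0 * signal


# ---------------------------------------------------------------------------
# sphere grids
# ---------------------------------------------------------------------------

_ICOSPHERE_SIZES = (12, 42, 162, 642, 2562)


def _icosahedron():
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _subdivide(vertices: np.ndarray) -> np.ndarray:
    """One icosphere subdivision: add midpoints of all hull edges."""
    hull = ConvexHull(vertices)
    edges = set()
    for simplex in hull.simplices:
        for a, b in ((0, 1), (1, 2), (0, 2)):
            edges.add(tuple(sorted((simplex[a], simplex[b]))))
    mids = np.array([(vertices[i] + vertices[j]) / 2.0 for i, j in sorted(edges)])
    mids /= np.linalg.norm(mids, axis=1, keepdims=True)
    return np.vstack([vertices, mids])


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """n points from a Fibonacci spiral, folded into the z >= 0 hemisphere."""
    i = np.arange(n)
    ga = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - (2.0 * i + 1.0) / (2.0 * n)
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = ga * i
    pts = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    pts[pts[:, 2] < 0] *= -1.0
    return pts


def _repel_antipodal(half: np.ndarray, n_iter: int = 250) -> np.ndarray:
    """Electrostatic repulsion of antipodally paired points on the sphere.

    Only one point per pair is free; forces are accumulated from the full
    mirrored set, then points are re-projected onto the sphere.  Fixed
    step schedule, fully deterministic.
    """
    p = half.copy()
    m2 = p.shape[0]
    step = 0.9 / m2
    for _ in range(n_iter):
        full = np.vstack([p, -p])
        diff = p[:, None, :] - full[None, :, :]          # (m2, 2*m2, 3)
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        np.fill_diagonal(d2[:, :m2], np.inf)
        inv = 1.0 / np.maximum(d2, 1e-12) ** 1.5
        force = np.einsum("ij,ijk->ik", inv, diff)
        # project tangentially, take a normalized step
        force -= p * np.einsum("ik,ik->i", force, p)[:, None]
        scale = np.max(np.linalg.norm(force, axis=1))
        if scale > 0:
            p = p + step * force / scale
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        p[p[:, 2] < 0] *= -1.0
    return p


def _hull_neighbors(vertices: np.ndarray):
    hull = ConvexHull(vertices)
    nb = [set() for _ in range(vertices.shape[0])]
    for simplex in hull.simplices:
        for a, b in ((0, 1), (1, 2), (0, 2)):
            nb[simplex[a]].add(int(simplex[b]))
            nb[simplex[b]].add(int(simplex[a]))
    return tuple(np.array(sorted(s), dtype=int) for s in nb)


def _antipode_index(vertices: np.ndarray) -> np.ndarray:
    neg = -vertices
    dots = vertices @ neg.T
    idx = np.argmax(dots, axis=1)
    if np.any(np.max(dots, axis=1) < 1.0 - 1e-8):
        raise ValueError("direction set is not antipodally symmetric")
    return idx.astype(int)


@functools.lru_cache(maxsize=8)
def make_sphere_grid(target_m: int = 724) -> SphereGrid:
    """Build an antipodally symmetric direction grid of about ``target_m`` points.

    Exact icosahedral subdivisions are used when ``target_m`` matches one of
    their sizes (12, 42, 162, 642, 2562); any other even count is produced
    exactly by electrostatic repulsion of antipodal pairs seeded from a
    Fibonacci spiral.  Adjacency comes from the convex-hull triangulation;
    the mean and SD of the neighbor angular separation are recorded in
    ``metadata``.
    """
    if target_m % 2 != 0 or target_m < 12:
        raise ValueError("target_m must be an even integer >= 12")
    if target_m in _ICOSPHERE_SIZES:
        vertices = _icosahedron()
        while vertices.shape[0] < target_m:
            vertices = _subdivide(vertices)
        method = "icosphere"
    else:
        half = _fibonacci_hemisphere(target_m // 2)
        half = _repel_antipodal(half)
        vertices = np.vstack([half, -half])
        method = "electrostatic"
    neighbors = _hull_neighbors(vertices)
    grid = SphereGrid(
        vertices=vertices,
        antipode_index=_antipode_index(vertices),
        neighbors=neighbors,
    )
    angles = grid.neighbor_angles_deg()
    grid.metadata.update(
        method=method,
        m=vertices.shape[0],
        mean_separation_deg=float(angles.mean()),
        sd_separation_deg=float(angles.std()),
    )
    return grid


def build_dictionary(
    scheme: AcquisitionScheme,
    grid: SphereGrid,
    profile: DiffusivityProfile,
) -> "KernelDictionary":
    """Assemble the N x (M+2) deconvolution dictionary.

    Column j <= M is the single-fiber response along grid direction j;
    the two rightmost columns are the GM and CSF isotropic responses.
    """
    b = scheme.bvals
    g = scheme.bvecs
    tensors = np.stack([fiber_tensor(v, profile) for v in grid.vertices])
    quad = np.einsum("ni,mij,nj->nm", g, tensors, g)
    h_wm = np.exp(-b[:, None] * quad)
    h_iso = np.exp(-b[:, None] * np.array([profile.d_gm, profile.d_csf])[None, :])
    h = profile.s0 * np.hstack([h_wm, h_iso])
    return KernelDictionary(H=h, grid=grid, profile=profile, scheme=scheme)


@dataclass(frozen=True)
class KernelDictionary:
    """Dictionary ``H`` of oriented WM responses plus GM and CSF columns."""

    H: np.ndarray
    grid: SphereGrid
    profile: DiffusivityProfile
    scheme: AcquisitionScheme

    @property
    def n_compartments(self) -> int:
        return int(self.H.shape[1])

    def export_directions(self, path) -> None:
        """Write the grid directions as a plain-text table, one per line."""
        np.savetxt(path, self.grid.vertices, fmt="%.10f")
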