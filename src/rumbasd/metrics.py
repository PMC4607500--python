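"""Peak extraction from fiber ODFs and recovery metrics against ground truth.

Peaks are grid vertices whose fODF value is at least that of every
triangulation neighbor, deduplicated across antipodes, thresholded at one
tenth of the largest peak and capped at the four largest.  Per voxel the
angular error is the mean, over true fibers, of the minimum angle between
the true direction and any detected peak (absolute dot product, so sign
flips are irrelevant); the volume-fraction error compares normalized peak
amplitudes with the true compartment fractions under closest-peak
matching.  Across a field, the success rate is the proportion of voxels
whose detected fiber count equals the true count, with the mean
over-detected (n+) and under-detected (n-) counts separating the two
failure modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernel import SphereGrid

__all__ = [
    "PeakSet",
    "GroundTruthVoxel",
    "MetricsReport",
    "extract_peaks",
    "angular_error",
    "volume_fraction_error",
    "detection_counts",
    "evaluate_field",
]

MAX_PEAKS = 4
RELATIVE_PEAK_THRESHOLD = 0.1


@dataclass(frozen=True)
class PeakSet:
    """Up to four fODF maxima: unit directions with descending amplitudes."""

    directions: np.ndarray          # (k, 3)
    amplitudes: np.ndarray          # (k,), descending, >= 0

    def __post_init__(self):
        d = np.asarray(self.directions, dtype=float).reshape(-1, 3)
        a = np.asarray(self.amplitudes, dtype=float).reshape(-1)
        if d.shape[0] != a.shape[0]:
            raise ValueError("one amplitude required per direction")
        if np.any(np.diff(a) > 0):
            raise ValueError("amplitudes must be descending")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "amplitudes", a)

    @property
    def count(self) -> int:
        return int(self.amplitudes.shape[0])


@dataclass(frozen=True)
class GroundTruthVoxel:
    """True fiber directions and volume fractions of one voxel."""

    fiber_dirs: np.ndarray          # (M_true, 3)
    fractions: np.ndarray           # (M_true,)

    def __post_init__(self):
        d = np.asarray(self.fiber_dirs, dtype=float).reshape(-1, 3)
        f = np.asarray(self.fractions, dtype=float).reshape(-1)
        if d.shape[0] != f.shape[0]:
            raise ValueError("one fraction required per fiber")
        if f.sum() > 1.0 + 1e-9:
            raise ValueError("fractions must sum to at most 1")
        object.__setattr__(self, "fiber_dirs", d)
        object.__setattr__(self, "fractions", f)

    @property
    def m_true(self) -> int:
        return int(self.fractions.shape[0])


@dataclass
class MetricsReport:
    """Field-level summary of the recovery quality."""

    theta_mean: float
    theta_sd: float
    df_mean: float
    df_sd: float
    success_rate: float
    n_plus: float
    n_minus: float
    n_voxels: int
    n_voxels_scored: int            # voxels contributing to theta / df
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "theta_mean_deg": self.theta_mean,
            "theta_sd_deg": self.theta_sd,
            "df_mean": self.df_mean,
            "df_sd": self.df_sd,
            "success_rate": self.success_rate,
            "n_plus": self.n_plus,
            "n_minus": self.n_minus,
            "n_voxels": self.n_voxels,
            "n_voxels_scored": self.n_voxels_scored,
        }
        d.update(self.extra)
        return d


def extract_peaks(fodf, grid: SphereGrid) -> PeakSet:
    """Local fODF maxima over the grid adjacency.

    ``fodf`` may be the WM weights (length M) or the full coefficient
    vector (length M + 2; the two isotropic entries are ignored).
    Vertices at least as large as every neighbor qualify; antipodal
    duplicates collapse to one peak; candidates below one tenth of the
    largest peak are dropped and at most the four largest are kept, no
    two of which are mutually adjacent.
    """
    fodf = np.asarray(fodf, dtype=float)
    wm = fodf[: grid.m]
    if np.any(wm < 0):
        raise ValueError("fODF weights must be non-negative")
    if not np.any(wm > 0):
        return PeakSet(np.empty((0, 3)), np.empty(0))

    is_max = np.array(
        [wm[i] > 0 and np.all(wm[i] >= wm[nb]) for i, nb in enumerate(grid.neighbors)]
    )
    candidates = np.flatnonzero(is_max)
    # antipodal dedup: one representative per pair, the larger-valued member
    best: dict[int, int] = {}
    for idx in candidates:
        pair = int(min(idx, grid.antipode_index[idx]))
        if pair not in best or wm[idx] > wm[best[pair]]:
            best[pair] = int(idx)
    candidates = np.array(sorted(best.values()), dtype=int)
    order = candidates[np.argsort(wm[candidates])[::-1]]
    threshold = RELATIVE_PEAK_THRESHOLD * wm[order[0]]

    kept: list[int] = []
    for idx in order:
        if wm[idx] < threshold:
            break
        close = False
        for j in kept:
            pair = {j, int(grid.antipode_index[j])}
            if idx in pair or int(grid.antipode_index[idx]) in pair:
                close = True
                break
            if idx in grid.neighbors[j] or int(grid.antipode_index[idx]) in grid.neighbors[j]:
                close = True
                break
        if not close:
            kept.append(int(idx))
        if len(kept) == MAX_PEAKS:
            break
    return PeakSet(grid.vertices[kept], wm[kept])


def angular_error(peaks: PeakSet, truth: GroundTruthVoxel) -> float:
    """Mean over true fibers of the minimum angle (degrees) to any peak.

    Uses the absolute dot product, so antipodal detections count as
    exact.  Undefined (raises) for an empty peak set; callers exclude
    such voxels and account for them through the under-detection count.
    """
    if truth.m_true < 1:
        raise ValueError("ground truth must contain at least one fiber")
    if peaks.count == 0:
        raise ValueError("angular error is undefined for an empty peak set")
    cosines = np.abs(truth.fiber_dirs @ peaks.directions.T)
    cosines = np.clip(cosines, -1.0, 1.0)
    best = np.degrees(np.arccos(cosines.max(axis=1)))
    return float(best.mean())


def _closest_peak_indices(peaks: PeakSet, truth: GroundTruthVoxel) -> np.ndarray:
    """Per true fiber, the index of the angularly closest peak (ties by amplitude)."""
    cosines = np.abs(truth.fiber_dirs @ peaks.directions.T)
    out = np.empty(truth.m_true, dtype=int)
    for k in range(truth.m_true):
        row = cosines[k]
        best = np.flatnonzero(row >= row.max() - 1e-12)
        out[k] = best[np.argmax(peaks.amplitudes[best])]
    return out


def volume_fraction_error(
    peaks: PeakSet,
    truth: GroundTruthVoxel,
    wm_fraction: float = 1.0,
) -> float:
    """Mean absolute error between normalized peak amplitudes and true fractions.

    Peak amplitudes are normalized to sum to ``wm_fraction`` (the voxel's
    estimated total WM fraction) so they are commensurable with the true
    compartment fractions; each true fiber is compared with its closest
    detected peak.
    """
    if peaks.count == 0:
        raise ValueError("volume-fraction error is undefined for an empty peak set")
    total = peaks.amplitudes.sum()
    norm_amp = peaks.amplitudes * (wm_fraction / total) if total > 0 else peaks.amplitudes
    match = _closest_peak_indices(peaks, truth)
    return float(np.mean(np.abs(norm_amp[match] - truth.fractions)))


def detection_counts(peaks_field, truth_field):
    """Success rate and mean over/under-detection across aligned voxel lists.

    ``SR`` is the fraction of voxels where the detected peak count equals
    the true fiber count; ``n_plus``/``n_minus`` are the means of the
    positive/negative parts of (detected - true).
    """
    detected = np.array([p.count for p in peaks_field], dtype=float)
    true = np.array([t.m_true for t in truth_field], dtype=float)
    if detected.shape != true.shape:
        raise ValueError("peak and truth lists must be aligned")
    if detected.size == 0:
        raise ValueError("empty field")
    diff = detected - true
    sr = float(np.mean(diff == 0))
    n_plus = float(np.mean(np.maximum(diff, 0.0)))
    n_minus = float(np.mean(np.maximum(-diff, 0.0)))
    return sr, n_plus, n_minus


def evaluate_field(
    fodf_coefficients,
    grid: SphereGrid,
    truths,
    wm_fractions=None,
) -> MetricsReport:
    """Extract peaks voxel by voxel and summarize recovery quality.

    ``fodf_coefficients`` is an iterable of per-voxel coefficient vectors
    aligned with ``truths`` (GroundTruthVoxel each).  Voxels with no
    detected peak are excluded from the angular and fraction errors but
    contribute to the success rate and the under-detection count.
    """
    truths = list(truths)
    peak_sets = [extract_peaks(f, grid) for f in fodf_coefficients]
    if len(peak_sets) != len(truths):
        raise ValueError("fODF and truth fields must be aligned")
    if wm_fractions is None:
        wm_fractions = [1.0] * len(truths)
    thetas, dfs = [], []
    for p, t, w in zip(peak_sets, truths, wm_fractions):
        if t.m_true >= 1 and p.count >= 1:
            thetas.append(angular_error(p, t))
            dfs.append(volume_fraction_error(p, t, wm_fraction=w))
    sr, n_plus, n_minus = detection_counts(peak_sets, truths)
    thetas = np.asarray(thetas)
    dfs = np.asarray(dfs)
    return MetricsReport(
        theta_mean=float(thetas.mean()) if thetas.size else float("nan"),
        theta_sd=float(thetas.std()) if thetas.size else float("nan"),
        df_mean=float(dfs.mean()) if dfs.size else float("nan"),
        df_sd=float(dfs.std()) if dfs.size else float("nan"),
        success_rate=sr,
        n_plus=n_plus,
        n_minus=n_minus,
        n_voxels=len(truths),
        n_voxels_scored=int(thetas.size),
    )
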