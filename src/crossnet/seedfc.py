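"""Seed-based voxelwise connectivity with Monte-Carlo cluster correction.

The seed is a small sphere (default: 4 mm diameter at standard-space mm
coordinates (1, -29, -12), the periaqueductal grey).  Its mean time series
is correlated with every voxel, the correlation map is Fisher-z transformed
per subject, and groups are compared with a pooled-variance two-sample
t-test.  Familywise error is controlled by cluster-extent thresholding: the
null distribution of the largest suprathreshold cluster is simulated from
smooth Gaussian noise (the AlphaSim procedure), and only clusters larger
than the null-calibrated extent survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .connectivity import fisher_z

_STRUCTURES = {
    "faces": ndimage.generate_binary_structure(3, 1),
    "edges": ndimage.generate_binary_structure(3, 2),
    "corners": ndimage.generate_binary_structure(3, 3),
}
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class SeedROI:
    """Spherical seed resolved to voxel indices on a specific grid."""

    center_mm: tuple[float, float, float]
    diameter_mm: float
    voxels: np.ndarray  # (k, 3) integer indices

    @property
    def n_voxels(self) -> int:
        return self.voxels.shape[0]


@dataclass
class FisherZMap:
    """Per-subject voxelwise Fisher-z seed-correlation map."""

    subject_id: str
    data: np.ndarray
    mask: np.ndarray
    n_clipped: int = 0


@dataclass(frozen=True)
class MonteCarloThreshold:
    """Null-calibrated cluster-extent threshold."""

    voxel_p: float
    alpha: float
    fwhm_mm: float
    n_iter: int
    min_cluster_extent: int
    min_cluster_extent_mm3: float
    connectivity: str
    voxel_volume_mm3: float


@dataclass(frozen=True)
class Cluster:
    """One surviving suprathreshold cluster."""

    cluster_id: int
    n_voxels: int
    extent_mm3: float
    peak_mm: tuple[float, float, float]
    peak_t: float
    mean_t: float
    sign: int


def _voxel_centers_mm(shape, affine) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    homo = np.column_stack([idx, np.ones(len(idx))])
    return (homo @ affine.T)[:, :3]


def make_sphere_roi(
    center_mm, diameter_mm: float, affine: np.ndarray, shape
) -> SeedROI:
    """Resolve a sphere in mm space to voxel indices on the grid.

    Includes every voxel whose centre lies within ``diameter_mm / 2`` of the
    sphere centre; if none does (diameter below the voxel spacing), falls
    back to the single nearest voxel so the seed is never empty.  A centre
    outside the grid's bounding box is an error.
    """
    center = np.asarray(center_mm, dtype=float)
    centers = _voxel_centers_mm(shape, affine)
    lo, hi = centers.min(axis=0), centers.max(axis=0)
    half = np.abs(np.diag(affine)[:3]) / 2.0
    if np.any(center < lo - half) or np.any(center > hi + half):
        raise ValueError(
            f"seed centre {tuple(center)} lies outside the grid bounds "
            f"[{tuple(lo - half)}, {tuple(hi + half)}]"
        )
    d = np.linalg.norm(centers - center, axis=1)
    inside = np.flatnonzero(d <= diameter_mm / 2.0)
    if inside.size == 0:
        inside = np.array([int(np.argmin(d))])
    idx = np.indices(shape).reshape(3, -1).T
    return SeedROI(tuple(center), diameter_mm, idx[inside])


def seed_fc_map(
    vol4d: np.ndarray,
    roi: SeedROI,
    mask: np.ndarray | None = None,
    subject_id: str = "subject",
) -> FisherZMap:
    """Correlate the seed-mean series with every in-mask voxel, Fisher-z it."""
    vol4d = np.asarray(vol4d, dtype=float)
    if vol4d.ndim != 4:
        raise ValueError("expected a 4D (x, y, z, t) array")
    if vol4d.shape[3] < 3:
        raise ValueError("need at least 3 time points")
    if mask is None:
        mask = np.ones(vol4d.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    i, j, k = roi.voxels.T
    if not mask[i, j, k].all():
        raise ValueError("seed voxels fall outside the analysis mask")
    seed_ts = vol4d[i, j, k, :].mean(axis=0)
    seed_sd = seed_ts.std()
    if seed_sd == 0:
        raise ValueError("seed series has zero variance")
    t = vol4d.shape[3]
    flat = vol4d.reshape(-1, t)[mask.ravel()]
    vc = flat - flat.mean(axis=1, keepdims=True)
    sc = seed_ts - seed_ts.mean()
    denom = np.sqrt((vc**2).sum(axis=1)) * np.sqrt((sc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, vc @ sc / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    n_clipped = int(np.sum(np.abs(r) >= 1 - 1e-7))
    z = np.zeros(vol4d.shape[:3])
    z[mask] = fisher_z(r)
    return FisherZMap(subject_id, z, mask, n_clipped)


def two_sample_tmap(
    maps_a: list[FisherZMap], maps_b: list[FisherZMap]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxelwise pooled-variance two-sample t between two groups of z-maps.

    Returns ``(t, p, valid)``: t and two-sided p volumes, and the mask of
    voxels inside the common analysis mask with non-zero pooled variance.
    """
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    mask = maps_a[0].mask.copy()
    for m in (*maps_a, *maps_b):
        mask &= m.mask
    a = np.stack([m.data[mask] for m in maps_a])
    b = np.stack([m.data[mask] for m in maps_b])
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    good = se > 0
    tvals = np.zeros(a.shape[1])
    tvals[good] = (a.mean(axis=0) - b.mean(axis=0))[good] / se[good]
    pvals = np.ones(a.shape[1])
    pvals[good] = 2.0 * stats.t.sf(np.abs(tvals[good]), df)
    tvol = np.zeros(mask.shape)
    pvol = np.ones(mask.shape)
    valid = np.zeros(mask.shape, dtype=bool)
    tvol[mask] = tvals
    pvol[mask] = pvals
    valid[mask] = good
    return tvol, pvol, valid


def estimate_smoothness(
    residual_maps: list[np.ndarray], voxel_size_mm: float = 1.0
) -> float:
    """Estimate spatial smoothness (FWHM, mm) from residual maps.

    Uses the variance-of-gradients estimator per axis,
    ``fwhm = dx * sqrt(-2 ln 2 / ln(1 - var(diff) / (2 var)))``,
    floored at one voxel (a sampled field cannot resolve smoothness below
    its grid spacing, so i.i.d. noise reports roughly the voxel size), and
    returns the geometric mean across axes averaged over maps.  A constant
    map is an error.
    """
    if not residual_maps:
        raise ValueError("need at least one residual map")
    fwhms = []
    for vol in residual_maps:
        vol = np.asarray(vol, dtype=float)
        v = vol.var()
        if v == 0:
            raise ValueError("constant residual map has undefined smoothness")
        per_axis = []
        for ax in range(vol.ndim):
            dv = np.diff(vol, axis=ax).var()
            ratio = dv / (2.0 * v)
            if ratio >= 1.0:
                per_axis.append(voxel_size_mm)  # rougher than white noise
                continue
            est = voxel_size_mm * np.sqrt(-2.0 * np.log(2.0) / np.log(1.0 - ratio))
            per_axis.append(max(est, voxel_size_mm))
        fwhms.append(float(np.exp(np.mean(np.log(per_axis)))))
    return float(np.mean(fwhms))


def _max_null_cluster(
    rng: np.random.Generator,
    shape,
    mask: np.ndarray,
    sigma_vox: float,
    z_thr: float,
    structure: np.ndarray,
) -> int:
    field = rng.standard_normal(shape)
    if sigma_vox > 0:
        field = ndimage.gaussian_filter(field, sigma_vox)
    vals = field[mask]
    field = field / vals.std()
    supra = (np.abs(field) > z_thr) & mask
    best = 0
    for signed in (supra & (field > 0), supra & (field < 0)):
        if not signed.any():
            continue
        lab, n = ndimage.label(signed, structure=structure)
        if n:
            best = max(best, int(np.bincount(lab.ravel())[1:].max()))
    return best


def mc_cluster_threshold(
    shape,
    mask: np.ndarray | None,
    fwhm_mm: float,
    voxel_size_mm: float,
    voxel_p: float = 0.05,
    alpha: float = 0.01,
    n_iter: int = 1000,
    connectivity: str = "faces",
    seed: int = 0,
) -> MonteCarloThreshold:
    """Calibrate the minimum cluster extent by Monte-Carlo simulation.

    ``n_iter`` Gaussian white-noise volumes are smoothed to ``fwhm_mm``,
    standardised, thresholded two-sided at ``voxel_p``, and the largest
    sign-pure cluster recorded per iterate.  The returned extent is the
    smallest cluster size whose null exceedance frequency is at most
    ``alpha``.
    """
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if n_iter < 100:
        raise ValueError("n_iter must be at least 100")
    if alpha < 1.0 / n_iter:
        raise ValueError(
            f"alpha={alpha} is below the Monte-Carlo resolution 1/{n_iter}"
        )
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    structure = _STRUCTURES[connectivity]
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / voxel_size_mm
    z_thr = stats.norm.isf(voxel_p / 2.0)
    rng = np.random.default_rng(seed)
    max_sizes = np.array(
        [
            _max_null_cluster(rng, shape, mask, sigma_vox, z_thr, structure)
            for _ in range(n_iter)
        ]
    )
    # Smallest k with P(max cluster >= k) <= alpha.
    k = 1
    while np.mean(max_sizes >= k) > alpha:
        k += 1
    vol = voxel_size_mm**3
    return MonteCarloThreshold(
        voxel_p, alpha, fwhm_mm, n_iter, k, k * vol, connectivity, vol
    )


def apply_cluster_threshold(
    tvol: np.ndarray,
    pvol: np.ndarray,
    thr: MonteCarloThreshold,
    affine: np.ndarray,
    valid: np.ndarray | None = None,
) -> list[Cluster]:
    """Keep sign-pure suprathreshold clusters at or above the calibrated extent.

    Positive and negative t-values are clustered separately; the report is
    sorted by extent, largest first.  An empty report is a valid outcome.
    """
    tvol = np.asarray(tvol, dtype=float)
    pvol = np.asarray(pvol, dtype=float)
    if valid is None:
        valid = np.ones(tvol.shape, dtype=bool)
    structure = _STRUCTURES[thr.connectivity]
    supra = (pvol < thr.voxel_p) & valid
    clusters: list[Cluster] = []
    cid = 0
    for sign in (1, -1):
        signed = supra & ((tvol > 0) if sign > 0 else (tvol < 0))
        lab, n = ndimage.label(signed, structure=structure)
        for comp in range(1, n + 1):
            where = np.argwhere(lab == comp)
            if len(where) < thr.min_cluster_extent:
                continue
            tv = tvol[tuple(where.T)]
            peak = where[np.argmax(np.abs(tv))]
            peak_mm = (affine @ np.append(peak, 1.0))[:3]
            cid += 1
            clusters.append(
                Cluster(
                    cluster_id=cid,
                    n_voxels=len(where),
                    extent_mm3=len(where) * thr.voxel_volume_mm3,
                    peak_mm=tuple(float(x) for x in peak_mm),
                    peak_t=float(tv[np.argmax(np.abs(tv))]),
                    mean_t=float(tv.mean()),
                    sign=sign,
                )
            )
    clusters.sort(key=lambda c: -c.n_voxels)
    return [
        Cluster(i + 1, c.n_voxels, c.extent_mm3, c.peak_mm, c.peak_t, c.mean_t, c.sign)
        for i, c in enumerate(clusters)
    ]
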