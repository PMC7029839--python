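"""Per-subject BOLD cleaning and parcel time-series extraction.

The cleaning chain mirrors a standard resting-state preprocessing recipe:
initial-volume removal (T1 equilibration), despiking, polynomial detrending,
ROI averaging over an integer-label atlas, and nuisance regression of
white-matter / CSF / global-mean signals from the regional series.  Slice
timing and motion correction are out of scope: inputs are assumed corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class RegionTimeSeriesSet:
    """Cleaned per-region BOLD time series for one subject.

    ``data`` is a T x R matrix; ``labels`` orders its columns.  ``provenance``
    records the cleaning steps applied, in order.
    """

    subject_id: str
    labels: list[str]
    data: np.ndarray
    tr: float = 2.0
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be T x R")
        if self.data.shape[1] != len(self.labels):
            raise ValueError(
                f"{self.data.shape[1]} columns but {len(self.labels)} labels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contain non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, subject_id: str, tr: float = 2.0) -> "RegionTimeSeriesSet":
        df = pd.read_csv(path, sep="\t")
        return cls(subject_id, list(df.columns), df.to_numpy(float), tr)


@dataclass
class NuisanceSet:
    """Named nuisance regressor columns (white-matter, CSF, global mean, ...)."""

    regressors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        lengths = {k: len(np.asarray(v)) for k, v in self.regressors.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"regressor lengths differ: {lengths}")
        for name, col in self.regressors.items():
            col = np.asarray(col, dtype=float)
            if np.ptp(col) == 0:
                raise ValueError(f"regressor {name!r} has zero variance")
            self.regressors[name] = col

    @property
    def n_timepoints(self) -> int:
        return len(next(iter(self.regressors.values())))

    def design_matrix(self) -> np.ndarray:
        """Intercept column followed by the named regressors."""
        cols = [np.ones(self.n_timepoints)]
        cols.extend(self.regressors[k] for k in self.regressors)
        return np.column_stack(cols)


def drop_initial_volumes(vol4d: np.ndarray, n: int = 5) -> np.ndarray:
    """Discard the first ``n`` volumes of a 4D (x, y, z, t) array.

    The leading volumes of an EPI run are acquired before longitudinal
    magnetization reaches steady state and are conventionally removed.
    """
    vol4d = np.asarray(vol4d)
    if vol4d.ndim != 4:
        raise ValueError("expected a 4D (x, y, z, t) array")
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= vol4d.shape[3]:
        raise ValueError(f"cannot drop {n} volumes from a run of {vol4d.shape[3]}")
    return vol4d[..., n:]


def despike(
    series: np.ndarray, cut: float = 2.5, squash_cap: float = 4.0
) -> np.ndarray:
    """Compress transient spikes toward a smooth linear fit.

    Residuals from a least-squares line are measured in robust SD units
    (1.4826 * median absolute deviation).  Points within ``cut`` robust SDs
    pass through unchanged; larger residuals are squashed by a saturating
    tanh map so no residual exceeds ``squash_cap`` robust SDs:

        r' = cut + (cap - cut) * tanh((|r| - cut) / (cap - cut))

    Constant or spike-free series are returned unchanged.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("despike expects a 1D series")
    t = series.size
    if t < 8:
        raise ValueError("despike needs at least 8 time points")
    if squash_cap <= cut:
        raise ValueError("squash_cap must exceed cut")
    if np.ptp(series) == 0:
        return series.copy()
    x = np.arange(t, dtype=float)
    fit = np.polynomial.polynomial.polyval(
        x, np.polynomial.polynomial.polyfit(x, series, 1)
    )
    resid = series - fit
    mad = np.median(np.abs(resid - np.median(resid)))
    sigma = 1.4826 * mad
    if sigma == 0:
        # Degenerate spread (over half the points on the fit): fall back to SD.
        sigma = resid.std()
        if sigma == 0:
            return series.copy()
    r = resid / sigma
    absr = np.abs(r)
    span = squash_cap - cut
    out = series.copy()
    hit = absr > cut
    out[hit] = (
        fit[hit]
        + np.sign(r[hit]) * (cut + span * np.tanh((absr[hit] - cut) / span)) * sigma
    )
    return out


def detrend(series: np.ndarray, order: int = 1) -> np.ndarray:
    """Remove a least-squares polynomial trend of the given order.

    The residual is orthogonal to every polynomial basis column up to
    ``order``; order 0 is mean removal.
    """
    series = np.asarray(series, dtype=float)
    if order < 0:
        raise ValueError("order must be >= 0")
    squeeze = series.ndim == 1
    y = series.reshape(series.shape[0], -1)
    t = y.shape[0]
    if t <= order + 1:
        raise ValueError(f"need more than {order + 1} time points for order {order}")
    x = np.arange(t, dtype=float)
    basis = np.polynomial.polynomial.polyvander(x, order)
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    resid = y - basis @ coef
    return resid[:, 0] if squeeze else resid.reshape(series.shape)


def extract_roi_timeseries(
    vol4d: np.ndarray,
    atlas: np.ndarray,
    wanted_labels: dict[str, int] | list[tuple[str, int]],
    subject_id: str = "subject",
    tr: float = 2.0,
) -> RegionTimeSeriesSet:
    """Average voxel time courses within each atlas region.

    ``wanted_labels`` maps region name -> integer atlas label; output column
    order follows it.  A requested label absent from the atlas is an error.
    """
    vol4d = np.asarray(vol4d, dtype=float)
    atlas = np.asarray(atlas)
    if vol4d.ndim != 4:
        raise ValueError("expected a 4D (x, y, z, t) array")
    if atlas.shape != vol4d.shape[:3]:
        raise ValueError(
            f"atlas grid {atlas.shape} does not match volume grid {vol4d.shape[:3]}"
        )
    items = list(wanted_labels.items()) if isinstance(wanted_labels, dict) else list(wanted_labels)
    t = vol4d.shape[3]
    data = np.empty((t, len(items)))
    names = []
    flat = vol4d.reshape(-1, t)
    atlas_flat = atlas.ravel()
    for j, (name, lab) in enumerate(items):
        mask = atlas_flat == lab
        if not mask.any():
            raise ValueError(f"atlas label {lab} (region {name!r}) not present in atlas")
        sub = flat[mask]
        # anchored mean: exact when all voxels share one series (zero noise)
        data[:, j] = sub[0] + (sub - sub[0]).mean(axis=0)
        names.append(name)
    return RegionTimeSeriesSet(
        subject_id, names, data, tr, provenance=["roi_extraction"]
    )


def nuisance_regress(
    ts: RegionTimeSeriesSet, nuis: NuisanceSet
) -> RegionTimeSeriesSet:
    """Replace each regional series by its OLS residual against the nuisance set.

    The design is an intercept plus the named regressors; residuals are
    orthogonal to every design column.  A rank-deficient design (collinear
    regressors) is rejected with the offending columns named.
    """
    if nuis.n_timepoints != ts.n_timepoints:
        raise ValueError(
            f"nuisance length {nuis.n_timepoints} != series length {ts.n_timepoints}"
        )
    design = nuis.design_matrix()
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        names = ["intercept", *nuis.regressors]
        # Identify columns whose removal restores full rank.
        collinear = [
            names[i]
            for i in range(design.shape[1])
            if np.linalg.matrix_rank(np.delete(design, i, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {collinear}")
    if ts.n_timepoints <= design.shape[1] + 1:
        raise ValueError("too few time points for the nuisance design")
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    resid = ts.data - design @ beta
    return replace(
        ts, data=resid, provenance=[*ts.provenance, "nuisance_regression"]
    )


def clean_volume_to_timeseries(
    vol4d: np.ndarray,
    atlas: np.ndarray,
    wanted_labels,
    subject_id: str = "subject",
    tr: float = 2.0,
    drop_n: int = 5,
    do_despike: bool = True,
    detrend_order: int = 1,
    nuisance: NuisanceSet | None = None,
) -> RegionTimeSeriesSet:
    """Full per-subject chain: drop -> despike -> detrend -> ROI mean -> nuisance.

    Despiking and detrending are applied voxelwise before ROI averaging so the
    regional means inherit the cleaned voxel signals.  Set ``drop_n=0``,
    ``do_despike=False`` or ``detrend_order=None`` to skip steps.
    """
    prov = []
    vol = np.asarray(vol4d, dtype=float)
    if drop_n:
        vol = drop_initial_volumes(vol, drop_n)
        prov.append(f"drop_initial_volumes(n={drop_n})")
    if do_despike:
        shape = vol.shape
        flat = vol.reshape(-1, shape[3])
        flat = np.stack([despike(v) for v in flat])
        vol = flat.reshape(shape)
        prov.append("despike")
    if detrend_order is not None:
        flat = vol.reshape(-1, vol.shape[3]).T
        flat = detrend(flat, detrend_order)
        vol = flat.T.reshape(vol.shape)
        prov.append(f"detrend(order={detrend_order})")
    ts = extract_roi_timeseries(vol, atlas, wanted_labels, subject_id, tr)
    ts.provenance = [*prov, *ts.provenance]
    if nuisance is not None:
        ts = nuisance_regress(ts, nuisance)
    return ts
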