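"""Synthetic cohorts with the covariance structure the analysis assumes.

The generator draws zero-mean Gaussian parcel time series with a block
correlation structure: region pairs inside the same network share a target
correlation ``r_within``, pairs in different networks share ``r_between``.
Patients (FBSS group) additionally have every striatum-involving coupling
reduced, by an amount tied linearly to their sampled pain score, so that
running the full pipeline on a generated cohort reproduces a negative
index-on-pain slope — the effect enters through the covariance, never by
relabeling outputs.

A companion volume generator paints parcel series into a low-resolution 4D
grid (voxel series = parcel series + white noise) with an integer-label
atlas, providing end-to-end inputs for the extraction and seed-connectivity
stages.

Also packaged here: the two study population tables (10 patients with pain
scores and striatum indices, one index missing due to imaging artifacts;
13 healthy controls with indices), loadable as SubjectRecords.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .extraction import RegionTimeSeriesSet
from .inference import SubjectRecord, records_from_frame
from .networks import NETWORK_NAMES, NetworkDefinition, load_network_table

#: Default pain-score grid (visual-analog scale), matching the patient range.
PAIN_GRID = np.arange(4.0, 9.01, 0.5)


class CovarianceError(ValueError):
    """Raised when a target covariance cannot be repaired to PSD."""


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    Defaults mirror the study conditions: 12 controls vs 10 patients, 175
    retained volumes at TR 2 s, within-network correlation 0.5, baseline
    cross-network correlation 0.27 (the control-group index level), and a
    patient index-on-pain relation with slope ``beta1`` = -0.0311 and mean
    group reduction ``delta_stm`` = 0.17 — the values the packaged patient
    table implies.  ``beta0`` defaults to
    ``r_between - delta_stm - beta1 * mean(pain grid)`` so that ``delta_stm``
    is exactly the mean reduction; pass it explicitly to override.
    Setting ``delta_stm = 0`` disables the patient modification entirely
    (the two groups are then drawn from the same distribution).
    """

    n_control: int = 12
    n_patient: int = 10
    n_regions_per_network: dict[str, int] | None = None
    T: int = 175
    TR: float = 2.0
    r_within: float = 0.5
    r_between: float = 0.27
    delta_stm: float = 0.17
    beta0: float | None = None
    beta1: float = -0.0311
    sigma_eps: float = 0.02
    pain_grid: np.ndarray = field(default_factory=lambda: PAIN_GRID.copy())
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.r_between <= self.r_within < 1:
            raise ValueError("need 0 <= r_between <= r_within < 1")
        if self.delta_stm < 0:
            raise ValueError("delta_stm must be >= 0")
        if self.T < 8:
            raise ValueError("T must be at least 8")
        if self.n_control < 1 or self.n_patient < 1:
            raise ValueError("both groups need at least one subject")
        if self.beta0 is None:
            self.beta0 = float(
                self.r_between
                - self.delta_stm
                - self.beta1 * float(np.mean(self.pain_grid))
            )

    def network_definition(self) -> NetworkDefinition:
        """Networks used by this cohort (packaged table unless overridden)."""
        if self.n_regions_per_network is None:
            return load_network_table()
        members = {
            net: [f"{net}_r{i + 1:02d}" for i in range(self.n_regions_per_network[net])]
            for net in NETWORK_NAMES
        }
        return NetworkDefinition(members)


def build_block_correlation(
    nets: NetworkDefinition,
    r_within: float,
    r_between: float,
    stm_cross: float | None = None,
    stm_within: float | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Block correlation matrix over all regions, in network order.

    ``stm_cross`` / ``stm_within`` override the couplings of striatum-to-other
    and within-striatum pairs (the patient modification); ``None`` keeps the
    baseline values.
    """
    labels = nets.all_regions
    net_of = np.array([nets.network_of(r) for r in labels])
    n = len(labels)
    r = np.full((n, n), r_between)
    for net in NETWORK_NAMES:
        mask = net_of == net
        r[np.ix_(mask, mask)] = r_within
    if stm_cross is not None:
        stm = net_of == "STM"
        r[np.ix_(stm, ~stm)] = stm_cross
        r[np.ix_(~stm, stm)] = stm_cross
    if stm_within is not None:
        stm = net_of == "STM"
        r[np.ix_(stm, stm)] = stm_within
    np.fill_diagonal(r, 1.0)
    return r, labels


def repair_psd(
    corr: np.ndarray,
    shrink: float = 0.95,
    max_steps: int = 200,
    tol: float = -1e-10,
) -> np.ndarray:
    """Shrink off-diagonal couplings uniformly toward 0 until PSD.

    Uniform shrinkage preserves the relative coupling structure.  Failure
    after ``max_steps`` (practically impossible, since the identity limit is
    PSD) names the most negative eigenvalue's dominant couplings.
    """
    c = corr.copy()
    for _ in range(max_steps):
        w = np.linalg.eigvalsh(c)
        if w[0] >= tol:
            return c
        off = ~np.eye(c.shape[0], dtype=bool)
        c[off] *= shrink
    w, v = np.linalg.eigh(c)
    worst = np.argsort(-np.abs(v[:, 0]))[:4]
    raise CovarianceError(
        f"covariance not PSD after {max_steps} shrinkage steps "
        f"(min eigenvalue {w[0]:.3g}); dominant offending regions: {list(worst)}"
    )


def _sample_mvn(rng: np.random.Generator, corr: np.ndarray, t: int) -> np.ndarray:
    """T x R draw from N(0, corr) via eigendecomposition (PSD-tolerant)."""
    w, v = np.linalg.eigh(corr)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((t, corr.shape[0]))
    return z @ root.T


def generate_parcel_cohort(
    spec: CohortSpec,
) -> tuple[list[RegionTimeSeriesSet], list[SubjectRecord]]:
    """Draw a full two-group cohort of parcel time series.

    Controls are drawn at the baseline couplings.  Each patient's pain score
    PL is sampled uniformly from the grid, a target index
    ``beta0 + beta1 * PL + N(0, sigma_eps)`` is formed, and that subject's
    striatum-to-other couplings are set to the target (within-striatum
    couplings are lowered by the same absolute amount).  All randomness flows
    from ``spec.seed`` through per-subject substreams, so outputs are
    bit-identical across calls.
    """
    nets = spec.network_definition()
    root = np.random.SeedSequence(spec.seed)
    n_total = spec.n_control + spec.n_patient
    streams = [np.random.default_rng(s) for s in root.spawn(n_total + 1)]
    master = streams[0]

    ts_sets: list[RegionTimeSeriesSet] = []
    records: list[SubjectRecord] = []
    base_corr, labels = build_block_correlation(nets, spec.r_within, spec.r_between)
    base_corr = repair_psd(base_corr)

    for i in range(spec.n_control):
        rng = streams[1 + i]
        data = _sample_mvn(rng, base_corr, spec.T)
        sid = f"CN_{i + 1:02d}"
        ts_sets.append(
            RegionTimeSeriesSet(sid, labels, data, spec.TR, ["synthetic"])
        )
        records.append(SubjectRecord(sid, "CN"))

    for i in range(spec.n_patient):
        rng = streams[1 + spec.n_control + i]
        pain = float(master.choice(spec.pain_grid))
        sid = f"FBSS_{i + 1:02d}"
        if spec.delta_stm == 0:
            corr = base_corr
        else:
            target = spec.beta0 + spec.beta1 * pain + master.normal(0, spec.sigma_eps)
            target = float(np.clip(target, 0.0, spec.r_within - 1e-3))
            reduction = spec.r_between - target
            stm_within = float(
                np.clip(spec.r_within - reduction, target, spec.r_within)
            )
            corr, _ = build_block_correlation(
                nets,
                spec.r_within,
                spec.r_between,
                stm_cross=target,
                stm_within=stm_within,
            )
            corr = repair_psd(corr)
        data = _sample_mvn(rng, corr, spec.T)
        ts_sets.append(
            RegionTimeSeriesSet(sid, labels, data, spec.TR, ["synthetic"])
        )
        records.append(SubjectRecord(sid, "FBSS", vas_pain=pain))
    return ts_sets, records


@dataclass
class SyntheticVolumeSpec:
    """Layout of the low-resolution synthetic 4D volumes.

    Regions occupy contiguous blocks of ``voxels_per_region`` voxels in a
    ``shape`` grid with isotropic ``voxel_size_mm`` voxels; the affine
    centres the grid on the origin so standard-space-style mm coordinates
    (e.g. the midbrain seed at (1, -29, -12)) resolve inside it.  Voxel
    series are the parent parcel series plus white noise of SD ``noise_sd``.
    ``effect_coupling > 0`` blends the seed region's series into the listed
    ``effect_targets`` for patient subjects only, planting a known group
    difference in seed connectivity.
    """

    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    voxels_per_region: int = 8
    noise_sd: float = 0.5
    seed_center_mm: tuple[float, float, float] = (1.0, -29.0, -12.0)
    seed_region: str | None = None
    effect_targets: tuple[str, ...] = ()
    effect_coupling: float = 0.0

    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = -np.array(self.shape) / 2.0 * self.voxel_size_mm
        return aff

    def capacity(self) -> int:
        return int(np.prod(self.shape))


@dataclass
class VolumeCohort:
    """In-memory synthetic volume cohort: per-subject 4D arrays + shared atlas."""

    volumes: dict[str, np.ndarray]
    atlas: np.ndarray
    affine: np.ndarray
    label_map: dict[str, int]
    records: list[SubjectRecord]
    parcel_series: dict[str, RegionTimeSeriesSet]
    tr: float


def generate_volume_cohort(
    vspec: SyntheticVolumeSpec, cohort: CohortSpec
) -> VolumeCohort:
    """Paint a parcel cohort into 4D volumes with an integer-label atlas.

    Every region receives a contiguous block of voxels (label = position in
    the network-ordered region list, starting at 1; 0 is background).  Voxel
    time series are the region's parcel series plus i.i.d. Gaussian noise.
    """
    ts_sets, records = generate_parcel_cohort(cohort)
    nets = cohort.network_definition()
    labels = nets.all_regions
    need = len(labels) * vspec.voxels_per_region
    if need > vspec.capacity():
        raise ValueError(
            f"{len(labels)} regions x {vspec.voxels_per_region} voxels "
            f"exceed grid capacity {vspec.capacity()}"
        )
    atlas = np.zeros(vspec.shape, dtype=np.int16)
    flat = atlas.ravel()
    for k in range(len(labels)):
        start = k * vspec.voxels_per_region
        flat[start : start + vspec.voxels_per_region] = k + 1
    label_map = {name: k + 1 for k, name in enumerate(labels)}

    seed_name = vspec.seed_region
    rng = np.random.default_rng(np.random.SeedSequence((cohort.seed, 915001)))
    volumes: dict[str, np.ndarray] = {}
    parcel: dict[str, RegionTimeSeriesSet] = {}
    group_of = {r.subject_id: r.group for r in records}
    for ts in ts_sets:
        data = ts.data.copy()
        if (
            seed_name is not None
            and vspec.effect_coupling > 0
            and group_of[ts.subject_id] == "FBSS"
        ):
            g = vspec.effect_coupling
            s = data[:, labels.index(seed_name)]
            for tgt in vspec.effect_targets:
                j = labels.index(tgt)
                data[:, j] = np.sqrt(max(0.0, 1 - g * g)) * data[:, j] + g * s
        vol = np.zeros((*vspec.shape, ts.n_timepoints))
        vol_flat = vol.reshape(-1, ts.n_timepoints)
        for name, lab in label_map.items():
            mask = flat == lab
            series = data[:, labels.index(name)]
            noise = (
                rng.standard_normal((mask.sum(), ts.n_timepoints)) * vspec.noise_sd
                if vspec.noise_sd > 0
                else 0.0
            )
            vol_flat[mask] = series + noise
        volumes[ts.subject_id] = vol
        parcel[ts.subject_id] = RegionTimeSeriesSet(
            ts.subject_id, labels, data, ts.tr, ["synthetic"]
        )
    return VolumeCohort(
        volumes, atlas, vspec.affine(), label_map, records, parcel, cohort.TR
    )


def write_volume_cohort(vc: VolumeCohort, out_dir) -> None:
    """Persist a volume cohort as NIfTI volumes + atlas + metadata TSV."""
    import pathlib

    import nibabel as nib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(vc.atlas, vc.affine), out / "atlas.nii.gz")
    for sid, vol in vc.volumes.items():
        img = nib.Nifti1Image(vol.astype(np.float32), vc.affine)
        img.header.set_zooms((*np.diag(vc.affine)[:3], vc.tr))
        nib.save(img, out / f"{sid}_bold.nii.gz")
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "vas_pain": r.vas_pain if r.vas_pain is not None else "NA",
            }
            for r in vc.records
        ]
    ).to_csv(out / "subjects.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(vc.label_map.items(), key=lambda kv: kv[1]),
        columns=["region", "label"],
    ).to_csv(out / "atlas_labels.tsv", sep="\t", index=False)


def load_paper_fixtures() -> list[SubjectRecord]:
    """Load the packaged study population tables as SubjectRecords.

    Returns the 10 patient records (pain score + striatum index; patient 7's
    index is missing — unavailable due to imaging artifacts) followed by the
    13 control records.  The study text counts 12 controls but its control
    table lists 13 rows; all 13 are kept and the discrepancy is documented
    rather than silently resolved.
    """
    recs: list[SubjectRecord] = []
    for fname in ("fbss_subjects.tsv", "control_subjects.tsv"):
        ref = importlib.resources.files("crossnet.data") / fname
        with importlib.resources.as_file(ref) as path:
            df = pd.read_csv(path, sep="\t", na_values=["NA"])
        recs.extend(records_from_frame(df))
    return recs
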