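"""End-to-end pipeline driver: volumes in, statistical reports out.

``run_pipeline`` chains extraction -> connectivity -> group inference (and
optionally seed-based connectivity) over a directory of per-subject NIfTI
volumes, writing per-subject TSVs, JSON reports and a provenance manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .extraction import NuisanceSet, clean_volume_to_timeseries
from .model import CrossNetworkModel
from .networks import load_network_table
from .seedfc import (
    apply_cluster_threshold,
    estimate_smoothness,
    make_sphere_roi,
    mc_cluster_threshold,
    seed_fc_map,
    two_sample_tmap,
)


@dataclass
class PipelineConfig:
    """Paths and options for one pipeline run."""

    bold_dir: str
    atlas_path: str
    labels_path: str  # TSV: region, label
    metadata_path: str  # TSV: subject_id, group, vas_pain
    out_dir: str
    networks_path: str | None = None  # packaged table when None
    nuisance_dir: str | None = None
    drop_n: int = 5
    do_despike: bool = True
    detrend_order: int = 1
    global_signal_regression: bool = True
    alpha: float = 0.05
    run_seed_fc: bool = False
    seed_center_mm: tuple[float, float, float] = (1.0, -29.0, -12.0)
    seed_diameter_mm: float = 4.0
    seed_voxel_p: float = 0.05
    seed_alpha: float = 0.01
    seed_iters: int = 1000
    seed_connectivity: str = "faces"
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("bold_dir", "atlas_path", "labels_path", "metadata_path"):
            p = getattr(self, name)
            if not pathlib.Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")
        if self.networks_path and not pathlib.Path(self.networks_path).exists():
            raise FileNotFoundError(f"networks_path does not exist: {self.networks_path}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the manifest dictionary."""
    import nibabel as nib

    config.validate()
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nets = load_network_table(config.networks_path)

    atlas_img = nib.load(config.atlas_path)
    atlas = np.asarray(atlas_img.dataobj)
    labels_df = pd.read_csv(config.labels_path, sep="\t")
    wanted = {
        row.region: int(row.label)
        for row in labels_df.itertuples(index=False)
        if row.region in set(nets.all_regions)
    }
    missing = [r for r in nets.all_regions if r not in wanted]
    if missing:
        raise ValueError(f"regions absent from the atlas label table: {missing}")

    meta = pd.read_csv(config.metadata_path, sep="\t", na_values=["NA"])
    bold_dir = pathlib.Path(config.bold_dir)
    ts_sets = []
    stage = "extraction"
    for row in meta.itertuples(index=False):
        sid = str(row.subject_id)
        path = bold_dir / f"{sid}_bold.nii.gz"
        if not path.exists():
            path = bold_dir / f"{sid}_bold.nii"
        if not path.exists():
            raise FileNotFoundError(f"[{stage}] no BOLD volume for subject {sid}")
        try:
            img = nib.load(path)
            vol = np.asarray(img.dataobj, dtype=float)
            tr = float(img.header.get_zooms()[3]) if img.header.get_zooms()[3] else 2.0
            nuis = _build_nuisance(config, sid, vol, config.drop_n)
            ts = clean_volume_to_timeseries(
                vol,
                atlas,
                wanted,
                subject_id=sid,
                tr=tr,
                drop_n=config.drop_n,
                do_despike=config.do_despike,
                detrend_order=config.detrend_order,
                nuisance=nuis,
            )
        except Exception as exc:  # annotate failures with stage + subject
            raise RuntimeError(f"[{stage}] subject {sid}: {exc}") from exc
        ts.to_tsv(out / f"{sid}_timeseries.tsv")
        ts_sets.append(ts)

    stage = "group_inference"
    results = CrossNetworkModel(ts_sets, meta, nets).fit(alpha=config.alpha)
    results.comparisons_frame().to_json(out / "group_comparisons.json", orient="records", indent=2)
    results.indices.to_csv(out / "stm_indices.tsv", sep="\t", index=False)
    reg_payload = None
    if results.regression is not None:
        rr = results.regression.as_regression_result()
        reg_payload = dataclasses.asdict(rr)
        reg_payload["excluded"] = list(rr.excluded)
        (out / "regression.json").write_text(json.dumps(reg_payload, indent=2))

    seed_payload = None
    if config.run_seed_fc:
        stage = "seed_fc"
        seed_payload = _run_seed_fc(config, meta, bold_dir, atlas_img, out)

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "rng_seed": config.rng_seed,
        "n_subjects": len(ts_sets),
        "stages": ["extraction", "connectivity", "group_inference"]
        + (["seed_fc"] if config.run_seed_fc else []),
        "input_hashes": {
            "atlas": _file_hash(config.atlas_path),
            "metadata": _file_hash(config.metadata_path),
        },
        "regression": reg_payload,
        "group_summary": results.group_summary(),
        "significant_comparisons": [c.label for c in results.significant_comparisons()],
        "seed_fc": seed_payload,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest


def _file_hash(path) -> str:
    return hashlib.sha256(pathlib.Path(path).read_bytes()).hexdigest()[:16]


def _build_nuisance(config, sid, vol, drop_n) -> NuisanceSet | None:
    """Assemble nuisance regressors: optional TSV extras + global mean."""
    cols: dict[str, np.ndarray] = {}
    t_kept = vol.shape[3] - drop_n
    if config.nuisance_dir:
        path = pathlib.Path(config.nuisance_dir) / f"{sid}_nuisance.tsv"
        if path.exists():
            df = pd.read_csv(path, sep="\t")
            for c in df.columns:
                col = df[c].to_numpy(float)
                cols[c] = col[-t_kept:] if len(col) > t_kept else col
    if config.global_signal_regression:
        gs = vol[..., drop_n:].mean(axis=(0, 1, 2))
        cols["global_mean"] = gs
    return NuisanceSet(cols) if cols else None


def _run_seed_fc(config, meta, bold_dir, atlas_img, out: pathlib.Path):
    import nibabel as nib

    affine = atlas_img.affine
    shape = atlas_img.shape
    mask = np.ones(shape, dtype=bool)
    roi = make_sphere_roi(config.seed_center_mm, config.seed_diameter_mm, affine, shape)
    zmaps = {"CN": [], "FBSS": []}
    for row in meta.itertuples(index=False):
        sid = str(row.subject_id)
        path = bold_dir / f"{sid}_bold.nii.gz"
        if not path.exists():
            path = bold_dir / f"{sid}_bold.nii"
        vol = np.asarray(nib.load(path).dataobj, dtype=float)[..., config.drop_n :]
        zm = seed_fc_map(vol, roi, mask, sid)
        nib.save(nib.Nifti1Image(zm.data.astype(np.float32), affine), out / f"{sid}_zmap.nii.gz")
        zmaps[str(row.group)].append(zm)
    tvol, pvol, valid = two_sample_tmap(zmaps["CN"], zmaps["FBSS"])
    nib.save(nib.Nifti1Image(tvol.astype(np.float32), affine), out / "group_tmap.nii.gz")
    resid = [m.data - np.mean([m.data for m in zmaps["CN"] + zmaps["FBSS"]], axis=0)
             for m in zmaps["CN"] + zmaps["FBSS"]]
    voxel_size = float(np.abs(np.diag(affine)[:3]).mean())
    fwhm = estimate_smoothness(resid, voxel_size)
    thr = mc_cluster_threshold(
        shape,
        mask,
        fwhm,
        voxel_size,
        voxel_p=config.seed_voxel_p,
        alpha=config.seed_alpha,
        n_iter=config.seed_iters,
        connectivity=config.seed_connectivity,
        seed=config.rng_seed,
    )
    clusters = apply_cluster_threshold(tvol, pvol, thr, affine, valid)
    pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "n_voxels": c.n_voxels,
                "mm3": c.extent_mm3,
                "peak_x": c.peak_mm[0],
                "peak_y": c.peak_mm[1],
                "peak_z": c.peak_mm[2],
                "peak_t": c.peak_t,
                "mean_t": c.mean_t,
                "sign": c.sign,
            }
            for c in clusters
        ]
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    payload = dataclasses.asdict(thr) | {"n_clusters": len(clusters)}
    (out / "seed_threshold.json").write_text(json.dumps(payload, indent=2))
    return payload
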