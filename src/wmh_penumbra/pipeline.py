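"""End-to-end orchestration: simulate -> fit-mwi -> fit-dti -> rois -> stats.

Stages communicate through an on-disk output tree so each can be run (or
re-run) independently::

    <out>/
      config.json            # snapshot of the resolved run configuration
      cohort/<sub>/...       # label/echo/DWI NIfTI volumes + gradient tables
      maps/<sub>/...         # fitted MWF/GMT2/flip and FA/MD maps
      rois/<sub>_rois.nii.gz # ROI code volumes (10 = WMH, 11-15 = rings)
      roi_table.tsv          # long-format subject x level x metric table
      stats_<model>.tsv      # per-model fixed-effect tables
      contrasts_<...>.tsv    # Tukey-adjusted post hoc contrasts
      manifest.json          # artifact checksums for reproducibility checks

A stage is skipped on resume when its outputs already exist in the
manifest; passing ``force=True`` (or deleting outputs) re-runs it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import phantom, rois, stats
from .diffusion import fit_dti_volume
from .relaxometry import T2Grid, fit_volume, CHI2_WINDOW_DEFAULT
from .sequences import SCANNER_A_32ECHO, SCANNER_B_48ECHO, read_bvals_bvecs

__all__ = ["RunConfig", "run_all", "load_config"]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_KNOWN_KEYS = {
    "seed", "n_older", "n_stroke", "shape", "voxel_size_mm", "echo_snr",
    "dwi_snr", "n_pv_wmh", "n_deep_wmh", "ring_edges_mm", "csf_guard_mm",
    "stroke_guard_mm", "chi2_window", "t2_grid_bins", "t2_min_ms", "t2_max_ms",
    "angle_step_deg", "models", "deep_only", "hemisphere_split", "out_dir",
    "fit_region_only",
}


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run (single source of truth)."""

    seed: int = 0
    n_older: int = 20
    n_stroke: int = 14
    shape: tuple = (36, 36, 36)
    voxel_size_mm: tuple = (1.75, 1.75, 1.75)
    echo_snr: float = 200.0
    dwi_snr: float = 40.0
    n_pv_wmh: int = 1
    n_deep_wmh: int = 1
    ring_edges_mm: tuple = rois.RING_EDGES_MM
    csf_guard_mm: float = rois.CSF_GUARD_MM
    stroke_guard_mm: float = rois.STROKE_GUARD_MM
    chi2_window: tuple = CHI2_WINDOW_DEFAULT
    t2_grid_bins: int = 40
    t2_min_ms: float = 10.0
    t2_max_ms: float = 2000.0
    angle_step_deg: float = 2.0
    models: tuple = ("distance_group", "wmh_volume")
    deep_only: bool = False
    hemisphere_split: bool = False
    fit_region_only: bool = True
    out_dir: str = "penumbra_run"

    def cohort_config(self) -> phantom.CohortConfig:
        return phantom.CohortConfig(
            shape=tuple(self.shape),
            voxel_size_mm=tuple(self.voxel_size_mm),
            echo_snr=self.echo_snr,
            dwi_snr=self.dwi_snr,
            n_pv_wmh=self.n_pv_wmh,
            n_deep_wmh=self.n_deep_wmh,
        )

    def t2_grid(self) -> T2Grid:
        return T2Grid.default(self.t2_grid_bins, self.t2_min_ms, self.t2_max_ms)


def load_config(path: str | Path) -> RunConfig:
    """Load a config from JSON/TOML-style key-value file; unknown keys are
    rejected (fail-closed)."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        raw = tomllib.loads(path.read_text())
    else:
        raw = json.loads(path.read_text())
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    for name, value in (("ring increments", cfg.ring_edges_mm),):
        if tuple(value) != rois.RING_EDGES_MM:
            raise ValueError(f"unsupported {name}: {value}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, root: Path):
        self.root = root
        self.path = root / "manifest.json"
        self.entries: dict[str, str] = {}
        if self.path.exists():
            self.entries = json.loads(self.path.read_text())

    def has(self, *rel: str) -> bool:
        return all(r in self.entries and (self.root / r).exists() for r in rel)

    def add(self, rel: str) -> None:
        self.entries[rel] = _sha256(self.root / rel)

    def save(self) -> None:
        self.path.write_text(json.dumps(self.entries, indent=1, sort_keys=True))


def _save_map(arr: np.ndarray, voxel_size, path: Path) -> None:
    import nibabel as nib

    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), path)


def _load_nii(path: Path) -> tuple[np.ndarray, tuple]:
    import nibabel as nib

    img = nib.load(path)
    return np.asarray(img.dataobj), tuple(float(z) for z in img.header.get_zooms()[:3])


def stage_simulate(cfg: RunConfig, root: Path, manifest: _Manifest, force=False) -> pd.DataFrame:
    table_rel = "cohort/participants.tsv"
    if manifest.has(table_rel) and not force:
        logger.info("simulate: resume (cohort exists)")
        return pd.read_csv(root / table_rel, sep="\t")
    records, data = phantom.simulate_cohort(
        cfg.n_older, cfg.n_stroke, cfg.cohort_config(), seed=cfg.seed,
        out_dir=root / "cohort",
    )
    for rec in records:
        for name in ("labels.nii.gz", "echo.nii.gz", "dwi.nii.gz", "bval", "bvec"):
            manifest.add(f"cohort/{rec.subject_id}/{name}")
    manifest.add(table_rel)
    manifest.save()
    return pd.read_csv(root / table_rel, sep="\t")


def _subject_masks(labels: np.ndarray, vs, cfg: RunConfig):
    wmh = labels == phantom.LABELS["wmh"]
    if cfg.fit_region_only and wmh.any():
        near = rois.distance_map_mm(wmh, vs) <= 10.5
        return (labels > 0) & near
    return labels > 0


def stage_fit_mwi(cfg: RunConfig, root: Path, manifest: _Manifest, table, force=False) -> None:
    grid = cfg.t2_grid()
    from .relaxometry import default_angle_grid

    angle_grid = default_angle_grid(cfg.angle_step_deg)
    for sub, scanner in zip(table["subject_id"], table["scanner"]):
        rels = [f"maps/{sub}/{m}.nii.gz" for m in ("mwf", "gmt2", "flip")]
        if manifest.has(*rels) and not force:
            continue
        labels, vs = _load_nii(root / "cohort" / sub / "labels.nii.gz")
        echo, _ = _load_nii(root / "cohort" / sub / "echo.nii.gz")
        seq = SCANNER_A_32ECHO if scanner == "A_32echo" else SCANNER_B_48ECHO
        if echo.shape[-1] != seq.n_echoes:
            raise RuntimeError(
                f"fit-mwi {sub}: echo count {echo.shape[-1]} != configured {seq.n_echoes}"
            )
        mask = _subject_masks(labels, vs, cfg) & (echo.sum(axis=-1) > 0)
        maps = fit_volume(echo, mask, seq, grid, cfg.chi2_window, angle_grid)
        (root / "maps" / sub).mkdir(parents=True, exist_ok=True)
        for name, rel in zip(("mwf", "gmt2", "flip"), rels):
            _save_map(maps[name], vs, root / rel)
            manifest.add(rel)
        sidecar_rel = f"maps/{sub}/mwi.json"
        from . import __version__
        from .relaxometry import IE_WINDOW_MS, MYELIN_WINDOW_MS

        (root / sidecar_rel).write_text(json.dumps({
            "software_version": __version__,
            "t2_grid_ms": list(grid.t2_values_ms),
            "mwf_window_ms": list(MYELIN_WINDOW_MS),
            "gmt2_window_ms": list(IE_WINDOW_MS),
            "chi2_window": list(cfg.chi2_window),
            "n_echoes": seq.n_echoes,
            "echo_spacing_ms": seq.echo_spacing_ms,
        }, indent=1))
        manifest.add(sidecar_rel)
        manifest.save()
        logger.info("fit-mwi: %s done (%d voxels)", sub, int(mask.sum()))


def stage_fit_dti(cfg: RunConfig, root: Path, manifest: _Manifest, table, force=False) -> None:
    for sub in table["subject_id"]:
        rels = [f"maps/{sub}/{m}.nii.gz" for m in ("fa", "md")]
        if manifest.has(*rels) and not force:
            continue
        labels, vs = _load_nii(root / "cohort" / sub / "labels.nii.gz")
        dwi, _ = _load_nii(root / "cohort" / sub / "dwi.nii.gz")
        scheme = read_bvals_bvecs(root / "cohort" / sub / "bval", root / "cohort" / sub / "bvec")
        mask = _subject_masks(labels, vs, cfg) & (dwi.sum(axis=-1) > 0)
        maps = fit_dti_volume(dwi, scheme, mask)
        (root / "maps" / sub).mkdir(parents=True, exist_ok=True)
        for name, rel in zip(("fa", "md"), rels):
            _save_map(getattr(maps, name), vs, root / rel)
            manifest.add(rel)
        manifest.save()
        logger.info("fit-dti: %s done", sub)


def stage_rois(cfg: RunConfig, root: Path, manifest: _Manifest, table, force=False) -> pd.DataFrame:
    table_rel = "roi_table.tsv"
    if manifest.has(table_rel) and not force:
        return pd.read_csv(root / table_rel, sep="\t")
    frames = []
    for _, rec in table.iterrows():
        sub = rec["subject_id"]
        labels, vs = _load_nii(root / "cohort" / sub / "labels.nii.gz")
        wmh = labels == phantom.LABELS["wmh"]
        if cfg.deep_only:
            cls = rois.classify_wmh(wmh, labels == phantom.LABELS["ventricular_csf"])
            wmh = cls == 2
            if not wmh.any():
                logger.warning("rois: %s has no deep WMH, skipped", sub)
                continue
        csf = (labels == phantom.LABELS["ventricular_csf"]) | (
            labels == phantom.LABELS["sulcal_csf"]
        )
        stroke = labels == phantom.LABELS["stroke"]
        ring_set = rois.make_rings(
            wmh, labels == phantom.LABELS["nawm"], csf,
            stroke if stroke.any() else None, vs,
        )
        metric_maps = {}
        for metric, fname in (("FA", "fa"), ("MD", "md"), ("MWF", "mwf"), ("GMT2", "gmt2")):
            metric_maps[metric], _ = _load_nii(root / "maps" / sub / f"{fname}.nii.gz")
        rois_rel = f"rois/{sub}_rois.nii.gz"
        (root / "rois").mkdir(exist_ok=True)
        _save_map(ring_set.to_code_volume(), vs, root / rois_rel)
        manifest.add(rois_rel)
        subject_info = rec.to_dict()
        # measured lesion volume for reference; the covariate stays the
        # whole-brain volume from the cohort table
        subject_info["lesion_volume_ml"] = rois.wmh_volume_ml(wmh, vs)
        frames.append(rois.extract_roi_means(ring_set, metric_maps, subject_info))
        if cfg.hemisphere_split and rec["hemisphere_of_stroke"] in ("left", "right"):
            # extra hemisphere-tagged rows; the whole-lesion rows above stay
            # the input of the group and volume models
            mid = labels.shape[0] // 2
            ipsi, contra = rois.split_by_hemisphere(
                ring_set, mid, rec["hemisphere_of_stroke"]
            )
            for hemi_name, rs in (("ipsilesional", ipsi), ("contralesional", contra)):
                df = rois.extract_roi_means(rs, metric_maps, subject_info)
                df["hemisphere"] = hemi_name
                frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(root / table_rel, sep="\t", index=False)
    manifest.add(table_rel)
    manifest.save()
    return out


def stage_stats(cfg: RunConfig, root: Path, manifest: _Manifest, roi_table, force=False) -> dict:
    results = {}
    metrics = ("FA", "MD", "MWF", "GMT2")
    fitters = {
        "distance_group": stats.fit_distance_group,
        "distance_hemisphere": stats.fit_distance_hemisphere,
        "wmh_volume": stats.fit_wmh_volume_model,
    }
    has_hemi = "hemisphere" in roi_table.columns
    whole = roi_table[roi_table["hemisphere"].isna()] if has_hemi else roi_table
    for model_name in cfg.models:
        fitter = fitters[model_name]
        if model_name == "distance_hemisphere":
            if not has_hemi:
                raise RuntimeError("hemisphere model requested without --hemisphere-split")
            table = roi_table[
                roi_table["hemisphere"].notna()
                & roi_table["hemisphere_of_stroke"].isin(["left", "right"])
            ]
        else:
            table = whole
        frames = []
        contrast_rows = []
        for metric in metrics:
            fit = fitter(table, metric)
            results[(model_name, metric)] = fit
            frame = fit.to_frame()
            frame.insert(0, "metric", metric)
            frame["converged"] = fit.converged
            frames.append(frame.reset_index())
            if model_name in ("distance_group", "distance_hemisphere") and fit.converged:
                factor = "group_oa" if model_name == "distance_group" else "hemi_contra"
                labels = (
                    ("stroke", "older_adult")
                    if model_name == "distance_group"
                    else ("ipsilesional", "contralesional")
                )
                for family in ("distance", "interaction"):
                    for c in stats.tukey_posthoc(fit, family, factor, labels):
                        contrast_rows.append(
                            {"metric": metric, "family": family, "contrast": c.label,
                             "estimate": c.estimate, "se": c.se,
                             "p_adjusted": c.p_adjusted}
                        )
        rel = f"stats_{model_name}.tsv"
        pd.concat(frames, ignore_index=True).to_csv(root / rel, sep="\t", index=False)
        manifest.add(rel)
        if contrast_rows:
            crel = f"contrasts_{model_name}.tsv"
            pd.DataFrame(contrast_rows).to_csv(root / crel, sep="\t", index=False)
            manifest.add(crel)
    manifest.save()
    return results


def run_all(cfg: RunConfig, force: bool = False) -> dict:
    """Run every stage; returns the stats-model results keyed by
    (model, metric).  Idempotent for a fixed config and seed."""
    root = Path(cfg.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    (root / "config.json").write_text(
        json.dumps(
            {"schema_version": SCHEMA_VERSION, **dataclasses.asdict(cfg)},
            indent=1, default=list,
        )
    )
    manifest = _Manifest(root)
    try:
        table = stage_simulate(cfg, root, manifest, force)
        stage_fit_mwi(cfg, root, manifest, table, force)
        stage_fit_dti(cfg, root, manifest, table, force)
        roi_table = stage_rois(cfg, root, manifest, table, force)
        return stage_stats(cfg, root, manifest, roi_table, force)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc
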