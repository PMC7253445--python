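"""File-format round-tripping: NIfTI volumes/masks, BIDS-style TSVs, JSON/YAML.

Voxel indices are 0-based everywhere inside the package; world (mm)
coordinates appear only at the NIfTI boundary through the image affine.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .clusters import Cluster, ClusterSet
from .connectivity import BoldTimeseries, ConfoundSet, RoiMask, TaskDesign

MOTION_COLS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def default_affine(voxel_mm: float = 2.0) -> np.ndarray:
    aff = np.diag([voxel_mm] * 3 + [1.0])
    return aff


# -- NIfTI ------------------------------------------------------------------

def save_nifti(data: np.ndarray, path, voxel_mm: float = 2.0,
               affine: np.ndarray | None = None) -> None:
    affine = default_affine(voxel_mm) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def save_bold(ts: BoldTimeseries, path, voxel_mm: float = 2.0) -> None:
    save_nifti(ts.data, path, voxel_mm)


def load_bold(path, tr_s: float, run_slices, condition: str = "",
              participant_id: str = "") -> BoldTimeseries:
    data, _ = load_nifti(path)
    return BoldTimeseries(data=data, tr_s=tr_s,
                          run_slices=[tuple(r) for r in run_slices],
                          condition=condition, participant_id=participant_id)


def save_mask(roi: RoiMask, path, voxel_mm: float = 2.0) -> None:
    save_nifti(roi.mask.astype(np.float64), path, voxel_mm)


def load_mask(path, label: str = "custom") -> RoiMask:
    data, _ = load_nifti(path)
    return RoiMask(mask=data > 0.5, label=label)


# -- TSV tables -------------------------------------------------------------

def save_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def load_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def save_confounds(conf: ConfoundSet, path) -> None:
    cols = {c: conf.motion6[:, i] for i, c in enumerate(MOTION_COLS)}
    cols.update(wm=conf.wm, csf=conf.csf, global_signal=conf.global_signal)
    for k in range(conf.outlier_indicators.shape[1]):
        cols[f"outlier_{k}"] = conf.outlier_indicators[:, k]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def load_confounds(path, run_slices) -> ConfoundSet:
    df = pd.read_csv(path, sep="\t")
    out_cols = [c for c in df.columns if c.startswith("outlier_")]
    return ConfoundSet(
        motion6=df[MOTION_COLS].to_numpy(),
        wm=df["wm"].to_numpy(), csf=df["csf"].to_numpy(),
        global_signal=df["global_signal"].to_numpy(),
        outlier_indicators=(df[out_cols].to_numpy() if out_cols
                            else np.zeros((len(df), 0))),
        run_slices=[tuple(r) for r in run_slices])


def save_events(task: TaskDesign, path) -> None:
    pd.DataFrame(task.events, columns=["onset", "duration", "run"]).to_csv(
        path, sep="\t", index=False)


def load_events(path, image_duration_s: float = 5.0, isi_s: float = 1.0,
                run_duration_s: float = 66.0) -> TaskDesign:
    df = pd.read_csv(path, sep="\t")
    events = [(float(r.onset), float(r.duration), int(r.run))
              for r in df.itertuples()]
    return TaskDesign(events=events, image_duration_s=image_duration_s,
                      isi_s=isi_s, run_duration_s=run_duration_s)


# -- ClusterSet -------------------------------------------------------------

def save_cluster_set(cs: ClusterSet, label_path, sidecar_path,
                     voxel_mm: float = 2.0) -> None:
    save_nifti(cs.label_image().astype(np.float64), label_path, voxel_mm)
    meta = {"seed_label": cs.seed_label, "adjacency": cs.adjacency,
            "grid_dims": list(cs.grid_dims),
            "clusters": [{"id": c.id, "sign": c.sign, "size": c.size,
                          "peak": list(map(int, c.peak))} for c in cs]}
    Path(sidecar_path).write_text(json.dumps(meta, indent=2))


def load_cluster_set(label_path, sidecar_path) -> ClusterSet:
    labels, _ = load_nifti(label_path)
    labels = labels.astype(int)
    meta = json.loads(Path(sidecar_path).read_text())
    clusters = []
    for rec in meta["clusters"]:
        voxels = np.argwhere(labels == rec["id"])
        clusters.append(Cluster(id=rec["id"], voxels=voxels, sign=rec["sign"],
                                peak=tuple(rec["peak"])))
    return ClusterSet(clusters=clusters, seed_label=meta["seed_label"],
                      adjacency=meta["adjacency"],
                      grid_dims=tuple(meta["grid_dims"]))


# -- results / configs ------------------------------------------------------

def save_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def save_yaml(obj: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))
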