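"""File I/O: NIfTI volumes with JSON schedule sidecars, GIFTI surfaces and
per-depth data arrays, TSV motion/profile/map tables, and JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel import gifti

from .contrast import VolumeSeries
from .lamsurf import LaminarMesh, SurfaceMesh
from .preprocess import MotionTrace

__all__ = [
    "save_volume_series",
    "load_volume_series",
    "save_volume",
    "load_volume",
    "save_motion_tsv",
    "load_motion_tsv",
    "save_laminar_mesh",
    "load_laminar_mesh",
    "save_censor_mask",
    "save_profile_tsv",
    "save_fcs_tsv",
    "save_parcellation_tsv",
    "save_json",
    "load_json",
]


def save_volume(path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_volume(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def save_volume_series(path, series: VolumeSeries) -> None:
    """Write a 4D NIfTI plus a JSON sidecar with the condition schedule."""
    path = Path(path)
    save_volume(path, series.data, series.affine)
    sidecar = {
        "volume_tr": series.volume_tr,
        "te": series.te,
        "schedule": list(series.schedule),
        "dummy": [bool(d) for d in series.dummy_flags],
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_volume_series(path) -> VolumeSeries:
    path = Path(path)
    data, affine = load_volume(path)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    return VolumeSeries(
        data=data,
        affine=affine,
        volume_tr=meta["volume_tr"],
        schedule=meta["schedule"],
        te=meta.get("te", 0.020),
        dummy_flags=np.array(meta["dummy"], dtype=bool),
    )


def save_motion_tsv(path, motion: MotionTrace) -> None:
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    pd.DataFrame(motion.params, columns=cols).to_csv(path, sep="\t", index=False)


def load_motion_tsv(path) -> MotionTrace:
    return MotionTrace(pd.read_csv(path, sep="\t").to_numpy(dtype=float))


def _surface_to_gifti(vertices: np.ndarray, triangles: np.ndarray) -> gifti.GiftiImage:
    img = gifti.GiftiImage()
    img.add_gifti_data_array(
        gifti.GiftiDataArray(np.asarray(vertices, dtype=np.float32), intent="NIFTI_INTENT_POINTSET")
    )
    img.add_gifti_data_array(
        gifti.GiftiDataArray(np.asarray(triangles, dtype=np.int32), intent="NIFTI_INTENT_TRIANGLE")
    )
    return img


def save_laminar_mesh(path_prefix, lmesh: LaminarMesh) -> None:
    """One GIFTI surface file per depth: ``<prefix>.depth<K>.surf.gii``."""
    for d in range(lmesh.n_depths):
        img = _surface_to_gifti(lmesh.coords[:, d, :], lmesh.base.triangles)
        nib.save(img, f"{path_prefix}.depth{d:02d}.surf.gii")
    meta = {"n_depths": lmesh.n_depths, "depth_fractions": list(lmesh.depth_fractions)}
    Path(f"{path_prefix}.laminar.json").write_text(json.dumps(meta, indent=1))


def load_laminar_mesh(path_prefix) -> LaminarMesh:
    meta = json.loads(Path(f"{path_prefix}.laminar.json").read_text())
    coords = []
    triangles = None
    for d in range(meta["n_depths"]):
        img = nib.load(f"{path_prefix}.depth{d:02d}.surf.gii")
        coords.append(img.darrays[0].data.astype(float))
        triangles = img.darrays[1].data.astype(np.int64)
    coords = np.stack(coords, axis=1)
    base = SurfaceMesh(coords[:, 0, :], triangles)
    return LaminarMesh(base=base, coords=coords, depth_fractions=np.array(meta["depth_fractions"]))


def save_censor_mask(path, keep: np.ndarray) -> None:
    np.savetxt(path, np.asarray(keep, dtype=int), fmt="%d")


def save_profile_tsv(path, mean: np.ndarray, sem: np.ndarray, n: int) -> None:
    pd.DataFrame(
        {"depth": np.arange(1, len(mean) + 1), "mean": mean, "sem": sem, "n": n}
    ).to_csv(path, sep="\t", index=False)


def save_fcs_tsv(path, values: np.ndarray) -> None:
    """Long-format (vertex, depth, value) table of a vertex-by-depth map."""
    V, D = values.shape
    v, d = np.meshgrid(np.arange(V), np.arange(1, D + 1), indexing="ij")
    pd.DataFrame(
        {"vertex": v.ravel(), "depth": d.ravel(), "value": values.ravel()}
    ).to_csv(path, sep="\t", index=False)


def save_parcellation_tsv(path, labels: np.ndarray) -> None:
    pd.DataFrame({"vertex": np.arange(len(labels)), "label": labels}).to_csv(
        path, sep="\t", index=False
    )


def save_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=default))


def load_json(path):
    return json.loads(Path(path).read_text())
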