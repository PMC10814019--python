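"""File interfaces: HDF5 IQ ensembles, TIFF images, CSV cohorts, ROI polygons."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

from .recon import HDMIImage
from .synth.cohort import BIOMARKER_COLUMNS, BRANCHING_BIOMARKERS
from .synth.iq import IQEnsemble

__all__ = [
    "write_ensemble",
    "read_ensemble",
    "write_image",
    "read_image",
    "write_cohort",
    "read_cohort",
    "load_roi",
    "roi_to_mask",
]

COHORT_COLUMNS = ["id", "label", "thickness_mm", *BIOMARKER_COLUMNS, "measurable_MD_BA"]


def write_ensemble(path: str | Path, ensemble: IQEnsemble) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("iq", data=ensemble.data.astype(np.complex64))
        ds.attrs["frame_rate_hz"] = ensemble.frame_rate_hz
        ds.attrs["fc_mhz"] = ensemble.center_frequency_mhz
        ds.attrs["c_mps"] = ensemble.sound_speed_m_s
        ds.attrs["pitch_um"] = ensemble.pixel_pitch_um


def read_ensemble(path: str | Path) -> IQEnsemble:
    with h5py.File(path, "r") as f:
        if "iq" not in f:
            raise ValueError(f"{path}: missing dataset 'iq'")
        ds = f["iq"]
        required = ["frame_rate_hz", "fc_mhz", "c_mps", "pitch_um"]
        missing = [a for a in required if a not in ds.attrs]
        if missing:
            raise ValueError(f"{path}: missing attributes {missing}")
        return IQEnsemble(
            data=ds[...],
            frame_rate_hz=float(ds.attrs["frame_rate_hz"]),
            center_frequency_mhz=float(ds.attrs["fc_mhz"]),
            sound_speed_m_s=float(ds.attrs["c_mps"]),
            pixel_pitch_um=float(ds.attrs["pitch_um"]),
        )


def write_image(path: str | Path, image: HDMIImage) -> None:
    meta = {"pixel_pitch_um": image.pixel_pitch_um, "provenance": image.provenance}
    tifffile.imwrite(
        path, image.intensity.astype(np.float32), description=json.dumps(meta, default=str)
    )


def read_image(path: str | Path) -> HDMIImage:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].tags.get("ImageDescription")
        pitch, prov = 1.0, []
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                pitch = float(meta.get("pixel_pitch_um", 1.0))
                prov = meta.get("provenance", [])
            except (json.JSONDecodeError, TypeError):
                pass
    return HDMIImage(intensity=arr.astype(float), pixel_pitch_um=pitch, provenance=prov)


def write_cohort(path: str | Path, cohort: pd.DataFrame) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    cohort[COHORT_COLUMNS].to_csv(path, index=False, na_rep="")


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cohort CSV missing columns {missing}")
    bad = ~df["label"].isin(["benign", "malignant"])
    if bad.any():
        raise ValueError(f"{path}: invalid labels {df.loc[bad, 'label'].unique().tolist()}")
    flag = df["measurable_MD_BA"].astype(int)
    for c in BRANCHING_BIOMARKERS:
        empty = df[c].isna()
        if ((flag == 1) & empty).any() or ((flag == 0) & ~empty).any():
            raise ValueError(
                f"{path}: column {c} inconsistent with measurable_MD_BA "
                "(cells must be empty exactly when the flag is 0)"
            )
    df["measurable_MD_BA"] = flag
    return df


def load_roi(path_or_obj: str | Path | dict) -> np.ndarray:
    """Load and validate an ROI polygon: {'vertices': [[row, col], ...]}.

    The polygon must have >= 3 vertices and be simple (non-self-intersecting).
    Returns the (N, 2) vertex array.
    """
    if isinstance(path_or_obj, (str, Path)):
        with open(path_or_obj) as f:
            obj = json.load(f)
    else:
        obj = path_or_obj
    if not isinstance(obj, dict) or "vertices" not in obj:
        raise ValueError("ROI must be an object with a 'vertices' field")
    verts = np.asarray(obj["vertices"], dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("ROI 'vertices' must be an (N>=3, 2) list of [row, col] pairs")
    if not np.isfinite(verts).all():
        raise ValueError("ROI vertices must be finite")
    poly = Polygon(verts)
    if not poly.is_valid or poly.area == 0:
        raise ValueError("ROI polygon is degenerate or self-intersecting")
    return verts


def roi_to_mask(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    verts = np.asarray(vertices, dtype=float)
    rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask
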