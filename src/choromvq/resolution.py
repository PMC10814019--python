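"""Minimum-detectable-vessel-diameter scan.

A straight vessel of known diameter is placed along the depth axis (so its
flow has a full axial Doppler component), an ultrafast ensemble is
synthesized at the study acquisition parameters, and the full
reconstruction + binarization + skeletonization chain is run. The vessel
counts as detected when a single connected skeleton segment covers at least
80% of the true centerline length. Scanning a diameter ladder downward
yields the smallest recoverable diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morpho import binarize, skeletonize_and_segment
from .recon import run_hdmi
from .synth.iq import IQEnsemble, simulate_iq
from .synth.raster import rasterize
from .synth.tree import Segment, VesselTree

__all__ = ["single_vessel_ensemble", "vessel_detection", "smallest_detectable_diameter"]

DEFAULT_DIAMETER_LADDER_UM = (400.0, 300.0, 200.0, 150.0, 100.0)


def single_vessel_ensemble(
    diameter_um: float,
    seed: int,
    *,
    grid_shape: tuple[int, int] = (128, 64),
    pixel_pitch_um: float = 50.0,
    n_frames: int = 1000,
    frame_rate_hz: float = 1000.0,
    center_frequency_mhz: float = 16.5,
    clutter_to_blood_db: float = 40.0,
    snr_db: float = 20.0,
    psf_sigma_px: float = 1.0,
    flow_mm_s: float = 10.0,
) -> tuple[IQEnsemble, VesselTree]:
    """Straight axial vessel of the given diameter, centered laterally."""
    pitch_mm = pixel_pitch_um * 1e-3
    depth_mm = grid_shape[0] * pitch_mm
    x0 = grid_shape[1] * pitch_mm / 2.0
    margin = max(0.4, diameter_um * 1e-3)
    centerline = np.array([[margin, x0], [depth_mm - margin, x0]])
    tree = VesselTree(
        segments=[Segment(centerline, diameter_um, flow_mm_s)],
        parent_of={0: None},
        bifurcations=[],
    )
    raster = rasterize(tree, pixel_pitch_um, grid_shape)
    ens = simulate_iq(
        raster,
        frame_rate_hz=frame_rate_hz,
        center_frequency_mhz=center_frequency_mhz,
        n_frames=n_frames,
        clutter_to_blood_db=clutter_to_blood_db,
        snr_db=snr_db,
        psf_sigma_px=psf_sigma_px,
        seed=seed,
    )
    return ens, tree


@dataclass
class DetectionResult:
    diameter_um: float
    coverage: float       # longest connected skeleton segment / true length
    n_segments: int
    detected: bool


def vessel_detection(
    diameter_um: float,
    seed: int,
    coverage_threshold: float = 0.8,
    recon_config: dict | None = None,
    morpho_config: dict | None = None,
    **ensemble_kwargs,
) -> DetectionResult:
    """Run the full chain on a single-vessel phantom and score recovery."""
    ens, tree = single_vessel_ensemble(diameter_um, seed, **ensemble_kwargs)
    image = run_hdmi(ens, recon_config)
    roi = np.ones(image.shape, dtype=bool)
    mcfg = {"prune_px": 4.0, "min_object_px": 4}
    if morpho_config:
        mcfg.update(morpho_config)
    mask = binarize(image, roi, min_object_px=int(mcfg["min_object_px"]))
    skel = skeletonize_and_segment(mask, prune_px=float(mcfg["prune_px"]))
    true_len_um = tree.total_centerline_length_mm() * 1e3
    if skel.n_segments == 0:
        return DetectionResult(diameter_um, 0.0, 0, False)
    longest = max(skel.segment_path_length_um(i) for i in range(skel.n_segments))
    coverage = longest / true_len_um
    return DetectionResult(
        diameter_um, coverage, skel.n_segments, coverage >= coverage_threshold
    )


def smallest_detectable_diameter(
    diameters_um: tuple[float, ...] = DEFAULT_DIAMETER_LADDER_UM,
    seed: int = 0,
    **kwargs,
) -> tuple[float, list[DetectionResult]]:
    """Scan a diameter ladder downward; return the smallest detected diameter
    before the first failure, plus the per-diameter results."""
    results = []
    smallest = float("inf")
    for d in sorted(diameters_um, reverse=True):
        res = vessel_detection(d, seed=seed, **kwargs)
        results.append(res)
        if res.detected:
            smallest = d
        else:
            break
    return smallest, results
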