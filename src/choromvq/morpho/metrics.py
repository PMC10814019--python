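"""The 12 quantitative microvessel biomarkers.

Vessel density (VD), segment count (NV), branch-point count (NB), mean and
maximum diameter (D), tortuosity (tau = path length / chord length),
Murray's deviation at bifurcations, box-counting fractal dimension (mvFD),
and bifurcation angle (BA). Diameter, tortuosity and the branching measures
are aggregated to participant level as both the mean and the maximum; MD
and BA are structurally unmeasurable when the network has no branch point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..recon import HDMIImage
from .binarize import BinaryVesselMask, binarize
from .skeleton import Skeleton, skeletonize_and_segment

__all__ = [
    "BiomarkerRecord",
    "vessel_density",
    "tortuosity",
    "murray_deviation",
    "fractal_dimension",
    "bifurcation_angle",
    "compute_biomarkers",
    "default_morpho_config",
]

logger = logging.getLogger(__name__)


@dataclass
class BiomarkerRecord:
    """Per-participant biomarker vector with branching measurability flag."""

    VD: float
    NV: int
    NB: int
    Dmean_um: float
    Dmax_um: float
    tau_mean: float
    tau_max: float
    mvFD: float
    MDmean: float
    MDmax: float
    BAmean_deg: float
    BAmax_deg: float
    measurable_MD_BA: bool

    def __post_init__(self) -> None:
        if not self.measurable_MD_BA:
            for name in ("MDmean", "MDmax", "BAmean_deg", "BAmax_deg"):
                if not np.isnan(getattr(self, name)):
                    raise ValueError("branching biomarkers must be NaN when unmeasurable")
        if self.measurable_MD_BA and self.NB == 0:
            raise ValueError("MD/BA measurable requires NB > 0")

    def to_row(self) -> dict:
        """Column names match the cohort-table convention."""
        return {
            "VD": self.VD,
            "Dmean": self.Dmean_um,
            "Dmax": self.Dmax_um,
            "NV": self.NV,
            "mvFD": self.mvFD,
            "NB": self.NB,
            "tau_mean": self.tau_mean,
            "tau_max": self.tau_max,
            "MDmean": self.MDmean,
            "MDmax": self.MDmax,
            "BAmean": self.BAmean_deg,
            "BAmax": self.BAmax_deg,
            "measurable_MD_BA": int(self.measurable_MD_BA),
        }


def vessel_density(mask: BinaryVesselMask) -> float:
    """Vessel area as a fraction of the ROI area."""
    roi_area = int(mask.roi.sum())
    if roi_area == 0:
        raise ValueError("ROI is empty")
    return float(mask.mask.sum() / roi_area)


def tortuosity(
    skeleton: Skeleton, end_trim_px: int = 3
) -> tuple[np.ndarray, float, float]:
    """Per-segment path/chord ratio and its mean and max.

    Thinning leaves 1-3 px diagonal jogs at segment terminals; the first and
    last ``end_trim_px`` pixels are trimmed (when the segment is long enough)
    so a straight vessel measures exactly 1. Closed loops (zero chord) carry
    no endpoint distance and are excluded.
    """
    if skeleton.n_segments == 0:
        raise ValueError("skeleton has no segments")
    taus = []
    pitch = skeleton.pixel_pitch_um
    for i in range(skeleton.n_segments):
        path = skeleton.segments[i]
        trim = min(end_trim_px, (len(path) - 4) // 2)
        if trim > 0:
            path = path[trim:-trim]
        chord = float(np.linalg.norm(path[-1] - path[0])) * pitch
        if chord <= pitch * 1e-9:
            logger.info("segment %d is a closed loop; excluded from tortuosity", i)
            continue
        length = float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum()) * pitch
        taus.append(length / chord)
    taus = np.asarray(taus, dtype=float)
    if taus.size == 0:
        return taus, float("nan"), float("nan")
    return taus, float(taus.mean()), float(taus.max())


def _local_diameter_um(skeleton: Skeleton, sid: int, junction: tuple[float, float], k: int) -> float:
    """Mean diameter over the k segment pixels nearest the junction."""
    path = skeleton.segments[sid]
    d = skeleton.segment_diameters_um[sid]
    jr, jc = junction
    dist = (path[:, 0] - jr) ** 2 + (path[:, 1] - jc) ** 2
    order = np.argsort(dist, kind="stable")[:k]
    return float(np.mean(d[order]))


def murray_deviation(
    skeleton: Skeleton, exponent: float = 3.0, k: int = 5
) -> tuple[np.ndarray, float, float, bool]:
    """Relative deviation from Murray's law at each branch point.

    MD = |d_p^g - sum_i d_i^g| / d_p^g with the parent taken as the incident
    segment of largest local diameter near the junction; unmeasurable
    (NaN aggregates) when there are no branch points.
    """
    if skeleton.n_branch_points == 0:
        return np.array([]), float("nan"), float("nan"), False
    mds = []
    for bp in skeleton.branch_points:
        dias = [_local_diameter_um(skeleton, sid, bp.centroid, k) for sid in bp.segments]
        if len(dias) < 2:
            continue
        dias = sorted(dias, reverse=True)
        d_p, daughters = dias[0], dias[1:]
        if d_p <= 0:
            continue
        md = abs(d_p**exponent - sum(d**exponent for d in daughters)) / d_p**exponent
        mds.append(md)
    mds = np.asarray(mds, dtype=float)
    if mds.size == 0:
        return mds, float("nan"), float("nan"), False
    return mds, float(mds.mean()), float(mds.max()), True


def fractal_dimension(
    skeleton_mask: np.ndarray, box_sizes: np.ndarray | None = None
) -> float:
    """Box-counting dimension of a binary structure.

    N(eps) = number of eps x eps grid boxes containing at least one foreground
    pixel, over dyadic eps; the dimension is the least-squares slope of
    log N against log(1/eps). Returns NaN for an empty input.
    """
    m = np.asarray(skeleton_mask, dtype=bool)
    if not m.any():
        logger.info("fractal dimension undefined for an empty structure")
        return float("nan")
    # crop to the structure's bounding box so box counts reflect the structure
    rows = np.any(m, axis=1).nonzero()[0]
    cols = np.any(m, axis=0).nonzero()[0]
    m = m[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    side = max(m.shape)
    if box_sizes is None:
        kmax = int(np.floor(np.log2(side)))
        box_sizes = 2 ** np.arange(1, max(kmax, 5))
    box_sizes = np.asarray(box_sizes, dtype=int)
    if len(box_sizes) < 4:
        raise ValueError("need at least 4 box sizes")
    counts = []
    for eps in box_sizes:
        H = int(np.ceil(m.shape[0] / eps)) * eps
        W = int(np.ceil(m.shape[1] / eps)) * eps
        pad = np.zeros((H, W), dtype=bool)
        pad[: m.shape[0], : m.shape[1]] = m
        boxes = pad.reshape(H // eps, eps, W // eps, eps).any(axis=(1, 3))
        counts.append(boxes.sum())
    counts = np.asarray(counts, dtype=float)
    ok = counts > 0
    slope = np.polyfit(np.log(1.0 / box_sizes[ok]), np.log(counts[ok]), 1)[0]
    return float(slope)


def _daughter_direction(skeleton: Skeleton, sid: int, junction: tuple[float, float], k: int):
    """Unit vector along a daughter's first k skeleton pixels from the junction.

    Anchored at the daughter's own junction-end pixel (not the cluster
    centroid, which sits off the daughter axis inside the junction zone).
    """
    path = skeleton.segments[sid].astype(float)
    jr, jc = junction
    dist = (path[:, 0] - jr) ** 2 + (path[:, 1] - jc) ** 2
    if dist[0] > dist[-1]:
        path = path[::-1]
    v = path[min(k, len(path) - 1)] - path[0]
    n = np.linalg.norm(v)
    return v / n if n > 0 else None


def bifurcation_angle(
    skeleton: Skeleton, k: int = 5
) -> tuple[np.ndarray, float, float, bool]:
    """Angle between daughter vessels at each branch point, in degrees.

    Daughters are the incident segments other than the parent (the segment
    of largest local diameter). With more than two daughters the maximum
    pairwise angle is reported. Unmeasurable when there are no branch points.
    """
    if skeleton.n_branch_points == 0:
        return np.array([]), float("nan"), float("nan"), False
    angles = []
    for bp in skeleton.branch_points:
        sids = bp.segments
        if len(sids) < 3:
            continue
        dias = [_local_diameter_um(skeleton, sid, bp.centroid, k) for sid in sids]
        parent = sids[int(np.argmax(dias))]
        daughters = [s for s in sids if s != parent]
        dirs = [
            u
            for s in daughters
            if (u := _daughter_direction(skeleton, s, bp.centroid, k)) is not None
        ]
        if len(dirs) < 2:
            continue
        best = 0.0
        for i in range(len(dirs)):
            for j in range(i + 1, len(dirs)):
                cosang = float(np.clip(np.dot(dirs[i], dirs[j]), -1.0, 1.0))
                best = max(best, np.degrees(np.arccos(cosang)))
        angles.append(best)
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        return angles, float("nan"), float("nan"), False
    return angles, float(angles.mean()), float(angles.max()), True


def default_morpho_config() -> dict:
    return {
        "binarize_method": "otsu",
        "binarize_quantile": 0.85,
        "min_object_px": 4,
        "prune_px": 4.0,
        "junction_merge_radius_px": 2.0,
        "murray_exponent": 3.0,
        "local_diameter_k": 5,
        "fd_on_skeleton": True,
        "box_sizes": None,
    }


def compute_biomarkers(
    image: HDMIImage | np.ndarray,
    roi: np.ndarray,
    config: dict | None = None,
    *,
    pixel_pitch_um: float | None = None,
) -> BiomarkerRecord:
    """Binarize, skeletonize, and extract the full 12-biomarker record."""
    cfg = default_morpho_config()
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ValueError(f"unknown morpho config keys: {sorted(unknown)}")
        cfg.update(config)

    mask = binarize(
        image,
        roi,
        method=cfg["binarize_method"],
        min_object_px=cfg["min_object_px"],
        quantile=cfg["binarize_quantile"],
        pixel_pitch_um=pixel_pitch_um,
    )
    skel = skeletonize_and_segment(
        mask,
        prune_px=cfg["prune_px"],
        merge_radius_px=cfg["junction_merge_radius_px"],
    )
    vd = vessel_density(mask)
    nv = skel.n_segments
    nb = skel.n_branch_points

    if nv == 0:
        return BiomarkerRecord(
            VD=vd,
            NV=0,
            NB=0,
            Dmean_um=float("nan"),
            Dmax_um=float("nan"),
            tau_mean=float("nan"),
            tau_max=float("nan"),
            mvFD=float("nan"),
            MDmean=float("nan"),
            MDmax=float("nan"),
            BAmean_deg=float("nan"),
            BAmax_deg=float("nan"),
            measurable_MD_BA=False,
        )

    seg_diams = np.array([skel.segment_mean_diameter_um(i) for i in range(nv)])
    _, tau_mean, tau_max = tortuosity(skel)
    _, md_mean, md_max, md_ok = murray_deviation(
        skel, exponent=cfg["murray_exponent"], k=cfg["local_diameter_k"]
    )
    _, ba_mean, ba_max, ba_ok = bifurcation_angle(skel, k=cfg["local_diameter_k"])
    fd_input = skel.skeleton_mask if cfg["fd_on_skeleton"] else skel.mask
    mvfd = fractal_dimension(fd_input, cfg["box_sizes"])
    measurable = bool(md_ok and ba_ok and nb > 0)
    if not measurable:
        md_mean = md_max = ba_mean = ba_max = float("nan")

    return BiomarkerRecord(
        VD=vd,
        NV=nv,
        NB=nb,
        Dmean_um=float(seg_diams.mean()),
        Dmax_um=float(seg_diams.max()),
        tau_mean=tau_mean,
        tau_max=tau_max,
        mvFD=mvfd,
        MDmean=md_mean,
        MDmax=md_max,
        BAmean_deg=ba_mean,
        BAmax_deg=ba_max,
        measurable_MD_BA=measurable,
    )
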