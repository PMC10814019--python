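"""Synthetic vascular tree generation.

Trees are grown by recursive binary branching from a root placed at the top
of the field of view. Each segment is a straight chord perturbed by a single
sine period orthogonal to the chord, which makes the arc length (and hence
the tortuosity of the rendered vessel) analytically controllable. Daughter
diameters obey Murray's law d_p^gamma = d_1^gamma + d_2^gamma exactly, so a
gamma=3 tree has zero Murray deviation by construction.

Coordinates are (z, x) in millimetres: z is depth (image row direction),
x is lateral position (column direction). z increases downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Segment", "Bifurcation", "VesselTree", "generate_vessel_tree"]


@dataclass
class Segment:
    """One vessel segment: an ordered polyline with constant diameter and flow."""

    centerline_mm: np.ndarray  # (N, 2) points, columns (z, x), N >= 2
    diameter_um: float
    flow_mm_s: float

    def __post_init__(self) -> None:
        self.centerline_mm = np.asarray(self.centerline_mm, dtype=float)
        if self.centerline_mm.ndim != 2 or self.centerline_mm.shape[1] != 2:
            raise ValueError("centerline must be an (N, 2) array of (z, x) mm points")
        if len(self.centerline_mm) < 2:
            raise ValueError("centerline needs at least two points")
        if not np.isfinite(self.centerline_mm).all():
            raise ValueError("centerline contains non-finite values")
        if self.diameter_um <= 0:
            raise ValueError("segment diameter must be positive")

    @property
    def path_length_mm(self) -> float:
        return float(np.linalg.norm(np.diff(self.centerline_mm, axis=0), axis=1).sum())

    @property
    def chord_length_mm(self) -> float:
        return float(np.linalg.norm(self.centerline_mm[-1] - self.centerline_mm[0]))


@dataclass
class Bifurcation:
    parent: int
    daughters: tuple[int, ...]
    planned_angle_deg: float

    def __post_init__(self) -> None:
        if not 0.0 < self.planned_angle_deg < 180.0:
            raise ValueError("planned bifurcation angle must lie in (0, 180) degrees")


@dataclass
class VesselTree:
    """Ground-truth vascular network: segments plus branching topology."""

    segments: list[Segment] = field(default_factory=list)
    parent_of: dict[int, int | None] = field(default_factory=dict)
    bifurcations: list[Bifurcation] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_bifurcations(self) -> int:
        return len(self.bifurcations)

    def bounding_box_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) corners over all centerlines, each an array (z, x)."""
        if not self.segments:
            zero = np.zeros(2)
            return zero, zero
        pts = np.vstack([s.centerline_mm for s in self.segments])
        return pts.min(axis=0), pts.max(axis=0)

    def total_centerline_length_mm(self) -> float:
        return sum(s.path_length_mm for s in self.segments)


def _sine_perturbed_chord(
    start: np.ndarray,
    heading: np.ndarray,
    length_mm: float,
    amplitude_mm: float,
    n_points: int,
) -> np.ndarray:
    """Straight chord from `start` along `heading`, offset by one sine period."""
    s = np.linspace(0.0, length_mm, n_points)
    normal = np.array([-heading[1], heading[0]])
    offset = amplitude_mm * np.sin(2.0 * np.pi * s / length_mm)
    return start[None, :] + s[:, None] * heading[None, :] + offset[:, None] * normal[None, :]


def _rotate(v: np.ndarray, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def generate_vessel_tree(
    seed: int,
    n_bifurcations: int,
    tortuosity_amplitude: float,
    murray_exponent: float = 3.0,
    root_diameter_um: float = 600.0,
    *,
    extent_mm: tuple[float, float] = (12.8, 12.8),
    root_position_frac: float = 0.5,
    segment_length_mm: float = 2.4,
    length_decay: float = 0.8,
    angle_range_deg: tuple[float, float] = (60.0, 120.0),
    daughter_split_range: tuple[float, float] = (0.4, 0.6),
    flow_mm_s: float = 10.0,
    daughter_flow_split: bool = True,
    points_per_mm: float = 40.0,
) -> VesselTree:
    """Grow a binary-branching vascular tree.

    Parameters
    ----------
    seed : int
        Seed for the private random generator; identical seeds give identical trees.
    n_bifurcations : int
        Exact number of branch points to create (breadth-first tip splitting).
    tortuosity_amplitude : float
        Amplitude (mm) of the single-period sinusoidal centerline perturbation.
    murray_exponent : float
        Exponent gamma in d_p^gamma = d_1^gamma + d_2^gamma; daughters satisfy
        it exactly, with a random flow split drawn per bifurcation.
    root_diameter_um : float
        Diameter of the root segment in micrometres.
    extent_mm : (depth, width)
        Field of view; growth is steered back toward the interior near edges.
    angle_range_deg : (lo, hi)
        Planned bifurcation angles are drawn uniformly from this range and split
        symmetrically about the parent heading.
    flow_mm_s : float
        Mean blood speed in the root segment. With ``daughter_flow_split`` the
        speed scales with d^(gamma-2) down the tree (flow conservation under
        Murray splitting); otherwise it is constant.
    """
    if n_bifurcations < 0:
        raise ValueError("n_bifurcations must be >= 0")
    if tortuosity_amplitude < 0:
        raise ValueError("tortuosity_amplitude must be >= 0")
    if root_diameter_um <= 0:
        raise ValueError("root_diameter_um must be positive")
    if murray_exponent <= 0:
        raise ValueError("murray_exponent must be positive")
    if not 0 < angle_range_deg[0] <= angle_range_deg[1] < 180:
        raise ValueError("angle range must satisfy 0 < lo <= hi < 180")

    rng = np.random.default_rng(seed)
    depth_mm, width_mm = float(extent_mm[0]), float(extent_mm[1])
    # keep the lumen inside the field: margin covers the root radius too
    margin = max(0.06 * min(depth_mm, width_mm), 1.25 * root_diameter_um / 2.0 * 1e-3)

    tree = VesselTree()
    root_start = np.array([margin, root_position_frac * width_mm])
    heading = np.array([1.0, 0.0])  # straight down

    def n_pts(length: float) -> int:
        return max(16, int(np.ceil(length * points_per_mm)) + 1)

    def add_segment(start, heading, length, diameter, flow, parent):
        # steer back toward the interior when the endpoint would leave the field
        for _ in range(24):
            end = start + length * heading
            lo = np.array([margin, margin])
            hi = np.array([depth_mm - margin, width_mm - margin])
            if np.all(end >= lo) and np.all(end <= hi):
                break
            center = np.array([0.6 * depth_mm, 0.5 * width_mm])
            to_center = center - start
            to_center /= np.linalg.norm(to_center) + 1e-12
            heading = heading + 0.35 * to_center
            heading /= np.linalg.norm(heading)
        else:
            length *= 0.5
        amp = min(tortuosity_amplitude, 0.35 * length) if length > 0 else 0.0
        if tortuosity_amplitude == 0:
            amp = 0.0
        pts = _sine_perturbed_chord(start, heading, length, amp, n_pts(length))
        sid = len(tree.segments)
        tree.segments.append(Segment(pts, diameter, flow))
        tree.parent_of[sid] = parent
        return sid, pts[-1], heading

    root_len = segment_length_mm
    sid, end, hd = add_segment(root_start, heading, root_len, root_diameter_um, flow_mm_s, None)
    # open tips: (segment id, end point, heading, diameter, flow, generation)
    tips: list[tuple[int, np.ndarray, np.ndarray, float, float, int]] = [
        (sid, end, hd, root_diameter_um, flow_mm_s, 0)
    ]

    for _ in range(n_bifurcations):
        parent_id, start, hd, d_p, v_p, gen = tips.pop(0)  # breadth-first
        theta = float(rng.uniform(*angle_range_deg))
        # Murray-exact daughters: split the parent's d^gamma flow share
        frac = float(rng.uniform(*daughter_split_range))
        d1 = d_p * frac ** (1.0 / murray_exponent)
        d2 = d_p * (1.0 - frac) ** (1.0 / murray_exponent)
        length = segment_length_mm * length_decay ** (gen + 1)
        daughters = []
        for d_i, sign, f_i in ((d1, +1.0, frac), (d2, -1.0, 1.0 - frac)):
            h_i = _rotate(hd, sign * theta / 2.0)
            if daughter_flow_split:
                # Q_i = f_i * Q_p; v = 4Q/(pi d^2) => v_i = v_p * f_i * (d_p/d_i)^2
                v_i = v_p * f_i * (d_p / d_i) ** 2
            else:
                v_i = v_p
            did, end_i, h_out = add_segment(start, h_i, length, d_i, v_i, parent_id)
            daughters.append(did)
            tips.append((did, end_i, h_out, d_i, v_i, gen + 1))
        tree.bifurcations.append(Bifurcation(parent_id, tuple(daughters), theta))

    return tree
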