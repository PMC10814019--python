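"""Skeletonization and conversion to a vessel-segment graph.

The binary mask is thinned to a 1-pixel skeleton; skeleton pixels with three
or more 8-connected skeleton neighbors are junction pixels. Nearby junction
pixels (within a small merge radius) are clustered into a single branch
point so that, e.g., two crossing vessels yield one branch point rather than
a pair of adjacent triple points. Maximal node-free pixel paths between
branch points / endpoints are the vessel segments; terminal spurs shorter
than a pruning length are treated as thinning artifacts and removed. The
local vessel diameter along each segment is read off the Euclidean distance
transform of the mask (x2, x pixel pitch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.morphology import skeletonize as _thin

from .binarize import BinaryVesselMask

__all__ = ["BranchPoint", "Skeleton", "skeletonize_and_segment"]

_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class BranchPoint:
    centroid: tuple[float, float]          # (row, col), sub-pixel
    pixels: list[tuple[int, int]]          # clustered junction pixels
    segments: list[int] = field(default_factory=list)  # incident segment ids


@dataclass
class Skeleton:
    """Segmented centerline network of a binary vessel mask."""

    segments: list[np.ndarray]                 # each (N>=2, 2) int pixel path
    segment_diameters_um: list[np.ndarray]     # diameter profile per path pixel
    branch_points: list[BranchPoint]
    pixel_pitch_um: float
    skeleton_mask: np.ndarray                  # (H, W) bool
    mask: np.ndarray                           # source binary mask

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_branch_points(self) -> int:
        return len(self.branch_points)

    def segment_path_length_um(self, i: int) -> float:
        path = self.segments[i]
        steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
        return float(steps.sum() * self.pixel_pitch_um)

    def segment_chord_length_um(self, i: int) -> float:
        path = self.segments[i]
        return float(np.linalg.norm(path[-1] - path[0]) * self.pixel_pitch_um)

    def segment_mean_diameter_um(self, i: int) -> float:
        return float(np.mean(self.segment_diameters_um[i]))


def _neighbors(px: tuple[int, int], skel_set: set) -> list[tuple[int, int]]:
    r, c = px
    return [(r + dr, c + dc) for dr, dc in _NEIGH if (r + dr, c + dc) in skel_set]


def _cluster_junctions(
    junctions: list[tuple[int, int]], merge_radius: float
) -> list[list[tuple[int, int]]]:
    """Group junction pixels whose Euclidean distance is <= merge_radius."""
    unvisited = set(junctions)
    r2 = merge_radius**2
    clusters = []
    while unvisited:
        seed = unvisited.pop()
        cluster = [seed]
        frontier = [seed]
        while frontier:
            p = frontier.pop()
            near = [
                q
                for q in list(unvisited)
                if (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 <= r2
            ]
            for q in near:
                unvisited.remove(q)
                cluster.append(q)
                frontier.append(q)
        clusters.append(cluster)
    return clusters


def _extract_paths(skel_set: set, junction_set: set):
    """Maximal node-free paths. Returns list of pixel paths (junction pixels
    included at the touched ends)."""
    paths = []
    visited_edges: set[frozenset] = set()

    def walk(start, first):
        """Walk from node pixel `start` through `first` until the next node."""
        path = [start, first]
        visited_edges.add(frozenset((start, first)))
        prev, cur = start, first
        while cur not in junction_set:
            nbrs = [q for q in _neighbors(cur, skel_set) if q != prev]
            # prefer continuing along unvisited edges; drop back-diagonal doubles
            nxt = None
            for q in nbrs:
                if frozenset((cur, q)) not in visited_edges:
                    nxt = q
                    break
            if nxt is None:
                break  # terminal endpoint
            visited_edges.add(frozenset((cur, nxt)))
            path.append(nxt)
            prev, cur = cur, nxt
        return path

    # start at junction pixels and endpoints
    starts = []
    for p in skel_set:
        deg = len(_neighbors(p, skel_set))
        if p in junction_set or deg == 1:
            starts.append(p)
    for p in starts:
        for q in _neighbors(p, skel_set):
            if p in junction_set and q in junction_set:
                continue  # intra/inter-junction contacts handled by clustering
            if frozenset((p, q)) in visited_edges:
                continue
            path = walk(p, q)
            if len(path) >= 2:
                paths.append(path)
    # leftover pure cycles (all degree-2, no nodes)
    covered = {px for path in paths for px in path}
    leftover = [p for p in skel_set if p not in covered and p not in junction_set]
    leftover_set = set(leftover)
    while leftover_set:
        start = leftover_set.pop()
        nbrs = _neighbors(start, skel_set)
        if not nbrs:
            continue  # isolated pixel: below the 2-pixel segment minimum
        path = walk(start, nbrs[0])
        paths.append(path)
        leftover_set -= set(path)
    return paths


def _junction_pixels(skel_set: set) -> set:
    out = set()
    for p in skel_set:
        if len(_neighbors(p, skel_set)) >= 3:
            out.add(p)
    return out


def skeletonize_and_segment(
    mask: BinaryVesselMask | np.ndarray,
    prune_px: float = 4.0,
    *,
    merge_radius_px: float = 2.0,
    pixel_pitch_um: float | None = None,
    max_prune_iter: int = 20,
) -> Skeleton:
    """Thin a vessel mask and segment its skeleton into a branch-point graph.

    An empty mask yields an empty skeleton (zero segments, zero branch
    points) rather than an error.
    """
    if isinstance(mask, BinaryVesselMask):
        m = mask.mask
        pitch = mask.pixel_pitch_um
    else:
        m = np.asarray(mask, dtype=bool)
        pitch = pixel_pitch_um if pixel_pitch_um is not None else 1.0

    skel = _thin(m)
    skel_set = {tuple(p) for p in np.argwhere(skel)}

    # iterative spur pruning: drop short terminal twigs, re-detect junctions
    for _ in range(max_prune_iter):
        junction_set = _junction_pixels(skel_set)
        paths = _extract_paths(skel_set, junction_set)
        removed = False
        for path in paths:
            a_node = path[0] in junction_set
            b_node = path[-1] in junction_set
            if a_node == b_node:
                continue  # internal segment or isolated chain: not a spur
            length_px = float(
                np.linalg.norm(np.diff(np.asarray(path, float), axis=0), axis=1).sum()
            )
            if length_px < prune_px:
                drop = [p for p in path if p not in junction_set]
                skel_set -= set(drop)
                removed = True
        if not removed:
            break

    junction_set = _junction_pixels(skel_set)
    raw_paths = _extract_paths(skel_set, junction_set)
    raw_paths = [p for p in raw_paths if len(p) >= 2]

    clusters = _cluster_junctions(sorted(junction_set), merge_radius_px)
    cluster_of: dict[tuple[int, int], int] = {}
    for ci, cl in enumerate(clusters):
        for p in cl:
            cluster_of[p] = ci

    # discard connector stubs that live entirely inside one junction cluster
    def endpoint_cluster(px):
        return cluster_of.get(px, None)

    seg_paths: list[list[tuple[int, int]]] = []
    incident: dict[int, list[int]] = {ci: [] for ci in range(len(clusters))}
    for path in raw_paths:
        ca, cb = endpoint_cluster(path[0]), endpoint_cluster(path[-1])
        interior = [p for p in path if p not in junction_set]
        if ca is not None and ca == cb and len(interior) == 0:
            continue  # intra-cluster contact
        sid = len(seg_paths)
        seg_paths.append(path)
        for ci in {c for c in (ca, cb) if c is not None}:
            incident[ci].append(sid)
        if ca is not None and ca == cb:
            incident[ca].append(sid)  # loop attached twice to the same node

    # merge pass-through "junction" clusters that connect exactly two segments
    changed = True
    while changed:
        changed = False
        for ci, sids in list(incident.items()):
            if len(sids) == 2 and len(set(sids)) == 2:
                s1, s2 = sids
                p1, p2 = seg_paths[s1], seg_paths[s2]
                if endpoint_cluster(p1[-1]) != ci:
                    p1 = p1[::-1]
                if endpoint_cluster(p2[0]) != ci:
                    p2 = p2[::-1]
                merged = p1 + p2
                seg_paths[s1] = merged
                seg_paths[s2] = []
                for cj, lst in incident.items():
                    incident[cj] = [s1 if s == s2 else s for s in lst]
                incident[ci] = []
                changed = True
                break
    keep = [i for i, p in enumerate(seg_paths) if len(p) >= 2]
    remap = {old: new for new, old in enumerate(keep)}
    seg_paths = [seg_paths[i] for i in keep]

    branch_points = []
    for ci, cl in enumerate(clusters):
        sids = sorted({remap[s] for s in incident.get(ci, []) if s in remap})
        if len(incident.get(ci, [])) >= 3 and len(sids) >= 1:
            arr = np.asarray(cl, float)
            branch_points.append(
                BranchPoint(centroid=tuple(arr.mean(axis=0)), pixels=list(cl), segments=sids)
            )

    skel_mask = np.zeros_like(m, dtype=bool)
    if skel_set:
        idx = np.asarray(sorted(skel_set))
        skel_mask[idx[:, 0], idx[:, 1]] = True

    edt = distance_transform_edt(m)
    seg_arrays = [np.asarray(p, dtype=int) for p in seg_paths]
    diameters = [2.0 * edt[p[:, 0], p[:, 1]] * pitch for p in seg_arrays]

    return Skeleton(
        segments=seg_arrays,
        segment_diameters_um=diameters,
        branch_points=branch_points,
        pixel_pitch_um=pitch,
        skeleton_mask=skel_mask,
        mask=m,
    )
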