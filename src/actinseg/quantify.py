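"""Biological quantification: foreground masks, area fractions, morphometry.

The marker channel (dendritic or axonal stain, imaged at confocal
resolution) defines the region of a process: a Gaussian blur with a wide
sigma (default 20 px) followed by Otsu thresholding.  Pattern prevalence
per image is the fraction of that mask covered by each segmented class
(a pixel may count in both classes).  Morphometry reduces the mask to a
unit-width skeleton graph whose segment lengths use chain-code step
distances (1 for axial, sqrt(2) for diagonal moves); the per-image
measurements are the total branch length and the weighted graph diameter
(shortest path between the two most distant connected nodes).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

__all__ = [
    "ForegroundMask", "SkeletonGraph", "foreground_mask", "area_fractions",
    "skeleton_graph", "total_branch_length", "max_branch_length",
    "condition_table_row",
]

SQRT2 = float(np.sqrt(2.0))


@dataclass
class ForegroundMask:
    mask: np.ndarray
    role: str = "dendrite_like"
    blur_sigma_px: float = 20.0

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def foreground_mask(
    channel: np.ndarray,
    sigma_px: float = 20.0,
    role: str = "dendrite_like",
) -> ForegroundMask:
    """Gaussian blur then Otsu threshold; pixels >= threshold are foreground."""
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2:
        raise ValueError("foreground_mask expects a single-channel 2-D image")
    blurred = gaussian_filter(channel, sigma_px)
    if np.ptp(blurred) == 0:
        raise ValueError("constant image: Otsu threshold undefined")
    t = threshold_otsu(blurred)
    return ForegroundMask(mask=blurred >= t, role=role, blur_sigma_px=sigma_px)


def area_fractions(
    seg_maps: dict[str, np.ndarray],
    mask: ForegroundMask | np.ndarray,
) -> dict[str, float]:
    """|seg ∩ mask| / |mask| per class, computed independently per class."""
    m = mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask, dtype=bool)
    area = int(m.sum())
    if area == 0:
        raise ValueError("empty foreground mask")
    out = {}
    for cls, seg in seg_maps.items():
        seg = np.asarray(seg, dtype=bool)
        if seg.shape != m.shape:
            raise ValueError(f"segmentation map {cls!r} shape mismatch")
        out[cls] = float(np.sum(seg & m)) / area
    return out


# ---------------------------------------------------------------------------
# skeleton graph

@dataclass
class Segment:
    node_a: int
    node_b: int
    length_px: float
    path: np.ndarray  # (n, 2) pixel coordinates, ends included


@dataclass
class SkeletonGraph:
    nodes: list[tuple[int, int]]          # representative pixel per node
    segments: list[Segment]

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(range(len(self.nodes)))
        for seg in self.segments:
            g.add_edge(seg.node_a, seg.node_b, weight=seg.length_px)
        return g

    def adjacency(self) -> np.ndarray:
        """Symmetric matrix of segment lengths, 0 where unconnected.

        Parallel segments keep the shorter length (shortest-path semantics).
        """
        n = len(self.nodes)
        a = np.zeros((n, n))
        for seg in self.segments:
            cur = a[seg.node_a, seg.node_b]
            val = seg.length_px if cur == 0 else min(cur, seg.length_px)
            a[seg.node_a, seg.node_b] = a[seg.node_b, seg.node_a] = val
        return a


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    from scipy.ndimage import convolve
    kernel = np.ones((3, 3)); kernel[1, 1] = 0
    return convolve(skel.astype(int), kernel, mode="constant")


def _intra_cluster_dists(start: tuple[int, int], members: set) -> dict:
    """Chain-code shortest distances from ``start`` to every cluster pixel."""
    import heapq

    dist = {start: 0.0}
    heap = [(0.0, start)]
    while heap:
        d, (r, c) = heapq.heappop(heap)
        if d > dist.get((r, c), np.inf):
            continue
        for dr, dc in _NEIGHBORS:
            nb = (r + dr, c + dc)
            if nb in members:
                nd = d + (1.0 if (dr == 0 or dc == 0) else SQRT2)
                if nd < dist.get(nb, np.inf):
                    dist[nb] = nd
                    heapq.heappush(heap, (nd, nb))
    return dist


def skeleton_graph(
    mask: ForegroundMask | np.ndarray,
    prune_spurs_px: float = 3.0,
) -> SkeletonGraph:
    """Node/segment graph of the morphological skeleton of a binary mask.

    Nodes are skeleton pixels with exactly one 8-neighbor (endpoints) or
    three and more (joints); adjacent node pixels are merged into one
    node.  Segments are maximal node-free paths; their length is the sum
    of per-step distances.  Leaf segments shorter than ``prune_spurs_px``
    are dropped (thinning artifacts).  An isolated cycle with no node
    pixel gets one arbitrary (deterministic) anchor node and a single
    loop segment.
    """
    m = mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask, dtype=bool)
    skel = skeletonize(m)
    if not skel.any():
        return SkeletonGraph(nodes=[], segments=[])

    counts = _neighbor_count(skel)
    node_px = skel & ((counts == 1) | (counts >= 3))

    # anchor node for pure cycles (components without any node pixel)
    from skimage.measure import label as cc_label
    comp = cc_label(skel, connectivity=2)
    for cid in range(1, comp.max() + 1):
        sel = comp == cid
        if not (node_px & sel).any():
            rr, cc = np.nonzero(sel)
            node_px[rr[0], cc[0]] = True

    # merge adjacent node pixels into clusters; pick a central representative
    # and remember each member's chain distance to it, so segment lengths do
    # not lose the steps swallowed by multi-pixel junctions
    clusters = cc_label(node_px, connectivity=2)
    n_nodes = clusters.max()
    nodes = []
    to_rep: dict[tuple[int, int], float] = {}
    for nid in range(1, n_nodes + 1):
        members = list(zip(*np.nonzero(clusters == nid)))
        members = [(int(r), int(c)) for r, c in members]
        dmats = {
            m: _intra_cluster_dists(m, set(members)) for m in members
        }
        rep = min(members, key=lambda m: (max(dmats[m].values()), m))
        nodes.append(rep)
        for m, dist in dmats[rep].items():
            to_rep[m] = dist

    h, w = skel.shape

    def neighbors(r, c):
        for dr, dc in _NEIGHBORS:
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and skel[r2, c2]:
                yield r2, c2

    visited = np.zeros_like(skel, dtype=bool)  # interior path pixels consumed
    segments: list[Segment] = []
    seen_direct = set()

    for nid in range(1, n_nodes + 1):
        for r0, c0 in zip(*np.nonzero(clusters == nid)):
            for r1, c1 in neighbors(r0, c0):
                if clusters[r1, c1]:  # node cluster directly adjacent to another
                    other = clusters[r1, c1]
                    if other != nid:
                        key = tuple(sorted([(r0, c0), (r1, c1)]))
                        if key not in seen_direct:
                            seen_direct.add(key)
                            step = 1.0 if (r1 == r0 or c1 == c0) else SQRT2
                            length = step + to_rep[(r0, c0)] + to_rep[(r1, c1)]
                            segments.append(Segment(nid - 1, other - 1, length,
                                                    np.array([[r0, c0], [r1, c1]])))
                    continue
                if visited[r1, c1]:
                    continue
                # walk the node-free path until the next node cluster
                path = [(r0, c0), (r1, c1)]
                length = 1.0 if (r1 == r0 or c1 == c0) else SQRT2
                visited[r1, c1] = True
                prev, cur = (r0, c0), (r1, c1)
                end_cluster = None
                while True:
                    nxt = None
                    for cand in neighbors(*cur):
                        if cand == prev or (len(path) > 2 and cand == path[-2]):
                            continue
                        if clusters[cand]:
                            end_cluster = clusters[cand]
                            nxt = cand
                            break
                        if not visited[cand]:
                            nxt = cand
                            break
                    if nxt is None:
                        break
                    step = 1.0 if (nxt[0] == cur[0] or nxt[1] == cur[1]) else SQRT2
                    length += step
                    path.append(nxt)
                    if end_cluster is not None:
                        break
                    visited[nxt] = True
                    prev, cur = cur, nxt
                length += to_rep[(r0, c0)]
                if end_cluster is None:
                    end_cluster = nid  # dead end back into its own cluster (loop)
                else:
                    length += to_rep[path[-1]]
                segments.append(Segment(nid - 1, int(end_cluster) - 1, length,
                                        np.asarray(path)))

    # prune short leaf spurs
    if prune_spurs_px > 0:
        degree = np.zeros(n_nodes, dtype=int)
        for seg in segments:
            degree[seg.node_a] += 1
            degree[seg.node_b] += 1
        kept = [
            seg for seg in segments
            if not (seg.length_px < prune_spurs_px
                    and (degree[seg.node_a] == 1 or degree[seg.node_b] == 1))
        ]
        if kept:
            segments = kept
    return SkeletonGraph(nodes=nodes, segments=segments)


def total_branch_length(graph: SkeletonGraph, pixel_size_nm: float) -> float:
    """Sum of all segment lengths, in micrometers."""
    return sum(s.length_px for s in graph.segments) * pixel_size_nm / 1000.0


def max_branch_length(graph: SkeletonGraph, pixel_size_nm: float) -> float:
    """Weighted graph diameter in micrometers.

    The maximum, over all node pairs in the same connected component, of
    the shortest-path distance between them.  This 'most distant connected
    nodes' rule yields one linear stretch and avoids non-physical
    concatenations of sibling branches.
    """
    if not graph.segments:
        return 0.0
    g = graph.to_networkx()
    best = 0.0
    for source, dists in nx.all_pairs_dijkstra_path_length(g, weight="weight"):
        if dists:
            best = max(best, max(dists.values()))
    return best * pixel_size_nm / 1000.0


def condition_table_row(
    image_id: str,
    condition: str,
    seg_maps: dict[str, np.ndarray],
    mask: ForegroundMask,
    pixel_size_nm: float,
    prune_spurs_px: float = 3.0,
) -> dict:
    """One row of the per-image measurement table (fractions + morphometry)."""
    fractions = area_fractions(seg_maps, mask)
    graph = skeleton_graph(mask, prune_spurs_px=prune_spurs_px)
    return {
        "image": image_id,
        "condition": condition,
        "ring_area_fraction": fractions.get("rings", np.nan),
        "fiber_area_fraction": fractions.get("fibers", np.nan),
        "ring_area_px": int(np.sum(np.asarray(seg_maps.get("rings"), dtype=bool) & mask.mask))
        if "rings" in seg_maps else 0,
        "fiber_area_px": int(np.sum(np.asarray(seg_maps.get("fibers"), dtype=bool) & mask.mask))
        if "fibers" in seg_maps else 0,
        "mask_area_px": mask.area_px,
        "total_branch_length_um": total_branch_length(graph, pixel_size_nm),
        "max_branch_length_um": max_branch_length(graph, pixel_size_nm),
    }
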