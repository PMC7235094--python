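"""Object-overlap colocalization, tripartite categorisation, and
nearest-neighbour statistics with a 180°-rotation spatial null.

Colocalization is object-based: a presynaptic or astrocytic object
counts as associated with a PSD when its binarised mask overlaps the
binarised PSD mask by at least one pixel, evaluated on the finer of the
two pixel grids.  PSDs are then classified into four categories:
PSD only, PSD + astrocyte, synapse (PSD + VGLUT bouton) and tripartite
synapse (PSD + bouton + astrocyte).

The spatial null rotates the comparison channel by 180° about the frame
centre: object counts, sizes and intensities are preserved exactly while
any spatial association with PSDs is destroyed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .core import BinaryMask, FrameMismatchError, ParameterError

__all__ = [
    "ColocFlags",
    "NeighborTable",
    "EdgeNeighborTable",
    "overlap_colocalize",
    "classify_category",
    "nearest_neighbors",
    "edge_edge_count",
    "rotate_mask",
    "rotate_points",
    "null_comparison",
]

CATEGORIES = ("psd_only", "psd_astro", "synapse", "tripartite")


@dataclass
class ColocFlags:
    psd_id: int
    vglut1: bool = False
    vglut2: bool = False
    astro: bool = False

    @property
    def category(self) -> str:
        return classify_category(self.vglut1 or self.vglut2, self.astro)


def classify_category(vglut: bool, astro: bool) -> str:
    """Four-way tripartite truth table.

    vglut & astro → tripartite; vglut only → synapse; astro only →
    psd_astro; neither → psd_only.
    """
    if vglut and astro:
        return "tripartite"
    if vglut:
        return "synapse"
    if astro:
        return "psd_astro"
    return "psd_only"


# ---------------------------------------------------------------------------
# overlap colocalization

def _resample_to(shape, pixel_size_from, arr, pixel_size_to, order0=True):
    """Nearest-neighbour lookup of `arr` (its own grid) onto a target grid."""
    h, w = shape
    rows = (((np.arange(h) + 0.5) * pixel_size_to) / pixel_size_from).astype(int)
    cols = (((np.arange(w) + 0.5) * pixel_size_to) / pixel_size_from).astype(int)
    rows = np.clip(rows, 0, arr.shape[0] - 1)
    cols = np.clip(cols, 0, arr.shape[1] - 1)
    return arr[np.ix_(rows, cols)]


def _check_frames(shape_a, px_a, shape_b, px_b):
    for axis in (0, 1):
        ea = shape_a[axis] * px_a
        eb = shape_b[axis] * px_b
        if abs(ea - eb) > max(px_a, px_b):
            raise FrameMismatchError(
                f"physical extents differ on axis {axis}: {ea:.1f} vs {eb:.1f} nm"
            )


def overlap_colocalize(
    labels_a: np.ndarray,
    pixel_size_a_nm: float,
    mask_b: BinaryMask,
    min_overlap_px: int = 1,
) -> dict[int, bool]:
    """Flag each object of ``labels_a`` overlapping ``mask_b``.

    An object is flagged when at least ``min_overlap_px`` of its pixels
    coincide with foreground of ``mask_b`` on the evaluation grid — the
    finer of the two grids, with nearest-neighbour resampling of the
    coarser input, so the "≥ 1 pixel" rule is applied at the resolution
    at which it was defined.
    """
    if min_overlap_px < 1:
        raise ParameterError("min_overlap_px must be ≥ 1")
    _check_frames(labels_a.shape, pixel_size_a_nm,
                  mask_b.shape, mask_b.pixel_size_nm)

    if pixel_size_a_nm <= mask_b.pixel_size_nm:
        lab = labels_a
        other = _resample_to(labels_a.shape, mask_b.pixel_size_nm,
                             mask_b.pixels, pixel_size_a_nm)
    else:
        lab = _resample_to(mask_b.shape, pixel_size_a_nm,
                           labels_a, mask_b.pixel_size_nm)
        other = mask_b.pixels

    n = int(lab.max())
    flags = {i: False for i in np.unique(labels_a) if i > 0}
    if n == 0:
        return flags
    overlap_counts = np.bincount(lab[other].ravel(), minlength=n + 1)
    for i in flags:
        flags[i] = bool(overlap_counts[i] >= min_overlap_px) if i <= n else False
    return flags


# ---------------------------------------------------------------------------
# nearest neighbours

@dataclass
class NeighborTable:
    psd_id: int
    nn_distances_um: list  # k ascending distances; NaN-padded if short
    count_within_radius: int
    padded: bool = False
    is_rotated_control: bool = False

    @property
    def mean_nn_um(self) -> float:
        d = np.asarray(self.nn_distances_um, dtype=float)
        d = d[np.isfinite(d)]
        return float(d.mean()) if d.size else float("nan")


def nearest_neighbors(
    psd_centroids_um: np.ndarray,
    astro_centroids_um: np.ndarray,
    k: int = 10,
    radius_um: float = 3.0,
    psd_ids: Optional[Sequence[int]] = None,
    is_rotated_control: bool = False,
) -> list[NeighborTable]:
    """Per-PSD centre–centre nearest-neighbour table.

    For each PSD: the ``k`` smallest Euclidean distances to astrocytic
    punctum centres (ascending, NaN-padded and flagged when fewer than
    ``k`` puncta exist) and the count of puncta within ``radius_um``
    (closed boundary: a punctum at exactly the radius is counted).
    """
    if k < 1:
        raise ParameterError("k must be ≥ 1")
    psd = np.atleast_2d(np.asarray(psd_centroids_um, dtype=float))
    if psd.size == 0:
        return []
    astro = np.asarray(astro_centroids_um, dtype=float).reshape(-1, 2)
    ids = list(psd_ids) if psd_ids is not None else list(range(len(psd)))

    tables = []
    if astro.shape[0] == 0:
        for pid in ids:
            tables.append(NeighborTable(pid, [float("nan")] * k, 0,
                                        padded=True,
                                        is_rotated_control=is_rotated_control))
        return tables

    tree = cKDTree(astro)
    kk = min(k, astro.shape[0])
    dists, _ = tree.query(psd, k=kk)
    dists = np.atleast_2d(dists)
    if kk == 1:
        dists = dists.reshape(-1, 1)
    counts = [len(tree.query_ball_point(p, r=radius_um)) for p in psd]
    for row, pid, cnt in zip(dists, ids, counts):
        padded = kk < k
        dlist = list(map(float, row)) + [float("nan")] * (k - kk)
        tables.append(NeighborTable(pid, dlist, int(cnt), padded=padded,
                                    is_rotated_control=is_rotated_control))
    return tables


# ---------------------------------------------------------------------------
# edge–edge distances

@dataclass
class EdgeNeighborTable:
    psd_id: int
    n_astro_within: int


def _boundaries(labels: np.ndarray) -> dict[int, np.ndarray]:
    """Boundary pixel coordinates (row, col) per label."""
    out = {}
    # per-label erosion keeps internal boundaries between touching
    # labels, unlike a single foreground erosion
    for lab in np.unique(labels):
        if lab == 0:
            continue
        m = labels == lab
        b = m & ~ndimage.binary_erosion(m, border_value=0)
        out[int(lab)] = np.column_stack(np.nonzero(b))
    return out


def edge_edge_count(
    psd_labels: np.ndarray,
    astro_labels: np.ndarray,
    pixel_size_nm: float,
    max_nm: float = 200.0,
) -> list[EdgeNeighborTable]:
    """Count astro objects within an edge–edge distance of each PSD.

    The edge–edge distance between two objects is 0 when their masks
    share a pixel, otherwise the minimum distance between the centres of
    their boundary pixels.  The window is a closed boundary (≤ max_nm).
    Both label images must share a pixel grid.
    """
    if psd_labels.shape != astro_labels.shape:
        raise FrameMismatchError("label images must share a pixel grid")
    psd_b = _boundaries(psd_labels)
    astro_b = _boundaries(astro_labels)
    counts = {pid: 0 for pid in psd_b}
    reach_px = max_nm / pixel_size_nm
    for aid, ab in astro_b.items():
        a_mask_idx = np.nonzero(astro_labels == aid)
        overlapping = np.unique(psd_labels[a_mask_idx])
        overlapping = set(int(x) for x in overlapping if x > 0)
        amin = ab.min(axis=0)
        amax = ab.max(axis=0)
        for pid, pb in psd_b.items():
            if pid in overlapping:
                counts[pid] += 1
                continue
            # bounding-box prefilter
            pmin = pb.min(axis=0)
            pmax = pb.max(axis=0)
            gap = np.maximum(pmin - amax, amin - pmax).clip(min=0)
            if np.hypot(*gap) > reach_px:
                continue
            d = cdist(ab, pb).min() * pixel_size_nm
            if d <= max_nm:
                counts[pid] += 1
    return [EdgeNeighborTable(pid, n) for pid, n in sorted(counts.items())]


# ---------------------------------------------------------------------------
# rotated control

def rotate_mask(pixels: np.ndarray) -> np.ndarray:
    """180° rotation about the frame centre: (r, c) → (H−1−r, W−1−c)."""
    return pixels[::-1, ::-1].copy()


def rotate_points(points_um: np.ndarray,
                  field_size_um: Sequence[float]) -> np.ndarray:
    """180° rotation of physical points: (x, y) → (W − x, H − y)."""
    pts = np.asarray(points_um, dtype=float).reshape(-1, 2)
    w, h = field_size_um
    return np.column_stack([w - pts[:, 0], h - pts[:, 1]])


def null_comparison(
    true_tables: Sequence[NeighborTable],
    rotated_tables: Sequence[NeighborTable],
) -> dict:
    """Paired summary of the true analysis versus the rotated control.

    Both inputs must cover the same PSD set with identical parameters.
    Reports the mean count-within-radius and the mean of the per-PSD
    mean 10-NN distances for each arm, their paired differences, and the
    effect direction (true association exceeds the null when the count
    difference is positive and the distance difference negative).
    """
    if len(true_tables) != len(rotated_tables):
        raise ParameterError("true and rotated tables must pair one-to-one")
    t_ids = [t.psd_id for t in true_tables]
    r_ids = [t.psd_id for t in rotated_tables]
    if t_ids != r_ids:
        raise ParameterError("true and rotated tables cover different PSDs")

    t_counts = np.array([t.count_within_radius for t in true_tables], float)
    r_counts = np.array([t.count_within_radius for t in rotated_tables], float)
    t_nn = np.array([t.mean_nn_um for t in true_tables], float)
    r_nn = np.array([t.mean_nn_um for t in rotated_tables], float)

    def _nanmean(a):
        a = a[np.isfinite(a)]
        return float(a.mean()) if a.size else float("nan")

    summary = {
        "n_psds": len(true_tables),
        "mean_count_true": _nanmean(t_counts),
        "mean_count_rotated": _nanmean(r_counts),
        "count_diff": _nanmean(t_counts) - _nanmean(r_counts),
        "mean_nn_true_um": _nanmean(t_nn),
        "mean_nn_rotated_um": _nanmean(r_nn),
        "nn_diff_um": _nanmean(t_nn) - _nanmean(r_nn),
    }
    summary["direction"] = (
        "true_exceeds_null" if summary["count_diff"] > 0 else
        ("null_exceeds_true" if summary["count_diff"] < 0 else "no_difference")
    )
    return summary
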