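"""2D lacuno-canalicular network quantification on silver-stained fields.

Stages:

* :func:`binarize_lcn` -- stain segmentation inside the bone ROI, with
  lacuna bodies (thick blobs) and cement lines (very long, thin,
  low-curvature components) removed so only the fine network remains.
* :func:`lcn_area_fraction` -- network area as a percentage of bone area.
* :func:`trace_canaliculi` -- skeleton-based tracing of unbranched
  canaliculi emanating from selected lacunae; geodesic path length.
* :func:`orientation_analysis` -- per-component major-axis angles from
  the vertical and the fraction within an angular window, after aligning
  the field so the mean lacunar long axis is horizontal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import disk, skeletonize

from .core import Field2D, wrap_angle_deg

log = logging.getLogger(__name__)

_SQRT2 = math.sqrt(2.0)


@dataclass
class LcnSegmentation:
    """Binarization result: the network mask plus the removed structures."""

    network: np.ndarray  # fine LCN, bodies and cement lines removed
    bodies: np.ndarray  # lacuna bodies (as detected, undilated)
    bodies_grown: np.ndarray  # bodies + guard ring (excluded from bone area)
    roi: np.ndarray
    threshold: float
    pixel_size_um: float


def binarize_lcn(
    field: Field2D,
    threshold: float | str = "auto",
    body_opening_radius_px: int = 3,
    body_guard_px: int = 2,
    remove_cement_lines: bool = True,
    cement_min_length_frac: float = 0.6,
    cement_min_eccentricity: float = 0.995,
) -> LcnSegmentation:
    """Segment the stained network inside the bone ROI.

    The stain is dark on light bone; pixels below the threshold (Otsu in
    ``"auto"`` mode) are stain. Lacuna bodies are recovered by a
    morphological opening with a disk wider than a canaliculus and removed
    together with a guard ring of ``body_guard_px`` (stain just outside the
    detected body belongs to the body boundary, not the network). Components longer than
    ``cement_min_length_frac`` of the field width with near-unit
    eccentricity are flagged as cement lines and removed.
    """
    roi = field.roi_mask()
    if not roi.any():
        raise ValueError("empty bone ROI")
    gray = field.grayscale()
    if threshold == "auto":
        thr = float(threshold_otsu(gray[roi]))
    else:
        thr = float(threshold)
    stain = (gray < thr) & roi
    bodies = ndimage.binary_opening(stain, structure=disk(body_opening_radius_px))
    bodies_grown = ndimage.binary_dilation(bodies, structure=disk(body_guard_px))
    network = stain & ~bodies_grown
    if remove_cement_lines and network.any():
        labels = sk_label(network, connectivity=2)
        min_len = cement_min_length_frac * network.shape[1]
        drop = [
            p.label
            for p in regionprops(labels)
            if p.axis_major_length > min_len
            and p.eccentricity >= cement_min_eccentricity
        ]
        if drop:
            network = network & ~np.isin(labels, drop)
    return LcnSegmentation(
        network=network,
        bodies=bodies,
        bodies_grown=bodies_grown,
        roi=roi,
        threshold=thr,
        pixel_size_um=field.pixel_size_um,
    )


def lcn_area_fraction(seg: LcnSegmentation) -> float:
    """Network area as a percentage of bone area (ROI minus lacuna bodies)."""
    denom = int((seg.roi & ~seg.bodies_grown).sum())
    if denom <= 0:
        raise ValueError("zero bone area after removing lacuna bodies")
    return 100.0 * float(seg.network.sum()) / denom


# ---------------------------------------------------------------------------
# Canaliculus tracing
# ---------------------------------------------------------------------------

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_neighbor_count(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant")


def _walk_branch(
    skel: np.ndarray,
    nb_count: np.ndarray,
    start: tuple[int, int],
    came_from: set[tuple[int, int]],
    stop_at_branch: bool,
    max_steps: int = 100_000,
) -> tuple[float, tuple[int, int], list[tuple[int, int]]]:
    """Follow the skeleton from `start` until a branch point or endpoint.

    Returns (path length in pixels, final pixel, path). With
    ``stop_at_branch=False`` the walk continues through branch points
    along the most collinear neighbor (full visible projection).
    """
    h, w = skel.shape
    path = [start]
    visited = set(came_from) | {start}
    length = 0.0
    cur = start
    prev_dir: tuple[int, int] | None = None
    for _ in range(max_steps):
        cands = []
        for dr, dc in _NEIGHBORS:
            r, c = cur[0] + dr, cur[1] + dc
            if 0 <= r < h and 0 <= c < w and skel[r, c] and (r, c) not in visited:
                cands.append((r, c))
        if not cands:
            break
        if len(cands) > 1 or (nb_count[cur] > 2 and len(path) > 1):
            if stop_at_branch:
                break
            if prev_dir is not None:  # pick the most collinear continuation
                cands.sort(
                    key=lambda p: -(
                        (p[0] - cur[0]) * prev_dir[0] + (p[1] - cur[1]) * prev_dir[1]
                    )
                )
        nxt = cands[0]
        step = (nxt[0] - cur[0], nxt[1] - cur[1])
        length += _SQRT2 if step[0] and step[1] else 1.0
        prev_dir = step
        visited.add(nxt)
        path.append(nxt)
        cur = nxt
    return length, cur, path


def trace_canaliculi(
    seg: LcnSegmentation,
    n_lacunae: int = 3,
    selection: str = "center",
    rng: np.random.Generator | None = None,
    stop_at_branch: bool = True,
    min_length_px: float = 3.0,
) -> pd.DataFrame:
    """Trace unbranched canaliculi from selected lacunae.

    The network is skeletonized; for each selected lacuna every skeleton
    branch emanating from its boundary is followed to its first branch
    point (or endpoint with ``stop_at_branch=False``). Path length is the
    geodesic step sum (1 px orthogonal, sqrt(2) px diagonal) times the
    pixel size. Selection is the ``n_lacunae`` bodies nearest the field
    centroid that have at least one emanating branch (``"center"``,
    deterministic) or a seeded random draw (``"random"``).

    Returns a DataFrame with ``lacuna_id``, ``length_um``, ``angle_deg``
    (end-to-end direction from the vertical, clockwise-positive).
    """
    skel = skeletonize(seg.network)
    nb_count = _skeleton_neighbor_count(skel)
    body_labels = sk_label(seg.bodies, connectivity=2)
    props = regionprops(body_labels)
    if not props:
        log.warning("no lacuna bodies detected; nothing to trace")
        return pd.DataFrame(columns=["lacuna_id", "length_um", "angle_deg"])

    h, w = skel.shape

    # candidate lacunae with at least one emanating skeleton pixel; the
    # attachment band is a ~3 px shell just outside the removed body region
    candidates = []
    for p in props:
        body = body_labels == p.label
        inner = ndimage.binary_dilation(body, structure=disk(3))
        band = ndimage.binary_dilation(inner, structure=disk(3)) & ~inner
        roots = skel & band & ~seg.bodies_grown
        if roots.any():
            candidates.append((p, roots))
    if not candidates:
        log.warning("no lacuna has an emanating canaliculus")
        return pd.DataFrame(columns=["lacuna_id", "length_um", "angle_deg"])
    if len(candidates) < n_lacunae:
        log.warning(
            "only %d lacunae with canaliculi available (%d requested)",
            len(candidates),
            n_lacunae,
        )
    if selection == "center":
        fc = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        candidates.sort(key=lambda t: float(np.hypot(*(np.array(t[0].centroid) - fc))))
        chosen = candidates[:n_lacunae]
    elif selection == "random":
        rng = rng if rng is not None else np.random.default_rng(0)
        idx = rng.choice(len(candidates), min(n_lacunae, len(candidates)), replace=False)
        chosen = [candidates[i] for i in sorted(idx)]
    else:
        raise ValueError("selection must be 'center' or 'random'")

    rows = []
    for p, roots in chosen:
        # one root group (= one emanating branch) per canaliculus; walk
        # outward from the group's outermost pixel
        body_dist = ndimage.distance_transform_edt(body_labels != p.label)
        group_labels = sk_label(roots, connectivity=2)
        for g in range(1, int(group_labels.max()) + 1):
            gpix = list(zip(*np.nonzero(group_labels == g)))
            start = max(gpix, key=lambda q: body_dist[q])
            length, end, _path = _walk_branch(
                skel, nb_count, start, set(gpix), stop_at_branch
            )
            if length < min_length_px:
                continue
            # measure from the lacuna boundary: add the straight-line gap
            # between the walk start and the detected body
            length += float(body_dist[start])
            dr = end[0] - start[0]
            dc = end[1] - start[1]
            angle = wrap_angle_deg(math.degrees(math.atan2(dc, -dr)))
            rows.append(
                {
                    "lacuna_id": int(p.label),
                    "length_um": length * seg.pixel_size_um,
                    "angle_deg": float(angle),
                }
            )
    return pd.DataFrame(rows, columns=["lacuna_id", "length_um", "angle_deg"])


# ---------------------------------------------------------------------------
# Orientation statistic
# ---------------------------------------------------------------------------

def _angle_from_vertical_deg(orientation_rad: float) -> float:
    """Map a regionprops orientation to degrees from the image vertical,
    clockwise-positive, in (-90, 90]."""
    return float(wrap_angle_deg(-math.degrees(orientation_rad)))


def _axial_mean_deg(angles_deg: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Mean of axial (mod-180) angles via the doubled-angle circular mean."""
    a = np.radians(np.asarray(angles_deg, dtype=float) * 2.0)
    if weights is None:
        weights = np.ones_like(a)
    s = float(np.sum(weights * np.sin(a)))
    c = float(np.sum(weights * np.cos(a)))
    return math.degrees(math.atan2(s, c)) / 2.0


def lamellar_tilt_deg(seg: LcnSegmentation) -> float:
    """Tilt of the mean lacunar long axis from the horizontal (degrees).

    Fields are acquired with lamellae roughly horizontal; any residual
    tilt is removed before assessing canaliculus alignment.
    """
    props = regionprops(sk_label(seg.bodies, connectivity=2))
    if not props:
        return 0.0
    ang = np.array([_angle_from_vertical_deg(p.orientation) for p in props])
    wts = np.array([p.area for p in props], dtype=float)
    mean_from_vertical = _axial_mean_deg(ang, wts)
    return float(wrap_angle_deg(mean_from_vertical - 90.0))


def orientation_analysis(
    seg: LcnSegmentation,
    window_deg: float = 20.0,
    align_to_lamellae: bool = True,
    min_component_px: int = 5,
) -> tuple[float, pd.DataFrame]:
    """Fraction of canaliculi aligned within ``window_deg`` of the vertical.

    Each network component's major-axis angle from the vertical is taken
    from its second moments; the field's residual lamellar tilt (from the
    lacuna bodies) is subtracted so "vertical" means perpendicular to the
    lamellae. Returns ``(aligned_fraction, per-component table)``;
    the fraction is NaN when no components are usable.
    """
    if not 0.0 < window_deg < 90.0:
        raise ValueError("window_deg must lie in (0, 90)")
    labels = sk_label(seg.network, connectivity=2)
    props = [p for p in regionprops(labels) if p.area >= min_component_px]
    if not props:
        return float("nan"), pd.DataFrame(columns=["label", "angle_deg", "aligned"])
    tilt = lamellar_tilt_deg(seg) if align_to_lamellae else 0.0
    rows = []
    for p in props:
        raw = _angle_from_vertical_deg(p.orientation)
        adj = float(wrap_angle_deg(raw - tilt))
        rows.append(
            {"label": p.label, "angle_deg": adj, "aligned": abs(adj) <= window_deg}
        )
    table = pd.DataFrame(rows, columns=["label", "angle_deg", "aligned"])
    return float(table["aligned"].mean()), table


# ---------------------------------------------------------------------------
# Per-field convenience
# ---------------------------------------------------------------------------

@dataclass
class FieldAnalysis:
    seg: LcnSegmentation
    traces: pd.DataFrame
    area_fraction_pct: float
    mean_length_um: float
    aligned_fraction: float
    orientation_table: pd.DataFrame = dc_field(repr=False, default=None)


def analyze_field(
    field: Field2D,
    threshold: float | str = "auto",
    window_deg: float = 20.0,
    n_lacunae: int = 3,
    stop_at_branch: bool = True,
) -> FieldAnalysis:
    """Run binarization, area fraction, tracing and orientation on a field."""
    seg = binarize_lcn(field, threshold=threshold)
    traces = trace_canaliculi(seg, n_lacunae=n_lacunae, stop_at_branch=stop_at_branch)
    area = lcn_area_fraction(seg)
    mean_len = float(traces["length_um"].mean()) if len(traces) else float("nan")
    aligned, otab = orientation_analysis(seg, window_deg=window_deg)
    return FieldAnalysis(seg, traces, area, mean_len, aligned, otab)
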