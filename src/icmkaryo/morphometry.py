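"""Chromosome segmentation, medial-axis morphometry and classification.

Chromosomes are segmented from the OD map by Otsu thresholding and
connected components, with a distance-transform watershed to split merged
objects.  Each object is reduced to its medial axis (longest skeleton
path); the width profile along the axis locates the primary constriction
(centromere) as the deepest interior width minimum, and optionally a
secondary (NOR) constriction on the short arm whose distal segment is the
satellite.  Pixels are partitioned into short arm (S), long arm (L) and
satellite (SAT) by the side of the centromere their nearest axis point
falls on; arm lengths, the arm ratio r = L/S, the centromeric index
CI = 100*S/(S+L) and the Levan-style class (M/m/sm/st/t thresholds as
revised by Guerra) follow from the partition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import find_peaks
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize
from skimage.segmentation import watershed

from .densitometry import ODMap
from .errors import AxisError, NoConstrictionError, SegmentationError, ValidationError
from .sizing import integrate_iod

#: Guerra-revision class thresholds on the arm ratio r = L/S (upper bounds).
DEFAULT_CLASS_TABLE = ((1.0, "M"), (1.5, "m"), (3.0, "sm"), (7.0, "st"), (float("inf"), "t"))

#: Components larger than this multiple of the median area get watershed-split.
SPLIT_AREA_FACTOR = 1.6


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _watershed_split(mask: np.ndarray, min_area_px: int) -> list[np.ndarray]:
    """Split a merged component on its distance transform.

    Markers are the connected regions where the distance transform exceeds
    0.6x its component maximum: the contact waist between touching
    chromosomes falls below that threshold while constriction dips (~40%
    width loss over a wide Gaussian) stay above it and do not fragment a
    single chromosome.
    """
    edt = ndi.distance_transform_edt(mask)
    markers, n_mark = ndi.label(edt >= 0.6 * edt.max())
    if n_mark < 2:
        return [mask]
    labels = watershed(-edt, markers, mask=mask)
    parts = []
    for lab in range(1, n_mark + 1):
        part = labels == lab
        if part.sum() >= min_area_px:
            parts.append(part)
    return parts or [mask]


def segment_chromosomes(
    od_map,
    min_area_px: int = 50,
    max_objects: int | None = None,
    expected_count: int | None = None,
) -> list[np.ndarray]:
    """Segment individual chromosomes from an OD map.

    Global Otsu threshold on OD -> connected components -> watershed split
    of components whose area exceeds 1.6x the median -> size filter.
    Returns boolean masks ordered by centroid (row, then column) for
    determinism.  Raises ``SegmentationError`` when nothing is found; warns
    when ``expected_count`` is given and not met.
    """
    od = od_map.od if isinstance(od_map, ODMap) else np.asarray(od_map, dtype=float)
    if not np.isfinite(od).all():
        raise ValidationError("OD map contains non-finite values")
    if np.ptp(od) == 0:
        raise SegmentationError("no objects: OD map is constant")
    binary = od > threshold_otsu(od)
    labels, n = ndi.label(binary)
    if n == 0:
        raise SegmentationError("no objects above the OD threshold")
    comps = [labels == i for i in range(1, n + 1)]
    comps = [c for c in comps if c.sum() >= min_area_px]
    if not comps:
        raise SegmentationError("no objects above the minimum area")
    areas = np.array([c.sum() for c in comps])
    median_area = np.median(areas)
    masks: list[np.ndarray] = []
    for comp, area in zip(comps, areas):
        if area > SPLIT_AREA_FACTOR * median_area:
            masks.extend(_watershed_split(comp, min_area_px))
        else:
            masks.append(comp)
    masks = [m for m in masks if m.sum() >= min_area_px]
    if not masks:
        raise SegmentationError("no objects above the minimum area")

    def _centroid(m):
        r, c = np.nonzero(m)
        return (float(r.mean()), float(c.mean()))

    masks.sort(key=_centroid)
    if max_objects is not None and len(masks) > max_objects:
        masks = sorted(masks, key=lambda m: -m.sum())[:max_objects]
        masks.sort(key=_centroid)
    if expected_count is not None and len(masks) != expected_count:
        warnings.warn(
            f"segmented {len(masks)} objects, expected {expected_count}"
        )
    return masks


# ---------------------------------------------------------------------------
# Medial axis
# ---------------------------------------------------------------------------

@dataclass
class AxisProfile:
    """Smoothed medial axis with width profile and arc lengths."""

    points: np.ndarray  # (n, 2) float (row, col)
    width_um: np.ndarray  # (n,)
    arc_um: np.ndarray  # (n,) cumulative arc length from the first point
    end_caps_um: tuple[float, float]  # tip extrapolation at each end
    total_length_um: float  # tip-to-tip

    def __len__(self):
        return len(self.points)


_NEIGH_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

#: Centerline-pull strength: pixels with a small distance-transform value
#: (mask edges, corner shortcuts) are expensive to traverse.
_RIDGE_PENALTY = 4.0


def _mask_graph(mask: np.ndarray, edt: np.ndarray):
    """8-connected pixel graph of a mask with ridge-weighted edge costs."""
    from scipy.sparse import csr_matrix

    H, W = mask.shape
    node_id = np.full((H, W), -1, dtype=np.int32)
    pts = np.argwhere(mask)
    node_id[pts[:, 0], pts[:, 1]] = np.arange(len(pts))
    rows, cols, w_euclid, w_ridge = [], [], [], []
    inv = 1.0 / np.clip(edt, 0.5, None)
    rr_all, cc_all = pts[:, 0], pts[:, 1]
    for dr, dc in _NEIGH_OFFSETS:
        r2, c2 = rr_all + dr, cc_all + dc
        ok = (r2 >= 0) & (r2 < H) & (c2 >= 0) & (c2 < W)
        r1, c1 = rr_all[ok], cc_all[ok]
        r2, c2 = r2[ok], c2[ok]
        keep = mask[r2, c2]
        r1, c1, r2, c2 = r1[keep], c1[keep], r2[keep], c2[keep]
        step = math.hypot(dr, dc)
        rows.append(node_id[r1, c1])
        cols.append(node_id[r2, c2])
        w_euclid.append(np.full(len(r1), step))
        w_ridge.append(
            step * (1.0 + _RIDGE_PENALTY * 0.5 * (inv[r1, c1] + inv[r2, c2]))
        )
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    g_euclid = csr_matrix(
        (np.concatenate(w_euclid), (rows, cols)), shape=(len(pts), len(pts))
    )
    g_ridge = csr_matrix(
        (np.concatenate(w_ridge), (rows, cols)), shape=(len(pts), len(pts))
    )
    return pts, g_euclid, g_ridge


def _centerline_path(mask: np.ndarray, edt: np.ndarray) -> np.ndarray:
    """Tip-to-tip centerline: ridge-weighted geodesic between the two
    geodesically farthest mask pixels."""
    from scipy.sparse.csgraph import dijkstra

    pts, g_euclid, g_ridge = _mask_graph(mask, edt)
    d0 = dijkstra(g_euclid, directed=False, indices=0)
    a = int(np.argmax(np.where(np.isfinite(d0), d0, -1.0)))
    da = dijkstra(g_euclid, directed=False, indices=a)
    b = int(np.argmax(np.where(np.isfinite(da), da, -1.0)))
    _, pred = dijkstra(
        g_ridge, directed=False, indices=a, return_predecessors=True
    )
    path = [b]
    while pred[path[-1]] >= 0:
        path.append(int(pred[path[-1]]))
    if path[-1] != a:
        raise AxisError("mask graph is not connected along the axis")
    return pts[np.array(path[::-1])]


def medial_axis_profile(mask: np.ndarray, um_per_px: float) -> AxisProfile:
    """Extract the medial axis, width profile and tip-to-tip length.

    The axis is the ridge-weighted geodesic between the two farthest mask
    pixels: it spans the chromosome tip to tip (crossing the narrow neck of
    a secondary constriction into the satellite, which a plain skeleton
    does not reach) while hugging the centerline.  The width at each axis
    point is twice the distance-transform value.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndi.label(mask)
    if n != 1:
        raise AxisError(f"mask must be a single connected component (got {n})")
    if mask.sum() < 50:
        raise AxisError("mask too small for axis extraction (< 50 px)")
    edt = ndi.distance_transform_edt(mask)
    full = _centerline_path(mask, edt).astype(float)
    if len(full) < 5:
        raise AxisError("ambiguous axis: centerline path too short")
    win = min(7, len(full))
    smooth = np.stack(
        [ndi.uniform_filter1d(full[:, k], win, mode="nearest") for k in range(2)],
        axis=1,
    )
    ij = np.clip(
        np.rint(full).astype(int),
        0,
        np.array(mask.shape) - 1,
    )
    width = 2.0 * edt[ij[:, 0], ij[:, 1]] * um_per_px
    width = ndi.uniform_filter1d(width, min(5, len(width)), mode="nearest")
    # arc length as raw steps projected on the local tangent of a heavily
    # smoothed path: pixel-lattice zigzag (and the diagonal run a geodesic
    # takes into a square corner) contributes only its axial advance
    heavy = np.stack(
        [ndi.uniform_filter1d(full[:, k], min(15, len(full)), mode="nearest")
         for k in range(2)],
        axis=1,
    )
    tang = np.gradient(heavy, axis=0)
    tang /= np.clip(np.linalg.norm(tang, axis=1, keepdims=True), 1e-9, None)
    # end tangents are unreliable where the path leaves the midline (a
    # geodesic enters a square tip diagonally); within one cap radius of
    # each end, use the chord direction of the adjacent interior stretch
    edt_path = edt[ij[:, 0], ij[:, 1]]
    r_cap = int(math.ceil(edt_path.max()))
    n_pts = len(full)
    if n_pts > 3 * r_cap and r_cap >= 2:
        a, b = r_cap, min(r_cap + 10, n_pts - 1)
        chord0 = heavy[b] - heavy[a]
        chord0 /= max(np.linalg.norm(chord0), 1e-9)
        tang[:a] = chord0
        a, b = n_pts - 1 - r_cap, max(n_pts - 1 - r_cap - 10, 0)
        chord1 = heavy[a] - heavy[b]
        chord1 /= max(np.linalg.norm(chord1), 1e-9)
        tang[a + 1 :] = chord1
    tmid = tang[:-1] + tang[1:]
    tmid /= np.clip(np.linalg.norm(tmid, axis=1, keepdims=True), 1e-9, None)
    steps = np.abs((np.diff(full, axis=0) * tmid).sum(axis=1)) * um_per_px
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    cap0 = float(edt[ij[0, 0], ij[0, 1]]) * um_per_px
    cap1 = float(edt[ij[-1, 0], ij[-1, 1]]) * um_per_px
    return AxisProfile(smooth, width, arc, (cap0, cap1), float(arc[-1] + cap0 + cap1))


# ---------------------------------------------------------------------------
# Constriction localization
# ---------------------------------------------------------------------------

def locate_centromere(
    width_profile, search_frac: float = 0.6, min_dip_frac: float = 0.05
) -> int:
    """Index of the primary constriction: the central width minimum.

    Takes the global minimum of the width profile restricted to the central
    ``search_frac`` of the axis (telomeric tapering is excluded from the
    search), then validates that it is a genuine dip: the full profile must
    rise by at least ``min_dip_frac`` relative to the minimum on *both*
    sides.  Flat profiles and monotone wedges raise
    ``NoConstrictionError``.
    """
    w = np.asarray(
        width_profile.width_um if isinstance(width_profile, AxisProfile) else width_profile,
        dtype=float,
    )
    n = len(w)
    if n < 10:
        raise ValidationError("width profile too short (< 10 samples)")
    lo = int(n * (0.5 - search_frac / 2.0))
    hi = int(np.ceil(n * (0.5 + search_frac / 2.0)))
    seg = w[lo:hi]
    amin = int(np.argmin(seg))
    # centre on the dip plateau: smoothing flattens the bottom of the dip
    tol = 0.01
    i0 = j0 = amin
    while i0 > 0 and seg[i0 - 1] <= seg[amin] + tol:
        i0 -= 1
    while j0 < len(seg) - 1 and seg[j0 + 1] <= seg[amin] + tol:
        j0 += 1
    idx = int(lo + (i0 + j0) // 2)
    wmin = w[idx]
    rise = (1.0 + min_dip_frac) * wmin
    if not (w[: idx + 1].max() >= rise and w[idx:].max() >= rise):
        raise NoConstrictionError(
            f"no constriction: width profile lacks a >= {100 * min_dip_frac:.0f}% "
            "dip interior to the axis"
        )
    return idx


def locate_secondary_constriction(
    width_profile: AxisProfile,
    centromere_index: int,
    enabled: bool | None = None,
    min_depth_frac: float = 0.5,
    exclusion_um: float = 1.0,
) -> int | None:
    """Index of the secondary (NOR) constriction on the short arm, if any.

    Only dips on the short-arm side are considered (the satellite sits on
    the short arm), excluding a ``exclusion_um`` neighbourhood of the
    centromere.  With ``enabled=None`` the detection is automatic: a dip
    qualifies when its depth below the median width is at least
    ``min_depth_frac`` of the primary constriction's depth.  Returns None
    when absent or when ``enabled`` is False.
    """
    if enabled is False:
        return None
    w = width_profile.width_um
    arc = width_profile.arc_um
    caps = width_profile.end_caps_um
    len0 = arc[centromere_index] + caps[0]
    len1 = arc[-1] - arc[centromere_index] + caps[1]
    short_first = len0 <= len1
    w_med = float(np.median(w))
    primary_depth = w_med - w[centromere_index]
    if primary_depth <= 0:
        return None
    if short_first:
        sel = arc < arc[centromere_index] - exclusion_um
    else:
        sel = arc > arc[centromere_index] + exclusion_um
    if not sel.any():
        return None
    offset = int(np.argmax(sel))  # selection is a contiguous prefix or suffix
    region = w[sel]
    if len(region) < 5:
        return None
    dips, _ = find_peaks(-region, prominence=0.05 * w_med)
    best = None
    for d in dips:
        depth = w_med - region[d]
        if depth >= min_depth_frac * primary_depth:
            if best is None or region[d] < region[best]:
                best = d
    if best is None:
        return None
    return int(best + offset)


# ---------------------------------------------------------------------------
# Arm partition
# ---------------------------------------------------------------------------

def partition_arms(
    mask: np.ndarray,
    axis: AxisProfile,
    centromere_index: int,
    sat_index: int | None = None,
) -> dict[str, np.ndarray]:
    """Partition a chromosome mask into arm submasks at the centromere.

    Each pixel joins the side of the centromere on which its nearest medial
    axis point lies (locally the perpendicular cut through the centromere,
    but robust on curved chromosomes).  With a secondary constriction the
    segment distal to it on the short-arm side becomes SAT.  Arms are
    labelled geometrically as ``a`` (axis start side) and ``b`` here;
    S/L assignment by length is done by the caller.  The submasks are
    disjoint and cover the mask exactly.
    """
    n = len(axis)
    if centromere_index <= 0 or centromere_index >= n - 1:
        raise ValidationError("centromere must be strictly interior to the axis")
    if sat_index is not None and not (0 <= sat_index < n):
        raise ValidationError("satellite boundary outside the axis")
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    tree = cKDTree(axis.points)
    _, nearest = tree.query(np.stack([rows, cols], axis=1).astype(float))
    out: dict[str, np.ndarray] = {}

    def _sub(sel):
        m = np.zeros(mask.shape, dtype=bool)
        m[rows[sel], cols[sel]] = True
        return m

    side_a = nearest < centromere_index
    sat_sel = np.zeros(len(nearest), dtype=bool)
    if sat_index is not None:
        sat_sel = nearest < sat_index if sat_index < centromere_index else nearest > sat_index
        out["SAT"] = _sub(sat_sel)
    out["a"] = _sub(side_a & ~sat_sel)
    out["b"] = _sub(~side_a & ~sat_sel)
    return out


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_class(arm_ratio: float, thresholds=DEFAULT_CLASS_TABLE) -> str:
    """Levan-style chromosome class from the arm ratio r = L/S.

    Default thresholds (Guerra revision): M at r = 1.00 exactly, m for
    1 < r < 1.5, sm for 1.5 <= r < 3, st for 3 <= r < 7, t for r >= 7.
    """
    if arm_ratio < 1.0 - 1e-9:
        raise ValidationError("arm ratio < 1: arms are mislabelled (L must be >= S)")
    for bound, label in thresholds:
        if arm_ratio <= bound if label == "M" else arm_ratio < bound:
            return label
    return thresholds[-1][1]


# ---------------------------------------------------------------------------
# Knob detection
# ---------------------------------------------------------------------------

@dataclass
class KnobBand:
    """A detected high-linear-density block along the axis."""

    start_index: int
    stop_index: int
    start_um: float
    stop_um: float
    peak_ratio: float  # peak linear density / chromosome median


def knob_band_profile(
    od_map,
    mask: np.ndarray,
    axis: AxisProfile,
    factor: float = 1.3,
    min_length_um: float = 0.5,
) -> list[KnobBand]:
    """Detect heterochromatic knob bands from the axial linear OD density.

    The OD mass of each pixel is assigned to its nearest axis sample; the
    resulting per-unit-length density profile is lightly smoothed and runs
    exceeding ``factor`` x the chromosome's median density for at least
    ``min_length_um`` are reported as bands.
    """
    od = od_map.od if isinstance(od_map, ODMap) else np.asarray(od_map, dtype=float)
    a_px = od_map.pixel_area_um2 if isinstance(od_map, ODMap) else 1.0
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    tree = cKDTree(axis.points)
    _, nearest = tree.query(np.stack([rows, cols], axis=1).astype(float))
    n = len(axis)
    od_per_sample = np.bincount(nearest, weights=od[rows, cols] * a_px, minlength=n)
    ds = np.gradient(axis.arc_um)
    ds = np.clip(ds, 1e-9, None)
    density = ndi.uniform_filter1d(od_per_sample / ds, min(7, n), mode="nearest")
    med = float(np.median(density))
    if med <= 0:
        return []
    above = density > factor * med
    bands: list[KnobBand] = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if axis.arc_um[j] - axis.arc_um[i] >= min_length_um:
                bands.append(
                    KnobBand(
                        i, j, float(axis.arc_um[i]), float(axis.arc_um[j]),
                        float(density[i : j + 1].max() / med),
                    )
                )
            i = j + 1
        else:
            i += 1
    return bands


# ---------------------------------------------------------------------------
# Per-chromosome measurement
# ---------------------------------------------------------------------------

@dataclass
class ChromosomeMeasurement:
    """All morphometric and densitometric descriptors of one chromosome."""

    mask: np.ndarray
    axis: AxisProfile
    centromere_index: int
    sat_index: int | None
    arm_masks: dict  # portion -> bool mask (S, L, optional SAT)
    lengths_um: dict  # portion -> length
    total_length_um: float
    area_um2: float
    mean_od: float
    iod: float
    arm_stats: dict  # portion -> IODResult
    flags: tuple = ()
    source_id: str | None = None
    pair_id: int | None = None  # filled by pairing / ground-truth matching

    @property
    def short_um(self) -> float:
        return self.lengths_um["S"]

    @property
    def long_um(self) -> float:
        return self.lengths_um["L"]

    @property
    def arm_ratio(self) -> float:
        return self.long_um / self.short_um

    @property
    def ci(self) -> float:
        """Centromeric index, 100*S/(S+L)."""
        return 100.0 * self.short_um / (self.short_um + self.long_um)

    @property
    def chromosome_class(self) -> str:
        return classify_class(self.arm_ratio)


@dataclass
class MorphoSummary:
    """Classification summary of one chromosome or pair."""

    arm_ratio: float
    ci: float
    label: str
    relative_length_pct: float | None = None


def summarize(measurement: ChromosomeMeasurement, complement_length_um: float | None = None):
    rel = (
        100.0 * measurement.total_length_um / complement_length_um
        if complement_length_um
        else None
    )
    return MorphoSummary(
        measurement.arm_ratio, measurement.ci, measurement.chromosome_class, rel
    )


def measure_chromosome(
    od_map: ODMap,
    mask: np.ndarray,
    source_id: str | None = None,
    detect_satellite: bool | None = None,
) -> ChromosomeMeasurement:
    """Measure one segmented chromosome end to end.

    Extracts the medial axis, locates the centromere (and optionally a
    secondary constriction whose distal segment becomes the satellite),
    partitions the mask into arms, labels the shorter arm S (ties broken by
    the lower IOD), and integrates area / mean OD / IOD per portion.  The
    per-portion IODs sum to the chromosome IOD exactly.
    """
    axis = medial_axis_profile(mask, od_map.pixel_size_um)
    cen = locate_centromere(axis)
    sat = locate_secondary_constriction(axis, cen, enabled=detect_satellite)
    parts = partition_arms(mask, axis, cen, sat)
    arc, caps = axis.arc_um, axis.end_caps_um

    len_a = arc[cen] + caps[0]
    len_b = arc[-1] - arc[cen] + caps[1]
    sat_len = 0.0
    if sat is not None:
        if sat < cen:
            sat_len = arc[sat] + caps[0]
            len_a = arc[cen] - arc[sat]
        else:
            sat_len = arc[-1] - arc[sat] + caps[1]
            len_b = arc[sat] - arc[cen]

    stats_a = integrate_iod(od_map, parts["a"])
    stats_b = integrate_iod(od_map, parts["b"])
    if not np.isclose(len_a, len_b, rtol=1e-9, atol=1e-9):
        a_is_short = len_a < len_b
    else:
        a_is_short = stats_a.iod <= stats_b.iod  # tie-break: lower IOD is S
    if a_is_short:
        arm_masks = {"S": parts["a"], "L": parts["b"]}
        lengths = {"S": float(len_a), "L": float(len_b)}
        arm_stats = {"S": stats_a, "L": stats_b}
    else:
        arm_masks = {"S": parts["b"], "L": parts["a"]}
        lengths = {"S": float(len_b), "L": float(len_a)}
        arm_stats = {"S": stats_b, "L": stats_a}
    if "SAT" in parts and parts["SAT"].any():
        arm_masks["SAT"] = parts["SAT"]
        lengths["SAT"] = float(sat_len)
        arm_stats["SAT"] = integrate_iod(od_map, parts["SAT"])

    area = sum(s.area_um2 for s in arm_stats.values())
    iod = sum(s.iod for s in arm_stats.values())
    mean_od = iod / area if area > 0 else 0.0
    flags = tuple(
        f"saturated-{arm}" for arm, s in arm_stats.items() if s.saturated
    )
    total_len = sum(lengths.values())
    return ChromosomeMeasurement(
        mask=mask,
        axis=axis,
        centromere_index=cen,
        sat_index=sat,
        arm_masks=arm_masks,
        lengths_um=lengths,
        total_length_um=float(total_len),
        area_um2=float(area),
        mean_od=float(mean_od),
        iod=float(iod),
        arm_stats=arm_stats,
        flags=flags,
        source_id=source_id,
    )
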