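"""Interproximal feature measurement on a segmented molar pair.

Five quantities characterize the tightness of a proximal contact and the
shape of the embrasures around it:

* **adjacent line length** ``L`` (mm) — the span of the dividing line
  between the two teeth in occlusal (horizontal) projection, measured
  between its two farthest points;
* **adjacent surface area** ``A`` (mm^2) — the area of the contact facet,
  measured on the vertical partition plane between the teeth;
* **tongue / buccal abduction gap angles** ``theta_t, theta_b``
  (degrees) — the opening angles of the lingual and buccal embrasures in
  occlusal projection;
* **occlusal abduction gap angle** ``theta_o`` (degrees) — the opening
  angle of the occlusal embrasure in mesiodistal (vertical) projection.

Contact selection uses a distance threshold ``contact_eps``: a point
belongs to the contact region when its estimated gap to the opposing
tooth (point-to-local-plane distance in 3D) is below the threshold.  Any
such rule admits a selection band of width ~ ``eps / (2 sin(theta/2))``
along the embrasures beyond the true contact, which would bias lengths
and areas outward.  Two defenses remove that bias: dividing-line ends
are refined to the intersection of the two fitted embrasure walls (a
total-least-squares fit that stays unbiased under scan jitter), and the
facet area is measured at two thresholds above the gap noise floor and
extrapolated linearly back to the floor.  Clouds whose estimated jitter
exceeds ``noise_floor`` are first denoised by moving-least-squares
projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError, cKDTree

from .geometry import (HORIZONTAL, VERTICAL, LabeledPointCloud, ProjectedCloud2D,
                       estimate_noise, project, smooth_cloud)

__all__ = [
    "MeasurementError",
    "NoContactError",
    "MeasurementConfig",
    "DividingLine",
    "FeatureRecord",
    "extract_dividing_line",
    "adjacent_line_length",
    "abduction_gap_angles",
    "occlusal_abduction_angle",
    "adjacent_surface_area",
    "polygon_area",
    "measure_all",
]


class MeasurementError(RuntimeError):
    """A feature measurement could not be completed."""


class NoContactError(MeasurementError):
    """No interproximal contact found within the configured threshold."""


@dataclass(frozen=True)
class MeasurementConfig:
    """Tunable measurement parameters (mm).

    ``contact_eps`` — gap threshold for contact selection.  0.1 mm bounds
    the clinical tight-contact criterion (feeler gauge < 60 um) with room
    for scan noise; the two-scale extrapolation keeps the measurements
    insensitive to its exact value.
    ``extension_len`` — probe distance beyond each dividing-line end used
    to construct the three-point embrasure angle; 1.5 mm stays on the
    near-planar embrasure walls of a molar while keeping the angle
    insensitive to residual jitter in the vertex and arm points.
    ``alpha`` — alpha-shape radius for the facet area; 0.5 mm bridges
    sampling gaps without swallowing real concavities.
    """

    contact_eps: float = 0.1
    extension_len: float = 1.5
    alpha: float = 0.5
    denoise: bool | str = "auto"
    noise_floor: float = 0.012

    def __post_init__(self) -> None:
        if self.contact_eps <= 0 or self.extension_len <= 0 or self.alpha <= 0:
            raise ValueError("all measurement parameters must be positive")
        if self.denoise not in (True, False, "auto"):
            raise ValueError("denoise must be True, False or 'auto'")


@dataclass
class DividingLine:
    """The contact boundary between two teeth in a 2D projection.

    ``boundary_points`` are cross-pair midpoints ordered along the line's
    principal direction; ``end_a``/``end_b`` are the two farthest boundary
    points (``end_a`` lexicographically smaller) and ``direction`` the unit
    vector from ``end_a`` to ``end_b``.
    """

    boundary_points: np.ndarray
    end_a: np.ndarray
    end_b: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.boundary_points = np.asarray(self.boundary_points, float)
        if self.boundary_points.ndim != 2 or self.boundary_points.shape[0] < 2:
            raise ValueError("a dividing line needs at least two boundary points")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end_b - self.end_a))


@dataclass
class FeatureRecord:
    """One measured molar pair: the five features plus optional group label."""

    adjacent_line_length_mm: float
    adjacent_surface_area_mm2: float
    tongue_angle_deg: float
    buccal_angle_deg: float
    occlusal_angle_deg: float
    group: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.adjacent_line_length_mm <= 0:
            raise ValueError("adjacent line length must be positive")
        if self.adjacent_surface_area_mm2 <= 0:
            raise ValueError("adjacent surface area must be positive")
        for name in ("tongue_angle_deg", "buccal_angle_deg", "occlusal_angle_deg"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"{name} must lie in (0, 180) degrees")

    def as_dict(self) -> dict[str, float]:
        return {
            "adjacent_line_length_mm": self.adjacent_line_length_mm,
            "adjacent_surface_area_mm2": self.adjacent_surface_area_mm2,
            "tongue_angle_deg": self.tongue_angle_deg,
            "buccal_angle_deg": self.buccal_angle_deg,
            "occlusal_angle_deg": self.occlusal_angle_deg,
        }


# ---------------------------------------------------------------------------
# gap estimation helpers
# ---------------------------------------------------------------------------

def _nearest_gaps_2d(p_from: np.ndarray, p_to: np.ndarray, prefilter: float,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest-cross-point gap per point of an already-2D pair.

    Returns (indices into p_from, gaps, cross-pair midpoints).  This plain
    nearest-neighbor gap suits noise-free 2D input; the 3D route used by
    :func:`measure_all` measures point-to-plane gaps on the surfaces
    instead, which stays robust under scan jitter.
    """
    tree = cKDTree(p_to)
    d, idx = tree.query(p_from)
    cand = np.flatnonzero(d <= prefilter)
    nearest = p_to[idx[cand]]
    mids = 0.5 * (p_from[cand] + nearest)
    return cand, d[cand], mids


def _plane_gaps_3d(p_from: np.ndarray, p_to: np.ndarray, prefilter: float,
                   k: int = 12) -> tuple[np.ndarray, np.ndarray]:
    """Point-to-local-plane gap from each candidate point to the opposing
    tooth surface in 3D.  Returns (gaps, midpoints)."""
    tree = cKDTree(p_to)
    d0, i0 = tree.query(p_from)
    cand = np.flatnonzero(d0 <= prefilter)
    if cand.size == 0:
        return np.empty(0), np.empty((0, 3))
    anchors = p_to[i0[cand]]
    kk = min(k, p_to.shape[0])
    _, nidx = tree.query(anchors, k=kk)
    nidx = np.atleast_2d(nidx.T).T
    neigh = p_to[nidx]  # (C, k, 3)
    centroid = neigh.mean(axis=1)
    centred = neigh - centroid[:, None, :]
    cov = np.einsum("cki,ckj->cij", centred, centred)
    _, vecs = np.linalg.eigh(cov)
    normal = vecs[:, :, 0]  # smallest-eigenvalue direction
    d_signed = np.einsum("ci,ci->c", p_from[cand] - centroid, normal)
    gap_plane = np.abs(d_signed)
    # the fitted plane is only valid over its neighborhood's footprint: a
    # point whose in-plane projection falls outside it (e.g. beyond a
    # crease) must not trust the extrapolated plane
    radius = np.linalg.norm(neigh - centroid[:, None, :], axis=2).max(axis=1)
    offset = (p_from[cand] - centroid) - d_signed[:, None] * normal
    lateral = np.linalg.norm(offset, axis=1)
    supported = lateral <= 1.2 * radius
    # the local plane cannot be farther than the nearest sample point
    gaps = np.where(supported, np.minimum(gap_plane, d0[cand]), d0[cand])
    mids_plane = p_from[cand] - 0.5 * d_signed[:, None] * normal
    mids_point = 0.5 * (p_from[cand] + anchors)
    mids = np.where(supported[:, None], mids_plane, mids_point)
    return gaps, mids


def _principal_direction(points: np.ndarray) -> np.ndarray:
    centred = points - points.mean(axis=0)
    cov = centred.T @ centred
    _, vecs = np.linalg.eigh(cov)
    u = vecs[:, -1]
    if u[1] < 0 or (u[1] == 0 and u[0] < 0):
        u = -u
    return u


def _coarse_edge(z: np.ndarray, gaps: np.ndarray,
                 cap: float) -> tuple[float, float | None]:
    """Coarse contact edge along +z from the gap-vs-position profile.

    Within the true contact the cross-tooth gap hovers at its noise floor;
    beyond the facet rim it rises along the embrasure walls.  Scans per-bin
    median gaps outward for the first sustained rise above the floor and
    extrapolates the crossing back to floor level.  Returns ``(edge,
    kink)`` where ``kink`` is the crossing position (None when the profile
    never rises, i.e. the contact reaches the end of the data).
    """
    zmax = float(z.max())
    if z.size < 30:
        return zmax, None
    span = zmax - float(z.min())
    if span <= 0:
        return zmax, None
    width = max(0.04, span / 60.0)
    nbins = max(3, int(math.ceil(span / width)))
    edges = np.linspace(float(z.min()), zmax, nbins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(np.digitize(z, edges) - 1, 0, nbins - 1)
    medians = np.full(nbins, np.nan)
    for i in range(nbins):
        sel = which == i
        if sel.sum() >= 5:
            medians[i] = np.median(gaps[sel])
    valid = np.flatnonzero(~np.isnan(medians))
    if valid.size < 4:
        return zmax, None
    centre = np.clip(np.searchsorted(edges, np.median(z)) - 1, valid[0], valid[-1])
    core = medians[valid[valid <= centre]]
    floor = float(np.median(core)) if core.size else float(np.nanmedian(medians))
    tail = float(np.nanmax(medians[valid[-3:]]))
    # a genuine embrasure band climbs from the floor toward the candidate
    # cap; mere fluctuation of a flat profile must not count as a rise
    if tail <= max(floor + 0.3 * cap, 2.0 * floor, 1e-9):
        return zmax, None  # no rise: contact extends to the end of the data
    tau = floor + 0.3 * (tail - floor)
    crossing = None
    for i in valid[valid > centre]:
        if medians[i] >= tau:
            crossing = i
            break
    if crossing is None:
        return zmax, None
    z_tau = float(centres[crossing])
    nxt = valid[valid > crossing]
    edge = min(z_tau, zmax)
    if nxt.size:
        i2 = nxt[0]
        slope = (medians[i2] - medians[crossing]) / max(centres[i2] - centres[crossing], 1e-9)
        if slope > 0:
            edge = min(z_tau - (medians[crossing] - floor) / slope, zmax)
    return float(edge), z_tau


def _wall_edge(walls: tuple[np.ndarray, np.ndarray], centre: np.ndarray,
               u: np.ndarray, side: int, kink: float,
               inner: float = 0.1, outer: float = 0.9) -> float | None:
    """Refine a contact edge as the intersection of the two embrasure walls.

    Near the contact the two teeth part along near-planar walls, which
    project to straight flanks; a total-least-squares line fit per tooth is
    unbiased under point jitter, and the intersection of the two fitted
    flanks localizes the contact corner without any boundary-of-a-point-set
    estimation.  ``kink`` is the coarse edge in the signed along-line
    coordinate.  Returns the refined signed edge, or None if the fit is not
    trustworthy.
    """
    v = np.array([-u[1], u[0]])
    fits = []
    for pts in walls:
        sz = side * ((pts - centre) @ u)
        q = (pts - centre) @ v
        sel = (sz >= kink + inner) & (sz <= kink + outer) & (np.abs(q) <= 1.0)
        if sel.sum() < 15:
            return None
        plane_pts = np.column_stack([sz[sel], q[sel]])
        c = plane_pts.mean(axis=0)
        d = _principal_direction(plane_pts - c)
        fits.append((c, d))
    (c1, d1), (c2, d2) = fits
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) < 1e-6:  # walls parallel: no corner
        return None
    dc = c2 - c1
    t1 = (dc[0] * d2[1] - dc[1] * d2[0]) / denom
    corner = c1 + t1 * d1
    if not kink - 0.6 <= corner[0] <= kink + 0.6:
        return None
    return float(corner[0])


def _farthest_pair(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact diameter pair of a 2D point set; lexicographic tie-break."""
    pts = points
    if pts.shape[0] > 400:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            # collinear set: extremes along the principal direction
            u = _principal_direction(pts)
            s = pts @ u
            order = np.argsort(s)
            pts = pts[order][[0, -1]]
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    dmax = d2.max()
    ii, jj = np.nonzero(d2 >= dmax - 1e-12 * max(dmax, 1.0))
    pairs = sorted(
        (tuple(sorted((tuple(pts[i]), tuple(pts[j])))) for i, j in zip(ii, jj) if i != j)
    )
    a, b = pairs[0]
    return np.array(a), np.array(b)


def _line_from_midpoints(mids: np.ndarray, gaps: np.ndarray,
                         contact_eps: float, cap: float | None = None,
                         walls: tuple[np.ndarray, np.ndarray] | None = None,
                         ) -> DividingLine:
    """Build a DividingLine from 2D contact midpoints and their gaps.

    ``mids``/``gaps`` may include candidates beyond ``contact_eps`` (up to
    ``cap``); they inform the edge profile but only midpoints within
    ``contact_eps`` become boundary points.  ``walls`` are the two teeth's
    own projected points, used to refine the line ends by embrasure-wall
    intersection.
    """
    cap = contact_eps if cap is None else cap
    inside = gaps <= contact_eps
    if not inside.any():
        raise NoContactError(
            f"no contact detected within contact_eps={contact_eps} mm"
        )
    u = _principal_direction(mids[inside])
    centre = mids[inside].mean(axis=0)
    s = (mids - centre) @ u
    bounds = []
    for side in (+1, -1):
        edge, kink = _coarse_edge(side * s, gaps, cap)
        if kink is not None and walls is not None:
            refined = _wall_edge(walls, centre, u, side, kink)
            if refined is not None:
                edge = min(refined, float((side * s).max()))
        bounds.append(side * edge)
    hi, lo = bounds
    if hi <= lo:
        lo, hi = float(s[inside].min()), float(s[inside].max())
    keep = inside & (s >= lo - 1e-9) & (s <= hi + 1e-9)
    if keep.sum() < 2:
        keep = inside
    s_kept = s[keep]
    order = np.argsort(s_kept, kind="stable")
    boundary = mids[keep][order]
    s_sorted = s_kept[order]
    # contiguity trim: the dividing line is a connected run; stray
    # midpoints separated by a clear break from the dense run are dropped
    if s_sorted.size > 10:
        mid_idx = int(np.searchsorted(s_sorted, np.median(s_sorted)))
        mid_idx = min(max(mid_idx, 0), s_sorted.size - 1)
        steps = np.diff(s_sorted)
        breaks = np.flatnonzero(steps > 0.2)
        lo_i, hi_i = 0, s_sorted.size - 1
        for b in breaks:
            if b < mid_idx:
                lo_i = max(lo_i, b + 1)
            else:
                hi_i = min(hi_i, b)
        boundary = boundary[lo_i:hi_i + 1]
    if boundary.shape[0] < 2:
        raise NoContactError("contact region too sparse to fit a dividing line")
    end_a, end_b = _farthest_pair(boundary)
    direction = end_b - end_a
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise NoContactError("degenerate dividing line (coincident endpoints)")
    return DividingLine(boundary, end_a, end_b, direction / norm)


def _dividing_line_2d(pa: np.ndarray, pb: np.ndarray, contact_eps: float) -> DividingLine:
    """Line extraction from a genuinely 2D pair (cross gaps measured in 2D)."""
    if pa.shape[0] == 0 or pb.shape[0] == 0:
        raise NoContactError("a tooth has no points in this projection")
    cap = 2.0 * contact_eps
    _, gab, mab = _nearest_gaps_2d(pa, pb, cap)
    _, gba, mba = _nearest_gaps_2d(pb, pa, cap)
    # no wall refinement: a filled 2D projection has no thin wall curves
    return _line_from_midpoints(np.vstack([mab, mba]),
                                np.concatenate([gab, gba]), contact_eps, cap)


def _contact_midpoints_3d(cloud: LabeledPointCloud,
                          contact_eps: float) -> tuple[np.ndarray, np.ndarray]:
    """Pooled 3D contact midpoints and gaps for both cross directions.

    Gaps are point-to-local-plane distances, which stay unbiased under
    point jitter (unlike minimum point-to-point distances, whose extreme
    -value bias grows with sampling density).
    """
    la, lb = cloud.require_pair()
    pa, pb = cloud.tooth(la), cloud.tooth(lb)
    prefilter = max(3.0 * contact_eps, 0.6)
    gab, mab = _plane_gaps_3d(pa, pb, prefilter)
    gba, mba = _plane_gaps_3d(pb, pa, prefilter)
    return np.concatenate([gab, gba]), np.vstack([mab, mba])


def _dividing_line_3d(cloud: LabeledPointCloud, contact_eps: float,
                      plane: str,
                      precomputed: tuple[np.ndarray, np.ndarray] | None = None,
                      ) -> DividingLine:
    """Line extraction with gaps measured on the 3D surfaces, then projected."""
    gaps, mids = precomputed if precomputed is not None else \
        _contact_midpoints_3d(cloud, contact_eps)
    cap = 2.0 * contact_eps
    sel = gaps <= cap
    gaps, mids = gaps[sel], mids[sel]
    inside = gaps <= contact_eps
    if not inside.any():
        raise NoContactError(
            f"no contact detected within contact_eps={contact_eps} mm"
        )
    # marginalize: candidates along the orthogonal embrasures (e.g. the
    # occlusal band when measuring the horizontal line) sit inside the
    # facet's in-plane range with large gaps and would pollute the edge
    # profile, so keep only the orthogonal core of the contact
    ortho = mids[:, 2] if plane == HORIZONTAL else mids[:, 1]
    olo, ohi = np.percentile(ortho[inside], [15.0, 85.0])
    core = (ortho >= olo) & (ortho <= ohi)
    if core.sum() >= 50:
        gaps, mids = gaps[core], mids[core]
    cols = [0, 1] if plane == HORIZONTAL else [0, 2]
    la, lb = cloud.require_pair()
    walls = []
    for label in (la, lb):
        pts = cloud.tooth(label)
        ortho_t = pts[:, 2] if plane == HORIZONTAL else pts[:, 1]
        sel = (ortho_t >= olo) & (ortho_t <= ohi)
        walls.append(pts[np.ix_(sel, cols)] if sel.any() else pts[:, cols])
    return _line_from_midpoints(mids[:, cols], gaps, contact_eps, cap,
                                walls=(walls[0], walls[1]))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def extract_dividing_line(source: ProjectedCloud2D | LabeledPointCloud,
                          contact_eps: float = 0.1) -> DividingLine:
    """Contact boundary of the pair in occlusal (horizontal) projection.

    Points of either tooth whose estimated gap to the other tooth is within
    ``contact_eps`` are collapsed to cross-pair midpoints, trimmed to their
    densely supported extent with two-scale extrapolation of the threshold
    band, and ordered along the principal direction of the boundary.

    Given the full 3D pair, gaps are measured on the surfaces (robust to
    scan jitter) and the midpoints projected; given an already-projected
    horizontal cloud, gaps are measured in 2D.
    """
    if isinstance(source, LabeledPointCloud):
        return _dividing_line_3d(source, contact_eps, HORIZONTAL)
    if source.plane != HORIZONTAL:
        raise ValueError("the dividing line is defined in the horizontal_xy projection")
    if np.unique(source.labels).size != 2:
        raise ValueError("dividing-line extraction needs exactly two tooth labels")
    la, lb = np.unique(source.labels)[:2]
    return _dividing_line_2d(source.tooth(int(la)), source.tooth(int(lb)), contact_eps)


def adjacent_line_length(line: DividingLine) -> float:
    """Distance between the two dividing-line ends (mm); by construction it
    equals the maximum pairwise distance over the boundary points."""
    return line.length


def _three_point_angle(points_by_tooth: tuple[np.ndarray, np.ndarray],
                       vertex: np.ndarray, outward: np.ndarray,
                       extension_len: float) -> float:
    probe = vertex + extension_len * outward
    arms = []
    for pts in points_by_tooth:
        if pts.shape[0] == 0:
            raise MeasurementError("open embrasure undefined: a tooth has no points")
        tree = cKDTree(pts)
        kk = min(40, pts.shape[0])
        dists, idx = tree.query(probe, k=kk)
        dists, idx = np.atleast_1d(dists), np.atleast_1d(idx)
        if dists[0] < 1e-9:
            raise MeasurementError(
                "open embrasure undefined: probe point lies on a tooth"
            )
        # all points nearly as close as the nearest lie on a short arc of
        # the tooth flank around the perpendicular foot; their median is a
        # jitter-robust version of "the point nearest the extension"
        near = idx[dists <= dists[0] + 0.08]
        arm = np.median(pts[near], axis=0) - vertex
        norm = np.linalg.norm(arm)
        if norm < 1e-9:
            raise MeasurementError(
                "open embrasure undefined: no tooth point beyond the contact end"
            )
        arms.append(arm / norm)
    cosang = float(np.clip(arms[0] @ arms[1], -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def abduction_gap_angles(proj: ProjectedCloud2D, line: DividingLine,
                         extension_len: float = 1.5) -> tuple[float, float]:
    """Tongue and buccal abduction gap angles (degrees) in occlusal view.

    Each dividing-line end is extended outward by ``extension_len`` along
    the line direction; the nearest projected point of each tooth to the
    extension point forms one arm, and the angle between the two arms at
    the contact end is the embrasure opening.  Under the canonical frame
    the end with the larger y is the buccal side (+y buccal).

    Returns ``(theta_t, theta_b)``.
    """
    if proj.plane != HORIZONTAL:
        raise ValueError("abduction gap angles are defined in the horizontal_xy projection")
    la, lb = np.unique(proj.labels)[:2]
    teeth = (proj.tooth(int(la)), proj.tooth(int(lb)))
    angles: dict[str, float] = {}
    for end, outward in ((line.end_b, line.direction), (line.end_a, -line.direction)):
        angles[_side_key(end, line)] = _three_point_angle(teeth, end, outward, extension_len)
    return angles["lingual"], angles["buccal"]


def _side_key(end: np.ndarray, line: DividingLine) -> str:
    buccal_end = line.end_a if line.end_a[1] > line.end_b[1] else line.end_b
    return "buccal" if end is buccal_end or np.array_equal(end, buccal_end) else "lingual"


def occlusal_abduction_angle(source: ProjectedCloud2D | LabeledPointCloud,
                             extension_len: float = 1.5,
                             contact_eps: float = 0.1) -> float:
    """Occlusal abduction gap angle (degrees) in mesiodistal vertical view.

    The dividing line is recomputed in the xz projection; its occlusal-side
    end (maximum z) is the vertex of the same three-point construction.
    Accepts the 3D pair (surface-measured gaps) or an xz projection.
    """
    if isinstance(source, LabeledPointCloud):
        line = _dividing_line_3d(source, contact_eps, VERTICAL)
        proj = project(source, VERTICAL)
    else:
        proj = source
        if proj.plane != VERTICAL:
            raise ValueError("the occlusal angle is defined in the vertical_xz projection")
        labs = np.unique(proj.labels)
        if labs.size != 2:
            raise ValueError("occlusal angle needs exactly two tooth labels")
        line = _dividing_line_2d(proj.tooth(int(labs[0])),
                                 proj.tooth(int(labs[1])), contact_eps)
    labs = np.unique(proj.labels)
    pa, pb = proj.tooth(int(labs[0])), proj.tooth(int(labs[1]))
    if line.end_a[1] >= line.end_b[1]:
        vertex, other = line.end_a, line.end_b
    else:
        vertex, other = line.end_b, line.end_a
    outward = vertex - other
    outward = outward / np.linalg.norm(outward)
    return _three_point_angle((pa, pb), vertex, outward, extension_len)


def polygon_area(points2d: np.ndarray, alpha: float | None = None) -> float:
    """Area of a 2D point set: alpha-shape area for a given alpha radius,
    convex-hull area when ``alpha`` is None or the alpha complex is empty."""
    area, _ = _region_area_perimeter(points2d, alpha)
    return area


def _region_area_perimeter(points2d: np.ndarray,
                           alpha: float | None) -> tuple[float, float]:
    """(area, boundary perimeter) of the alpha complex of a 2D point set,
    falling back to the convex hull when the complex is empty."""
    pts = np.asarray(points2d, float)
    if pts.shape[0] < 3:
        raise MeasurementError("need at least three points to measure an area")
    if alpha is not None:
        try:
            tri = Delaunay(pts)
        except QhullError:
            return _hull_area_perimeter(pts)
        simplices = pts[tri.simplices]  # (T, 3, 2)
        a = np.linalg.norm(simplices[:, 0] - simplices[:, 1], axis=1)
        b = np.linalg.norm(simplices[:, 1] - simplices[:, 2], axis=1)
        c = np.linalg.norm(simplices[:, 2] - simplices[:, 0], axis=1)
        e1 = simplices[:, 1] - simplices[:, 0]
        e2 = simplices[:, 2] - simplices[:, 0]
        areas = 0.5 * np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
        with np.errstate(divide="ignore", invalid="ignore"):
            circumradius = np.where(areas > 1e-12, a * b * c / (4.0 * areas), np.inf)
        keep = circumradius <= alpha
        if keep.any():
            area = float(areas[keep].sum())
            # boundary edges of the kept complex appear in exactly one triangle
            kept = tri.simplices[keep]
            edges = np.sort(
                np.concatenate([kept[:, [0, 1]], kept[:, [1, 2]], kept[:, [2, 0]]]),
                axis=1,
            )
            uniq, counts = np.unique(edges, axis=0, return_counts=True)
            border = uniq[counts == 1]
            perimeter = float(
                np.linalg.norm(pts[border[:, 0]] - pts[border[:, 1]], axis=1).sum()
            )
            return area, perimeter
    return _hull_area_perimeter(pts)


def _hull_area_perimeter(pts: np.ndarray) -> tuple[float, float]:
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise MeasurementError("degenerate (collinear) contact region") from exc
    return float(hull.volume), float(hull.area)  # 2D: .volume=area, .area=perimeter


def adjacent_surface_area(cloud: LabeledPointCloud, contact_eps: float = 0.1,
                          alpha: float = 0.5,
                          precomputed: tuple[np.ndarray, np.ndarray] | None = None,
                          ) -> float:
    """Contact facet area (mm^2) on the vertical partition plane.

    3D points of either tooth whose point-to-local-plane gap to the other
    tooth is within ``contact_eps`` are collapsed to gap midpoints and
    projected onto the vertical plane (containing z) fitted through them;
    the facet area is the alpha-shape area of the projection, extrapolated
    over the two thresholds (eps, eps/2) to remove the selection band along
    the embrasure walls.
    """
    gaps, mids = precomputed if precomputed is not None else \
        _contact_midpoints_3d(cloud, contact_eps)
    if (gaps <= contact_eps).sum() < 3:
        raise NoContactError("no measurable contact facet")
    support = gaps <= 2.0 * contact_eps
    gaps, mids = gaps[support], mids[support]
    full = mids[gaps <= contact_eps]
    # vertical partition plane: principal xy direction of the contact, plus z
    u = _principal_direction(full[:, :2])
    centre = full.mean(axis=0)
    coords = np.column_stack(
        [(mids[:, :2] - centre[:2]) @ u, mids[:, 2] - centre[2]]
    )
    floor = float(np.percentile(gaps[gaps <= contact_eps], 20))
    if floor >= contact_eps:
        raise NoContactError("no measurable contact facet within contact_eps")

    def corrected_area(threshold: float) -> float:
        sel = coords[gaps <= threshold]
        if sel.shape[0] < 3:
            raise NoContactError("no measurable contact facet")
        area, perimeter = _region_area_perimeter(sel, alpha)
        # a point-sampled region loses about half a point spacing at its
        # rim; midpoints pool both query directions into near-coincident
        # twins, so the 3rd neighbor estimates the underlying spacing
        sub = cKDTree(sel)
        spacing = float(np.median(sub.query(sel, k=3)[0][:, 2]))
        return area + 0.5 * spacing * perimeter

    # the selected region grows linearly with the threshold along the
    # embrasure walls; two thresholds above the crease-blur zone of the
    # local plane fits, extrapolated back to the noise floor, recover the
    # true facet extent to first order
    tau2 = floor + 0.45 * (contact_eps - floor)
    tau1 = floor + 0.90 * (contact_eps - floor)
    area2 = corrected_area(tau2)
    area1 = corrected_area(tau1)
    extrapolated = area2 - (area1 - area2) * (tau2 - floor) / (tau1 - tau2)
    if extrapolated < 0.5 * area2:  # extrapolation unreliable
        return area2
    return float(extrapolated)


def measure_all(cloud: LabeledPointCloud, config: MeasurementConfig | None = None,
                group: str | None = None) -> FeatureRecord:
    """Run the full measurement chain on one pair.

    Projects the pair horizontally and vertically, extracts the dividing
    line and measures all five features; the configuration used is recorded
    in the record's provenance.  Stage failures propagate with the stage
    name prefixed.
    """
    config = config or MeasurementConfig()
    cloud.require_pair()

    def _stage(name, fn):
        try:
            return fn()
        except MeasurementError as exc:
            raise type(exc)(f"{name}: {exc}") from exc

    noise_estimate = None
    denoised = False
    if config.denoise is True:
        denoised = True
    elif config.denoise == "auto":
        noise_estimate = estimate_noise(cloud)
        denoised = noise_estimate > config.noise_floor
    if denoised:
        cloud = smooth_cloud(cloud)

    proj_xy = project(cloud, HORIZONTAL)
    pre = _stage("contact_selection",
                 lambda: _contact_midpoints_3d(cloud, config.contact_eps))
    line = _stage(
        "extract_dividing_line",
        lambda: _dividing_line_3d(cloud, config.contact_eps, HORIZONTAL, pre))
    length = adjacent_line_length(line)
    theta_t, theta_b = _stage(
        "abduction_gap_angles",
        lambda: abduction_gap_angles(proj_xy, line, config.extension_len))

    def _occlusal() -> float:
        vline = _dividing_line_3d(cloud, config.contact_eps, VERTICAL, pre)
        proj_xz = project(cloud, VERTICAL)
        labs = np.unique(proj_xz.labels)
        pa, pb = proj_xz.tooth(int(labs[0])), proj_xz.tooth(int(labs[1]))
        if vline.end_a[1] >= vline.end_b[1]:
            vertex, other = vline.end_a, vline.end_b
        else:
            vertex, other = vline.end_b, vline.end_a
        outward = vertex - other
        outward = outward / np.linalg.norm(outward)
        return _three_point_angle((pa, pb), vertex, outward, config.extension_len)

    theta_o = _stage("occlusal_abduction_angle", _occlusal)
    area = _stage(
        "adjacent_surface_area",
        lambda: adjacent_surface_area(cloud, config.contact_eps, config.alpha, pre))
    return FeatureRecord(
        adjacent_line_length_mm=length,
        adjacent_surface_area_mm2=area,
        tongue_angle_deg=theta_t,
        buccal_angle_deg=theta_b,
        occlusal_angle_deg=theta_o,
        group=group,
        provenance={"config": asdict(config), "denoised": denoised,
                    "noise_estimate_mm": noise_estimate},
    )
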