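"""Point-cloud plumbing for molar-pair morphometry.

The measurement pipeline works on a pair of segmented tooth surfaces
represented as a single labeled point cloud in a canonical frame:

* ``x`` — mesiodistal axis (the two teeth face each other along x),
* ``y`` — buccolingual axis (+y is buccal),
* ``z`` — occlusal axis (+z toward the chewing surface).

All coordinates are millimetres.  This module provides the containers,
STL/PLY ingestion, mesh-to-cloud sampling, local curvature estimation,
curvature-weighted ("geometric") subsampling and the 2D projections the
feature measurements are defined on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "LabeledPointCloud",
    "ProjectedCloud2D",
    "read_model",
    "write_ply",
    "read_ply",
    "sample_mesh",
    "estimate_curvature",
    "estimate_noise",
    "smooth_cloud",
    "geometric_sample",
    "project",
    "normalize_frame",
    "mirror_buccolingual",
]

HORIZONTAL = "horizontal_xy"
VERTICAL = "vertical_xz"


@dataclass
class LabeledPointCloud:
    """3D surface points with an integer tooth label per point.

    Parameters
    ----------
    points : (N, 3) float array, mm
    labels : (N,) int array; tooth ids (1 = mesial tooth, 2 = distal tooth
        for pair operations)
    normals : optional (N, 3) unit vectors
    """

    points: np.ndarray
    labels: np.ndarray
    normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if self.labels.shape != (self.points.shape[0],):
            raise ValueError("labels must be one integer per point")
        if not np.isfinite(self.points).all():
            raise ValueError("points contain non-finite coordinates")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float)
            if self.normals.shape != self.points.shape:
                raise ValueError("normals must match points in shape")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def unique_labels(self) -> np.ndarray:
        return np.unique(self.labels)

    def tooth(self, label: int) -> np.ndarray:
        """Points of one tooth."""
        return self.points[self.labels == label]

    def require_pair(self) -> tuple[int, int]:
        """Return the two tooth labels, or fail if not exactly two."""
        labs = self.unique_labels
        if labs.size != 2:
            raise ValueError(
                f"pair operation needs exactly two tooth labels, found {labs.tolist()}"
            )
        return int(labs[0]), int(labs[1])

    def subset(self, mask: np.ndarray) -> "LabeledPointCloud":
        normals = self.normals[mask] if self.normals is not None else None
        return LabeledPointCloud(self.points[mask], self.labels[mask], normals)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LabeledPointCloud":
        """Rigidly move the cloud: ``p -> R p + t``."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        pts = self.points @ rotation.T + translation
        normals = self.normals @ rotation.T if self.normals is not None else None
        return LabeledPointCloud(pts, self.labels.copy(), normals)


@dataclass
class ProjectedCloud2D:
    """2D orthographic projection of a labeled cloud.

    ``horizontal_xy`` is the occlusal (top) view obtained by dropping z;
    ``vertical_xz`` is the buccal (side) view obtained by dropping y.
    """

    points: np.ndarray
    labels: np.ndarray
    plane: str

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("projected points must be (N, 2)")
        if self.labels.shape != (self.points.shape[0],):
            raise ValueError("labels must be one integer per point")
        if self.plane not in (HORIZONTAL, VERTICAL):
            raise ValueError(f"unknown projection plane {self.plane!r}")

    def tooth(self, label: int) -> np.ndarray:
        return self.points[self.labels == label]


def project(cloud: LabeledPointCloud, plane: str) -> ProjectedCloud2D:
    """Orthographic projection onto the horizontal (xy) or vertical (xz) plane."""
    if plane == HORIZONTAL:
        pts = cloud.points[:, [0, 1]]
    elif plane == VERTICAL:
        pts = cloud.points[:, [0, 2]]
    else:
        raise ValueError(f"unknown projection plane {plane!r}")
    return ProjectedCloud2D(pts.copy(), cloud.labels.copy(), plane)


def mirror_buccolingual(cloud: LabeledPointCloud) -> LabeledPointCloud:
    """Mirror the cloud about the xz-plane (y -> -y), swapping buccal/lingual."""
    pts = cloud.points * np.array([1.0, -1.0, 1.0])
    normals = None
    if cloud.normals is not None:
        normals = cloud.normals * np.array([1.0, -1.0, 1.0])
    return LabeledPointCloud(pts, cloud.labels.copy(), normals)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_model(
    path: str | Path | Sequence[str | Path],
    fmt: str | None = None,
) -> LabeledPointCloud:
    """Read a segmented molar pair from disk.

    Two STL files (one per tooth) become labels 1 and 2, in the order given.
    A single labeled ASCII PLY (as written by :func:`write_ply`) carries its
    own per-vertex integer ``label`` property.  STL vertices are taken as the
    point cloud; use :func:`sample_mesh` to densify if needed.
    """
    if isinstance(path, (str, Path)):
        paths = [Path(path)]
    else:
        paths = [Path(p) for p in path]
    if fmt is None:
        fmt = paths[0].suffix.lower().lstrip(".")
    fmt = fmt.lower()

    if fmt == "ply":
        if len(paths) != 1:
            raise ValueError("labeled PLY input must be a single file")
        return read_ply(paths[0])
    if fmt == "stl":
        if len(paths) != 2:
            raise ValueError("STL input must be exactly two files (one per tooth)")
        chunks, labels = [], []
        for label, p in zip((1, 2), paths):
            mesh = trimesh.load_mesh(str(p), file_type="stl")
            verts = np.asarray(mesh.vertices, dtype=float)
            if verts.shape[0] < 3 or np.asarray(mesh.faces).shape[0] == 0:
                raise ValueError(f"{p}: STL contains no usable facets")
            chunks.append(verts)
            labels.append(np.full(verts.shape[0], label, dtype=int))
        return LabeledPointCloud(np.vstack(chunks), np.concatenate(labels))
    raise ValueError(f"unsupported model format {fmt!r}")


def write_ply(cloud: LabeledPointCloud, path: str | Path) -> Path:
    """Write a labeled point cloud as ASCII PLY with an integer ``label``
    vertex property (the pair interchange format of this package)."""
    path = Path(path)
    n = len(cloud)
    has_normals = cloud.normals is not None
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\ncomment interprox labeled point cloud (mm)\n")
        fh.write(f"element vertex {n}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        if has_normals:
            fh.write("property float nx\nproperty float ny\nproperty float nz\n")
        fh.write("property int label\nend_header\n")
        cols = [cloud.points]
        if has_normals:
            cols.append(cloud.normals)
        data = np.column_stack(cols)
        for row, lab in zip(data, cloud.labels):
            coords = " ".join(f"{v:.6f}" for v in row)
            fh.write(f"{coords} {lab}\n")
    return path


def read_ply(path: str | Path) -> LabeledPointCloud:
    """Read the ASCII PLY layout produced by :func:`write_ply`."""
    path = Path(path)
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path}: not a PLY file")
        n = None
        props: list[str] = []
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated PLY header")
            line = line.strip()
            if line.startswith("format") and "ascii" not in line:
                raise ValueError(f"{path}: only ASCII PLY is supported")
            if line.startswith("element vertex"):
                n = int(line.split()[-1])
            elif line.startswith("property"):
                props.append(line.split()[-1])
            elif line == "end_header":
                break
        if n is None:
            raise ValueError(f"{path}: PLY without vertex element")
        for needed in ("x", "y", "z", "label"):
            if needed not in props:
                raise ValueError(f"{path}: PLY lacks vertex property {needed!r}")
        body = np.loadtxt(fh, dtype=float, max_rows=n)
    body = np.atleast_2d(body)
    if body.shape[0] != n or body.shape[1] != len(props):
        raise ValueError(f"{path}: PLY body does not match header")
    col = {name: i for i, name in enumerate(props)}
    pts = body[:, [col["x"], col["y"], col["z"]]]
    labels = body[:, col["label"]].astype(int)
    normals = None
    if all(k in col for k in ("nx", "ny", "nz")):
        normals = body[:, [col["nx"], col["ny"], col["nz"]]]
    return LabeledPointCloud(pts, labels, normals)


# ---------------------------------------------------------------------------
# Sampling and curvature
# ---------------------------------------------------------------------------

def sample_mesh(
    mesh: trimesh.Trimesh,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Area-weighted uniform sampling of ``n`` points on a triangle mesh."""
    if n < 1:
        raise ValueError("n must be >= 1")
    faces = np.asarray(mesh.faces)
    if faces.shape[0] == 0:
        raise ValueError("cannot sample an empty mesh")
    rng = np.random.default_rng(rng)
    tri = mesh.triangles  # (F, 3, 3)
    areas = np.asarray(mesh.area_faces, dtype=float)
    total = areas.sum()
    if total <= 0:
        raise ValueError("mesh has zero surface area")
    idx = rng.choice(faces.shape[0], size=n, p=areas / total)
    # uniform barycentric coordinates via the square-root trick
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    a, b, c = tri[idx, 0], tri[idx, 1], tri[idx, 2]
    return (1.0 - r1)[:, None] * a + (r1 * (1.0 - r2))[:, None] * b + (r1 * r2)[:, None] * c


def estimate_curvature(
    cloud: LabeledPointCloud | np.ndarray,
    k_neighbors: int = 16,
) -> np.ndarray:
    """Per-point surface-variation curvature score.

    The score is lambda_3 / (lambda_1 + lambda_2 + lambda_3), the smallest
    eigenvalue fraction of the local neighborhood covariance; 0 on perfect
    planes, up to 1/3 for isotropic scatter.  Degenerate (collinear or
    duplicated) neighborhoods score 0.
    """
    pts = cloud.points if isinstance(cloud, LabeledPointCloud) else np.asarray(cloud, float)
    n = pts.shape[0]
    if k_neighbors < 4:
        raise ValueError("k_neighbors must be >= 4")
    if n <= k_neighbors:
        raise ValueError("need more points than k_neighbors")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k_neighbors + 1)
    neigh = pts[idx]  # (N, k+1, 3)
    centred = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centred, centred) / (k_neighbors + 1)
    eigvals = np.linalg.eigvalsh(cov)  # ascending
    total = eigvals.sum(axis=1)
    score = np.zeros(n)
    ok = total > 1e-18
    score[ok] = eigvals[ok, 0] / total[ok]
    return np.clip(score, 0.0, 1.0 / 3.0)


def geometric_sample(
    cloud: LabeledPointCloud,
    n_out: int,
    curvature: np.ndarray | None = None,
    floor_prob: float = 0.05,
    k_neighbors: int = 16,
    rng: np.random.Generator | int | None = None,
) -> LabeledPointCloud:
    """Curvature-weighted subsampling without replacement.

    Points are kept with probability proportional to ``curvature +
    floor_prob``, concentrating the budget on high-curvature regions
    (contact facets, embrasure edges) where the impaction-relevant
    geometry lives, while the floor keeps flat regions represented.
    """
    n = len(cloud)
    if not 0 < n_out <= n:
        raise ValueError("n_out must be in (0, N]")
    if curvature is None:
        curvature = estimate_curvature(cloud, k_neighbors=k_neighbors)
    curvature = np.asarray(curvature, dtype=float)
    if curvature.shape != (n,):
        raise ValueError("curvature must be one score per point")
    weights = curvature + floor_prob
    total = weights.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero (raise floor_prob)")
    rng = np.random.default_rng(rng)
    idx = rng.choice(n, size=n_out, replace=False, p=weights / total)
    idx.sort()
    return cloud.subset(idx)


def estimate_noise(cloud: LabeledPointCloud, k_neighbors: int = 12,
                   max_points: int = 4000,
                   rng: np.random.Generator | int | None = 0) -> float:
    """Estimate the isotropic jitter (mm) of a surface point cloud.

    Fits local planes over k-neighborhoods of a random subset of points
    (per tooth, so coincident contact surfaces do not mix) and returns the
    median out-of-plane RMS residual.
    """
    rng = np.random.default_rng(rng)
    residuals = []
    for label in cloud.unique_labels:
        pts = cloud.points[cloud.labels == label]
        if pts.shape[0] <= k_neighbors:
            continue
        take = min(max_points, pts.shape[0])
        sub = pts[rng.choice(pts.shape[0], take, replace=False)]
        tree = cKDTree(pts)
        _, idx = tree.query(sub, k=k_neighbors + 1)
        neigh = pts[idx]
        centred = neigh - neigh.mean(axis=1, keepdims=True)
        cov = np.einsum("nki,nkj->nij", centred, centred) / (k_neighbors + 1)
        eigvals = np.linalg.eigvalsh(cov)
        residuals.append(np.sqrt(np.maximum(eigvals[:, 0], 0.0)))
    if not residuals:
        return 0.0
    return float(np.median(np.concatenate(residuals)))


def smooth_cloud(cloud: LabeledPointCloud, k_neighbors: int = 20,
                 iterations: int = 1) -> LabeledPointCloud:
    """Moving-least-squares denoising: project each point onto the plane
    fitted to its k-neighborhood (within its own tooth).

    Reduces isotropic scan jitter by roughly 1/sqrt(k) on smooth regions
    at the cost of slightly rounding sharp creases over the neighborhood
    radius.
    """
    points = cloud.points.copy()
    for _ in range(iterations):
        for label in cloud.unique_labels:
            mask = cloud.labels == label
            pts = points[mask]
            if pts.shape[0] <= k_neighbors:
                continue
            tree = cKDTree(pts)
            _, idx = tree.query(pts, k=k_neighbors + 1)
            neigh = pts[idx]
            centroid = neigh.mean(axis=1)
            centred = neigh - centroid[:, None, :]
            cov = np.einsum("nki,nkj->nij", centred, centred)
            _, vecs = np.linalg.eigh(cov)
            normal = vecs[:, :, 0]
            offset = np.einsum("ni,ni->n", pts - centroid, normal)
            points[mask] = pts - offset[:, None] * normal
    return LabeledPointCloud(points, cloud.labels.copy(), cloud.normals)


# ---------------------------------------------------------------------------
# Frame normalization
# ---------------------------------------------------------------------------

def normalize_frame(
    cloud: LabeledPointCloud,
    occlusal_direction: np.ndarray | None = None,
) -> LabeledPointCloud:
    """Rigidly align a pair to the canonical frame.

    The inter-centroid axis of the two teeth becomes +x, the supplied
    occlusal direction (or, failing that, the third principal axis of the
    pooled cloud) becomes +z, and the origin moves to the midpoint between
    the tooth centroids.  Already-aligned input passes through unchanged up
    to numerical precision.
    """
    la, lb = cloud.require_pair()
    ca = cloud.tooth(la).mean(axis=0)
    cb = cloud.tooth(lb).mean(axis=0)
    x_axis = cb - ca
    nx = np.linalg.norm(x_axis)
    if nx == 0:
        raise ValueError("tooth centroids coincide; cannot orient the pair")
    x_axis = x_axis / nx
    if occlusal_direction is not None:
        z_axis = np.asarray(occlusal_direction, dtype=float)
    else:
        pooled = cloud.points - cloud.points.mean(axis=0)
        _, _, vt = np.linalg.svd(pooled, full_matrices=False)
        z_axis = vt[2]
        if z_axis[2] < 0:
            z_axis = -z_axis
    z_axis = z_axis - x_axis * (z_axis @ x_axis)
    nz = np.linalg.norm(z_axis)
    if nz < 1e-9:
        raise ValueError("occlusal direction is parallel to the mesiodistal axis")
    z_axis = z_axis / nz
    y_axis = np.cross(z_axis, x_axis)
    rotation = np.vstack([x_axis, y_axis, z_axis])  # world -> canonical
    origin = 0.5 * (ca + cb)
    return cloud.transformed(rotation, -rotation @ origin)
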