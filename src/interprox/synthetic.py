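"""Synthetic molar pairs and cohort tables with known ground truth.

Real intraoral scans of first/second molar pairs are not redistributable,
so every downstream stage of this package is exercised on two synthetic
inputs instead:

* :func:`generate_tooth_pair` builds a labeled two-tooth point cloud whose
  interproximal geometry (contact facet extent, embrasure opening angles)
  is known exactly by construction, so the feature measurements can be
  validated against analytic ground truth;
* :func:`generate_cohort` draws per-patient feature tables from specified
  group distributions, optionally attaching a binary impaction outcome via
  a logistic model, so the statistical stages can be validated by
  parameter recovery.

Geometry of a generated tooth (mm, canonical frame: x mesiodistal,
y buccolingual with +y buccal, z occlusal):  the crown body is a
superellipse cylinder extruded in z; its mesial face is carved back to a
recession surface ``x = f(y, z)`` that is exactly 0 on a rectangular
contact facet and rises as planar chamfers outside it.  The mesial tooth
is the mirror image about the contact plane x = 0, so the dihedral
opening between the two teeth on each side of the facet equals the
requested embrasure angle, the facet of the pair is a true flat contact
of the requested width and height, and the five morphometric features
have closed-form ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import LabeledPointCloud

__all__ = [
    "FEATURE_COLUMNS",
    "ToothPairSpec",
    "GroundTruth",
    "GroupDistribution",
    "NONIMPACTION_GROUP",
    "IMPACTION_GROUP",
    "REFERENCE_SPEC",
    "generate_tooth_pair",
    "generate_cohort",
]

#: Canonical feature column names, in reporting order.
FEATURE_COLUMNS = (
    "adjacent_line_length_mm",
    "adjacent_surface_area_mm2",
    "tongue_angle_deg",
    "buccal_angle_deg",
    "occlusal_angle_deg",
)

# Opening angle of the (unmeasured) cervical embrasure below the facet;
# fixed so the facet is bounded below without adding a sixth parameter.
_CERVICAL_OPENING_DEG = 80.0

# Superellipse exponent of the crown cross-section; 4 gives the squarish,
# rounded-corner outline of a molar crown in occlusal view.
_SUPERELLIPSE_EXPONENT = 4.0

# Mesial shift of the crown body behind the contact plane, so the flat
# facet is embedded in (not tangent to) the crown.
_BODY_SHIFT_MM = 1.2

# Half-width of the densified interproximal acquisition window beyond the
# facet rim, and the fraction of the point budget allocated to it.  This
# emulates the high effective resolution that curvature-weighted
# acquisition concentrates on the contact region.
_CONTACT_WINDOW_MM = 1.8
_CONTACT_WINDOW_FRACTION = 0.45

# Clearance (mm) the probe construction needs around the facet.
_PROBE_CLEARANCE_MM = 2.2


@dataclass(frozen=True)
class ToothPairSpec:
    """Ground-truth parameters of one synthetic molar pair.

    Lengths in mm, angles in degrees.  Defaults are a clinically plausible
    tight-contact scenario: contact line 3.52 mm, facet area 6.21 mm^2,
    lingual/buccal embrasures of 52.24 and 54.15 degrees and an occlusal
    embrasure of 89.26 degrees.
    """

    crown_width_md: float = 10.0
    crown_width_bl: float = 11.0
    crown_height: float = 8.0
    contact_width: float = 3.52
    contact_height: float = 6.21 / 3.52
    angle_buccal: float = 54.15
    angle_lingual: float = 52.24
    angle_occlusal: float = 89.26
    points_per_tooth: int = 30_000
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crown_width_md", "crown_width_bl", "crown_height",
                     "contact_width", "contact_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.contact_width >= self.crown_width_bl:
            raise ValueError("contact_width must be smaller than crown_width_bl")
        if self.contact_height >= self.crown_height:
            raise ValueError("contact_height must be smaller than crown_height")
        for name in ("angle_buccal", "angle_lingual", "angle_occlusal"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"{name} must lie in (0, 180) degrees")
        if self.points_per_tooth < 100:
            raise ValueError("points_per_tooth must be at least 100")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        # The chamfers and the probe construction must fit inside the crown.
        half_depth = self.crown_width_md / 2.0
        window = _CONTACT_WINDOW_MM
        worst = max(self.angle_buccal, self.angle_lingual, self.angle_occlusal)
        if window * math.tan(math.radians(worst) / 2.0) >= half_depth:
            raise ValueError("embrasure chamfers would exceed the crown depth")
        if self.contact_width / 2.0 + _PROBE_CLEARANCE_MM >= self.crown_width_bl / 2.0:
            raise ValueError("facet too wide: no lateral room for the embrasures")
        if self.contact_height + 2.0 * _PROBE_CLEARANCE_MM >= self.crown_height:
            raise ValueError("facet too tall: no occlusal room for the embrasure")

    def mirrored(self) -> "ToothPairSpec":
        """The same pair mirrored about the xz-plane (buccal/lingual swap)."""
        return replace(self, angle_buccal=self.angle_lingual,
                       angle_lingual=self.angle_buccal)

    @property
    def contact_area(self) -> float:
        return self.contact_width * self.contact_height


@dataclass(frozen=True)
class GroundTruth:
    """The five interproximal features a spec encodes, by construction."""

    adjacent_line_length: float
    adjacent_surface_area: float
    tongue_angle: float
    buccal_angle: float
    occlusal_angle: float

    @classmethod
    def from_spec(cls, spec: ToothPairSpec) -> "GroundTruth":
        return cls(
            adjacent_line_length=spec.contact_width,
            adjacent_surface_area=spec.contact_area,
            tongue_angle=spec.angle_lingual,
            buccal_angle=spec.angle_buccal,
            occlusal_angle=spec.angle_occlusal,
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "adjacent_line_length_mm": self.adjacent_line_length,
            "adjacent_surface_area_mm2": self.adjacent_surface_area,
            "tongue_angle_deg": self.tongue_angle,
            "buccal_angle_deg": self.buccal_angle,
            "occlusal_angle_deg": self.occlusal_angle,
        }


#: The tight-contact reference scenario used throughout the docs and tests.
REFERENCE_SPEC = ToothPairSpec(noise_sd=0.0)


# ---------------------------------------------------------------------------
# Tooth-pair generation
# ---------------------------------------------------------------------------

def _recession(spec: ToothPairSpec, y: np.ndarray, z: np.ndarray,
               z_lo: float, z_hi: float) -> np.ndarray:
    """Mesial recession depth x = f(y, z) of the distal tooth (>= 0).

    Zero on the facet rectangle, planar chamfers outside it; the maximum
    of the four chamfer terms makes them meet in straight edges so each
    projected silhouette is governed by a single opening angle.
    """
    half_w = spec.contact_width / 2.0
    t_b = math.tan(math.radians(spec.angle_buccal) / 2.0)
    t_l = math.tan(math.radians(spec.angle_lingual) / 2.0)
    t_o = math.tan(math.radians(spec.angle_occlusal) / 2.0)
    t_c = math.tan(math.radians(_CERVICAL_OPENING_DEG) / 2.0)
    buccal = np.maximum(y - half_w, 0.0) * t_b
    lingual = np.maximum(-y - half_w, 0.0) * t_l
    occlusal = np.maximum(z - z_hi, 0.0) * t_o
    cervical = np.maximum(z_lo - z, 0.0) * t_c
    return np.maximum.reduce([buccal, lingual, occlusal, cervical])


def _superellipse_xy(t: np.ndarray, a: float, b: float, n: float) -> tuple[np.ndarray, np.ndarray]:
    c, s = np.cos(t), np.sin(t)
    x = a * np.sign(c) * np.abs(c) ** (2.0 / n)
    y = b * np.sign(s) * np.abs(s) ** (2.0 / n)
    return x, y


def _body_min_x(y: np.ndarray, cx: float, a: float, b: float, n: float) -> np.ndarray:
    """Mesial-most x of the superellipse body at buccolingual offset y."""
    frac = 1.0 - (np.abs(y) / b) ** n
    out = np.full_like(np.asarray(y, float), np.inf)
    ok = frac > 0
    out[ok] = cx - a * frac[ok] ** (1.0 / n)
    return out


def _collect(sampler: Callable[[int], np.ndarray], n: int,
             max_rounds: int = 60) -> np.ndarray:
    """Run a rejection sampler until n points are collected."""
    chunks: list[np.ndarray] = []
    have = 0
    for _ in range(max_rounds):
        need = n - have
        if need <= 0:
            break
        got = sampler(max(2 * need, 64))
        if got.shape[0]:
            chunks.append(got)
            have += got.shape[0]
    if have < n:
        raise RuntimeError("rejection sampling failed to fill the point budget")
    return np.vstack(chunks)[:n]


def _sample_tooth(spec: ToothPairSpec, rng: np.random.Generator) -> np.ndarray:
    """Sample the distal tooth (x >= 0 side) surface. Returns (n, 3) points."""
    n_exp = _SUPERELLIPSE_EXPONENT
    a = spec.crown_width_md / 2.0
    b = spec.crown_width_bl / 2.0
    height = spec.crown_height
    cx = a - _BODY_SHIFT_MM  # body centre sits behind the contact plane
    z_lo = (height - spec.contact_height) / 2.0
    z_hi = z_lo + spec.contact_height

    def recession(y: np.ndarray, z: np.ndarray) -> np.ndarray:
        return _recession(spec, y, z, z_lo, z_hi)

    n_total = spec.points_per_tooth
    n_window = int(round(_CONTACT_WINDOW_FRACTION * n_total))
    n_rest = n_total - n_window
    # Rough area split of the remaining budget between the lateral wall,
    # the mesial face outside the window, and the two caps.
    n_lateral = int(round(0.55 * n_rest))
    n_mesial = int(round(0.25 * n_rest))
    n_caps = n_rest - n_lateral - n_mesial

    w2 = spec.contact_width / 2.0
    win_y = w2 + _CONTACT_WINDOW_MM
    win_z = (z_lo - _CONTACT_WINDOW_MM, z_hi + _CONTACT_WINDOW_MM)

    def sample_mesial(count: int, window_only: bool) -> np.ndarray:
        if window_only:
            y = rng.uniform(-win_y, win_y, count)
            z = rng.uniform(win_z[0], win_z[1], count)
        else:
            y = rng.uniform(-b, b, count)
            z = rng.uniform(0.0, height, count)
            inside = (np.abs(y) <= win_y) & (z >= win_z[0]) & (z <= win_z[1])
            y, z = y[~inside], z[~inside]
        x = recession(y, z)
        keep = x >= _body_min_x(y, cx, a, b, n_exp)
        return np.column_stack([x[keep], y[keep], z[keep]])

    def sample_lateral(count: int) -> np.ndarray:
        t = rng.uniform(0.0, 2.0 * math.pi, count)
        x, y = _superellipse_xy(t, a, b, n_exp)
        x = x + cx
        z = rng.uniform(0.0, height, count)
        keep = x >= recession(y, z)
        return np.column_stack([x[keep], y[keep], z[keep]])

    def sample_caps(count: int) -> np.ndarray:
        x = rng.uniform(cx - a, cx + a, count)
        y = rng.uniform(-b, b, count)
        inside = (np.abs(x - cx) / a) ** n_exp + (np.abs(y) / b) ** n_exp <= 1.0
        x, y = x[inside], y[inside]
        z = np.where(rng.random(x.shape[0]) < 0.5, 0.0, height)
        keep = x >= recession(y, z)
        return np.column_stack([x[keep], y[keep], z[keep]])

    parts = [
        _collect(lambda c: sample_mesial(c, True), n_window),
        _collect(sample_lateral, n_lateral),
        _collect(lambda c: sample_mesial(c, False), n_mesial),
        _collect(sample_caps, n_caps),
    ]
    return np.vstack(parts)


def generate_tooth_pair(spec: ToothPairSpec) -> tuple[LabeledPointCloud, GroundTruth]:
    """Generate a labeled molar-pair point cloud with known ground truth.

    The distal tooth (label 2) occupies x >= 0; the mesial tooth (label 1)
    is its exact mirror image about the contact plane x = 0.  The two flat
    facets coincide at x = 0, so at zero noise the pair is in ideal tight
    contact.  Isotropic Gaussian jitter of ``spec.noise_sd`` mm is added to
    every coordinate.
    """
    rng = np.random.default_rng(spec.seed)
    # two independent samplings so the coincident facets are not
    # point-for-point identical
    mesial = _sample_tooth(spec, rng) * np.array([-1.0, 1.0, 1.0])
    distal = _sample_tooth(spec, rng)
    points = np.vstack([mesial, distal])
    labels = np.concatenate([
        np.full(mesial.shape[0], 1, dtype=int),
        np.full(distal.shape[0], 2, dtype=int),
    ])
    if spec.noise_sd > 0:
        points = points + rng.normal(0.0, spec.noise_sd, points.shape)
    return LabeledPointCloud(points, labels), GroundTruth.from_spec(spec)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupDistribution:
    """Per-group feature distribution: independent normals by default.

    ``moments`` maps each feature column to its (mean, sd) pair.
    """

    name: str
    moments: Mapping[str, tuple[float, float]]
    n: int = 250

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be at least 2")
        for feat, (_, sd) in self.moments.items():
            if sd <= 0:
                raise ValueError(f"{self.name}/{feat}: sd must be positive")
        missing = set(FEATURE_COLUMNS) - set(self.moments)
        if missing:
            raise ValueError(f"{self.name}: missing moments for {sorted(missing)}")


#: Group feature distributions of the study cohort (mean, SD per feature).
NONIMPACTION_GROUP = GroupDistribution(
    "nonimpaction",
    {
        "adjacent_line_length_mm": (3.304, 1.187),
        "adjacent_surface_area_mm2": (7.763, 0.466),
        "tongue_angle_deg": (53.630, 10.275),
        "buccal_angle_deg": (55.849, 15.047),
        "occlusal_angle_deg": (92.006, 13.091),
    },
    n=250,
)

IMPACTION_GROUP = GroupDistribution(
    "impaction",
    {
        "adjacent_line_length_mm": (4.267, 0.937),
        "adjacent_surface_area_mm2": (8.278, 0.390),
        "tongue_angle_deg": (50.236, 9.673),
        "buccal_angle_deg": (51.462, 12.121),
        "occlusal_angle_deg": (59.466, 29.288),
    },
    n=250,
)


def generate_cohort(
    groups: Sequence[GroupDistribution] = (NONIMPACTION_GROUP, IMPACTION_GROUP),
    outcome_rule: str = "by_group",
    coefficients: Mapping[str, float] | None = None,
    seed: int | np.random.Generator | None = None,
    correlation: np.ndarray | None = None,
    n_per_group: int | None = None,
) -> pd.DataFrame:
    """Draw a cohort feature table.

    Parameters
    ----------
    groups : the per-group feature distributions to draw from
    outcome_rule : ``"by_group"`` labels the outcome 1 for the group named
        ``"impaction"`` and 0 otherwise; ``"by_logistic_model"`` draws the
        outcome Bernoulli(p) with logit(p) = intercept + X . beta from
        ``coefficients`` (keys: feature column names plus ``"intercept"``).
    correlation : optional feature x feature correlation matrix applied via
        a Gaussian copula; features are independent by default.
    n_per_group : override each group's own ``n``.

    Returns a DataFrame with the five feature columns plus ``group`` and
    ``outcome`` (int 0/1), reproducible under a fixed seed.
    """
    if not groups:
        raise ValueError("need at least one group")
    if outcome_rule not in ("by_group", "by_logistic_model"):
        raise ValueError(f"unknown outcome_rule {outcome_rule!r}")
    if outcome_rule == "by_logistic_model" and coefficients is None:
        raise ValueError("by_logistic_model requires coefficients")
    rng = np.random.default_rng(seed)
    p = len(FEATURE_COLUMNS)
    if correlation is not None:
        correlation = np.asarray(correlation, float)
        if correlation.shape != (p, p):
            raise ValueError("correlation must be features x features")
        chol = np.linalg.cholesky(correlation)
    frames = []
    for g in groups:
        n = int(n_per_group) if n_per_group is not None else g.n
        z = rng.standard_normal((n, p))
        if correlation is not None:
            z = z @ chol.T
        data = {}
        for j, feat in enumerate(FEATURE_COLUMNS):
            mean, sd = g.moments[feat]
            data[feat] = mean + sd * z[:, j]
        frame = pd.DataFrame(data)
        frame["group"] = g.name
        frames.append(frame)
    cohort = pd.concat(frames, ignore_index=True)
    if outcome_rule == "by_group":
        cohort["outcome"] = (cohort["group"] == "impaction").astype(int)
    else:
        assert coefficients is not None
        logit = np.full(len(cohort), float(coefficients.get("intercept", 0.0)))
        for feat in FEATURE_COLUMNS:
            if feat in coefficients:
                logit += float(coefficients[feat]) * cohort[feat].to_numpy()
        prob = 1.0 / (1.0 + np.exp(-logit))
        cohort["outcome"] = (rng.random(len(cohort)) < prob).astype(int)
    return cohort
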