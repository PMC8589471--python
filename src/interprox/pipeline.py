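"""End-to-end orchestration: simulate -> measure -> analyze -> score.

The pipeline emulates a full study on synthetic data: molar-pair specs are
drawn per group from the cohort feature distributions, each pair is
generated as a labeled point cloud and re-measured by the features module,
the measured records are assembled into a cohort table, the statistical
chain is run, and every record is scored with the published risk model.
One global seed fans out into independent child seeds per stage, so each
stage is reproducible on its own and reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import geometry as geo
from . import stats as st
from . import synthetic as syn

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

log = logging.getLogger("interprox")

#: valid parameter windows for simulated molar pairs (mm / degrees)
_SPEC_LIMITS = {
    "contact_width": (1.5, 5.5),
    "contact_height": (1.0, 3.0),
    "angle": (25.0, 125.0),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of a full pipeline run (all units mm/deg)."""

    seed: int = 0
    n_pairs_per_group: int = 20
    points_per_tooth: int = 18_000
    noise_sd: float = 0.02
    # measurement
    contact_eps: float = 0.1
    extension_len: float = 1.5
    alpha: float = 0.5
    # curvature-weighted subsampling before measurement (None: keep all)
    n_sample: int | None = None
    k_neighbors: int = 16
    floor_prob: float = 0.05
    # analysis
    ttest_variant: str = "welch"
    corr_method: str = "spearman"
    ks_variant: str = "lilliefors"
    analysis_subset_n: int | None = 50

    def measurement_config(self) -> feat.MeasurementConfig:
        return feat.MeasurementConfig(
            contact_eps=self.contact_eps,
            extension_len=self.extension_len,
            alpha=self.alpha,
        )

    def analysis_config(self) -> st.AnalysisConfig:
        return st.AnalysisConfig(
            ttest_variant=self.ttest_variant,
            corr_method=self.corr_method,
            ks_variant=self.ks_variant,
            analysis_subset_n=self.analysis_subset_n,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _draw_spec(group: syn.GroupDistribution, rng: np.random.Generator,
               base: syn.ToothPairSpec, points_per_tooth: int,
               noise_sd: float) -> syn.ToothPairSpec:
    """Draw a molar-pair spec whose ground truth follows a group
    distribution, clipped to the generator's valid parameter windows."""
    def draw(feature: str, lo: float, hi: float) -> float:
        mean, sd = group.moments[feature]
        return float(np.clip(rng.normal(mean, sd), lo, hi))

    w_lo, w_hi = _SPEC_LIMITS["contact_width"]
    h_lo, h_hi = _SPEC_LIMITS["contact_height"]
    a_lo, a_hi = _SPEC_LIMITS["angle"]
    width = draw("adjacent_line_length_mm", w_lo, w_hi)
    area = draw("adjacent_surface_area_mm2", h_lo * width, h_hi * width)
    return dataclasses.replace(
        base,
        contact_width=width,
        contact_height=area / width,
        angle_lingual=draw("tongue_angle_deg", a_lo, a_hi),
        angle_buccal=draw("buccal_angle_deg", a_lo, a_hi),
        angle_occlusal=draw("occlusal_angle_deg", a_lo, a_hi),
        points_per_tooth=points_per_tooth,
        noise_sd=noise_sd,
        seed=int(rng.integers(1 << 31)),
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 groups: tuple[syn.GroupDistribution, syn.GroupDistribution] = (
                     syn.NONIMPACTION_GROUP, syn.IMPACTION_GROUP),
                 ) -> dict:
    """Execute the full chain and return the manifest of produced files.

    Artifacts (all inside ``out_dir``): ``config.yaml`` (resolved config),
    ``features.csv`` (measured pairs), ``report/`` (analysis tables),
    ``scored.csv`` (features plus ``risk_probability``), and
    ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(config.seed).spawn(2)
    spec_rng = np.random.default_rng(children[0])
    sample_rng = np.random.default_rng(children[1])
    config.to_yaml(out / "config.yaml")
    mconfig = config.measurement_config()

    records: list[dict] = []
    base = syn.ToothPairSpec()
    stage = "simulate+measure"
    try:
        for group in groups:
            for i in range(config.n_pairs_per_group):
                spec = _draw_spec(group, spec_rng, base,
                                  config.points_per_tooth, config.noise_sd)
                cloud, truth = syn.generate_tooth_pair(spec)
                if config.n_sample is not None and config.n_sample < len(cloud):
                    curv = geo.estimate_curvature(cloud, config.k_neighbors)
                    cloud = geo.geometric_sample(
                        cloud, config.n_sample, curv, config.floor_prob,
                        rng=sample_rng)
                log.info("%s pair %d/%d: %d points", group.name, i + 1,
                         config.n_pairs_per_group, len(cloud))
                rec = feat.measure_all(cloud, mconfig, group=group.name)
                row = rec.as_dict()
                row["group"] = group.name
                records.append(row)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed "
                           f"(config: {dataclasses.asdict(config)})") from exc

    cohort = pd.DataFrame(records)
    cohort["outcome"] = (cohort["group"] == "impaction").astype(int)
    features_csv = out / "features.csv"
    cohort.to_csv(features_csv, index=False)

    stage = "analyze"
    try:
        report = st.run_full_analysis(cohort, config.analysis_config())
        report_files = report.to_dir(out / "report")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed "
                           f"(config: {dataclasses.asdict(config)})") from exc

    stage = "score"
    scored = cohort.copy()
    scored["risk_probability"] = st.published_risk_score(cohort)
    scored_csv = out / "scored.csv"
    scored.to_csv(scored_csv, index=False)

    manifest = {
        "seed": config.seed,
        "files": ["config.yaml", "features.csv", "scored.csv"]
        + [f"report/{name}" for name in report_files]
        + ["manifest.json"],
        "n_pairs": int(len(cohort)),
        "significant_features": report.significant_features(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def validate_inputs(path: str | Path | tuple[str, str]) -> dict:
    """Diagnostic check of a segmented-pair input file.

    Reports the format, point and label counts, per-tooth bounding boxes
    and warnings (single label, implausible units); never raises for
    content problems — parsing failures are reported as errors.
    """
    diagnostics: dict = {"path": str(path), "warnings": [], "errors": []}
    try:
        cloud = geo.read_model(path)
    except Exception as exc:
        diagnostics["errors"].append(str(exc))
        diagnostics["status"] = "error"
        return diagnostics
    diagnostics["n_points"] = len(cloud)
    labels = cloud.unique_labels.tolist()
    diagnostics["labels"] = {
        int(lab): int((cloud.labels == lab).sum()) for lab in labels
    }
    if len(labels) != 2:
        diagnostics["warnings"].append(
            f"{len(labels)} tooth label(s) found: pair operations unavailable"
        )
    for lab in labels:
        pts = cloud.tooth(int(lab))
        extent = pts.max(axis=0) - pts.min(axis=0)
        diagnostics[f"extent_label_{int(lab)}_mm"] = [round(float(e), 3)
                                                      for e in extent]
        largest = float(extent.max())
        if not 2.0 <= largest <= 30.0:
            diagnostics["warnings"].append(
                f"tooth {int(lab)} extent {largest:.3g} mm outside the "
                "plausible 2-30 mm molar range: check units (mm expected)"
            )
    diagnostics["status"] = "ok" if not diagnostics["warnings"] else "warnings"
    return diagnostics
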