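"""Cohort statistics for food-impaction risk analysis.

The analysis chain mirrors how a tight-proximal-contact impaction cohort
is evaluated: per-feature normality checks (Kolmogorov-Smirnov and
Shapiro-Wilk), independent two-sample t-tests between the impaction and
non-impaction groups, rank correlations among the impaction group's
features, principal component analysis with communality screening, and a
binary logistic regression of impaction on the morphometric features.

A fixed published risk scorer is included: the logistic model

    ln(p / (1 - p)) = 0.889 L + 3.396 A - 0.071 theta_b - 0.089 theta_o
                      - 19.797

with L the adjacent line length (mm), A the adjacent surface area
(mm^2), theta_b the buccal and theta_o the occlusal abduction gap angle
(degrees), and p the probability of food impaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .synthetic import FEATURE_COLUMNS

__all__ = [
    "PUBLISHED_MODEL",
    "NormalityResult",
    "TTestResult",
    "CorrelationResult",
    "PCAResult",
    "LogisticModel",
    "SeparationError",
    "describe_normality",
    "two_sample_ttest",
    "ttest_from_summary",
    "correlation",
    "corr_pvalue_from_r",
    "pca_with_screening",
    "fit_logistic",
    "published_risk_score",
    "odds_ratio",
    "AnalysisConfig",
    "AnalysisReport",
    "run_full_analysis",
]

#: Coefficients of the published impaction risk model (logit scale).
PUBLISHED_MODEL: dict[str, float] = {
    "intercept": -19.797,
    "adjacent_line_length_mm": 0.889,
    "adjacent_surface_area_mm2": 3.396,
    "buccal_angle_deg": -0.071,
    "occlusal_angle_deg": -0.089,
}


# ---------------------------------------------------------------------------
# normality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalityResult:
    """Moments plus Kolmogorov-Smirnov and Shapiro-Wilk normality tests."""

    n: int
    mean: float
    sd: float
    skewness: float
    excess_kurtosis: float
    ks_D: float
    ks_p: float
    sw_W: float
    sw_p: float
    ks_variant: str


def describe_normality(x: Sequence[float],
                       ks_variant: str = "lilliefors") -> NormalityResult:
    """Describe a sample and test it for normality.

    ``ks_variant`` selects how the Kolmogorov-Smirnov statistic is
    converted to a p-value: ``"lilliefors"`` (default) corrects for the
    mean and SD being estimated from the data; ``"fitted_normal"`` is the
    naive one-sample KS test against N(mean, sd).  Skewness is the
    standardized third moment and kurtosis is reported as excess kurtosis
    (normal = 0).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("normality description needs at least 8 observations")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("constant sample: normality is undefined")
    if ks_variant == "lilliefors":
        ks_D, ks_p = lilliefors(x, dist="norm")
    elif ks_variant == "fitted_normal":
        ks_D, ks_p = sps.kstest(x, "norm", args=(float(np.mean(x)), sd))
    else:
        raise ValueError(f"unknown ks_variant {ks_variant!r}")
    sw_W, sw_p = sps.shapiro(x)
    return NormalityResult(
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=sd,
        skewness=float(sps.skew(x, bias=False)),
        excess_kurtosis=float(sps.kurtosis(x, fisher=True, bias=False)),
        ks_D=float(ks_D),
        ks_p=float(ks_p),
        sw_W=float(sw_W),
        sw_p=float(sw_p),
        ks_variant=ks_variant,
    )


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    variant: str


def two_sample_ttest(x: Sequence[float], y: Sequence[float],
                     variant: str = "welch") -> TTestResult:
    """Independent two-sample t-test (two-sided).

    Welch's unequal-variance form is the default; ``variant="student"``
    pools the variances.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two observations")
    return ttest_from_summary(
        float(np.mean(x)), float(np.std(x, ddof=1)), x.size,
        float(np.mean(y)), float(np.std(y, ddof=1)), y.size,
        variant=variant,
    )


def ttest_from_summary(m1: float, s1: float, n1: int,
                       m2: float, s2: float, n2: int,
                       variant: str = "welch") -> TTestResult:
    """Two-sample t-test from printed summary statistics (means, SDs, ns)."""
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least two observations")
    if s1 == 0 and s2 == 0:
        raise ValueError("zero variance in both groups")
    res = sps.ttest_ind_from_stats(
        m1, s1, n1, m2, s2, n2, equal_var=(variant == "student"))
    if variant == "student":
        df = float(n1 + n2 - 2)
    else:  # Welch-Satterthwaite
        v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return TTestResult(
        t=float(res.statistic), df=float(df), p=float(res.pvalue),
        mean1=m1, sd1=s1, n1=int(n1), mean2=m2, sd2=s2, n2=int(n2),
        variant=variant,
    )


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    method: str
    r: float
    n: int
    t_stat: float
    p: float


def corr_pvalue_from_r(r: float, n: int) -> float:
    """Two-sided p-value of a correlation coefficient via the t-approximation

    t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom,

    the same conversion for Pearson's r and (approximately) Spearman's rho.
    """
    if n < 3:
        raise ValueError("need at least 3 observations")
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def correlation(x: Sequence[float], y: Sequence[float],
                method: str = "spearman") -> CorrelationResult:
    """Correlation between two features with a t-approximation p-value.

    Spearman's rank correlation is the default (robust to monotone
    non-linearity); ``method="pearson"`` is available.  Both use the same
    p-value conversion as :func:`corr_pvalue_from_r` so printed
    coefficients can be checked against printed p-values.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples of at least 3")
    if method == "spearman":
        r = float(sps.spearmanr(x, y).statistic)
    elif method == "pearson":
        r = float(sps.pearsonr(x, y).statistic)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    n = int(x.size)
    p = corr_pvalue_from_r(r, n)
    t = math.inf if abs(r) >= 1 else r * math.sqrt((n - 2) / (1 - r * r))
    return CorrelationResult(method=method, r=r, n=n, t_stat=float(t), p=p)


# ---------------------------------------------------------------------------
# PCA with communality screening
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """One screening round of a correlation-matrix PCA.

    ``loadings`` has one row per item and one column per retained
    component (eigenvalue above the Kaiser threshold); ``communalities``
    are the row sums of squared loadings, i.e. the variance share of each
    item captured by the retained components.
    """

    items: list[str]
    eigenvalues: np.ndarray
    loadings: np.ndarray
    communalities: np.ndarray
    n_retained: int
    kaiser: float
    communality_threshold: float
    dropped_item: str | None = None

    def as_frame(self) -> pd.DataFrame:
        cols = {f"component_{k + 1}": self.loadings[:, k]
                for k in range(self.n_retained)}
        cols["communality"] = self.communalities
        return pd.DataFrame(cols, index=pd.Index(self.items, name="item"))


def _pca_round(table: pd.DataFrame, kaiser: float,
               threshold: float) -> PCAResult:
    x = table.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    corr = np.corrcoef(x, rowvar=False)
    if not np.isfinite(corr).all():
        raise ValueError("singular correlation matrix (constant item?)")
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    retained = int(np.sum(eigvals > kaiser))
    retained = max(retained, 1)
    loadings = eigvecs[:, :retained] * np.sqrt(np.maximum(eigvals[:retained], 0.0))
    # sign convention: each component's largest-magnitude loading positive
    for k in range(retained):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
    communalities = np.sum(loadings ** 2, axis=1)
    return PCAResult(
        items=list(table.columns),
        eigenvalues=eigvals,
        loadings=loadings,
        communalities=communalities,
        n_retained=retained,
        kaiser=kaiser,
        communality_threshold=threshold,
    )


def pca_with_screening(table: pd.DataFrame, kaiser: float = 1.0,
                       communality_threshold: float = 0.4) -> list[PCAResult]:
    """Correlation-matrix PCA with iterative communality screening.

    Components with eigenvalue above ``kaiser`` are retained.  An item
    whose communality falls below ``communality_threshold`` is poorly
    captured by the retained components; the worst such item is dropped
    and the analysis re-run until every remaining item passes.  Every
    round is returned (the last one is the accepted solution).
    """
    if table.shape[1] < 2:
        raise ValueError("PCA needs at least two items")
    if table.shape[0] <= table.shape[1]:
        raise ValueError("PCA needs more observations than items")
    rounds: list[PCAResult] = []
    current = table.copy()
    while True:
        result = _pca_round(current, kaiser, communality_threshold)
        rounds.append(result)
        below = result.communalities < communality_threshold
        if not below.any() or current.shape[1] <= 2:
            return rounds
        worst = int(np.argmin(result.communalities))
        dropped = result.items[worst]
        result.dropped_item = dropped
        current = current.drop(columns=[dropped])


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

class SeparationError(RuntimeError):
    """The two outcome classes are (quasi-)separable: the MLE diverges."""


@dataclass
class LogisticModel:
    """Binary logistic regression fit (maximum likelihood via IRLS).

    Arrays are ordered intercept first, then one entry per feature.
    Wald chi-square is (beta / SE)^2; odds ratios and their confidence
    bounds are exp-transforms of the coefficients.
    """

    feature_names: list[str]
    coef: np.ndarray
    se: np.ndarray
    wald_chi2: np.ndarray
    p_values: np.ndarray
    odds_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    converged: bool
    n_iter: int
    log_likelihood: float
    n: int

    @property
    def intercept(self) -> float:
        return float(self.coef[0])

    def coefficient(self, name: str) -> float:
        return float(self.coef[1 + self.feature_names.index(name)])

    def predict_proba(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, float)
        eta = self.coef[0] + X @ self.coef[1:]
        return 1.0 / (1.0 + np.exp(-eta))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "wald_chi2": self.wald_chi2,
                "p": self.p_values,
                "odds_ratio": self.odds_ratios,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            },
            index=pd.Index(["intercept"] + list(self.feature_names),
                           name="term"),
        )


def fit_logistic(X: np.ndarray | pd.DataFrame, y: Sequence[int],
                 feature_names: Sequence[str] | None = None,
                 max_iter: int = 100, tol: float = 1e-8) -> LogisticModel:
    """Fit a binary logistic regression by iteratively reweighted least
    squares.

    Standard errors come from the observed information matrix at the
    optimum; confidence intervals are 95% Wald intervals on the odds-ratio
    scale.  (Quasi-)separation is detected and raised as
    :class:`SeparationError` rather than silently diverging.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j + 1}" for j in range(p)]
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < p + 1:
        raise ValueError("singular design matrix (collinear or constant feature)")
    beta = np.zeros(p + 1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = mu * (1.0 - mu)
        if np.max(w) < 1e-12 or np.abs(beta).max() > 1e3:
            raise SeparationError(
                "outcome classes are (quasi-)separated: coefficients diverge"
            )
        wx = design * w[:, None]
        hessian = design.T @ wx
        score = design.T @ (y - mu)
        try:
            delta = np.linalg.solve(hessian, score)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular design matrix (collinear or constant feature)"
            ) from exc
        beta = beta + delta
        if np.abs(delta).max() < tol:
            converged = True
            break
    eta = design @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    if not converged and np.abs(beta).max() > 1e2:
        raise SeparationError(
            "outcome classes are (quasi-)separated: coefficients diverge"
        )
    w = mu * (1.0 - mu)
    info = design.T @ (design * w[:, None])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    wald = (beta / se) ** 2
    p_values = sps.chi2.sf(wald, df=1)
    z = sps.norm.ppf(0.975)
    log_lik = float(np.sum(y * np.log(mu + 1e-300)
                           + (1 - y) * np.log(1 - mu + 1e-300)))
    return LogisticModel(
        feature_names=list(feature_names),
        coef=beta,
        se=se,
        wald_chi2=wald,
        p_values=p_values,
        odds_ratios=np.exp(beta),
        ci_lower=np.exp(beta - z * se),
        ci_upper=np.exp(beta + z * se),
        converged=converged,
        n_iter=it,
        log_likelihood=log_lik,
        n=n,
    )


def odds_ratio(beta: float, se: float,
               level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Odds ratio exp(beta) with its Wald confidence interval
    exp(beta +/- z * se)."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = sps.norm.ppf(0.5 + level / 2.0)
    return float(np.exp(beta)), (float(np.exp(beta - z * se)),
                                 float(np.exp(beta + z * se)))


def published_risk_score(record: Mapping[str, float] | pd.DataFrame | pd.Series,
                         ) -> float | np.ndarray:
    """Impaction probability from the fixed published logistic model.

    Accepts a mapping / Series with the feature columns (mm, mm^2,
    degrees) or a DataFrame (returns one probability per row).  The
    tongue angle is not part of the published model.
    """
    needed = [k for k in PUBLISHED_MODEL if k != "intercept"]
    if isinstance(record, pd.DataFrame):
        missing = set(needed) - set(record.columns)
        if missing:
            raise KeyError(f"missing features: {sorted(missing)}")
        logit = np.full(len(record), PUBLISHED_MODEL["intercept"])
        for feat in needed:
            logit = logit + PUBLISHED_MODEL[feat] * record[feat].to_numpy(float)
        return 1.0 / (1.0 + np.exp(-logit))
    getter = record.get if hasattr(record, "get") else None
    values = {}
    for feat in needed:
        val = getter(feat) if getter is not None else getattr(record, feat, None)
        if val is None:
            raise KeyError(f"missing feature: {feat}")
        values[feat] = float(val)
    logit = PUBLISHED_MODEL["intercept"] + sum(
        PUBLISHED_MODEL[f] * values[f] for f in needed)
    return float(1.0 / (1.0 + math.exp(-logit)))


# ---------------------------------------------------------------------------
# full analysis report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of the cohort analysis chain."""

    ttest_variant: str = "welch"
    corr_method: str = "spearman"
    ks_variant: str = "lilliefors"
    kaiser: float = 1.0
    communality_threshold: float = 0.4
    alpha: float = 0.05
    #: subsample size per group for the correlation / PCA stages (the
    #: printed correlation p-values of the study are consistent with ~50
    #: subjects per group even though recruitment was larger)
    analysis_subset_n: int | None = 50
    subset_seed: int = 0


@dataclass
class AnalysisReport:
    """All analysis tables plus metadata, writable as CSV + JSON bundle."""

    normality: pd.DataFrame
    group_comparison: pd.DataFrame
    correlations: pd.DataFrame
    pca_rounds: list[PCAResult]
    logistic: LogisticModel | None
    metadata: dict

    def significant_features(self) -> list[str]:
        alpha = self.metadata["alpha"]
        return list(self.group_comparison.index[self.group_comparison["p"] < alpha])

    def to_dir(self, out_dir) -> list[str]:
        """Write one CSV per table plus a JSON bundle; returns filenames."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        self.normality.to_csv(out / "normality.csv")
        written.append("normality.csv")
        self.group_comparison.to_csv(out / "group_comparison.csv")
        written.append("group_comparison.csv")
        self.correlations.to_csv(out / "correlations.csv")
        written.append("correlations.csv")
        for i, rnd in enumerate(self.pca_rounds, start=1):
            name = f"pca_round_{i}.csv"
            rnd.as_frame().to_csv(out / name)
            written.append(name)
        if self.logistic is not None:
            self.logistic.as_frame().to_csv(out / "logistic.csv")
            written.append("logistic.csv")
        bundle = {
            "metadata": self.metadata,
            "normality": self.normality.to_dict(orient="index"),
            "group_comparison": self.group_comparison.to_dict(orient="index"),
            "correlations": self.correlations.to_dict(orient="index"),
            "pca_dropped_items": [r.dropped_item for r in self.pca_rounds
                                  if r.dropped_item],
            "logistic": (self.logistic.as_frame().to_dict(orient="index")
                         if self.logistic is not None else None),
        }
        with open(out / "report.json", "w") as fh:
            json.dump(bundle, fh, indent=2, default=float)
        written.append("report.json")
        return written


def run_full_analysis(cohort: pd.DataFrame,
                      config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the whole cohort analysis on a feature table.

    ``cohort`` needs the five feature columns plus ``outcome`` (0/1);
    a ``group`` column is used for labeling when present.  Produces the
    normality block (impaction group), the between-group t-tests, the
    within-impaction correlations of the angles against line length and
    area, the PCA screening rounds, and the logistic regression of outcome
    on the four published-model features, with p < alpha flagged.
    """
    config = config or AnalysisConfig()
    missing = set(FEATURE_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort lacks feature columns: {sorted(missing)}")
    if "outcome" not in cohort.columns:
        raise ValueError("cohort lacks an 'outcome' column")
    if cohort[list(FEATURE_COLUMNS) + ["outcome"]].isna().any().any():
        raise ValueError("cohort contains missing values")
    impaction = cohort[cohort["outcome"] == 1]
    control = cohort[cohort["outcome"] == 0]
    if len(impaction) < 8 or len(control) < 8:
        raise ValueError("need at least 8 subjects per outcome class")

    normality = pd.DataFrame(
        {feat: vars(describe_normality(impaction[feat], config.ks_variant))
         for feat in FEATURE_COLUMNS}
    ).T.drop(columns=["ks_variant"])
    normality.index.name = "feature"

    rows = {}
    for feat in FEATURE_COLUMNS:
        res = two_sample_ttest(control[feat], impaction[feat],
                               config.ttest_variant)
        rows[feat] = {
            "mean_nonimpaction": res.mean1, "sd_nonimpaction": res.sd1,
            "mean_impaction": res.mean2, "sd_impaction": res.sd2,
            "t": res.t, "df": res.df, "p": res.p,
            "significant": res.p < config.alpha,
        }
    group_comparison = pd.DataFrame(rows).T
    group_comparison.index.name = "feature"

    subset = impaction
    if config.analysis_subset_n is not None and len(impaction) > config.analysis_subset_n:
        subset = impaction.sample(config.analysis_subset_n,
                                  random_state=config.subset_seed)
    angle_feats = ["tongue_angle_deg", "buccal_angle_deg", "occlusal_angle_deg"]
    size_feats = ["adjacent_surface_area_mm2", "adjacent_line_length_mm"]
    corr_rows = {}
    for af in angle_feats:
        for sf in size_feats:
            res = correlation(subset[af], subset[sf], config.corr_method)
            corr_rows[f"{af}~{sf}"] = {
                "r": res.r, "n": res.n, "p": res.p,
                "significant": res.p < config.alpha,
            }
    correlations = pd.DataFrame(corr_rows).T
    correlations.index.name = "pair"

    pca_table = cohort[list(FEATURE_COLUMNS)]
    if config.analysis_subset_n is not None:
        per_group = []
        for _, grp in cohort.groupby("outcome"):
            take = min(config.analysis_subset_n, len(grp))
            per_group.append(grp.sample(take, random_state=config.subset_seed))
        pca_table = pd.concat(per_group)[list(FEATURE_COLUMNS)]
    pca_rounds = pca_with_screening(pca_table, config.kaiser,
                                    config.communality_threshold)

    model_feats = [f for f in PUBLISHED_MODEL if f != "intercept"]
    logistic_error = None
    try:
        logistic = fit_logistic(cohort[model_feats], cohort["outcome"])
    except SeparationError as exc:
        # small cohorts with strong effects can be quasi-separable; the
        # diagnostic is reported instead of a diverged fit
        logistic = None
        logistic_error = str(exc)

    metadata = {
        "n_impaction": int(len(impaction)),
        "n_nonimpaction": int(len(control)),
        "alpha": config.alpha,
        "ttest_variant": config.ttest_variant,
        "corr_method": config.corr_method,
        "ks_variant": config.ks_variant,
        "analysis_subset_n": config.analysis_subset_n,
        "logistic_error": logistic_error,
        "note": (
            "correlation and PCA stages run on a per-group subsample of "
            f"{config.analysis_subset_n} subjects; the full cohort is used "
            "for the t-tests and the logistic fit"
            if config.analysis_subset_n is not None else
            "all stages use the full cohort"
        ),
    }
    return AnalysisReport(
        normality=normality,
        group_comparison=group_comparison,
        correlations=correlations,
        pca_rounds=pca_rounds,
        logistic=logistic,
        metadata=metadata,
    )
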