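"""Phenotype preparation: exclusions, transformation, covariate screen.

Three steps precede every mapping stage:

1. drop mice flagged at necropsy (sick, tumors);
2. diagnose the trait distribution and log-transform when it is
   right-skewed (adipose depot weights typically are), confirming the
   transform with a Kolmogorov–Smirnov test against a fitted normal;
3. screen candidate covariates by Pearson correlation — body weight
   is strongly related to depot weight and is retained, whereas age
   (tightly controlled at necropsy) is not.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .panel import CongenicPanel

logger = logging.getLogger(__name__)


@dataclass
class CovariateScreen:
    r: float
    p: float
    retained: bool
    defined: bool = True


@dataclass
class PhenoPrepReport:
    """Record of every preparation decision, for downstream provenance."""

    n_excluded: int = 0
    exclusion_reasons: dict[str, int] = field(default_factory=dict)
    n_missing_phenotype: int = 0
    raw_skewness: float = float("nan")
    raw_kurtosis: float = float("nan")
    raw_ks_stat: float = float("nan")
    raw_ks_p: float = float("nan")
    transform_applied: bool = False
    final_skewness: float = float("nan")
    final_ks_stat: float = float("nan")
    final_ks_p: float = float("nan")
    covariates: dict[str, CovariateScreen] = field(default_factory=dict)


def apply_exclusions(panel: CongenicPanel) -> tuple[CongenicPanel, PhenoPrepReport]:
    """Remove mice flagged as excluded (tumor/sick) at load time."""
    report = PhenoPrepReport()
    flags = panel.phenotypes["excluded"].astype(bool)
    report.n_excluded = int(flags.sum())
    for reason, count in panel.phenotypes.loc[flags, "reason"].value_counts().items():
        report.exclusion_reasons[str(reason)] = int(count)
    keep = panel.phenotypes.index[~flags]
    if len(keep) == 0:
        warnings.warn("all mice excluded; panel is empty", stacklevel=2)
        out = CongenicPanel(
            panel.markers,
            panel.genotypes.iloc[0:0].copy(),
            panel.phenotypes.iloc[0:0].copy(),
            dict(panel.strain_labels),
        )
        return out, report
    logger.info("excluded %d mice (%s)", report.n_excluded, report.exclusion_reasons)
    return panel.subset(list(keep)), report


def _ks_against_fitted_normal(x: np.ndarray) -> tuple[float, float]:
    # Estimated mean/sd make this a Lilliefors-style screen; the
    # nominal KS p-value is anti-conservative and is used only as a
    # coarse normality flag, not as a calibrated test.
    return stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))[:2]


def diagnose_and_transform(
    weights: np.ndarray,
    skew_threshold: float = 0.5,
    ks_alpha: float = 0.05,
    mouse_ids: list[str] | None = None,
) -> tuple[np.ndarray, PhenoPrepReport]:
    """Decide on, and apply, a natural-log transform of the trait.

    The transform is applied when the raw data look non-normal: either
    moment skewness above ``skew_threshold`` or a KS test against a
    normal with estimated parameters rejecting at ``ks_alpha``. The
    decision is a pure function of the data and thresholds.
    """
    x = np.asarray(weights, dtype=float)
    bad = ~(x > 0)
    if bad.any():
        i = int(np.argmax(bad))
        name = mouse_ids[i] if mouse_ids else f"index {i}"
        raise ValueError(f"non-positive depot weight for mouse {name}")
    if np.ptp(x) == 0:
        raise ValueError("constant phenotype vector: zero variance")

    report = PhenoPrepReport()
    report.raw_skewness = float(stats.skew(x))
    report.raw_kurtosis = float(stats.kurtosis(x))
    report.raw_ks_stat, report.raw_ks_p = map(float, _ks_against_fitted_normal(x))

    transform = report.raw_skewness > skew_threshold or report.raw_ks_p < ks_alpha
    out = np.log(x) if transform else x
    report.transform_applied = bool(transform)
    report.final_skewness = float(stats.skew(out))
    report.final_ks_stat, report.final_ks_p = map(float, _ks_against_fitted_normal(out))
    if transform:
        logger.info(
            "log transform applied (raw skew %.2f, raw KS p %.3g); post-transform KS p %.3g",
            report.raw_skewness,
            report.raw_ks_p,
            report.final_ks_p,
        )
    return out, report


def screen_covariates(
    panel: CongenicPanel,
    corr_threshold: float = 0.3,
    alpha: float = 0.05,
    force_retain: tuple[str, ...] = ("bw_g",),
    force_drop: tuple[str, ...] = ("age_d",),
) -> PhenoPrepReport:
    """Pearson screen of body weight and age against depot weight.

    A covariate is retained when |r| > ``corr_threshold`` and
    p < ``alpha``. Defaults pin the published choice: body weight is
    always used as a covariate and age never is (its range is tightly
    controlled by design); pass empty tuples to let the rule decide.
    """
    pheno = panel.phenotypes.dropna(subset=["depot_g"])
    if len(pheno) < 3:
        raise ValueError("covariate screening needs at least 3 mice with phenotypes")
    report = PhenoPrepReport()
    report.n_missing_phenotype = int(panel.phenotypes["depot_g"].isna().sum())
    pairs = {
        "bw_g": (pheno["depot_g"], pheno["bw_g"]),
        "age_d": (pheno["depot_g"], pheno["age_d"]),
        "bw_age": (pheno["bw_g"], pheno["age_d"]),
    }
    for name, (u, v) in pairs.items():
        if np.ptp(u.to_numpy(dtype=float)) == 0 or np.ptp(v.to_numpy(dtype=float)) == 0:
            report.covariates[name] = CovariateScreen(float("nan"), float("nan"), False, False)
            continue
        r, p = stats.pearsonr(u, v)
        retained = bool(abs(r) > corr_threshold and p < alpha)
        if name in force_retain:
            retained = True
        if name in force_drop or name == "bw_age":
            retained = False
        report.covariates[name] = CovariateScreen(float(r), float(p), retained)
    return report


def prepare_phenotypes(
    panel: CongenicPanel,
    skew_threshold: float = 0.5,
) -> tuple[CongenicPanel, PhenoPrepReport]:
    """Full preparation: exclusions, missing-phenotype drop, transform.

    Returns a panel whose phenotype table carries an additional
    ``depot_t`` column (the analysis trait: log grams when the
    transform fired, grams otherwise).
    """
    panel, report = apply_exclusions(panel)
    has_pheno = panel.phenotypes["depot_g"].notna()
    n_missing = int((~has_pheno).sum())
    if n_missing:
        logger.info("dropping %d mice without depot weight", n_missing)
        panel = panel.subset(list(panel.phenotypes.index[has_pheno]))
    transformed, treport = diagnose_and_transform(
        panel.phenotypes["depot_g"].to_numpy(dtype=float),
        skew_threshold=skew_threshold,
        mouse_ids=list(panel.phenotypes.index),
    )
    report.n_missing_phenotype = n_missing
    report.raw_skewness = treport.raw_skewness
    report.raw_kurtosis = treport.raw_kurtosis
    report.raw_ks_stat = treport.raw_ks_stat
    report.raw_ks_p = treport.raw_ks_p
    report.transform_applied = treport.transform_applied
    report.final_skewness = treport.final_skewness
    report.final_ks_stat = treport.final_ks_stat
    report.final_ks_p = treport.final_ks_p
    panel.phenotypes = panel.phenotypes.copy()
    panel.phenotypes["depot_t"] = transformed
    screen = screen_covariates(panel)
    report.covariates = screen.covariates
    return panel, report
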