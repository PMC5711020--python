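"""Pooled-population marker association scan.

All congenic mice are treated as one mapping population. At each
marker the prepared trait (log depot weight) is fit by a general
linear model with terms entering in a fixed order — body weight
covariate, strain, then marker genotype — using sequential (Type-1)
sums of squares, so the genotype test is adjusted for both. The
per-marker genotype p-values are reported as −log10 p against
Bonferroni-style thresholds, with effect sizes (Cohen's D) and
drop-based QTL support intervals.

Strains that do not segregate at a marker (all A or all H there)
cannot separate a strain effect from the genotype contrast at that
marker; they are pooled into a single factor level so they still
inform the covariate and residual variance while the genotype
contrast stays estimable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import Term, fit_adjusted_groups, fit_glm
from .intervals import Interval
from .panel import CongenicPanel


def significance_threshold(n_markers: int, alpha: float = 0.05) -> float:
    """Bonferroni-corrected scan threshold on the −log10 p scale.

    −log10(alpha / N): with alpha = 0.05 this is the 'significant'
    line; alpha = 0.63 gives the conventional 'suggestive' line (one
    false positive per scan).
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return float(-np.log10(alpha / n_markers))


def cohens_d(group_a, group_h) -> float:
    """Signed standardized mean difference, (mean_H − mean_A)/pooled SD.

    Positive values mean the 129 (donor) allele increases the trait.
    """
    a = np.asarray(group_a, dtype=float)
    h = np.asarray(group_h, dtype=float)
    if len(a) < 2 or len(h) < 2:
        raise ValueError("both genotype groups need n >= 2")
    na, nh = len(a), len(h)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nh - 1) * h.var(ddof=1)) / (na + nh - 2)
    if pooled_var == 0:
        warnings.warn("zero pooled SD; Cohen's D undefined", stacklevel=2)
        return float("nan")
    return float((h.mean() - a.mean()) / np.sqrt(pooled_var))


@dataclass
class ScanResult:
    """Per-marker association table plus scan-level summaries."""

    table: pd.DataFrame
    significant_threshold: float
    suggestive_threshold: float
    term_order: tuple[str, ...]
    peak_marker: str | None = None
    support_intervals: list[Interval] = field(default_factory=list)

    @property
    def peak_row(self) -> pd.Series | None:
        if self.peak_marker is None:
            return None
        return self.table.set_index("marker_id").loc[self.peak_marker]


def scan_markers(
    panel: CongenicPanel,
    alpha: float = 0.05,
    alpha_suggestive: float = 0.63,
    drop: float = 2.0,
    trait_column: str = "depot_t",
) -> ScanResult:
    """Per-marker GLM scan of the prepared panel.

    Requires imputed genotypes and a prepared trait column (see
    ``phenoprep.prepare_phenotypes``). Markers monomorphic in the
    analyzed mice get a missing −log10 p. Thresholds use the number
    of markers scanned.
    """
    if trait_column not in panel.phenotypes.columns:
        raise ValueError(
            f"phenotypes lack {trait_column!r}; run phenoprep.prepare_phenotypes first"
        )
    y = panel.phenotypes[trait_column].to_numpy(dtype=float)
    bw = panel.phenotypes["bw_g"].to_numpy(dtype=float)
    strains = panel.phenotypes["strain"].astype(str).to_numpy()
    geno = panel.genotypes

    rows = []
    for marker_id, pos in zip(panel.markers.marker_ids, panel.markers.positions):
        g = geno[marker_id].to_numpy()
        if "X" in g:
            raise ValueError(f"marker {marker_id} has missing genotypes; impute first")
        n_a = int((g == "A").sum())
        n_h = int((g == "H").sum())
        row = {
            "marker_id": marker_id,
            "pos_bp": pos,
            "n_A": n_a,
            "n_H": n_h,
            "neg_log10_p": np.nan,
            "mean_A": np.nan,
            "mean_H": np.nan,
            "cohens_d": np.nan,
        }
        if n_a == 0 or n_h == 0:
            rows.append(row)
            continue
        # strains with both genotypes present at this marker keep their
        # own level; the rest are pooled
        seg = {
            s
            for s in np.unique(strains)
            if len(np.unique(g[strains == s])) > 1
        }
        strain_factor = np.where(np.isin(strains, sorted(seg)), strains, "_pooled")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_glm(
                y,
                [
                    Term.covariate("bw", bw),
                    Term.factor("strain", strain_factor),
                    Term.factor("genotype", g),
                ],
            )
        if "genotype" in fit.terms:
            row["neg_log10_p"] = fit.neg_log10_p("genotype")
        adj = fit_adjusted_groups(y, g, covariate=bw)
        row["mean_A"] = adj.means["A"]
        row["mean_H"] = adj.means["H"]
        if n_a >= 2 and n_h >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row["cohens_d"] = cohens_d(y[g == "A"], y[g == "H"])
        rows.append(row)

    table = pd.DataFrame(rows)
    n_scanned = len(table)
    result = ScanResult(
        table=table,
        significant_threshold=significance_threshold(n_scanned, alpha),
        suggestive_threshold=significance_threshold(n_scanned, alpha_suggestive),
        term_order=("bw", "strain", "genotype"),
    )
    scores = table["neg_log10_p"]
    if scores.notna().any():
        result.peak_marker = str(table.loc[scores.idxmax(), "marker_id"])
    result.support_intervals = qtl_support_intervals(result, drop=drop)
    return result


def qtl_support_intervals(scan: ScanResult, drop: float = 2.0) -> list[Interval]:
    """Drop-based confidence intervals around scan peaks.

    For each local peak exceeding the significant threshold, the
    interval extends left and right over consecutive markers whose
    −log10 p stays within ``drop`` units of that peak, stopping where
    the profile first falls below (peak − drop). Peaks already inside
    a previously called interval are absorbed by it.
    """
    table = scan.table
    values = table["neg_log10_p"].to_numpy(dtype=float)
    pos = table["pos_bp"].to_numpy(dtype=int)
    n = len(values)
    finite = np.nan_to_num(values, nan=-np.inf)

    def is_local_peak(i: int) -> bool:
        left = finite[i - 1] if i > 0 else -np.inf
        right = finite[i + 1] if i < n - 1 else -np.inf
        return finite[i] >= left and finite[i] >= right

    peaks = [
        i
        for i in range(n)
        if finite[i] > scan.significant_threshold and is_local_peak(i)
    ]
    peaks.sort(key=lambda i: -finite[i])
    intervals: list[tuple[int, int]] = []
    for i in peaks:
        if any(lo <= i <= hi for lo, hi in intervals):
            continue
        floor = finite[i] - drop
        lo = i
        while lo > 0 and finite[lo - 1] >= floor:
            lo -= 1
        hi = i
        while hi < n - 1 and finite[hi + 1] >= floor:
            hi += 1
        intervals.append((lo, hi))
    merged: list[list[int]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [Interval(int(pos[lo]), int(pos[hi])) for lo, hi in merged]
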