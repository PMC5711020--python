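"""Ordinary least squares with Type-1 (sequential) sums of squares.

The mapping analyses all reduce to one linear-model recipe: the
(log-transformed) depot weight is regressed on an ordered list of
terms — body-weight covariate first, then design factors — and each
term is tested by the reduction in residual SS when it enters after
the terms before it (sequential / Type-1 decomposition). Group
contrasts use Fisher's LSD: t-tests of adjusted group means against
the joint model's residual mean square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class Term:
    """One model term: a numeric covariate or a categorical factor."""

    name: str
    values: np.ndarray
    kind: str  # "covariate" | "factor"

    @classmethod
    def covariate(cls, name: str, values) -> "Term":
        return cls(name, np.asarray(values, dtype=float), "covariate")

    @classmethod
    def factor(cls, name: str, values) -> "Term":
        return cls(name, np.asarray(values, dtype=object), "factor")


@dataclass
class TermStats:
    ss: float
    df: int
    ms: float
    f: float
    p: float
    rank_deficient: bool = False


@dataclass
class GlmFit:
    """Sequential-SS fit: per-term stats plus residual quantities."""

    term_names: list[str]
    terms: dict[str, TermStats]
    dropped_terms: list[str]
    n_obs: int
    rss: float
    df_resid: int
    mse: float
    total_ss: float
    coef: np.ndarray = field(repr=False, default=None)

    def neg_log10_p(self, term: str) -> float:
        p = max(self.terms[term].p, 1e-300)
        return float(-np.log10(p))


def _encode(term: Term) -> np.ndarray:
    if term.kind == "covariate":
        return term.values.reshape(-1, 1)
    levels = sorted({str(v) for v in term.values})
    # full one-hot; rank bookkeeping below absorbs the redundancy
    cols = [np.asarray([str(v) == lev for v in term.values], dtype=float) for lev in levels]
    return np.column_stack(cols)


def _rss_rank(X: np.ndarray, y: np.ndarray) -> tuple[float, int, np.ndarray]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank), beta


def fit_glm(y, terms: Sequence[Term]) -> GlmFit:
    """Fit y on the ordered terms; test each by sequential SS.

    Terms enter in the order given; each term's SS is the drop in
    residual SS relative to the model with only the preceding terms,
    its df the increase in design rank, and its F-ratio uses the full
    model's residual mean square. Factors observed at fewer than two
    levels are dropped with a warning; a rank-deficient term keeps its
    generalized-inverse SS and is flagged.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    kept: list[Term] = []
    dropped: list[str] = []
    for term in terms:
        if len(term.values) != n:
            raise ValueError(f"term {term.name!r} length {len(term.values)} != n {n}")
        if term.kind == "factor" and len(set(map(str, term.values))) < 2:
            warnings.warn(f"factor {term.name!r} has < 2 observed levels; dropped", stacklevel=2)
            dropped.append(term.name)
            continue
        kept.append(term)

    X = np.ones((n, 1))
    rss_prev, rank_prev, _ = _rss_rank(X, y)
    total_ss = rss_prev
    steps: list[tuple[str, float, int, bool]] = []
    for term in kept:
        X = np.column_stack([X, _encode(term)])
        rss, rank, beta = _rss_rank(X, y)
        df = rank - rank_prev
        expected_df = 1 if term.kind == "covariate" else len(set(map(str, term.values))) - 1
        steps.append((term.name, rss_prev - rss, df, df < expected_df))
        rss_prev, rank_prev = rss, rank

    df_resid = n - rank_prev
    if df_resid <= 0:
        raise ValueError(f"model saturated: n={n}, design rank={rank_prev}")
    mse = rss_prev / df_resid
    stats_by_term: dict[str, TermStats] = {}
    for name, ss, df, deficient in steps:
        if df > 0 and mse > 0:
            f = (ss / df) / mse
            p = float(stats.f.sf(f, df, df_resid))
        else:
            f, p = float("nan"), float("nan")
        if deficient:
            warnings.warn(f"term {name!r} rank-deficient in this design", stacklevel=2)
        stats_by_term[name] = TermStats(ss, df, ss / df if df else float("nan"), f, p, deficient)
    _, _, beta = _rss_rank(X, y)
    return GlmFit(
        term_names=[t.name for t in kept],
        terms=stats_by_term,
        dropped_terms=dropped,
        n_obs=n,
        rss=rss_prev,
        df_resid=df_resid,
        mse=mse,
        total_ss=total_ss,
        coef=beta,
    )


@dataclass
class AdjustedGroups:
    """Cell-means ANCOVA: adjusted group means sharing one residual MSE."""

    means: dict[str, float]
    n: dict[str, int]
    mse: float
    df_resid: int

    def lsd(self, g1: str, g2: str) -> tuple[float, float, float]:
        """LSD contrast of two groups: (difference g1-g2, t, two-sided p).

        t = (m1 - m2) / sqrt(MSE * (1/n1 + 1/n2)) on the joint
        residual df — Fisher's least significant difference, with no
        multiplicity adjustment.
        """
        delta = self.means[g1] - self.means[g2]
        se = np.sqrt(self.mse * (1.0 / self.n[g1] + 1.0 / self.n[g2]))
        if se == 0:
            return delta, float("nan"), 1.0 if delta == 0 else 0.0
        t = delta / se
        p = float(2.0 * stats.t.sf(abs(t), self.df_resid))
        return float(delta), float(t), p


def fit_adjusted_groups(y, groups, covariate=None) -> AdjustedGroups:
    """Fit y ~ group cells (+ centered covariate); return adjusted means.

    With the covariate centered on its grand mean, the cell
    coefficients are the covariate-adjusted (least-squares) group
    means evaluated at the average covariate value.
    """
    y = np.asarray(y, dtype=float)
    labels = [str(g) for g in groups]
    levels = sorted(set(labels))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    cells = np.column_stack(
        [np.asarray([g == lev for g in labels], dtype=float) for lev in levels]
    )
    X = cells
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        X = np.column_stack([cells, cov - cov.mean()])
    rss, rank, beta = _rss_rank(X, y)
    df_resid = len(y) - rank
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom for LSD contrasts")
    return AdjustedGroups(
        means={lev: float(beta[i]) for i, lev in enumerate(levels)},
        n={lev: labels.count(lev) for lev in levels},
        mse=rss / df_resid,
        df_resid=df_resid,
    )
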