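"""Candidate-gene filtering downstream of QTL mapping.

Expression evidence: per-gene log2 fold change and p-value from two
independent donor-vs-host comparisons; a gene passes an experiment's
filter at |log2FC| > 0.58 (1.5-fold) and/or a Benjamini–Hochberg FDR
below 0.05, and is "reproducible" when it passes in both experiments
and lies inside the congenic donor region. Variant-effect and human
GWAS-orthologue evidence arrive as precomputed boolean flags; the
final step cross-tabulates all evidence classes over the genes inside
the inferred QTL intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .intervals import IntervalSet
from .sequential import QtlModel

EXPRESSION_COLUMNS = ["gene_id", "chrom", "start", "end", "log2fc", "p_value"]

EVIDENCE_FLAGS = ["differential_expression", "missense_variant", "human_gwas_orthologue"]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone in the p ranking)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _validate_expression(frame: pd.DataFrame, name: str) -> pd.DataFrame:
    missing = set(EXPRESSION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{name} missing columns: {sorted(missing)}")
    if frame["gene_id"].duplicated().any():
        raise ValueError(f"{name} has duplicated gene ids")
    return frame


@dataclass
class DeFilterResult:
    """Per-experiment pass sets and the reproducible intersection."""

    passed: dict[str, set[str]]
    reproducible: set[str]
    q_values: dict[str, pd.Series]


def de_filter(
    experiments: dict[str, pd.DataFrame],
    region: IntervalSet | None = None,
    fc_threshold_log2: float = 0.58,
    q_threshold: float = 0.05,
    require_both_subfilters: bool = False,
) -> DeFilterResult:
    """Differential-expression filter with cross-experiment reproducibility.

    Within each experiment a gene passes at |log2fc| > threshold OR
    FDR q < threshold (set ``require_both_subfilters`` for AND). The
    reproducible set is the intersection of the per-experiment pass
    sets, restricted to genes inside ``region`` when given. Gene
    universes are intersected (with a warning) if they differ.
    """
    if len(experiments) < 2:
        raise ValueError("need at least two experiments for reproducibility")
    frames = {name: _validate_expression(f, name) for name, f in experiments.items()}
    universes = [set(f["gene_id"]) for f in frames.values()]
    shared = set.intersection(*universes)
    if any(u != shared for u in universes):
        import warnings

        warnings.warn("experiments have mismatched gene universes; using intersection",
                      stacklevel=2)
    passed: dict[str, set[str]] = {}
    qvals: dict[str, pd.Series] = {}
    coords: dict[str, tuple[str, int, int]] = {}
    for name, frame in frames.items():
        sub = frame[frame["gene_id"].isin(shared)].reset_index(drop=True)
        q = bh_fdr(sub["p_value"].to_numpy())
        qvals[name] = pd.Series(q, index=sub["gene_id"])
        fc_pass = sub["log2fc"].abs() > fc_threshold_log2
        q_pass = pd.Series(q < q_threshold, index=sub.index)
        ok = (fc_pass & q_pass) if require_both_subfilters else (fc_pass | q_pass)
        passed[name] = set(sub.loc[ok, "gene_id"])
        for _, row in sub.iterrows():
            coords[row["gene_id"]] = (str(row["chrom"]), int(row["start"]), int(row["end"]))
    reproducible = set.intersection(*passed.values())
    if region is not None:
        reproducible = {
            g
            for g in reproducible
            if region.contains(coords[g][1]) or region.contains(coords[g][2])
        }
    return DeFilterResult(passed=passed, reproducible=reproducible, q_values=qvals)


@dataclass
class EvidenceTable:
    """Per-gene evidence flags within QTL intervals + intersection counts."""

    genes: pd.DataFrame
    intersection_counts: dict[tuple[bool, bool, bool], int]

    def count(self, de: bool, missense: bool, gwas: bool) -> int:
        return self.intersection_counts.get((de, missense, gwas), 0)


def overlap_evidence(
    qtl_model: QtlModel,
    gene_table: pd.DataFrame,
    flags: pd.DataFrame,
) -> EvidenceTable:
    """Cross-tabulate evidence flags over genes inside the QTL intervals.

    ``gene_table`` columns: gene_id, chrom, start, end. ``flags``
    columns: gene_id plus the three boolean evidence columns (missing
    flags default to False). All 2^3 intersection cells are reported.
    """
    qtl_region = IntervalSet(
        [(q.interval.start, q.interval.end) for q in qtl_model.qtls]
    )
    if not qtl_model.qtls:
        empty = pd.DataFrame(columns=["gene_id", *EVIDENCE_FLAGS])
        counts = {combo: 0 for combo in _all_combos()}
        return EvidenceTable(genes=empty, intersection_counts=counts)
    flags = flags.set_index("gene_id") if "gene_id" in flags.columns else flags
    rows = []
    for _, gene in gene_table.iterrows():
        inside = qtl_region.contains(int(gene["start"])) or qtl_region.contains(
            int(gene["end"])
        )
        if not inside:
            continue
        row = {"gene_id": gene["gene_id"]}
        for flag in EVIDENCE_FLAGS:
            row[flag] = bool(flags[flag].get(gene["gene_id"], False)) if flag in flags else False
        rows.append(row)
    genes = pd.DataFrame(rows, columns=["gene_id", *EVIDENCE_FLAGS])
    counts = {combo: 0 for combo in _all_combos()}
    for _, row in genes.iterrows():
        combo = tuple(bool(row[f]) for f in EVIDENCE_FLAGS)
        counts[combo] += 1
    return EvidenceTable(genes=genes, intersection_counts=counts)


def _all_combos():
    from itertools import product

    return list(product((False, True), repeat=3))
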