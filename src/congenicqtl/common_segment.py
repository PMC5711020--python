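"""Common segment method: strain classification and shared-region test.

The common segment method assumes the mapped region carries a single
QTL: every congenic strain whose donor fragment covers the QTL should
differ between donor and host littermates, every other strain should
not, and the QTL must then lie in the region shared by all positive
strains and absent from all negative ones. The method is run in two
variants — a narrow analysis restricted to strains with large groups
of full-length donor mice, and a broad analysis using nearly all mice
— and its failure mode (no shared region, because linked QTLs of
opposite sign mask each other) is exactly what motivates the
sequential method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import fit_adjusted_groups
from .panel import CongenicPanel

logger = logging.getLogger(__name__)


@dataclass
class StrainClassification:
    strain_id: str
    n_host: int
    n_donor: int
    mean_host: float
    mean_donor: float
    lsd_p: float
    verdict: str  # "positive" | "negative" | "untestable"


@dataclass
class SharedRegionResult:
    """Per-marker single-QTL predicate and overall verdict.

    A marker supports a single shared QTL when it is H in the
    full-length donor genotype of every positive strain and A in that
    of every negative strain.
    """

    per_marker: pd.Series  # bool per marker_id
    single_region_exists: bool
    n_positive: int
    n_negative: int
    vacuous: bool = False


def select_strains(
    panel: CongenicPanel,
    mode: str = "narrow",
    min_n: int = 12,
    broad_floor: int = 4,
) -> tuple[list[str], pd.Series]:
    """Choose strains and mice for a common-segment analysis.

    narrow: strains with at least ``min_n`` mice per genotype group,
    counting only full-length donor mice on the donor side; partial
    mice are excluded from the analysis subset.
    broad: every strain and every mouse, except strains with any
    genotype group smaller than ``broad_floor``.

    Returns (strain ids, boolean mask over panel mice to analyze).
    """
    if mode not in {"narrow", "broad"}:
        raise ValueError(f"mode must be 'narrow' or 'broad', got {mode!r}")
    if panel.n_mice == 0:
        return [], pd.Series(dtype=bool)
    strain_regions = panel.strain_donor_regions()
    regions = panel.donor_regions()
    pheno = panel.phenotypes
    is_donor = pd.Series(
        {mid: bool(regions[str(mid)]) for mid in pheno.index}, dtype=bool
    )
    full = pd.Series(
        {mid: panel.is_full_length(str(mid), strain_regions) for mid in pheno.index},
        dtype=bool,
    )
    selected: list[str] = []
    mask = pd.Series(False, index=pheno.index)
    for strain in panel.strains:
        in_strain = pheno["strain"].astype(str) == strain
        n_host = int((in_strain & ~is_donor).sum())
        if mode == "narrow":
            donor_ok = in_strain & is_donor & full
            if n_host >= min_n and int(donor_ok.sum()) >= min_n:
                selected.append(strain)
                mask |= (in_strain & ~is_donor) | donor_ok
        else:
            n_donor = int((in_strain & is_donor).sum())
            if n_host >= broad_floor and n_donor >= broad_floor:
                selected.append(strain)
                mask |= in_strain
            else:
                logger.info(
                    "broad analysis: excluding strain %s (host n=%d, donor n=%d)",
                    strain,
                    n_host,
                    n_donor,
                )
    return selected, mask


def classify_strains(
    panel: CongenicPanel,
    strains: list[str],
    mask: pd.Series,
    alpha: float = 0.05,
    trait_column: str = "depot_t",
) -> list[StrainClassification]:
    """Classify each strain as QTL-positive or -negative.

    One joint GLM over all selected mice — strain x genotype cell
    means with a body-weight covariate — then a per-strain Fisher's
    LSD contrast of donor vs host adjusted means using the shared
    residual MSE, at unadjusted ``alpha``.
    """
    if len(strains) < 2:
        raise ValueError("classification needs at least 2 strains")
    sub = panel.subset(list(panel.phenotypes.index[mask]))
    regions = sub.donor_regions()
    pheno = sub.phenotypes
    strain_arr = pheno["strain"].astype(str)
    geno_arr = pd.Series(
        {mid: "donor" if regions[str(mid)] else "host" for mid in pheno.index}
    )
    cells = strain_arr + "|" + geno_arr
    adj = fit_adjusted_groups(
        pheno[trait_column].to_numpy(dtype=float),
        cells.to_numpy(),
        covariate=pheno["bw_g"].to_numpy(dtype=float),
    )
    out = []
    for strain in sorted(strains):
        host_cell, donor_cell = f"{strain}|host", f"{strain}|donor"
        n_host = adj.n.get(host_cell, 0)
        n_donor = adj.n.get(donor_cell, 0)
        if n_host < 2 or n_donor < 2:
            out.append(
                StrainClassification(
                    strain, n_host, n_donor, float("nan"), float("nan"),
                    float("nan"), "untestable",
                )
            )
            continue
        delta, _, p = adj.lsd(donor_cell, host_cell)
        verdict = "positive" if p < alpha else "negative"
        out.append(
            StrainClassification(
                strain,
                n_host,
                n_donor,
                adj.means[host_cell],
                adj.means[donor_cell],
                p,
                verdict,
            )
        )
    return out


def shared_region_test(
    classifications: list[StrainClassification],
    panel: CongenicPanel,
) -> SharedRegionResult:
    """Test the single-QTL shared-segment hypothesis marker by marker.

    Uses each strain's full-length donor region: a marker satisfies
    the predicate when it lies inside the donor region of every
    positive strain and outside that of every negative strain. The
    hypothesis survives iff at least one marker satisfies it.
    """
    positives = [c.strain_id for c in classifications if c.verdict == "positive"]
    negatives = [c.strain_id for c in classifications if c.verdict == "negative"]
    strain_regions = panel.strain_donor_regions()
    per_marker = {}
    for marker_id, pos in zip(panel.markers.marker_ids, panel.markers.positions):
        ok = all(strain_regions[s].contains(pos) for s in positives) and all(
            not strain_regions[s].contains(pos) for s in negatives
        )
        per_marker[marker_id] = ok
    vacuous = len(positives) == 0
    if vacuous:
        warnings.warn("no positive strains; shared-region verdict is vacuous", stacklevel=2)
    series = pd.Series(per_marker)
    return SharedRegionResult(
        per_marker=series,
        single_region_exists=bool(series.any()) and not vacuous,
        n_positive=len(positives),
        n_negative=len(negatives),
        vacuous=vacuous,
    )
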