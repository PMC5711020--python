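"""Synthetic congenic-panel generator.

Emulates a branching backcross congenic panel on one chromosome: each
strain is defined by a single paternal donor fragment (129-derived,
heterozygous in carriers), every mouse carries zero or one copy of
it, and a configurable fraction of donor mice inherit a fragment
shortened from the distal end by a single recombination. Phenotypes
follow the generative model the analyses assume:

    log depot = b0 + b_bw (bw − μ_bw) + Σ_q effect_q σ_pheno 1[donor ∋ q] + ε,
    ε ~ N(0, σ_resid),   bw ~ N(μ_bw, σ_bw)

where σ_pheno = sqrt(σ_resid² + b_bw² σ_bw²) is the phenotypic SD of
log depot among host mice, so a QTL's configured effect equals the
expected Cohen's D between genotype groups at a fully linked marker.
With lognormal residuals (default) the raw depot weights in grams are
right-skewed, which trips the preparation stage's log transform.

The default preset mirrors the branching 12-strain structure that the
sequential method needs: four QTLs (three with the 129 allele
increasing depot weight, one decreasing), strains whose donor
fragments isolate each QTL, strains spanning the opposing pair (whose
net effects cancel — the masked configuration), and two duplicated
donor regions (merged by the MST builder).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .panel import CongenicPanel, MarkerMap
from .panel import write_panel as _write_panel_files

MB = 1_000_000


@dataclass(frozen=True)
class QtlSpec:
    """One planted QTL: position and signed standardized effect.

    ``effect`` is in units of the host-population phenotypic SD of
    log depot weight; positive means the 129 (donor) allele increases
    the trait.
    """

    pos_bp: int
    effect: float

    @property
    def sign(self) -> str:
        return "+" if self.effect >= 0 else "-"


@dataclass(frozen=True)
class StrainSpec:
    """One congenic strain: defining donor fragment and group sizes."""

    strain_id: str
    start_bp: int
    end_bp: int
    n_donor: int
    n_host: int

    @property
    def region(self) -> IntervalSet:
        return IntervalSet([(self.start_bp, self.end_bp)])


@dataclass
class SimConfig:
    """All generative knobs for one synthetic panel."""

    marker_positions: tuple[int, ...]
    strains: tuple[StrainSpec, ...]
    qtls: tuple[QtlSpec, ...]
    chrom: str = "chr9"
    bw_mean_g: float = 31.0
    bw_sd_g: float = 3.0
    log_depot_baseline: float = math.log(0.5)
    bw_slope: float = 0.08  # log-depot units per gram of body weight
    resid_sd: float = 0.35  # residual SD of log depot
    lognormal: bool = True
    partial_prob: float = 0.1
    truncate_both_ends: bool = False
    missing_rate: float = 0.0
    exclusion_rate: float = 0.01
    age_mean_d: float = 180.0
    age_sd_d: float = 2.0
    seed: int = 17

    @property
    def pheno_sd(self) -> float:
        """Host-population SD of log depot (residual + body-weight paths)."""
        return math.sqrt(self.resid_sd**2 + (self.bw_slope * self.bw_sd_g) ** 2)

    def validate(self) -> None:
        lo, hi = min(self.marker_positions), max(self.marker_positions)
        for q in self.qtls:
            if not lo <= q.pos_bp <= hi:
                raise ValueError(
                    f"QTL at {q.pos_bp} lies outside the marker span [{lo}, {hi}]"
                )


def _mb(x: float) -> int:
    return int(round(x * MB))


#: Donor fragments (Mb) of the default branching 12-strain preset.
#: With four ordered QTLs a single contiguous fragment can realize
#: only ten distinct non-empty QTL subsets; the preset uses all ten,
#: plus two exact duplicate fragments (3.2 of 3.1, 4.2 of 3.1.2) that
#: exercise the MST duplicate-merge path. Distinct QTL content for
#: every merged node pair means every possible strain comparison
#: differs in at least one QTL.
DEFAULT_STRAIN_FRAGMENTS_MB: dict[str, tuple[float, float]] = {
    "1": (42.0, 44.2),        # QTL1
    "1.1": (42.0, 53.0),      # QTL1+2
    "1.1.1": (42.0, 56.0),    # QTL1+2+3
    "1.2": (42.0, 124.6),     # all four
    "3": (50.0, 53.0),        # QTL2
    "3.1": (50.0, 56.0),      # QTL2+3 (opposing pair -> masked)
    "3.2": (50.0, 56.0),      # duplicate of 3.1
    "3.1.1": (53.9, 56.0),    # QTL3
    "3.1.2": (53.9, 124.6),   # QTL3+4 (opposing pair -> masked)
    "4": (108.0, 120.0),      # QTL4
    "4.1": (50.0, 124.6),     # QTL2+3+4
    "4.2": (53.9, 124.6),     # duplicate of 3.1.2
}

#: Planted QTLs: positions (Mb) and standardized effects. Signs follow
#: the motivating architecture (+, +, −, +); magnitudes are equal at
#: 1.25 phenotypic SD so that (a) the opposing pair cancels exactly in
#: a spanning fragment and (b) a single 30-vs-30 adjusted contrast
#: detects one QTL with ~99% power — the regime a sequential congenic
#: comparison is designed for.
DEFAULT_QTLS_MB: tuple[tuple[float, float], ...] = (
    (43.5, +1.25),
    (52.5, +1.25),
    (54.26, -1.25),
    (113.9, +1.25),
)


def default_marker_positions(n_markers: int = 148) -> tuple[int, ...]:
    """Deterministic marker map: ~3–124.6 Mb with anchored positions.

    Markers sit at every strain-fragment boundary and every QTL
    position of the default preset (so realized donor regions match
    their definitions at marker resolution), with the remainder on a
    uniform grid.
    """
    fixed = {_mb(b) for se in DEFAULT_STRAIN_FRAGMENTS_MB.values() for b in se}
    fixed |= {_mb(pos) for pos, _ in DEFAULT_QTLS_MB}
    grid = np.linspace(3 * MB, 124.6 * MB, n_markers * 2).astype(int)
    positions = sorted(fixed)
    for g in grid:
        if len(positions) >= n_markers:
            break
        if all(abs(g - p) > 100_000 for p in positions):
            positions.append(int(g))
            positions.sort()
    return tuple(sorted(positions)[:n_markers])


def default_config(n_per_genotype: int = 30, seed: int = 17, **overrides) -> SimConfig:
    """The branching 12-strain, 4-QTL preset."""
    strains = tuple(
        StrainSpec(sid, _mb(s), _mb(e), n_per_genotype, n_per_genotype)
        for sid, (s, e) in DEFAULT_STRAIN_FRAGMENTS_MB.items()
    )
    qtls = tuple(QtlSpec(_mb(pos), eff) for pos, eff in DEFAULT_QTLS_MB)
    cfg = SimConfig(
        marker_positions=default_marker_positions(),
        strains=strains,
        qtls=qtls,
        seed=seed,
    )
    cfg = replace(cfg, **overrides) if overrides else cfg
    cfg.validate()
    return cfg


#: 22-strain panel at published group sizes (3–176 mice per strain,
#: ~1,293 in total), including three strains too small to test.
FULL_PANEL_MB: tuple[tuple[str, float, float, int], ...] = (
    ("1", 42.0, 56.0, 113),
    ("1.1", 42.0, 53.0, 176),
    ("1.1.1", 42.0, 50.0, 3),
    ("1.2", 42.0, 44.2, 14),
    ("3", 50.0, 124.6, 175),
    ("3.1", 50.0, 56.0, 120),
    ("3.1.1", 53.9, 56.0, 106),
    ("3.1.1.1", 53.9, 54.5, 127),
    ("3.1.1.2", 54.5, 56.0, 34),
    ("3.1.1.3", 53.9, 124.6, 14),
    ("3.1.1.4", 56.5, 124.6, 63),
    ("3.1.2", 50.0, 53.0, 21),
    ("3.1.3", 50.0, 52.0, 6),
    ("3.1.4", 52.0, 56.0, 11),
    ("3.1.4.1", 52.0, 53.9, 26),
    ("4", 42.6, 58.3, 119),
    ("4.1", 42.6, 53.0, 44),
    ("4.1a", 42.6, 52.0, 22),
    ("4.2", 44.5, 58.3, 16),
    ("4.3", 56.5, 120.0, 18),
    ("4.4", 108.0, 120.0, 61),
    ("4.5", 42.6, 124.6, 4),
)


def full_config(seed: int = 17, **overrides) -> SimConfig:
    """22-strain preset with realistic (highly unbalanced) group sizes."""
    strains = tuple(
        StrainSpec(sid, _mb(s), _mb(e), n // 2, n - n // 2)
        for sid, s, e, n in FULL_PANEL_MB
    )
    qtls = tuple(QtlSpec(_mb(pos), eff) for pos, eff in DEFAULT_QTLS_MB)
    cfg = SimConfig(
        marker_positions=default_marker_positions(),
        strains=strains,
        qtls=qtls,
        seed=seed,
    )
    cfg = replace(cfg, **overrides) if overrides else cfg
    cfg.validate()
    return cfg


def simulate_panel(config: SimConfig) -> tuple[CongenicPanel, dict]:
    """Draw one panel; fully reproducible from ``config.seed``.

    Returns the panel plus a truth record (planted QTLs, defined and
    realized per-mouse donor fragments, truncation points) for test
    assertions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    positions = np.asarray(config.marker_positions)
    marker_ids = [f"m{i + 1:03d}" for i in range(len(positions))]
    markers = MarkerMap(
        tuple(marker_ids),
        tuple(config.chrom for _ in marker_ids),
        tuple(int(p) for p in positions),
    )

    geno_rows: dict[str, list[str]] = {}
    pheno_rows = []
    truth_mice = {}
    for strain in config.strains:
        for is_donor, count in ((True, strain.n_donor), (False, strain.n_host)):
            for i in range(count):
                mouse_id = f"{strain.strain_id}_{'d' if is_donor else 'h'}{i + 1:03d}"
                start, end = strain.start_bp, strain.end_bp
                truncated = False
                if is_donor and config.partial_prob > 0 and rng.random() < config.partial_prob:
                    truncated = True
                    if config.truncate_both_ends and rng.random() < 0.5:
                        start = int(rng.uniform(start, end))
                    else:
                        end = int(rng.uniform(start, end))
                if is_donor:
                    codes = np.where(
                        (positions >= start) & (positions <= end), "H", "A"
                    ).tolist()
                    realized = [start, end]
                else:
                    codes = ["A"] * len(positions)
                    realized = None
                if config.missing_rate > 0:
                    mask = rng.random(len(codes)) < config.missing_rate
                    codes = ["X" if m else c for c, m in zip(codes, mask)]
                bw = rng.normal(config.bw_mean_g, config.bw_sd_g)
                bw = max(bw, 15.0)
                genetic = sum(
                    q.effect * config.pheno_sd
                    for q in config.qtls
                    if is_donor and start <= q.pos_bp <= end
                )
                log_depot = (
                    config.log_depot_baseline
                    + config.bw_slope * (bw - config.bw_mean_g)
                    + genetic
                    + rng.normal(0.0, config.resid_sd)
                )
                depot = math.exp(log_depot) if config.lognormal else max(
                    0.01, math.exp(config.log_depot_baseline) + log_depot - config.log_depot_baseline
                )
                age = int(round(rng.normal(config.age_mean_d, config.age_sd_d)))
                excluded = bool(rng.random() < config.exclusion_rate)
                geno_rows[mouse_id] = codes
                pheno_rows.append(
                    {
                        "mouse_id": mouse_id,
                        "strain": strain.strain_id,
                        "depot_g": round(depot, 6),
                        "bw_g": round(bw, 4),
                        "age_d": age,
                        "excluded": excluded,
                        "reason": "tumor" if excluded else "",
                    }
                )
                truth_mice[mouse_id] = {
                    "donor": is_donor,
                    "truncated": truncated,
                    "realized_region": realized,
                }

    geno = pd.DataFrame.from_dict(geno_rows, orient="index", columns=marker_ids)
    geno.index.name = "mouse_id"
    pheno = pd.DataFrame(pheno_rows).set_index("mouse_id")
    panel = CongenicPanel(markers, geno, pheno)
    truth = {
        "seed": config.seed,
        "chrom": config.chrom,
        "qtls": [
            {"pos_bp": q.pos_bp, "effect": q.effect, "sign": q.sign} for q in config.qtls
        ],
        "strains": {
            s.strain_id: {
                "region": [s.start_bp, s.end_bp],
                "n_donor": s.n_donor,
                "n_host": s.n_host,
            }
            for s in config.strains
        },
        "pheno_sd": config.pheno_sd,
        "mice": truth_mice,
    }
    return panel, truth


def simulate_pooled_population(
    n_mice: int = 2000,
    effect: float = 0.5,
    seed: int = 17,
    qtl_pos_mb: float = 52.5,
    **overrides,
) -> tuple[CongenicPanel, dict]:
    """Balanced two-genotype pooled population with one planted QTL.

    Half the mice carry a donor fragment spanning the QTL, half are
    host littermates; the expected Cohen's D of log depot weight at a
    marker fully linked to the QTL equals ``effect``.
    """
    strain = StrainSpec("pool", _mb(45.0), _mb(60.0), n_mice // 2, n_mice - n_mice // 2)
    cfg = SimConfig(
        marker_positions=default_marker_positions(),
        strains=(strain,),
        qtls=(QtlSpec(_mb(qtl_pos_mb), effect),),
        partial_prob=0.0,
        exclusion_rate=0.0,
        seed=seed,
    )
    cfg = replace(cfg, **overrides) if overrides else cfg
    return simulate_panel(cfg)


def write_panel(panel: CongenicPanel, out_dir: str | Path, truth: dict | None = None):
    """Write the three panel input files plus (optionally) truth.json."""
    paths = _write_panel_files(panel, out_dir)
    if truth is not None:
        truth_path = Path(out_dir) / "truth.json"
        truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
        paths["truth"] = truth_path
    return paths
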