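"""Congenic panel container and file I/O.

A panel bundles the three inputs every mapping stage consumes:

* a marker map (marker id, chromosome, bp position),
* a per-mouse genotype matrix with backcross codes
  ``A`` = homozygous host (B6/B6), ``H`` = heterozygous donor (129/B6),
  ``X`` = missing — a backcross design carries zero or one copy of the
  donor region, so a third allele state never occurs,
* a phenotype table (mouse id, strain, gonadal depot weight in grams,
  body weight in grams, age in days, exclusion flag + reason).

Donor regions are derived from genotypes: one interval per maximal run
of ``H`` markers, bounded at the observed marker positions (the true
recombination breakpoint lies between the outermost ``H`` and the next
``A`` marker; inner marker bounds avoid inventing midpoints and match
how marker-resolved QTL coordinates are reported).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalSet

logger = logging.getLogger(__name__)

GENOTYPE_CODES = frozenset({"A", "H", "X"})

#: canonical phenotype column names
PHENO_COLUMNS = ["mouse_id", "strain", "depot_g", "bw_g", "age_d", "excluded", "reason"]


class PanelError(ValueError):
    """Raised for malformed panel inputs."""


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker map for one or more chromosomes.

    Positions must be strictly increasing within a chromosome and
    marker ids unique. The analyses here are single-chromosome but the
    type is chromosome-aware.
    """

    marker_ids: tuple[str, ...]
    chroms: tuple[str, ...]
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.marker_ids) == len(self.chroms) == len(self.positions)):
            raise PanelError("marker map fields must have equal length")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            dupes = [m for m, k in Counter(self.marker_ids).items() if k > 1]
            raise PanelError(f"duplicate marker ids: {dupes}")
        last: dict[str, int] = {}
        for mid, chrom, pos in zip(self.marker_ids, self.chroms, self.positions):
            if pos < 1:
                raise PanelError(f"marker {mid}: position {pos} < 1")
            if chrom in last and pos <= last[chrom]:
                raise PanelError(
                    f"marker {mid}: position {pos} not strictly increasing on {chrom}"
                )
            last[chrom] = pos

    def __len__(self) -> int:
        return len(self.marker_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MarkerMap":
        required = {"marker_id", "chrom", "pos_bp"}
        missing = required - set(frame.columns)
        if missing:
            raise PanelError(f"marker map missing columns: {sorted(missing)}")
        return cls(
            tuple(str(m) for m in frame["marker_id"]),
            tuple(str(c) for c in frame["chrom"]),
            tuple(int(p) for p in frame["pos_bp"]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker_id": self.marker_ids, "chrom": self.chroms, "pos_bp": self.positions}
        )

    def index_of(self, marker_id: str) -> int:
        return self.marker_ids.index(marker_id)

    def nearest_marker(self, pos_bp: int, chrom: str | None = None) -> int:
        """Index of the marker closest to ``pos_bp`` (ties -> proximal)."""
        best, best_dist = -1, None
        for i, (c, p) in enumerate(zip(self.chroms, self.positions)):
            if chrom is not None and c != chrom:
                continue
            d = abs(p - pos_bp)
            if best_dist is None or d < best_dist:
                best, best_dist = i, d
        if best < 0:
            raise PanelError(f"no markers on chromosome {chrom!r}")
        return best


@dataclass
class MouseRecord:
    """One mouse: identity, genotype vector, and phenotype."""

    mouse_id: str
    strain_id: str
    genotypes: tuple[str, ...]
    depot_weight_g: float | None
    body_weight_g: float
    age_days: int
    excluded: bool = False
    reason: str = ""


@dataclass
class CongenicPanel:
    """Marker map + genotype matrix + phenotype table for one panel.

    ``genotypes`` is a DataFrame indexed by mouse_id with one column
    per marker (codes A/H/X); ``phenotypes`` is indexed by mouse_id
    with columns strain, depot_g, bw_g, age_d, excluded, reason.
    """

    markers: MarkerMap
    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame
    strain_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if list(self.genotypes.columns) != list(self.markers.marker_ids):
            raise PanelError("genotype columns do not match marker map")
        if self.genotypes.index.has_duplicates:
            dupes = self.genotypes.index[self.genotypes.index.duplicated()].tolist()
            raise PanelError(f"duplicate mouse ids: {dupes}")
        if not self.genotypes.index.equals(self.phenotypes.index):
            raise PanelError("genotype and phenotype tables list different mice")
        values = self.genotypes.to_numpy()
        bad = ~np.isin(values, list(GENOTYPE_CODES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PanelError(
                f"unknown genotype code {values[i, j]!r} for mouse "
                f"{self.genotypes.index[i]!r} at marker {self.genotypes.columns[j]!r}"
            )
        for strain in self.phenotypes["strain"].unique():
            self.strain_labels.setdefault(str(strain), str(strain))
        depot = self.phenotypes["depot_g"]
        bw = self.phenotypes["bw_g"]
        if (bw <= 0).any():
            bad_id = bw.index[bw <= 0][0]
            raise PanelError(f"non-positive body weight for mouse {bad_id!r}")
        with_depot = depot.notna()
        if (depot[with_depot] <= 0).any():
            bad_id = depot[with_depot].index[depot[with_depot] <= 0][0]
            raise PanelError(f"non-positive depot weight for mouse {bad_id!r}")
        over = with_depot & (depot > bw)
        if over.any():
            raise PanelError(
                f"depot weight exceeds body weight for mouse {depot.index[over][0]!r}"
            )

    # -- accessors ----------------------------------------------------

    @property
    def n_mice(self) -> int:
        return len(self.genotypes)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def strains(self) -> list[str]:
        return sorted(self.phenotypes["strain"].unique())

    def mouse(self, mouse_id: str) -> MouseRecord:
        row = self.phenotypes.loc[mouse_id]
        depot = row["depot_g"]
        return MouseRecord(
            mouse_id=str(mouse_id),
            strain_id=str(row["strain"]),
            genotypes=tuple(self.genotypes.loc[mouse_id]),
            depot_weight_g=None if pd.isna(depot) else float(depot),
            body_weight_g=float(row["bw_g"]),
            age_days=int(row["age_d"]),
            excluded=bool(row["excluded"]),
            reason=str(row["reason"]) if not pd.isna(row["reason"]) else "",
        )

    def subset(self, mouse_ids: Sequence[str]) -> "CongenicPanel":
        ids = list(mouse_ids)
        return CongenicPanel(
            self.markers,
            self.genotypes.loc[ids].copy(),
            self.phenotypes.loc[ids].copy(),
            dict(self.strain_labels),
        )

    # -- donor regions ------------------------------------------------

    def donor_region(self, mouse_id: str) -> IntervalSet:
        return donor_region(tuple(self.genotypes.loc[mouse_id]), self.markers)

    def donor_regions(self) -> dict[str, IntervalSet]:
        return {str(mid): self.donor_region(mid) for mid in self.genotypes.index}

    def strain_donor_regions(self) -> dict[str, IntervalSet]:
        """Modal (most frequent) donor region per strain.

        Donor mice of a strain mostly carry the strain-defining full
        fragment; a minority inherit a shortened ("partial") fragment
        from a paternal recombination. The modal region over donor
        mice therefore identifies the full-length fragment; ties break
        toward the longer region.
        """
        regions: dict[str, IntervalSet] = {}
        for strain, ids in self.phenotypes.groupby("strain").groups.items():
            counts: Counter[IntervalSet] = Counter()
            for mid in ids:
                region = self.donor_region(mid)
                if region:
                    counts[region] += 1
            if counts:
                regions[str(strain)] = max(
                    counts, key=lambda r: (counts[r], r.total_length)
                )
        return regions

    def is_full_length(self, mouse_id: str, strain_regions: Mapping[str, IntervalSet]) -> bool:
        strain = str(self.phenotypes.loc[mouse_id, "strain"])
        modal = strain_regions.get(strain)
        if modal is None:
            return False
        return self.donor_region(mouse_id) == modal


def donor_region(genotypes: Sequence[str], markers: MarkerMap) -> IntervalSet:
    """Donor-region intervals for one mouse: maximal runs of H markers.

    Requires imputed genotypes (no ``X``) so that run boundaries are
    defined; interval bounds are the positions of the first and last
    ``H`` marker of each run.
    """
    if len(genotypes) != len(markers):
        raise PanelError("genotype vector length does not match marker map")
    if "X" in genotypes:
        raise PanelError("genotypes contain missing calls; run imputation first")
    intervals: list[tuple[int, int]] = []
    run_start: int | None = None
    for i, code in enumerate(genotypes):
        same_chrom = i > 0 and markers.chroms[i] == markers.chroms[i - 1]
        if code == "H":
            if run_start is None or not same_chrom:
                if run_start is not None:
                    intervals.append((markers.positions[run_start], markers.positions[i - 1]))
                run_start = i
        else:
            if run_start is not None:
                intervals.append((markers.positions[run_start], markers.positions[i - 1]))
                run_start = None
    if run_start is not None:
        intervals.append((markers.positions[run_start], markers.positions[-1]))
    return IntervalSet(intervals)


# -- file I/O ---------------------------------------------------------


def read_panel(
    map_path: str | Path,
    genotype_path: str | Path,
    phenotype_path: str | Path,
) -> CongenicPanel:
    """Read a panel from a marker TSV, genotype TSV, and phenotype CSV.

    Marker map: columns ``marker_id, chrom, pos_bp`` (TSV). Genotypes:
    TSV with mice as rows (``mouse_id`` first column) and markers as
    columns, cells in {A, H, X}. Phenotypes: CSV with columns
    ``mouse_id, strain, depot_g, bw_g, age_d, excluded, reason``.
    """
    markers = MarkerMap.from_frame(pd.read_csv(map_path, sep="\t", dtype=str).astype(
        {"pos_bp": int}
    ))
    geno = pd.read_csv(genotype_path, sep="\t", dtype=str).set_index("mouse_id")
    pheno = pd.read_csv(
        phenotype_path,
        dtype={"mouse_id": str, "strain": str, "reason": str},
    ).set_index("mouse_id")
    pheno["excluded"] = pheno["excluded"].astype(bool)
    pheno["reason"] = pheno["reason"].fillna("")
    pheno = pheno.loc[geno.index]
    panel = CongenicPanel(markers, geno, pheno)
    logger.info(
        "read panel: %d mice x %d markers, %d strains",
        panel.n_mice,
        panel.n_markers,
        len(panel.strains),
    )
    return panel


def write_panel(panel: CongenicPanel, out_dir: str | Path) -> dict[str, Path]:
    """Write the three panel files; returns the paths keyed by role."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "markers": out / "markers.tsv",
        "genotypes": out / "genotypes.tsv",
        "phenotypes": out / "phenotypes.csv",
    }
    panel.markers.to_frame().to_csv(paths["markers"], sep="\t", index=False)
    panel.genotypes.to_csv(paths["genotypes"], sep="\t", index_label="mouse_id")
    pheno = panel.phenotypes.copy()
    pheno.to_csv(paths["phenotypes"], index_label="mouse_id")
    return paths
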