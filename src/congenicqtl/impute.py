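"""Missing-genotype imputation by parental-origin logic.

In a backcross congenic panel each mouse inherits at most one donor
fragment, produced by at most a handful of recombinations. A missing
call flanked on both sides by the SAME genotype can therefore be
filled with that genotype, provided the flanking markers are close
enough that a double recombination between them can be excluded. The
distance criterion defaults to 26 Mb — the smallest gap at which two
recombination events have been observed in densely genotyped related
populations.

Chromosome-terminal missing calls have only one informative flank,
which cannot exclude a distal recombination; they are left missing
unless ``fill_terminal=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .panel import CongenicPanel

MB = 1_000_000


@dataclass
class ImputationReport:
    """Counts and per-mouse positions of filled genotypes."""

    n_initial_missing: int = 0
    n_filled_a: int = 0
    n_filled_h: int = 0
    n_left_missing: int = 0
    filled_positions: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_filled(self) -> int:
        return self.n_filled_a + self.n_filled_h

    def check(self) -> None:
        assert self.n_filled + self.n_left_missing == self.n_initial_missing


def _impute_vector(
    codes: list[str],
    positions: list[int],
    chroms: list[str],
    max_gap_bp: float,
    fill_terminal: bool,
) -> list[int]:
    """Return indices filled in-place in ``codes``; deterministic."""
    filled = []
    n = len(codes)
    for i in range(n):
        if codes[i] != "X":
            continue
        left = None
        for j in range(i - 1, -1, -1):
            if chroms[j] != chroms[i]:
                break
            if codes[j] != "X":
                left = j
                break
        right = None
        for j in range(i + 1, n):
            if chroms[j] != chroms[i]:
                break
            if codes[j] != "X":
                right = j
                break
        if left is not None and right is not None:
            if codes[left] == codes[right] and (
                positions[right] - positions[left] <= max_gap_bp
            ):
                codes[i] = codes[left]
                filled.append(i)
        elif fill_terminal and (left is not None or right is not None):
            flank = left if left is not None else right
            if abs(positions[flank] - positions[i]) <= max_gap_bp:
                codes[i] = codes[flank]
                filled.append(i)
    return filled


def impute_genotypes(
    panel: CongenicPanel,
    max_gap_mb: float = 26.0,
    fill_terminal: bool = False,
) -> tuple[CongenicPanel, ImputationReport]:
    """Fill missing genotypes under the no-double-recombination rule.

    An ``X`` call is filled when its nearest non-missing flanking
    markers (on the same chromosome) carry the same code and lie at
    most ``max_gap_mb`` apart, flank to flank. The operation never
    changes a non-missing call and is idempotent.
    """
    if max_gap_mb <= 0:
        raise ValueError(f"max_gap_mb must be positive, got {max_gap_mb}")
    max_gap_bp = max_gap_mb * MB
    positions = list(panel.markers.positions)
    chroms = list(panel.markers.chroms)
    marker_ids = list(panel.markers.marker_ids)

    report = ImputationReport()
    new_rows = {}
    for mouse_id, row in panel.genotypes.iterrows():
        codes = list(row)
        n_missing = codes.count("X")
        report.n_initial_missing += n_missing
        if n_missing:
            filled_idx = _impute_vector(codes, positions, chroms, max_gap_bp, fill_terminal)
            for i in filled_idx:
                if codes[i] == "A":
                    report.n_filled_a += 1
                else:
                    report.n_filled_h += 1
            if filled_idx:
                report.filled_positions[str(mouse_id)] = [marker_ids[i] for i in filled_idx]
            report.n_left_missing += n_missing - len(filled_idx)
        new_rows[mouse_id] = codes
    report.check()
    geno = pd.DataFrame.from_dict(new_rows, orient="index", columns=marker_ids)
    geno = geno.loc[panel.genotypes.index]
    geno.index.name = panel.genotypes.index.name
    out = CongenicPanel(panel.markers, geno, panel.phenotypes.copy(), dict(panel.strain_labels))
    return out, report
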