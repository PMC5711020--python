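"""Sequential strain-comparison method: MST order + multi-QTL inference.

The common segment method fails when one donor region carries linked
QTLs of opposite sign. The sequential method instead compares strains
in a predetermined order given by a minimum spanning tree (MST) over
donor-region dissimilarity: neighboring strains differ by a small
genomic region, so where a phenotype difference appears (or
disappears) along the tree localizes a QTL to that difference region
and gives the sign of the 129 allele's effect.

Inference generalizes the branch-by-branch logic to a search: donor
breakpoints partition the chromosome into atomic bins, each bin may
carry no QTL, an increasing (+) or a decreasing (−) 129 allele, and
an assignment is consistent with the comparison verdicts when every
significant comparison has a matching-sign active bin inside its
difference region and every null comparison's difference region is
either free of active bins or contains bins of both signs (two linked
QTLs cancelling — a "masked" configuration). The minimal consistent
assignments are the inferred QTL models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .glm import fit_adjusted_groups
from .intervals import Interval, IntervalSet, atomic_bins
from .panel import CongenicPanel

logger = logging.getLogger(__name__)

MB = 1_000_000

HOST = "host"


@dataclass
class StrainGraph:
    """Strain-similarity graph: nodes, MST edges, and traversal order.

    Nodes are strains plus a synthetic host node with an empty donor
    region; strains with identical donor regions are merged into one
    node (the lexicographically first id names it). Edge weights are
    the bp length of the symmetric difference of the two nodes' donor
    regions.
    """

    nodes: list[str]
    regions: dict[str, IntervalSet]
    members: dict[str, list[str]]
    mst_edges: list[tuple[str, str, int]]
    traversal: list[tuple[str, str]]  # (parent, child) in comparison order


def build_mst(strain_regions: Mapping[str, IntervalSet], host_label: str = HOST) -> StrainGraph:
    """Build the donor-similarity MST and its host-rooted traversal.

    Kruskal's algorithm on the complete graph with symmetric-
    difference-length weights; deterministic tie-breaking by
    (weight, lexicographic node pair). Traversal is breadth-first
    from the host node, children visited in ascending edge weight.
    """
    if len(strain_regions) < 1:
        raise ValueError("need at least one strain with a donor region")
    by_region: dict[IntervalSet, list[str]] = {}
    for sid in sorted(strain_regions):
        by_region.setdefault(strain_regions[sid], []).append(sid)
    regions: dict[str, IntervalSet] = {host_label: IntervalSet.empty()}
    members: dict[str, list[str]] = {host_label: []}
    for region, sids in by_region.items():
        if len(sids) > 1:
            warnings.warn(
                f"strains {sids} share an identical donor region; merged into node {sids[0]!r}",
                stacklevel=2,
            )
        regions[sids[0]] = region
        members[sids[0]] = sids
    nodes = sorted(regions)
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for u, v in combinations(nodes, 2):
        graph.add_edge(u, v, weight=regions[u].symmetric_difference(regions[v]).total_length)
    edges_sorted = sorted(
        graph.edges(data="weight"), key=lambda e: (e[2], tuple(sorted(e[:2])))
    )
    mst = nx.Graph()
    mst.add_nodes_from(nodes)
    parent_of = {n: n for n in nodes}

    def find(n):
        while parent_of[n] != n:
            parent_of[n] = parent_of[parent_of[n]]
            n = parent_of[n]
        return n

    mst_edges = []
    for u, v, w in edges_sorted:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent_of[ru] = rv
            mst.add_edge(u, v, weight=w)
            mst_edges.append((*sorted((u, v)), int(w)))
        if len(mst_edges) == len(nodes) - 1:
            break

    traversal: list[tuple[str, str]] = []
    visited = {host_label}
    frontier = [host_label]
    while frontier:
        nxt = []
        for node in frontier:
            children = sorted(
                (child for child in mst.neighbors(node) if child not in visited),
                key=lambda c: (mst.edges[node, c]["weight"], c),
            )
            for child in children:
                visited.add(child)
                traversal.append((node, child))
                nxt.append(child)
        frontier = nxt
    return StrainGraph(nodes, regions, members, mst_edges, traversal)


@dataclass
class ComparisonOutcome:
    """One ordered strain-pair contrast along the MST."""

    group_1: str  # child node (larger/different donor region)
    group_2: str  # parent node
    n_1: int
    n_2: int
    mean_1: float
    mean_2: float
    lsd_p: float
    verdict: str  # "greater" | "less" | "equal"
    difference_region: IntervalSet

    @property
    def symbol(self) -> str:
        return {"greater": ">", "less": "<", "equal": "="}[self.verdict]


def run_comparisons(
    graph: StrainGraph,
    panel: CongenicPanel,
    mask: pd.Series | None = None,
    alpha: float = 0.05,
    trait_column: str = "depot_t",
) -> list[ComparisonOutcome]:
    """LSD contrasts along the MST traversal, from one joint GLM.

    The host group pools homozygous (B6/B6) littermates from all
    analyzed strains; each strain node's group holds its full-length
    heterozygous donor mice (merged nodes pool their member strains).
    A single cell-means model with a body-weight covariate supplies
    the adjusted means and shared residual MSE for every contrast.
    """
    if mask is None:
        mask = pd.Series(True, index=panel.phenotypes.index)
    sub = panel.subset(list(panel.phenotypes.index[mask]))
    regions = sub.donor_regions()
    strain_regions = sub.strain_donor_regions()
    strain_of = sub.phenotypes["strain"].astype(str)

    node_of_strain = {
        sid: node for node, sids in graph.members.items() for sid in sids
    }
    labels = {}
    for mid in sub.phenotypes.index:
        if not regions[str(mid)]:
            labels[mid] = HOST
        elif sub.is_full_length(str(mid), strain_regions):
            labels[mid] = node_of_strain.get(strain_of[mid])
        else:
            labels[mid] = None  # partial-fragment mouse: not comparable
    keep = [mid for mid, lab in labels.items() if lab is not None]
    y = sub.phenotypes.loc[keep, trait_column].to_numpy(dtype=float)
    bw = sub.phenotypes.loc[keep, "bw_g"].to_numpy(dtype=float)
    group = np.asarray([labels[mid] for mid in keep], dtype=object)

    adj = fit_adjusted_groups(y, group, covariate=bw)
    outcomes: list[ComparisonOutcome] = []
    for parent, child in graph.traversal:
        diff = graph.regions[child].symmetric_difference(graph.regions[parent])
        n1, n2 = adj.n.get(child, 0), adj.n.get(parent, 0)
        if n1 < 2 or n2 < 2:
            logger.warning(
                "comparison %s vs %s skipped: group sizes %d/%d", child, parent, n1, n2
            )
            continue
        delta, _, p = adj.lsd(child, parent)
        if p < alpha:
            verdict = "greater" if delta > 0 else "less"
        else:
            verdict = "equal"
        if not diff and verdict != "equal":
            warnings.warn(
                f"{child} vs {parent}: empty difference region but verdict {verdict}",
                stacklevel=2,
            )
        outcomes.append(
            ComparisonOutcome(
                child, parent, n1, n2, adj.means[child], adj.means[parent], p,
                verdict, diff,
            )
        )
    return outcomes


@dataclass(frozen=True)
class Qtl:
    interval: Interval
    sign: str  # "+" (129 allele increases trait) | "-"
    bins: tuple[Interval, ...]
    support: tuple[int, ...]  # indices into the comparison list
    refined: bool = False


@dataclass
class QtlModel:
    qtls: tuple[Qtl, ...]
    n_active_bins: int
    active_length: int
    masked_comparisons: tuple[int, ...] = ()

    @property
    def n_qtls(self) -> int:
        return len(self.qtls)

    def signs(self) -> tuple[str, ...]:
        return tuple(q.sign for q in self.qtls)


@dataclass
class QtlInference:
    """All co-minimal consistent QTL models plus the search substrate."""

    models: list[QtlModel]
    bins: list[Interval]
    outcomes: list[ComparisonOutcome]

    @property
    def best(self) -> QtlModel:
        return self.models[0]


class InconsistentComparisonsError(RuntimeError):
    pass


def _bin_in(bin_: Interval, region: IntervalSet) -> bool:
    # bins are atomic wrt every region, so membership of the start
    # position decides containment of the whole bin
    return region.contains(bin_.start)


def infer_qtl_model(
    outcomes: Sequence[ComparisonOutcome],
    regions: Mapping[str, IntervalSet],
    max_qtls: int = 6,
) -> QtlInference:
    """Search for the minimal QTL models consistent with the verdicts.

    Bins are the atomic intervals cut by all donor-region endpoints;
    candidate bins are those inside at least one comparison's
    difference region. Assignments of {+, −} to k active bins are
    enumerated for k = 0, 1, ... until consistent assignments exist;
    among those, models are ranked by (number of merged QTLs, total
    active length) and all co-optimal models are returned. Adjacent
    same-sign active bins merge into one QTL.
    """
    bins = atomic_bins([r for r in regions.values() if r])
    diff_union = IntervalSet.empty()
    for oc in outcomes:
        diff_union = diff_union.union(oc.difference_region)
    candidates = [b for b in bins if _bin_in(b, diff_union)]
    if len(candidates) > 24:
        warnings.warn(
            f"{len(candidates)} candidate bins; exhaustive search may be slow",
            stacklevel=2,
        )

    # per outcome: list of (candidate index, orientation) inside its
    # difference region; orientation +1 when the bin lies in group_1's
    # donor region (so a + QTL there pushes group_1 above group_2)
    constraints = []
    for oc in outcomes:
        touched = []
        for ci, b in enumerate(candidates):
            if _bin_in(b, oc.difference_region):
                orient = 1 if _bin_in(b, regions[oc.group_1]) else -1
                touched.append((ci, orient))
        constraints.append((oc.verdict, touched))

    def consistent(assignment: dict[int, int]) -> tuple[bool, tuple[int, ...]]:
        masked = []
        for idx, (verdict, touched) in enumerate(constraints):
            oriented = [assignment[ci] * orient for ci, orient in touched if ci in assignment]
            if verdict == "greater":
                if +1 not in oriented:
                    return False, ()
            elif verdict == "less":
                if -1 not in oriented:
                    return False, ()
            else:
                if oriented and not (+1 in oriented and -1 in oriented):
                    return False, ()
                if oriented:
                    masked.append(idx)
        return True, tuple(masked)

    found: list[tuple[dict[int, int], tuple[int, ...]]] = []
    for k in range(0, len(candidates) + 1):
        if k > max_qtls:
            break
        for active in combinations(range(len(candidates)), k):
            for signs in product((+1, -1), repeat=k):
                assignment = dict(zip(active, signs))
                ok, masked = consistent(assignment)
                if ok:
                    found.append((assignment, masked))
        if found:
            break
    if not found:
        conflicts = [
            f"{oc.group_1} {oc.symbol} {oc.group_2} (p={oc.lsd_p:.3g})" for oc in outcomes
        ]
        raise InconsistentComparisonsError(
            f"no consistent model with <= {max_qtls} QTLs; comparisons: {conflicts}"
        )

    models = [
        _assemble_model(assignment, masked, candidates, constraints)
        for assignment, masked in found
    ]
    best_key = min((m.n_qtls, m.active_length) for m in models)
    minimal = [m for m in models if (m.n_qtls, m.active_length) == best_key]
    logger.info(
        "QTL inference: %d consistent assignment(s) at %d active bin(s); %d co-minimal model(s)",
        len(found),
        len(found[0][0]),
        len(minimal),
    )
    return QtlInference(models=minimal, bins=candidates, outcomes=list(outcomes))


def _assemble_model(
    assignment: dict[int, int],
    masked: tuple[int, ...],
    candidates: list[Interval],
    constraints,
) -> QtlModel:
    active = sorted(assignment)
    merged: list[tuple[list[Interval], int]] = []
    for ci in active:
        b, sign = candidates[ci], assignment[ci]
        if merged and merged[-1][1] == sign and merged[-1][0][-1].end + 1 == b.start:
            merged[-1][0].append(b)
        else:
            merged.append(([b], sign))
    qtls = []
    for bins_, sign in merged:
        bin_set = set(bins_)
        support = tuple(
            idx
            for idx, (_, touched) in enumerate(constraints)
            if any(candidates[ci] in bin_set for ci, _ in touched)
        )
        qtls.append(
            Qtl(
                interval=Interval(bins_[0].start, bins_[-1].end),
                sign="+" if sign > 0 else "-",
                bins=tuple(bins_),
                support=support,
            )
        )
    return QtlModel(
        qtls=tuple(qtls),
        n_active_bins=len(active),
        active_length=sum(candidates[ci].length for ci in active),
        masked_comparisons=masked,
    )


def refine_qtl(
    model: QtlModel,
    anchor_bp: int,
    flank_mb: float = 10.0,
    min_width_mb: float = 20.0,
) -> QtlModel:
    """Shrink a poorly localized QTL to a window around an anchor marker.

    External evidence (e.g., a marginally significant peak from an
    earlier intercross) can pin a broad QTL to one marker; the QTL
    interval containing ``anchor_bp`` is replaced by a ``flank_mb``-Mb
    window centred on the anchor (anchor ± flank/2), clipped to the
    original interval. Intervals narrower than ``min_width_mb`` are
    left alone.
    """
    target = None
    for i, q in enumerate(model.qtls):
        if q.interval.contains(anchor_bp):
            target = i
            break
    if target is None:
        raise ValueError(f"anchor {anchor_bp} lies in no QTL interval")
    q = model.qtls[target]
    if q.interval.length <= min_width_mb * MB:
        return model
    half = int(round(flank_mb * MB / 2))
    window = IntervalSet([(max(1, anchor_bp - half), anchor_bp + half)])
    clipped = window.intersection(IntervalSet([(q.interval.start, q.interval.end)]))
    new_iv = clipped.intervals[0]
    new_q = Qtl(new_iv, q.sign, q.bins, q.support, refined=True)
    qtls = list(model.qtls)
    qtls[target] = new_q
    logger.info(
        "refined QTL %s -> [%d, %d] around anchor %d",
        q.interval,
        new_iv.start,
        new_iv.end,
        anchor_bp,
    )
    return QtlModel(tuple(qtls), model.n_active_bins, model.active_length, model.masked_comparisons)


def qtl_effect_table(
    panel: CongenicPanel,
    model: QtlModel,
    mask: pd.Series | None = None,
    trait_column: str = "depot_t",
) -> pd.DataFrame:
    """Adjusted genotype means ± 95% CI at one marker per QTL.

    For each inferred QTL, the marker nearest the interval midpoint
    represents it. The heterozygous group uses mice from strains whose
    donor fragment covers this QTL but no other inferred QTL (the
    strains that isolate it — carriers of multiple QTLs would blend
    effects); when no strain isolates it, all carriers are used. The
    host group pools all B6/B6 mice at the marker. Means come from a
    body-weight-covaried cell-means model.
    """
    from scipy import stats as _st

    if mask is not None:
        panel = panel.subset(list(panel.phenotypes.index[mask]))
    strain_regions = panel.strain_donor_regions()
    strain_of = panel.phenotypes["strain"].astype(str)
    y_all = panel.phenotypes[trait_column].to_numpy(dtype=float)
    bw_all = panel.phenotypes["bw_g"].to_numpy(dtype=float)
    rows = []
    for q in model.qtls:
        others = [o for o in model.qtls if o is not q]
        isolating = {
            sid
            for sid, region in strain_regions.items()
            if region.contains((q.interval.start + q.interval.end) // 2)
            and not any(region.contains((o.interval.start + o.interval.end) // 2) for o in others)
        }
        if not isolating:
            isolating = {
                sid
                for sid, region in strain_regions.items()
                if region.contains((q.interval.start + q.interval.end) // 2)
            }
        mid = (q.interval.start + q.interval.end) // 2
        mi = panel.markers.nearest_marker(mid)
        marker_id = panel.markers.marker_ids[mi]
        g_all = panel.genotypes[marker_id].to_numpy()
        use = (g_all == "A") | ((g_all == "H") & strain_of.isin(isolating).to_numpy())
        y, bw, g = y_all[use], bw_all[use], g_all[use]
        adj = fit_adjusted_groups(y, g, covariate=bw)
        tcrit = _st.t.ppf(0.975, adj.df_resid)
        for code in ("A", "H"):
            se = np.sqrt(adj.mse / adj.n[code])
            rows.append(
                {
                    "qtl": f"{q.interval}{q.sign}",
                    "marker_id": marker_id,
                    "genotype": code,
                    "n": adj.n[code],
                    "ls_mean": adj.means[code],
                    "ci_low": adj.means[code] - tcrit * se,
                    "ci_high": adj.means[code] + tcrit * se,
                }
            )
    return pd.DataFrame(rows)
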