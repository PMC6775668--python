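"""Weighted single-copy marker roles: completeness and contamination.

For each taxonomic grouping (species, genus or family level), a *marker
role* is one annotated exactly once in at least 97% of the grouping's
genomes.  Marker roles are clustered by co-occurrence: two markers are
linked when both are present (multiplicity >= 1) in at least 90% of the
grouping's genomes, and clusters are the connected components of that
graph.  Each member of a cluster of size N carries weight 1/N, so a
cluster of collocated roles contributes like a single marker.

With M the marker-role set, O = {x in M : n_x > 0} the occurring markers,
n_x the count of marker x in the evaluated genome and N_x its cluster size:

    contamination = 100 * [sum_{x in O} (n_x - 1)/N_x] / [sum_{x in O} n_x/N_x]
    completeness  = 100 * [sum_{x in O} 1/N_x] / [sum_{x in M} 1/N_x]

Contamination is a 0-100 fraction of the genome attributable to redundant
marker content (it tends to 100% asymptotically as counts grow, unlike the
unbounded CheckM convention).  A genome is evaluated against the most
granular available grouping on its lineage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
from sklearn.base import BaseEstimator

from .genome import AnnotatedGenome, RoleSet
from .matrix import RoleMultiplicityMatrix, genomes_to_matrix

__all__ = [
    "MarkerCluster",
    "MarkerRoleSet",
    "EvalGResult",
    "MarkerSetEstimator",
    "derive_markers",
    "cluster_markers",
    "select_grouping",
    "contamination",
    "completeness",
    "save_marker_sets",
    "load_marker_sets",
]

logger = logging.getLogger(__name__)

#: lineage positions (from the specific end) at which each rank is read
DEFAULT_RANK_POSITIONS: dict[str, int] = {"species": -1, "genus": -2, "family": -3}


@dataclass(frozen=True)
class MarkerCluster:
    """A set of co-occurring marker roles; its size N is the weight denominator."""

    roles: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.roles)


@dataclass
class MarkerRoleSet:
    """The clustered marker roles of one taxonomic grouping."""

    grouping_id: str
    rank: str
    clusters: list[MarkerCluster]
    n_genomes_used: int

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cluster in self.clusters:
            if cluster.roles & seen:
                raise ValueError(
                    f"grouping {self.grouping_id!r}: clusters are not disjoint"
                )
            seen |= cluster.roles

    @property
    def marker_roles(self) -> set[str]:
        """M, the union of all cluster roles."""
        return {role for c in self.clusters for role in c.roles}

    def weights(self) -> dict[str, int]:
        """Cluster size N_x for every marker role x."""
        return {role: c.size for c in self.clusters for role in c.roles}


@dataclass
class EvalGResult:
    """Completeness/contamination of one genome against one marker set."""

    completeness: float
    contamination: float
    grouping_used: str
    rank: str
    occurring_roles: set[str] = field(default_factory=set)
    counts: dict[str, int] = field(default_factory=dict)
    no_markers_found: bool = False

    def to_dict(self) -> dict:
        return {
            "completeness": self.completeness,
            "contamination": self.contamination,
            "grouping_used": self.grouping_used,
            "rank": self.rank,
            "occurring_roles": sorted(self.occurring_roles),
            "counts": dict(self.counts),
            "no_markers_found": self.no_markers_found,
        }


def derive_markers(
    counts: pd.DataFrame, single_copy_fraction: float = 0.97
) -> set[str]:
    """Roles single-copy in at least ``single_copy_fraction`` of the genomes.

    ``counts`` is the genomes x roles multiplicity frame of one taxonomic
    grouping; the bound is closed (exactly 97% qualifies).
    """
    if counts.shape[0] == 0:
        raise ValueError("grouping has no genomes")
    single_copy = (counts == 1).mean(axis=0)
    return set(counts.columns[single_copy >= single_copy_fraction])


def cluster_markers(
    markers: set[str],
    counts: pd.DataFrame,
    co_occurrence_fraction: float = 0.90,
) -> list[MarkerCluster]:
    """Cluster markers by pairwise co-occurrence; single-linkage components.

    Roles a and b are linked when the fraction of grouping genomes
    containing both (multiplicity >= 1 each) is at least
    ``co_occurrence_fraction``; clusters are the connected components, so
    every marker lands in exactly one cluster.
    """
    ordered = [r for r in counts.columns if r in markers]
    graph = nx.Graph()
    graph.add_nodes_from(ordered)
    if ordered:
        present = (counts[ordered] > 0).to_numpy(dtype=float)
        joint = present.T @ present / present.shape[0]
        for i, a in enumerate(ordered):
            for j in range(i + 1, len(ordered)):
                if joint[i, j] >= co_occurrence_fraction:
                    graph.add_edge(a, ordered[j])
    return [
        MarkerCluster(roles=frozenset(component))
        for component in sorted(
            nx.connected_components(graph), key=lambda c: sorted(c)[0]
        )
    ]


def select_grouping(
    lineage: Sequence[str], available: Sequence[MarkerRoleSet]
) -> MarkerRoleSet:
    """Marker set of the most granular grouping on the genome's lineage.

    The lineage is ordered general -> specific; the available marker set
    whose grouping id appears deepest wins, falling back to coarser ranks
    when finer ones are missing.
    """
    if not available:
        raise ValueError("no marker sets available")
    by_grouping = {ms.grouping_id: ms for ms in available}
    for taxon in reversed(list(lineage)):
        if taxon in by_grouping:
            return by_grouping[taxon]
    raise LookupError(
        f"no marker set matches any lineage entry of {list(lineage)!r}"
    )


def _check_counts(counts: Mapping[str, int], weights: Mapping[str, int]) -> dict[str, int]:
    full = {x: int(counts.get(x, 0)) for x in weights}
    negative = [x for x, n in full.items() if n < 0]
    if negative:
        raise ValueError(f"negative marker counts for: {sorted(negative)[:5]}")
    return full


def contamination(counts: Mapping[str, int], marker_set: MarkerRoleSet) -> float:
    """Weighted redundancy of occurring marker roles, as a 0-100 percentage.

    Returns 0 when no marker role occurs (no evidence of redundancy).
    """
    weights = marker_set.weights()
    full = _check_counts(counts, weights)
    numerator = sum((n - 1) / weights[x] for x, n in full.items() if n > 0)
    denominator = sum(n / weights[x] for x, n in full.items() if n > 0)
    if denominator == 0:
        return 0.0
    return 100.0 * numerator / denominator


def completeness(counts: Mapping[str, int], marker_set: MarkerRoleSet) -> float:
    """Weighted fraction of expected marker roles present, as a percentage."""
    weights = marker_set.weights()
    if not weights:
        raise ValueError(
            f"grouping {marker_set.grouping_id!r} has an empty marker set"
        )
    full = _check_counts(counts, weights)
    numerator = sum(1.0 / weights[x] for x, n in full.items() if n > 0)
    denominator = sum(1.0 / weights[x] for x in weights)
    return 100.0 * numerator / denominator


class MarkerSetEstimator(BaseEstimator):
    """Derive per-grouping marker sets from reference genomes; score genomes.

    ``fit`` groups the reference genomes at each configured rank (taxa are
    read off the lineage at fixed positions from the specific end), derives
    single-copy marker roles per grouping, and clusters them by
    co-occurrence.  ``evaluate`` scores a genome against the most granular
    grouping on its lineage.

    Parameters
    ----------
    single_copy_fraction : float
        Minimum fraction of grouping genomes in which a marker occurs
        exactly once (default 0.97).
    co_occurrence_fraction : float
        Minimum joint-presence fraction linking two markers (default 0.90).
    min_group_size : int
        Groupings with fewer genomes are skipped with a warning.
    rank_positions : dict rank -> negative lineage index
        Where each rank is read on the lineage (default species/genus/family
        at positions -1/-2/-3).

    Attributes
    ----------
    marker_sets_ : list of MarkerRoleSet
    """

    def __init__(
        self,
        single_copy_fraction: float = 0.97,
        co_occurrence_fraction: float = 0.90,
        min_group_size: int = 2,
        rank_positions: dict[str, int] | None = None,
    ):
        self.single_copy_fraction = single_copy_fraction
        self.co_occurrence_fraction = co_occurrence_fraction
        self.min_group_size = min_group_size
        self.rank_positions = rank_positions

    def fit(self, X: Sequence[AnnotatedGenome], y=None) -> "MarkerSetEstimator":
        genomes = list(X)
        if not genomes:
            raise ValueError("need at least one reference genome")
        universe = sorted({role for g in genomes for role in g.roles()})
        role_set = RoleSet(universe)
        matrix = genomes_to_matrix(genomes, role_set)
        positions = self.rank_positions or DEFAULT_RANK_POSITIONS
        self.marker_sets_ = []
        for rank, pos in positions.items():
            groups: dict[str, list[int]] = {}
            for i, genome in enumerate(genomes):
                if len(genome.lineage) >= abs(pos):
                    groups.setdefault(genome.lineage[pos], []).append(i)
            for taxon, rows in sorted(groups.items()):
                if len(rows) < self.min_group_size:
                    logger.warning(
                        "skipping %s grouping %r: only %d genome(s)",
                        rank, taxon, len(rows),
                    )
                    continue
                counts = matrix.data.iloc[rows]
                markers = derive_markers(counts, self.single_copy_fraction)
                clusters = cluster_markers(
                    markers, counts, self.co_occurrence_fraction
                )
                self.marker_sets_.append(
                    MarkerRoleSet(
                        grouping_id=taxon,
                        rank=rank,
                        clusters=clusters,
                        n_genomes_used=len(rows),
                    )
                )
        return self

    def evaluate(self, genome: AnnotatedGenome) -> EvalGResult:
        """Completeness/contamination of ``genome`` at its deepest grouping."""
        if not hasattr(self, "marker_sets_"):
            raise RuntimeError("MarkerSetEstimator is not fitted")
        marker_set = select_grouping(genome.lineage, self.marker_sets_)
        return evaluate_counts(_genome_marker_counts(genome, marker_set), marker_set)


def _genome_marker_counts(
    genome: AnnotatedGenome, marker_set: MarkerRoleSet
) -> dict[str, int]:
    counts: dict[str, int] = {x: 0 for x in marker_set.marker_roles}
    for role in genome.roles():
        if role in counts:
            counts[role] += 1
    return counts


def evaluate_counts(
    counts: Mapping[str, int], marker_set: MarkerRoleSet
) -> EvalGResult:
    """Score a role-count mapping against one marker set."""
    occurring = {x for x in marker_set.marker_roles if counts.get(x, 0) > 0}
    return EvalGResult(
        completeness=completeness(counts, marker_set),
        contamination=contamination(counts, marker_set),
        grouping_used=marker_set.grouping_id,
        rank=marker_set.rank,
        occurring_roles=occurring,
        counts={x: int(counts.get(x, 0)) for x in marker_set.marker_roles},
        no_markers_found=not occurring,
    )


# ---------------------------------------------------------------------------
# persistence: TSV of (grouping_id, rank, cluster_index, role) + manifest
# ---------------------------------------------------------------------------

def save_marker_sets(
    marker_sets: Sequence[MarkerRoleSet], directory: str | Path
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "grouping_id": ms.grouping_id,
            "rank": ms.rank,
            "cluster_index": ci,
            "role": role,
        }
        for ms in marker_sets
        for ci, cluster in enumerate(ms.clusters)
        for role in sorted(cluster.roles)
    ]
    pd.DataFrame(
        rows, columns=["grouping_id", "rank", "cluster_index", "role"]
    ).to_csv(directory / "marker_roles.tsv", sep="\t", index=False)
    manifest = {
        ms.grouping_id: {"rank": ms.rank, "n_genomes_used": ms.n_genomes_used}
        for ms in marker_sets
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_marker_sets(directory: str | Path) -> list[MarkerRoleSet]:
    directory = Path(directory)
    table = pd.read_csv(directory / "marker_roles.tsv", sep="\t")
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    marker_sets = []
    for grouping_id, group in table.groupby("grouping_id", sort=True):
        clusters = [
            MarkerCluster(roles=frozenset(sub["role"]))
            for _, sub in group.groupby("cluster_index", sort=True)
        ]
        meta = manifest[str(grouping_id)]
        marker_sets.append(
            MarkerRoleSet(
                grouping_id=str(grouping_id),
                rank=meta["rank"],
                clusters=clusters,
                n_genomes_used=int(meta["n_genomes_used"]),
            )
        )
    return marker_sets
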