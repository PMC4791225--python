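"""Cross-condition integration of ITR rankings.

Given per-condition regulator rankings this module computes the pairwise
top-N overlap matrix (the percentage of shared regulators between two
conditions' top lists), the common regulator core across conditions, the
interaction subnetwork induced by that core, hypergeometric pathway
enrichment of node sets, and long-format activation-z profiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .knowledge_io import canon
from .regulator_activity import DEFAULT_TOP_N, ITRRanking


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class OverlapMatrix:
    """Symmetric matrix of top-N overlap percentages between conditions."""

    conditions: list[str]
    values: pd.DataFrame  # square, integer percentages

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="condition")

    def __getitem__(self, pair: tuple[str, str]) -> int:
        a, b = pair
        return int(self.values.loc[a, b])


def topn_overlap_matrix(
    rankings: Sequence[ITRRanking], n: int = DEFAULT_TOP_N
) -> OverlapMatrix:
    """Pairwise percentage overlap of top-n regulator lists.

    ``O_AB = 100 * |topN(A) ∩ topN(B)| / n`` rounded half-up to an integer;
    the diagonal is 100 by construction. Rankings shorter than n are used
    in full with a warning.
    """
    if n <= 0:
        raise ValidationError("n must be > 0")
    tops: dict[str, set[str]] = {}
    conditions = []
    for r in rankings:
        if len(r) < n:
            warnings.warn(
                f"{r.condition}: ranking has {len(r)} < {n} calls; using all",
                stacklevel=2,
            )
        if r.condition in tops:
            raise ValidationError(f"duplicate condition label {r.condition!r}")
        conditions.append(r.condition)
        tops[r.condition] = set(r.top(n))
    mat = pd.DataFrame(0, index=conditions, columns=conditions, dtype=int)
    for a in conditions:
        for b in conditions:
            mat.loc[a, b] = _round_half_up(100.0 * len(tops[a] & tops[b]) / n)
    return OverlapMatrix(conditions=conditions, values=mat)


@dataclass
class CoreSet:
    """Regulators shared by the top-N lists of enough conditions."""

    regulators: set[str]
    membership: dict[str, set[str]]  # regulator -> conditions whose top-N has it

    def __len__(self) -> int:
        return len(self.regulators)


def common_core(
    rankings: Sequence[ITRRanking],
    n: int = DEFAULT_TOP_N,
    min_conditions: int | None = None,
) -> CoreSet:
    """Regulators present in the top-n of at least ``min_conditions``
    rankings (default: all of them)."""
    if min_conditions is None:
        min_conditions = len(rankings)
    if min_conditions > len(rankings):
        raise ValidationError(
            f"min_conditions={min_conditions} exceeds {len(rankings)} rankings"
        )
    membership: dict[str, set[str]] = {}
    for r in rankings:
        for reg in r.top(n):
            membership.setdefault(reg, set()).add(r.condition)
    core = {reg for reg, conds in membership.items() if len(conds) >= min_conditions}
    return CoreSet(
        regulators=core, membership={r: membership[r] for r in core}
    )


@dataclass
class CoreNetworkSummary:
    n_nodes: int
    n_edges: int
    largest_component: int
    fraction_isolated: float
    n_excluded: int  # regulators dropped by the type filter


def core_network(
    core: CoreSet,
    graph: nx.Graph,
    regulator_types: Mapping[str, str] | None = None,
    exclude_types: Iterable[str] = ("chemical", "drug"),
) -> tuple[nx.Graph, CoreNetworkSummary]:
    """Interaction subgraph induced by the core regulators.

    Chemical/drug regulators are dropped when a type tag marks them (the
    protein interaction map covers proteins only); all core members are
    kept when no type map is given. Nodes absent from the interaction
    graph appear as isolated nodes.
    """
    exclude = set(exclude_types)
    members = {canon(r) for r in core.regulators}
    if regulator_types:
        types = {canon(k): v for k, v in regulator_types.items()}
        kept = {r for r in members if types.get(r, "protein") not in exclude}
    else:
        kept = members
    sub = nx.Graph()
    sub.add_nodes_from(sorted(kept))
    sub.add_edges_from(
        (a, b, d) for a, b, d in graph.edges(data=True) if a in kept and b in kept
    )
    components = list(nx.connected_components(sub)) if kept else []
    largest = max((len(c) for c in components), default=0)
    isolated = sum(1 for node in sub if sub.degree(node) == 0)
    summary = CoreNetworkSummary(
        n_nodes=sub.number_of_nodes(),
        n_edges=sub.number_of_edges(),
        largest_component=largest,
        fraction_isolated=(isolated / len(kept)) if kept else 0.0,
        n_excluded=len(members) - len(kept),
    )
    return sub, summary


def pathway_enrichment(
    node_set: Iterable[str],
    pathways: Mapping[str, set[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each pathway in a node set.

    For each pathway the upper-tail probability of observing at least the
    seen intersection with ``node_set`` when drawing ``|node_set|`` genes
    from ``universe``; BH FDR across pathways; sorted by p. Pathways with
    no member in the universe are skipped with a warning.
    """
    node_set = {canon(g) for g in node_set}
    universe = {canon(g) for g in universe}
    if not node_set <= universe:
        extra = sorted(node_set - universe)[:5]
        raise ValidationError(f"node_set outside universe, e.g. {extra}")
    rows = []
    for name in sorted(pathways):
        members = {canon(g) for g in pathways[name]} & universe
        if not members:
            warnings.warn(f"pathway {name!r} has no member in universe", stacklevel=2)
            continue
        k_in = len(members & node_set)
        if k_in == 0:
            p = 1.0
        else:
            p = float(
                hypergeom.sf(k_in - 1, len(universe), len(members), len(node_set))
            )
        rows.append((name, k_in, len(members), p))
    df = pd.DataFrame(rows, columns=["pathway", "k_in", "k_set", "p"])
    if len(df):
        df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["fdr"] = pd.Series(dtype=float)
    return df.sort_values(["p", "pathway"], kind="mergesort").reset_index(drop=True)


def z_profiles(
    rankings: Sequence[ITRRanking],
    regulators: Iterable[str],
) -> pd.DataFrame:
    """Long-format (regulator, condition, z, p_overlap) table for profiling
    activation across conditions; a regulator absent from a condition's
    calls simply has no row for that condition, undefined z is NaN."""
    wanted = {canon(r) for r in regulators}
    rows = []
    for ranking in rankings:
        for call in ranking.calls:
            if call.regulator in wanted:
                rows.append(
                    (
                        call.regulator,
                        ranking.condition,
                        np.nan if call.z is None else call.z,
                        call.p_overlap,
                    )
                )
    return pd.DataFrame(rows, columns=["regulator", "condition", "z", "p_overlap"])
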