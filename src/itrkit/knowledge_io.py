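"""Read, validate and write the prior knowledge inputs.

Three kinds of prior knowledge feed regulator inference:

* a signed regulator -> target network (the stand-in for a curated
  regulatory knowledge base), TSV with columns
  ``regulator  target  sign  [weight]``;
* pathway gene sets in Broad GMT dialect;
* an undirected protein-protein interaction edge list, TSV with columns
  ``node_a  node_b  [score]``.

All identifiers are canonicalised to upper case on input so that gene
symbols from different omic layers (mRNA tables, miRNA tables, protein
lists) join reliably.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import FormatError, ValidationError

SIGN_ACTIVATES = "activates"
SIGN_REPRESSES = "represses"
SIGN_UNKNOWN = "unknown"

_SIGN_ALIASES = {
    "+": SIGN_ACTIVATES,
    "-": SIGN_REPRESSES,
    "?": SIGN_UNKNOWN,
    "activates": SIGN_ACTIVATES,
    "represses": SIGN_REPRESSES,
    "unknown": SIGN_UNKNOWN,
}

_SIGN_TO_SYMBOL = {SIGN_ACTIVATES: "+", SIGN_REPRESSES: "-", SIGN_UNKNOWN: "?"}

#: numeric value of a predicted edge sign; unknown edges carry no direction
SIGN_VALUE = {SIGN_ACTIVATES: +1, SIGN_REPRESSES: -1}


def canon(identifier: str) -> str:
    """Canonical identifier form: stripped, upper-cased."""
    return str(identifier).strip().upper()


def normalize_sign(sign: str) -> str:
    try:
        return _SIGN_ALIASES[str(sign).strip().lower()]
    except KeyError:
        raise ValidationError(f"unrecognised edge sign {sign!r}")


@dataclass(frozen=True)
class PriorEdge:
    """One signed regulator -> target relation with a positive weight."""

    regulator: str
    target: str
    sign: str = SIGN_UNKNOWN
    weight: float = 1.0

    def __post_init__(self):
        if self.weight <= 0:
            raise ValidationError(
                f"edge ({self.regulator},{self.target}) has non-positive "
                f"weight {self.weight}"
            )
        if self.sign not in (SIGN_ACTIVATES, SIGN_REPRESSES, SIGN_UNKNOWN):
            raise ValidationError(f"bad sign {self.sign!r}")


@dataclass
class PriorNetwork:
    """Validated collection of prior edges with regulator/target indexes.

    ``by_regulator`` maps each regulator to its (deduplicated) edge list;
    the ``regulators`` / ``targets`` sets are always derived from the
    edges, never stored independently.
    """

    edges: list[PriorEdge]
    by_regulator: dict[str, list[PriorEdge]] = field(init=False, repr=False)

    def __post_init__(self):
        index: dict[str, list[PriorEdge]] = {}
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            key = (e.regulator, e.target)
            if key in seen:
                raise ValidationError(f"duplicate edge {key} in validated network")
            seen.add(key)
            index.setdefault(e.regulator, []).append(e)
        self.by_regulator = index

    @property
    def regulators(self) -> set[str]:
        return set(self.by_regulator)

    @property
    def targets(self) -> set[str]:
        return {e.target for e in self.edges}

    def edges_of(self, regulator: str) -> list[PriorEdge]:
        return self.by_regulator.get(canon(regulator), [])

    def __len__(self) -> int:
        return len(self.edges)


def _collapse_duplicates(rows: Iterable[PriorEdge]) -> list[PriorEdge]:
    """Collapse duplicate (regulator, target) rows: conflicting signs become
    unknown, the maximum weight is kept (weights are never summed)."""
    merged: dict[tuple[str, str], PriorEdge] = {}
    for e in rows:
        key = (e.regulator, e.target)
        prev = merged.get(key)
        if prev is None:
            merged[key] = e
            continue
        sign = prev.sign if prev.sign == e.sign else SIGN_UNKNOWN
        merged[key] = PriorEdge(
            e.regulator, e.target, sign=sign, weight=max(prev.weight, e.weight)
        )
    return list(merged.values())


def build_prior_network(rows: Iterable[PriorEdge]) -> PriorNetwork:
    """Validate a raw edge iterable into a PriorNetwork (idempotent)."""
    edges = _collapse_duplicates(rows)
    if not edges:
        raise ValidationError("prior network has no edges")
    n_self = sum(1 for e in edges if e.regulator == e.target)
    if n_self:
        warnings.warn(f"prior network contains {n_self} self-edge(s)", stacklevel=2)
    return PriorNetwork(edges)


def read_prior_network(path: str | Path) -> PriorNetwork:
    """Read a signed regulator->target edge list from TSV.

    Requires header columns ``regulator``, ``target``, ``sign``; ``weight``
    is optional and defaults to 1.0. Sign dialects {+,-,?} and
    {activates,represses,unknown} are both accepted.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.empty:
        raise ValidationError(f"{path}: empty prior network file")
    required = {"regulator", "target", "sign"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if "weight" in df.columns:
        weights = df["weight"].map(float)  # exact round-trip parsing
    else:
        weights = pd.Series(1.0, index=df.index)
    rows = [
        PriorEdge(
            canon(reg), canon(tgt), sign=normalize_sign(sgn), weight=float(w)
        )
        for reg, tgt, sgn, w in zip(df["regulator"], df["target"], df["sign"], weights)
    ]
    return build_prior_network(rows)


def write_prior_network(network: PriorNetwork, path: str | Path) -> None:
    """Canonical TSV write: edges sorted by (regulator, target), symbolic signs."""
    rows = sorted(network.edges, key=lambda e: (e.regulator, e.target))
    df = pd.DataFrame(
        {
            "regulator": [e.regulator for e in rows],
            "target": [e.target for e in rows],
            "sign": [_SIGN_TO_SYMBOL[e.sign] for e in rows],
            "weight": [e.weight for e in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pathway gene sets (GMT)

PathwaySets = dict  # mapping pathway name -> set of gene identifiers


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read Broad-dialect GMT: ``name<TAB>description<TAB>member...``.

    Members are deduplicated and case-folded; duplicate set names and
    member-less lines are rejected.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >= 3"
                )
            name = fields[0].strip()
            members = {canon(m) for m in fields[2:] if m.strip()}
            if not members:
                raise ValidationError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = members
    return sets


def write_gene_sets(sets: Mapping[str, set[str]], path: str | Path) -> None:
    """Canonical GMT write: sets by name, members sorted."""
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t-\t{members}\n")


# ---------------------------------------------------------------------------
# protein-protein interaction edge lists


def read_interactions(path: str | Path) -> nx.Graph:
    """Read an undirected interaction edge list from TSV.

    Columns ``node_a``, ``node_b`` and optional ``score`` in [0, 1].
    (a, b) and (b, a) rows are merged keeping the maximum score; self-edges
    are dropped with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = {"node_a", "node_b"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    graph = nx.Graph()
    n_self = 0
    has_score = "score" in df.columns
    for _, row in df.iterrows():
        a, b = canon(row["node_a"]), canon(row["node_b"])
        score = float(row["score"]) if has_score else None
        if score is not None and not (0.0 <= score <= 1.0):
            raise ValidationError(f"{path}: score {score} outside [0, 1] for ({a},{b})")
        if a == b:
            n_self += 1
            continue
        if graph.has_edge(a, b):
            old = graph.edges[a, b].get("score")
            if score is not None and (old is None or score > old):
                graph.edges[a, b]["score"] = score
        else:
            attrs = {} if score is None else {"score": score}
            graph.add_edge(a, b, **attrs)
    if n_self:
        warnings.warn(f"{path}: dropped {n_self} self-edge(s)", stacklevel=2)
    return graph


def write_interactions(graph: nx.Graph, path: str | Path) -> None:
    rows = []
    for a, b, data in graph.edges(data=True):
        a, b = sorted((a, b))
        rows.append((a, b, data.get("score", "")))
    rows.sort()
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "score"])
    df.to_csv(path, sep="\t", index=False)
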