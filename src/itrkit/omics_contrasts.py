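"""Differential-expression contrast tables and uniform evidence sets.

A :class:`ContrastTable` holds one condition's per-gene DE results
(log2 fold change, p, FDR) over a measured-gene universe. Thresholding it
yields a directional :class:`EvidenceSet`; non-directional evidence
(ChIP-bound genes, co-IP interactors, screen hits) is wrapped in the same
object so regulator inference treats all evidence kinds uniformly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .knowledge_io import canon

EVIDENCE_KINDS = ("de", "bound", "interactor", "screen_hit")


@dataclass
class ContrastTable:
    """Per-gene DE results for one condition.

    ``records`` is a DataFrame indexed by canonical gene identifier with
    columns ``log2fc``, ``p``, ``fdr``; the universe is every measured gene.
    """

    condition: str
    records: pd.DataFrame

    def __post_init__(self):
        if self.records.index.has_duplicates:
            dupes = self.records.index[self.records.index.duplicated()].unique()
            raise ValidationError(
                f"{self.condition}: duplicate gene rows {list(dupes[:5])}"
            )
        for col in ("log2fc", "p", "fdr"):
            if col not in self.records.columns:
                raise FormatError(f"{self.condition}: missing column {col!r}")
        if not np.isfinite(self.records["log2fc"]).all():
            raise ValidationError(f"{self.condition}: non-finite log2fc")
        for col in ("p", "fdr"):
            vals = self.records[col]
            if ((vals < 0) | (vals > 1)).any():
                raise ValidationError(f"{self.condition}: {col} outside [0, 1]")

    @property
    def universe(self) -> set[str]:
        return set(self.records.index)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class EvidenceSet:
    """A gene set with optional per-gene directions over an explicit universe.

    ``kind`` records the assay the evidence came from (de / bound /
    interactor / screen_hit); only DE evidence carries directions by
    default.
    """

    condition: str
    genes: set[str]
    universe: set[str]
    kind: str = "de"
    directions: dict[str, int] | None = None

    def __post_init__(self):
        if self.kind not in EVIDENCE_KINDS:
            raise ValidationError(f"unknown evidence kind {self.kind!r}")
        if not self.genes <= self.universe:
            extra = sorted(self.genes - self.universe)[:5]
            raise ValidationError(
                f"{self.condition}: evidence genes outside universe, e.g. {extra}"
            )
        if self.directions is not None:
            if not set(self.directions) <= self.genes:
                raise ValidationError(
                    f"{self.condition}: directions for genes not in evidence"
                )
            bad = {d for d in self.directions.values() if d not in (-1, 1)}
            if bad:
                raise ValidationError(f"direction values must be +1/-1, got {bad}")

    @property
    def directional(self) -> bool:
        return self.directions is not None

    def __len__(self) -> int:
        return len(self.genes)


def load_contrast(path: str | Path, condition: str) -> ContrastTable:
    """Read a DE contrast TSV with header ``gene  log2fc  p  fdr``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"gene", "log2fc", "p", "fdr"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df["gene"] = df["gene"].map(canon)
    dupes = df["gene"][df["gene"].duplicated()].unique()
    if len(dupes):
        raise ValidationError(f"{path}: duplicate gene rows {list(dupes[:5])}")
    records = df.set_index("gene")[["log2fc", "p", "fdr"]].astype(float)
    return ContrastTable(condition=condition, records=records)


def write_contrast(table: ContrastTable, path: str | Path) -> None:
    out = table.records.sort_index().reset_index()
    out.columns = ["gene", "log2fc", "p", "fdr"]
    out.to_csv(path, sep="\t", index=False)


def significant_set(
    table: ContrastTable,
    fdr_max: float = 0.05,
    min_abs_log2fc: float = 0.0,
) -> EvidenceSet:
    """Threshold a contrast into a directional evidence set.

    A gene is significant when ``fdr <= fdr_max`` and
    ``|log2fc| >= min_abs_log2fc``; its direction is the sign of log2fc.
    The default keeps significance alone (no fold-change cut).
    """
    if fdr_max < 0 or min_abs_log2fc < 0:
        raise ValidationError("thresholds must be >= 0")
    rec = table.records
    mask = (rec["fdr"] <= fdr_max) & (rec["log2fc"].abs() >= min_abs_log2fc)
    sig = rec[mask]
    directions = {
        gene: (1 if fc > 0 else -1)
        for gene, fc in sig["log2fc"].items()
        if fc != 0
    }
    return EvidenceSet(
        condition=table.condition,
        genes=set(directions),
        universe=table.universe,
        kind="de",
        directions=directions,
    )


def evidence_from_genes(
    genes: Iterable[str],
    universe: Iterable[str],
    condition: str,
    kind: str,
    directions: Mapping[str, int] | None = None,
) -> EvidenceSet:
    """Wrap a plain gene list (bound genes, interactors, screen hits) as
    evidence. The universe must be supplied explicitly: these assays have
    no measurement-based universe and overlap p-values depend on it."""
    genes = {canon(g) for g in genes}
    universe = {canon(g) for g in universe}
    dirs = None
    if directions is not None:
        dirs = {canon(g): int(d) for g, d in directions.items()}
    return EvidenceSet(
        condition=condition, genes=genes, universe=universe, kind=kind, directions=dirs
    )


def up_down_proportions(evidence: EvidenceSet) -> tuple[float, float]:
    """Percentages of up- and down-regulated genes in directional evidence.

    Returns ``(pct_up, pct_down)`` summing to 100 for non-empty evidence;
    (nan, nan) for an empty directional set.
    """
    if not evidence.directional:
        raise ValidationError(
            f"{evidence.condition}: proportions need directional evidence"
        )
    dirs = list(evidence.directions.values())
    if not dirs:
        warnings.warn(f"{evidence.condition}: empty evidence set", stacklevel=2)
        return (float("nan"), float("nan"))
    n_up = sum(1 for d in dirs if d > 0)
    pct_up = 100.0 * n_up / len(dirs)
    return (pct_up, 100.0 - pct_up)
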