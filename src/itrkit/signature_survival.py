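"""ITR-derived gene signatures and patient survival stratification.

A signature is built from the DE genes that contributed to a regulator
being called an ITR across several conditions: a gene enters the signature
when it was a contributing target, with the same observed direction, in at
least ``min_conditions`` conditions (genes with conflicting directions are
dropped). The signature scores each patient in an expression cohort as the
direction-weighted mean of z-scored expression; a median split of the
scores is compared by Kaplan-Meier curves and a two-sided log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .errors import EmptySignatureError, ValidationError
from .knowledge_io import canon


@dataclass
class Signature:
    """Directional gene list for one regulator.

    ``genes`` maps gene -> expected direction (+1/-1); ``provenance`` maps
    gene -> the conditions in which it contributed.
    """

    regulator: str
    genes: dict[str, int]
    provenance: dict[str, set[str]]

    def __post_init__(self):
        if not self.genes:
            raise EmptySignatureError(f"{self.regulator}: empty signature")

    def __len__(self) -> int:
        return len(self.genes)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (g, d, len(self.provenance.get(g, ())))
            for g, d in sorted(self.genes.items())
        ]
        pd.DataFrame(
            rows, columns=["gene", "direction", "n_supporting_conditions"]
        ).to_csv(path, sep="\t", index=False)


def build_signature(
    regulator: str,
    itr_contributions: Mapping[str, Mapping[str, int]],
    min_conditions: int = 2,
) -> Signature:
    """Combine per-condition contributing genes into a signature.

    ``itr_contributions`` maps condition -> (gene -> observed direction).
    A gene is kept when it appears with one identical direction in at
    least ``min_conditions`` conditions; genes seen with both directions
    anywhere are dropped (and reported via a warning).
    """
    support: dict[str, dict[int, set[str]]] = {}
    for condition, genes in itr_contributions.items():
        for gene, direction in genes.items():
            gene = canon(gene)
            if direction not in (-1, 1):
                raise ValidationError(f"{gene}: direction must be +1/-1")
            support.setdefault(gene, {}).setdefault(direction, set()).add(condition)
    kept: dict[str, int] = {}
    provenance: dict[str, set[str]] = {}
    conflicted = []
    for gene, by_dir in sorted(support.items()):
        if len(by_dir) > 1:
            conflicted.append(gene)
            continue
        (direction, conditions), = by_dir.items()
        if len(conditions) >= min_conditions:
            kept[gene] = direction
            provenance[gene] = set(conditions)
    if conflicted:
        warnings.warn(
            f"{regulator}: dropped {len(conflicted)} conflicting-direction "
            f"gene(s), e.g. {conflicted[:5]}",
            stacklevel=2,
        )
    return Signature(regulator=canon(regulator), genes=kept, provenance=provenance)


@dataclass
class CohortData:
    """Expression matrix (genes x patients) plus per-patient survival.

    ``survival`` is indexed by patient with columns ``time`` (non-negative)
    and ``event`` (1 = death observed, 0 = censored).
    """

    expression: pd.DataFrame
    survival: pd.DataFrame

    def __post_init__(self):
        if set(self.expression.columns) != set(self.survival.index):
            raise ValidationError("expression columns and survival rows differ")
        if self.survival["time"].isna().any() or (self.survival["time"] < 0).any():
            raise ValidationError("survival times must be present and >= 0")
        if not self.survival["event"].isin((0, 1)).all():
            raise ValidationError("event indicator must be 0/1")

    @property
    def n_patients(self) -> int:
        return len(self.survival)


def load_cohort(expression_path: str | Path, survival_path: str | Path) -> CohortData:
    expr = pd.read_csv(expression_path, sep="\t", index_col=0, comment="#")
    expr.index = expr.index.map(canon)
    surv = pd.read_csv(survival_path, sep="\t", comment="#").set_index("patient")
    return CohortData(expression=expr, survival=surv[["time", "event"]])


def score_cohort(signature: Signature, cohort: CohortData) -> pd.Series:
    """Per-patient signature score.

    Each usable signature gene's expression row is standardised to mean 0 /
    sd 1 across patients (population sd); the patient score is the mean of
    direction x standardised expression over those genes. Genes missing
    from the matrix or with zero variance are skipped with a warning.
    """
    expr = cohort.expression
    used = []
    skipped_absent, skipped_flat = [], []
    for gene, direction in sorted(signature.genes.items()):
        if gene not in expr.index:
            skipped_absent.append(gene)
            continue
        row = expr.loc[gene].astype(float)
        sd = row.std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            skipped_flat.append(gene)
            continue
        used.append(direction * (row - row.mean()) / sd)
    if skipped_absent:
        warnings.warn(
            f"{signature.regulator}: {len(skipped_absent)} signature gene(s) "
            f"absent from cohort, e.g. {skipped_absent[:5]}",
            stacklevel=2,
        )
    if skipped_flat:
        warnings.warn(
            f"{signature.regulator}: skipped zero-variance rows {skipped_flat[:5]}",
            stacklevel=2,
        )
    if not used:
        raise ValidationError(f"{signature.regulator}: no usable signature genes")
    scores = pd.concat(used, axis=1).mean(axis=1)
    scores.name = "score"
    return scores


@dataclass
class StratificationResult:
    groups: pd.Series  # patient -> "high" / "low"
    statistic: float
    p: float
    km_curves: dict[str, pd.DataFrame]  # group -> (time, survival) step curve


def stratify_and_test(
    scores: pd.Series,
    cohort: CohortData,
    quantile: float = 0.5,
) -> StratificationResult:
    """Split patients at a score quantile (median by default) and compare
    the two groups' survival with a two-sided log-rank test.

    Ties at the threshold go to the low group. Either group having fewer
    than 2 patients is an error.
    """
    if not 0 < quantile < 1:
        raise ValidationError("quantile must be in (0, 1)")
    scores = scores.loc[cohort.survival.index]
    threshold = float(scores.quantile(quantile))
    groups = pd.Series(
        np.where(scores > threshold, "high", "low"),
        index=scores.index,
        name="group",
    )
    sizes = groups.value_counts()
    if sizes.get("high", 0) < 2 or sizes.get("low", 0) < 2:
        raise ValidationError(
            f"degenerate split at quantile {quantile}: sizes {sizes.to_dict()}"
        )
    surv = cohort.survival
    masks = {name: groups == name for name in ("low", "high")}
    result = logrank_test(
        surv.loc[masks["low"], "time"],
        surv.loc[masks["high"], "time"],
        event_observed_A=surv.loc[masks["low"], "event"],
        event_observed_B=surv.loc[masks["high"], "event"],
    )
    curves = {}
    for name, mask in masks.items():
        km = KaplanMeierFitter()
        km.fit(surv.loc[mask, "time"], surv.loc[mask, "event"])
        sf = km.survival_function_
        curves[name] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return StratificationResult(
        groups=groups,
        statistic=float(result.test_statistic),
        p=float(result.p_value),
        km_curves=curves,
    )
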