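"""Core ITR statistic: target-overlap enrichment and activation z-scores.

For each regulator in a signed prior network, two questions are asked of an
evidence set (typically the significant DE genes of one contrast):

* *Is the regulator's known target module enriched in the evidence?* —
  upper-tail hypergeometric p-value of the overlap between the regulator's
  targets (restricted to the measured universe) and the evidence genes.

* *Which way is the regulator acting?* — an activation z-score over the
  signed overlapping edges,

  .. math:: z = \\frac{\\sum_g w_g m_g}{\\sqrt{\\sum_g w_g^2}}

  where :math:`m_g = +1` when the predicted regulation sign (activates
  -> +1, represses -> -1) matches the observed DE direction and −1
  otherwise. With unit weights this reduces to
  ``(n_consistent - n_inconsistent) / sqrt(n_signed_overlap)``. Positive z
  means the regulator is activated, negative inhibited.

Unknown-sign edges count toward the overlap (module enrichment) but are
excluded from z (direction). Regulators are ranked by overlap p-value into
an ITR (inferred transcriptional regulator) ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .knowledge_io import SIGN_UNKNOWN, SIGN_VALUE, PriorEdge, PriorNetwork, canon
from .omics_contrasts import EvidenceSet

STATE_ACTIVATED = "activated"
STATE_INHIBITED = "inhibited"
STATE_INDETERMINATE = "indeterminate"

DEFAULT_Z_THRESHOLD = 2.0
DEFAULT_TOP_N = 100


def overlap_pvalue(
    n_targets_in_universe: int,
    n_evidence: int,
    n_universe: int,
    n_overlap: int,
) -> float:
    """Upper-tail hypergeometric overlap p-value, P(X >= n_overlap).

    X counts evidence genes among the regulator's targets when
    ``n_evidence`` genes are drawn without replacement from a universe of
    ``n_universe`` genes containing ``n_targets_in_universe`` targets.
    Equals 1 when the overlap is zero.
    """
    if not (
        0 <= n_overlap <= min(n_targets_in_universe, n_evidence)
        and max(n_targets_in_universe, n_evidence) <= n_universe
    ):
        raise ValidationError(
            "inconsistent overlap counts: "
            f"targets={n_targets_in_universe}, evidence={n_evidence}, "
            f"universe={n_universe}, overlap={n_overlap}"
        )
    if n_overlap == 0:
        return 1.0
    return float(
        hypergeom.sf(n_overlap - 1, n_universe, n_targets_in_universe, n_evidence)
    )


def activation_z(
    edges: Sequence[PriorEdge],
    directions: Mapping[str, int],
) -> float | None:
    """Activation z over one regulator's signed edges that overlap observed
    directions; None (undefined) when no signed edge overlaps."""
    regs = {e.regulator for e in edges}
    if len(regs) > 1:
        raise ValidationError(f"edges span multiple regulators: {sorted(regs)}")
    bad = {d for d in directions.values() if d not in (-1, 1)}
    if bad:
        raise ValidationError(f"direction values must be +1/-1, got {bad}")
    num = 0.0
    sumsq = 0.0
    for e in edges:
        if e.sign == SIGN_UNKNOWN or e.target not in directions:
            continue
        m = 1 if SIGN_VALUE[e.sign] == directions[e.target] else -1
        num += e.weight * m
        sumsq += e.weight**2
    if sumsq == 0.0:
        return None
    return num / math.sqrt(sumsq)


def call_state(z: float | None, z_threshold: float = DEFAULT_Z_THRESHOLD) -> str:
    """Dichotomise z into activated / inhibited / indeterminate
    (boundary inclusive; undefined z is indeterminate)."""
    if z_threshold <= 0:
        raise ValidationError("z_threshold must be > 0")
    if z is None or (isinstance(z, float) and math.isnan(z)):
        return STATE_INDETERMINATE
    if z >= z_threshold:
        return STATE_ACTIVATED
    if z <= -z_threshold:
        return STATE_INHIBITED
    return STATE_INDETERMINATE


@dataclass(frozen=True)
class RegulatorCall:
    """One regulator's evidence against one evidence set."""

    regulator: str
    n_targets_in_universe: int
    n_overlap: int
    n_consistent: int
    n_inconsistent: int
    p_overlap: float
    fdr_overlap: float
    z: float | None
    state: str


@dataclass
class ITRRanking:
    """Regulators ranked by ascending overlap p-value for one condition.

    Ties are broken by larger |z| (undefined z last), then by regulator
    name, so rankings are fully deterministic.
    """

    condition: str
    calls: list[RegulatorCall] = field(default_factory=list)

    def top(self, n: int = DEFAULT_TOP_N) -> list[str]:
        return [c.regulator for c in self.calls[:n]]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "regulator": [c.regulator for c in self.calls],
                "n_targets_in_universe": [c.n_targets_in_universe for c in self.calls],
                "n_overlap": [c.n_overlap for c in self.calls],
                "n_consistent": [c.n_consistent for c in self.calls],
                "n_inconsistent": [c.n_inconsistent for c in self.calls],
                "p_overlap": [c.p_overlap for c in self.calls],
                "fdr_overlap": [c.fdr_overlap for c in self.calls],
                "z": [np.nan if c.z is None else c.z for c in self.calls],
                "state": [c.state for c in self.calls],
            }
        )

    def __len__(self) -> int:
        return len(self.calls)


def _sort_key(call: RegulatorCall):
    abs_z = -1.0 if call.z is None else abs(call.z)
    return (call.p_overlap, -abs_z, call.regulator)


def infer_itrs(
    network: PriorNetwork,
    evidence: EvidenceSet,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> ITRRanking:
    """Score every regulator with >= 1 target in the evidence universe.

    Overlap counts include unknown-sign edges; z and the consistency counts
    use signed edges only, and are undefined for non-directional evidence.
    FDR is Benjamini-Hochberg across the returned calls.
    """
    universe = evidence.universe
    if not universe:
        raise ValidationError(f"{evidence.condition}: empty evidence universe")
    ev_genes = evidence.genes & universe
    n_universe = len(universe)
    n_evidence = len(ev_genes)
    directions = evidence.directions if evidence.directional else {}

    raw = []
    for regulator, edges in network.by_regulator.items():
        in_universe = [e for e in edges if e.target in universe]
        if not in_universe:
            continue
        n_t = len(in_universe)
        overlap_edges = [e for e in in_universe if e.target in ev_genes]
        n_overlap = len(overlap_edges)
        p = overlap_pvalue(n_t, n_evidence, n_universe, n_overlap)
        signed = [e for e in overlap_edges if e.sign != SIGN_UNKNOWN]
        n_cons = sum(
            1
            for e in signed
            if e.target in directions and SIGN_VALUE[e.sign] == directions[e.target]
        )
        n_incons = sum(
            1
            for e in signed
            if e.target in directions and SIGN_VALUE[e.sign] != directions[e.target]
        )
        z = activation_z(in_universe, directions) if directions else None
        raw.append((regulator, n_t, n_overlap, n_cons, n_incons, p, z))

    if raw:
        fdrs = multipletests([r[5] for r in raw], method="fdr_bh")[1]
    else:
        fdrs = []
    calls = [
        RegulatorCall(
            regulator=reg,
            n_targets_in_universe=n_t,
            n_overlap=n_ov,
            n_consistent=n_c,
            n_inconsistent=n_i,
            p_overlap=p,
            fdr_overlap=float(fdr),
            z=z,
            state=call_state(z, z_threshold),
        )
        for (reg, n_t, n_ov, n_c, n_i, p, z), fdr in zip(raw, fdrs)
    ]
    calls.sort(key=_sort_key)
    return ITRRanking(condition=evidence.condition, calls=calls)


def contributions(
    network: PriorNetwork,
    evidence: EvidenceSet,
    regulator: str,
) -> dict[str, int]:
    """Observed DE directions of a regulator's overlapping target genes —
    the genes that contributed to the regulator being called an ITR.
    Used downstream to build gene signatures."""
    if not evidence.directional:
        raise ValidationError("contributions need directional evidence")
    regulator = canon(regulator)
    out: dict[str, int] = {}
    for e in network.edges_of(regulator):
        if e.target in evidence.genes and e.target in evidence.directions:
            out[e.target] = evidence.directions[e.target]
    return out


def write_ranking(ranking: ITRRanking, path: str | Path) -> None:
    """TSV export with a condition metadata header line."""
    with open(path, "w") as fh:
        fh.write(f"# condition: {ranking.condition}\n")
        ranking.as_frame().to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_ranking(path: str | Path) -> ITRRanking:
    path = Path(path)
    condition = path.stem
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# condition:"):
            condition = first.split(":", 1)[1].strip()
            df = pd.read_csv(fh, sep="\t", na_values=["NA"])
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", na_values=["NA"])
    calls = [
        RegulatorCall(
            regulator=str(row.regulator),
            n_targets_in_universe=int(row.n_targets_in_universe),
            n_overlap=int(row.n_overlap),
            n_consistent=int(row.n_consistent),
            n_inconsistent=int(row.n_inconsistent),
            p_overlap=float(row.p_overlap),
            fdr_overlap=float(row.fdr_overlap),
            z=None if pd.isna(row.z) else float(row.z),
            state=str(row.state),
        )
        for row in df.itertuples()
    ]
    return ITRRanking(condition=condition, calls=calls)
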