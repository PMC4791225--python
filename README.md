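# itrkit

Regulator-level integration of multi-omic evidence: infer the activity of
transcriptional regulators from differential-expression data against a
signed prior network, compare regulator rankings across conditions,
reconstruct core regulator networks, derive prognostic gene signatures,
and normalize/score RNAi viability screens.

## The problem

In cancers driven by a broadly acting transcription factor (the motivating
system is MYCN-amplified neuroblastoma), per-gene differential-expression
lists are noisy and platform-specific, but the *upstream regulators* that
explain those lists are far more stable. The idea is to integrate every
omic layer — RNA-seq contrasts, ChIP-bound gene sets, protein interactors,
screen hits — at the level of **inferred transcriptional regulators
(ITRs)**: regulators (genes, proteins, or chemical compounds) whose known
target module significantly overlaps the observed evidence, with an
activation state read off the direction of that evidence.

## The statistics

For a regulator *R* with target set *T(R)* (restricted to the measured
universe of *M* genes) and an evidence set *E* of *n* genes:

* **Overlap p-value** — upper-tail hypergeometric probability of the
  observed intersection, `p = P(X >= |T(R) ∩ E|)` with
  `X ~ Hypergeom(M, |T(R)|, n)`. Regulators are ranked by this p-value
  (Benjamini–Hochberg FDR is reported alongside).

* **Activation z-score** — over the signed overlapping edges,

  ```
  z = Σ_g w_g·m_g / sqrt(Σ_g w_g²),   m_g = +1 if the predicted sign
      (activates→+1, represses→−1) matches the observed DE direction,
      −1 otherwise
  ```

  With unit weights this is `(n_consistent − n_inconsistent)/√n_signed`.
  `z ≥ 2` calls the regulator activated, `z ≤ −2` inhibited. Unknown-sign
  edges count toward the overlap but never toward z.

Cross-condition integration uses the **top-N overlap percentage**
`O_AB = 100·|top_N(A) ∩ top_N(B)|/N` (N = 100 by default), common-core
extraction, induced protein-interaction subnetworks with hypergeometric
pathway enrichment, **directional gene signatures** (contributing DE genes
consistent in ≥ 2 conditions) scored on patient cohorts and tested by
Kaplan–Meier/log-rank, **loess plate normalization** (surface fitted on
the sample fraction only, controls in lines 1-2/23-24 excluded) with
median/MAD robust z and ±1 log2FC hit calls, and **ChIP peak context
classification** (promoter > exon > intron > immediate downstream >
distal, by peak midpoint).

Every input has a synthetic generator with planted ground truth
(`itrkit.synthetic_data`), so the full workflow is testable on a desktop
without any external data.

## Worked example

```bash
python analysis/01_simulate_inputs.py --seed 1   # writes results/inputs/
python analysis/02_infer_regulators.py           # writes results/itrs/
python analysis/03_integrate_conditions.py       # writes results/integration/
```

which prints (seed 1):

```
trio_1: 1399 DE genes (51% up / 49% down); planted recovered in top-100 with correct sign: 60/60
...
top-100 overlap matrix (%):
           trio_1  trio_2  trio_3  unrelated
trio_1        100      85      82         44
trio_2         85     100      84         44
trio_3         82      84     100         46
unrelated      44      44      46        100

core common to all 3 trio conditions: 77 regulators
core network: 77 nodes, 136 edges, largest component 73, 5% isolated
```

The three conditions planted with a shared 60-regulator core overlap each
other at 82–85% of their top-100 ITRs but only 44–46% with the unrelated
condition — the block structure that motivates integrating at the
regulator level. All 60 planted regulators are recovered in each top-100
with the correct activation sign. `analysis/04–06` continue with the
survival signature (log-rank p ≈ 1e-16 at the planted hazard ratio of 3),
screen normalization (16/16 planted hits recovered, 0 false positives)
and peak classification (20/20 fixture peaks labelled correctly).

The same workflow runs as one command over a YAML config:

```bash
itrkit --seed 1 run --config run.yaml --out results/run
```

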