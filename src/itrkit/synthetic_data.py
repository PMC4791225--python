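"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the *downstream products* of a multi-omic study at
desk scale — per-condition DE tables over a shared gene universe against a
signed regulator->target prior, a protein-interaction graph and pathway
sets over the regulator space, an expression + survival patient cohort,
384-well viability plate grids, and a small annotated genome with placed
ChIP peaks — never raw reads or spectra. Every generator is a pure
function of its configuration: sub-seeds are derived by hashing the
generator name with the master seed, so adding a generator never perturbs
the streams of the others.

Defaults define the study conditions: 5,000 measured genes, 200 regulators
with Poisson(30) out-degrees, edge signs 60% activating / 35% repressing /
5% unknown, planted regulator consistency 0.8 over a 5% background DE
rate; a 300-patient cohort with hazard ratio 3 per score sd and 30%
censoring; plates with a 0.5 log2 bilinear gradient, -1.5 log2 planted
hits and 10% multiplicative noise.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .knowledge_io import (
    SIGN_ACTIVATES,
    SIGN_REPRESSES,
    SIGN_UNKNOWN,
    SIGN_VALUE,
    PriorEdge,
    PriorNetwork,
    build_prior_network,
)
from .omics_contrasts import ContrastTable
from .peak_context import GeneModel, GenomicInterval
from .screen_phenotype import (
    N_COLS,
    N_ROWS,
    PlateGrid,
    default_control_mask,
    well_name,
)
from .signature_survival import CohortData, Signature


def subseed(master_seed: int, name: str) -> int:
    """Deterministic sub-seed: generator name hashed with the master seed,
    kept below 2**31."""
    digest = hashlib.blake2b(name.encode(), digest_size=4).digest()
    return (int.from_bytes(digest, "big") ^ (master_seed * 2654435761)) % (2**31)


def _rng(master_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(subseed(master_seed, name))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ConditionSpec:
    """One synthetic contrast: which regulators are planted active and how
    faithfully their targets respond."""

    name: str
    planted: dict[str, int] = field(default_factory=dict)  # regulator -> +1/-1
    consistency: float = 0.8  # P(signed target is DE in the predicted direction)
    background_rate: float = 0.05  # P(any other gene is DE)


@dataclass
class CohortSpec:
    n_patients: int = 300
    hazard_ratio_per_sd: float = 3.0
    censoring_fraction: float = 0.3
    n_background_genes: int = 40
    baseline_median_days: float = 1500.0


@dataclass
class PlateSpec:
    baseline_log2: float = 17.0  # ~1.3e5 luminescence counts
    gradient_amplitude: float = 0.5  # log2 units
    n_hits: int = 16
    hit_effect: float = -1.5  # log2 units
    noise_cv: float = 0.1  # multiplicative; log2 sd = cv / ln 2


@dataclass
class GenomeSpec:
    n_genes: int = 5
    gene_length: int = 10_000
    gene_spacing: int = 40_000
    peak_width: int = 200
    #: categories drawn on per gene; with peaks_per_gene=4 and 5 genes the
    #: rotation yields a mixed plan of 20 peaks covering every category
    plan: tuple[str, ...] = (
        "promoter",
        "exon",
        "intron",
        "immediate_downstream",
        "distal",
    )
    peaks_per_gene: int = 4


@dataclass
class ScenarioConfig:
    """Full synthetic scenario: network shape, conditions, cohort, plate
    and genome fixture parameters, driven by one master seed."""

    seed: int = 0
    n_genes: int = 5000
    n_regulators: int = 200
    out_degree_mean: float = 30.0
    sign_fractions: tuple[float, float, float] = (0.6, 0.35, 0.05)
    conditions: list[ConditionSpec] = field(default_factory=list)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    plate: PlateSpec = field(default_factory=PlateSpec)
    genome: GenomeSpec = field(default_factory=GenomeSpec)

    def __post_init__(self):
        if abs(sum(self.sign_fractions) - 1.0) > 1e-9:
            raise ValidationError("sign fractions must sum to 1")
        for spec in self.conditions:
            if not 0 <= spec.consistency <= 1:
                raise ValidationError(f"{spec.name}: consistency outside [0,1]")
            if not 0 <= spec.background_rate <= 1:
                raise ValidationError(f"{spec.name}: background rate outside [0,1]")

    @property
    def regulator_names(self) -> list[str]:
        return [f"R{i:03d}" for i in range(1, self.n_regulators + 1)]

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]


def default_scenario(
    seed: int = 0,
    n_core: int = 60,
    n_trio: int = 3,
    consistency: float = 0.8,
    background_rate: float = 0.05,
) -> ScenarioConfig:
    """The default study layout: three conditions sharing a planted core of
    regulators (analogous to a block of related amplified cell lines) plus
    one unrelated condition planted with a disjoint regulator set."""
    config = ScenarioConfig(seed=seed)
    rng = _rng(seed, "scenario-layout")
    regs = np.array(config.regulator_names)
    picked = rng.choice(len(regs), size=2 * n_core, replace=False)
    core = regs[picked[:n_core]]
    other = regs[picked[n_core:]]
    core_dirs = rng.choice([-1, 1], size=n_core)
    other_dirs = rng.choice([-1, 1], size=n_core)
    conditions = [
        ConditionSpec(
            name=f"trio_{i + 1}",
            planted={r: int(d) for r, d in zip(core, core_dirs)},
            consistency=consistency,
            background_rate=background_rate,
        )
        for i in range(n_trio)
    ]
    conditions.append(
        ConditionSpec(
            name="unrelated",
            planted={r: int(d) for r, d in zip(other, other_dirs)},
            consistency=consistency,
            background_rate=background_rate,
        )
    )
    config.conditions = conditions
    return config


def scenario_from_yaml(path) -> ScenarioConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return scenario_from_dict(raw)


def scenario_from_dict(raw: Mapping, seed: int | None = None) -> ScenarioConfig:
    raw = dict(raw)
    if seed is not None:
        raw["seed"] = int(seed)
    conditions = [
        ConditionSpec(
            name=c["name"],
            planted={str(k): int(v) for k, v in (c.get("planted") or {}).items()},
            consistency=float(c.get("consistency", 0.8)),
            background_rate=float(c.get("background_rate", 0.05)),
        )
        for c in raw.pop("conditions", [])
    ]
    cohort = CohortSpec(**raw.pop("cohort", {}))
    plate = PlateSpec(**raw.pop("plate", {}))
    genome_raw = raw.pop("genome", {})
    if "plan" in genome_raw:
        genome_raw["plan"] = tuple(genome_raw["plan"])
    genome = GenomeSpec(**genome_raw)
    if "sign_fractions" in raw:
        raw["sign_fractions"] = tuple(raw["sign_fractions"])
    return ScenarioConfig(
        conditions=conditions, cohort=cohort, plate=plate, genome=genome, **raw
    )


# ---------------------------------------------------------------------------
# prior network


def generate_prior_network(config: ScenarioConfig) -> PriorNetwork:
    """Regulators with Poisson out-degrees (clipped to >= 1), targets drawn
    uniformly without replacement, signs per the configured fractions."""
    rng = _rng(config.seed, "prior-network")
    genes = config.gene_names
    if config.out_degree_mean >= config.n_genes:
        raise ValidationError("mean out-degree exceeds the gene universe")
    p_act, p_rep, p_unk = config.sign_fractions
    edges: list[PriorEdge] = []
    for regulator in config.regulator_names:
        degree = max(1, int(rng.poisson(config.out_degree_mean)))
        degree = min(degree, config.n_genes)
        targets = rng.choice(config.n_genes, size=degree, replace=False)
        signs = rng.choice(
            [SIGN_ACTIVATES, SIGN_REPRESSES, SIGN_UNKNOWN],
            size=degree,
            p=[p_act, p_rep, p_unk],
        )
        edges.extend(
            PriorEdge(regulator, genes[t], sign=s)
            for t, s in zip(targets, signs)
        )
    return build_prior_network(edges)


# ---------------------------------------------------------------------------
# contrast tables


def _truncated_abs_fc(rng: np.random.Generator, n: int) -> np.ndarray:
    """|log2FC| ~ Normal(1.5, 0.5) truncated to > 0.2, by resampling."""
    out = rng.normal(1.5, 0.5, size=n)
    bad = out <= 0.2
    while bad.any():
        out[bad] = rng.normal(1.5, 0.5, size=int(bad.sum()))
        bad = out <= 0.2
    return out


def generate_contrasts(
    network: PriorNetwork,
    config: ScenarioConfig,
) -> tuple[dict[str, ContrastTable], dict[str, dict[str, int]]]:
    """Per-condition DE tables plus the planted-activity truth record.

    For each planted regulator with direction d, every signed target is DE
    with probability ``consistency`` in direction (edge sign x d); the
    remaining genes are DE at the background rate with random direction.
    DE genes get fdr ~ U(0, 0.01), everything else fdr ~ U(0.2, 1).
    """
    genes = config.gene_names
    gene_index = {g: i for i, g in enumerate(genes)}
    tables: dict[str, ContrastTable] = {}
    truth: dict[str, dict[str, int]] = {}
    for spec in config.conditions:
        missing = set(spec.planted) - network.regulators
        if missing:
            raise ValidationError(
                f"{spec.name}: planted regulators not in network: {sorted(missing)[:5]}"
            )
        rng = _rng(config.seed, f"contrast:{spec.name}")
        directions = np.zeros(config.n_genes, dtype=int)  # 0 = not DE
        for regulator, d in spec.planted.items():
            for edge in network.edges_of(regulator):
                if edge.sign == SIGN_UNKNOWN:
                    continue
                idx = gene_index[edge.target]
                if directions[idx] != 0:
                    continue  # first planted assignment wins
                if rng.random() < spec.consistency:
                    directions[idx] = SIGN_VALUE[edge.sign] * d
        free = directions == 0
        bg = free & (rng.random(config.n_genes) < spec.background_rate)
        directions[bg] = rng.choice([-1, 1], size=int(bg.sum()))

        de = directions != 0
        n_de = int(de.sum())
        log2fc = np.zeros(config.n_genes)
        log2fc[de] = directions[de] * _truncated_abs_fc(rng, n_de)
        log2fc[~de] = rng.normal(0.0, 0.15, size=config.n_genes - n_de)
        fdr = np.empty(config.n_genes)
        fdr[de] = rng.uniform(0.0, 0.01, size=n_de)
        fdr[~de] = rng.uniform(0.2, 1.0, size=config.n_genes - n_de)
        p = fdr * rng.uniform(0.0, 1.0, size=config.n_genes)
        records = pd.DataFrame(
            {"log2fc": log2fc, "p": p, "fdr": fdr}, index=pd.Index(genes, name="gene")
        )
        tables[spec.name] = ContrastTable(condition=spec.name, records=records)
        truth[spec.name] = dict(spec.planted)
    return tables, truth


# ---------------------------------------------------------------------------
# regulator-space priors for integration (interactions, pathways)


def generate_interactions(
    config: ScenarioConfig,
    edge_probability: float = 0.05,
):
    """Erdos-Renyi interaction graph over the regulator space with
    confidence scores ~ U(0.4, 1)."""
    import networkx as nx

    rng = _rng(config.seed, "interactions")
    regs = config.regulator_names
    graph = nx.Graph()
    graph.add_nodes_from(regs)
    for i, a in enumerate(regs):
        for b in regs[i + 1 :]:
            if rng.random() < edge_probability:
                graph.add_edge(a, b, score=float(rng.uniform(0.4, 1.0)))
    return graph


def generate_pathway_sets(
    config: ScenarioConfig,
    n_pathways: int = 20,
    size_range: tuple[int, int] = (8, 30),
) -> dict[str, set[str]]:
    """Random pathway sets over the regulator space (for enrichment of
    regulator cores)."""
    rng = _rng(config.seed, "pathways")
    regs = np.array(config.regulator_names)
    sets = {}
    for i in range(1, n_pathways + 1):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = rng.choice(len(regs), size=size, replace=False)
        sets[f"PW{i:02d}"] = set(regs[members])
    return sets


# ---------------------------------------------------------------------------
# patient cohort


def generate_cohort(
    signature: Signature,
    config: ScenarioConfig,
) -> tuple[CohortData, pd.Series]:
    """Expression + survival cohort with a planted prognostic factor.

    Each patient carries a latent factor f ~ N(0,1); signature genes are
    expressed as direction x f plus unit noise, background genes as pure
    noise. Survival is exponential with hazard scaled by HR^f, and
    censoring is Bernoulli(censoring_fraction) with a censoring time drawn
    uniformly before the event. Returns the cohort and the latent truth.
    """
    spec = config.cohort
    rng = _rng(config.seed, "cohort")
    n = spec.n_patients
    patients = [f"P{i:04d}" for i in range(1, n + 1)]
    latent = rng.normal(0.0, 1.0, size=n)

    sig_genes = sorted(signature.genes)
    bg_genes = [f"BG{i:04d}" for i in range(1, spec.n_background_genes + 1)]
    rows = {}
    for gene in sig_genes:
        rows[gene] = signature.genes[gene] * latent + rng.normal(0, 1, size=n)
    for gene in bg_genes:
        rows[gene] = rng.normal(0, 1, size=n)
    expression = pd.DataFrame(rows, index=patients).T

    base_rate = np.log(2.0) / spec.baseline_median_days
    hazard = base_rate * spec.hazard_ratio_per_sd**latent
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < spec.censoring_fraction
    time = np.where(censored, rng.uniform(0.0, event_time), event_time)
    survival = pd.DataFrame(
        {"time": time, "event": (~censored).astype(int)},
        index=pd.Index(patients, name="patient"),
    )
    cohort = CohortData(expression=expression, survival=survival)
    return cohort, pd.Series(latent, index=patients, name="latent_factor")


# ---------------------------------------------------------------------------
# viability plates


def generate_plate(
    config: ScenarioConfig,
    plate_id: str = "plate_1",
) -> tuple[PlateGrid, pd.DataFrame]:
    """One 384-well plate: log2 baseline + bilinear spatial gradient +
    multiplicative noise, with planted hit wells among the sample
    fraction. Returns the plate and the per-hit truth table."""
    spec = config.plate
    rng = _rng(config.seed, f"plate:{plate_id}")
    rows, cols = np.indices((N_ROWS, N_COLS))
    u_r = rows / (N_ROWS - 1) - 0.5
    u_c = cols / (N_COLS - 1) - 0.5
    a1, a2, a3 = rng.uniform(-1.0, 1.0, size=3)
    gradient = spec.gradient_amplitude * (a1 * u_r + a2 * u_c + a3 * u_r * u_c)

    mask = default_control_mask()
    sample_wells = [
        (r, c) for r in range(N_ROWS) for c in range(N_COLS) if not mask[r, c]
    ]
    annotation = {}
    for i, (r, c) in enumerate(sample_wells, start=1):
        annotation[well_name(r, c)] = (f"SCR{i:04d}", "sample")
    for r in range(N_ROWS):
        for c in range(N_COLS):
            if mask[r, c]:
                annotation[well_name(r, c)] = ("CTRL", "neg_ctrl")

    hit_idx = rng.choice(len(sample_wells), size=spec.n_hits, replace=False)
    effects = np.zeros((N_ROWS, N_COLS))
    truth_rows = []
    for i in hit_idx:
        r, c = sample_wells[i]
        effects[r, c] = spec.hit_effect
        truth_rows.append((well_name(r, c), annotation[well_name(r, c)][0],
                           spec.hit_effect))

    sd_log2 = spec.noise_cv / np.log(2.0)
    noise = rng.normal(0.0, sd_log2, size=(N_ROWS, N_COLS)) if sd_log2 > 0 else 0.0
    log2_signal = spec.baseline_log2 + gradient + effects + noise
    plate = PlateGrid(
        plate_id=plate_id,
        values=2.0**log2_signal,
        control_mask=mask,
        annotation=annotation,
    )
    truth = pd.DataFrame(truth_rows, columns=["well", "gene", "effect_log2"])
    return plate, truth


# ---------------------------------------------------------------------------
# genome fixture


def generate_genome_fixture(
    config: ScenarioConfig,
) -> tuple[list[GeneModel], list[GenomicInterval], pd.DataFrame]:
    """Non-overlapping gene models on one synthetic chromosome plus peaks
    placed with known intended context labels.

    Gene i occupies ``[20000 + i*spacing, +gene_length)`` with three exons
    (at offsets 0-500, 4000-4500, 9500-10000 scaled to the gene length);
    strands alternate. Each gene receives ``peaks_per_gene`` peaks whose
    categories rotate through the plan (so the default 5-gene fixture has
    20 peaks covering every category), placed where the classifier
    defaults must recover the label:
    promoters 1 kb upstream of the TSS, exon peaks inside the middle exon,
    intron peaks between exons 1 and 2, immediate-downstream peaks 1 kb
    past the TES, distal peaks 12 kb upstream of the gene start.
    """
    spec = config.genome
    chrom = "chrS"
    L = spec.gene_length
    if L < 6000:
        raise ValidationError("gene_length must be >= 6000 for the exon layout")
    if spec.gene_spacing < L + 30_000:
        raise ValidationError("gene_spacing too small for distal placements")
    exon_offsets = [
        (0, int(0.05 * L)),
        (int(0.40 * L), int(0.45 * L)),
        (int(0.95 * L), L),
    ]
    genes: list[GeneModel] = []
    for i in range(spec.n_genes):
        start = 20_000 + i * spec.gene_spacing
        end = start + L
        strand = "+" if i % 2 == 0 else "-"
        exons = [
            GenomicInterval(chrom, start + a, start + b, strand=strand)
            for a, b in exon_offsets
        ]
        genes.append(
            GeneModel(
                gene_id=f"SGENE{i + 1:02d}",
                interval=GenomicInterval(chrom, start, end, strand=strand),
                exons=exons,
            )
        )

    half = spec.peak_width // 2
    peaks: list[GenomicInterval] = []
    truth_rows = []
    for gene_idx, gene in enumerate(genes):
        start, end = gene.interval.start, gene.interval.end
        strand = gene.interval.strand
        placements = {
            "promoter": gene.tss - 1000 if strand == "+" else gene.tss + 1000,
            "exon": start + int(0.425 * L),  # middle of exon 2
            "intron": start + int(0.22 * L),  # between exons 1 and 2
            "immediate_downstream": (
                gene.tes + 1000 if strand == "+" else gene.tes - 1000
            ),
            "distal": start - 12_000,
        }
        k = min(spec.peaks_per_gene, len(spec.plan))
        categories = [
            spec.plan[(gene_idx + j) % len(spec.plan)] for j in range(k)
        ]
        for category in categories:
            if category not in placements:
                raise ValidationError(f"unknown plan category {category!r}")
            mid = placements[category]
            if mid - half < 0:
                raise ValidationError(
                    f"{gene.gene_id}/{category}: placement exceeds chromosome start"
                )
            name = f"{gene.gene_id}_{category}"
            peaks.append(
                GenomicInterval(chrom, mid - half, mid + half, name=name)
            )
            truth_rows.append((name, category))
    truth = pd.DataFrame(truth_rows, columns=["name", "category"])
    return genes, peaks, truth
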