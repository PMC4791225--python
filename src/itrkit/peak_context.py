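"""Genomic-context classification of ChIP peaks.

Each peak is assigned by its midpoint to one of five mutually exclusive
categories with fixed precedence:

    promoter > exon > intron > immediate_downstream > distal

Promoters are strand-aware windows around the TSS (default 2 kb upstream /
500 bp downstream); the immediate-downstream window extends past the TES
(default 2 kb). Distal peaks that fall inside a user-supplied enhancer
interval set are sub-labelled ``enhancer``; without such a set they stay
plain ``distal``. Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .errors import FormatError, ValidationError

CATEGORIES = ("promoter", "exon", "intron", "immediate_downstream", "distal")

DEFAULT_PROMOTER_WINDOW = (2000, 500)  # bp upstream, downstream of TSS
DEFAULT_DOWNSTREAM_BP = 2000  # bp past the TES


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval, optionally stranded."""

    chromosome: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"bad interval {self.chromosome}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GeneModel:
    """A gene body with merged exon structure on one strand."""

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: gene strand must be +/-")
        merged = []
        for ex in sorted(self.exons, key=lambda e: e.start):
            if ex.chromosome != self.interval.chromosome:
                raise ValidationError(f"{self.gene_id}: exon on wrong chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValidationError(f"{self.gene_id}: exon outside gene body")
            if merged and ex.start <= merged[-1].end:
                prev = merged.pop()
                ex = GenomicInterval(
                    ex.chromosome, prev.start, max(prev.end, ex.end),
                    strand=self.interval.strand,
                )
            merged.append(ex)
        self.exons = merged

    @property
    def tss(self) -> int:
        return self.interval.start if self.interval.strand == "+" else self.interval.end

    @property
    def tes(self) -> int:
        return self.interval.end if self.interval.strand == "+" else self.interval.start


def read_peaks_bed(path: str | Path) -> list[GenomicInterval]:
    """Read peaks from BED3+ (extra columns ignored, track lines skipped)."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has < 3 fields")
            name = fields[3] if len(fields) > 3 else f"peak_{lineno}"
            peaks.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), name=name)
            )
    return peaks


def read_genes_bed12(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 (blocks become exons)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 line has {len(f)} fields")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [
                GenomicInterval(chrom, start + s, start + s + size, strand=strand)
                for s, size in zip(starts, sizes)
            ]
            genes.append(
                GeneModel(
                    gene_id=name,
                    interval=GenomicInterval(chrom, start, end, strand=strand),
                    exons=exons,
                )
            )
    return genes


def read_genes_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene + exon features) from GTF via pyranges."""
    import pyranges  # deferred: heavy import

    df = pyranges.read_gtf(str(path)).df
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: GTF lacks gene_id attributes")
    genes = []
    for gene_id, grp in df.groupby("gene_id", sort=True):
        gene_rows = grp[grp["Feature"] == "gene"]
        exon_rows = grp[grp["Feature"] == "exon"]
        if gene_rows.empty:
            # fall back to the exon span
            if exon_rows.empty:
                continue
            chrom = exon_rows["Chromosome"].iloc[0]
            strand = exon_rows["Strand"].iloc[0]
            start, end = int(exon_rows["Start"].min()), int(exon_rows["End"].max())
        else:
            row = gene_rows.iloc[0]
            chrom, strand = row["Chromosome"], row["Strand"]
            start, end = int(row["Start"]), int(row["End"])
        exons = [
            GenomicInterval(str(chrom), int(r.Start), int(r.End), strand=str(strand))
            for r in exon_rows.itertuples()
        ]
        genes.append(
            GeneModel(
                gene_id=str(gene_id),
                interval=GenomicInterval(str(chrom), start, end, strand=str(strand)),
                exons=exons,
            )
        )
    return genes


@dataclass
class ContextSummary:
    counts: dict[str, int]
    percentages: dict[str, float]
    n_enhancer: int  # distal peaks overlapping a supplied enhancer set

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(CATEGORIES),
                "count": [self.counts[c] for c in CATEGORIES],
                "percent": [self.percentages[c] for c in CATEGORIES],
            }
        )


def _window(lo: int, hi: int) -> tuple[int, int]:
    return max(0, min(lo, hi)), max(lo, hi)


def classify_peaks(
    peaks: list[GenomicInterval],
    genes: list[GeneModel],
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
    downstream_bp: int = DEFAULT_DOWNSTREAM_BP,
    enhancers: list[GenomicInterval] | None = None,
) -> tuple[ContextSummary, pd.DataFrame]:
    """Label every peak midpoint with its genomic context.

    Returns the category summary and a per-peak table (chromosome, start,
    end, name, category, sublabel). Chromosomes present in peaks but not
    in gene models are classified distal and counted in a warning.
    """
    up_bp, down_bp = promoter_window
    if up_bp < 0 or down_bp < 0 or downstream_bp < 0:
        raise ValidationError("windows must be >= 0")

    promoter_trees: dict[str, IntervalTree] = {}
    exon_trees: dict[str, IntervalTree] = {}
    body_trees: dict[str, IntervalTree] = {}
    down_trees: dict[str, IntervalTree] = {}
    gene_chroms = set()
    for g in genes:
        chrom = g.interval.chromosome
        gene_chroms.add(chrom)
        if g.interval.strand == "+":
            prom = _window(g.tss - up_bp, g.tss + down_bp)
            down = _window(g.tes, g.tes + downstream_bp)
        else:
            prom = _window(g.tss - down_bp, g.tss + up_bp)
            down = _window(g.tes - downstream_bp, g.tes)
        if prom[0] < prom[1]:
            promoter_trees.setdefault(chrom, IntervalTree()).addi(*prom)
        if down[0] < down[1]:
            down_trees.setdefault(chrom, IntervalTree()).addi(*down)
        body_trees.setdefault(chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end
        )
        for ex in g.exons:
            exon_trees.setdefault(chrom, IntervalTree()).addi(ex.start, ex.end)

    enhancer_trees: dict[str, IntervalTree] = {}
    for e in enhancers or []:
        enhancer_trees.setdefault(e.chromosome, IntervalTree()).addi(e.start, e.end)

    def hit(trees: dict[str, IntervalTree], chrom: str, pos: int) -> bool:
        tree = trees.get(chrom)
        return bool(tree is not None and tree.overlaps(pos))

    counts = {c: 0 for c in CATEGORIES}
    n_enh = 0
    n_unmatched = 0
    rows = []
    for peak in peaks:
        chrom, mid = peak.chromosome, peak.midpoint
        if chrom not in gene_chroms:
            n_unmatched += 1
        if hit(promoter_trees, chrom, mid):
            category = "promoter"
        elif hit(exon_trees, chrom, mid):
            category = "exon"
        elif hit(body_trees, chrom, mid):
            category = "intron"
        elif hit(down_trees, chrom, mid):
            category = "immediate_downstream"
        else:
            category = "distal"
        sublabel = ""
        if category == "distal" and hit(enhancer_trees, chrom, mid):
            sublabel = "enhancer"
            n_enh += 1
        counts[category] += 1
        rows.append((chrom, peak.start, peak.end, peak.name, category, sublabel))
    if n_unmatched:
        warnings.warn(
            f"{n_unmatched} peak(s) on chromosomes absent from gene models",
            stacklevel=2,
        )
    total = len(peaks)
    percentages = {
        c: (100.0 * counts[c] / total if total else 0.0) for c in CATEGORIES
    }
    labels = pd.DataFrame(
        rows,
        columns=["chromosome", "start", "end", "name", "category", "sublabel"],
    )
    return ContextSummary(counts=counts, percentages=percentages, n_enhancer=n_enh), labels


def write_labelled_peaks(labels: pd.DataFrame, path: str | Path) -> None:
    """Per-peak BED with the context label in the name field."""
    out = labels.copy()
    name = out["name"].astype(str) + "|" + out["category"]
    enh = out["sublabel"] == "enhancer"
    name[enh] = name[enh] + "|enhancer"
    bed = pd.DataFrame(
        {
            "chromosome": out["chromosome"],
            "start": out["start"],
            "end": out["end"],
            "name": name,
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
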