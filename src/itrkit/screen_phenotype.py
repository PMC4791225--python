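"""RNAi viability screen normalization, hit calling and morphology stats.

384-well plates (16 rows A-P x 24 columns) are normalized in log2 space by
fitting a locally-weighted quadratic (loess) surface over well coordinates
using sample wells only — the control lines (columns 1-2 and 23-24 by
default) are excluded from the fit so that they do not drag the surface.
Corrected values are residuals re-centred at the grand median of the
fitted sample wells. Robust z-scores use median / MAD (scaled by 1.4826
for normal consistency), and genes are called viability hits at
|log2FC| >= 1 versus the plate sample median.

The differentiation ratio D = L / W (longest neurite length over cell-body
width) summarises neurite outgrowth per cell; groups are compared with
Welch two-sample t-tests.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .errors import ValidationError

N_ROWS, N_COLS = 16, 24
ROW_LETTERS = "ABCDEFGHIJKLMNOP"

#: scaling making MAD a consistent estimator of the normal sd
MAD_SCALE = 1.4826


def default_control_mask() -> np.ndarray:
    """Control lines 1-2 and 23-24 along the 24-position axis (a 16-row
    plate has no line 23, so these are plate columns)."""
    mask = np.zeros((N_ROWS, N_COLS), dtype=bool)
    mask[:, [0, 1, 22, 23]] = True
    return mask


def well_name(row: int, col: int) -> str:
    return f"{ROW_LETTERS[row]}{col + 1:02d}"


def parse_well(name: str) -> tuple[int, int]:
    m = re.fullmatch(r"([A-P])(\d{1,2})", name.strip().upper())
    if not m:
        raise ValidationError(f"bad well name {name!r}")
    row = ROW_LETTERS.index(m.group(1))
    col = int(m.group(2)) - 1
    if not 0 <= col < N_COLS:
        raise ValidationError(f"well column out of range in {name!r}")
    return row, col


@dataclass
class PlateGrid:
    """One 384-well plate: raw (or corrected) signal grid plus metadata.

    ``values`` is 16 x 24; ``control_mask`` marks wells excluded from
    normalization fitting; ``annotation`` maps well name -> (gene, role)
    with role in {sample, neg_ctrl, pos_ctrl}. ``log2_scale`` records
    whether ``values`` already live in log2 space (true after
    normalization).
    """

    plate_id: str
    values: np.ndarray
    control_mask: np.ndarray = field(default_factory=default_control_mask)
    annotation: dict[str, tuple[str, str]] = field(default_factory=dict)
    log2_scale: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.control_mask = np.asarray(self.control_mask, dtype=bool)
        if self.values.shape != (N_ROWS, N_COLS):
            raise ValidationError(
                f"{self.plate_id}: plate must be {N_ROWS}x{N_COLS}, "
                f"got {self.values.shape}"
            )
        if self.control_mask.shape != (N_ROWS, N_COLS):
            raise ValidationError(f"{self.plate_id}: bad control mask shape")

    @property
    def sample_mask(self) -> np.ndarray:
        return ~self.control_mask


def read_plate_csv(
    path: str | Path,
    plate_id: str | None = None,
    annotation_path: str | Path | None = None,
) -> PlateGrid:
    """Read a 16x24 CSV grid of raw luminescence, optionally with a well
    annotation CSV (columns well, gene, role)."""
    path = Path(path)
    values = pd.read_csv(path, header=None).to_numpy(dtype=float)
    annotation: dict[str, tuple[str, str]] = {}
    mask = default_control_mask()
    if annotation_path is not None:
        annot = pd.read_csv(annotation_path)
        missing = {"well", "gene", "role"} - set(annot.columns)
        if missing:
            raise ValidationError(
                f"{annotation_path}: missing columns {sorted(missing)}"
            )
        mask = np.zeros((N_ROWS, N_COLS), dtype=bool)
        for _, row in annot.iterrows():
            r, c = parse_well(row["well"])
            annotation[well_name(r, c)] = (str(row["gene"]), str(row["role"]))
            if row["role"] != "sample":
                mask[r, c] = True
    return PlateGrid(
        plate_id=plate_id or path.stem,
        values=values,
        control_mask=mask,
        annotation=annotation,
    )


def _loess2d_fit(
    coords: np.ndarray,
    z: np.ndarray,
    eval_coords: np.ndarray,
    span: float,
    robust_iterations: int = 2,
) -> np.ndarray:
    """Locally-weighted quadratic surface fit with bisquare robustness.

    For each evaluation point the nearest ``ceil(span * n)`` fitting points
    (Euclidean distance in well coordinates) get tricube weights and a
    weighted quadratic polynomial in (row, col) is solved by least squares.
    ``robust_iterations`` bisquare re-weighting passes down-weight outlying
    wells (e.g. strong hits) so they do not drag the surface. Exact on any
    globally quadratic surface: the local basis contains it and clean
    residuals leave the robustness weights at 1.
    """
    n = len(z)
    k = max(int(np.ceil(span * n)), 6)  # quadratic basis needs 6 points
    k = min(k, n)

    def basis(pts: np.ndarray) -> np.ndarray:
        x, y = pts[:, 0], pts[:, 1]
        return np.column_stack([np.ones(len(pts)), x, y, x * y, x**2, y**2])

    def fit_at(points: np.ndarray, robust_w: np.ndarray) -> np.ndarray:
        fitted = np.empty(len(points))
        for i, pt in enumerate(points):
            d = np.hypot(coords[:, 0] - pt[0], coords[:, 1] - pt[1])
            idx = np.argsort(d, kind="stable")[:k]
            dmax = d[idx].max()
            if dmax == 0:
                w = np.ones(len(idx))
            else:
                w = (1 - np.clip(d[idx] / dmax, 0, 1) ** 3) ** 3
            w = w * robust_w[idx]
            w[w <= 0] = 1e-9  # keep boundary/outlier points in the system
            A = basis(coords[idx]) * np.sqrt(w)[:, None]
            b = z[idx] * np.sqrt(w)
            beta, *_ = np.linalg.lstsq(A, b, rcond=None)
            fitted[i] = basis(pt[None, :])[0] @ beta
        return fitted

    robust_w = np.ones(n)
    for _ in range(robust_iterations):
        resid = z - fit_at(coords, robust_w)
        s = np.median(np.abs(resid))
        if s == 0:
            break
        u = np.clip(resid / (6.0 * s), -1, 1)
        robust_w = (1 - u**2) ** 2
    return fit_at(eval_coords, robust_w)


def loess_normalize(plate: PlateGrid, span: float = 0.5) -> PlateGrid:
    """Remove spatial artifacts from a plate by loess surface correction.

    The surface is fitted on non-control ("sample fraction") wells with
    positive signal only; every well — controls included — is corrected by
    evaluating the surface at its coordinates. Corrected value =
    log2(signal) - fitted + grand median of fitted sample wells, so a
    spatially flat plate is returned unchanged. Non-positive wells are
    dropped (NaN) with a warning.
    """
    if not 0 < span <= 1:
        raise ValidationError("span must be in (0, 1]")
    raw = plate.values
    log2 = np.where(raw > 0, np.log2(np.maximum(raw, 1e-300)), np.nan) \
        if not plate.log2_scale else raw.copy()
    n_nonpos = int(np.isnan(log2).sum())
    if n_nonpos:
        warnings.warn(
            f"{plate.plate_id}: dropped {n_nonpos} non-positive well(s)",
            stacklevel=2,
        )
    fit_mask = plate.sample_mask & np.isfinite(log2)
    if fit_mask.sum() < 30:
        raise ValidationError(
            f"{plate.plate_id}: only {int(fit_mask.sum())} usable sample wells "
            "(need >= 30)"
        )
    rows, cols = np.indices((N_ROWS, N_COLS))
    coords_fit = np.column_stack([rows[fit_mask], cols[fit_mask]]).astype(float)
    z_fit = log2[fit_mask]
    eval_mask = np.isfinite(log2)
    coords_all = np.column_stack([rows[eval_mask], cols[eval_mask]]).astype(float)
    fitted_all = _loess2d_fit(coords_fit, z_fit, coords_all, span)
    fitted = np.full((N_ROWS, N_COLS), np.nan)
    fitted[eval_mask] = fitted_all
    center = float(np.median(fitted[fit_mask]))
    corrected = log2 - fitted + center
    return PlateGrid(
        plate_id=plate.plate_id,
        values=corrected,
        control_mask=plate.control_mask.copy(),
        annotation=dict(plate.annotation),
        log2_scale=True,
    )


def robust_z(values: Sequence[float]) -> tuple[np.ndarray, bool]:
    """Median/MAD z-scores: z = (x - median) / (1.4826 * MAD).

    Returns (z, degenerate_flag); when MAD is 0 all z are set to 0 and the
    flag is raised.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)] if np.isnan(x).any() else x
    if x.size < 2:
        raise ValidationError("robust_z needs at least 2 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    full = np.asarray(values, dtype=float)
    if mad == 0:
        warnings.warn("degenerate scale: MAD is 0, all z set to 0", stacklevel=2)
        return np.zeros_like(full), True
    return (full - med) / (MAD_SCALE * mad), False


def well_results(plate: PlateGrid) -> pd.DataFrame:
    """Per-well corrected signal, robust z (over sample wells' corrected
    distribution) and log2FC versus the plate sample median."""
    if not plate.log2_scale:
        raise ValidationError("well_results expects a loess-corrected plate")
    corrected = plate.values
    sample_vals = corrected[plate.sample_mask]
    sample_vals = sample_vals[np.isfinite(sample_vals)]
    med = float(np.median(sample_vals))
    mad = float(np.median(np.abs(sample_vals - med)))
    degenerate = mad == 0
    if degenerate:
        warnings.warn(f"{plate.plate_id}: MAD is 0 across sample wells", stacklevel=2)
    rows = []
    for r in range(N_ROWS):
        for c in range(N_COLS):
            v = corrected[r, c]
            if not np.isfinite(v):
                continue
            name = well_name(r, c)
            gene, role = plate.annotation.get(
                name, ("", "neg_ctrl" if plate.control_mask[r, c] else "sample")
            )
            z = 0.0 if degenerate else (v - med) / (MAD_SCALE * mad)
            rows.append((name, gene, role, v, z, v - med))
    return pd.DataFrame(
        rows, columns=["well", "gene", "role", "corrected", "z", "log2fc"]
    )


def gene_log2fc(plates: Iterable[PlateGrid]) -> pd.DataFrame:
    """Per-gene mean log2FC across replicate sample wells of one or more
    corrected plates (the screen pools all siRNAs for a gene in one well,
    so gene aggregation is over plate replicates only)."""
    frames = [well_results(p) for p in plates]
    wells = pd.concat(frames, ignore_index=True)
    samples = wells[(wells["role"] == "sample") & (wells["gene"] != "")]
    agg = (
        samples.groupby("gene")["log2fc"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "log2fc", "count": "n_wells"})
        .reset_index()
    )
    return agg


def call_hits(gene_table: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Flag viability hits at |log2FC| >= threshold (boundary inclusive):
    ``decreased`` (viability loss), ``increased``, or ``none``."""
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    out = gene_table.copy()
    fc = out["log2fc"]
    out["hit"] = np.select(
        [fc <= -threshold, fc >= threshold], ["decreased", "increased"], "none"
    )
    return out


def differentiation_stats(
    measurements: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differentiation ratio D = L / W per cell, summarised per group.

    ``measurements`` needs columns ``group``, ``neurite_length``,
    ``cell_width``. Returns (group summary with mean ratio and SEM,
    pairwise two-sided Welch t-tests for the requested pairs — all pairs
    by default).
    """
    required = {"group", "neurite_length", "cell_width"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValidationError(f"missing columns {sorted(missing)}")
    df = measurements.copy()
    if (df["cell_width"] <= 0).any():
        raise ValidationError("cell_width must be > 0")
    if (df["neurite_length"] < 0).any():
        raise ValidationError("neurite_length must be >= 0")
    df["ratio"] = df["neurite_length"] / df["cell_width"]
    counts = df.groupby("group").size()
    small = counts[counts < 2]
    if len(small):
        raise ValidationError(f"groups with < 2 cells: {list(small.index)}")
    summary = (
        df.groupby("group")["ratio"]
        .agg(n="size", mean_ratio="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)))
        .reset_index()
    )
    groups = list(summary["group"])
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    tests = []
    for a, b in pairs:
        xa = df.loc[df["group"] == a, "ratio"]
        xb = df.loc[df["group"] == b, "ratio"]
        t, p = ttest_ind(xa, xb, equal_var=False)
        tests.append((a, b, float(t), float(p)))
    tests_df = pd.DataFrame(tests, columns=["group_a", "group_b", "t", "p"])
    return summary, tests_df
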