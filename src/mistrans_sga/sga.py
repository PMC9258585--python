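"""Colony-array normalization and multiplicative genetic-interaction scoring.

A synthetic genetic array (SGA) screen crosses a query mutation into an
arrayed collection of single mutants and reads out double-mutant colony
sizes. Under the multiplicative null model the fitness of a double mutant
is the product of the single-mutant fitnesses, and the interaction score is
the deviation

    epsilon = W_AB - W_A * W_B

with W in wild-type units (wild type = 1). A negative epsilon means the
double mutant is sicker than expected (synthetic sick/lethal); calls
require both an effect-size gate (mean epsilon below -0.2 by default) and a
Benjamini-Hochberg adjusted p-value below 0.05.

Fitness estimation works at replicate resolution: each array allele is
pinned as a 2x2 quadruplicate block, and per-replicate epsilon values feed
a one-sample t-test against zero.

Normalization modes
-------------------
``median``
    rescale the plate so its median non-missing, non-border colony equals
    the reference size (assumes the typical array strain grows like wild
    type -- reasonable for screens run at a permissive temperature);
``gradient``
    remove multiplicative row/column trends by median polish in log space
    without touching the overall plate scale (use when colony sizes are
    already on the reference scale, e.g. calibrated pinning);
``polish``
    both of the above; ``none`` leaves the plate untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ArrayKey, PlateGrid, TableFormatError

__all__ = [
    "FitnessTable",
    "InteractionRecord",
    "normalize_plate",
    "fitness_from_block",
    "epsilon",
    "estimate_query_fitness",
    "build_fitness_table",
    "score_alleles",
    "bh_adjust",
    "call_interactions",
    "score_screen",
    "records_to_frame",
]

DEFAULT_EPS_THRESHOLD = -0.2
DEFAULT_Q_THRESHOLD = 0.05

#: Minimum usable colonies in a row/column before the median polish trusts
#: its effect estimate (half of a full 1,536-plate row is 24).
_MIN_LINE_COUNT = 12


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_plate(
    grid: PlateGrid,
    reference: float = 500.0,
    mode: str = "median",
    border_mask: np.ndarray | None = None,
    n_polish_iter: int = 10,
) -> PlateGrid:
    """Return a normalized copy of *grid* (missing flags preserved).

    ``border_mask`` marks positions (True) to exclude from the statistics,
    typically the outer ring of border-control colonies.
    """
    if mode not in ("none", "median", "gradient", "polish"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    out = grid.copy()
    if mode == "none":
        return out
    use = ~out.missing
    if border_mask is not None:
        use &= ~border_mask
    if not use.any():
        raise TableFormatError(f"plate {grid.plate_id!r}: all positions missing")
    if use.sum() < 0.5 * use.size and border_mask is None:
        raise TableFormatError(
            f"plate {grid.plate_id!r}: fewer than 50% usable positions")

    if mode in ("gradient", "polish"):
        out.sizes = _median_polish(out.sizes, use, n_polish_iter)
    if mode in ("median", "polish"):
        med = np.nanmedian(np.where(use, out.sizes, np.nan))
        if med <= 0:
            raise TableFormatError(
                f"plate {grid.plate_id!r}: non-positive plate median")
        out.sizes = out.sizes * (reference / med)
    out.sizes = np.where(out.missing, np.nan, out.sizes)
    return out


def _median_polish(sizes: np.ndarray, use: np.ndarray, n_iter: int) -> np.ndarray:
    """Remove multiplicative row/column effects, preserving the plate scale.

    Classic Tukey median polish on log sizes over usable positions; the
    grand effect is added back so only the spatial gradient is divided out.
    Zero colonies (dead spots) are left untouched -- the polish is fit on
    positive colonies only and its correction applied multiplicatively.
    Rows/columns with fewer than ``_MIN_LINE_COUNT`` usable colonies (sparse
    plates) get no correction: with a handful of colonies the line median is
    the colonies themselves and the polish would erase real signal.
    """
    with np.errstate(divide="ignore"):
        logs = np.log(sizes)
    fit_mask = use & np.isfinite(logs)
    sparse_rows = fit_mask.sum(axis=1) < _MIN_LINE_COUNT
    sparse_cols = fit_mask.sum(axis=0) < _MIN_LINE_COUNT
    fit_mask &= ~sparse_rows[:, None] & ~sparse_cols[None, :]
    work = np.where(fit_mask, logs, np.nan)
    row_eff = np.zeros(sizes.shape[0])
    col_eff = np.zeros(sizes.shape[1])
    with warnings.catch_warnings():
        # rows/cols with no usable colonies yield all-NaN slices by design
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(n_iter):
            rm = np.nanmedian(work, axis=1)
            rm = np.where(np.isfinite(rm), rm, 0.0)
            work -= rm[:, None]
            row_eff += rm
            cm = np.nanmedian(work, axis=0)
            cm = np.where(np.isfinite(cm), cm, 0.0)
            work -= cm[None, :]
            col_eff += cm
            if np.max(np.abs(rm)) < 1e-12 and np.max(np.abs(cm)) < 1e-12:
                break
    # spatial part only: deviations of row/col effects from their medians,
    # taken over rows/cols that actually carry data (empty ones have a
    # zero effect and must not drag the centring)
    rows_with = fit_mask.any(axis=1)
    cols_with = fit_mask.any(axis=0)
    row_dev = row_eff - np.median(row_eff[rows_with])
    col_dev = col_eff - np.median(col_eff[cols_with])
    row_dev[~rows_with] = 0.0
    col_dev[~cols_with] = 0.0
    spatial = row_dev[:, None] + col_dev[None, :]
    return sizes / np.exp(spatial)


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------

def fitness_from_block(sizes, reference: float) -> np.ndarray | None:
    """Per-replicate fitness of one quadruplicate block.

    Missing replicates (NaN) are dropped; fewer than two usable replicates
    makes the allele unscorable (returns None). Zero colonies are kept --
    lethality is signal, not missing data.
    """
    if reference <= 0:
        raise ValueError("reference colony size must be positive")
    arr = np.asarray(sizes, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        return None
    if (arr < 0).any():
        raise ValueError("negative colony size")
    return arr / reference


def epsilon(w_ab: float, w_a: float, w_b: float) -> float:
    """Multiplicative-model interaction score W_AB - W_A*W_B."""
    if w_ab < 0 or w_a < 0 or w_b < 0:
        raise ValueError("fitness values must be non-negative")
    return w_ab - w_a * w_b


def estimate_query_fitness(
    plates: list[PlateGrid],
    reference: float,
    mode: str = "gradient",
    border_mask: np.ndarray | None = None,
) -> float:
    """Query single-mutant fitness W_B from the query x neutral control cross.

    Every colony on these plates carries the query mutation in an otherwise
    wild-type background, so W_B is the median colony fitness across the
    array (the median of an even count averages the middle pair).
    """
    vals = []
    for g in plates:
        ng = normalize_plate(g, reference=reference, mode=mode,
                             border_mask=border_mask)
        use = ~ng.missing
        if border_mask is not None:
            use &= ~border_mask
        vals.append(ng.sizes[use])
    allv = np.concatenate(vals)
    if allv.size == 0:
        raise TableFormatError("no usable colonies on query control plates")
    return float(np.median(allv)) / reference


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass
class FitnessTable:
    """Single- and double-mutant fitness estimates for one screen.

    ``w_a`` maps allele -> single-mutant fitness; ``w_ab_reps`` maps allele
    -> per-replicate double-mutant fitness (no premature averaging);
    unscorable alleles (fewer than 2 usable replicates on either cross)
    appear in ``unscorable``.
    """

    w_b: float
    w_a: dict[str, float]
    w_ab_reps: dict[str, np.ndarray]
    genes: dict[str, str] = field(default_factory=dict)
    unscorable: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.w_b < 0:
            raise ValueError("query fitness must be non-negative")
        for a, w in self.w_a.items():
            if w < 0:
                raise ValueError(f"negative single fitness for {a}")


@dataclass
class InteractionRecord:
    """Scored interaction for one array allele."""

    allele_id: str
    gene_id: str
    eps_replicates: np.ndarray
    eps_mean: float
    p_raw: float
    q_bh: float = np.nan
    call: str = "none"


def score_alleles(fit: FitnessTable) -> list[InteractionRecord]:
    """Per-replicate epsilon, mean, and one-sample t-test against zero.

    Records are sorted by mean epsilon (most negative first). Unscorable
    alleles are appended with call "none" and NaN statistics.
    """
    alleles = sorted(set(fit.w_a) & set(fit.w_ab_reps))
    eps_list = [np.asarray(fit.w_ab_reps[a], float) - fit.w_a[a] * fit.w_b
                for a in alleles]
    means = np.array([e.mean() for e in eps_list])
    sds = np.array([e.std(ddof=1) for e in eps_list])
    ns = np.array([e.size for e in eps_list])
    # one vectorized two-sided t-test against 0 across all alleles
    p = np.ones(len(alleles))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / (sds / np.sqrt(ns))
    pos = sds > 0
    p[pos] = 2.0 * stats.t.sf(np.abs(t[pos]), ns[pos] - 1)
    p[~pos & (means != 0)] = 0.0
    records = [
        InteractionRecord(
            allele_id=a, gene_id=fit.genes.get(a, a), eps_replicates=e,
            eps_mean=float(m), p_raw=float(pi),
        )
        for a, e, m, pi in zip(alleles, eps_list, means, p)
    ]
    records.sort(key=lambda r: r.eps_mean)
    for a in fit.unscorable:
        records.append(InteractionRecord(
            allele_id=a, gene_id=fit.genes.get(a, a),
            eps_replicates=np.array([]), eps_mean=np.nan, p_raw=np.nan,
        ))
    return records


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    NaN entries (unscorable alleles) pass through as NaN and do not count
    toward the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def call_interactions(
    records: list[InteractionRecord],
    eps_threshold: float = DEFAULT_EPS_THRESHOLD,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> list[InteractionRecord]:
    """Attach BH-adjusted q-values and negative/positive/none calls.

    Negative: eps_mean < eps_threshold and q < q_threshold. The positive
    rule is mirrored at |eps_threshold| (a design default; the screen this
    models reported a single positive interaction without printing a
    positive threshold).
    """
    if eps_threshold >= 0:
        raise ValueError("eps_threshold must be negative")
    q = bh_adjust([r.p_raw for r in records])
    for rec, q_i in zip(records, q):
        rec.q_bh = float(q_i) if np.isfinite(q_i) else np.nan
        if np.isnan(rec.eps_mean) or np.isnan(rec.q_bh):
            rec.call = "none"
        elif rec.eps_mean < eps_threshold and rec.q_bh < q_threshold:
            rec.call = "negative"
        elif rec.eps_mean > abs(eps_threshold) and rec.q_bh < q_threshold:
            rec.call = "positive"
        else:
            rec.call = "none"
    return records


# ---------------------------------------------------------------------------
# End-to-end screen scoring
# ---------------------------------------------------------------------------

def build_fitness_table(
    double_plates: list[PlateGrid],
    control_plates: list[PlateGrid],
    key: ArrayKey,
    reference: float,
    w_b: float | None = None,
    query_plates: list[PlateGrid] | None = None,
    mode: str = "gradient",
    border_mask: np.ndarray | None = None,
) -> FitnessTable:
    """Normalize plates and assemble per-allele fitness estimates.

    * double_plates: query x array double mutants (one plate set);
    * control_plates: control strain x array, giving W_A per allele;
    * query_plates or w_b: query x neutral array, giving W_B.
    """
    if w_b is None:
        if query_plates is None:
            raise ValueError("provide either w_b or query_plates")
        w_b = estimate_query_fitness(query_plates, reference, mode=mode,
                                     border_mask=border_mask)

    norm_d = {g.plate_id: normalize_plate(g, reference, mode, border_mask)
              for g in double_plates}
    norm_c = {g.plate_id: normalize_plate(g, reference, mode, border_mask)
              for g in control_plates}

    blocks = key.blocks()
    w_a: dict[str, float] = {}
    w_ab: dict[str, np.ndarray] = {}
    genes: dict[str, str] = {}
    unscorable: list[str] = []
    for row in blocks.itertuples(index=False):
        genes[row.allele] = row.gene
        r0, c0 = int(row.row0) - 1, int(row.col0) - 1
        d = norm_d.get(str(row.plate))
        c = norm_c.get(str(row.plate))
        if d is None or c is None:
            unscorable.append(row.allele)
            continue
        fa = fitness_from_block(c.sizes[r0:r0 + 2, c0:c0 + 2].ravel(), reference)
        fab = fitness_from_block(d.sizes[r0:r0 + 2, c0:c0 + 2].ravel(), reference)
        if fa is None or fab is None:
            unscorable.append(row.allele)
            continue
        w_a[row.allele] = float(np.mean(fa))
        w_ab[row.allele] = fab
    return FitnessTable(w_b=w_b, w_a=w_a, w_ab_reps=w_ab, genes=genes,
                        unscorable=unscorable)


def score_screen(
    double_plates: list[PlateGrid],
    control_plates: list[PlateGrid],
    key: ArrayKey,
    reference: float = 500.0,
    w_b: float | None = None,
    query_plates: list[PlateGrid] | None = None,
    mode: str = "gradient",
    border_mask: np.ndarray | None = None,
    eps_threshold: float = DEFAULT_EPS_THRESHOLD,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> list[InteractionRecord]:
    """Full scoring pipeline: normalize, fit, score, adjust, call."""
    fit = build_fitness_table(double_plates, control_plates, key, reference,
                              w_b=w_b, query_plates=query_plates, mode=mode,
                              border_mask=border_mask)
    records = score_alleles(fit)
    return call_interactions(records, eps_threshold, q_threshold)


def records_to_frame(records: list[InteractionRecord]) -> pd.DataFrame:
    """Flatten interaction records to one table row per allele."""
    return pd.DataFrame({
        "allele": [r.allele_id for r in records],
        "gene": [r.gene_id for r in records],
        "eps_mean": [r.eps_mean for r in records],
        "n_replicates": [len(r.eps_replicates) for r in records],
        "p_raw": [r.p_raw for r in records],
        "q_bh": [r.q_bh for r in records],
        "call": [r.call for r in records],
    })
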