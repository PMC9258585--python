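"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of (scenario, seed): colony-array
screens with planted interaction scores, PSM tables with a planted
substitution rate, OD600 series with planted doubling times, and spot
grids with planted dose-response factors. Truth tables come back in
machine-readable form so recovery can be checked end to end.

Noise models: colony sizes and spot intensities get multiplicative
lognormal noise (positive, right-skewed, like real pinning/spotting);
OD readings get additive Gaussian noise (detector-dominated).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    BLANK,
    BORDER,
    PRO_SER_DELTA,
    ArrayKey,
    ODSeries,
    PlateGrid,
    PSMRecord,
    SpotGrid,
)
from .dose_response import CONSTRUCT_LEVELS, LEVELS
from .growth import logistic

__all__ = [
    "ScreenScenario",
    "ProteomeScenario",
    "GrowthSpec",
    "SimulatedScreen",
    "simulate_screen",
    "simulate_psms",
    "simulate_growth",
    "simulate_spots",
    "simulate_validation_cohort",
    "factors_for_rel_synth",
    "plate_border_mask",
    "frame_digest",
]

_AMINO_ACIDS = "ACDEFGHIKLMNQRSTVWY"  # proline drawn separately

N_ROWS, N_COLS = 32, 48
_BLOCK_ROWS, _BLOCK_COLS = (N_ROWS - 2) // 2, (N_COLS - 2) // 2  # 15 x 23
BLOCKS_PER_PLATE = _BLOCK_ROWS * _BLOCK_COLS  # 345 alleles per 1,536 plate


# ---------------------------------------------------------------------------
# Colony-array screens
# ---------------------------------------------------------------------------

@dataclass
class ScreenScenario:
    """A planted genetic-interaction screen.

    Single-mutant fitnesses are uniform on ``w_a_range`` (wild type = 1);
    the query fitness ``w_b`` defaults to 0.86, the growth cost of the
    mistranslating tRNA implied by a 98 vs 84 min doubling time.
    ``interactions`` maps allele index -> planted epsilon; colony noise is
    multiplicative lognormal with log-sd ``noise_sd``; optional linear
    row/column multiplicative gradients of amplitude ``row_gradient`` /
    ``col_gradient`` emulate pinning artifacts.
    """

    seed: int
    n_alleles: int = 1000
    w_a_range: tuple[float, float] = (0.5, 1.0)
    w_b: float = 0.86
    interactions: dict[int, float] = field(default_factory=dict)
    noise_sd: float = 0.05
    row_gradient: float = 0.0
    col_gradient: float = 0.0
    reference: float = 500.0

    def __post_init__(self) -> None:
        if self.n_alleles < 1:
            raise ValueError("need at least one allele")
        lo, hi = self.w_a_range
        if not (0 <= lo <= hi):
            raise ValueError("invalid single-fitness range")
        # feasibility: the planted double fitness W_A*W_B + eps must be >= 0
        # for every possible W_A draw
        for idx, eps in self.interactions.items():
            if not (0 <= idx < self.n_alleles):
                raise ValueError(f"interaction index {idx} out of range")
            if eps < -lo * self.w_b:
                raise ValueError(
                    f"planted epsilon {eps} infeasible: fitness would go "
                    f"below 0 for W_A={lo}, W_B={self.w_b}"
                )


@dataclass
class SimulatedScreen:
    double_plates: list[PlateGrid]
    control_plates: list[PlateGrid]
    query_plates: list[PlateGrid]
    key: ArrayKey
    truth: pd.DataFrame  # allele, gene, w_a, eps_planted
    reference: float


def plate_border_mask(n_rows: int = N_ROWS, n_cols: int = N_COLS) -> np.ndarray:
    """Boolean mask of the outer ring of a plate."""
    m = np.zeros((n_rows, n_cols), dtype=bool)
    m[0, :] = m[-1, :] = True
    m[:, 0] = m[:, -1] = True
    return m


def _gradient(sc: ScreenScenario) -> np.ndarray:
    rf = np.linspace(1 - sc.row_gradient, 1 + sc.row_gradient, N_ROWS)
    cf = np.linspace(1 - sc.col_gradient, 1 + sc.col_gradient, N_COLS)
    return rf[:, None] * cf[None, :]


def simulate_screen(sc: ScreenScenario) -> SimulatedScreen:
    """Lay out a screen in quadruplicate 1,536 format and synthesize plates.

    Interior positions hold 2x2 blocks (one allele each, row-major); the
    outer ring is annotated as border and left blank; leftover blocks on
    the last plate are blanks. Three plate sets are emitted: double
    mutants (query x array), control crosses (array singles, for W_A) and
    one query x neutral plate (for W_B).
    """
    rng = np.random.default_rng(sc.seed)
    lo, hi = sc.w_a_range
    w_a = rng.uniform(lo, hi, size=sc.n_alleles)
    eps = np.zeros(sc.n_alleles)
    for idx, e in sc.interactions.items():
        eps[idx] = e
    infeasible = w_a * sc.w_b + eps < 0
    if infeasible.any():
        raise ValueError("planted epsilon drives double fitness below 0")

    n_plates = -(-sc.n_alleles // BLOCKS_PER_PLATE)
    alleles = [f"a{i + 1:04d}" for i in range(sc.n_alleles)]
    genes = [f"GENE{i + 1:04d}" for i in range(sc.n_alleles)]
    # array layout is arbitrary with respect to phenotype: scatter alleles
    # across blocks so planted interactions never cluster in rows/columns
    # (clusters would be indistinguishable from spatial artifacts)
    layout = rng.permutation(sc.n_alleles)
    grad = _gradient(sc)
    border = plate_border_mask()

    key_rows = []
    doubles, controls = [], []
    a_idx = 0
    for p in range(n_plates):
        plate_id = f"P{p + 1:02d}"
        w_a_map = np.full((N_ROWS, N_COLS), np.nan)
        w_ab_map = np.full((N_ROWS, N_COLS), np.nan)
        for br in range(_BLOCK_ROWS):
            for bc in range(_BLOCK_COLS):
                r0, c0 = 1 + 2 * br, 1 + 2 * bc  # 0-based, inside border
                if a_idx < sc.n_alleles:
                    j = layout[a_idx]
                    allele, gene = alleles[j], genes[j]
                    w_a_map[r0:r0 + 2, c0:c0 + 2] = w_a[j]
                    w_ab_map[r0:r0 + 2, c0:c0 + 2] = w_a[j] * sc.w_b + eps[j]
                    block = f"{plate_id}_b{br * _BLOCK_COLS + bc + 1:03d}"
                    for dr in range(2):
                        for dc in range(2):
                            key_rows.append((plate_id, r0 + dr + 1, c0 + dc + 1,
                                             allele, gene, block))
                    a_idx += 1
                else:
                    for dr in range(2):
                        for dc in range(2):
                            key_rows.append((plate_id, r0 + dr + 1, c0 + dc + 1,
                                             BLANK, BLANK, ""))
        rr, cc = np.where(border)
        for r, c in zip(rr, cc):
            key_rows.append((plate_id, r + 1, c + 1, BORDER, BORDER, ""))

        noise_d = np.exp(rng.normal(0.0, sc.noise_sd, (N_ROWS, N_COLS)))
        noise_c = np.exp(rng.normal(0.0, sc.noise_sd, (N_ROWS, N_COLS)))
        d_sizes = sc.reference * w_ab_map * grad * noise_d
        c_sizes = sc.reference * w_a_map * grad * noise_c
        doubles.append(PlateGrid(plate_id, N_ROWS, N_COLS, d_sizes))
        controls.append(PlateGrid(plate_id, N_ROWS, N_COLS, c_sizes))

    # query x neutral-array cross: every interior colony carries only the
    # query mutation
    q_sizes = np.full((N_ROWS, N_COLS), np.nan)
    interior = ~border
    noise_q = np.exp(rng.normal(0.0, sc.noise_sd, (N_ROWS, N_COLS)))
    q_sizes[interior] = (sc.reference * sc.w_b * grad * noise_q)[interior]
    query = [PlateGrid("Q01", N_ROWS, N_COLS, q_sizes)]

    key = ArrayKey(pd.DataFrame(
        key_rows, columns=["plate", "row", "col", "allele", "gene", "block"]))
    truth = pd.DataFrame({"allele": alleles, "gene": genes, "w_a": w_a,
                          "eps_planted": eps})
    return SimulatedScreen(doubles, controls, query, key, truth, sc.reference)


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

@dataclass
class ProteomeScenario:
    """A planted mistranslation proteome.

    Each observation of a proline-containing peptide is mistranslated with
    probability ``rate`` at one uniformly chosen proline site. A fraction
    ``sibling_dropout`` of mistranslated peptide species lose their
    unmodified sibling record (emulating siblings below detection).
    ``decoy_fraction`` adds records with q-values above the FDR cutoff.
    """

    seed: int
    n_proteins: int = 200
    peptides_per_protein: int = 5
    peptide_length: tuple[int, int] = (7, 25)
    proline_content: float = 0.08
    rate: float = 0.049
    total_counts: int = 20000
    sibling_dropout: float = 0.0
    decoy_fraction: float = 0.05
    seed_q_max: float = 0.009

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 0.15):
            raise ValueError("substitution rate must lie in [0, 0.15]")
        if not (0.0 <= self.sibling_dropout <= 1.0):
            raise ValueError("sibling dropout must lie in [0, 1]")


def simulate_psms(sc: ProteomeScenario) -> tuple[list[PSMRecord], dict]:
    """PSM records plus a truth dict (rate, counts actually planted)."""
    rng = np.random.default_rng(sc.seed)
    n_pep = sc.n_proteins * sc.peptides_per_protein
    lengths = rng.integers(sc.peptide_length[0], sc.peptide_length[1] + 1,
                           size=n_pep)
    peptides = []
    for ln in lengths:
        aas = rng.choice(list(_AMINO_ACIDS), size=ln)
        is_pro = rng.random(ln) < sc.proline_content
        aas[is_pro] = "P"
        peptides.append("".join(aas))
    proteins = [f"prot{i // sc.peptides_per_protein + 1:04d}"
                for i in range(n_pep)]
    weights = rng.lognormal(0.0, 1.0, size=n_pep)
    counts = rng.multinomial(sc.total_counts, weights / weights.sum())

    records: list[PSMRecord] = []
    n_mis_total = 0
    n_pro_obs = 0
    dropped_species = 0
    for pep, prot, n in zip(peptides, proteins, counts):
        if n == 0:
            continue
        pro_sites = [i + 1 for i, aa in enumerate(pep) if aa == "P"]
        if not pro_sites:
            records.append(_true_record(rng, sc, pep, prot, int(n), []))
            continue
        n_pro_obs += int(n)
        k = rng.binomial(int(n), sc.rate)
        n_mis_total += int(k)
        drop_sibling = k > 0 and rng.random() < sc.sibling_dropout
        if drop_sibling:
            dropped_species += 1
        elif n - k > 0:
            records.append(_true_record(rng, sc, pep, prot, int(n - k), []))
        if k > 0:
            site_choice = rng.choice(len(pro_sites), size=int(k))
            for s_idx, s_count in zip(*np.unique(site_choice, return_counts=True)):
                mods = [(pro_sites[int(s_idx)], PRO_SER_DELTA)]
                records.append(_true_record(rng, sc, pep, prot,
                                            int(s_count), mods))

    n_decoys = int(sc.decoy_fraction * n_pep)
    for _ in range(n_decoys):
        ln = int(rng.integers(*sc.peptide_length))
        pep = "".join(rng.choice(list(_AMINO_ACIDS + "P"), size=ln))
        records.append(PSMRecord(
            peptide=pep, mod_sites=[], psm_q=float(rng.uniform(0.02, 0.5)),
            count=int(rng.integers(1, 4)), protein_id="decoy",
        ))
    truth = {
        "rate": sc.rate,
        "n_mistranslated_planted": n_mis_total,
        "n_pro_observations": n_pro_obs,
        "sibling_species_dropped": dropped_species,
    }
    return records, truth


def _true_record(rng, sc, pep, prot, count, mods) -> PSMRecord:
    return PSMRecord(peptide=pep, mod_sites=mods,
                     psm_q=float(rng.uniform(0.0, sc.seed_q_max)),
                     count=count, protein_id=prot)


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------

@dataclass
class GrowthSpec:
    """One strain's planted logistic curve (doubling time in minutes)."""

    strain_id: str
    doubling_min: float
    K: float = 1.4
    N0: float = 0.1
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.doubling_min <= 0:
            raise ValueError("doubling time must be positive")


def simulate_growth(
    specs: list[GrowthSpec],
    seed: int,
    duration_min: float = 1440.0,
    step_min: float = 15.0,
) -> tuple[list[ODSeries], pd.DataFrame]:
    """OD600 series sampled every 15 min over 24 h (by default).

    Additive Gaussian noise, truncated so OD stays positive.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_min + step_min / 2, step_min)
    out, rows = [], []
    for sp in specs:
        r = np.log(2.0) / sp.doubling_min
        clean = logistic(t, sp.K, sp.N0, r)
        od = clean + rng.normal(0.0, sp.noise_sd, size=t.shape)
        od = np.maximum(od, 1e-4)
        out.append(ODSeries(sp.strain_id, t.copy(), od))
        rows.append({"strain": sp.strain_id, "doubling_min": sp.doubling_min,
                     "K": sp.K, "N0": sp.N0, "r": r})
    return out, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spot grids
# ---------------------------------------------------------------------------

#: Wild-type strain dose profile: normalized growth fractions at
#: (low, medium, high) mistranslation, the near-linear decrease measured
#: for BY4742 (71%, 55%, 37% of the wild-type tRNA construct).
WT_DOSE_FACTORS = (0.71, 0.55, 0.37)


def factors_for_rel_synth(
    rel_pct: tuple[float, float, float],
    wt_factors: tuple[float, float, float] = WT_DOSE_FACTORS,
) -> tuple[float, float, float]:
    """Strain dose factors that plant a given relative-synthetic-effect
    triple (percent of the wild-type strain at each level)."""
    return tuple(r / 100.0 * w for r, w in zip(rel_pct, wt_factors))


def simulate_spots(
    strain_factors: dict[str, tuple[float, float, float]],
    seed: int,
    noise_sd: float = 0.05,
    n_reps: int = 3,
    base_intensity: float = 10000.0,
    wt_strain: str = "BY4742",
    wt_factors: tuple[float, float, float] = WT_DOSE_FACTORS,
) -> tuple[SpotGrid, pd.DataFrame]:
    """Spot-assay intensities for a dose-response cohort.

    ``strain_factors`` maps mutant strain -> fraction of its own WT-tS
    growth at (low, medium, high); the wild-type strain is added
    automatically with ``wt_factors``. Each strain gets a random baseline
    intensity so normalization has real work to do. Truth lists the
    planted relative synthetic effect per level.
    """
    rng = np.random.default_rng(seed)
    all_factors = {wt_strain: wt_factors, **strain_factors}
    level_constructs = {lv: c for c, lv in CONSTRUCT_LEVELS.items()}
    rows, truth_rows = [], []
    for strain, factors in all_factors.items():
        if not all(0 < f <= 1.5 for f in factors):
            raise ValueError(f"{strain}: dose factors must lie in (0, 1.5]")
        baseline = base_intensity * rng.lognormal(0.0, 0.2)
        for rep in range(1, n_reps + 1):
            rows.append((strain, "WT-tS", rep,
                         baseline * np.exp(rng.normal(0, noise_sd))))
        for lv, f in zip(LEVELS, factors):
            for rep in range(1, n_reps + 1):
                rows.append((strain, level_constructs[lv], rep,
                             baseline * f * np.exp(rng.normal(0, noise_sd))))
        truth_rows.append({
            "strain": strain,
            **{f"rel_synth_{lv}": 100.0 * f / w
               for lv, f, w in zip(LEVELS, factors, wt_factors)},
        })
    grid = SpotGrid(pd.DataFrame(
        rows, columns=["strain", "construct", "replicate", "intensity"]))
    return grid, pd.DataFrame(truth_rows)


def simulate_validation_cohort(
    seed: int,
    n_true: int = 20,
    n_null: int = 20,
    true_ratio: float = 0.6,
    noise_sd: float = 0.05,
    n_reps: int = 3,
    w_b: float = 0.86,
    base_intensity: float = 10000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spot intensities for hit validation with planted observed/expected
    ratios (true hits at ``true_ratio``, nulls at 1.0).

    Returns (long-format table with roles double/single_ts/single_trna/
    control, truth table).
    """
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for i in range(n_true + n_null):
        is_true = i < n_true
        strain = f"ts{i + 1:03d}"
        ratio = true_ratio if is_true else 1.0
        w_ts = rng.uniform(0.5, 0.9)
        means = {
            "control": base_intensity,
            "single_ts": base_intensity * w_ts,
            "single_trna": base_intensity * w_b,
            "double": base_intensity * w_ts * w_b * ratio,
        }
        for role, mu in means.items():
            for rep in range(1, n_reps + 1):
                rows.append((strain, role, rep,
                             mu * np.exp(rng.normal(0, noise_sd))))
        truth.append({"strain": strain, "ratio_planted": ratio,
                      "is_interaction": is_true})
    table = pd.DataFrame(rows, columns=["strain", "role", "replicate",
                                        "intensity"])
    return table, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Reproducibility helper
# ---------------------------------------------------------------------------

def frame_digest(df: pd.DataFrame) -> str:
    """SHA-256 of a DataFrame's CSV image (reproducibility checks)."""
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()
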