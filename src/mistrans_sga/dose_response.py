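"""Dose-response of synthetic interactions across mistranslation levels.

Each strain carries one of four tRNA constructs setting the Pro->Ser
mistranslation frequency: wild-type tRNA-Ser (background, ~0.3%), the
variant silenced by a downstream GAL1 promoter (low, ~0.9%), by an
upstream GAL1 promoter (medium, ~3.5%), or unregulated (high, ~5.6%).

Two normalizations stack:

* normalized growth -- spot intensity of a construct divided by the same
  strain carrying wild-type tRNA-Ser, as a percent (removes the strain's
  baseline fitness);
* relative synthetic effect -- normalized growth of the mutant strain as a
  percent of the wild-type strain's normalized growth at the same level
  (100% = no synthetic interaction, NOT no mistranslation cost).

Profiles over (low, medium, high) are classified into four response
categories. The biology is a continuum; the numeric boundaries here are
this module's operationalization, exposed in :class:`CategoryRules`:

* uniform -- near-equal synthetic effect at all three levels;
* proportional -- little interaction at low frequency, monotonically
  stronger with dose;
* threshold -- mild at low but a shared strong defect at medium and high;
* low_sensitive -- disproportionate impact already at the lowest
  frequency, and any remaining irregular profile (the fallback, so every
  admissible profile receives exactly one category).

The proportional and threshold regions are disjoint in the low-level
coordinate (>=90 vs [75, 90)); this keeps classification monotone: once a
profile is threshold, deepening the high-level defect cannot re-label it
proportional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import SpotGrid

__all__ = [
    "LEVELS",
    "CONSTRUCT_LEVELS",
    "NOMINAL_FREQUENCY_PCT",
    "CATEGORIES",
    "CategoryRules",
    "DoseResponseProfile",
    "normalized_growth",
    "relative_synthetic_effect",
    "classify_profile",
    "classify_grid",
    "welch_bonferroni",
    "profile_strains",
    "profiles_to_frame",
]

LEVELS = ("low", "medium", "high")

#: Mistranslating construct providing each dose level; WT-tS is the
#: within-strain normalizer.
CONSTRUCT_LEVELS = {
    "3'-tS(UGG)": "low",
    "5'-tS(UGG)": "medium",
    "tS(UGG)": "high",
}

#: Nominal Pro->Ser frequencies (%) measured for each construct.
NOMINAL_FREQUENCY_PCT = {
    "WT-tS": 0.3,
    "3'-tS(UGG)": 0.9,
    "5'-tS(UGG)": 3.5,
    "tS(UGG)": 5.6,
}

CATEGORIES = ("uniform", "proportional", "threshold", "low_sensitive")


@dataclass(frozen=True)
class CategoryRules:
    """Numeric boundaries of the response categories (percent points)."""

    uniform_range: float = 10.0       # max-min within this => uniform
    proportional_low_min: float = 90.0
    threshold_low_min: float = 75.0
    threshold_level_max: float = 75.0  # medium & high both below this
    threshold_gap: float = 10.0        # |medium - high| within this
    low_sensitive_frac: float = 0.6    # drop at low >= frac * drop at high


DEFAULT_RULES = CategoryRules()


@dataclass
class DoseResponseProfile:
    strain_id: str
    norm_growth: dict[str, float]            # level -> % of same-strain WT-tS
    rel_synth: dict[str, float] | None       # level -> % of wild-type strain
    category: str | None
    n_reps: dict[str, int] = field(default_factory=dict)
    norm_growth_sd: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalized_growth(
    spots: SpotGrid,
    strain: str,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[dict[str, float], dict[str, int], dict[str, float]]:
    """Per-level growth of *strain* as a percent of its WT-tS construct.

    Returns (percent per level, replicate count per level, bootstrap sd per
    level). Dispersion comes from resampling replicate intensities of both
    the construct and the WT-tS normalizer (ratio-of-means statistic).
    """
    wt = spots.intensities(strain, "WT-tS")
    if wt.size == 0:
        raise ValueError(f"{strain}: no WT-tS construct intensities")
    if wt.mean() <= 0:
        raise ValueError(f"{strain}: WT-tS mean intensity must be positive")
    rng = np.random.default_rng(seed)
    pct: dict[str, float] = {}
    n_reps: dict[str, int] = {}
    sds: dict[str, float] = {}
    for construct, level in CONSTRUCT_LEVELS.items():
        v = spots.intensities(strain, construct)
        if v.size == 0:
            raise ValueError(f"{strain}: no intensities for {construct}")
        pct[level] = 100.0 * v.mean() / wt.mean()
        n_reps[level] = int(v.size)
        if n_boot > 0:
            bv = rng.choice(v, size=(n_boot, v.size)).mean(axis=1)
            bw = rng.choice(wt, size=(n_boot, wt.size)).mean(axis=1)
            sds[level] = float(np.std(100.0 * bv / bw, ddof=1))
    return pct, n_reps, sds


def relative_synthetic_effect(
    profile: dict[str, float],
    wt_profile: dict[str, float],
) -> dict[str, float]:
    """Strain normalized growth as a percent of the wild-type strain's.

    100 at a level means no synthetic interaction there. Undefined (NaN)
    where the wild-type strain's normalized growth is zero.
    """
    if set(profile) != set(wt_profile):
        raise ValueError("strain and wild-type profiles cover different levels")
    out = {}
    for level, wt in wt_profile.items():
        out[level] = 100.0 * profile[level] / wt if wt > 0 else float("nan")
    return out


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_profile(
    rel_synth: dict[str, float],
    rules: CategoryRules = DEFAULT_RULES,
) -> str:
    """Assign one of the four response categories to a (low, medium, high)
    relative-synthetic-effect triple.

    The cascade is total: uniform, then proportional, then threshold, with
    low_sensitive as the fallback, so every triple in (0, 200] maps to
    exactly one category.
    """
    missing = [lv for lv in LEVELS if lv not in rel_synth]
    if missing:
        raise ValueError(f"missing levels {missing}")
    lo, me, hi = (float(rel_synth[lv]) for lv in LEVELS)
    for v in (lo, me, hi):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"relative synthetic effect {v} not in (0, inf)")
    r = rules
    if max(lo, me, hi) - min(lo, me, hi) <= r.uniform_range:
        return "uniform"
    if lo >= r.proportional_low_min and lo > me > hi:
        return "proportional"
    if (r.threshold_low_min <= lo < r.proportional_low_min
            and me < r.threshold_level_max and hi < r.threshold_level_max
            and abs(me - hi) <= r.threshold_gap):
        return "threshold"
    return "low_sensitive"


def classify_grid(
    lo: np.ndarray, me: np.ndarray, hi: np.ndarray,
    rules: CategoryRules = DEFAULT_RULES,
) -> np.ndarray:
    """Vectorized :func:`classify_profile` over arrays of triples.

    Returns integer codes indexing :data:`CATEGORIES`. Used for exhaustive
    totality checks over dense grids.
    """
    lo, me, hi = (np.asarray(a, float) for a in (lo, me, hi))
    r = rules
    stacked = np.stack([lo, me, hi])
    uniform = stacked.max(axis=0) - stacked.min(axis=0) <= r.uniform_range
    prop = (lo >= r.proportional_low_min) & (lo > me) & (me > hi)
    thresh = ((lo >= r.threshold_low_min) & (lo < r.proportional_low_min)
              & (me < r.threshold_level_max) & (hi < r.threshold_level_max)
              & (np.abs(me - hi) <= r.threshold_gap))
    code = np.full(lo.shape, 3, dtype=np.int8)  # low_sensitive fallback
    code[thresh] = 2
    code[prop] = 1  # disjoint from thresh in lo, but cascade order anyway
    code[uniform] = 0  # uniform is checked first in the cascade
    return code


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def welch_bonferroni(
    pairs: list[tuple], m: int | None = None,
) -> list[tuple[float, float, float]]:
    """Welch's unequal-variance t-test per pair with Bonferroni correction.

    ``pairs`` is a list of (group_a, group_b) replicate arrays; ``m``
    defaults to the number of comparisons. Returns (t, p_raw, p_adj)
    per pair, p_adj = min(1, m * p_raw). Two zero-variance groups with
    equal means give p = 1.
    """
    m = len(pairs) if m is None else m
    out = []
    for a, b in pairs:
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if a.size < 2 or b.size < 2:
            raise ValueError("need >=2 values per group")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                out.append((0.0, 1.0, 1.0))
                continue
            out.append((np.inf, 0.0, 0.0))
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        out.append((float(t), float(p), float(min(1.0, m * p))))
    return out


# ---------------------------------------------------------------------------
# Cohort driver
# ---------------------------------------------------------------------------

def profile_strains(
    spots: SpotGrid,
    wt_strain: str = "BY4742",
    rules: CategoryRules = DEFAULT_RULES,
    n_boot: int = 1000,
    seed: int | None = None,
) -> list[DoseResponseProfile]:
    """Normalized growth, relative synthetic effect and category per strain.

    The wild-type strain anchors the relative effect (its own profile is
    100% at every level by construction and it is not categorized).
    """
    if wt_strain not in spots.strains:
        raise ValueError(f"wild-type strain {wt_strain!r} absent from spot table")
    profiles = []
    wt_norm, _, _ = normalized_growth(spots, wt_strain, n_boot=0)
    for i, strain in enumerate(spots.strains):
        sub_seed = None if seed is None else seed + i
        norm, n_reps, sds = normalized_growth(spots, strain, n_boot=n_boot,
                                              seed=sub_seed)
        if strain == wt_strain:
            rel = {lv: 100.0 for lv in LEVELS}
            cat = None
        else:
            rel = relative_synthetic_effect(norm, wt_norm)
            cat = classify_profile(rel, rules)
        profiles.append(DoseResponseProfile(
            strain_id=strain, norm_growth=norm, rel_synth=rel,
            category=cat, n_reps=n_reps, norm_growth_sd=sds,
        ))
    return profiles


def profiles_to_frame(profiles: list[DoseResponseProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"strain": p.strain_id, "category": p.category or ""}
        for lv in LEVELS:
            row[f"norm_growth_{lv}"] = p.norm_growth[lv]
            row[f"rel_synth_{lv}"] = p.rel_synth[lv] if p.rel_synth else np.nan
            row[f"n_reps_{lv}"] = p.n_reps.get(lv, 0)
            row[f"norm_growth_sd_{lv}"] = p.norm_growth_sd.get(lv, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
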