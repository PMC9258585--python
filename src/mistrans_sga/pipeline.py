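"""Run configuration and the end-to-end screen -> validate -> dose-response
pipeline.

The pipeline is re-entrant: every stage reads and writes plain TSV/CSV, no
stage mutates its inputs, and a provenance manifest (config hash, seed,
package version, per-stage record counts) is written alongside the
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .dose_response import CategoryRules, profile_strains, profiles_to_frame
from .growth import fit_logistic
from .io import (
    read_array_key,
    read_od_table,
    read_plate_table,
    read_psm_table,
    read_spot_table,
    write_array_key,
    write_plate_table,
    write_spot_table,
)
from .mistranslation import frequency
from .sga import records_to_frame, score_screen
from .simulate import (
    ScreenScenario,
    factors_for_rel_synth,
    plate_border_mask,
    simulate_screen,
    simulate_spots,
    simulate_validation_cohort,
)
from .validation import validate_cohort

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("mistrans_sga")


@dataclass
class RunConfig:
    """Thresholds, modes and paths for one pipeline run.

    The config round-trips losslessly through YAML; every threshold is
    validated against its admissible range on construction.
    """

    seed: int = 1729
    eps_threshold: float = -0.2
    q_threshold: float = 0.05
    theta: float = 0.9
    fdr: float = 0.01
    reference: float = 500.0
    normalization_mode: str = "gradient"
    count_mode: str = "spectral"
    category_rules: dict = field(default_factory=lambda: asdict(CategoryRules()))
    # input paths; None means "simulate this stage's inputs"
    plates: str | None = None
    key: str | None = None
    control_plates: str | None = None
    query_plates: str | None = None
    spots: str | None = None
    # simulation scenario used when inputs are not supplied
    n_alleles: int = 1000
    n_interactions: int = 20
    planted_eps: float = -0.4
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.eps_threshold >= 0:
            raise ValueError("eps_threshold must be negative")
        if not (0 < self.q_threshold < 1):
            raise ValueError("q_threshold must lie in (0, 1)")
        if not (0 < self.theta <= 1.5):
            raise ValueError("theta must lie in (0, 1.5]")
        if not (0 < self.fdr <= 1):
            raise ValueError("fdr must lie in (0, 1]")
        if self.normalization_mode not in ("none", "median", "gradient", "polish"):
            raise ValueError(f"unknown normalization mode "
                             f"{self.normalization_mode!r}")
        if self.count_mode not in ("spectral", "unique"):
            raise ValueError(f"unknown count mode {self.count_mode!r}")

    # -- round trip -----------------------------------------------------
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def rules(self) -> CategoryRules:
        return CategoryRules(**self.category_rules)


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute screen scoring, hit validation and dose-response profiling.

    With no input paths configured, each stage runs on synthetic inputs
    planted from the config's scenario parameters (written to the run
    directory first, so the run is reproducible from its own outputs).
    Returns the provenance manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_sha256": cfg.digest(),
        "seed": cfg.seed,
        "version": __version__,
        "stages": {},
    }
    log.info("pipeline start: eps<%s q<%s theta=%s mode=%s seed=%s",
             cfg.eps_threshold, cfg.q_threshold, cfg.theta,
             cfg.normalization_mode, cfg.seed)
    cfg.to_yaml(outdir / "config.yaml")

    # -- stage 1: screen scoring ---------------------------------------
    border = None
    if cfg.plates and cfg.key and cfg.control_plates:
        doubles = read_plate_table(cfg.plates)
        controls = read_plate_table(cfg.control_plates)
        key = read_array_key(cfg.key)
        query = read_plate_table(cfg.query_plates) if cfg.query_plates else None
    else:
        rng_idx = range(cfg.n_interactions)
        sc = ScreenScenario(
            seed=cfg.seed, n_alleles=cfg.n_alleles,
            interactions={i: cfg.planted_eps for i in rng_idx},
            noise_sd=cfg.noise_sd, reference=cfg.reference,
        )
        sim = simulate_screen(sc)
        doubles, controls, query, key = (sim.double_plates, sim.control_plates,
                                         sim.query_plates, sim.key)
        border = plate_border_mask()
        write_plate_table(doubles, outdir / "double_plates.tsv")
        write_plate_table(controls, outdir / "control_plates.tsv")
        write_plate_table(query, outdir / "query_plates.tsv")
        write_array_key(key, outdir / "array_key.tsv")
        sim.truth.to_csv(outdir / "screen_truth.tsv", sep="\t", index=False)

    records = score_screen(
        doubles, controls, key, reference=cfg.reference, query_plates=query,
        mode=cfg.normalization_mode, border_mask=border,
        eps_threshold=cfg.eps_threshold, q_threshold=cfg.q_threshold,
    )
    hits_df = records_to_frame(records)
    hits_df.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
    hit_alleles = hits_df.loc[hits_df["call"] == "negative", "allele"].tolist()
    manifest["stages"]["score"] = {
        "alleles_in": len(records), "negative_calls": len(hit_alleles),
        "positive_calls": int((hits_df["call"] == "positive").sum()),
    }
    log.info("score: %d alleles, %d negative calls", len(records),
             len(hit_alleles))

    # -- stage 2: spot validation --------------------------------------
    if cfg.spots:
        spot_table = read_spot_table(cfg.spots).table
        val_table = None  # dose-response spots supplied, not validation
        validated = None
    else:
        val_table, _truth = simulate_validation_cohort(
            seed=cfg.seed + 1, n_true=min(len(hit_alleles), 20) or 5,
            noise_sd=cfg.noise_sd)
        val_table.to_csv(outdir / "validation_spots.tsv", sep="\t", index=False)
        validated = validate_cohort(val_table, theta=cfg.theta)
        validated.to_csv(outdir / "validated.tsv", sep="\t", index=False)
        manifest["stages"]["validate"] = {
            "strains_in": len(validated),
            "validated": int(validated["validated"].sum()),
        }
        log.info("validate: %d/%d validated",
                 int(validated["validated"].sum()), len(validated))

    # -- stage 3: dose response ----------------------------------------
    if cfg.spots:
        spots = read_spot_table(cfg.spots)
    else:
        spots, dr_truth = simulate_spots(
            {"tsA": factors_for_rel_synth((95, 70, 40)),
             "tsB": factors_for_rel_synth((80, 50, 48)),
             "tsC": factors_for_rel_synth((60, 58, 55))},
            seed=cfg.seed + 2, noise_sd=cfg.noise_sd)
        write_spot_table(spots, outdir / "dose_spots.tsv")
        dr_truth.to_csv(outdir / "dose_truth.tsv", sep="\t", index=False)
    profiles = profile_strains(spots, rules=cfg.rules(), seed=cfg.seed + 3)
    prof_df = profiles_to_frame(profiles)
    prof_df.to_csv(outdir / "profiles.tsv", sep="\t", index=False)
    manifest["stages"]["dose_response"] = {
        "strains_in": len(profiles),
        "categories": prof_df["category"].value_counts().to_dict(),
    }
    log.info("dose response: %d strains profiled", len(profiles))

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return manifest


def summarize_growth(od_path, out_path, blank: float = 0.0):
    """Fit every series in an OD CSV; write one row per strain."""
    import pandas as pd

    fits = [fit_logistic(s, blank=blank) for s in read_od_table(od_path)]
    df = pd.DataFrame({
        "strain": [f.strain_id for f in fits],
        "converged": [f.converged for f in fits],
        "K": [f.K for f in fits],
        "N0": [f.N0 for f in fits],
        "r_per_min": [f.r for f in fits],
        "doubling_min": [f.doubling_time for f in fits],
        "rss": [f.rss for f in fits],
        "message": [f.message for f in fits],
    })
    df.to_csv(out_path, sep="\t", index=False)
    return df


def summarize_frequency(psm_path, out_path, fdr: float = 0.01,
                        count_mode: str = "spectral"):
    """Substitution frequency for one PSM table; write a one-row TSV."""
    import pandas as pd

    records, rejected = read_psm_table(psm_path)
    res = frequency(records, sample_id=str(psm_path), fdr=fdr,
                    count_mode=count_mode)
    df = pd.DataFrame([{
        "sample": res.sample_id,
        "n_mistranslated": res.n_mistranslated,
        "n_target_total": res.n_target_total,
        "frequency_pct": res.frequency_pct,
        "n_qualified_unique_peptides": res.n_qualified_unique_peptides,
        "excluded_no_sibling": res.excluded_no_sibling,
        "rejected_rows": len(rejected),
    }])
    df.to_csv(out_path, sep="\t", index=False)
    return df
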