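"""Amino-acid substitution frequency from peptide-spectrum-match tables.

Cells expressing a mistranslating tRNA insert the wrong amino acid at a
fraction of target codons; shotgun proteomics sees this as peptides whose
spectra match the reference sequence with a diagnostic mass shift
(serine-for-proline is -10.0207 Da). The frequency estimator is:

1. keep PSMs passing the 1% FDR filter (q <= 0.01);
2. a mistranslated peptide qualifies only if its non-mistranslated sibling
   -- the identical reference sequence with no substitution modification --
   was also observed (guards against sequence-database artifacts);
   unqualified mistranslated peptides are dropped from numerator *and*
   denominator;
3. frequency (%) = 100 x counts of qualified mistranslated peptides /
   counts of all peptides whose reference sequence contains the target
   residue.

Counting modes: spectral counts (default) or distinct peptide sequences;
and per-peptide (one event per observation, default) or per-site counting
for doubly substituted peptides.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import MOD_MATCH_TOL, PRO_SER_DELTA, PSMRecord

__all__ = [
    "FrequencyResult",
    "filter_psms",
    "is_mistranslated",
    "qualify_siblings",
    "frequency",
]

DEFAULT_FDR = 0.01


@dataclass
class FrequencyResult:
    sample_id: str
    n_mistranslated: int
    n_target_total: int
    frequency_pct: float
    n_qualified_unique_peptides: int
    excluded_no_sibling: int


def filter_psms(records: list[PSMRecord], fdr: float = DEFAULT_FDR) -> list[PSMRecord]:
    """PSMs passing the q-value cutoff (q <= fdr)."""
    return [r for r in records if r.psm_q <= fdr]


def is_mistranslated(
    rec: PSMRecord,
    delta: float = PRO_SER_DELTA,
    from_aa: str = "P",
    tol: float = MOD_MATCH_TOL,
) -> bool:
    """True if the record carries >=1 substitution mod on the target residue."""
    return len(rec.sites_matching(delta, from_aa, tol)) > 0


def qualify_siblings(
    records: list[PSMRecord],
    delta: float = PRO_SER_DELTA,
    from_aa: str = "P",
) -> tuple[list[PSMRecord], int]:
    """Apply the sibling-peptide rule to mistranslated records.

    Returns (qualified mistranslated records, spectral counts excluded for
    lack of a sibling). A mistranslated peptide qualifies iff some retained
    record has the identical reference sequence with no substitution
    modification (other modifications, e.g. oxidation, do not disqualify a
    sibling).
    """
    unmodified_seqs = {r.peptide for r in records
                       if not is_mistranslated(r, delta, from_aa)}
    qualified = []
    excluded_counts = 0
    for r in records:
        if not is_mistranslated(r, delta, from_aa):
            continue
        if r.peptide in unmodified_seqs:
            qualified.append(r)
        else:
            excluded_counts += r.count
    return qualified, excluded_counts


def frequency(
    records: list[PSMRecord],
    sample_id: str = "",
    delta: float = PRO_SER_DELTA,
    from_aa: str = "P",
    fdr: float = DEFAULT_FDR,
    count_mode: str = "spectral",
    per_site: bool = False,
) -> FrequencyResult:
    """Substitution frequency (%) from a PSM table.

    The denominator is all retained observations of peptides whose
    reference sequence contains the target residue, including the
    qualified mistranslated forms; mistranslated peptides whose sibling was
    never seen are removed from both sides of the ratio. With
    ``count_mode="unique"`` distinct peptide sequences are counted instead
    of spectral counts; with ``per_site=True`` a doubly substituted peptide
    contributes one event per substituted site.
    """
    if count_mode not in ("spectral", "unique"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    retained = filter_psms(records, fdr)
    qualified, excluded = qualify_siblings(retained, delta, from_aa)
    qualified_ids = {id(r) for r in qualified}

    def weight(rec: PSMRecord) -> int:
        return rec.count if count_mode == "spectral" else 1

    n_mis = 0
    n_total = 0
    seen_unique: set[tuple[str, bool]] = set()
    for r in retained:
        mis = is_mistranslated(r, delta, from_aa)
        if mis and id(r) not in qualified_ids:
            continue  # no sibling: out of numerator and denominator
        if from_aa not in r.peptide:
            continue
        if count_mode == "unique":
            kk = (r.peptide, mis)
            if kk in seen_unique:
                continue
            seen_unique.add(kk)
        w = weight(r)
        n_total += w
        if mis:
            n_sites = len(r.sites_matching(delta, from_aa))
            n_mis += w * (n_sites if per_site else 1)
    if n_total == 0:
        raise ValueError("no peptides containing the target residue; "
                         "frequency undefined")
    return FrequencyResult(
        sample_id=sample_id,
        n_mistranslated=n_mis,
        n_target_total=n_total,
        frequency_pct=100.0 * n_mis / n_total,
        n_qualified_unique_peptides=len({r.peptide for r in qualified}),
        excluded_no_sibling=excluded,
    )
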