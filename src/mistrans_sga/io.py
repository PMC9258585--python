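"""Data model and plain-text readers/writers for colony-array screens.

Five table kinds flow through the pipeline, all UTF-8 text with a header
row:

* plate TSV (``plate, row, col, size``) -- colony sizes on a pinned array,
  1,536 / 384 / 96 format, 1-based row-major coordinates;
* array-key TSV (``plate, row, col, allele, gene, block``) -- which allele
  sits at each position; array strains are pinned as 2x2 technical
  quadruplicate blocks, border/blank positions are annotated explicitly;
* spot TSV (``strain, construct, replicate, intensity``) -- quantified
  spot-assay densities;
* OD CSV (``strain, time_min, od``) -- microplate OD600 time series;
* PSM TSV (``peptide, protein, mods, q, count``) -- post-search
  peptide-spectrum matches with variable-modification annotations.

Missing colonies (contamination, pinning failure) are first-class missing
values: they are flagged, never encoded as zero, and excluded from all
downstream statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlateGrid",
    "ArrayKey",
    "SpotGrid",
    "ODSeries",
    "PSMRecord",
    "BORDER",
    "BLANK",
    "SPOT_CONSTRUCTS",
    "DEFAULT_MOD_CATALOGUE",
    "PRO_SER_DELTA",
    "read_plate_table",
    "write_plate_table",
    "read_array_key",
    "write_array_key",
    "read_spot_table",
    "write_spot_table",
    "read_od_table",
    "write_od_table",
    "read_psm_table",
    "write_psm_table",
]

#: Annotations for unmapped array positions.
BORDER = "BORDER"
BLANK = "BLANK"

#: tRNA constructs used in the regulated-mistranslation spot assays, ordered
#: by nominal Pro->Ser frequency (wild-type tRNA-Ser, then the variant with a
#: downstream GAL1 promoter, upstream GAL1 promoter, and unregulated).
SPOT_CONSTRUCTS = ("WT-tS", "3'-tS(UGG)", "5'-tS(UGG)", "tS(UGG)")

#: Monoisotopic mass shift (Da) of a serine-for-proline substitution.
PRO_SER_DELTA = -10.0207

#: Variable/constant modifications recognised by default: Ser-for-Pro
#: substitution, methionine oxidation, cysteine carbamidomethylation.
DEFAULT_MOD_CATALOGUE: dict[str, tuple[float, str]] = {
    "pro_to_ser": (PRO_SER_DELTA, "P"),
    "oxidation": (15.9949, "M"),
    "carbamidomethyl": (57.0215, "C"),
}

#: Tolerance (Da) when matching an annotated delta mass to the catalogue.
MOD_MATCH_TOL = 0.01

_VALID_FORMATS = {1536: (32, 48), 384: (16, 24), 96: (8, 12)}


class TableFormatError(ValueError):
    """A table violates its format contract (bad index, duplicate, ...)."""


# ---------------------------------------------------------------------------
# Plate grids
# ---------------------------------------------------------------------------

@dataclass
class PlateGrid:
    """Colony sizes of one plate, addressed by 1-based (row, col).

    ``sizes`` holds arbitrary area units, NaN at missing positions;
    ``missing`` is the authoritative missing-data mask.
    """

    plate_id: str
    n_rows: int
    n_cols: int
    sizes: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.n_rows * self.n_cols
        if n not in _VALID_FORMATS or _VALID_FORMATS[n] != (self.n_rows, self.n_cols):
            raise TableFormatError(
                f"plate {self.plate_id!r}: {self.n_rows}x{self.n_cols} is not a "
                "recognised colony-array format (32x48, 16x24 or 8x12)"
            )
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.sizes.shape != (self.n_rows, self.n_cols):
            raise TableFormatError(
                f"plate {self.plate_id!r}: size matrix shape {self.sizes.shape} "
                f"does not match {self.n_rows}x{self.n_cols}"
            )
        if self.missing is None:
            self.missing = np.isnan(self.sizes)
        self.missing = np.asarray(self.missing, dtype=bool)
        if np.nanmin(self.sizes[~self.missing], initial=0.0) < 0:
            raise TableFormatError(f"plate {self.plate_id!r}: negative colony size")
        # missing positions carry NaN so they can never leak into arithmetic
        self.sizes = np.where(self.missing, np.nan, self.sizes)

    @property
    def n_positions(self) -> int:
        return self.n_rows * self.n_cols

    def copy(self) -> "PlateGrid":
        return PlateGrid(
            self.plate_id, self.n_rows, self.n_cols,
            self.sizes.copy(), self.missing.copy(),
        )


def read_plate_table(path) -> list[PlateGrid]:
    """Read a plate TSV into one :class:`PlateGrid` per plate id.

    ``size`` may be empty or ``NA`` for a missing colony. Duplicate
    (plate,row,col) entries and out-of-range indices are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"plate": str},
                     na_values=["NA"], keep_default_na=True)
    _require_columns(df, ("plate", "row", "col", "size"), path)
    dup = df.duplicated(subset=["plate", "row", "col"])
    if dup.any():
        r = df[dup].iloc[0]
        raise TableFormatError(
            f"{path}: duplicate position (plate={r['plate']}, row={r['row']}, "
            f"col={r['col']})"
        )
    grids = []
    for plate_id, sub in df.groupby("plate", sort=True):
        n_rows, n_cols = _infer_format(sub, plate_id, path)
        sizes = np.full((n_rows, n_cols), np.nan)
        rows = sub["row"].to_numpy(dtype=int) - 1
        cols = sub["col"].to_numpy(dtype=int) - 1
        sizes[rows, cols] = sub["size"].to_numpy(dtype=float)
        grids.append(PlateGrid(str(plate_id), n_rows, n_cols, sizes))
    return grids


def write_plate_table(grids: list[PlateGrid], path) -> None:
    frames = []
    for g in grids:
        r, c = np.indices((g.n_rows, g.n_cols))
        frames.append(pd.DataFrame({
            "plate": g.plate_id,
            "row": r.ravel() + 1,
            "col": c.ravel() + 1,
            "size": g.sizes.ravel(),
        }))
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, sep="\t", index=False, na_rep="NA",
               float_format="%.12g")


def _infer_format(sub: pd.DataFrame, plate_id, path) -> tuple[int, int]:
    n = len(sub)
    if n not in _VALID_FORMATS:
        raise TableFormatError(
            f"{path}: plate {plate_id!r} has {n} positions; expected a full "
            "1536/384/96 array"
        )
    n_rows, n_cols = _VALID_FORMATS[n]
    bad = sub[(sub["row"] < 1) | (sub["row"] > n_rows)
              | (sub["col"] < 1) | (sub["col"] > n_cols)]
    if len(bad):
        line = bad.index[0] + 2  # header + 1-based
        raise TableFormatError(
            f"{path}: line {line}: position ({bad.iloc[0]['row']}, "
            f"{bad.iloc[0]['col']}) outside {n_rows}x{n_cols} plate "
            f"{plate_id!r}"
        )
    return n_rows, n_cols


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")


# ---------------------------------------------------------------------------
# Array keys
# ---------------------------------------------------------------------------

@dataclass
class ArrayKey:
    """Maps plate positions to array alleles.

    ``positions`` has columns plate, row, col, allele, gene, block; border
    and blank positions carry the :data:`BORDER` / :data:`BLANK` sentinel in
    the allele column. Each real allele occupies exactly one 2x2 block of
    four positions per plate (the technical quadruplicate of the 384->1,536
    condensation).
    """

    positions: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.positions, ("plate", "row", "col", "allele",
                                          "gene", "block"), "array key")
        self.positions = self.positions.reset_index(drop=True)
        self._verify_blocks()

    def _verify_blocks(self) -> None:
        mapped = self.positions[~self.positions["allele"].isin((BORDER, BLANK))]
        for (plate, allele), sub in mapped.groupby(["plate", "allele"]):
            if len(sub) != 4:
                raise TableFormatError(
                    f"allele {allele!r} has {len(sub)} positions on plate "
                    f"{plate!r}; expected a quadruplicate of 4"
                )
            r0, c0 = int(sub["row"].min()), int(sub["col"].min())
            got = set(zip(sub["row"].astype(int), sub["col"].astype(int)))
            want = {(r0, c0), (r0, c0 + 1), (r0 + 1, c0), (r0 + 1, c0 + 1)}
            if got != want:
                raise TableFormatError(
                    f"allele {allele!r} positions {sorted(got)} on plate "
                    f"{plate!r} do not form a 2x2 block"
                )

    @property
    def alleles(self) -> list[str]:
        a = self.positions.loc[
            ~self.positions["allele"].isin((BORDER, BLANK)), "allele"]
        return sorted(a.unique())

    def gene_of(self, allele: str) -> str:
        sub = self.positions[self.positions["allele"] == allele]
        return str(sub["gene"].iloc[0])

    def blocks(self) -> pd.DataFrame:
        """One row per (plate, allele) block: plate, allele, gene, row0, col0."""
        mapped = self.positions[~self.positions["allele"].isin((BORDER, BLANK))]
        g = mapped.groupby(["plate", "allele"], sort=True).agg(
            gene=("gene", "first"), row0=("row", "min"), col0=("col", "min"),
        ).reset_index()
        return g


def read_array_key(path) -> ArrayKey:
    df = pd.read_csv(path, sep="\t", dtype={"plate": str, "allele": str,
                                            "gene": str, "block": str},
                     keep_default_na=False)
    return ArrayKey(df)


def write_array_key(key: ArrayKey, path) -> None:
    key.positions.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Spot grids
# ---------------------------------------------------------------------------

@dataclass
class SpotGrid:
    """Spot-assay intensities: strain x construct x replicate, >=3 reps."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.table, ("strain", "construct", "replicate",
                                      "intensity"), "spot table")
        if (self.table["intensity"] < 0).any():
            raise TableFormatError("spot table: negative intensity")
        counts = self.table.groupby(["strain", "construct"]).size()
        low = counts[counts < 3]
        if len(low):
            s, c = low.index[0]
            raise TableFormatError(
                f"spot table: ({s}, {c}) has {low.iloc[0]} replicates; "
                "at least 3 required"
            )

    def intensities(self, strain: str, construct: str) -> np.ndarray:
        sub = self.table[(self.table["strain"] == strain)
                         & (self.table["construct"] == construct)]
        return sub["intensity"].to_numpy(dtype=float)

    @property
    def strains(self) -> list[str]:
        return sorted(self.table["strain"].unique())


def read_spot_table(path) -> SpotGrid:
    df = pd.read_csv(path, sep="\t", dtype={"strain": str, "construct": str})
    return SpotGrid(df)


def write_spot_table(grid: SpotGrid, path) -> None:
    grid.table.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# OD600 series
# ---------------------------------------------------------------------------

@dataclass
class ODSeries:
    """One growth curve: OD600 vs time in minutes, >=10 points."""

    strain_id: str
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise TableFormatError(
                f"{self.strain_id}: times and od lengths differ")
        if len(self.times) < 10:
            raise TableFormatError(
                f"{self.strain_id}: need >=10 time points, got {len(self.times)}")
        if not np.all(np.diff(self.times) > 0):
            raise TableFormatError(f"{self.strain_id}: times not strictly increasing")
        if np.any(self.od <= 0):
            raise TableFormatError(f"{self.strain_id}: non-positive OD reading")


def read_od_table(path) -> list[ODSeries]:
    df = pd.read_csv(path, dtype={"strain": str})
    _require_columns(df, ("strain", "time_min", "od"), path)
    out = []
    for sid, sub in df.groupby("strain", sort=True):
        sub = sub.sort_values("time_min")
        out.append(ODSeries(str(sid), sub["time_min"].to_numpy(),
                            sub["od"].to_numpy()))
    return out


def write_od_table(series: list[ODSeries], path) -> None:
    frames = [pd.DataFrame({"strain": s.strain_id, "time_min": s.times,
                            "od": s.od}) for s in series]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.12g")


# ---------------------------------------------------------------------------
# Peptide-spectrum matches
# ---------------------------------------------------------------------------

@dataclass
class PSMRecord:
    """One peptide-spectrum match.

    ``peptide`` is the reference (database) sequence; ``mod_sites`` lists
    (1-based position, delta mass in Da) pairs; ``count`` is the spectral
    count behind this record.
    """

    peptide: str
    mod_sites: list[tuple[int, float]]
    psm_q: float
    count: int
    protein_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.psm_q <= 1.0):
            raise TableFormatError(
                f"psm_q {self.psm_q} outside [0,1] for {self.peptide}")
        if self.count < 1:
            raise TableFormatError(f"non-positive count for {self.peptide}")
        for pos, _ in self.mod_sites:
            if not (1 <= pos <= len(self.peptide)):
                raise TableFormatError(
                    f"mod position {pos} outside peptide {self.peptide!r}")

    def sites_matching(self, delta: float, residue: str | None = None,
                       tol: float = MOD_MATCH_TOL) -> list[int]:
        """1-based positions carrying a modification with the given delta."""
        out = []
        for pos, d in self.mod_sites:
            if abs(d - delta) <= tol:
                if residue is None or self.peptide[pos - 1] == residue:
                    out.append(pos)
        return out


def _format_mods(mods: list[tuple[int, float]]) -> str:
    return ";".join(f"{p}:{d:.4f}" for p, d in mods)


def _parse_mods(text) -> list[tuple[int, float]]:
    if text is None or (isinstance(text, float) and math.isnan(text)) or text == "":
        return []
    out = []
    for item in str(text).split(";"):
        item = item.strip()
        if not item:
            continue
        pos_s, delta_s = item.split(":")
        out.append((int(pos_s), float(delta_s)))
    return out


def read_psm_table(
    path,
    catalogue: dict[str, tuple[float, str]] | None = None,
    max_per_mod: int = 2,
) -> tuple[list[PSMRecord], list[dict]]:
    """Read a PSM TSV, enforcing the modification contract.

    Each annotated delta mass must match a catalogued modification within
    +-0.01 Da and sit on that modification's residue; a Ser-for-Pro delta on
    a non-proline residue is a hard error. Records carrying more than
    ``max_per_mod`` copies of one variable modification are rejected with a
    reason (mirroring the search-engine constraint) and returned separately,
    so accepted + rejected always equals the input row count.
    """
    catalogue = catalogue if catalogue is not None else DEFAULT_MOD_CATALOGUE
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "protein": str,
                                            "mods": str})
    _require_columns(df, ("peptide", "protein", "mods", "q", "count"), path)
    accepted: list[PSMRecord] = []
    rejected: list[dict] = []
    for idx, row in df.iterrows():
        peptide = row["peptide"]
        mods = _parse_mods(row["mods"])
        per_mod: dict[str, int] = {}
        for pos, delta in mods:
            name = _match_mod(delta, catalogue)
            if name is None:
                raise TableFormatError(
                    f"{path}: line {idx + 2}: delta {delta} Da not in the "
                    "modification catalogue"
                )
            _, residue = catalogue[name]
            if not (1 <= pos <= len(peptide)) or peptide[pos - 1] != residue:
                raise TableFormatError(
                    f"{path}: line {idx + 2}: modification {name} "
                    f"({delta} Da) at position {pos} of {peptide!r} does not "
                    f"sit on {residue}"
                )
            per_mod[name] = per_mod.get(name, 0) + 1
        over = [n for n, k in per_mod.items() if k > max_per_mod]
        if over:
            rejected.append({
                "line": idx + 2, "peptide": peptide,
                "reason": f">{max_per_mod} copies of {over[0]}",
            })
            continue
        accepted.append(PSMRecord(
            peptide=peptide, mod_sites=mods, psm_q=float(row["q"]),
            count=int(row["count"]), protein_id=str(row["protein"]),
        ))
    return accepted, rejected


def _match_mod(delta: float, catalogue) -> str | None:
    for name, (d, _residue) in catalogue.items():
        if abs(delta - d) <= MOD_MATCH_TOL:
            return name
    return None


def write_psm_table(records: list[PSMRecord], path) -> None:
    pd.DataFrame({
        "peptide": [r.peptide for r in records],
        "protein": [r.protein_id for r in records],
        "mods": [_format_mods(r.mod_sites) for r in records],
        "q": [r.psm_q for r in records],
        "count": [r.count for r in records],
    }).to_csv(path, sep="\t", index=False, float_format="%.12g")
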