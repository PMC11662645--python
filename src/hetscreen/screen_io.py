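"""Reading, validation, correction and writing of screen tables.

All tables are tidy/long: one row per colony observation, keyed by
(screen, medium, plate_id, row, col, bio_rep, tech_rep).  Missing colony
sizes are empty cells and become NaN; an explicit 0 size is kept here and
mapped to missing at the ratio stage (see :mod:`hetscreen.scoring`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hetscreen import MEDIA, SCREENS
from hetscreen.errors import AmbiguityError, FormatError, IntegrityError

COLONY_COLUMNS = [
    "screen",
    "medium",
    "plate_id",
    "row",
    "col",
    "strain_id",
    "gene_name",
    "bio_rep",
    "tech_rep",
    "size",
]

OBSERVATION_KEY = ["screen", "medium", "plate_id", "row", "col", "bio_rep", "tech_rep"]

STRAIN_COLUMNS = ["strain_id", "gene_name", "status", "corrected_name", "exclusion_reason"]

#: 384-format plate bounds
N_ROWS, N_COLS = 16, 24

#: GO/FYPO terms behind the gold-standard heterochromatin-factor list.  The
#: list itself is a plain-text input file (one gene per line); these term IDs
#: document its provenance only.
GOLD_STANDARD_TERMS = ("GO:0000792", "GO:0000781", "GO:0033696", "FYPO:0004604")


@dataclass
class PlateSet:
    """Colony observations plus the strain annotations they reference."""

    observations: pd.DataFrame
    strains: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=STRAIN_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in COLONY_COLUMNS if c not in self.observations.columns]
        if missing:
            raise FormatError(f"observations missing columns: {missing}")

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, PlateSet):
            return NotImplemented
        return self.observations.equals(other.observations)


def _sep_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_colony_table(path: str | Path, delimiter: str | None = None) -> PlateSet:
    """Read a long-format colony-size table into a :class:`PlateSet`.

    Malformed rows (out-of-bounds wells, negative sizes, unknown enum
    values) are dropped with a row-level warning.  Empty ``size`` cells
    become NaN.  Duplicate observation keys raise :class:`IntegrityError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path, delimiter), dtype={"plate_id": str, "strain_id": str})
    missing = [c for c in COLONY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = df[COLONY_COLUMNS].copy()
    df["size"] = pd.to_numeric(df["size"], errors="coerce")

    bad = pd.Series(False, index=df.index)
    bad |= ~df["screen"].isin(SCREENS)
    bad |= ~df["medium"].isin(MEDIA)
    for col, hi in (("row", N_ROWS), ("col", N_COLS)):
        v = pd.to_numeric(df[col], errors="coerce")
        bad |= v.isna() | (v < 1) | (v > hi) | (v != v.round())
    bad |= df["size"].notna() & (df["size"] < 0)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # +2: header + 1-based file lines
        warnings.warn(f"{path}: rejected {int(bad.sum())} malformed row(s) at file line(s) {rows}")
        df = df[~bad].copy()

    for col in ("row", "col", "bio_rep", "tech_rep"):
        df[col] = df[col].astype(int)

    dup = df.duplicated(subset=OBSERVATION_KEY, keep=False)
    if dup.any():
        keys = df.loc[dup, OBSERVATION_KEY].drop_duplicates().to_dict("records")
        raise IntegrityError(f"{path}: duplicate observation key(s): {keys[:5]}")

    strains = (
        df[["strain_id", "gene_name"]]
        .drop_duplicates("strain_id")
        .assign(status="verified", corrected_name="", exclusion_reason="")
        .reset_index(drop=True)
    )
    return PlateSet(observations=df.reset_index(drop=True), strains=strains)


def read_strain_corrections(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a strain-annotation correction table.

    Columns: strain_id, status (verified/corrected/excluded), corrected_name,
    exclusion_reason.  Validates the per-status invariants.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, delimiter), dtype=str).fillna("")
    required = {"strain_id", "status"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: correction table needs columns {sorted(required)}")
    for col in ("corrected_name", "exclusion_reason"):
        if col not in df.columns:
            df[col] = ""
    return validate_corrections(df)


def validate_corrections(df: pd.DataFrame) -> pd.DataFrame:
    both = (df["corrected_name"].str.len() > 0) & (df["exclusion_reason"].str.len() > 0)
    if both.any():
        raise AmbiguityError(
            f"correction rows with both corrected_name and exclusion_reason: "
            f"{df.loc[both, 'strain_id'].tolist()}"
        )
    corr = df["status"] == "corrected"
    if (corr & (df["corrected_name"] == "")).any():
        raise FormatError("status=corrected requires a nonempty corrected_name")
    if (corr & ~df["corrected_name"].str.endswith("*")).any():
        raise FormatError("corrected_name must end with '*'")
    excl = df["status"] == "excluded"
    if (excl & (df["exclusion_reason"] == "")).any():
        raise FormatError("status=excluded requires a nonempty exclusion_reason")
    return df


def apply_strain_corrections(plateset: PlateSet, corrections: pd.DataFrame) -> PlateSet:
    """Apply exclusion/rename corrections to a plateset.

    Excluded strains are removed.  Corrected strains are renamed to
    ``corrected_name`` (which carries a trailing ``*``).  When the corrected
    gene duplicates an uncorrected strain of the same gene, only the
    explicitly confirmed (corrected) copy is kept.  Idempotent.
    """
    corrections = validate_corrections(corrections.fillna(""))
    obs = plateset.observations.copy()
    strains = plateset.strains.copy()

    known = set(obs["strain_id"])
    unknown = sorted(set(corrections["strain_id"]) - known)
    if unknown:
        warnings.warn(f"corrections reference unknown strain_id(s): {unknown}")

    excluded = set(corrections.loc[corrections["status"] == "excluded", "strain_id"])
    renames = dict(
        corrections.loc[corrections["status"] == "corrected", ["strain_id", "corrected_name"]]
        .itertuples(index=False, name=None)
    )

    obs = obs[~obs["strain_id"].isin(excluded)].copy()
    renamed_mask = obs["strain_id"].isin(renames)
    obs.loc[renamed_mask, "gene_name"] = obs.loc[renamed_mask, "strain_id"].map(renames)

    # Drop uncorrected duplicates of a confirmed gene: strain X corrected to
    # "swi6*" displaces the original swi6 strain.
    displaced_genes = {name.rstrip("*") for name in renames.values()}
    dup_mask = obs["gene_name"].isin(displaced_genes) & ~obs["strain_id"].isin(renames)
    obs = obs[~dup_mask].copy()

    strains = strains[strains["strain_id"].isin(set(obs["strain_id"]))].copy()
    renamed_strains = strains["strain_id"].isin(renames)
    strains.loc[renamed_strains, "gene_name"] = strains.loc[renamed_strains, "strain_id"].map(renames)
    strains.loc[renamed_strains, "status"] = "corrected"
    strains.loc[renamed_strains, "corrected_name"] = strains.loc[renamed_strains, "gene_name"]

    return PlateSet(observations=obs.reset_index(drop=True), strains=strains.reset_index(drop=True))


def write_scores(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as TSV with stable column order.

    Reals are written with 17 significant digits so that re-reading
    reproduces them bit-for-bit (well inside the 1e-12 contract); missing
    values are written as empty cells.
    """
    if len(table) == 0:
        raise ValueError("refusing to write a 0-row table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="")
    return path


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_scores`."""
    return pd.read_csv(path, sep="\t")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text one-gene-per-line list (``#`` comments allowed)."""
    genes: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def read_complex_map(path: str | Path, delimiter: str | None = None) -> dict[str, set[str]]:
    """Read a two-column (complex_id, gene) membership table into a dict."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, delimiter), dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: complex map needs two columns (complex_id, gene)")
    cid, gene = df.columns[:2]
    out: dict[str, set[str]] = {}
    for c, g in df[[cid, gene]].itertuples(index=False, name=None):
        out.setdefault(c, set()).add(g)
    return out


def read_xlsx_table(path: str | Path, sheet: str | int = 0) -> pd.DataFrame:
    """Read a supplementary-style score table from an XLSX workbook.

    Used only in replication mode, where the study's processed score tables
    are consumed instead of raw colony sizes.  Requires a header row.
    """
    df = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    if df.empty:
        raise FormatError(f"{path}: sheet {sheet!r} is empty")
    return df


def read_cell_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a per-cell fluorescence CSV (cell_id, sample_id, green, orange, red)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, delimiter))
    required = {"sample_id", "green", "orange", "red"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: cell table missing columns {sorted(missing)}")
    for col in ("green", "orange", "red"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if np.isinf(df[["green", "orange", "red"]].to_numpy()).any():
        raise FormatError(f"{path}: non-finite fluorescence values")
    return df
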