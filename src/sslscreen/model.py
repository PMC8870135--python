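"""Data model and I/O for arrayed siRNA screens.

The screen is a two-arm (query-depleted vs. query-proficient) arrayed RNAi
experiment in 384-well plates. An siRNA library maps oligo identifiers to
target genes; per-well nucleus counts are stored in long (tidy) format, one
record per well per arm per replicate.

Well contents are encoded in a single ``content`` column: a sample well
carries its siRNA identifier, control wells carry one of the reserved labels
``mock``, ``nontargeting``, ``cytotoxic_positive`` or ``empty``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError, ValidationError

#: Row letters of a 384-well plate, top to bottom.
PLATE_ROWS = "ABCDEFGHIJKLMNOP"
#: Number of columns of a 384-well plate.
PLATE_COLS = 24

#: Reserved content labels that are not siRNA identifiers.
CONTROL_CONTENTS = ("mock", "nontargeting", "cytotoxic_positive", "empty")
#: Content labels treated as negative controls by default (pooled).
NEGATIVE_CONTROLS = ("mock", "nontargeting")

ARMS = ("query_proficient", "query_depleted")

MEASUREMENT_COLUMNS = [
    "plate_id",
    "well",
    "content",
    "arm",
    "bio_rep",
    "tech_rep",
    "nuclei_count",
]

_WELL_RE = re.compile(r"^([A-P])(\d{1,2})$")


@dataclass(frozen=True)
class WellAddress:
    """A well position on a named 384-well plate ("A01" .. "P24")."""

    plate_id: str
    row: str
    col: int

    def __post_init__(self) -> None:
        if self.row not in PLATE_ROWS:
            raise FormatError(f"row {self.row!r} outside A-{PLATE_ROWS[-1]}")
        if not 1 <= self.col <= PLATE_COLS:
            raise FormatError(f"column {self.col} outside 1-{PLATE_COLS}")

    @property
    def label(self) -> str:
        return f"{self.row}{self.col:02d}"


def parse_well(well: str) -> tuple[str, int]:
    """Parse a well label like ``"B07"`` into ``("B", 7)``.

    Raises :class:`FormatError` for labels outside the 16x24 grid.
    """
    m = _WELL_RE.match(str(well).strip())
    if m is None:
        raise FormatError(f"malformed well label {well!r}")
    row, col = m.group(1), int(m.group(2))
    if not 1 <= col <= PLATE_COLS:
        raise FormatError(f"well {well!r}: column outside 1-{PLATE_COLS}")
    return row, col


def well_label(row: str, col: int) -> str:
    return f"{row}{col:02d}"


@dataclass
class SiRNALibrary:
    """The arrayed siRNA library: oligo -> target gene, plus control roles.

    Parameters
    ----------
    entries
        DataFrame with columns ``sirna_id`` and ``gene``, one row per oligo.
    controls
        Mapping from control role (``mock``, ``nontargeting``,
        ``cytotoxic_positive``) to the content label used for it in
        measurement tables. Defaults to the identity mapping.
    """

    entries: pd.DataFrame
    controls: dict[str, str] = field(
        default_factory=lambda: {c: c for c in CONTROL_CONTENTS[:3]}
    )

    def __post_init__(self) -> None:
        missing = {"sirna_id", "gene"} - set(self.entries.columns)
        if missing:
            raise FormatError(f"library missing columns: {sorted(missing)}")
        dup = self.entries["sirna_id"][self.entries["sirna_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate sirna_id: {sorted(set(dup))}")
        reserved = set(self.entries["sirna_id"]) & set(CONTROL_CONTENTS)
        if reserved:
            raise ValidationError(
                f"sirna_id collides with control label: {sorted(reserved)}"
            )
        self.entries = self.entries.reset_index(drop=True)

    @property
    def sirna_ids(self) -> list[str]:
        return list(self.entries["sirna_id"])

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.entries["gene"]))

    @property
    def n_genes(self) -> int:
        return self.entries["gene"].nunique()

    def gene_of(self, sirna_id: str) -> str:
        return self._gene_map()[sirna_id]

    def _gene_map(self) -> dict[str, str]:
        return dict(zip(self.entries["sirna_id"], self.entries["gene"]))

    def sirnas_per_gene(self) -> pd.Series:
        return self.entries.groupby("gene")["sirna_id"].count()


@dataclass
class ScreenDesign:
    """Replication structure of the two-arm screen."""

    library: SiRNALibrary
    n_bio_reps: int = 3
    n_tech_reps: int = 2
    arms: tuple[str, str] = ARMS

    def __post_init__(self) -> None:
        if self.n_bio_reps < 1 or self.n_tech_reps < 1:
            raise ValidationError("replicate counts must be >= 1")
        if len(self.arms) != 2:
            raise ValidationError("a screen has exactly two arms")


def content_role(content: str) -> str:
    """Classify a content label as ``sample`` or one of the control roles."""
    return content if content in CONTROL_CONTENTS else "sample"


def load_library(path: str | Path) -> SiRNALibrary:
    """Read an siRNA library from a comma- or tab-delimited text table.

    The table must have columns ``sirna_id`` and ``gene``; an optional
    ``control_role`` column declares control reagents (those rows are taken
    out of the target entries and recorded in ``controls``).
    """
    df = _read_delimited(path)
    if not {"sirna_id", "gene"} <= set(df.columns):
        raise FormatError(
            f"{path}: library table needs columns sirna_id, gene "
            f"(found {list(df.columns)})"
        )
    controls = {c: c for c in CONTROL_CONTENTS[:3]}
    if "control_role" in df.columns:
        is_ctrl = df["control_role"].notna() & (df["control_role"] != "")
        for _, row in df[is_ctrl].iterrows():
            role = str(row["control_role"])
            if role not in CONTROL_CONTENTS[:3]:
                raise ValidationError(f"unknown control role {role!r}")
            controls[role] = str(row["sirna_id"])
        df = df[~is_ctrl]
    return SiRNALibrary(df[["sirna_id", "gene"]].astype(str), controls)


def write_library(library: SiRNALibrary, path: str | Path) -> None:
    library.entries.to_csv(path, sep="\t", index=False)


def load_measurements(
    path: str | Path, design: ScreenDesign | None = None
) -> pd.DataFrame:
    """Read per-well measurements and validate them.

    Returns a DataFrame with columns ``plate_id, well, row, col, content,
    role, arm, bio_rep, tech_rep, nuclei_count``. Counts must be
    nonnegative; wells must parse within the 384-well grid; if a design is
    given, every sample content must be a known sirna_id and
    ``(plate_id, well, arm, bio_rep, tech_rep)`` must be unique.
    """
    df = _read_delimited(path)
    return validate_measurements(df, design)


def validate_measurements(
    df: pd.DataFrame, design: ScreenDesign | None = None
) -> pd.DataFrame:
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"measurement table missing columns: {sorted(missing)}")
    df = df[MEASUREMENT_COLUMNS].copy()
    parsed = [parse_well(w) for w in df["well"]]
    df["row"] = [p[0] for p in parsed]
    df["col"] = [p[1] for p in parsed]
    df["well"] = [well_label(r, c) for r, c in parsed]
    df["nuclei_count"] = pd.to_numeric(df["nuclei_count"], errors="raise")
    if (df["nuclei_count"] < 0).any():
        bad = df.loc[df["nuclei_count"] < 0].iloc[0]
        raise ValidationError(
            f"negative nuclei_count {bad['nuclei_count']} in well "
            f"{bad['plate_id']}:{bad['well']}"
        )
    bad_arm = set(df["arm"]) - set(ARMS)
    if bad_arm:
        raise ValidationError(f"unknown arm labels: {sorted(bad_arm)}")
    for col in ("bio_rep", "tech_rep"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
        if (df[col] < 1).any():
            raise ValidationError(f"{col} must be >= 1")
    df["content"] = df["content"].astype(str)
    df["role"] = df["content"].map(content_role)
    key = ["plate_id", "well", "arm", "bio_rep", "tech_rep"]
    if df.duplicated(key).any():
        dup = df[df.duplicated(key)].iloc[0]
        raise ValidationError(
            f"duplicate record for {tuple(dup[k] for k in key)}"
        )
    if design is not None:
        known = set(design.library.sirna_ids)
        samples = set(df.loc[df["role"] == "sample", "content"])
        unknown = samples - known
        if unknown:
            raise ValidationError(
                f"unknown sirna_id in measurements: {sorted(unknown)[:5]}"
            )
    cols = ["plate_id", "well", "row", "col", "content", "role", "arm",
            "bio_rep", "tech_rep", "nuclei_count"]
    return df[cols].reset_index(drop=True)


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    """Write measurements in the long text format ``load_measurements`` reads."""
    out = df[MEASUREMENT_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False)


def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    """Write the per-gene hit table, tab-delimited.

    Columns: gene, n_sirnas, sirna_ids, epsilons, best_rank_index, rsa_p,
    is_hit. Rows are ordered by ascending rsa_p, ties broken by gene symbol,
    so output is deterministic.
    """
    cols = ["gene", "n_sirnas", "sirna_ids", "epsilons", "best_rank_index",
            "rsa_p", "is_hit"]
    if len(hits) == 0:
        out = pd.DataFrame(columns=cols)
    else:
        out = hits[cols].sort_values(
            ["rsa_p", "gene"], kind="mergesort"
        ).reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-delimited table, sniffing the delimiter."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    return pd.read_csv(path, sep=sep, dtype={"well": str, "plate_id": str})
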