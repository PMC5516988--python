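"""Domain types and delimited-text I/O for morphometric records.

A record is one animal: snout-vent length (SVL, cm), total body mass (g),
wet-fat mass (g), sex, and an optional specimen-handling flag. All lengths
are centimetres and all masses grams; no unit auto-detection is attempted
(silent unit guessing is a classic allometry bug), so conversion is the
caller's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MorphRecord",
    "Stratum",
    "ConfigurationError",
    "ValidationError",
    "read_morph_table",
    "write_morph_table",
    "stratify",
    "records_to_frame",
]

SEX_LABELS = ("female", "male")
HANDLING_LABELS = ("fresh", "frozen", "unknown")

#: Fixed CSV header (comma-separated, UTF-8, "." decimal).
COLUMNS = ("id", "sex", "svl_cm", "mass_g", "fat_g", "handling")
REQUIRED_COLUMNS = COLUMNS[:5]


class ConfigurationError(Exception):
    """Input file or configuration is structurally unusable (e.g. missing column)."""


class ValidationError(ValueError):
    """A data value violates a domain invariant; the message names the offender."""


@dataclass(frozen=True)
class MorphRecord:
    """One animal's morphometric measurements.

    Parameters
    ----------
    id : str
        Free-text specimen label.
    sex : str
        ``"female"`` or ``"male"``.
    svl : float
        Snout-vent length in cm, strictly positive.
    mass : float
        Total body mass in g, strictly positive.
    fat : float
        Wet mass of the dissected coelomic fat bodies in g, strictly
        positive and strictly less than total mass.
    handling : str or None
        Optional specimen-handling flag (``"fresh"``/``"frozen"``/
        ``"unknown"``); ``None`` when not recorded.
    """

    id: str
    sex: str
    svl: float
    mass: float
    fat: float
    handling: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEX_LABELS:
            raise ValidationError(
                f"record {self.id!r}: unknown sex label {self.sex!r} "
                f"(expected one of {SEX_LABELS})"
            )
        for name in ("svl", "mass", "fat"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValidationError(
                    f"record {self.id!r}: {name} must be strictly positive, got {v!r}"
                )
        if not self.fat < self.mass:
            raise ValidationError(
                f"record {self.id!r}: fat ({self.fat} g) must be less than "
                f"total mass ({self.mass} g)"
            )
        if self.handling is not None and self.handling not in HANDLING_LABELS:
            raise ValidationError(
                f"record {self.id!r}: unknown handling label {self.handling!r} "
                f"(expected one of {HANDLING_LABELS} or empty)"
            )


@dataclass(frozen=True)
class Stratum:
    """A homogeneous group of records sharing one stratifying attribute value.

    Regression fits and their confidence intervals need at least three
    points, so ``n >= 3`` is enforced at construction.
    """

    label: str
    records: tuple[MorphRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 3:
            raise ValidationError(
                f"stratum {self.label!r} has n = {len(self.records)} < 3; "
                "regression fits and confidence intervals are undefined"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    def column(self, name: str) -> list[float]:
        """Extract one numeric field (``svl``, ``mass`` or ``fat``) in record order."""
        return [getattr(r, name) for r in self.records]


def records_to_frame(records: Iterable[MorphRecord]) -> pd.DataFrame:
    """Tabulate records as a DataFrame with the canonical column names."""
    rows = [
        (r.id, r.sex, r.svl, r.mass, r.fat, "" if r.handling is None else r.handling)
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(COLUMNS))


def read_morph_table(
    path: str | Path, columns: dict[str, str] | None = None
) -> list[MorphRecord]:
    """Read a morphometric CSV into validated records.

    Parameters
    ----------
    path : path-like
        CSV file with header ``id,sex,svl_cm,mass_g,fat_g[,handling]``.
    columns : dict, optional
        Mapping from canonical column names to the names actually used in
        the file, e.g. ``{"svl_cm": "SVL"}``.

    Returns
    -------
    list of MorphRecord
        One record per data row, in file order.

    Raises
    ------
    ConfigurationError
        If a required column is absent.
    ValidationError
        If any row violates a domain invariant; the message lists the
        offending row numbers (2-based, counting the header as line 1).
    """
    path = Path(path)
    rename = dict(columns or {})
    try:
        df = pd.read_csv(
            path, dtype={rename.get("id", "id"): str}, float_precision="round_trip"
        )
    except FileNotFoundError:
        raise
    df = df.rename(columns={v: k for k, v in rename.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    has_handling = "handling" in df.columns

    records: list[MorphRecord] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        raw = dict(zip(df.columns, row))
        handling = raw.get("handling") if has_handling else None
        if handling is not None and (pd.isna(handling) or handling == ""):
            handling = None
        try:
            records.append(
                MorphRecord(
                    id=str(raw["id"]),
                    sex=str(raw["sex"]),
                    svl=float(raw["svl_cm"]),
                    mass=float(raw["mass_g"]),
                    fat=float(raw["fat_g"]),
                    handling=handling,
                )
            )
        except (ValidationError, TypeError, ValueError) as exc:
            problems.append(f"line {line_no}: {exc}")
    if problems:
        raise ValidationError(
            f"{path}: {len(problems)} malformed row(s):\n  " + "\n  ".join(problems)
        )
    return records


def write_morph_table(records: Sequence[MorphRecord], path: str | Path) -> Path:
    """Write records as CSV with the fixed header, numeric fields at full precision.

    An empty record list yields a header-only file. Round-trips losslessly
    with :func:`read_morph_table`.
    """
    path = Path(path)
    df = records_to_frame(records)
    # shortest-round-trip reprs so read_morph_table recovers values exactly
    for col in ("svl_cm", "mass_g", "fat_g"):
        df[col] = df[col].map(lambda v: repr(float(v)))
    df.to_csv(path, index=False)
    return path


def stratify(records: Sequence[MorphRecord], key: str = "sex") -> list[Stratum]:
    """Partition records by ``sex`` or ``handling``.

    Strata appear in order of first appearance of each label; within-stratum
    record order is preserved. When stratifying by ``handling``, records
    with an unrecorded or ``"unknown"`` flag are excluded (the flag is
    optional in the data model).

    Raises
    ------
    ValidationError
        If ``key`` is not a stratifiable attribute, or any resulting
        stratum has fewer than 3 records.
    """
    if key not in ("sex", "handling"):
        raise ValidationError(f"cannot stratify by {key!r}; use 'sex' or 'handling'")
    groups: dict[str, list[MorphRecord]] = {}
    for r in records:
        value = getattr(r, key)
        if key == "handling" and (value is None or value == "unknown"):
            continue
        groups.setdefault(value, []).append(r)
    if not groups:
        raise ValidationError(f"no records with a usable {key!r} value")
    return [Stratum(label, tuple(recs)) for label, recs in groups.items()]
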