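"""Fatty-acid profile data model.

Fatty acids are identified by the shorthand ``C<carbons>:<double bonds>``
with an optional omega suffix (``n-3``, ``n-6``, ``n-9``), e.g. ``C18:1`` or
``C20:3 n-6``.  A profile is a compositional vector of weight-% of total
fatty acids for one strain in one medium; rows are expected to sum to 100
within a configurable tolerance.  Cells reported as "n.d." (not detected)
are treated as exactly zero, not as missing values, so that downstream
weighted sums are well defined.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd

__all__ = [
    "FattyAcid",
    "FAProfile",
    "UnsatClass",
    "FAParseError",
    "FAValidationError",
    "parse_fa_label",
    "classify",
    "group_totals",
    "normalize",
    "load_profile",
    "load_profiles",
    "profiles_to_frame",
]

#: sentinel used in composition tables for acids below the detection limit
ND_SENTINEL = "n.d."

#: default tolerance (percentage points) on the reported profile sum
DEFAULT_SUM_TOL = 0.5

_LABEL_RE = re.compile(r"^C(\d+):(\d+)(?:\s+n-(\d+))?$")


class FAParseError(ValueError):
    """A fatty-acid label could not be parsed."""


class FAValidationError(ValueError):
    """A fatty acid or profile violates a structural invariant."""


class UnsatClass(Enum):
    """Unsaturation class, an exhaustive partition by double-bond count."""

    SFA = 0      # saturated
    MUFA = 1     # monounsaturated
    DUFA = 2     # di-unsaturated
    TUFA = 3     # tri-unsaturated
    PUFA_4PLUS = 4  # four or more double bonds


@dataclass(frozen=True, order=True)
class FattyAcid:
    """One fatty acid identified by chain length, unsaturation and omega class.

    Equality and ordering are by ``(carbons, double_bonds, omega_class)``;
    the canonical string form round-trips through :func:`parse_fa_label`.
    """

    carbons: int
    double_bonds: int
    omega_class: int | None = None

    def __post_init__(self) -> None:
        if self.carbons < 4:
            raise FAValidationError(
                f"carbon count must be >= 4, got {self.carbons}"
            )
        if self.double_bonds < 0:
            raise FAValidationError(
                f"double-bond count must be >= 0, got {self.double_bonds}"
            )
        if self.double_bonds > self.carbons / 2:
            raise FAValidationError(
                f"C{self.carbons}:{self.double_bonds}: {self.double_bonds} "
                f"double bonds exceed carbons/2 = {self.carbons / 2:g}"
            )
        if self.omega_class is not None and self.omega_class not in (3, 6, 9):
            raise FAValidationError(
                f"omega class must be 3, 6 or 9, got {self.omega_class}"
            )

    @property
    def label(self) -> str:
        """Canonical label, e.g. ``"C18:3 n-3"``."""
        base = f"C{self.carbons}:{self.double_bonds}"
        if self.omega_class is not None:
            base += f" n-{self.omega_class}"
        return base

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_fa_label(label: str) -> FattyAcid:
    """Parse a shorthand fatty-acid label into a :class:`FattyAcid`.

    Parameters
    ----------
    label:
        A string of the form ``C<int>:<int>``, optionally followed by
        whitespace and ``n-<int>`` (the omega class).

    Raises
    ------
    FAParseError
        If the label does not match the shorthand grammar.
    FAValidationError
        If the parsed numbers are chemically impossible (e.g. more double
        bonds than carbons/2).
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise FAParseError(f"malformed fatty-acid label: {label!r}")
    carbons, double_bonds = int(m.group(1)), int(m.group(2))
    omega = int(m.group(3)) if m.group(3) is not None else None
    return FattyAcid(carbons, double_bonds, omega)


def classify(fa: FattyAcid) -> UnsatClass:
    """Classify a fatty acid by its double-bond count (0/1/2/3/>=4)."""
    if fa.double_bonds >= 4:
        return UnsatClass.PUFA_4PLUS
    return UnsatClass(fa.double_bonds)


@dataclass
class FAProfile:
    """A compositional fatty-acid profile (weight-% of total fatty acids).

    Attributes
    ----------
    entries:
        Mapping of :class:`FattyAcid` to weight-%.  Acids reported as
        "n.d." are absent (equivalent to 0 in every sum).
    strain_id, medium_id:
        Free-text provenance of the row.
    """

    entries: dict[FattyAcid, float] = field(default_factory=dict)
    strain_id: str = ""
    medium_id: str = ""

    def __post_init__(self) -> None:
        for fa, pct in self.entries.items():
            if pct < 0:
                raise FAValidationError(
                    f"{self.strain_id or '<profile>'}: negative weight-% "
                    f"{pct} for {fa.label}"
                )

    def total(self) -> float:
        """Sum of all weight-% entries."""
        return float(sum(self.entries.values()))

    def validate_sum(self, tol: float = DEFAULT_SUM_TOL, strict: bool = False) -> bool:
        """Check the reported sum is within ``tol`` of 100.

        Returns True when within tolerance.  Outside tolerance a warning is
        emitted, or :class:`FAValidationError` raised when ``strict``.
        """
        ok = abs(self.total() - 100.0) <= tol
        if not ok:
            msg = (
                f"profile {self.strain_id!r}/{self.medium_id!r} sums to "
                f"{self.total():.4f}, outside 100 +/- {tol}"
            )
            if strict:
                raise FAValidationError(msg)
            warnings.warn(msg, stacklevel=2)
        return ok

    def normalize(self) -> "FAProfile":
        """Rescale entries so they sum to exactly 100 (proportions kept)."""
        s = self.total()
        if s <= 0:
            raise FAValidationError(
                f"cannot normalize profile {self.strain_id!r}: sum is {s}"
            )
        return FAProfile(
            entries={fa: pct * 100.0 / s for fa, pct in self.entries.items()},
            strain_id=self.strain_id,
            medium_id=self.medium_id,
        )

    def group_totals(self) -> dict[UnsatClass, float]:
        """Total weight-% per unsaturation class.

        The five class totals partition the profile sum exactly.
        """
        totals = {cls: 0.0 for cls in UnsatClass}
        for fa, pct in self.entries.items():
            totals[classify(fa)] += pct
        return totals

    def get(self, label: str) -> float:
        """Weight-% for a label ("n.d."/absent acids return 0)."""
        return self.entries.get(parse_fa_label(label), 0.0)


# module-level aliases mirroring the functional surface
def group_totals(profile: FAProfile) -> dict[UnsatClass, float]:
    """Total weight-% per unsaturation class; partitions the profile sum."""
    return profile.group_totals()


def normalize(profile: FAProfile) -> FAProfile:
    """Return a copy of ``profile`` rescaled to sum exactly 100."""
    return profile.normalize()


def _coerce_cell(value, decimal: str = ".") -> float | None:
    """Numeric cell -> float; the "n.d." sentinel (or blank) -> None."""
    if value is None:
        return None
    if isinstance(value, float) and pd.isna(value):
        return None
    if isinstance(value, str):
        text = value.strip()
        if text == "" or text.lower() == ND_SENTINEL:
            return None
        if decimal != ".":
            text = text.replace(decimal, ".")
        return float(text)
    return float(value)


def load_profile(
    record: Mapping[str, object],
    strain_id: str = "",
    medium_id: str = "",
    decimal: str = ".",
    tol: float = DEFAULT_SUM_TOL,
    strict: bool = False,
) -> FAProfile:
    """Build a profile from one record of label -> percentage cells.

    Cells holding the "n.d." sentinel become absent entries.  The profile's
    sum invariant is checked (warning, or error in strict mode); an
    all-"n.d." record is an error in strict mode.
    """
    entries: dict[FattyAcid, float] = {}
    for label, cell in record.items():
        pct = _coerce_cell(cell, decimal=decimal)
        if pct is None:
            continue
        entries[parse_fa_label(str(label))] = pct
    prof = FAProfile(entries=entries, strain_id=strain_id, medium_id=medium_id)
    if not entries:
        if strict:
            raise FAValidationError(
                f"profile {strain_id!r}/{medium_id!r} has no detected acids"
            )
        return prof
    prof.validate_sum(tol=tol, strict=strict)
    return prof


def load_profiles(
    source: Union[str, Path, io.IOBase],
    decimal: str = ".",
    sep: str = ",",
    tol: float = DEFAULT_SUM_TOL,
    strict: bool = False,
) -> list[FAProfile]:
    """Read a wide composition table (one row per strain x medium).

    The table must have ``strain`` and (optionally) ``medium`` columns; every
    other column header is parsed as a fatty-acid label.  Use
    ``decimal=","`` for comma-decimal exports.
    """
    df = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    if "strain" not in df.columns:
        raise FAValidationError("composition table must have a 'strain' column")
    meta_cols = {"strain", "medium"}
    fa_cols = [c for c in df.columns if c not in meta_cols]
    profiles = []
    for _, row in df.iterrows():
        record = {c: row[c] for c in fa_cols}
        profiles.append(
            load_profile(
                record,
                strain_id=str(row["strain"]),
                medium_id=str(row.get("medium", "")),
                decimal=decimal,
                tol=tol,
                strict=strict,
            )
        )
    return profiles


def profiles_to_frame(profiles: Iterable[FAProfile]) -> pd.DataFrame:
    """Tidy wide DataFrame (strain, medium, one column per acid label)."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {"strain": p.strain_id, "medium": p.medium_id}
        for fa, pct in sorted(p.entries.items()):
            row[fa.label] = pct
        rows.append(row)
    return pd.DataFrame(rows)
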