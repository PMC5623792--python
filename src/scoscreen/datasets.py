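"""Packaged reference fixtures: published composition, endpoint and RFLP tables.

All loaders return the package's own in-memory types so that the shipped
tables flow through exactly the same code paths as user data.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .biodiesel_props import CetaneTable
from .culture_kinetics import load_table4_wide
from .fa_core import FAProfile, load_profiles
from .rflp_typing import DigestPattern, DnaSequence, load_pattern_db, read_fasta

__all__ = [
    "fixture_path",
    "load_fatty_acid_profiles",
    "load_culture_endpoints",
    "load_its_sequences",
    "load_reference_patterns",
    "default_cetane_table",
]


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    path = resources.files("scoscreen.data").joinpath(name)
    return Path(str(path))


def load_fatty_acid_profiles(strict: bool = True) -> list[FAProfile]:
    """The published YPGlc fatty-acid composition table (7 strains)."""
    return load_profiles(fixture_path("table5_fatty_acids.csv"), strict=strict)


def load_culture_endpoints() -> pd.DataFrame:
    """The published culture endpoint table (wide layout, 14 rows)."""
    return load_table4_wide(fixture_path("table4_culture.csv"))


def load_its_sequences() -> list[DnaSequence]:
    """Partial ITS amplicon sequences of the seven isolates."""
    return read_fasta(fixture_path("table1_its.fasta"))


def load_reference_patterns() -> list[DigestPattern]:
    """Gel-derived amplicon/fragment reference patterns (7 strains)."""
    return load_pattern_db(fixture_path("table2_patterns.json"))


def default_cetane_table() -> CetaneTable:
    """The packaged correlation-derived per-ester cetane table."""
    return CetaneTable.default()
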