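"""Biodiesel fuel-property panel predicted from a fatty-acid profile.

Given a FAME composition in weight-%, the panel comprises:

* **UD** — unsaturation degree, ``(1*%MU + 2*%DU + 3*%TU) / 100`` over the
  mono-, di- and tri-unsaturated weight fractions.  Acids with four or more
  double bonds contribute nothing: the defining formula has no higher term.
* **LC** — mean chain length, the weight-%-weighted mean carbon number,
  ``sum(nC_n * c_n) / 100``.
* **CN** — mixture cetane number, ``sum(X_ME * CN_ME) / 100`` with per-ester
  cetane numbers from a versioned, overridable lookup table.
* **LCV** — low calorific value in kJ/kg,
  ``29385.4 + 486.866*LC - 387.766*UD``.
* **viscosity** — kinematic viscosity in mm^2/s, a quadratic in (LC, UD):
  ``-1.8327 + 0.209794*LC + 0.738911*UD + 0.0166791*LC^2
  - 0.16336*LC*UD + 0.335547*UD^2``.
* **FP** — flash point in degC, from a pluggable model (no canonical
  closed form ships with the panel; see :data:`FP_MODELS`).

LCV and viscosity must be evaluated from the *unrounded* LC and UD of the
same profile; rounding the intermediates to 2 dp visibly shifts the results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Callable, Mapping

from .fa_core import FAProfile, FattyAcid, UnsatClass, parse_fa_label

__all__ = [
    "BiodieselProperties",
    "CetaneTable",
    "CetaneLookupError",
    "unsaturation_degree",
    "chain_length",
    "cetane_number",
    "low_caloric_value",
    "kinematic_viscosity",
    "flash_point",
    "predict_all",
    "round2",
    "FP_MODELS",
    "EN14214_MIN_CN",
    "ASTM_D6751_MIN_CN",
]

# cetane-number floors of the two biodiesel standards, kept as annotations
EN14214_MIN_CN = 54.0
ASTM_D6751_MIN_CN = 47.0

_DATA_DIR = Path(__file__).parent / "data"


class CetaneLookupError(KeyError):
    """A profile acid has no per-ester cetane (or flash-point) entry."""


def round2(x: float) -> float:
    """Round half-to-even at 2 decimal places (report formatting)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), ROUND_HALF_EVEN))


@dataclass(frozen=True)
class CetaneTable:
    """Per-methyl-ester cetane numbers, tagged with a version string."""

    values: Mapping[FattyAcid, float]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        for fa, cn in self.values.items():
            if cn <= 0:
                raise ValueError(f"CN_ME for {fa.label} must be > 0, got {cn}")

    def lookup(self, fa: FattyAcid) -> float:
        try:
            return self.values[fa]
        except KeyError:
            raise CetaneLookupError(
                f"no cetane number for {fa.label} in table {self.version!r}"
            ) from None

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float], version: str = "user") -> "CetaneTable":
        return cls(
            values={parse_fa_label(k): float(v) for k, v in mapping.items()},
            version=version,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CetaneTable":
        doc = json.loads(Path(path).read_text())
        return cls.from_mapping(
            doc["cetane_numbers"], version=doc.get("version", str(path))
        )

    @classmethod
    def default(cls) -> "CetaneTable":
        """The packaged correlation-derived table (see its JSON header)."""
        return cls.from_json(_DATA_DIR / "cetane_numbers.json")


@dataclass(frozen=True)
class BiodieselProperties:
    """Predicted fuel-property bundle for one profile."""

    UD: float
    LC: float
    CN: float
    LCV: float
    viscosity: float
    FP: float | None = None
    cetane_table_version: str = "unversioned"
    fp_model: str = "none"

    @property
    def meets_en14214_cn(self) -> bool:
        return self.CN >= EN14214_MIN_CN

    @property
    def meets_astm_d6751_cn(self) -> bool:
        return self.CN >= ASTM_D6751_MIN_CN

    def report(self, decimal: str = ".") -> dict[str, str]:
        """2-dp rendering of the panel; ``decimal=","`` mirrors locale tables."""
        def fmt(x: float | None) -> str:
            if x is None:
                return ""
            s = f"{round2(x):.2f}"
            return s.replace(".", decimal) if decimal != "." else s

        return {
            "UD": fmt(self.UD),
            "CN": fmt(self.CN),
            "LC": fmt(self.LC),
            "LCV_kJ_per_kg": fmt(self.LCV),
            "FP_C": fmt(self.FP),
            "viscosity_mm2_s": fmt(self.viscosity),
        }


def unsaturation_degree(profile: FAProfile) -> float:
    """UD = (1*%MU + 2*%DU + 3*%TU)/100; >=4 double bonds contribute 0.

    Profiles not summing to 100 are normalized first, so UD depends only on
    relative composition.
    """
    if profile.entries and abs(profile.total() - 100.0) > 1e-9:
        profile = profile.normalize()
    g = profile.group_totals()
    return (
        1.0 * g[UnsatClass.MUFA]
        + 2.0 * g[UnsatClass.DUFA]
        + 3.0 * g[UnsatClass.TUFA]
    ) / 100.0


def chain_length(profile: FAProfile) -> float:
    """Weight-%-weighted mean carbon count.

    Profiles whose reported sum is not 100 are normalized first, so LC is
    invariant under uniform rescaling of the composition.
    """
    if not profile.entries:
        raise ValueError("chain length of an empty profile is undefined")
    total = profile.total()
    if abs(total - 100.0) > 1e-9:
        profile = profile.normalize()
    return sum(fa.carbons * pct for fa, pct in profile.entries.items()) / 100.0


def cetane_number(profile: FAProfile, table: CetaneTable) -> float:
    """Mixture CN = sum(X_ME * CN_ME)/100 over the profile's acids."""
    return sum(
        pct * table.lookup(fa) for fa, pct in profile.entries.items()
    ) / 100.0


def low_caloric_value(LC: float, UD: float) -> float:
    """LCV in kJ/kg from unrounded LC and UD."""
    return 29385.4 + 486.866 * LC - 387.766 * UD


def kinematic_viscosity(LC: float, UD: float) -> float:
    """Kinematic viscosity in mm^2/s from unrounded LC and UD."""
    return (
        -1.8327
        + 0.209794 * LC
        + 0.738911 * UD
        + 0.0166791 * LC**2
        - 0.16336 * LC * UD
        + 0.335547 * UD**2
    )


# ---------------------------------------------------------------------------
# flash point: pluggable models
# ---------------------------------------------------------------------------

def _load_fp_table() -> tuple[dict[FattyAcid, float], str]:
    doc = json.loads((_DATA_DIR / "fame_flash_points_synthetic.json").read_text())
    return (
        {parse_fa_label(k): float(v) for k, v in doc["flash_points"].items()},
        doc.get("version", "unversioned"),
    )


def _fp_none(profile: FAProfile, fp_table: Mapping[FattyAcid, float] | None) -> None:
    return None


def _fp_per_ester_mixture(
    profile: FAProfile, fp_table: Mapping[FattyAcid, float] | None
) -> float:
    """Weight-fraction-weighted mean of per-ester flash points.

    Uses the packaged lookup (synthetic estimates; see the JSON header)
    unless an explicit table is supplied.
    """
    if fp_table is None:
        fp_table, _ = _load_fp_table()
    total = profile.total()
    if total <= 0:
        raise ValueError("flash point of an empty profile is undefined")
    acc = 0.0
    for fa, pct in profile.entries.items():
        try:
            acc += pct * fp_table[fa]
        except KeyError:
            raise CetaneLookupError(
                f"no flash point for {fa.label} in the FP lookup"
            ) from None
    return acc / total


FP_MODELS: dict[str, Callable] = {
    "none": _fp_none,
    "per_ester_mixture": _fp_per_ester_mixture,
}

DEFAULT_FP_MODEL = "per_ester_mixture"


def flash_point(
    profile: FAProfile,
    model: str = DEFAULT_FP_MODEL,
    fp_table: Mapping[FattyAcid, float] | None = None,
) -> float | None:
    """Flash point (degC) under a registered model; ``"none"`` -> None."""
    try:
        fn = FP_MODELS[model]
    except KeyError:
        raise ValueError(
            f"unregistered flash-point model {model!r}; "
            f"known: {sorted(FP_MODELS)}"
        ) from None
    return fn(profile, fp_table)


def predict_all(
    profile: FAProfile,
    cetane_table: CetaneTable | None = None,
    fp_model: str = DEFAULT_FP_MODEL,
    fp_table: Mapping[FattyAcid, float] | None = None,
) -> BiodieselProperties:
    """Full property panel; every component uses the same unrounded LC/UD."""
    if not profile.entries:
        raise ValueError("cannot predict properties of an empty profile")
    table = cetane_table if cetane_table is not None else CetaneTable.default()
    ud = unsaturation_degree(profile)
    lc = chain_length(profile)
    return BiodieselProperties(
        UD=ud,
        LC=lc,
        CN=cetane_number(profile, table),
        LCV=low_caloric_value(lc, ud),
        viscosity=kinematic_viscosity(lc, ud),
        FP=flash_point(profile, model=fp_model, fp_table=fp_table),
        cetane_table_version=table.version,
        fp_model=fp_model,
    )
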