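"""Growth-rate, productivity and lipid-content arithmetic for batch cultures.

The specific growth rate over a log-phase window is the two-point slope of
ln(OD): ``mu = (ln OD_f - ln OD_i) / (t_f - t_i)``, in 1/h.  Because the
growth-rate symbol collides with the kinematic-viscosity symbol in fuel
work, this module consistently calls it ``mu_growth``.

Endpoint bookkeeping: volumetric productivity Q = final concentration /
culture duration (g/L/h), and lipid content as percent of cell dry weight,
100 * lipids / biomass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "ODSeries",
    "CultureRecord",
    "ElementalComposition",
    "LogPhaseNotFound",
    "specific_growth_rate",
    "detect_log_phase",
    "generation_time",
    "volumetric_productivity",
    "lipid_content_pct",
    "cnp_ratio",
    "read_culture_records",
    "read_od_series",
    "load_table4_wide",
    "kinetics_table",
]

#: nominal plate-reader sampling interval, hours (one reading per 15 min)
DEFAULT_SAMPLING_H = 0.25


class LogPhaseNotFound(RuntimeError):
    """No window of the series satisfies the log-linearity criteria."""


@dataclass(frozen=True)
class ODSeries:
    """An optical-density time series (times in hours)."""

    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", y)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if len(t) < 2:
            raise ValueError("an OD series needs at least 2 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t[0] < 0:
            raise ValueError("times must be non-negative")
        if np.any(y < 0):
            raise ValueError("OD readings must be >= 0")

    def __len__(self) -> int:
        return len(self.times)

    def od_at(self, t: float) -> float:
        """OD at time ``t``, linearly interpolated between samples."""
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(f"time {t} h outside series range")
        return float(np.interp(t, self.times, self.od))


@dataclass(frozen=True)
class CultureRecord:
    """Endpoint record of one culture: biomass, optional lipids, duration."""

    strain_id: str
    medium_id: str
    duration_h: float
    biomass_g_per_l: float
    lipids_g_per_l: float | None = None

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("culture duration must be > 0")
        if self.biomass_g_per_l < 0:
            raise ValueError("biomass must be >= 0")
        if self.lipids_g_per_l is not None:
            if not 0 <= self.lipids_g_per_l <= self.biomass_g_per_l:
                raise ValueError(
                    f"{self.strain_id}: lipids {self.lipids_g_per_l} g/L must "
                    f"lie in [0, biomass {self.biomass_g_per_l} g/L]"
                )


@dataclass(frozen=True)
class ElementalComposition:
    """Elemental masses of a medium, g/L per element symbol."""

    masses: dict[str, float]

    def __post_init__(self) -> None:
        for el, m in self.masses.items():
            if m < 0:
                raise ValueError(f"negative mass for element {el}")

    def __getitem__(self, el: str) -> float:
        return self.masses[el]


def specific_growth_rate(
    series: ODSeries, window: tuple[float, float]
) -> float:
    """Two-point specific growth rate over ``window = (t_i, t_f)``, 1/h.

    Window endpoints may fall between samples (linear interpolation of OD).
    """
    t_i, t_f = window
    if t_f <= t_i:
        raise ValueError(f"window must have t_f > t_i, got {window}")
    od_i, od_f = series.od_at(t_i), series.od_at(t_f)
    if od_i <= 0 or od_f <= 0:
        raise ValueError("OD must be > 0 at both window endpoints")
    return (math.log(od_f) - math.log(od_i)) / (t_f - t_i)


def _linfit_r2(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R^2 of y on t (R^2 = 0 when y is constant)."""
    t = t - t.mean()
    y_c = y - y.mean()
    sst = float(y_c @ y_c)
    if sst == 0.0:
        return 0.0, 0.0
    slope = float((t @ y_c) / (t @ t))
    sse = float(((y_c - slope * t) ** 2).sum())
    return slope, 1.0 - sse / sst


def detect_log_phase(
    series: ODSeries,
    min_points: int = 5,
    r2_min: float = 0.98,
    quota: float = 0.95,
    min_slope: float = 1e-6,
) -> tuple[float, float]:
    """Locate the exponential phase by a max-slope sliding-window fit.

    Fits ln(OD) vs t by least squares over every window of ``min_points``
    consecutive samples, keeps the windows with positive slope and
    R^2 >= ``r2_min``, anchors on the steepest one (earliest on exact ties),
    and merges the contiguous run of qualifying windows whose slope is at
    least ``quota`` times the anchor slope.  Returns the merged window's
    time bounds.  Deterministic for fixed parameters; windows straddling the
    lag or plateau corner fall below the quota, so on a clean curve the
    bounds land within one sampling interval of the true phase.

    Raises
    ------
    LogPhaseNotFound
        When no window qualifies (e.g. a flat series).
    """
    if len(series) < max(min_points, 6):
        raise ValueError("need at least 6 points to detect a log phase")
    if np.any(series.od <= 0):
        raise ValueError("log-phase detection requires strictly positive OD")
    t = series.times
    ln_od = np.log(series.od)
    n = len(t)
    w = min_points
    fits = [
        _linfit_r2(t[i : i + w], ln_od[i : i + w]) for i in range(n - w + 1)
    ]
    qualifying = {
        i for i, (slope, r2) in enumerate(fits)
        if slope > min_slope and r2 >= r2_min
    }
    if not qualifying:
        raise LogPhaseNotFound(
            f"no window of {min_points} points reaches R^2 >= {r2_min} "
            f"with positive slope (series of {n} points, "
            f"OD range {series.od.min():.3g}-{series.od.max():.3g})"
        )
    best_slope = max(fits[i][0] for i in qualifying)
    anchor = min(
        i for i in qualifying if fits[i][0] >= best_slope * (1.0 - 1e-12)
    )
    keep = {
        i for i in qualifying if fits[i][0] >= quota * best_slope
    }
    left = anchor
    while left - 1 in keep:
        left -= 1
    right = anchor
    while right + 1 in keep:
        right += 1
    return float(t[left]), float(t[right + w - 1])


def generation_time(mu_growth: float) -> float:
    """Population doubling time ln(2)/mu, hours."""
    if mu_growth <= 0:
        raise ValueError(f"generation time requires mu > 0, got {mu_growth}")
    return math.log(2.0) / mu_growth


def volumetric_productivity(final_conc: float, duration_h: float) -> float:
    """Q = final concentration / duration, g/L/h (unrounded).

    Reporting paths round to 3 dp to match endpoint-table conventions.
    """
    if duration_h <= 0:
        raise ValueError("duration must be > 0")
    if final_conc < 0:
        raise ValueError("concentration must be >= 0")
    return final_conc / duration_h


def lipid_content_pct(lipids_g_per_l: float, biomass_g_per_l: float) -> float:
    """Lipid content as % of cell dry weight: 100 * lipids / biomass."""
    if biomass_g_per_l <= 0:
        raise ValueError("biomass must be > 0")
    if not 0 <= lipids_g_per_l <= biomass_g_per_l:
        raise ValueError("lipids must lie in [0, biomass]")
    return 100.0 * lipids_g_per_l / biomass_g_per_l


def _sig(x: float, figures: int = 3) -> str:
    """Format with <= ``figures`` significant digits, trailing zeros stripped."""
    if x == 0:
        return "0"
    s = f"{x:.{figures}g}"
    if "e" in s or "E" in s:  # fall back for extreme magnitudes
        s = f"{x:f}"
    if "." in s:
        s = s.rstrip("0").rstrip(".")
    return s


def cnp_ratio(comp: ElementalComposition) -> tuple[tuple[float, float, float], str]:
    """C:N:P ratio normalized to N = 1, plus its conventional string form.

    Returns ``((C/N, 1.0, P/N), "C/N : 1 : P/N")`` formatted to 3
    significant figures (e.g. "12.3 : 1 : 0.204").
    """
    c = comp.masses.get("C", 0.0)
    n = comp.masses.get("N", 0.0)
    p = comp.masses.get("P", 0.0)
    if n <= 0:
        raise ValueError("C:N:P ratio requires N > 0")
    triple = (c / n, 1.0, p / n)
    return triple, f"{_sig(triple[0])} : 1 : {_sig(triple[2])}"


# ---------------------------------------------------------------------------
# readers and table-level helpers
# ---------------------------------------------------------------------------

def read_culture_records(source: str | Path) -> list[CultureRecord]:
    """Read a long endpoint CSV: strain, medium, biomass, lipids, duration."""
    df = pd.read_csv(source)
    required = {"strain", "medium", "biomass", "duration"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"endpoint table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        lipids = row.get("lipids")
        records.append(
            CultureRecord(
                strain_id=str(row["strain"]),
                medium_id=str(row["medium"]),
                duration_h=float(row["duration"]),
                biomass_g_per_l=float(row["biomass"]),
                lipids_g_per_l=None if pd.isna(lipids) else float(lipids),
            )
        )
    return records


def read_od_series(source: str | Path) -> dict[str, ODSeries]:
    """Read a long OD CSV (well, time_h, od) into one series per well."""
    df = pd.read_csv(source)
    required = {"well", "time_h", "od"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"OD table missing columns: {sorted(missing)}")
    out = {}
    for well, grp in df.groupby("well", sort=False):
        grp = grp.sort_values("time_h")
        out[str(well)] = ODSeries(
            times=grp["time_h"].to_numpy(float), od=grp["od"].to_numpy(float)
        )
    return out


def round_dp(x: float, dp: int) -> float:
    """Round half-to-even at ``dp`` decimals on the decimal value of ``x``."""
    q = Decimal(1).scaleb(-dp)
    return float(Decimal(repr(x)).quantize(q, ROUND_HALF_EVEN))


def _round_quotient(num: float, den: float, dp: int) -> float:
    """Half-even rounding of num/den evaluated in decimal arithmetic.

    Avoids float artefacts on exactly-representable decimal quotients
    (e.g. 2.16/96 = 0.0225 must round to 0.022, not 0.023).
    """
    q = Decimal(1).scaleb(-dp)
    quotient = Decimal(repr(num)) / Decimal(repr(den))
    return float(quotient.quantize(q, ROUND_HALF_EVEN))


def _round_pct(num: float, den: float, dp: int) -> float:
    q = Decimal(1).scaleb(-dp)
    pct = Decimal(100) * Decimal(repr(num)) / Decimal(repr(den))
    return float(pct.quantize(q, ROUND_HALF_EVEN))


CARBON_SOURCES = ("glc", "lac", "gly")


def load_table4_wide(source: str | Path) -> pd.DataFrame:
    """Read an endpoint table in the printed wide layout.

    One row per strain x medium family with per-carbon-source biomass and
    lipid columns (``biomass_glc`` ... ``lipids_gly``) and ``duration_h``.
    """
    df = pd.read_csv(source)
    needed = {"strain", "medium_family", "duration_h"} | {
        f"{m}_{c}" for m in ("biomass", "lipids") for c in CARBON_SOURCES
    }
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"wide endpoint table missing columns: {sorted(missing)}")
    return df


def kinetics_table(wide: pd.DataFrame) -> pd.DataFrame:
    """Q_x, Q_L and %CDW per carbon source from a wide endpoint table.

    Output keeps one row per strain x medium family, with productivities at
    3 dp and lipid content at 1 dp, mirroring endpoint-table conventions.
    Rows with lipids > biomass raise (they violate mass balance).
    """
    out = wide[["strain", "medium_family"]].copy()
    for c in CARBON_SOURCES:
        dur = wide["duration_h"].astype(float)
        x = wide[f"biomass_{c}"].astype(float)
        l = wide[f"lipids_{c}"].astype(float)
        if (l > x).any():
            bad = wide.loc[l > x, "strain"].tolist()
            raise ValueError(f"lipids exceed biomass for {bad} ({c})")
        for v, d in zip(x, dur):
            volumetric_productivity(v, d)  # validate domain
        out[f"Qx_{c}"] = [_round_quotient(v, d, 3) for v, d in zip(x, dur)]
        out[f"QL_{c}"] = [_round_quotient(v, d, 3) for v, d in zip(l, dur)]
        for lv, xv in zip(l, x):
            lipid_content_pct(lv, xv)  # validate domain
        out[f"pct_cdw_{c}"] = [_round_pct(lv, xv, 1) for lv, xv in zip(l, x)]
    return out
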