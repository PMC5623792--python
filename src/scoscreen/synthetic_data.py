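"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators, all pure functions of ``(seed, parameters)``:

* compositional fatty-acid profiles — Dirichlet resampling around a
  template, because weight-% vectors live on the simplex and additive noise
  would break the sum-to-100 constraint;
* plate-reader growth curves — lag / exponential / plateau, sampled every
  15 min by default, with multiplicative log-normal noise (OD error scales
  with signal); the noiseless curve's log-slope in the exponential phase
  equals the planted growth rate exactly;
* DNA sequences with planted restriction sites and a guaranteed absence of
  accidental ones, so digests recover the planted fragment lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .culture_kinetics import DEFAULT_SAMPLING_H, ODSeries
from .fa_core import FAProfile
from .rflp_typing import DEFAULT_ENZYMES, DnaSequence, RestrictionEnzyme

__all__ = [
    "GrowthParams",
    "SyntheticGrowthCurve",
    "gen_fa_profile",
    "gen_growth_curve",
    "gen_sequence_with_sites",
]


def gen_fa_profile(
    template: FAProfile,
    concentration: float = 500.0,
    rng: np.random.Generator | int | None = None,
    strain_id: str | None = None,
) -> FAProfile:
    """Dirichlet perturbation of a template profile, rescaled to sum 100.

    ``concentration`` controls noise: the Dirichlet parameters are
    ``concentration * template fractions``, so the expected composition is
    the template itself and larger values mean tighter profiles;
    ``concentration=inf`` returns the template exactly.  Acids absent from
    the template stay absent.
    """
    total = template.total()
    if not template.entries or total <= 0:
        raise ValueError("template profile must have positive total")
    if abs(total - 100.0) > 1e-6:
        raise ValueError(f"template must sum to 100, got {total:.4f}")
    if concentration <= 0:
        raise ValueError("concentration must be > 0 (use inf for no noise)")
    acids = sorted(template.entries)
    fractions = np.array([template.entries[fa] / total for fa in acids])
    nonzero = fractions > 0
    if math.isinf(concentration):
        drawn = fractions
    else:
        rng = np.random.default_rng(rng)
        drawn = np.zeros_like(fractions)
        drawn[nonzero] = rng.dirichlet(concentration * fractions[nonzero])
    return FAProfile(
        entries={fa: 100.0 * f for fa, f in zip(acids, drawn)},
        strain_id=strain_id if strain_id is not None else template.strain_id,
        medium_id=template.medium_id,
    )


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the piecewise lag/exponential/plateau growth model."""

    mu: float                      # specific growth rate in log phase, 1/h
    lag_h: float = 2.0             # lag duration
    od0: float = 0.05              # inoculum OD
    plateau_od: float = 1.5        # stationary-phase OD (inf -> no plateau)
    duration_h: float = 24.0
    sampling_h: float = DEFAULT_SAMPLING_H  # plate-reader cadence
    noise_sigma: float = 0.0       # sd of log-normal multiplicative noise

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.od0 <= 0 or self.plateau_od <= self.od0:
            raise ValueError("need plateau_od > od0 > 0")
        if self.lag_h < 0 or self.noise_sigma < 0:
            raise ValueError("lag and noise sigma must be >= 0")
        if self.sampling_h <= 0 or self.duration_h <= self.sampling_h:
            raise ValueError("invalid sampling interval or duration")

    @property
    def log_phase(self) -> tuple[float, float]:
        """(t_i, t_f) of the exponential phase, snapped to sampled times.

        Both bounds are sampling-grid points lying strictly inside the
        exponential branch, so the two-point log-slope between them equals
        ``mu`` exactly on the noiseless curve.
        """
        h = self.sampling_h
        t_i = math.ceil(self.lag_h / h - 1e-9) * h
        if math.isinf(self.plateau_od):
            t_sat = self.duration_h
        else:
            t_sat = self.lag_h + math.log(self.plateau_od / self.od0) / self.mu
        t_f = math.floor(min(t_sat, self.duration_h) / h + 1e-9) * h
        return t_i, t_f


@dataclass(frozen=True)
class SyntheticGrowthCurve:
    """A generated OD series plus the planted ground truth."""

    series: ODSeries
    params: GrowthParams
    log_window: tuple[float, float]


def gen_growth_curve(
    params: GrowthParams, rng: np.random.Generator | int | None = None
) -> SyntheticGrowthCurve:
    """Sample the growth model at the plate-reader cadence.

    The noiseless curve is exactly ``od0`` during the lag, exponential at
    the planted rate afterwards, and hard-saturated at ``plateau_od`` —
    so the log-slope anywhere inside the log window is exactly ``mu``.
    """
    t = np.arange(0.0, params.duration_h + 1e-9, params.sampling_h)
    grown = params.od0 * np.exp(params.mu * np.clip(t - params.lag_h, 0.0, None))
    od = np.minimum(grown, params.plateau_od)
    if params.noise_sigma > 0:
        rng = np.random.default_rng(rng)
        od = od * rng.lognormal(0.0, params.noise_sigma, size=od.shape)
    return SyntheticGrowthCurve(
        series=ODSeries(times=t, od=od),
        params=params,
        log_window=params.log_phase,
    )


def _random_bases(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(list("ACGT"), size=n))


def gen_sequence_with_sites(
    length: int,
    sites: Mapping[str, Sequence[int]],
    rng: np.random.Generator | int | None = None,
    enzymes: Mapping[str, RestrictionEnzyme] | None = None,
    seq_id: str = "synthetic",
    max_tries: int = 200,
) -> DnaSequence:
    """Random sequence with recognition sites planted only where requested.

    ``sites`` maps enzyme name to the 0-based start positions at which its
    recognition site is written; everywhere else the sequence is guaranteed
    free of every listed enzyme's site, so digesting recovers exactly the
    planted fragment pattern.  Positions must be in range and the planted
    windows must not overlap.

    Raises
    ------
    RuntimeError
        When ``max_tries`` resamplings cannot remove accidental sites
        (positions too dense).
    """
    if enzymes is None:
        enzymes = DEFAULT_ENZYMES
    planted: list[tuple[int, str]] = []  # (start, site string)
    for name, starts in sites.items():
        site = enzymes[name].recognition_site
        for s in starts:
            if not 0 <= s <= length - len(site):
                raise ValueError(f"{name} site at {s} outside sequence of {length} bp")
            planted.append((int(s), site))
    planted.sort()
    for (a, sa), (b, sb) in zip(planted, planted[1:]):
        if a + len(sa) > b:
            raise ValueError(f"planted sites at {a} and {b} overlap")

    rng = np.random.default_rng(rng)
    protected = set()
    for start, site in planted:
        protected.update(range(start, start + len(site)))

    bases = _random_bases(rng, length)
    for start, site in planted:
        bases[start : start + len(site)] = list(site)

    all_sites = [enzymes[name].recognition_site for name in sites] or [
        e.recognition_site for e in enzymes.values()
    ]
    planted_starts = {(s, site) for s, site in planted}
    for _ in range(max_tries):
        text = "".join(bases)
        accidental = []
        for site in set(all_sites):
            start = text.find(site)
            while start != -1:
                if (start, site) not in planted_starts:
                    accidental.append((start, site))
                start = text.find(site, start + 1)
        if not accidental:
            return DnaSequence(id=seq_id, seq=text)
        # mutate one free base inside each accidental occurrence
        for start, site in accidental:
            free = [i for i in range(start, start + len(site)) if i not in protected]
            if not free:
                raise RuntimeError(
                    "planted sites overlap an unavoidable accidental site"
                )
            i = int(rng.choice(free))
            bases[i] = str(rng.choice([b for b in "ACGT" if b != bases[i]]))
    raise RuntimeError(
        f"could not eliminate accidental sites within {max_tries} tries "
        f"(sites too dense for a {length} bp sequence)"
    )
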