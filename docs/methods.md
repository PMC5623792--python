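# Methods

## Fatty-acid profiles as compositions

A profile is a vector of weight-% of total fatty acids. Identity of an acid
is structural — `(carbons, double_bonds, omega_class)` — not textual, so
`"C18:1"` and `" C18:1 "` compare equal while `"C18:1 n-9"` is a distinct
acid. Cells reported as **"n.d." (not detected) are treated as exactly
zero**, not missing-at-random: downstream quantities are weighted sums over
the composition and need a number, and a detection limit of a GC-FID trace
is far below the 2-dp precision the tables carry. Odd-chain acids (C17:1)
are first-class; nothing assumes even chains.

Reported row sums are validated against 100 with a default tolerance of
0.5 percentage points (published tables close to 100.00; user exports often
do not). `normalize()` rescales to exactly 100 and is idempotent;
`group_totals()` partitions the profile mass over the five unsaturation
classes (0, 1, 2, 3, ≥4 double bonds) exactly.

## Fuel-property panel

All properties are computed from the **unrounded** UD and LC of the same
profile; a property test documents that feeding 2-dp-rounded intermediates
into the LCV/viscosity polynomials visibly shifts the outputs. Report
formatting rounds half-to-even at 2 dp (in decimal, not float, arithmetic).

* **UD** counts only mono-, di- and tri-unsaturated weight fractions; acids
  with ≥4 double bonds (C20:4, C22:4) contribute to LC and CN but not to UD —
  the defining formula has no higher term and we stay literal to it.
* **UD and LC normalize internally**, so both are invariant under uniform
  rescaling of the composition.
* **CN** requires a per-ester cetane number for every detected acid and
  fails loudly (naming the acid) otherwise. The packaged default table
  (`cn-mw-correlation-v1`) is computed from the published empirical
  correlation CN_i = −7.8 + 0.302·M_i − 20·N_db (Ramírez-Verduzco et al.
  2012, *Fuel* 91:102–111), with M_i the FAME molecular weight; it covers
  every acid in the packaged fixtures and is fully overridable from a config
  mapping. Results always carry the table's version tag.
* **Flash point** has no canonical closed form in this panel, so it is a
  pluggable model registry: `"none"` (omit FP) and `"per_ester_mixture"`
  (weight-fraction-weighted mean of per-ester flash points; the default).
  The packaged per-ester lookup is **synthetic** — a linear
  homologous-series estimate (≈10.5 °C per carbon, anchored near methyl
  laurate's ≈112 °C) shipped for demonstration; replace it with measured
  values for real work. FP is excluded from all reproduction tests.
* The EN 14214 (CN ≥ 54) and ASTM D6751 (CN ≥ 47) floors are exposed as
  boolean annotations only; no further certification logic is implemented.

## Growth kinetics

The specific growth rate over a window is the two-point slope of ln OD, per
the standard plate-reader bookkeeping; OD at off-sample times is linearly
interpolated, and only OD ratios matter.

**Log-phase detection** is a max-slope sliding-window procedure (the same
family as the "easy linear" method of Hall et al. 2014 used by the
`growthrates` R package): least-squares fits of ln OD vs t over every window
of `min_points` consecutive samples; windows with positive slope and
R² ≥ 0.98 qualify; the steepest window (earliest on ties) anchors the phase,
and the contiguous run of qualifying windows with slope ≥ 95% of the anchor
slope is merged into the reported window. Defaults (5 points, R² 0.98) suit
clean curves; for noisy plate-reader data a wider window (15 points ≈ 3.75 h
at 15-min cadence) is the appropriate choice and is what the recovery tests
use. A flat or non-growing series raises `LogPhaseNotFound` with a
diagnostic rather than returning a degenerate window.

Endpoint arithmetic (Q = concentration/duration; lipid %CDW = 100·lipids/
biomass) is rounded for reporting at 3/3/1 dp **in decimal arithmetic** —
float quotients such as 2.16/96 = 0.0225 must round half-even to 0.022, and
binary floats get this wrong. The packaged endpoint fixture uses the 96-h
culture duration throughout. C:N:P ratios are computed from elemental
masses supplied directly (deriving elemental content from complex-medium
recipes is out of scope) and formatted to 3 significant figures, N = 1.

Known limitation: published productivity tables are not always internally
consistent with their own printed concentrations — values computed from
unrounded replicate means can differ by a unit or more in the 3rd decimal
from concentration/duration. The package always reports the recomputed
quotient.

## In-silico PCR-RFLP

Coordinates are 0-based and between-base: a cut at k splits [0,k) and
[k,len). Recognition sites are taken from the standard enzyme definitions
(HaeIII GG^CC, RsaI GT^AC); both are palindromic blunt cutters, so only the
top strand is scanned — completeness is asserted by a reverse-complement
property test. Overlapping site occurrences all cut. Digestion conserves
length exactly.

Pattern matching against gel-derived references assigns fragments greedily
largest-to-largest per enzyme; paired fragments score their absolute length
difference, unmatched fragments score `tol_bp + length`. Greedy assignment
was chosen over optimal bipartite matching for transparency (patterns have
≤ 4 bands; the two coincide there) and is documented as replaceable. A
candidate is "consistent" when all counts agree and every pair differs by
≤ `tol_bp`. The default gel tolerance is 20 bp, justified by the packaged
reference database itself: one strain's fragments sum to 680 bp against a
690 bp amplicon, a typical band-size reading error. The packaged partial ITS
sequences (326–484 bp) are shorter than the full amplicons (460–700 bp), so
their in-silico digests are *not* expected to equal the gel patterns; tests
assert digestion invariants on them, not gel equality. Strains with
identical reference patterns (the three *D. hansenii* isolates) are
inherently indistinguishable by this method; self-matching then returns a
zero-score tie broken lexicographically.

## Synthetic data

* **Profiles**: Dirichlet resampling around a template with concentration
  parameter α·(template fractions); the expectation is the template itself
  (unbiasedness is Monte-Carlo-tested on UD), zeros stay zero, and draws
  always satisfy the profile invariants. Dirichlet noise is used because
  weight-% vectors live on the simplex; additive noise would break the
  sum-to-100 constraint. The default concentration 500 reproduces the few-
  percent relative spread typical of replicate GC-FID compositions.
* **Growth curves**: piecewise lag → exponential → plateau, sampled every
  15 min (the plate-reader cadence). The plateau is a hard cap rather than a
  smooth logistic shoulder so that the noiseless log-slope inside the
  exponential phase equals the planted μ *exactly* (round-tripped at 1e-9);
  the reported true log window is snapped to the sampling grid for the same
  reason. Noise is multiplicative log-normal (OD error scales with signal);
  σ = 0.02 matches the replicate scatter of endpoint tables. What this
  generator does **not** emulate: diauxie, death phase, smooth lag-to-log
  transitions — so passing recovery tests show correctness of the estimator
  arithmetic, not robustness to every real curve shape.
* **Sequences**: uniform random background patched so that *no* recognition
  site of the listed enzymes occurs except the planted ones (bounded retries,
  then an error when sites are too dense). Digesting a generated sequence
  therefore recovers exactly the planted fragment multiset, giving the digest
  code a sharp round-trip oracle.

All generators are pure functions of (seed, parameters).

## Problem sizes in the test suite

Stochastic checks run at: 1000 random 10-acid profiles for the UD/LC/CN
oracle-equivalence battery (tolerance 1e-12), 1000 random sequences for
digestion conservation/symmetry, 100 noisy growth curves (σ = 0.02) for
rate recovery (median relative error < 5%), 50 planted-site sequences for
the digestion round-trip, and 1000 Dirichlet draws for generator
unbiasedness. These sizes make the whole suite run in a few seconds while
keeping the Monte-Carlo standard errors an order of magnitude below the
asserted bounds.
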