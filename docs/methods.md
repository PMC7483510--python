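# Methods

This note documents the models, the default parameters and their
rationale, the synthetic-data generator, and the numerical choices made
where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Growth and expression fitting (`growth_fit`)

Growth curves are fit on log₂(OD₆₁₀) so the slope is directly in
doublings per unit time; rates are reported in doublings/hour, time is
kept in minutes internally and converted only at reporting boundaries.
Two window modes exist:

* **fixed** — the longest contiguous run of samples with OD inside
  `[od_lo, od_hi]`, defaults 0.02–0.2. This matches threshold-based
  manual window selection.
* **auto** — an exhaustive sliding-window search returning the longest
  contiguous window (OD > 0.005) whose log-linear fit has positive
  slope and R² at or above a floor (default 0.999). This is our
  documented stand-in for published automated linear-range detectors,
  whose exact algorithm we do not reproduce. On noiseless logistic
  curves a stricter floor (0.9999) keeps the window low enough that the
  fitted μ is within 5% of the true exponential rate; with realistic
  noise the default floor is needed for windows to qualify at all.

Both slopes (log-OD vs t, channel vs OD) use ordinary least squares:
deterministic, and consistent with "slope of the plot" definitions.
Using the channel-vs-OD slope makes the concentration estimate exactly
invariant to constant channel offsets; μ is invariant to rescaling OD.

ONPG kinetics are fit by bounded nonlinear least squares
(`scipy.optimize.curve_fit`, trust-region reflective) on
A(1 − e^(−γt))/γ, initialized at (A = end-to-end slope, γ = 10⁻³ min⁻¹)
with A, γ ≥ 0 and tight convergence tolerances (1e−14) so that the
γ → 0 limit degenerates cleanly to the linear law A·t. The Miller-unit
coefficient is computed in code as 1,000 × (1/0.01) × 20 = 2×10⁶.

## Autofluorescence (`plate_io`)

Background is modeled per medium as a piecewise-linear interpolation of
(OD, RFU) points pooled from non-fluorescent (wild-type) blank wells,
clamped at the ends and floored at zero. Interpolation (rather than
binned lookup) was an open choice; it is exact for the linear
backgrounds the generator produces and unbiased for smooth ones.
Subtraction is linear in the channel and never clips negative residuals.
CSV round-trips are bit-exact: floats are written with 17 significant
digits and parsed with pandas' `round_trip` converter.

## Promoter energies (`promoter_energy`)

The default parameterization is the simplified discrimination rule: a
uniform penalty of 2 energy units per non-consensus base in either
hexamer (consensus TTGACA / TATAAT), plus a spacer-length table
{17: 0, 16: 2, 18: 2, other: 4}. Energies are dimensionless and only
differences matter (K_j = K_i·e^(E_j−E_i)), so no kT conversion is
applied. The full position-specific matrices used in the original
energy-model literature are not reproduced here; both matrices and the
spacer table are overridable via a YAML config, and numeric energies for
specific natural promoters should be treated as machinery demonstrations
unless a calibrated matrix is supplied. Annotation files use 1-based
inclusive coordinates (the common promoter-table convention) and are
converted to 0-based half-open internally; minus-strand annotations are
reverse-complemented into promoter orientation before scoring.

## Free-RNAP inference (`rnap_ppgpp`)

Units: all concentrations (c_f, K₅, K_Ltet, K₁) are molecules per cubic
micron, the convention of the literature growth-law data the model is
anchored to. Defaults a = 10.5 and K₅ = 90 μm⁻³ are the reference fitted
constants; K_Ltet has no published value and defaults to 2000 μm⁻³ in
the generator (chosen so the resting PLtet/P5 ratio falls in the
observed 2–3 range) — it is always a config parameter and can be linked
to K₅ through a binding-energy difference instead.

All fits operate on log-transformed ratios/concentrations, reflecting
the multiplicative noise of plate-reader data; this also makes the
lognormal generator noise median-unbiased in fit space. The
ratio-constant fit is bounded nonlinear least squares with a fixed,
deterministic starting point (a₀ = max observed ratio, K₅₀ = median
c_f); no multistart is needed in practice. The RNAP double-exponential
law is fit with `curve_fit` on log c_f; the ppGpp law is log-linear and
solved in closed form. Whether the original double-exponential fits used
log- or linear-space residuals is not stated anywhere we could check;
log-space is our choice and is used consistently.

The decomposition of production rates into transcription × translation
assumes the GFP translation rate is promoter-independent; the anchor
promoter (P5) fixes the shared translation rate, and per-promoter
fractional residuals report where that assumption fails. The ratio
inversion c_f = (aK₅ − R·K_Ltet)/(R − a) is only defined on the open
interval (aK₅/K_Ltet, a); the pipeline maps out-of-range ratios to NaN
rather than extrapolating.

## Processivity (`processivity`)

Defaults: k_on = 0.034 (μM·min)⁻¹ (literature Cm–ribosome binding
constant); elongation rate v = 1,050 aa/min (17.5 aa/s) — the value
consistent with the worked hit probabilities (23% at 1,024 aa, 6% at
238 aa, 8 μM Cm) and inside the measured fast-growth range. v depends
in vivo on the RNA/protein mass ratio; it is a plain parameter, and any
condition-dependent v(μ) mapping can be applied by the caller. The
baseline stall rate β₀ defaults to 3×10⁻⁴ per aa (order of magnitude of
processivity estimates from length-variant activity data) and is fit
from data when provided; the β₀ fit is closed-form OLS through the
origin in log space, floored at zero, with a degeneracy flag when all
lengths coincide.

The operon model treats a stall anywhere in the upstream gene(s) as
abolishing downstream expression (stall-triggered mRNA degradation), so
downstream/upstream = C·(1 − y)·∏ P_complete(upstream). C absorbs
RBS-strength and maturation differences and is fit at Cm = 0. The
multiplicative (1 − y) form for the intergenic terminator is our
reconstruction; its key testable consequence — the Cm-normalized ratio
is identical for every terminator efficiency, and β₀ cancels from
length-normalized ratios — holds exactly and is asserted in the suite.
Growth-rate-vs-Cm closed forms from the translation-inhibition
literature are not implemented; a user-supplied μ(Cm) mapping hook
(`SimulationTruth.mu_vs_cm`) fills that role.

## Synthetic data (`synthetic_data`)

The generator emulates a 96-well plate read every 7 min for 30 h over
the reference 4-media × 4-Cm grid (media doubling rates 0.65–1.75
dbl/h; Cm 0, 2, 4, 8 μM). OD follows a logistic curve (carrying
capacity 1.0 OD) so stationary phase exists and window selection is
non-trivial; `carrying_capacity=inf` selects the pure-exponential
regime. Fluorescence is a medium-specific linear autofluorescence plus
concentration × OD, with the concentration produced by the forward model
itself: promoter activity at the growth-law c_f, times the drug
completion probability of the 238-aa reporter, times a shared
expression scale (2,000 RFU/OD). Growth inhibition by Cm defaults to a
linear slowdown reaching ≈50% at 8 μM (sublethal regime); replaceable
via `mu_vs_cm`. Noise is multiplicative lognormal (CV 2% by default,
median-unbiased) plus additive read floors of 0.002 OD and 5 RFU.
Everything is a pure function of (truth, seed).

What the generator does **not** emulate: lag-phase physiology,
well-to-well spatial effects, reporter maturation delays, OD
nonlinearity at high density, and any deviation of c_f from the growth
law under drug (the simulated truth places c_f on the law at the
realized μ). Passing recovery tests therefore demonstrates that the
estimators invert the assumed measurement model correctly at realistic
noise — not that real cultures obey these laws.

On the logistic curve the instantaneous doubling rate is μ(1 − OD/K),
so a fit window reaching OD = 0.2 carries an O(OD/K) downward bias in
μ at K = 1; the bias is below 5% once K ≥ 4, and it cancels exactly
from production-rate *ratios* (both constructs share μ), which is why
free-RNAP recovery is unbiased even where μ itself is not. Exact
(<10⁻⁴) identifiability checks are therefore run in the
pure-exponential regime, while the 10%-accuracy checks at 2% noise use
the full logistic default.

## Problem sizes

Recovery suites use 200 replicate datasets for the ratio-constant and
growth-law fits (6 growth rates each, 5% noise), 50 replicate plates
(48 wells each) for end-to-end free-RNAP recovery at 2% noise, and 10⁵
draws for the Monte-Carlo ribosome oracle — sizes at which the medians
under test are stable to well inside the asserted tolerances.

## Known limitations

* Absolute RFU→molecule calibration is out of scope; all expression
  quantities are relative (RFU/OD and ratios thereof).
* The Hill constants of the ppGpp curve are procedure-only: no
  published numeric (b, k_p, n) triple exists to assert against, so
  the suite checks fitting/inversion self-consistency.
* The energy model's default matrices are uniform; they order promoters
  correctly by mismatch count but are not calibrated to measured
  affinities.
* Ribosome-traffic (TASEP) congestion and transcription–translation
  coupling mechanics are deliberately outside the model.
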