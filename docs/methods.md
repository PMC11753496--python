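# Methods

This note records the models behind each module, the defaults and why they
were chosen, the numerical decisions that affect results, and what the
synthetic-data tests do and do not demonstrate about real data.

## Thermal denaturation and scan-rate kinetics (`melt`)

**Model.** Dye-reported melts are fitted with a two-state transition on
linear baselines,

F(T) = B_pre(T) + [B_post(T) − B_pre(T)] / (1 + exp((Tm − T)/m)),

by least squares. Because fluorescence noise is predominantly
multiplicative, residuals are weighted by the observed signal (floored at
5% of its maximum so near-zero baseline points do not dominate). The
default fit window runs from the first temperature to the global maximum of
a lightly smoothed trace: environment-sensitive dyes lose signal above the
transition as the dye is released, and the two-state model is invalid on
that dissociation limb. Smoothing the trace before taking the argmax keeps
point noise from moving the window endpoint along the peak. The initial Tm
is the maximum of a smoothed first derivative, ties broken towards lower
temperature; Tm is bounded to the window and m to (0, window span].

For serpins the "unfolded" state reached in these melts is the
polymerisation intermediate, so the transition is kinetically controlled
and Tm depends on scan rate. Treating denaturation as first-order and
irreversible with Arrhenius rate k(T) = A·e^(−Ea/RT) under a linear ramp
of rate v, ordinary least squares of ln(v/Tm²) on 1/Tm has slope −Ea/R —
the canonical scan-rate (Kissinger-type) transformation for irreversible
denaturation. An alternative ln(v) vs 1/Tm mode is exposed
(`mode="lnv"`); the two differ by ≈ 2R·Tm ≈ 5.5 kJ/mol, inside typical
replicate error. The regression is unweighted by default (midpoint
standard errors across rates are near-uniform); a 1/SE(Tm)² weighted mode
exists. A non-monotone Tm-vs-rate series is flagged
"non-kinetic behaviour" rather than rejected.

**Known systematic.** On curves generated by the irreversible-kinetic
model, the symmetric sigmoid's fitted midpoint sits ~3 °C above the true
half-denaturation temperature: the kinetic survival curve has a long
low-temperature tail and a sharp finish that no logistic can match. The
offset is essentially scan-rate independent, so it cancels in the
scan-rate regression; recovered activation energies agree with the
generator to ~1% noise-free. Fitted midpoints should therefore be compared
between conditions, not read as absolute half-denaturation temperatures.

## Polymerisation kinetics (`polym`)

**Half-times.** The default extractor is model-free plateau crossing,
chosen because aggregation traces take sigmoidal or biphasic shapes no
single rate law describes: the lower plateau starts as the median of the
first 5% of points (refined once from the points before 10% of the
provisional half-time, since slow traces may be rising from the first
sample); the upper plateau is the asymptote of a saturating-exponential
fit to the final quarter of the rise, bounded to at most half a dynamic
range above the observed maximum so a truncated curve cannot fake
completion; t₀.₅ is the first linear-interpolated crossing of the
normalized signal through 0.5 (earliest time on a flat segment). A curve
whose final normalized value is below 0.8 is rejected as incomplete; the
alternative `exponential_fit` mode (y = y₀ + Δ(1 − e^(−kt)), t₀.₅ = ln2/k)
remains available for truncated curves and is flagged rather than
rejected. The extractor is invariant to affine transforms of the signal.

**Arrhenius comparison.** ln t₀.₅ is regressed on 1/T (≥ 3 distinct
temperatures); with this sign convention Ea = slope·R is positive when
polymerisation accelerates with temperature. Half-times at a reference
temperature — default 54.8 °C (328.0 K exactly, a mid-range point at which
variants are conventionally compared) — are interpolated as
exp(intercept + slope/T_ref); references more than 2 K outside the fitted
range are flagged as extrapolation. Variant fold-changes are ratios of
interpolated half-times with a delta-method standard error from the two
regression covariance matrices (ln ratio is linear in the coefficients).

## Sphere-of-action quenching (`quench`)

Stepwise addition of quencher both concentrates the quencher and dilutes
the fluorophore, so raw fluorescence is corrected by
(current volume)/(initial volume) before analysis; [Q] at each step is
cumulative quencher moles over current volume. The corrected ratio F₀/F vs
[Q] is fitted with F₀/F = Y_int + K_SV·[Q]·e^(V[Q]): K_SV (M⁻¹) is the
dynamic Stern–Volmer constant and V (M⁻¹) produces the upward curvature
caused by quenchers already adjacent to a fluorophore at excitation.
Initial values are Y_int = 1, K_SV from the OLS slope of the first three
points, V = 0; V is bounded to [0, 50] M⁻¹ and a fit pinned at the bound is
flagged "sphere term unidentifiable"; |Y_int − 1| > 0.1 flags bad
normalization. Fitting the ratio (not F itself) matches the plotted
quantity and assumes homoscedastic ratio errors.

The default simulated protocol is five equal additions of 1.9 µL of a
5.26 M stock into 90.5 µL (final volume 100 µL), stepping nominal [Q] by
≈ 0.1 M to ≈ 0.5 M. The published protocol states only the initial and
final volumes and "0.1 M added five times"; a five-step addition *of* a
0.1 M stock could not reach meaningful [Q] in 9.5 µL, so the steps are
read as ≈ 0.1 M increments, and the builder takes volumes and stock
concentration as explicit inputs so either reading is expressible.

## Spectral metrics and inhibition stoichiometry (`assays`)

COSM is the intensity-weighted mean emission wavelength, computed on the
wavelength axis (nm) as spectra are reported; it is invariant to intensity
scaling. Intensity ratios are max/max (`peak`) or trapezoidal-area ratios
over the wavelength overlap (`integral`).

The stoichiometry of inhibition is the x-intercept of an OLS line through
(inhibitor:enzyme ratio, residual activity) points, using only activities
above a 0.05 floor (saturated zero readings carry no slope information);
the intercept SE comes from the delta method on −b₀/b₁. The regression is
not forced through (0, 1); an activity at ratio 0 outside [0.8, 1.2] flags
bad normalization instead. SI maps to percent activity loss as
(1 − 1/SI)·100 — the fraction of inhibitor consumed as substrate rather
than forming the inhibitory complex — so SI = 1.7 corresponds to ≈ 41%
loss.

## B-factor comparison (`bfactor`)

Raw per-residue B is the mean over selected atoms (all heavy atoms by
default, Cα optional), first model only, waters and hetero groups
excluded, alternate conformers contributing once via the
highest-occupancy copy. "Normalization" is per-structure z-scoring of
these residue means (sample SD), the standard way to compare flexibility
across crystals refined at different resolutions, where overall-B offset
and spread are dataset properties; mean-relative and min–max schemes are
selectable. Averaging across structures of the same variant and
differencing between variants operate on the intersection of residue keys
(chain, author residue number, insertion code — the structures share
numbering, so no alignment is attempted), with dropped residues (e.g.
unmodelled loop stretches) reported, never imputed. Min–max rescaling to
[0, 1] is applied only for final visualization maps, which can be written
back into a PDB B column (fixed format, two decimals) for molecular
graphics colouring.

Applying the pipeline to the real deposited AAT structures (1QLP, 3NE4 vs
8P4J, 8P4U) requires downloading them and is a documented workflow, not a
test dependency.

## Synthetic data (`simulate`)

The generators exist so every analysis stage can be validated by parameter
recovery; each returns its ground truth as metadata.

- **Melts** integrate dN/dT = −k_d(T)·N/v on a 0.1 K grid over 25–90 °C
  and mix linear pre/post baselines by 1 − N; a sigmoidal post-peak decay
  (onset 12 K above the midpoint, width 1.5 K) emulates dye release, giving
  traces that peak and fall as real ones do. The default denaturation step
  uses the wild-type apparent barrier (Ea = 282.2 kJ/mol) with the
  prefactor calibrated by the closed-form midpoint condition
  k(Tm)·R·Tm²/(vEa) = ln 2 so the 1 K/min midpoint is 58.6 °C — placing
  all four ramp-rate midpoints in the observed 56–63 °C band. That closed
  form is the standard asymptotic evaluation of the temperature integral;
  it agrees with direct integration to about 0.06 K at these parameters.
- **Polymerisation** integrates the M ⇌ M\*, M\* + M\* → P scheme (state
  M, M\*, and polymerised monomer equivalents, so mass is conserved
  exactly) with LSODA at rtol 1e-8; the FRET proxy is the polymerised
  mass fraction, i.e. dimer formation is the committed, signal-generating
  step and elongation beyond it is not modelled. No experimental rate
  constants exist, so the defaults are calibrated constructs —
  k1(328 K) = 0.02 min⁻¹ (Ea 250 kJ/mol), k₋1(328 K) = 0.01 min⁻¹ (Ea
  100), k2(328 K) = 10⁵ M⁻¹min⁻¹ (Ea 50), M₀ = 5 µM — an
  activation-limited regime giving half-times from ~3 h at 50 °C to
  ~4.5 min at 65 °C with Arrhenius-linear ln t₀.₅ (R² ≈ 0.999). True
  half-times (P = M₀/2) come from event detection on the dense solution.
- **Titrations and structures**: quenching titrations are the exact
  inverse of the analysis pipeline (so noise-free round trips are exact);
  SI series are the piecewise-linear activity law on an even ratio grid;
  toy structure pairs share an ideal-helix backbone with a seeded
  per-residue B profile and a region-localized inflation in the second
  copy. All randomness flows from explicit integer seeds; identical
  configurations produce identical outputs.

**What passing tests show, and don't.** Recovery tests demonstrate that
the estimators invert their own generating models at realistic noise
levels (1–2% multiplicative) and study-scale problem sizes: four ramp
rates × ~650-point melts, six hold temperatures × 200-point progress
curves, six-point titrations, 40-residue structures, 10–100 Monte-Carlo
replicates. Real data add baseline drift, lamp flicker (correlated noise),
temperature-sensor lag, multi-phasic aggregation and crystallographic
model bias, none of which the generators emulate; published values with no
public raw data (K_SV, FRET-derived Ea, the 3.8× fold-change) are used as
magnitude context only.

## Error handling conventions

Operations raise typed exceptions (`serpinkin.errors`) for malformed
input, insufficient data, and degenerate or unphysical cases; fits that
run but fail to converge return flagged results rather than raising, and
every fit reports parameters, standard errors, point count and convergence
status, with `--json-report` exposing the same machine-readably from the
CLI.

## Limitations

- No equilibrium thermodynamics (ΔH, ΔG) from melts, and no
  multi-transition deconvolution.
- No mechanistic fitting of FRET traces to the kinetic scheme (simulation
  is forward-only) and no nucleation–elongation model selection.
- Quenching does not separate dynamic from static mechanisms (needs
  lifetime data).
- PDB only; no mmCIF, reflection data or anisotropic ADP handling.
- Residue matching by author numbering only — appropriate within one
  protein's structure family, not across homologues.
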