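# Methods

## The model

`mkrbe` evaluates clonogenic survival under the modified microdosimetric
kinetic (mMK) model for a schedule of N photon fields separated by
interruptions. Each field is an instantaneous pulse of dose Dₙ (Gy):

    −ln S = Σₙ [(α₀ + γβ₀) Dₙ + β₀ Dₙ²]
            + 2 Σ_{n<m} β₀ e^{−(a+c)·Δt(n,m)} Dₙ D_m

The first sum is ordinary linear-quadratic (LQ) kill per field with the
track-quality correction γβ₀ added to the linear coefficient. The double
sum counts lethal lesions formed by pairing sublethal lesions from
*different* fields; the pool of sublethal lesions decays by first-order
sublethal-damage repair (rate a+c, h⁻¹) during the pauses, so each pair is
weighted by the elapsed time Δt(n,m) between its two fields.

Assumptions inherited from the model:

- only sublethal-damage repair acts between fields — no potentially-lethal
  damage repair, repopulation, or reoxygenation;
- fields are instantaneous. The model carries no intra-field
  (Lea–Catcheside) protraction factor, so the dose rate is metadata used
  only for reporting elapsed delivery time. At clinical dose rates
  (3 Gy/min) and field doses ≤ 4 Gy each field lasts ≤ 80 s, over which
  repair at 0.46 h⁻¹ changes the cross term by well under the 0.002 RBE
  tolerance used throughout;
- the repair exponent uses the *total elapsed time* between fields n and m,
  i.e. the sum of the intervening gaps. For equal gaps τ this is the
  familiar (m−n)·τ form; for unequal gaps it is the natural generalization
  and the schedule type accepts arbitrary gap lists.

### γ and units

γ = y_D / (ρ π r_d²) converts the dose-mean lineal energy of the beam into
the single-event dose-mean specific energy (Gy). With y_D in keV/µm, ρ in
g/cm³ and r_d in µm, the conversion constant is written out explicitly:

    γ[Gy] = 0.1602176634 · y_D / (ρ π r_d²)

(1 keV = 1.602176634×10⁻¹⁶ J; µm³ of unit-density matter = 10⁻¹⁵ kg).
Interruption times are stored in minutes and (a+c) in h⁻¹; the min→h
conversion happens exactly once, inside `neg_log_sf`.

### RBE

The reference is the same cell irradiated instantaneously (all gaps zero),
i.e. plain LQ with α = α₀ + γβ₀ and β = β₀. The iso-survival reference dose
is the positive root D = (−α + √(α² + 4β·(−lnS)))/(2β) and
RBE = D_ref / D_physical. This is an iso-effect dose ratio: the quantity
inside the inversion is the survival *exponent* −lnS, not the raw surviving
fraction. RBE is exactly 1 for uninterrupted schedules, strictly decreasing
in every gap (for positive repair rate and ≥2 positive doses), and
approaches the independent-fields limit Σ(αDₙ + β₀Dₙ²) as all gaps → ∞.

## Parameters

The packaged `NCI-H460_6MV` bundle (human non-small-cell lung cancer line,
6-MV photons):

| parameter | value | units | meaning |
|---|---|---|---|
| α₀ | 0.21 | Gy⁻¹ | linear lethal-lesion coefficient (±0.16 reported, stored as metadata) |
| β₀ | 0.07 | Gy⁻² | quadratic coefficient; multiplies D², hence Gy⁻² even though source tables sometimes print Gy⁻¹ |
| a+c | 0.46 | h⁻¹ | sublethal-damage repair rate, = ln2/T½ (T½ ≈ 1.51 h) |
| y_D | 2.34 | keV/µm | dose-mean lineal energy of 6-MV photons |
| ρ, r_d | 1.0, 0.5 | g/cm³, µm | domain density and radius; γ ≈ 0.4773 Gy |
| dose rate | 3.0 | Gy/min | metadata only (300 MU/min at 1 MU = 0.01 Gy) |

Two published y_D values exist for this beam: 2.34 (the tabulated parameter,
used by the bundle) and 2.32 (a depth-averaged figure). Both are exposed as
named constants and never averaged; the 0.002-RBE tolerance below absorbs
the difference. y_D itself is *not* computed here — that requires Monte
Carlo particle transport — so it enters only as a packaged constant, and the
microdosimetry module computes moments only for user-supplied or synthetic
spectra.

## Reference values and the verified flag

The packaged reference CSV transcribes 72 previously reported RBE cells
(doses 2/8 Gy × 2/4 fields × τ ∈ {1,3,5,10,30,60} min × a+c ∈
{0.46, 1.0, 2.0} h⁻¹). Recomputing the grid shows the reported series are
not internally consistent with the model under any single parameterization:
only 11 of the 72 cells agree with the computed values within 0.002
(absolute; this tolerance covers three-decimal rounding of the reported
numbers plus the y_D ambiguity). Those cells carry `verified = true` and are
asserted by the tests; the rest are carried for context and flagged, never
asserted. The comparison tooling (`compare_to_reference`) reports per-cell
absolute differences against any reference table.

## Numerical choices

- **Spectrum quadrature**: trapezoid rule on the supplied grid, which is
  deterministic and grid-faithful; a single-row spectrum is a point mass
  (y_F = y_D = y₀). Densities are normalized to unit integral on
  construction. For near-degenerate spectra y_D ≥ y_F can be violated by
  one part in 10¹² of floating-point roundoff; tests allow exactly that.
- **Survival evaluation**: vectorized over the upper triangle of field
  pairs; verified against a naive double loop to 1e-12 on random schedules.
- **LQ inversion**: closed-form positive quadratic root; β = 0 is rejected
  (linear-only inversion is out of scope).
- **Parameter fitting**: bounded least squares (scipy Trust Region
  Reflective) on −lnS over (α, β₀, a+c), x₀ = (0.1, 0.05, 1.0), tolerances
  1e-15. The objective is quadratic in (α, β₀) given a+c, so the problem is
  benign; noiseless data are recovered to ~1e-12. Only the combined
  α = α₀ + γβ₀ is identifiable from survival data, so only it is reported.
  The design must contain ≥2 distinct total doses (separates α from β₀) and
  ≥2 distinct positive gap patterns (pins a+c); degenerate designs raise an
  error naming the missing axis.

## Synthetic data

The generator stands in for in-vitro clonogenic data, which this package
does not ship:

- `make_spectrum` tabulates a lognormal-shaped density (dispersion `shape`,
  default 0.6 — a realistic width for photon lineal-energy spectra at the
  micron scale) on a seed-jittered geometric grid, then stretches the
  y-axis so the trapezoid dose-mean hits the target exactly (the stretch
  covariance makes this rescaling exact, not iterative).
- `simulate_survival` multiplies the model SF by lognormal noise
  (additive Gaussian on −lnS), the standard error structure of clonogenic
  assays; it keeps observations positive and makes the least-squares fit on
  −lnS the matching estimator. Default study conditions mirror the packaged
  bundle; the 48-scenario recovery design uses total doses {1,2,4,8} Gy ×
  {2,4} fields × the six τ values.
- All randomness flows through one explicit integer seed
  (`numpy.random.default_rng`); no global state.

What passing tests do **not** show about real data: synthetic observations
are generated by the same model family that is fitted, so recovery accuracy
says nothing about model misspecification (plating-efficiency drift,
cell-cycle redistribution, dose-rate effects within fields, non-first-order
repair). The grid reproductions validate the arithmetic of the model, not
its biology.

## Problem sizes

Everything is small by construction: grids are ≤ 72 deterministic scenarios,
property tests use ≤ 100 random cases, and recovery studies use 48 scenarios
over a handful of seeds. The full test suite runs in a few seconds on one
CPU; the acceptance script in well under a second.

## Known limitations

- Photon-only, instantaneous-pulse fields; no saturation correction or
  track-structure stochastics, so not applicable to high-LET beams.
- No potentially-lethal-damage repair, repopulation, or
  hypoxia/reoxygenation terms.
- y_D for specific beams must come from measurement or external transport
  simulation; the package only computes moments of supplied spectra.
- The reference RBE table is mostly unverifiable against the model (61 of
  72 cells); conclusions should rest on the verified subset or on fresh
  computation.
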