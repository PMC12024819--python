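# Methods

## Optical model

The pipeline assumes the Beer–Lambert law in its homogeneous, single-layer
form: transmitted (here: remitted) intensity `I(λ) = I₀(λ)·exp(−ε·C·l)`,
with blood treated as a two-chromophore mixture so that the effective
extinction coefficient at saturation `s` is
`ε_mix(s, λ) = s·ε_HbO₂(λ) + (1−s)·ε_Hb(λ)`. Scattering, pathlength
dispersion and other chromophores are not modeled; the optical pathlength
`l(λ)` is taken constant (a per-wavelength override exists for robustness
experiments), and the white-card reference `I₀*` stands in for the true
incident intensity. These are the standard simplifications behind
pulse-oximetry-style quasi-DC analysis; everything downstream is therefore a
statement about the idealized model, not about layered tissue.

Extinction coefficients at the five device wavelengths are stored as the
conventional base-10 tabulation (cm⁻¹ M⁻¹) in `src/ppgvo2/data/` and
converted to the natural-log convention (× ln 10) at load, matching the
base-e exponential above. The tabulated Hb and HbO₂ values at 810 nm differ
by a few percent; both are replaced by their mean at load so the isosbestic
point is exact. This makes the pivot construction exactly testable and has
no effect on model behavior (features are scale-equivariant in the
coefficients).

## Isosbestic pivot scaling

The scaling `α(λ) = ε̄(810)/ε̄(λ)`, with `ε̄ = (ε_Hb + ε_HbO₂)/2`, is chosen
so that `α(λ)·ε_mix(s, λ)` passes through the common point
`(810 nm, ε̄(810))` for every saturation. Consequences (all asserted in
tests): `α(810) = 1`; the OLS slope of the scaled mixture against wavelength
is exactly affine in `s`, zero at `s = 0.5`, antisymmetric about it; and the
slope scales linearly with any common rescaling of the coefficients. Other
constructions that "move the intercept to 810 nm" are conceivable; this one
is the unique choice that pins *all* mixture lines to the same pivot, which
is what makes the slope a clean one-parameter function of saturation.

Two genuinely open choices were resolved as follows. The slope abscissa is
wavelength in nm (the natural axis of the extinction plots); any monotone
re-parameterisation of the abscissa would give monotonically related slopes
and identical ensemble behavior. The per-window features use raw (un-scaled)
absorbance — the α scaling motivates the feature design and lives in the
theory layer, but the absorbance definition is pre-regression, and a fixed
per-wavelength rescaling is an affine change of the regression ordinates
that a tree ensemble is insensitive to.

## Signal chain

* PD combination: the four photodiodes are averaged pairwise into a
  horizontal (PD1) and vertical (PD2) group — the mean preserves photocurrent
  units and is idempotent on already-combined inputs.
* Quasi-DC: non-overlapping 10-s block means (100 Hz → 0.1 Hz). Block
  averaging was preferred over decimation or filtering because the DC level
  itself is the measurand and the mean maximally suppresses zero-mean AC
  ripple and bursty noise at this rate. Windows start at t = 0, half-open
  `[start, start+10)`; a trailing partial window is dropped.
* Absorbance: `A = −ln(I/I₀*)` with `I₀*` from the calibration table at the
  record's drive current (default 50 mA; linear interpolation between the
  tabulated 10…90 mA levels, no extrapolation). Nonpositive intensities are
  a hard error by default; `nonpositive="clip"` substitutes the channel's
  smallest positive value and logs, for audit-friendly handling of motion
  dropouts.
* Features: per window and PD group, the OLS slope of `A(λ)` vs λ over the
  active wavelength subset → `m1`, `m2`. The three-wavelength subset
  defaults to {670, 810, 950} nm: the two spectral extremes plus the
  isosbestic anchor maximize slope leverage per LED.
* Reference alignment: breath-by-breath VO₂ samples are averaged within each
  window's interval; windows with no breath sample are dropped and counted.

## Ensemble model

100 regression trees, each fitted on a bootstrap resample of the training
windows (with replacement, same size), unlimited depth, minimum two samples
per leaf, all four features considered at every split (with four features,
per-split feature subsampling would only add variance). The prediction is
the arithmetic mean of the trees. Fitting delegates to scikit-learn
(`RandomForestRegressor` with `max_features=1.0`, which is exactly bagging);
the contract the tests pin down is bootstrap aggregation, mean aggregation,
schema checking and bit-reproducibility for a fixed seed. One caveat: the
library's splitter breaks exact ties between candidate splits using its RNG
stream, so schema-level no-ops (e.g. adding a constant feature) reproduce
predictions only statistically, not bit-exactly; the suite asserts a tight
statistical tolerance there.

Evaluation: MAE and `R² = 1 − SS_res/SS_tot` on held-out windows. The
default split is pooled-random 80/20 over windows (floor convention for the
training size), which shares subjects between train and test and mirrors a
pooled residual analysis; leave-one-subject-out is provided as the stricter
generalization protocol and is reported fold-by-fold plus pooled.

## Synthetic cohort

The generator emulates an 8-subject graded treadmill session: sitting 30 s,
walking 120 s @ 1.5 mph and 120 s @ 2.5 mph, running 60 s @ 4 mph and 180 s
@ 6 mph (510 s = 51 windows/subject → 408 feature rows for 8 subjects).

* VO₂ kinetics: first-order relaxation `dV/dt = (V* − V)/τ` toward a
  stage-dependent demand `V* = V_rest + k_speed·speed`, integrated with the
  exact exponential update (τ default 30 s, the standard
  exercise-physiology approximation for moderate intensities; V_rest =
  3.5 mL/kg/min ≈ 1 MET).
* Saturation coupling: `s = clip(s_rest − k_sat·(V − V_rest), 0.2, 1)` with
  s_rest ≈ 0.85 and k_sat ≈ 0.012 per mL/kg/min. This linear coupling is a
  generator convention (its parameters are config-exposed), chosen to give
  the slope features a usable dynamic range — it is not a physiological
  claim.
* Forward model: `I = I₀*·exp(−ε_mix(s)·c_tot·l)·(1 + AC ripple)·(1 + noise)`
  plus additive motion bursts. Defaults: c_tot ~ U(2.0, 2.6) mM,
  l ~ U(0.25, 0.35) cm, cardiac ripple 1% of DC at a heart rate interpolated
  between rest and max with VO₂, multiplicative sensor noise 2% SD
  (independent per PD group), motion bursts only during ≥ 4 mph stages
  (Poisson 0.1 s⁻¹, exponential amplitudes of 5% of I₀*, 0.2 s decay) —
  magnitudes picked as typical of reflectance PPG at a stable wrist mount.
  Reference VO₂ is emitted at breath-like U(2, 4) s intervals with 5%
  multiplicative noise.
* Population draws: height U(155, 190) cm, weight U(50, 95) kg, demand slope
  k_speed ~ U(3.2, 4.2) mL/kg/min per mph, τ ~ U(25, 35) s, plus the optical
  ranges above. The k_speed range centers the protocol-weighted cohort-mean
  VO₂ at ≈ 15.3 mL/kg/min (the generator's calibration point) with
  per-subject peaks approaching ~29 mL/kg/min.

What passing on this cohort shows — and does not. The simulator's PPG is
generated by the same idealized Beer–Lambert forward model the features
invert, with a deterministic saturation→VO₂ link; surrogate accuracy
numbers therefore certify the pipeline's internal consistency, conditioning
and noise robustness, not field accuracy on real tissue, where scattering,
perfusion heterogeneity, contact pressure and subject-specific optics break
the clean forward model. The pooled split additionally shares subjects
between train and test; leave-one-subject-out is the number to look at for
cross-subject generalization.

## Numerical conventions

* OLS slopes use the closed-form centered normal equations; degenerate
  abscissae (all equal) and length mismatches raise.
* Seed fan-out: a single run seed is hashed (SHA-256 of `seed:stage`) into
  independent sub-seeds for calibration synthesis, cohort draws, per-subject
  noise streams, the split and the bootstrap, so stages are independently
  reproducible and all derived seeds stay below 2³¹.
* Determinism: identical seed ⇒ bit-identical cohort (and manifest hashes),
  features, predictions and metrics; asserted end-to-end in the suite.
* Problem sizes: the default experiment is 8 subjects × 510 s × 10 channels
  at 100 Hz (~4 M raw samples), which runs in seconds; tests that exercise
  the simulator repeatedly use 1–3 subjects.

## Known limitations

* Single-layer Beer–Lambert optics; no scattering, melanin or pulsatile
  pathlength modeling. The AC waveform is phenomenological (a sinusoid),
  adequate as a nuisance component for DC analysis but not for morphology
  work.
* The VO₂↔saturation coupling is linear with hard clipping; real tissue
  desaturation kinetics are nonlinear and site-dependent.
* Channel monochromaticity: LED spectral width and photodiode spectral
  sensitivity are collapsed onto the nominal wavelengths.
* Calibration units (µA) are nominal; only the ratio I/I₀* enters the
  features.
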