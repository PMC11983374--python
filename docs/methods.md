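# Methods

This note documents the models implemented in `cmxrf`, the assumptions
behind them, the tunable parameters that matter, and the design choices
made where the design was genuinely open.

## 1. Fundamental-parameter data backend (`cmxrf.physics`)

All atomic data come from an analytic compilation authored for this
package (`cmxrf/_fp_synthetic.py`), a synthetic stand-in for a full
X-ray database:

* **Line and edge energies.** Sparse anchors of well-known tabulated
  values (Kα1, Kβ1, Lα1, Lβ1 lines; K and L3 edges) are interpolated
  linearly in √E versus Z.  Moseley's law makes √E locally linear in Z,
  so interpolation error between anchors a few Z apart is well below
  0.1% — verified in the test suite against independently hand-typed
  literature values, including interpolated elements.
* **Mass attenuation.** Bragg–Pierce-type photoelectric power law
  τ = C·Z³·⁷⁵/A·E⁻²·⁹ (calibrated at Fe, 10 keV) with edge-jump factors
  (J_K = 125/Z + 3.5; merged L1/L2 jump 1.6; L3 jump 2.5; M jump 5),
  plus Klein–Nishina incoherent scattering and a small coherent term.
  Accuracy versus reference tables is of order tens of percent for
  extreme Z — sufficient here because the *same* backend drives both
  the forward simulation and the learned inversion, so the pipeline is
  self-consistent by construction.  The invariants that matter for the
  physics (positivity, monotone decrease between edges, exact linear
  mixing, edge jumps) hold exactly.
* **Fluorescence yields.** Saturation fits ω = Z⁴/(Z⁴ + c) with
  c = 9.0·10⁵ (K) and 7.5·10⁷ (L), reproducing literature magnitudes
  (e.g. ω_K(Cu) ≈ 0.44).
* **Dark matrix.** The mass fraction not assigned to a detectable
  element attenuates as a cellulose-like pseudo-compound C₆H₁₀O₅
  (44.5% C, 6.2% H, 49.3% O by mass).  Some compositional stand-in is
  mandatory — the dark matrix dominates absorption in the target
  samples — and a light-element carbohydrate is representative of the
  biological/geological pellets the method addresses.  Configurable per
  composition.

## 2. MXRF forward model (`cmxrf.forward`)

Φ₀(E) is produced deterministically, not by Monte-Carlo transport:

* **Tube**: Kramers continuum I(E) ∝ Z·(E₀/E − 1) at 50 kV with an
  inherent-filtration factor exp(−(1.5 keV/E)³), plus Rh K and L
  characteristic lines carried as fixed fractions of the total flux
  (4%/0.8% Kα/Kβ, 2%/1.2% Lα/Lβ).  Total emitted photons per depth
  step default to 2·10⁷, chosen so a typical profile accumulates
  ~10⁶ counts — the counting-statistics regime of real depth scans at
  seconds-per-step measurement times.
* **Primary fluorescence**: thick-sample Sherman equation per line,
  summed over excitation channels above the shell's edge, with the
  shell photo-ionization share derived from the edge-jump structure and
  a 50% Coster–Kronig transfer of L1/L2 ionization into L3.  Secondary
  enhancement is deliberately out of scope.
* **Scatter continuum**: tube spectrum weighted by the sample's
  scattering cross section over its self-absorption (the same geometry
  factors as fluorescence), plus an optional flat floor.  This gives
  the background the same dark-matrix sensitivity as real spectra.
* **Detector**: each line rendered as a Gaussian with
  FWHM(E) = √(noise² + k·E), k fixed by FWHM(Mn Kα) = 150 eV,
  noise = 80 eV.  No escape peaks, no pile-up.
* **Grid**: 2048 channels × 20 eV (0–40.96 keV).

The module boundary is deliberate: anything that produces an
`MXRFSpectrum` (e.g. an external Monte-Carlo code) can be substituted
upstream of the confocal transformation.

## 3. Confocal transformation (`cmxrf.confocal`)

Φ(E, xₙ) = Φ₀(E)·T(E)·R(xₙ − x₀; μ̄(E), σ(E)) on a 40-step × 5 μm depth
grid.  The functional forms of the two instrument curves are a design
choice of this package (they are not uniquely determined by the
qualitative behaviors they must reproduce):

| parameter | meaning | default | unit |
|---|---|---|---|
| T_A | low-energy transmission roll-off | 6.0 | keV |
| T_B | high-energy transmission roll-off | 25.0 | keV |
| T_M | peak transmission | 0.8 | – |
| σ_MAX | probe-width power-law amplitude | 42.0 | μm |
| σ_exp | probe-width decay exponent | 0.7 | – |
| σ_OFF | probe-width floor | 3.0 | μm |
| ϑ_E, ϑ_D | excitation/detection angles | 50 | deg |
| E_in | effective ingoing-path energy | 17 | keV |

* `T(E) = T_M·exp(−T_A/E)·exp(−E/T_B)` is band-pass shaped with its
  maximum at √(T_A·T_B) ≈ 12.2 keV; both required roll-offs (soft
  X-rays absorbed in the optic, hard X-rays not guided) fall out of one
  two-parameter form.
* `σ(E) = σ_OFF + σ_MAX·E^(−σ_exp)` decreases strictly with energy;
  the defaults are set so 2√(2 ln 2)·σ(8.048 keV) = 30 μm, the depth
  resolution at Cu Kα.
* `R` is evaluated through the scaled complementary error function:
  R = ½·erfcx(u)·exp(−d²/2σ²) with u = (μσ² − d)/(√2 σ), which is
  algebraically identical to the erfc form but immune to overflow at
  large μσ; for u < −25 (probe deeply buried) the asymptotic
  full-burial form exp(μ²σ²/2 − μd) is used, whose exponent is provably
  non-positive there.  Equivalence to adaptive quadrature of the
  defining integral is tested to 10⁻⁶ relative on random parameter
  triples.
* The **ingoing attenuation path** of a polychromatic tube is strictly
  channel-entangled; it is approximated by a single effective incident
  energy E_in = 17 keV (configurable).  Self-consistency again makes
  the inversion insensitive to the exact value.
* **Calibration randomization**: each of the six parameters uniform in
  ±20% of nominal per profile (resampled if invariants break).  This
  spread is what makes the trained network calibration-free; it is also
  the dominant systematic on soft lines, where a ±20% shift of T_A
  moves T(3.3 keV) by ~±35%.
* **Depth convention**: μm, increasing into the sample, origin at the
  first scan position; x₀ lives on the same axis and is drawn uniformly
  in [25, 125] μm during data generation so the surface rise is always
  inside the scan window.
* **Amplitude convention**: the transform returns expected counts per
  channel per depth step at unit exposure; `add_poisson_noise`'s
  `exposure_scale` maps to measurement time.

One physical subtlety: the spectral centroid hardens monotonically with
depth only once the probing volume is fully inside the sample.  Within
about one probe FWHM (at the soft end of the band) of the surface, the
half-submerged probe produces a small non-monotonic transition; tests
assert monotonicity beyond that margin.

## 4. Synthetic samples (`cmxrf.samples`)

Per element: presence ~ Bernoulli(occurrence rate); if present, the
mass fraction is log-normal; density uniform in 0.5–3.5 g/cm³; the
remainder is dark matrix.  The bundled default table is hand-set to
plausible geochemical magnitudes (Fe/Ca/K common at percent level,
trace metals rare at ppm level, REE rates 0.2–0.4) and produces samples
that are on average ~88% (always ≥ 65%) dark matrix.  It is a
user-replaceable stand-in — the algorithm, not the specific table, is
the point — and `build_occurrence_table` re-derives a table from any
set of reference compositions.  If the detectable draws sum above a cap
of 0.35 they are rescaled proportionally, keeping samples inside the
dark-matrix-dominated regime the method targets.  Concentrations are
mass fractions in [0, 1] everywhere internally; percent appears only in
I/O.

## 5. Quantification model (`cmxrf.model`)

Architecture (desk-scale default, fully config-swappable):

* conv blocks 3×3, channels 12/24/48/48, ReLU, 2×2 max-pool after the
  first three blocks, on the (40 × 150)-bin input image;
* two sum-spectrum shortcuts into the head: the depth-averaged log
  spectrum, and its high-passed residual (15-bin moving-average
  subtracted).  The residual is the log peak-to-local-continuum ratio,
  which cancels the smooth randomized optic transmission to first
  order — measurably the dominant error source for lines below 5 keV;
* MLP 384 → 128 → 55, linear output.

Input conditioning: counts are normalized per profile (removing the
exposure scale) as x = log1p(counts·10⁵/total), then standardized
per bin with training-set statistics.  Targets: concentrations as
log10(w + 10⁻⁶) (five decades of dynamic range), density and x₀ raw,
all 55 slots standardized (std floored at 0.25 to keep rarely-present
element slots well-conditioned on small training sets).

Training: MSE with a 3x loss weight on concentration slots of elements
present above 10⁻⁴ mass fraction (weights normalized to unit mean) — the
plain unweighted loss spends most of its gradient on confirming
absences, while the scored quantity is the accuracy on present
elements; Adam; fresh Poisson noise drawn from the expected-count
profiles every epoch (noise augmentation); 10% validation split when no
validation set is given; divergence (non-finite loss) aborts with
diagnostics.  The desk-scale default learning rate is 2·10⁻³: at a few
thousand optimizer steps (5 000 profiles × ~15 epochs on one CPU) Adam
at 10⁻⁴ cannot leave the initialization basin — that rate is
appropriate for the tens-of-thousands-of-steps GPU regime, which is
available as a configuration choice, not the default.

All scaling constants, the architecture and the generator settings are
stored in the checkpoint; save → load → predict is bitwise stable.

## 6. Evaluation (`cmxrf.evaluation`)

Relative deviations for concentrations and density, absolute deviations
(μm) for x₀.  Elements certified below 0.1% mass fraction are scored by
order-of-magnitude agreement (|log₁₀ ratio| ≤ 1) — the relative
deviation is meaningless at trace level; the boundary is inclusive:
exactly 0.1% counts as "over 0.1%".  Predicted mass for certified-absent
elements is accumulated per sample (`nonpresent_sum`).  Density
deviations are reported both per profile and per sample mean.

## 7. What the synthetic data do and do not show

The generator emulates: occurrence-driven compositions, a dark-matrix-
dominated absorption regime, calibration drift, exposure variation, and
Poisson counting noise.  It does **not** emulate: the
simulation-to-reality gap of a real instrument (background mis-modeling,
detector artifacts such as escape/pile-up, inhomogeneous samples,
surface roughness).  Passing the parameter-recovery tests therefore
demonstrates that the method — transformation, data generation, network
and training loop — is implemented correctly and that the inverse
problem is solvable under its own forward model; it does not certify
accuracy on measured spectra from any particular spectrometer.

Known accuracy structure on held-out synthetic data mirrors what one
expects physically: hard, isolated lines (Fe Kα, Sr Kα) are recovered
best; the 3–5 keV region (K, Ca, Ti) suffers from strong matrix
absorption, transmission-randomization leverage and mutual overlaps;
Ba is hardest of the common elements because its Kα lies outside the
sensitive band and its L lines coincide with Ti Kα to within the
detector resolution.

## 8. Problem sizes

The test suite trains the default model on 5 000 synthetic profiles and
evaluates on 500 held-out profiles — the package's desk-scale study
condition, sized for a single CPU.  Larger corpora (the generator
produces ~60 profiles/s) improve the concentration medians further; the
trend with training-set size is monotone in our experiments.
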