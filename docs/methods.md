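# Methods

This note records the modelling choices, parameter provenance, numerical
conventions and known limitations of `respdose`.

## Deposition model

The respiratory tract is modelled as nine filters in series: ET1, ET2, BB,
bb, AI on inhalation and bb, BB, ET2, ET1 on exhalation. The fraction of
inhaled air reaching each stage (volumetric factor φ) is derived from the
anatomical dead spaces (ET 50 cm³, BB 49 cm³, bb 47 cm³) and the tidal
volume of the active breathing pattern. Stage deposition follows the
standard recursion `DE_j = DE_{j−1} η_j (φ_j/φ_{j−1})(1/η_{j−1} − 1)` with
`DE₁ = φ₁η₁`; internally the algebraically equivalent escape-fraction form
`A_j = φ_j ∏_{k<j}(1 − η_k)`, `DE_j = A_j η_j` is evaluated so that a zero
upstream efficiency needs no special case. Exhaled activity is the residual
`inhalable − Σ DE_j`, which the telescoping form guarantees is non-negative;
deposited + exhaled + not-inhaled therefore sums to exactly one.

Each regional filter combines an aerodynamic efficiency (inertial impaction,
argument `d_ae²·V̇`; gravitational settling, argument `d_ae²·t`) and a
thermodynamic efficiency (diffusion, argument `D(d_th)·t`) in quadrature,
`η = √(η_ae² + η_th²)`, the convention of the source deposition model. The
functional forms are `1 − (1 + aRᵖ)⁻¹` for the extrathoracic filters and
`1 − exp(−aRᵖ)` for the thoracic ones. The extrathoracic aerodynamic
constants (3.0×10⁻⁴, p = 1 for ET1; 5.5×10⁻⁵, p = 1.17 for ET2, on
`d_ae²·V̇` in µm²·cm³·s⁻¹) follow the widely reproduced empirical fits; the
thoracic and thermodynamic constants are package-adopted representative
values of the same family, chosen once from physical magnitudes (settling
velocity over airway calibre, Brownian diffusivity over residence time) and
frozen — they are data with provenance strings, never code. The resulting
total-deposition curve is U-shaped with the expected magnitudes (≈ 0.31 at
0.3 µm, 0.84 at 5 µm, 0.67 at 20 µm for the reference worker) but is *not*
a digit-for-digit reproduction of the published reference tables, which
would require the externally distributed constant set; the benchmark
harness (`benchmark_deposition`, RD%/AD) accepts any externally transcribed
reference table, and the bundled comparison table is this package's own
frozen curve, labelled synthetic.

Aerodynamic ↔ thermodynamic diameters are converted through the
slip-corrected relation `(ρ/χ) d_th² C(d_th) = d_ae² C(d_ae)` (Cunningham
correction, mean free path 0.0712 µm) solved by fixed-point iteration.
Defaults: particle density 3 g/cm³, shape factor 1.5, aerosol GSD 2.5 — the
occupational defaults; only the 5 µm AMAD is scenario-specific. The
reference worker mixes sitting (0.54 m³/h, ⅓ of the shift) and light
exercise (1.5 m³/h, ⅔), weighted by the fraction of air breathed
(0.153/0.847); `Fn` is the nose-breathing fraction, with the oral path
bypassing the anterior-nose filter and using a weaker oral impaction fit.
After filtering, 65% of the anterior-nose filter deposit stays in ET1 and
35% is reassigned to ET2 (extrathoracic redistribution of the updated
model). Uncertainty multipliers scale the fitting parameters `a` of both
passes (inhalation and exhalation) of a region — one multiplier per
region/component.

Polydisperse integration uses Gauss–Hermite quadrature in ln d with 64
nodes, with one node-doubling refinement check (tolerance 1e−6 per
component; violation raises). A quirk inherited from the literal recursion:
because φ rises again on the exhalation pass, dead-space air rejoins at the
deeper stream's concentration, so deposition is not perfectly monotone in
the efficiencies (relative effects ~1e−8); documented, not corrected.

## Biokinetics

Compartments: the nine deposit compartments plus LNET/LNTH, oesophagus,
lumped gut, blood (iodide and organic), thyroid (trapped iodide and organic),
salivary glands, stomach wall, other tissue, urinary bladder contents, and
the environment/excreta sinks. Particle-transport rates are the reference
values of the updated respiratory-tract model; Type F dissolution is a
single fast rate (30 d⁻¹, complete fractional uptake) from every
particle-bearing compartment except ET1. The alimentary tract is lumped:
oesophagus → gut at 720 d⁻¹ and competing gut rates `6·fA/(1−fA)` to blood
vs 6 d⁻¹ onward (fA = 0.99 for iodine), the small-intestine convention; a
full alimentary-tract model is out of scope. The systemic iodine rates are
transcribed at reduced granularity from the published physiological iodine
model (blood iodide clearance 32.9 d⁻¹ split 7.26 thyroid / 11.84 urine /
5.16 salivary / 8.60 stomach wall; organification 95 d⁻¹ against a 36 d⁻¹
leak; hormone secretion 0.0077 d⁻¹; deiodination 1.32 d⁻¹). The source
papers do not print the exact rate set used alongside the reconstructed
figures, so these tables are this package's transcription; they are CSVs
with per-entry provenance and can be replaced wholesale.

Radioactive decay (`λ = ln2/8.0252 d⁻¹`) is added uniformly to every
diagonal, including the sinks — which makes the identity
`e^{+λt} x(t) ≡ x_{λ=0}(t)` exact and testable. The eight correlated
transport routes (ET1→ET2′, ET1→Env, ETseq→LNET, ET2′→oesophagus,
BBseq→LNTH, BB′→ET2′, bbseq→LNTH, bb′→BB′) are scaled by one factor `Kpt`;
the three alveolar-interstitial rates are replaced, not scaled, by their
sampled values.

Retention is solved in closed form via eigendecomposition; the commitment
integral uses `∫₀^τ e^{λt} dt = expm1(λτ)/λ` in eigenspace. When any
relative eigenvalue gap falls below 1e−10 the solver switches to the
scaled-and-squared matrix exponential (per time point for retention; an
augmented-matrix exponential `[[A,0],[I,0]]` for the integral, which is
exact rather than quadrature-based). The full coupled system *always* takes
this branch: the twin sequestration compartments and the two sinks make
repeated eigenvalues structural, so the fallback is the normal path there
and runs silently. Commitment period: 50 y = 18 262.5 d (365.25 d/y).
Negative round-off below −1e−9 triggers a warning; smaller is clipped.

Source regions aggregate compartments through a bundled mapping (e.g.
BB′+BBseq → bronchial source, thyroid pools → thyroid); excretion-path
contents (gut, bladder) are retained as sources, configurable via the
mapping CSV.

## Dosimetry

`h(T) = Σ_S U_S · 86 400 · S_w(T←S)` — the single unit conversion from
Bq·d to nuclear transformations lives in one named constant. Effective dose
averages the sexes and weights with the bundled w_T table (15 tissues,
remainder as one pseudo-tissue, Σw_T = 1). S-coefficient uncertainty is
deliberately out of scope. The synthetic S-table generator draws lognormal
values around a magnitude (default 1e−15 Sv per transformation) with a ×50
boost on self-irradiation terms — the qualitative signature of a
short-range emitter — and is a pure function of its seed. It emulates the
*structure* of real S-tables, not their values: absolute dose coefficients
computed with it are on an arbitrary scale, and conclusions that depend on
the relative weighting of source regions (notably which deposition
parameter ranks second in the sensitivity analysis) do not transfer from
synthetic to real tables. What the passing tests show is that the chain,
given correct S-coefficients, computes the corresponding dose coefficients;
with realistic iodine S magnitudes the chain reproduces the published order
of 1e−8 Sv/Bq.

## Uncertainty analysis

The 18-parameter catalogue binds each distribution to its model slot.
Lognormals are parameterised (GM, GSD); table entries labelled "mean" 1.00
are read as geometric means, consistent with the stated "GMs of one".
Deposition-multiplier GSDs equal √c_i of the bundled scaling constants (a
cross-checked identity in the tests). `Fn` is right-angled triangular
(0.4, 1, 1), inverted through `F(x) = (x−min)²/((max−min)(mode−min))`.
Latin-hypercube sampling permutes stratum order per column and draws
uniformly within each stratum (not midpoints); stratification is exact for
every n and seed. No correlation structure is imposed across columns — the
correlated transport rates are correlated *through* `Kpt` by construction.
A degenerate "fixed" family exists so neutral point-mass designs can
reproduce the deterministic chain bit-for-bit in tests.

The sample-size helper implements `n = ⌈(z·sd/E)²⌉` for a mean-precision
target. Summaries use the n−1 SD and linear-interpolation percentiles (the
convention matters in the fourth digit of Q_L/Q_U). Distribution fitting
ranks maximum-likelihood fits of a candidate family list (default: norm,
lognorm, gamma, loggamma, beta, weibull_min, triang, uniform) by the
one-sample two-sided K–S statistic, with p > 0.05 required of an accepted
best fit. Two caveats are inherent to this procedure and documented rather
than patched: fitting parameters on the same sample biases the K–S p-value
upward, and flexible three-parameter families that nest simpler shapes
(lognorm/gamma/loggamma vs normal) can attain marginally smaller D on data
generated from the simpler family — so "best family" is meaningful only up
to such nesting. The uncertainty factor is `max(C/Q_L, Q_U/C)`, reported to
two decimals, scale-invariant, with the deterministic coefficient as the
default central estimate.

## Sensitivity analysis

The response is min–max scaled to [0,1] (stored extrema make the inverse
exact). A random-forest regression surrogate is grid-searched over tree
counts {50, 100, 150, 200, 300} on a seeded 75/25 split by held-out RMSE
(ties → fewer trees), depth unlimited so leaves are pure. Impurity (Gini)
importances are the normalised ranking; Shapley attributions use the exact
polynomial-time tree-path algorithm implemented in `_treeshap.py` — feature
coalitions absent from the conditioning set are marginalised by training
coverage, local accuracy (base + Σφ = prediction) holds to machine
precision, and single-tree attributions equal brute-force coalition
enumeration exactly (tested). Attribution cost is O(leaves·depth²) per
sample and tree, so pipeline runs cap the number of explained rows
(`explain_limit`, default 256); importances always use the full sample.

## Problem sizes and reproducibility

Default stochastic runs in the examples and test suite use n = 200–1000
design rows, chosen as the package's own desk-scale working sizes; the
propagation loop evaluates roughly 110 rows/s on one core, so the full
n = 10 000 analysis is a matter of minutes. One global seed expands into
named per-stage child seeds (s_table, lhs, sensitivity) via a CRC-keyed
seed sequence, so any stage can be rerun in isolation; identical
configuration and seed reproduce every output checksum.

## Known limitations

- Deposition constants are a faithful-in-form, package-adopted transcription;
  digit-level agreement with published reference deposition tables requires
  substituting the externally distributed constant set (drop-in CSV).
- The systemic iodine model is reduced-granularity; organ-level dose detail
  beyond the bundled source regions is outside scope.
- Only absorption Type F and the reference-worker scenario are modelled;
  no age/sex airway scaling, hygroscopic growth, or progeny ingrowth.
- The alimentary tract is a two-compartment lump; doses to alimentary
  segments other than the lumped contents are not resolved.
- Best-fit family identification is subject to the nested-family caveat
  above; ranking by K–S D follows the stated procedure.
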