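# Methods

`oxanox` models regime shifts between oxic and anoxic states of a microbial
ecosystem, and provides the data-analysis stages used to look for the same
signatures (hysteresis in stratification–oxygen space, mutual exclusion of
functional groups) in lake monitoring data. This note records the model, the
numerical choices, what the synthetic data do and do not emulate, and known
limitations.

## The ecosystem model

A well-mixed box contains three bacterial functional groups — cyanobacteria
(CB, oxygenic phototrophs), phototrophic sulfur bacteria (PB, anoxygenic
phototrophs oxidizing sulfide) and sulfate-reducing bacteria (SB) — and four
substrates: oxidized sulfur S_O, reduced sulfur S_R, oxygen O and
phosphorus P. Units: cells L⁻¹, μM, hours.

Population dynamics (j ∈ {CB, PB, SB}):

    dN_j/dt = g_j(·) h_j(·) N_j − m_j N_j

with Monod growth, multiplicative when two substrates limit,

    g_j(X, Y) = g_max,j · X/(K_{j,X}+X) · Y/(K_{j,Y}+Y),

and Haldane inhibition

    h_j(X) = 1 / (1 + X/H_{j,X}),

which halves the growth rate at X = H. CB grows on P and is inhibited by
S_R; PB grows on P and S_R and is inhibited by O; SB grows on P and S_O and
is inhibited by O. Substrate dynamics couple the populations through yields
y (cells per μmole): PB oxidizes S_R to S_O, SB reduces S_O to S_R, CB
produces oxygen at p_CB μmole per cell of realized growth, reduced sulfur is
abiotically oxidized at rate c·O·S_R (consuming one O per S_R), and every
substrate exchanges diffusively with a background concentration at rate
α_X(X_b − X). The oxygen diffusivity α_O is the control parameter: it mimics
turbulent mixing across a thermocline (small when strongly stratified, large
when mixed).

The reciprocal inhibition (sulfide suppresses the oxygen producer; oxygen
suppresses the sulfide producers) is the feedback that creates alternative
stable states: an oxic state dominated by CB and an anoxic state carried by
SB, alone or in coexistence with PB.

### Default parameter set (calibrated, not published)

The shipped defaults (`oxanox.default_parameters()`) are **calibrated**
values, not a published table: magnitudes were chosen in ranges typical of
freshwater-lake microbial communities (maximum growth rates 0.05–0.1 h⁻¹,
μM-scale phosphorus half-saturations, 10⁷–10⁸ cells per μmole sulfur yields,
~10⁸ cells per μmole phosphorus yields, backgrounds of 300 μM for both
sulfur pools and oxygen) and then tuned so that the model is bistable at
P_b = 9.5 μM with α_O = 8×10⁻⁴ h⁻¹ inside the bistable window. The only
parameter adjusted during calibration was the CB phosphorus half-saturation
(K_CB_P = 0.5 μM, equal to the PB/SB values): with a smaller value CB drew
phosphorus so low in the oxic state that SB was phosphorus-excluded at every
oxygen diffusivity and the oxic branch never lost stability (no lower
tipping point). At the defaults the tipping points bracket
[T2, T1] ≈ [4×10⁻⁴, 2×10⁻³] h⁻¹, the anoxic state at 8×10⁻⁴ h⁻¹ is the
SB+PB coexistence form, an SB-only anoxic form appears at intermediate
diffusivity (abiotic oxidation diverts reduced sulfur from PB while
resupplying SB), and the bistable region widens with background phosphorus.

## Numerics

* **Integrators.** A fixed-step classic RK4 scheme (step chosen by a
  stability pre-check from the fastest linear rate, ≤1 h at defaults) and a
  stiff-capable adaptive scheme (LSODA, rtol 10⁻⁸, population atol 10⁻⁶
  cells L⁻¹, substrate atol 10⁻⁹ μM) sit behind one interface; they agree to
  10⁻⁴ relative at defaults. The adaptive scheme is the default because
  steady-state searches cover up to 10⁶ h.
* **Negative excursions.** Neither scheme guarantees positivity; components
  whose negative magnitude is below 10⁻⁹ of the state scale are clipped to
  zero, anything larger aborts with an error (silent clipping of large
  negatives would mask step-size bugs).
* **Steady-state criterion.** max_i |dx_i/dt| / (|x_i| + s_i) < 10⁻⁸ with
  scales s_i of 1 cell L⁻¹ for populations and 10⁻³ μM for substrates;
  integration proceeds in doubling chunks (2×10³ → 2.56×10⁵ h) up to
  t_max = 10⁶ h. Near transcritical boundaries relaxation times reach
  ~7×10⁵ h, hence the large default t_max. Non-convergence is reported via a
  flag, never an exception.
* **Extinction threshold.** A population below 1 cell L⁻¹ counts as
  collapsed for classification. Steady states are classified by community
  composition: oxic (CB only), anoxic SB-only, anoxic SB+PB, collapsed, or
  "other" (reported as such, never relabelled).
* **Continuation with an inoculum.** Branches are tracked by reseeding each
  control step from the previous equilibrium, with every population topped
  up to an inoculum of 10 cells L⁻¹. The inoculum is essential: a population
  that decays to numerical zero could otherwise never re-invade, and the
  tracker would follow "ghost" states that a single immigrant cell would
  overturn. With the inoculum, branch termination is an invasibility test.
  Termination is judged on the coarse oxic/anoxic regime by default, so the
  interior hand-off between the SB-only and SB+PB anoxic forms does not end
  the anoxic branch; exact-class tracking is available.
* **Tipping points.** T1 = last control value where the anoxic branch
  (tracked under increasing α_O) persists; T2 = the analogue for the oxic
  branch tracked downward; hysteresis width T1 − T2, with a no-bistability
  flag when the branches are the same regime or the width is not positive.
* **Regime map.** For each background-phosphorus value an increasing sweep
  seeded from an anoxic community and a decreasing sweep seeded from an oxic
  community are run across the α_O grid (log-spaced in α_O, linear in P_b);
  each cell is labelled from the two outcomes. At exact borders the
  increasing-sweep outcome decides — a documented, reproducible tie-break.
  Unconverged cells are labelled "other". The brute-force oracle
  (`attractor_census`) relaxes many starts per cell and stabilizes each
  outcome against invasion before counting it as an attractor.
* **Separatrix.** Log-scale bisection over the initial CB density with the
  other initial conditions fixed, to 5% relative tolerance, erroring when
  both bracket endpoints reach the same attractor.

## Stratification analysis

* **Density.** Thiesen–Scheel–Diesselhorst pure-water polynomial
  ρ(T) = 1000·[1 − (T+288.9414)/(508929.2·(T+68.12963))·(T−3.9863)²]
  kg m⁻³ (maximum density at 3.9863 °C); salinity corrections are out of
  scope for a freshwater lake. Valid on −2…40 °C; outside, a warning is
  issued and the polynomial still evaluated.
* **Buoyancy frequency.** N² = (g/ρ)·dρ/dz with g = 9.8 m s⁻², centered
  finite differences in the interior and one-sided at the boundaries, depth
  positive downward. The thermocline is the depth of the steepest density
  gradient — the natural algorithmic reading of "at the thermocline".
  Density inversions give negative N², which is flagged, never silently
  zeroed.
* **Mixing proxy.** Vertical eddy diffusivity scales as 1/N² (K_z = Γε/N²
  with mixing efficiency Γ and dissipation ε, neither of which is measured
  here), so 1/N² serves as a simple oxygen-diffusivity proxy. N² is floored
  at 10⁻⁶ s⁻² so a fully mixed profile maps to a large finite proxy; capped
  values are flagged.
* **Oxygen saturation.** Benson–Krause equilibrium concentration of
  air-saturated fresh water at standard pressure (USGS coefficient set,
  recorded as a swappable constant table), converted to μM with the O₂
  molar mass; percent saturation is 100·O/O_sat(T).
* **Hysteresis loop.** For each profile, the mixing proxy (thermocline N²)
  is paired with the oxygen saturation at a fixed hypolimnion depth (nearest
  sampled depth; warning beyond 0.5 m). The loop statistic is the shoelace
  signed area of the closed time-ordered polygon in (log₁₀ proxy, %sat)
  coordinates — the log axis because the proxy spans orders of magnitude; a
  retracing path has zero area in any monotone axis transform. Positive area
  means the breakdown limb is oxygen-poorer than the stratifying limb at the
  same mixing intensity (the regime-shift signature). A second statistic,
  the phase separation, interpolates both limbs (split at peak
  stratification, capped points excluded) onto a common proxy grid and
  reports the mean saturation difference.

## Co-occurrence network

A simplified, documented re-implementation of the ensemble idea used by
CoNet-style tools — not a bit-compatible clone; the exact ensemble merging
and permutation internals of those tools are not public in sufficient
detail.

* **Functional groups.** CB: phylum Cyanobacteria. PB: phylum Chlorobi or
  order Chromatiales. SB: orders Desulfobacterales, Desulfuromonadales,
  Desulfovibrionales. Everything else (including unparseable taxonomy
  strings, with a warning): OTHER.
* **Scores.** Spearman rank correlation (average ranks on ties) and
  symmetrized Kullback–Leibler dissimilarity (vectors shifted by a 0.5-count
  pseudocount, normalized to distributions over samples) of the pair's
  relative abundances.
* **Permutation null.** One taxon's counts are shuffled across samples;
  sample totals are then recomputed and both taxa's relative abundances
  renormalized before rescoring — the compositional guard that
  renormalization-style ("ReBoot") procedures use, in simplified form.
  Two-sided empirical p-values with the (b+1)/(n+1) correction; each pair
  draws from an independent stream spawned from the user's seed (mandatory
  for the CLI). A table containing only the scored pair carries no
  compositional context — closure would force ρ = −1 under every
  permutation — so two-taxon tables are scored on raw counts.
* **Merging.** The two p-values are combined with the maximum (intersection
  test: both scores must be individually extreme). Fisher's combination is
  available but is not the default: the two p-values are computed from the
  same data and are strongly positively dependent under the null, and in a
  calibration experiment (100 null tables, 20 taxa × 24 samples, 1000
  permutations, BH at 5%) Fisher merging produced at least one false edge on
  41/100 tables versus 0/100 for the maximum, while the maximum still
  recovered 120/120 planted edges. The max-p rule is valid under arbitrary
  dependence at the cost of conservatism.
* **FDR and signs.** Benjamini–Hochberg at the requested rate (default 5%)
  on the merged p-values; surviving edges are signed by the Spearman
  correlation. Constant taxa are excluded (undefined scores).

## Synthetic data

The generators produce desk-scale stand-ins for one year of biweekly
monitoring of a small, seasonally stratified, eutrophic temperate lake
(11 depths over 0–10 m, ~27 dates, stratified early May to early November).

* **Profiles.** Temperature is a logistic two-layer structure whose
  epilimnion follows a sinusoidal annual cycle (winter 4 °C, peak 22 °C,
  hypolimnion 7 °C, thermocline 5 m) with the layer contrast tapering to
  zero at onset and breakdown; measurement noise is Gaussian (0.05 °C,
  1% on O₂). Hypolimnetic oxygen saturation during stratification is
  100·exp(−0.2·ΔT) percent with ΔT the layer contrast — a pure function of
  stratification strength, so an `oxic`-turnover year retraces its path in
  (1/N², %sat) space. An `anoxic`-turnover year engages a latch once
  saturation first reaches 8%: the hypolimnion, and after breakdown the
  whole mixed column, stays at 8% until a late-winter recovery date,
  opening a loop of the planted (positive) orientation.
* **Community.** A smooth latent stratified-anoxic indicator s(t) drives
  log-abundances: CB ∝ exp(a(1−2s)), PB and SB ∝ exp(a(2s−1)) with default
  amplitude a = 2 (an e⁴ ≈ 55-fold seasonal contrast, comparable to the
  near-complete turnover seen in such lakes); remaining taxa are independent
  lognormal noise. Counts are negative-binomial (gamma–Poisson, shape 5)
  around proportional means at a 2×10⁴ sequencing depth — the standard
  overdispersed stand-in for amplicon count data. Taxonomy strings are
  assigned so the functional-group mapper recovers the planted groups.
* **Parameter jitter.** Independent lognormal factors on every positive
  parameter, for robustness experiments.

What the generators do **not** emulate: vertical chemistry profiles coupled
to the ODE model, depth-dependent community composition, irregular sampling,
detection limits, taxonomic mis-annotation, or any fit to real lake
measurements. Passing tests on these data therefore demonstrate that the
analysis stages recover structure that is genuinely present at realistic
magnitudes and noise levels — not that real lakes behave this way.

## Problem sizes used by the test suite

Simulation-heavy checks run at sizes chosen for a laptop-class machine: the
transcription and sulfur-closure oracles use 1000 random states; the 1D
continuation uses 100 log-spaced control steps; the regime map is 20×20
cells with a 5-start invasion-stabilized census per cell (the map itself is
resolution-configurable); network calibration uses 100 null tables and
power uses 5 planted tables at 1000 permutations (4000 is the analysis
default).

## Known limitations

* The parameter set is calibrated to reproduce the qualitative regime
  structure, not fitted to measurements; absolute tipping-point values and
  basin boundaries are illustrative. In particular, along the standard
  initial-condition line used for separatrix scans (dense anaerobes,
  sulfidic, 150 μM O₂), the oxic basin is gated by a phosphorus pre-emption
  race and the threshold CB density at defaults is ~10⁹ cells L⁻¹ — the
  separatrix exists and behaves correctly, but its absolute position is a
  property of the calibrated set.
* The box model has no light dependence, no depth resolution, no nitrogen
  or iron chemistry, and no biotic oxygen consumption other than the
  sulfide sink; "oxic" and "anoxic" are community-composition labels.
* Stability of tracked equilibria is established by simulation (perturb and
  relax), not by eigenvalue analysis; periodic or chaotic attractors would
  appear as non-convergence, not be characterized.
* The network stage approximates, and is not numerically interchangeable
  with, the CoNet/ReBoot ensemble; its merged p-values are conservative by
  design.
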