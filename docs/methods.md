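# Methods

## The model

One MnmE dimer is treated as a single cooperative unit whose G-domain
pair traverses an irreversible chain: nucleotide binding, G-domain
dimerization (closing), GTP hydrolysis inside the closed dimer, dimer
dissociation (opening), and Pi release.  Per-protomer behaviour is not
resolved — the observed transients are mono- or biphasic, which a single
cooperative unit reproduces; modelling two semi-independent protomers
would add parameters no observable constrains.

State variables (µM): free nucleotide `T_free`; open apo enzyme `E_apo`;
dead-end inhibitor complexes `E_I`; open GTP-bound `E_T`; closed dimer
with GTP `D_T`; closed dimer with GDP·Pi `D_P`; open dimer still holding
GDP·Pi `E_DP` (populated only when release is slower than opening); open
GDP-bound `E_D`; free products `Pi_free`, `GDP_free`.

**Binding.**  Measured k_obs follows the saturating law
k_obs = k_max·[E]/(K_D + [E]): a rapid-equilibrium encounter (K_D)
followed by an isomerization (k_max).  The simulator integrates the flux
dT/dt = −k_max·E_avail/(K_D + E_avail)·[T] with the free enzyme
co-consumed.  This collapses exactly onto the hyperbolic law under
enzyme excess (the property the Bateman cross-check asserts to 1e-6) and
remains well-defined for equimolar mixing, where a literal
pseudo-first-order treatment would not be.  One consequence worth
knowing: at equimolar concentrations the binding tail is second order
and approaches completion algebraically, not exponentially.  A
`pseudo_first_order_binding` switch applies k_max directly as a
first-order rate; the panel pipeline uses it with each construct's
printed apparent k1, because that number is itself an apparent rate
measured at 2.5 µM and sits ~12% above the titration hyperbola's
prediction there (both values are retained in the fixtures; they come
from different experiments and the package does not force them to
agree).

**Hydrolysis, dissociation, release.**  First-order steps k3 (hydrolysis,
Pi-sensitive, see below), k4 (dissociation).  By default Pi and GDP
release are concerted with opening (`k_pi_rel = inf`): the closed dimer
buries the nucleotide, and products leave as the dimer is undone.  A
finite `k_pi_rel` inserts the `E_DP` intermediate; the panel uses it for
the release-defective variants, identified as k5 < 0.5·k4 (L274G, L274A,
G285A, D253A, R288A).  GDP stays bound under single-turnover conditions
(its ~0.5 µM affinity is 10-fold below the post-hydrolysis GDP level);
the FRET chase is therefore modelled analytically: after competitor
addition the signal decays at the exchange-limited off-rate
(~300 min⁻¹) with amplitude comp/(comp + w), w defaulting to the
released-mGDP pool — rate independent of competitor, amplitude
saturating with it.

**Product inhibition.**  GDP sequesters open apo enzyme in a dead-end
complex, scaling the bindable pool by 1/(1+[GDP]/K_IE_gdp).  Pi scales
the bindable pool by 1/(1+[Pi]/K_IE_pi) and hydrolysis by
1/(1+[Pi]/K_IES_pi).  Inhibitor pools are treated as buffered (µM-scale
turnover against mM-scale inhibitor); released Pi is added to the
context Pi.  Above 2 mM Pi the simulator warns that dissociation of
GTP-containing dimers can contribute fluorescence the model ignores.

**Observables.**  Signals are linear in nucleotide fractions
(concentration/t0).  Default mant coefficients 0 / 0.095 / 0.15 / 0.15 /
0.10 for apo, E_T, D_T, D_P, E_D encode that hydrolysis produces no
fluorescence change — hence the silent lag between the fluorescence peak
and the decay, and the decay reporting dissociation only.  Quench
projects 100·(T_free+E_T+D_T)/t0 (% uncleaved GTP); the Pi sensor is
treated as instantaneous and non-depleting (its finite on-rate and
capacity are a documented simplification).  Rates are stored in min⁻¹,
time grids in seconds; the single 1/60 conversion lives in the cycle
module.

## Numerical choices

LSODA with rtol 1e-9 / atol 1e-12; enzyme and γ-phosphate mass are
checked to 1e-6 relative after every run and violations raise.  The
Bateman closed form requires pairwise-distinct rates (1e-9 relative);
near-degenerate chains either raise or, with `perturb=True`, are
perturbed by 1e-6 relative with a warning.  All exponential fits start
from a log-spaced rate grid (1e-1–1e5 min⁻¹) with linear parameters
profiled out, then refine by Levenberg–Marquardt — no user-supplied
starting values, stable across the four decades of rates in the panel.
Double-exponential phases are labelled by magnitude (k_fast ≥ k_slow);
when they separate by less than 3-fold the fit is compared against a
single exponential by AIC and the simpler model returned if preferred.

## Synthetic data and noise

Additive i.i.d. Gaussian noise; replicate r of seed s uses generator
seed s+r, so every dataset is bit-reproducible.  Defaults (the study
conditions): optical traces 10 ms sampling, sd 0.003
relative-fluorescence units, 6 averaged replicates, 2 ms dead time
trimmed; quench-flow 2% relative noise on 12 points; k_obs titrations 5%
relative on 8 concentrations (0.5–50 µM); initial-rate grids 3%
relative.  The quench grid places its first quenched point at 0.4 s,
past the binding/dimerization transient at 50 µM, so the sampled decay
isolates hydrolysis; the t=0 point is the 100% normalization control.
Binding-phase traces for rate recovery are sampled at 1 ms (a
3528 min⁻¹ phase has a 17 ms time constant; 10 ms sampling cannot
resolve it).  The generators emulate noise and replicate structure only
— no photobleaching, mixing artefacts or drift — so passing recovery
tests demonstrates estimator correctness under the stated noise model,
not robustness to real instrument pathology.

## Fitting windows and known biases

The biphasic rise is fitted on 0–0.2 s by the pipeline (stretched to 2.4
dimerization time constants for slow-dimerizing variants): the
double-exponential model neglects the slow dissociation leak, whose
contribution grows with the window and biases both rates by ~+10% at
0.5 s.  The dissociation decay is fitted after the hydrolysis lag
(1.2–17 s default in the pipeline); at the figure-convention window
(0.5–17 s, available as `fitting.DISSOCIATION_WINDOW`) the composite
lag depresses the recovered rate by ~3%.  The quench one-phase decay
uses a free initial value (the instrument-software convention): with an
upstream dimerization only 3.6-fold faster than hydrolysis, the decay's
back-extrapolated intercept is ~139%, and pinning it to 100% would bias
the rate by ~40%.  For variants whose hydrolysis is less than 3-fold
faster than dissociation the decay phase is composite; the fitted k4 is
reported as-is with a warning, as no correction formula exists.

## Inhibition analysis

Dixon (1/v vs [I]) and Cornish–Bowden ([S]/v vs [I]) constants are read
from the least-squares common intersection of the lines, computed as a
constrained simultaneous fit: all lines forced through one point
(x0, y0), inverse-variance weights (1/y², matching relative rate noise),
x0 profiled and its standard error taken from the profile curvature.  On
noiseless model-generated grids the intersection lands exactly at −K_IE
(Dixon, competitive/mixed) or −K_IES (Cornish–Bowden, mixed) — an
analytic property of the rate laws used as an oracle in the tests.  A
naive "intersect fitted line pairs" estimator suffers severe regression
dilution here, because the [S]/v slopes at 2.5–7.5 µM substrate differ
by only ~6% while 3% rate noise perturbs each slope by a comparable
amount; K_IES is intrinsically a low-information estimand at these
conditions.  Accordingly single-grid K_IES estimates scatter widely
(IQR ≈ ±40%), grids whose noisy slopes fall within the 5% parallel
guard are reported as unbounded, and summaries use the median over many
seeded grids with unbounded estimates entered as +inf (dropping them
would censor only the high tail).  A global log-residual fit of the full
rate law — the maximum-likelihood estimator under multiplicative noise —
is reported alongside as a cross-check, never as the primary value.

Classification: apparent Km rising with inhibitor (Spearman ρ ≥ 0.7,
tolerating one noise-induced rank swap, plus a >1.3-fold overall
increase) and kcat falling by >25% is mixed; Km rising with kcat held or
drifting up is competitive (the GDP series' kcat drifts *up* ~50% while
Km quadruples — a drop threshold, not a symmetric variation threshold,
is what separates the patterns); kcat falling alone is uncompetitive.

IC50 for a competitive inhibitor is K_IE·(1 + [S]/Km).  For a mixed
inhibitor the conventional shorthand is ambiguous; the implementation
evaluates K_IE / ((Km/[S]) + (K_IE/K_IES)) and also returns the textbook
([S]+Km)/(Km/K_IE + [S]/K_IES) for comparison.  `fraction_inhibited`
defines the competitive fraction as the equilibrium dead-end occupancy
(i/K_IE)/(1 + i/K_IE + s/Km) and the mixed fraction as the rate
reduction 1 − v(i)/v(0); these are the package's own definitions, stated
here because more than one reading is defensible.

Percentages in reports round half away from zero; two printed
percent-inhibition values in the reference panel (GTP binding at the
highest GDP and Pi levels) differ from this arithmetic by one point and
are left as source discrepancies.

## Problem sizes

Recovery summaries use medians over 41 seeded datasets (101 for K_IES,
whose single-grid scatter is largest); traces are 1,700 points (10 ms ×
17 s) or 500 points (1 ms × 0.5 s); quench-flow datasets 12 points;
titrations 8 concentrations; inhibition grids 3×5 or 5×5.  These sizes
match the experimental designs they emulate and keep a full panel run
under a minute on one CPU.

## Limitations

Potassium dependence is a boolean (NaCl mode: k_dim = 0), multi-turnover
behaviour is reduced to the steady-state rate law, the Pi sensor is
ideal, tight-binding and slow-onset inhibition are out of scope, and the
chase partition weight is a one-parameter surrogate for a full
rebinding-competition model.  Printed panel constants for the variants
are apparent rates; simulating a variant reproduces the chain those
rates imply, not per-residue structural mechanism.
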