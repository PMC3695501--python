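# mnmekin

Single-turnover kinetic modelling and inference for the GTPase cycle of
MnmE, the homodimeric G protein that drives wobble-uridine tRNA
modification in bacteria.

MnmE is unusual among GTPases: its two G domains dimerize *in cis* upon
GTP and potassium binding, hydrolyse GTP inside the closed dimer, and the
physical re-opening of the dimer — not the chemistry — limits the cycle.
`mnmekin` encodes that five-step cycle,

```
            k1 (k_max, K_D)      k2           k3           k4          k5
E_apo + GTP ───────────────► E·GTP ──► D·GTP ──► D·GDP·Pi ──► E·GDP + Pi
   binding                   dimerization  hydrolysis   dissociation  release
```

with competitive product inhibition by GDP (dead-end complex with the
open enzyme, constant K_IE) and mixed inhibition by inorganic phosphate
(K_IE toward free enzyme, K_IES toward the enzyme–substrate complex).
On top of the mechanistic core it provides:

* **simulation** — stiff-safe ODE integration of the cycle with true
  second-order binding (valid for equimolar stopped-flow mixing), a
  Bateman closed form for the pseudo-first-order chain as an analytic
  cross-check, and projections onto the four instrument channels
  (mant fluorescence, tryptophan–mant FRET, MDCC–PBP phosphate sensor,
  quench-flow % uncleaved GTP);
* **synthetic data** — seeded generators reproducing the statistical
  structure of the experiments: replicate-averaged 10-ms optical traces,
  log-spaced quench-flow points, k_obs titrations, and initial-rate
  grids over [substrate] × [inhibitor];
* **inference** — single/double-exponential and one-phase-decay fits
  (grid-search initialised, rates in min⁻¹), the hyperbolic titration fit
  k_obs = k_max·[E]/(K_D+[E]), lag-phase detection, Dixon (1/v vs [I])
  and Cornish–Bowden ([S]/v vs [I]) inhibition constants via a weighted
  least-squares common-intersection estimator, inhibition-type
  classification, IC50 formulas and inhibited fractions at cellular
  nucleotide/phosphate concentrations;
* **reporting** — a pipeline that simulates a construct, refits every
  step, and emits the panel-style rate tables (k1–k5 with
  percent-of-reference columns) for the wild type and 13 catalytic-loop
  variants, plus a small `mnmekin` CLI.

## Worked example

```python
import mnmekin as mk

params = mk.wt_parameters()          # k1 law (3896, 0.60 uM), k2=717, k3=201, k4=12.4

# stopped-flow mant experiment: 2.5 uM enzyme + 2.5 uM mGTP, 6 replicates
replicates, avg = mk.generate_traces(params, channel="mant", e0=2.5, t0=2.5,
                                     noise_sd=0.003, n_replicates=6, seed=1)
decay = mk.fit_single_exponential(avg, "decay", window=(0.5, 17.0))
print(f"dissociation rate k4 = {decay['k']:.1f} +/- {decay.se('k'):.1f} min^-1")
print(f"lag before dissociation = {mk.detect_lag(avg):.2f} s")

# quench-flow hydrolysis rate at 50 uM enzyme:GTP
quench = mk.generate_quench_flow(params, noise_frac=0.02, seed=1)
hyd = mk.fit_one_phase_decay(quench)
print(f"hydrolysis rate k3 = {hyd['k']:.0f} +/- {hyd.se('k'):.0f} min^-1")

# GDP product inhibition: Dixon constant, IC50, inhibited fraction in vivo
grid = mk.generate_inhibition_grid(0.23, 30.0, 19.5, "GDP", ki_e=41.2,
                                   noise_frac=0.03, seed=1)
dixon = mk.dixon_fit(grid)
print(f"GDP inhibition constant K_IE = {dixon['K_IE']:.1f} uM")
print(f"IC50 at cellular GTP = {mk.ic50_competitive(dixon['K_IE'], 710.0, 5000.0):.0f} uM")
f = mk.fraction_inhibited("competitive", 700.0, 5000.0, 710.0, dixon["K_IE"])
print(f"fraction inhibited at 0.7 mM GDP = {f:.2f}")
```

Output:

```
dissociation rate k4 = 12.2 +/- 0.1 min^-1
lag before dissociation = 0.69 s
hydrolysis rate k3 = 203 +/- 1 min^-1
GDP inhibition constant K_IE = 40.7 uM
IC50 at cellular GTP = 327 uM
fraction inhibited at 0.7 mM GDP = 0.68
```

Reading: hydrolysis (≈200 min⁻¹) is ~16-fold faster than G-domain
dissociation (≈12 min⁻¹), which the 0.7-s silent lag between the
fluorescence peak and the decay makes visible — the dimer stays closed
while chemistry completes, so dissociation, not hydrolysis, limits the
cycle.  At cellular GTP/GDP levels roughly two thirds of the enzyme is
expected to sit in the GDP-inhibited state.

The same chain run end-to-end for a mutant panel:

```bash
mnmekin panel-report --construct wt --construct T250S --seed 3
```

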