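# cristaflux

Steady-state reaction–diffusion modeling of ADP/ATP handling inside
mitochondrial cristae, and the analysis layer that quantifies how
inner-membrane topology — crista length, branching, and the number, size
and placement of crista junctions (CJs) — modulates ATP synthase flux.

Cardiomyocyte mitochondria pack their inner membrane into dense lamellar
cristae. ADP reaches the ATP synthase only by diffusing through narrow CJ
necks into 20 nm-wide intracristal spaces, where the adenine nucleotide
translocase (ANT) imports it into the matrix. At physiological workloads
this creates standing intracristal ADP gradients, lowering matrix [ADP]
and imposing a *diffusion penalty* on ATP output. `cristaflux` is for
computational biophysicists and mitochondrial physiologists who want to
reproduce, probe or extend this analysis.

## Model

The reduced metabolic model couples three reactions on a parameterized
crista geometry:

* ANT exchange (1:1 ADP³⁻ in / ATP⁴⁻ out, driven by ψ_m = 172 mV),
* F₁F₀ ATP synthase kinetics in the well-mixed matrix pool
  (ADP_m + ATP_m = 1.16 mM conserved),
* a mass-action "surrogate kinase" cycling ATP ↔ ADP outside the matrix.

External ADP/ATP fields obey D∇²c + sources = 0 with cytosolic Dirichlet
boundaries (ATP 4.0 mM; ADP 0.0185–0.074 mM); membrane fluxes enter as
surface sources and the matrix closes the system through the global
balance Σ J_ANT dS = J_AS,total. Steady-state profiles of intracristal
ADP follow the quadratic gradient law ADP(x) = ADP₀ − a·x(L−x) with
steepness k = a·L/ADP₀, and one-CJ cristae of length L match the first
half of two-CJ cristae of length 2L (the *Rule of 2*). See
`docs/methods.md` for the full model, numerics and calibration.

## Worked example

```python
import cristaflux as cf
from cristaflux import analysis, experiments

p = cf.default_params()          # bundled calibrated parameter set

# crista-free reference: the maximum flux J_MAX at high workload
ref = cf.solve_steady_state(cf.build_no_crista_2d(h=0.004), p,
                            cf.BoundaryConditions(ADP_cyt=0.074))
print(f"J_MAX = {ref.j_AS:.1f} molecules/ms/um^2, ADP_m = {ref.ADP_m:.3f} mM")

# branched crista (trunk 0.9 um with CJs at both ends + L/3, L/4 branches)
var = experiments.variable_topology(p, L_CRIS=0.9, ADP_cyt=0.0185, h=0.004)
print(f"trunk depletion  = {100 * var['depletion_trunk']:.1f} %")
print(f"branch depletion = {100 * var['depletion_branch_quarter']:.1f} %")
```

prints

```
J_MAX = 99.8 molecules/ms/um^2, ADP_m = 0.348 mM
trunk depletion  = 59.2 %
branch depletion = 36.7 %
```

i.e. at low workload the 0.9 μm crista trunk loses ~59% of its
intracristal ADP (area under the midline profile relative to a flat
profile at the CJ-mouth concentration), while the short L/4 side branch
loses only ~37% — branching shortens effective diffusion paths. The
scoring pipeline turns 3-D flux–length curves into a whole-mitochondrion
estimate for a crista census:

```python
scores = experiments.census_pipeline(h=0.01)
# {'score_observed': 0.714, 'score_detached': 0.560, 'score_baffle': 0.845, ...}
```

— the observed-like topology runs at ~0.71 of the diffusion-free maximum,
between the all-detached (~0.56) and all-baffle (~0.85) extremes.

A command-line interface mirrors the library
(`cristaflux simulate|curves|score|census|calibrate|reproduce|convert`),
e.g. `cristaflux reproduce branching`.

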