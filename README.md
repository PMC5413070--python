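# egctools

Detection and minimal-removal correction of **energy-generating cycles
(EGCs)** in constraint-based genome-scale metabolic models.

## The problem

Flux-balance analysis (FBA) optimizes steady-state fluxes `S·v = 0` under
bounds, without thermodynamics. Many published reconstructions — especially
automatically generated ones — therefore contain cycles that charge energy
metabolites (ADP→ATP, NAD⁺→NADH, or a transmembrane proton gradient) with
**no nutrient uptake at all**. Such energy-generating cycles are
thermodynamically impossible, inflate predicted biomass yields, and corrupt
any downstream analysis of energy metabolism. `egctools` is for model
curators and pipeline builders who want to find these cycles and repair them
with the smallest possible intervention.

## The method

**Detection.** For each of 15 energy metabolites (ATP, CTP, GTP, UTP, ITP,
NADH, NADPH, FADH₂, FMNH₂, ubiquinol-8, menaquinol-8,
2-demethylmenaquinol-8, acetyl-CoA, L-glutamate, and the periplasm/cytosol
proton gradient) an irreversible *energy-dissipation reaction* (EDR) is
added, e.g. `atp + h2o → adp + pi + h` for ATP. With every exchange closed
and every internal flux clamped to `[-1, 1]` (reversible) or `[0, 1]`
(irreversible), the LP

```
max v_d   s.t.  S·v = 0,  v_i = 0 ∀ i ∈ exchanges,  clamped bounds
```

has optimum `v_d* > 0` **iff** the model contains an EGC for metabolite *d*;
under unit clamps `v_d*` is also a lower bound on the number of
non-overlapping cycles.

**Correction.** A bi-level MILP searches for the minimum-weight set of
*unidirectional* reaction deactivations (binaries `δ_y^RF`, `δ_y^RB`; a
reversible reaction contributes two independent candidates) such that

* the growth case still reaches biomass `v_Bio ≥ T_g` on rich medium, and
* the non-growth case (exchanges closed) has **zero** maximal summed
  dissipation flux.

The inner maximization is pinned to zero via LP strong duality (dual
feasibility + dual objective ≤ 0, binary–dual products linearized with
big-M), giving a single-level MILP. Every solution is independently
re-certified by re-solving the 15 detection LPs and the growth LP; removals
constrain bounds to zero and never delete reactions. A second pass can
protect ATP synthase (or any user pattern) so respiration is not sacrificed
to kill ATP cycles.

## Worked example

```python
import egctools as egc
from egctools import correct as C

model, truth = egc.make_fixture("fig6a")     # malate/Na+/H+ transporter triangle
model, _ = egc.normalize_model(model)
attached = egc.attach_default(model)         # add the 15 dissipation reactions

report = egc.detect_egc(attached)
print(report.results["ATP"].optimum)         # 0.25
print(report.results["HGRADIENT"].optimum)   # 1.0

cands = C.split_reversibles(attached, protect_atp_synthase=True)
sol = C.solve_correction(C.build_bilevel(attached, cands))
print(sorted(sol.removals))                  # [('MALt2rpp', 'forward')]
print(sol.biomass_before, sol.biomass_after) # 1000.0 1000.0
```

The transporter triangle nets one free periplasmic proton per turn
(proton-gradient optimum 1.0); ATP synthase converts four protons into one
ATP, hence the ATP optimum 0.25 under unit clamps. With the synthase
protected, the cheapest repair deactivates the export direction of the
malate symporter — growth is untouched because the cycle feeds nothing else.

The same API runs on real models: `egc.load_model("iJO1366.xml",
namespace="bigg")`, or from the shell
`egc detect MODEL.xml --report out.tsv` and
`egc correct MODEL.xml --protect-atp-synthase --out fixed.xml`.

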