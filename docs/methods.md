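# Methods

## Scope and model assumptions

`egctools` operates on constraint-based metabolic models: a stoichiometric
matrix `S` (boundary species excluded), flux bounds per reaction, one
biomass pseudo-reaction, and exchange reactions that each touch a single
non-boundary metabolite. Substrates are negative, products positive;
exchange fluxes are secretion-positive. Identifiers are passed through
verbatim — no cross-namespace translation is attempted; the namespace tag
(`bigg` / `modelseed` / `metanetx`) only selects which synonym table is used
to resolve dissipation-reaction metabolites.

Preprocessing (`normalize_model`) flips uptake-positive exchanges, zeroes a
positive lower bound on the ATP-maintenance reaction (matched per namespace
by id patterns such as `ATPM` / `rxn00062` or names containing
"maintenance"), and logs every altered bound. Models unable to produce
biomass on the rich medium are filtered before analysis. Mass/charge
imbalance is *flagged* (`check_balance`, from metabolite formulas parsed in
Hill notation) but never repaired: cycles induced by unbalanced
stoichiometry can be detected but not meaningfully removed, so balancing is
a prerequisite the user must handle upstream.

## Energy-dissipation reactions

One irreversible dissipation reaction per energy metabolite converts any
charging cycle into an internal (type-III) cycle that the detection LP can
see. The shipped stoichiometry templates are *reconstructions*: the ATP and
NADH forms (`atp + h2o -> adp + pi + h`, `nadh -> nad + h`) are the
canonical ones and the remaining thirteen follow the same pattern (NTP
hydrolysis for CTP/GTP/UTP/ITP; `XH2 -> X + 2 h` for FADH₂, FMNH₂ and the
three quinols; `accoa + h2o -> ac + coa + h`; `glu__L + h2o -> akg + nh4`;
`h[p] -> h[c]` for the proton gradient, falling back to `h[e] -> h[c]` in
two-compartment models). Users can replace all of them via a TSV catalog
(`DissipationCatalog.from_tsv`). Two deliberate choices:

* **Electron imbalance.** Redox EDRs omit the electron acceptor. A balanced
  acceptor pair could be re-reduced by internal reactions, letting the EDR
  carry flux in cycle-free models — exactly what the probe must not do.
* **Quinol set.** The three quinols are ubiquinol-8, menaquinol-8 and
  2-demethylmenaquinol-8; menaquinol is included because menaquinone-driven
  proton pumping is a documented EGC motif.

The ModelSEED `cpd…` and MetaNetX `MNXM…` synonym defaults are standard
database identifiers written from domain knowledge; treat them as editable
defaults, not authoritative mappings. An EDR whose template metabolites are
not all present has integration < 1, can carry no flux, and is reported
inactive rather than attached.

## Detection

Per target `d`: maximize `v_d` subject to `S v = 0`, all exchanges fixed to
zero, and every internal non-EDR reaction clamped to `[-1,1]`/`[0,1]`
intersected with its own bounds (EDRs keep `[0, 1000]`). Zero flux is always
feasible, so the optimum is non-negative and the LP can never be infeasible;
unboundedness is impossible through the clamp, and either outcome raises an
internal error rather than a verdict. Optima in `(0, 1e-6]` are reported as
"numerically zero" (LP solvers return 1e-9-scale noise; the `1e-6` zero
tolerance is configurable). An aggregate LP maximizing the summed
dissipation flux is provided as a one-shot pre-screen; per-target LPs are
the primary mode. Under unit clamps `v_d*` bounds the number of
non-overlapping cycles from below; note the bound can be fractional — the
malate-triangle example yields 0.25 ATP per turn because four pumped protons
make one ATP — and is reported without flooring.

`enumerate_cycle_support` re-minimizes the flux 1-norm at the fixed optimum
(dual simplex, so a vertex is returned) and reports the nonzero support —
the candidate cycle a curator should inspect.

## Correction

The outer objective minimizes the weighted count of direction removals
(uniform weights by default; per-candidate weights accepted, e.g. to
penalize removing irreversible reactions). The growth case uses the model's
own bounds with all exchanges opened to ±1000 ("maximally rich"
environment — the magnitude is a convention, configurable); the non-growth
case closes exchanges and applies the detection clamps. Both cases share one
binary per candidate direction, gating the corresponding bound via
`v ≤ ub·(1−δ)` / `v ≥ lb·(1−δ)`.

The inner requirement — the non-growth maximization of `cᵀv` over the gated
polytope equals zero — is enforced by duality: dual feasibility
`Sᵀλ + μU − μL = c`, `μ ≥ 0`, plus dual objective
`U(δ)ᵀμU − L(δ)ᵀμL ≤ 0`. Since `v = 0` is primal feasible, weak duality pins
the inner optimum at exactly zero. Products `(1−δ)·μ` are linearized with
big-M (default 1000, with `μ ∈ [0, M]`). Big-M truncation would make the
MILP *conservative* (reject feasible assignments), never unsound, and every
solution is re-certified post hoc with plain LPs; a certificate failure
raises rather than returning an uncertified solution. The test suite
additionally enumerates all binary assignments on small fixtures and checks
that the MILP's feasible set coincides exactly with the two-LP semantics.

Numerical choices: growth threshold `T_g` defaults to 1% of the unmodified
rich-medium optimum (relative or absolute, configurable; a threshold above
the optimum is rejected before solving); binaries are rounded at 0.5;
determinism among equal-weight optima comes from HiGHS being deterministic
plus a tiny index-lexicographic tie-break added to the objective (scaled so
it can never flip the primary optimum). Alternative optima are enumerated
with no-good cuts that exclude each previously returned binary pattern while
capping the objective at the incumbent value. The solver time limit defaults
to 3600 s; on timeout the incumbent is returned flagged non-optimal.

Two-pass protocol: pass 1 allows every candidate; pass 2 fixes ATP synthase
(pattern-matched on ids like `ATPS…` or names containing "ATP synthase",
user-overridable) to stay active, since deleting the synthase kills ATP
cycles *and* respiration. EDRs and exchanges are never candidates. Removals
are applied by zeroing the offending bound — reactions stay in the model and
are listed in the model notes for possible reactivation.

## Fixtures and the synthetic generator

The named fixtures rebuild the classic EGC motifs in ≤ 20 reactions:
a symporter/uniporter proton pump (`fig2`); the malate/Na⁺/H⁺ transporter
triangle with ATP synthase (`fig6a`, ATP optimum 0.25); the
tartrate/succinate/aspartate antiporter chain (`fig6b`); an
NADH:menaquinone oxidoreductase loop closed by a four-enzyme chain
(`fig6c`, three protons per turn); the APS-forming/consuming isoenzyme pair
that charges a GTP per turn (`fig6d`); an EGC-free control; a two-pathway
model whose biomass collapses from 1000 to 50 once its ATP cycle is cut
(ratio 0.05); and a doubled APS model whose detection optimum is 2 and
minimal cut is 2. Reconstructions are qualitative — proton counts follow the
standard conventions (one proton per symport step; ATP synthase
`4 h[p] + adp + pi → atp + h2o + 3 h[c]`) and each cycle's stoichiometry is
made proton-consistent so the dissipation reaction's proton product is
consumed by the cycle itself (e.g. the APS-regenerating step consumes one
`h_c`). No number from the fixtures is asserted on authority: planted
verdicts, optima and minimal cuts are re-derived in the test suite by an
exact-arithmetic elementary-mode oracle and exhaustive subset search.

`make_random_egc_model(n, k, seed)` composes an irreversible linear nutrient
backbone plus random forward branches — a DAG, hence provably EGC-free on
its own — with `k` disjoint planted motifs (ATP-charging pairs and/or proton
pump pairs sharing the cofactor pools), deterministic under the seed and
capped at 60 reactions to keep the oracle tractable. What these synthetic
models do **not** emulate: realistic network density, multiple intracellular
compartments, mass-imbalanced stoichiometry, or cycles interleaved with
biomass-essential pathways; passing on them demonstrates correctness of the
algorithms, not performance or repair quality on organism-scale
reconstructions.

## Verification strategy and problem sizes

The detection oracle (tests) is deliberately LP-free: reactions are pruned
to those on directed cycles of the bipartite metabolite/reaction graph
(networkx SCCs) — any steady-state flux with closed exchanges is supported
on such reactions — and every support subset containing the EDR is checked
for a sign-consistent flux mode via exact rational nullspaces (sympy),
using the elementary-mode characterization (one-dimensional nullspace on
the support). The correction oracle enumerates candidate subsets by size and
certifies each with the two plain LPs. The shipped suite covers the eight
fixtures plus 50 seeded random models of 20–59 reactions (detection) and
all ≤ 2¹⁰ binary assignments on three fixtures (reformulation equivalence);
the full suite plus the acceptance script complete in well under a minute on
one CPU. These sizes were chosen so the exhaustive oracles stay exact;
organism-scale models run through the same code paths but are certified
only by the LP certificates, not by enumeration.

## Known limitations

* MILP matrices are built dense-sparse via scipy and solved with HiGHS;
  genome-scale corrections work but have no warm starts or indicator
  constraints (big-M only). For very large models a commercial solver
  backend would be the natural extension.
* The `v_d*` cycle-count lower bound is not floored; fractional
  energy-per-turn stoichiometries yield bounds below one.
* Reaction *additions* to restore viability when no removal-only correction
  exists are out of scope; such models raise `InfeasibleCorrectionError`.
* Imbalanced reactions are reported, never fixed; namespace translation is
  not performed.
* SBML export covers species/compartments/fbc bounds/objective and exchange
  SBO terms; gene-protein rules survive only the JSON dialect.
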