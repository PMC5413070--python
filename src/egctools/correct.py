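"""Minimal reaction removals eliminating all EGCs while preserving growth.

The search is a bi-level program in the GlobalFit family: the outer problem
minimizes the weighted number of unidirectional reaction deactivations
(binary delta variables, one per direction of each candidate reaction); the
constraints couple a *growth case* (rich medium, biomass >= T_g) and a
*non-growth case* (all exchanges closed, internal fluxes unit-clamped) whose
inner maximization of the summed dissipation flux must be zero.

The inner problem  max c'v  s.t.  S v = 0, L(delta) <= v <= U(delta)  always
admits v = 0, so its optimum is >= 0; it is pinned to exactly zero by strong
LP duality: the single-level MILP carries a dual-feasible point
(S' lam + muU - muL = c, mu >= 0) whose dual objective
U(delta)' muU - L(delta)' muL is constrained <= 0.  Weak duality then bounds
the inner maximum by zero.  Products of binaries with duals are linearized
with big-M; because big-M truncation is the classic failure mode of this
construction, every returned solution is independently re-certified by
re-solving the 15 detection LPs and the growth LP on the constrained model.

Removals constrain bounds to zero -- reactions are never deleted, so a
curator can reactivate them in conditions where they are thermodynamically
feasible.
"""
from __future__ import annotations

import fnmatch
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from ._lp import SolverError, solve_lp
from .detect import DetectionSettings, clamped_bounds, detect_egc
from .dissipation import LABELS
from .model_core import MetabolicModel, biomass_optimum

log = logging.getLogger(__name__)

#: id/name patterns (fnmatch, lower-cased) identifying ATP synthase.
ATP_SYNTHASE_PATTERNS = ("atps*", "*atp synthase*", "rxn08173*", "rxn10042*")


class ConfigurationError(ValueError):
    """The correction request is inconsistent before any solving starts."""


class InfeasibleCorrectionError(RuntimeError):
    """No removal-only correction exists (reaction additions would be needed)."""


class CertificationError(SolverError):
    """A MILP solution failed the independent LP re-certification."""


@dataclass(frozen=True)
class RemovalCandidate:
    reaction_id: str
    direction: str            # "forward" | "backward"
    weight: float = 1.0
    protected: bool = False


@dataclass
class CorrectionSettings:
    clamp: float = 1.0
    big_M: float = 1000.0
    rich_bound: float = 1000.0
    edr_upper: float = 1000.0
    zero_tolerance: float = 1e-6
    time_limit: float = 3600.0
    growth_threshold: float = 0.01   # fraction of the unmodified optimum ...
    threshold_relative: bool = True  # ... unless marked absolute

    def detection(self) -> DetectionSettings:
        return DetectionSettings(internal_flux_clamp=self.clamp,
                                 zero_tolerance=self.zero_tolerance,
                                 edr_upper=self.edr_upper)


@dataclass
class RemovalSolution:
    removals: frozenset
    objective: float
    biomass_before: float
    biomass_after: float
    certified_egc_free: bool
    status: str = "optimal"
    alternatives: list | None = None


def _matches(reaction, patterns) -> bool:
    rid, name = reaction.id.lower(), (reaction.name or "").lower()
    return any(fnmatch.fnmatch(rid, p) or fnmatch.fnmatch(name, p)
               for p in patterns)


def split_reversibles(model: MetabolicModel, protected_patterns=(),
                      weights: dict | None = None,
                      protect_atp_synthase: bool = False
                      ) -> list[RemovalCandidate]:
    """One removal candidate per usable direction of each internal reaction.

    Reversible reactions yield two independent candidates; EDRs and exchange
    reactions are never candidates.  ``weights`` may be keyed by reaction id
    or by (reaction id, direction).  Protected candidates keep their binaries
    fixed to zero in the MILP.
    """
    pats = tuple(p.lower() for p in protected_patterns)
    if protect_atp_synthase:
        pats += ATP_SYNTHASE_PATTERNS
    weights = weights or {}
    out: list[RemovalCandidate] = []
    matched: set[str] = set()
    for r in model.reactions.values():
        if r.is_exchange or r.is_dissipation:
            continue
        prot = _matches(r, pats)
        if prot:
            matched.update(p for p in pats if _matches(r, (p,)))
        for direction, present in (("forward", r.upper_bound > 0),
                                   ("backward", r.lower_bound < 0)):
            if not present:
                continue
            w = weights.get((r.id, direction), weights.get(r.id, 1.0))
            if w <= 0:
                raise ConfigurationError(
                    f"weight for {r.id}:{direction} must be positive")
            out.append(RemovalCandidate(r.id, direction, float(w), prot))
    for p in pats:
        if p not in matched:
            log.warning("protection pattern %r matched no reaction", p)
    return out


@dataclass
class BilevelProgram:
    """The assembled single-level MILP (see module docstring).

    Variable vector layout: [delta | v_growth | v_nongrowth | lambda |
    muU | muL | w], where w_j linearizes (1 - delta_j) * mu for candidate j.
    """
    model: MetabolicModel
    candidates: list[RemovalCandidate]
    T_g: float
    settings: CorrectionSettings
    c_obj: np.ndarray = field(repr=False, default=None)
    integrality: np.ndarray = field(repr=False, default=None)
    lb: np.ndarray = field(repr=False, default=None)
    ub: np.ndarray = field(repr=False, default=None)
    A_eq: sparse.csr_matrix = field(repr=False, default=None)
    b_eq: np.ndarray = field(repr=False, default=None)
    A_ub: sparse.csr_matrix = field(repr=False, default=None)
    b_ub: np.ndarray = field(repr=False, default=None)
    n_delta: int = 0
    rxn_ids: list = field(default_factory=list)

    def weight_vector(self) -> np.ndarray:
        return np.array([c.weight for c in self.candidates])


def _case_bounds(model, settings):
    """(growth lo/hi, non-growth lo/hi) arrays over the reaction order."""
    rxn_ids = model.reaction_ids()
    glo, ghi, nlo, nhi = (np.zeros(len(rxn_ids)) for _ in range(4))
    for j, rid in enumerate(rxn_ids):
        r = model.reactions[rid]
        if r.is_exchange:
            glo[j], ghi[j] = -settings.rich_bound, settings.rich_bound
            nlo[j], nhi[j] = 0.0, 0.0
        elif r.is_dissipation:
            glo[j], ghi[j] = 0.0, settings.edr_upper
            nlo[j], nhi[j] = 0.0, settings.edr_upper
        else:
            glo[j], ghi[j] = r.lower_bound, r.upper_bound
            nlo[j], nhi[j] = clamped_bounds(r, settings.clamp,
                                            settings.edr_upper)
    return glo, ghi, nlo, nhi


def build_bilevel(model: MetabolicModel, candidates: list[RemovalCandidate],
                  T_g: float | None = None,
                  settings: CorrectionSettings | None = None
                  ) -> BilevelProgram:
    """Assemble the single-level MILP.

    ``T_g`` (absolute biomass threshold) defaults to the settings' fraction of
    the unmodified model's rich-medium optimum; a threshold above that optimum
    is a configuration error, reported before any MILP solving.
    """
    settings = settings or CorrectionSettings()
    if not model.notes.get("edrs"):
        raise ValueError("attach dissipation reactions before building "
                         "the bi-level program")
    b0 = biomass_optimum(model, rich=True, rich_bound=settings.rich_bound)
    if T_g is None:
        T_g = (settings.growth_threshold * b0 if settings.threshold_relative
               else settings.growth_threshold)
    if T_g > b0 + 1e-9:
        raise ConfigurationError(
            f"growth threshold {T_g:g} exceeds the unmodified rich-medium "
            f"optimum {b0:g}")

    S, met_index, rxn_ids = model.stoichiometric_matrix()
    pos = {rid: j for j, rid in enumerate(rxn_ids)}
    nm, nr = S.shape
    nd = len(candidates)
    M = settings.big_M

    glo, ghi, nlo, nhi = _case_bounds(model, settings)

    # variable offsets
    o_d, o_vg, o_vng = 0, nd, nd + nr
    o_lam, o_muU, o_muL = nd + 2 * nr, nd + 2 * nr + nm, nd + 2 * nr + nm + nr
    o_w = o_muL + nr
    N = o_w + nd

    lb = np.full(N, -np.inf)
    ub = np.full(N, np.inf)
    lb[o_d:o_d + nd], ub[o_d:o_d + nd] = 0.0, 1.0
    for j, cand in enumerate(candidates):
        if cand.protected:
            ub[o_d + j] = 0.0
    lb[o_vg:o_vg + nr], ub[o_vg:o_vg + nr] = glo, ghi
    lb[o_vng:o_vng + nr], ub[o_vng:o_vng + nr] = nlo, nhi
    lb[o_muU:o_muU + nr], ub[o_muU:o_muU + nr] = 0.0, M
    lb[o_muL:o_muL + nr], ub[o_muL:o_muL + nr] = 0.0, M
    lb[o_w:o_w + nd], ub[o_w:o_w + nd] = 0.0, M

    # dissipation selector c over reactions
    c_sel = np.zeros(nr)
    for info in model.notes["edrs"].values():
        if info["active"]:
            c_sel[pos[info["reaction_id"]]] = 1.0

    eq_rows, eq_cols, eq_vals, b_eq = [], [], [], []
    ub_rows, ub_cols, ub_vals, b_ub = [], [], [], []
    n_eq = n_ub = 0

    def _eq(entries, rhs):
        nonlocal n_eq
        for col, val in entries:
            eq_rows.append(n_eq)
            eq_cols.append(col)
            eq_vals.append(val)
        b_eq.append(rhs)
        n_eq += 1

    def _le(entries, rhs):
        nonlocal n_ub
        for col, val in entries:
            ub_rows.append(n_ub)
            ub_cols.append(col)
            ub_vals.append(val)
        b_ub.append(rhs)
        n_ub += 1

    Scoo = S.tocoo()
    # steady state, growth and non-growth cases
    for offset in (o_vg, o_vng):
        for i, j, v in zip(Scoo.row, Scoo.col, Scoo.data):
            eq_rows.append(n_eq + i)
            eq_cols.append(offset + j)
            eq_vals.append(v)
        b_eq.extend([0.0] * nm)
        n_eq += nm

    # dual stationarity: S' lam + muU - muL = c_sel
    ST = S.T.tocoo()
    for j, i, v in zip(ST.row, ST.col, ST.data):
        eq_rows.append(n_eq + j)
        eq_cols.append(o_lam + i)
        eq_vals.append(v)
    for j in range(nr):
        eq_rows.extend([n_eq + j, n_eq + j])
        eq_cols.extend([o_muU + j, o_muL + j])
        eq_vals.extend([1.0, -1.0])
    b_eq.extend(c_sel.tolist())
    n_eq += nr

    # biomass threshold: -v_bio <= -T_g
    _le([(o_vg + pos[model.biomass_reaction_id], -1.0)], -T_g)

    # delta-gated bounds and big-M linearizations
    fwd_cand = {}   # reaction column -> candidate index
    bwd_cand = {}
    for j, cand in enumerate(candidates):
        y = pos[cand.reaction_id]
        dj = o_d + j
        if cand.direction == "forward":
            fwd_cand[y] = j
            _le([(o_vg + y, 1.0), (dj, ghi[y])], ghi[y])
            _le([(o_vng + y, 1.0), (dj, nhi[y])], nhi[y])
            mu = o_muU + y
        else:
            bwd_cand[y] = j
            _le([(o_vg + y, -1.0), (dj, -glo[y])], -glo[y])
            _le([(o_vng + y, -1.0), (dj, -nlo[y])], -nlo[y])
            mu = o_muL + y
        # w_j = (1 - delta_j) * mu within [0, M]
        wj = o_w + j
        _le([(wj, 1.0), (mu, -1.0)], 0.0)
        _le([(wj, 1.0), (dj, M)], M)
        _le([(mu, 1.0), (wj, -1.0), (dj, -M)], 0.0)

    # dual objective <= 0: sum_y U_y(delta) muU_y - L_y(delta) muL_y <= 0
    dual_entries = []
    for y in range(nr):
        if nhi[y] != 0.0:
            j = fwd_cand.get(y)
            dual_entries.append((o_w + j if j is not None else o_muU + y,
                                 nhi[y]))
        if nlo[y] != 0.0:
            j = bwd_cand.get(y)
            dual_entries.append((o_w + j if j is not None else o_muL + y,
                                 -nlo[y]))
    _le(dual_entries, 0.0)

    # objective: weighted removals + a tiny index-lexicographic tie-break
    c_obj = np.zeros(N)
    wts = np.array([c.weight for c in candidates]) if nd else np.zeros(0)
    if nd:
        eps = 1e-5 * wts.min() / (nd * (nd + 1))
        c_obj[o_d:o_d + nd] = wts + eps * np.arange(1, nd + 1)
    integrality = np.zeros(N)
    integrality[o_d:o_d + nd] = 1

    A_eq = sparse.csr_matrix((eq_vals, (eq_rows, eq_cols)), shape=(n_eq, N))
    A_ub = sparse.csr_matrix((ub_vals, (ub_rows, ub_cols)), shape=(n_ub, N))
    return BilevelProgram(
        model=model, candidates=list(candidates), T_g=float(T_g),
        settings=settings, c_obj=c_obj, integrality=integrality,
        lb=lb, ub=ub, A_eq=A_eq, b_eq=np.array(b_eq),
        A_ub=A_ub, b_ub=np.array(b_ub), n_delta=nd, rxn_ids=rxn_ids)


def solve_milp(program: BilevelProgram, fixed_delta=None, cuts=(),
               time_limit: float | None = None):
    """Low-level MILP solve; returns the raw scipy result."""
    lb, ub = program.lb.copy(), program.ub.copy()
    nd = program.n_delta
    if fixed_delta is not None:
        fixed = np.asarray(fixed_delta, dtype=float)
        lb[:nd] = ub[:nd] = fixed
    constraints = [LinearConstraint(program.A_eq, program.b_eq, program.b_eq),
                   LinearConstraint(program.A_ub, -np.inf, program.b_ub)]
    for a, rhs in cuts:
        constraints.append(LinearConstraint(a, -np.inf, rhs))
    opts = {"time_limit": time_limit or program.settings.time_limit}
    return milp(c=program.c_obj, constraints=constraints,
                integrality=program.integrality, bounds=Bounds(lb, ub),
                options=opts)


# ---------------------------------------------------------------------------
# applying and certifying solutions

def apply_removals(model: MetabolicModel, removals) -> MetabolicModel:
    """Constrain the removed directions to zero flux (never delete)."""
    mm = model.copy()
    for rid, direction in removals:
        r = mm.reactions[rid]
        if direction == "forward":
            r.upper_bound = 0.0
            r.lower_bound = min(r.lower_bound, 0.0)
        elif direction == "backward":
            r.lower_bound = 0.0
            r.upper_bound = max(r.upper_bound, 0.0)
        else:
            raise ValueError(f"unknown direction {direction!r}")
    mm.notes.setdefault("deactivated", []).extend(
        [f"{rid}:{d}" for rid, d in sorted(removals)])
    return mm


def certify(model: MetabolicModel, removals, T_g: float,
            settings: CorrectionSettings):
    """Independent LP certificate: (egc_free, biomass_after).

    Re-solves all 15 detection LPs and the rich-medium growth LP on the
    constrained model; never trusts the MILP's own feasibility claim.
    """
    constrained = apply_removals(model, removals)
    report = detect_egc(constrained, settings.detection())
    egc_free = all(t.optimum <= settings.zero_tolerance
                   for t in report.results.values())
    after = biomass_optimum(constrained, rich=True,
                            rich_bound=settings.rich_bound)
    return egc_free, after


def check_assignment(model: MetabolicModel, candidates, delta, T_g: float,
                     settings: CorrectionSettings | None = None):
    """Direct two-LP feasibility of one binary assignment.

    Growth LP: rich medium with delta-gated bounds, biomass must reach T_g.
    Non-growth LP: exchanges closed, clamped delta-gated bounds, maximal
    summed dissipation flux must be zero.  This is the reference semantics the
    single-level MILP must reproduce; it is also the brute-force oracle for
    small instances.
    """
    settings = settings or CorrectionSettings()
    S, _, rxn_ids = model.stoichiometric_matrix()
    pos = {rid: j for j, rid in enumerate(rxn_ids)}
    glo, ghi, nlo, nhi = _case_bounds(model, settings)
    glo, ghi, nlo, nhi = glo.copy(), ghi.copy(), nlo.copy(), nhi.copy()
    for cand, d in zip(candidates, delta):
        if not d:
            continue
        y = pos[cand.reaction_id]
        if cand.direction == "forward":
            ghi[y] = 0.0
            nhi[y] = 0.0
            glo[y] = min(glo[y], 0.0)
            nlo[y] = min(nlo[y], 0.0)
        else:
            glo[y] = 0.0
            nlo[y] = 0.0
            ghi[y] = max(ghi[y], 0.0)
            nhi[y] = max(nhi[y], 0.0)
    b_eq = np.zeros(S.shape[0])
    cbio = np.zeros(len(rxn_ids))
    cbio[pos[model.biomass_reaction_id]] = 1.0
    res_g = solve_lp(cbio, list(zip(glo, ghi)), A_eq=S, b_eq=b_eq,
                     maximize=True)
    growth_ok = res_g.optimal and res_g.objective >= T_g - 1e-7

    c_sel = np.zeros(len(rxn_ids))
    for info in model.notes["edrs"].values():
        if info["active"]:
            c_sel[pos[info["reaction_id"]]] = 1.0
    res_ng = solve_lp(c_sel, list(zip(nlo, nhi)), A_eq=S, b_eq=b_eq,
                      maximize=True)
    ng_ok = res_ng.optimal and res_ng.objective <= settings.zero_tolerance
    return growth_ok, ng_ok


# ---------------------------------------------------------------------------
# top-level solving

def _extract_solution(program: BilevelProgram, res) -> RemovalSolution:
    nd = program.n_delta
    delta = np.round(res.x[:nd]).astype(int)
    removals = frozenset(
        (c.reaction_id, c.direction)
        for c, d in zip(program.candidates, delta) if d)
    objective = float(sum(c.weight for c, d in
                          zip(program.candidates, delta) if d))
    before = biomass_optimum(program.model, rich=True,
                             rich_bound=program.settings.rich_bound)
    egc_free, after = certify(program.model, removals, program.T_g,
                              program.settings)
    status = "optimal" if res.status == 0 else "feasible_incumbent"
    if not egc_free or after < program.T_g - 1e-6:
        raise CertificationError(
            f"MILP solution failed the independent certificate "
            f"(egc_free={egc_free}, biomass_after={after:g}, "
            f"T_g={program.T_g:g}); consider a larger big_M")
    return RemovalSolution(
        removals=removals, objective=objective, biomass_before=before,
        biomass_after=after, certified_egc_free=True, status=status)


def solve_correction(program: BilevelProgram,
                     time_limit: float | None = None) -> RemovalSolution:
    """Solve the single-level MILP and certify the result.

    Raises :class:`InfeasibleCorrectionError` when no removal-only correction
    exists; on hitting the time limit the best incumbent is returned flagged
    ``feasible_incumbent``.
    """
    res = solve_milp(program, time_limit=time_limit)
    if res.status == 2:
        raise InfeasibleCorrectionError(
            "no removal-only correction exists for this model "
            "(reaction additions would be required)")
    if res.x is None:
        raise SolverError(f"MILP failed: {res.message}")
    return _extract_solution(program, res)


def enumerate_alternatives(program: BilevelProgram,
                           k: int) -> list[RemovalSolution]:
    """Up to k distinct equally-optimal removal sets (no-good cuts)."""
    first = solve_correction(program)
    sols = [first]
    zstar = first.objective
    nd = program.n_delta
    N = program.lb.size
    cuts = []
    wts = program.weight_vector()
    seen = {first.removals}
    while len(sols) < k:
        pattern = np.array([
            1 if (c.reaction_id, c.direction) in sols[-1].removals else 0
            for c in program.candidates])
        a = np.zeros(N)
        a[:nd] = np.where(pattern == 1, 1.0, -1.0)
        cuts.append((a, float(pattern.sum() - 1)))
        res = solve_milp(program, cuts=cuts)
        if res.status == 2 or res.x is None:
            break
        delta = np.round(res.x[:nd]).astype(int)
        obj = float(wts @ delta)
        if obj > zstar + 1e-6:
            break
        sol = _extract_solution(program, res)
        if sol.removals in seen:   # numerically repeated pattern; stop
            break
        seen.add(sol.removals)
        sols.append(sol)
    first.alternatives = sols[1:]
    return sols


def run_two_pass(model: MetabolicModel,
                 settings: CorrectionSettings | None = None,
                 protected_patterns=(), weights: dict | None = None,
                 synthase_patterns=ATP_SYNTHASE_PATTERNS):
    """(simple, synthase) removal searches, as reported side by side.

    Pass 1 allows every candidate; pass 2 re-runs with ATP synthase (or a
    user-supplied protected set) fixed active, because removing the synthase
    eliminates most ATP cycles but also the model's natural respiration.
    """
    settings = settings or CorrectionSettings()
    cands1 = split_reversibles(model, protected_patterns, weights)
    sol1 = solve_correction(build_bilevel(model, cands1, settings=settings))
    cands2 = split_reversibles(
        model, tuple(protected_patterns) + tuple(synthase_patterns), weights)
    if not any(c.protected for c in cands2):
        log.warning("no ATP synthase matched; synthase pass equals simple pass")
        return sol1, replace(sol1)
    sol2 = solve_correction(build_bilevel(model, cands2, settings=settings))
    return sol1, sol2


def biomass_impact(model: MetabolicModel, solution: RemovalSolution,
                   tolerance: float = 1e-9) -> float:
    """biomass_after / biomass_before on the rich medium (NaN if before ~ 0)."""
    if solution.biomass_before <= tolerance:
        log.warning("biomass_before is ~0; impact ratio undefined")
        return math.nan
    return solution.biomass_after / solution.biomass_before
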