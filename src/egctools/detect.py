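"""Energy-generating cycle detection via bounded-flux maximization LPs.

For each attached energy-dissipation reaction d the LP

    max v_d   s.t.   S v = 0,  v_i = 0 for every exchange i,
                     -1 <= v <= 1 (reversible) / 0 <= v <= 1 (irreversible)
                     for every internal non-EDR reaction,

is solved.  A positive optimum proves the model can charge that energy
metabolite with no nutrient uptake -- an energy-generating cycle.  Because
every internal flux is clamped to unit magnitude, the optimum is also a lower
bound on the number of non-overlapping cycles for that metabolite (each unit
of dissipation flux needs its own unit-flux cycle).  An aggregate LP
maximizing the summed dissipation flux serves as a fast pre-screen.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._lp import SolverError, solve_lp
from .dissipation import LABELS
from .model_core import MetabolicModel

#: optima in (0, zero_tolerance] are LP solver noise, not cycles.
ZERO_TOL = 1e-6


@dataclass
class DetectionSettings:
    internal_flux_clamp: float = 1.0
    zero_tolerance: float = ZERO_TOL
    edr_upper: float = 1000.0
    keep_fluxes: bool = False

    def __post_init__(self):
        if self.internal_flux_clamp <= 0:
            raise ValueError("internal_flux_clamp must be > 0")
        if self.zero_tolerance < 0:
            raise ValueError("zero_tolerance must be >= 0")


@dataclass
class TargetResult:
    optimum: float
    has_egc: bool
    status: str
    fluxes: dict[str, float] | None = None


@dataclass
class EGCReport:
    model_id: str
    results: dict[str, TargetResult]
    aggregate_optimum: float
    settings: DetectionSettings = field(default_factory=DetectionSettings)

    @property
    def has_egcs(self) -> bool:
        return any(t.has_egc for t in self.results.values())

    def to_row(self) -> dict:
        row = {"model_id": self.model_id, "hasEGCs": self.has_egcs}
        for label in LABELS:
            t = self.results.get(label)
            row[f"generates.{label}"] = t.optimum if t else 0.0
        return row


def clamped_bounds(reaction, clamp: float, edr_upper: float):
    """Detection-mode flux bounds for one reaction.

    Exchanges are closed; EDRs keep [0, edr_upper] (exempt from the clamp);
    every other reaction is clamped to [-clamp, clamp] intersected with its
    own sign restrictions.
    """
    if reaction.is_exchange:
        return (0.0, 0.0)
    if reaction.is_dissipation:
        return (0.0, edr_upper)
    lo = max(reaction.lower_bound, -clamp)
    hi = min(reaction.upper_bound, clamp)
    lo = min(lo, hi)   # guard against forced fluxes beyond the clamp
    return (lo, hi)


def _edr_registry(model: MetabolicModel) -> dict:
    edrs = model.notes.get("edrs")
    if not edrs:
        raise ValueError(
            "no dissipation reactions attached; call attach_dissipation first")
    return edrs


def detect_egc(model: MetabolicModel,
               settings: DetectionSettings | None = None) -> EGCReport:
    """Run the per-target detection LPs plus the aggregate pre-screen."""
    settings = settings or DetectionSettings()
    edrs = _edr_registry(model)
    S, _, rxn_ids = model.stoichiometric_matrix()
    pos = {rid: j for j, rid in enumerate(rxn_ids)}
    bounds = [clamped_bounds(model.reactions[rid],
                             settings.internal_flux_clamp, settings.edr_upper)
              for rid in rxn_ids]
    b_eq = np.zeros(S.shape[0])
    tol = settings.zero_tolerance

    results: dict[str, TargetResult] = {}
    active_cols = []
    for label in LABELS:
        info = edrs.get(label)
        if info is None or not info["active"]:
            results[label] = TargetResult(0.0, False, "not integrated")
            continue
        j = pos[info["reaction_id"]]
        active_cols.append(j)
        c = np.zeros(len(rxn_ids))
        c[j] = 1.0
        res = solve_lp(c, bounds, A_eq=S, b_eq=b_eq, maximize=True)
        if not res.optimal:
            # v = 0 is always feasible and the clamp bounds the optimum, so
            # anything but "optimal" signals an internal modeling bug.
            raise SolverError(
                f"detection LP for {label} returned {res.status}")
        opt = max(res.objective, 0.0)
        status = "optimal"
        if 0.0 < opt <= tol:
            status = "numerically zero"
        fluxes = None
        if settings.keep_fluxes:
            fluxes = {rid: float(v) for rid, v in zip(rxn_ids, res.x)}
        results[label] = TargetResult(opt, opt > tol, status, fluxes)

    aggregate = 0.0
    if active_cols:
        c = np.zeros(len(rxn_ids))
        c[active_cols] = 1.0
        res = solve_lp(c, bounds, A_eq=S, b_eq=b_eq, maximize=True)
        if not res.optimal:
            raise SolverError(f"aggregate detection LP returned {res.status}")
        aggregate = max(res.objective, 0.0)

    return EGCReport(model.id, results, aggregate, settings)


def count_lower_bound(report: EGCReport, target: str) -> float:
    """v_d* as a lower bound on the number of non-overlapping cycles.

    Valid only under unit clamps: each unit of dissipation flux then requires
    a distinct unit-flux cycle.  Note that when the dissipation stoichiometry
    yields fractional energy per unit of cycle flux the bound can be below 1
    even though one cycle exists; the value is reported as-is.
    """
    if report.settings.internal_flux_clamp != 1:
        raise ValueError(
            "the non-overlapping-cycle bound requires internal_flux_clamp=1")
    if target not in report.results:
        raise KeyError(f"unknown target {target!r}")
    return report.results[target].optimum


def enumerate_cycle_support(model: MetabolicModel, target: str,
                            settings: DetectionSettings | None = None
                            ) -> set[str]:
    """Reactions carrying flux in one sparsest optimal detection solution.

    Solves the detection LP for ``target``, then re-minimizes the flux 1-norm
    at the fixed optimum; the support of that vertex solution is the candidate
    cycle shown to the curator.
    """
    settings = settings or DetectionSettings()
    edrs = _edr_registry(model)
    info = edrs.get(target)
    if info is None or not info["active"]:
        raise ValueError(f"target {target!r} has no active EDR in this model")
    S, _, rxn_ids = model.stoichiometric_matrix()
    pos = {rid: j for j, rid in enumerate(rxn_ids)}
    n = len(rxn_ids)
    j = pos[info["reaction_id"]]
    bounds = [clamped_bounds(model.reactions[rid],
                             settings.internal_flux_clamp, settings.edr_upper)
              for rid in rxn_ids]
    c = np.zeros(n)
    c[j] = 1.0
    res = solve_lp(c, bounds, A_eq=S, b_eq=np.zeros(S.shape[0]), maximize=True)
    if not res.optimal or res.objective <= settings.zero_tolerance:
        raise ValueError(f"no energy-generating cycle for target {target!r}")
    vstar = res.objective

    # phase 2: min sum(t) with t >= |v|, v_d pinned at the phase-1 optimum
    from scipy import sparse as sp
    eps = 1e-9 * max(1.0, vstar)
    bounds2 = list(bounds) + [(0.0, None)] * n
    bounds2[j] = (vstar - eps, vstar + eps)
    A_eq = sp.hstack([S, sp.csr_matrix((S.shape[0], n))], format="csr")
    eye = sp.identity(n, format="csr")
    A_ub = sp.vstack([sp.hstack([eye, -eye]),
                      sp.hstack([-eye, -eye])], format="csr")
    c2 = np.concatenate([np.zeros(n), np.ones(n)])
    res2 = solve_lp(c2, bounds2, A_eq=A_eq, b_eq=np.zeros(S.shape[0]),
                    A_ub=A_ub, b_ub=np.zeros(2 * n), simplex=True)
    if not res2.optimal:
        raise SolverError(f"support-minimization LP returned {res2.status}")
    v = res2.x[:n]
    return {rid for rid, flux in zip(rxn_ids, v)
            if abs(flux) > settings.zero_tolerance}
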