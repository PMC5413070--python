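"""Independent brute-force oracles used by the test suite.

``oracle_has_egc`` decides EGC existence without any LP: the bipartite
metabolite/reaction digraph is pruned to reactions lying on directed cycles
(any steady-state flux with closed exchanges is supported on such reactions),
then every support subset containing the dissipation reaction is checked for
a sign-consistent exact-rational flux mode.  Completeness rests on the
elementary-flux-mode characterization: if any admissible flux drives the
dissipation reaction, some elementary mode does, and elementary modes are
exactly the supports whose restricted stoichiometric matrix has a
one-dimensional nullspace.

``brute_force_min_cut`` enumerates candidate-direction subsets by increasing
size and certifies each with the two plain LPs (growth + non-growth), the
reference semantics of the correction MILP.
"""
from fractions import Fraction
from itertools import combinations

import networkx as nx
import sympy

from egctools.correct import check_assignment


def _rational(x):
    return sympy.Rational(Fraction(float(x)).limit_denominator(10 ** 9))


def cyclic_reactions(model):
    """Reaction ids lying on a directed cycle of the closed-exchange network."""
    G = nx.DiGraph()
    for r in model.reactions.values():
        if r.is_exchange:
            continue
        rn = ("r", r.id)
        for mid, coef in r.stoichiometry.items():
            if model.metabolites[mid].boundary:
                continue
            mn = ("m", mid)
            if r.upper_bound > 0:   # forward direction possible
                G.add_edge(mn, rn) if coef < 0 else G.add_edge(rn, mn)
            if r.lower_bound < 0:   # backward direction possible
                G.add_edge(rn, mn) if coef < 0 else G.add_edge(mn, rn)
    cyclic = set()
    for scc in nx.strongly_connected_components(G):
        if len(scc) > 1:
            cyclic.update(n[1] for n in scc if n[0] == "r")
    return cyclic


def _sign_consistent_mode(model, support, target):
    """Does a flux mode with support within ``support`` and positive flux on
    ``target`` exist?  Exact rational arithmetic, dim-1 nullspace check."""
    support = list(support)
    mets = sorted({mid for rid in support
                   for mid in model.reactions[rid].stoichiometry
                   if not model.metabolites[mid].boundary})
    mpos = {mid: i for i, mid in enumerate(mets)}
    M = sympy.zeros(len(mets), len(support))
    for j, rid in enumerate(support):
        for mid, coef in model.reactions[rid].stoichiometry.items():
            if mid in mpos:
                M[mpos[mid], j] = _rational(coef)
    null = M.nullspace()
    if len(null) != 1:
        return False
    w = null[0]
    t = support.index(target)
    if w[t] == 0:
        return False
    if w[t] < 0:
        w = -w
    for j, rid in enumerate(support):
        r = model.reactions[rid]
        if r.lower_bound >= 0 and w[j] < 0:
            return False
        if r.upper_bound <= 0 and w[j] > 0:
            return False
    return True


def oracle_has_egc(model, label, max_candidates=16):
    """EGC verdict for one energy metabolite, independent of any LP."""
    info = model.notes["edrs"].get(label)
    if info is None or not info["active"]:
        return False
    edr = info["reaction_id"]
    cyc = cyclic_reactions(model)
    if edr not in cyc:
        return False
    others = sorted(cyc - {edr})
    if len(others) > max_candidates:
        raise RuntimeError(
            f"cyclic subnetwork too large for the brute-force oracle "
            f"({len(others)} reactions)")
    for size in range(1, len(others) + 1):
        for combo in combinations(others, size):
            if _sign_consistent_mode(model, (edr,) + combo, edr):
                return True
    return False


def brute_force_min_cut(model, candidates, T_g, settings, max_size=4):
    """(min size, list of minimal cut sets) via exhaustive subset search.

    Each subset is certified with the two plain LPs.  Returns (None, [])
    if no cut of size <= max_size works.
    """
    n = len(candidates)
    usable = [i for i in range(n) if not candidates[i].protected]
    for size in range(0, max_size + 1):
        cuts = []
        for combo in combinations(usable, size):
            delta = [1 if i in combo else 0 for i in range(n)]
            growth_ok, ng_ok = check_assignment(
                model, candidates, delta, T_g, settings)
            if growth_ok and ng_ok:
                cuts.append(frozenset(
                    (candidates[i].reaction_id, candidates[i].direction)
                    for i in combo))
        if cuts:
            return size, cuts
    return None, []
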