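"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's pruning/merge machinery: transition
probabilities come from scipy.linalg.expm on an independently constructed
rate matrix, and likelihoods/marginals are computed by explicit enumeration
over all internal-node state assignments.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import scipy.linalg

from stygotrace.dec import (
    CladogenesisSpec,
    DECParams,
    GeographyData,
    RangeStateSpace,
    StratifiedDispersalModel,
    cladogenesis_distribution,
)
from stygotrace.treeio import TimeTree, slice_branch_by_strata


def oracle_dec_Q(params: DECParams, mult: np.ndarray, space: RangeStateSpace) -> np.ndarray:
    """Independent DEC rate-matrix construction (set arithmetic, not bitmasks)."""
    n = space.universe.n_areas
    eff = mult.astype(float).copy()
    inner = (eff > 0) & (eff < 1)
    eff[inner] = eff[inner] ** params.w
    sets = [frozenset(i for i in range(n) if m >> i & 1) for m in space.states]
    idx = {s: i for i, s in enumerate(sets)}
    S = len(sets)
    Q = np.zeros((S, S))
    for si, R in enumerate(sets):
        if not R:
            continue
        for a in range(n):
            if a in R:
                Q[si, idx[R - {a}]] += params.e
            else:
                grown = R | {a}
                if grown in idx:
                    Q[si, idx[grown]] += params.d * sum(eff[i, a] for i in R)
    for si in range(S):
        Q[si, si] = -Q[si].sum()
    return Q


def _clado_table(space, spec, params, mult):
    """Symmetrized per-ancestor daughter-pair probabilities; the null range
    passes (null, null) with probability 1."""
    u = space.universe
    table = {}
    for si, mask in enumerate(space.states):
        if mask == 0:
            table[si] = {(0, 0): 1.0}
            continue
        dist = cladogenesis_distribution(mask, spec, params, mult, space)
        sym: dict[tuple[int, int], float] = {}
        for (d1, d2), p in dist.items():
            i1, i2 = space.index[u.set_to_mask(d1)], space.index[u.set_to_mask(d2)]
            if i1 == i2:
                sym[(i1, i2)] = sym.get((i1, i2), 0.0) + p
            else:
                sym[(i1, i2)] = sym.get((i1, i2), 0.0) + p / 2
                sym[(i2, i1)] = sym.get((i2, i1), 0.0) + p / 2
        table[si] = sym
    return table


def brute_dec(
    tree: TimeTree,
    geog: GeographyData,
    params: DECParams,
    dispersal: StratifiedDispersalModel,
    spec: CladogenesisSpec,
    max_range_size: int | None = None,
):
    """(log-likelihood, per-internal-node marginals) by full enumeration."""
    space = RangeStateSpace(dispersal.universe, max_range_size)
    ages = tree.node_ages()
    strat = dispersal.stratification
    Qs = [oracle_dec_Q(params, m, space) for m in dispersal.matrices]

    Pbr = {}
    for v in tree.postorder():
        v = int(v)
        if v == tree.root:
            continue
        P = np.eye(space.n_states)
        for stratum, dur in slice_branch_by_strata((ages[tree.parent[v]], ages[v]), strat):
            P = P @ scipy.linalg.expm(Qs[stratum] * dur)
        Pbr[v] = P

    # raw matrices: cladogenesis_distribution applies the w exponent itself
    tables = [_clado_table(space, spec, params, m) for m in dispersal.matrices]
    node_stratum = {
        int(v): strat.stratum_of(ages[int(v)])
        for v in tree.postorder()
        if not tree.is_tip(int(v))
    }
    internal = [int(v) for v in tree.postorder() if not tree.is_tip(int(v))]
    tip_state = {
        i: space.index[geog.ranges[tree.tip_label[i]]] for i in tree.tip_label
    }
    pi = np.ones(space.n_states)
    pi[0] = 0.0
    pi /= pi.sum()

    total = 0.0
    marg = {v: np.zeros(space.n_states) for v in internal}
    for assign in itertools.product(range(space.n_states), repeat=len(internal)):
        states = dict(zip(internal, assign))
        states.update(tip_state)
        p = pi[states[tree.root]]
        if p == 0:
            continue
        for v in internal:
            c1, c2 = tree.children[v]
            table = tables[node_stratum[v]][states[v]]
            term = 0.0
            for (d1, d2), cp in table.items():
                term += cp * Pbr[c1][d1, states[c1]] * Pbr[c2][d2, states[c2]]
            p *= term
            if p == 0:
                break
        if p > 0:
            total += p
            for v in internal:
                marg[v][states[v]] += p
    lnL = math.log(total) if total > 0 else -math.inf
    if total > 0:
        for v in internal:
            marg[v] /= total
    return lnL, marg


def brute_mk(tree: TimeTree, tip_states, Q: np.ndarray, labels, root_prior: np.ndarray):
    """(log-likelihood, per-internal-node marginals) for an Mk model by
    enumeration over internal-node assignments."""
    S = Q.shape[0]
    idx = {l: i for i, l in enumerate(labels)}
    Pbr = {
        int(v): scipy.linalg.expm(Q * tree.branch_length[int(v)])
        for v in tree.postorder()
        if int(v) != tree.root
    }
    internal = [int(v) for v in tree.postorder() if not tree.is_tip(int(v))]
    tipvec = {}
    for i, lab in tree.tip_label.items():
        obs = tip_states[lab]
        allowed = [idx[obs]] if isinstance(obs, str) else [idx[x] for x in obs]
        tipvec[i] = allowed
    total = 0.0
    marg = {v: np.zeros(S) for v in internal}
    tips = list(tipvec)
    for assign in itertools.product(range(S), repeat=len(internal)):
        states = dict(zip(internal, assign))
        for tip_assign in itertools.product(*(tipvec[t] for t in tips)):
            states.update(dict(zip(tips, tip_assign)))
            p = root_prior[states[tree.root]]
            for v in internal:
                for c in tree.children[v]:
                    p *= Pbr[c][states[v], states[c]]
                    if p == 0:
                        break
            if p > 0:
                total += p
                for v in internal:
                    marg[v][states[v]] += p
    lnL = math.log(total) if total > 0 else -math.inf
    if total > 0:
        for v in internal:
            marg[v] /= total
    return lnL, marg


def poisson_parity_mean_changes(q: float, t: float, same_endpoints: bool) -> float:
    """E[# state changes | endpoints] for the symmetric 2-state CTMC: the
    change count is Poisson(qt) and the endpoints agree iff it is even."""
    lam = q * t
    ns = np.arange(0, max(200, int(10 * lam)))
    logp = -lam + ns * np.log(lam) - np.array([math.lgamma(n + 1) for n in ns])
    p = np.exp(logp)
    keep = (ns % 2 == 0) if same_endpoints else (ns % 2 == 1)
    return float((ns[keep] * p[keep]).sum() / p[keep].sum())


def yule_expected_crown_age(birth_rate: float, n_tips: int) -> float:
    """Expected crown age of the simulator's stopping rule under pure birth:
    the waiting times through 2..n lineages, cut just before the next event."""
    return sum(1.0 / (birth_rate * k) for k in range(2, n_tips + 1))
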