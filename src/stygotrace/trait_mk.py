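"""Constrained discrete-trait CTMCs (Mk/ARD), marginal ancestral states,
stochastic character mapping, and habitat-colonization counting.

Two structured state spaces matter for subterranean radiations:

* a **habitat** space with one epigean (surface) state plus interstitial and
  subterranean states subdivided by palaeovalley, with a transition mask
  that forbids subterranean dispersal between palaeovalleys, allows
  interstitial-to-subterranean shifts only within a palaeovalley, and (by
  default) treats subterranean life as irreversible;
* an **altitude** space of five maximum-altitude bands with an unconstrained
  all-rates-different (ARD) mask.

Stochastic character mapping draws complete trait histories conditional on
the tip data: node states from their conditional distributions, then branch
paths from the endpoint-conditioned CTMC by uniformization (exact, no
rejection).  Colonization and subterranean-speciation counts are read off
the sampled histories.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .dec import _Propagator  # same eigendecomposition-backed expm cache
from .model_selection import aicc
from .treeio import TimeTree

__all__ = [
    "TraitStateSpace",
    "RootPrior",
    "SimmapHistory",
    "ColonizationSummary",
    "MkModel",
    "build_habitat_space",
    "build_altitude_space",
    "ALTITUDE_BANDS",
    "mk_loglik",
    "fit_ard",
    "fit_tied_rates",
    "marginal_ancestral_states",
    "simmap_sample",
    "sample_conditioned_path",
    "count_colonizations",
    "read_trait_table",
    "write_trait_table",
    "simmap_event_log",
]

#: maximum-altitude bands (m) used for the five-state altitude model
ALTITUDE_BANDS = ("<=1000", "1001-2000", "2001-3000", "3001-4000", ">4000")

HABITAT_CLASSES = ("epigean", "interstitial", "subterranean")


@dataclass(frozen=True)
class TraitStateSpace:
    """Ordered trait states, optionally structured.

    For habitat spaces each label is ``epigean``, ``interstitial:<valley>``
    or ``subterranean:<valley>`` and carries a (class, palaeovalley) pair;
    unstructured spaces (e.g. altitude bands) have ``classes=None``.
    """

    labels: tuple[str, ...]
    classes: tuple[str, ...] | None = None
    valleys: tuple[str | None, ...] | None = None

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("trait state labels must be unique")
        if self.classes is not None and len(self.classes) != len(self.labels):
            raise ValueError("classes must align with labels")
        if self.valleys is not None and len(self.valleys) != len(self.labels):
            raise ValueError("valleys must align with labels")

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def class_of(self, i: int) -> str | None:
        return None if self.classes is None else self.classes[i]

    def valley_of(self, i: int) -> str | None:
        return None if self.valleys is None else self.valleys[i]


def build_habitat_space(
    palaeovalleys: list[str],
    allow_exit_from_subterranean: bool = False,
    allow_epigean_to_subterranean: bool = True,
) -> tuple[TraitStateSpace, np.ndarray]:
    """Palaeovalley-structured habitat space and its transition mask.

    States: one ``epigean`` plus ``interstitial:<p>`` and
    ``subterranean:<p>`` per palaeovalley.  Allowed transitions (mask True):

    * epigean <-> interstitial:p (both directions, any valley);
    * epigean -> subterranean:p (direct colonization; switchable off);
    * interstitial:p -> subterranean:p (same valley only).

    Everything else is forbidden — in particular subterranean movement
    between palaeovalleys and, by default, any exit from a subterranean
    state (regressive evolution of subterranean specialists is treated as
    irreversible; ``allow_exit_from_subterranean`` relaxes this for
    sensitivity analysis, permitting subterranean:p -> interstitial:p and
    subterranean:p -> epigean).
    """
    valleys = [str(p) for p in palaeovalleys]
    if len(valleys) < 1:
        raise ValueError("need at least one palaeovalley")
    if len(set(valleys)) != len(valleys):
        raise ValueError("duplicate palaeovalley ids")
    labels: list[str] = ["epigean"]
    classes: list[str] = ["epigean"]
    vals: list[str | None] = [None]
    for p in valleys:
        labels.append(f"interstitial:{p}")
        classes.append("interstitial")
        vals.append(p)
    for p in valleys:
        labels.append(f"subterranean:{p}")
        classes.append("subterranean")
        vals.append(p)
    space = TraitStateSpace(tuple(labels), tuple(classes), tuple(vals))
    S = space.n_states
    mask = np.zeros((S, S), dtype=bool)
    for i in range(S):
        for k in range(S):
            if i == k:
                continue
            ci, ck = classes[i], classes[k]
            vi, vk = vals[i], vals[k]
            if ci == "epigean" and ck == "interstitial":
                mask[i, k] = True
            elif ci == "interstitial" and ck == "epigean":
                mask[i, k] = True
            elif ci == "epigean" and ck == "subterranean":
                mask[i, k] = allow_epigean_to_subterranean
            elif ci == "interstitial" and ck == "subterranean":
                mask[i, k] = vi == vk
            elif ci == "subterranean" and allow_exit_from_subterranean:
                if ck == "epigean" or (ck == "interstitial" and vi == vk):
                    mask[i, k] = True
    return space, mask


def build_altitude_space() -> tuple[TraitStateSpace, np.ndarray]:
    """Five maximum-altitude bands with a full (unconstrained) ARD mask."""
    space = TraitStateSpace(ALTITUDE_BANDS)
    mask = ~np.eye(space.n_states, dtype=bool)
    return space, mask


@dataclass(frozen=True)
class RootPrior:
    """Prior over the root state: flat, stationary, fixed, or restricted."""

    kind: str
    probs: np.ndarray

    @staticmethod
    def flat(space: TraitStateSpace) -> "RootPrior":
        p = np.full(space.n_states, 1.0 / space.n_states)
        return RootPrior("flat", p)

    @staticmethod
    def fixed(space: TraitStateSpace, label: str) -> "RootPrior":
        p = np.zeros(space.n_states)
        p[space.index(label)] = 1.0
        return RootPrior(f"fixed({label})", p)

    @staticmethod
    def restricted(space: TraitStateSpace, labels) -> "RootPrior":
        p = np.zeros(space.n_states)
        for l in labels:
            p[space.index(l)] = 1.0
        if p.sum() == 0:
            raise ValueError("restricted prior needs at least one state")
        return RootPrior("restricted", p / p.sum())

    @staticmethod
    def stationary(Q: np.ndarray) -> "RootPrior":
        """Left null vector of Q (stationary distribution), when it exists."""
        w, V = np.linalg.eig(Q.T)
        i = int(np.argmin(np.abs(w)))
        pi = np.abs(V[:, i].real)
        return RootPrior("stationary", pi / pi.sum())

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0) or not math.isclose(p.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("root prior must be a probability vector")
        object.__setattr__(self, "probs", p)


def _check_Q(Q: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    S = Q.shape[0]
    if Q.shape != (S, S):
        raise ValueError("Q must be square")
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < 0):
        raise ValueError("off-diagonal rates must be >= 0")
    if np.max(np.abs(Q.sum(axis=1))) > 1e-9:
        raise ValueError("Q rows must sum to 0")
    if mask is not None and np.any(off[~mask & ~np.eye(S, dtype=bool)] != 0):
        raise ValueError("Q has nonzero rate on a masked (forbidden) transition")
    return Q


class MkModel:
    """Pruning likelihood, marginals and stochastic maps for one dataset.

    ``tip_states`` maps tip label to a state label or to a set of labels
    (ambiguity: each listed state has conditional likelihood 1).
    """

    def __init__(
        self,
        tree: TimeTree,
        tip_states: dict[str, object],
        space: TraitStateSpace,
        root_prior: RootPrior,
    ):
        self.tree = tree
        self.space = space
        self.root_prior = root_prior
        S = space.n_states
        self._tipvec: dict[int, np.ndarray] = {}
        coded = set(tip_states)
        tips = set(tree.tip_label.values())
        if coded != tips:
            raise ValueError(
                f"tip states do not match tree tips (missing {sorted(tips - coded)},"
                f" extra {sorted(coded - tips)})"
            )
        for nid, label in tree.tip_label.items():
            obs = tip_states[label]
            labels = [obs] if isinstance(obs, str) else list(obs)
            v = np.zeros(S)
            for l in labels:
                if l not in space.labels:
                    raise ValueError(f"tip {label!r}: unknown state {l!r}")
                v[space.index(l)] = 1.0
            self._tipvec[nid] = v
        self._tip_state_labels = dict(tip_states)

    def _downpass(self, Q: np.ndarray):
        prop = _Propagator(Q)
        tree = self.tree
        CL: dict[int, np.ndarray] = {}
        Pbr: dict[int, np.ndarray] = {}
        logscale = 0.0
        dead = False
        for v in tree.postorder():
            v = int(v)
            if tree.is_tip(v):
                CL[v] = self._tipvec[v]
                continue
            c1, c2 = tree.children[v]
            prod = np.ones(self.space.n_states)
            for c in (c1, c2):
                Pc = prop.P(tree.branch_length[c])
                Pbr[c] = Pc
                prod = prod * (Pc @ CL[c])
            mx = prod.max()
            if mx <= 0 or not np.isfinite(mx):
                dead = True
                prod = np.zeros_like(prod)
            else:
                logscale += math.log(mx)
                prod = prod / mx
            CL[v] = prod
        return CL, Pbr, logscale, dead, prop

    def loglik(self, Q: np.ndarray, mask: np.ndarray | None = None) -> float:
        Q = _check_Q(Q, mask)
        CL, _, logscale, dead, _ = self._downpass(Q)
        L = float(self.root_prior.probs @ CL[self.tree.root])
        if dead or L <= 0:
            return -math.inf
        return math.log(L) + logscale

    def marginals(self, Q: np.ndarray) -> dict[int, np.ndarray]:
        """Marginal ancestral state distributions at root and internal nodes."""
        Q = _check_Q(Q)
        CL, Pbr, _, dead, _ = self._downpass(Q)
        if dead:
            raise ValueError("data have zero likelihood under this Q")
        tree = self.tree
        O: dict[int, np.ndarray] = {tree.root: self.root_prior.probs.copy()}
        out: dict[int, np.ndarray] = {}
        for v in tree.preorder():
            v = int(v)
            if tree.is_tip(v):
                continue
            post = O[v] * CL[v]
            tot = post.sum()
            if tot <= 0:
                raise ValueError("zero marginal normalizer at an internal node")
            out[v] = post / tot
            c1, c2 = tree.children[v]
            D = {c: Pbr[c] @ CL[c] for c in (c1, c2)}
            for c, other in ((c1, c2), (c2, c1)):
                if not tree.is_tip(c):
                    Otop = O[v] * D[other]
                    Oc = Pbr[c].T @ Otop
                    s = Oc.sum()
                    O[c] = Oc / s if s > 0 else Oc
        return out

    def sample_histories(
        self, Q: np.ndarray, n_sims: int, seed, mask: np.ndarray | None = None
    ) -> list["SimmapHistory"]:
        """Stochastic character maps conditional on the tip data.

        Node states are drawn from their joint conditional distribution
        (preorder, conditioning on the sampled parent state), branch paths
        from the endpoint-conditioned CTMC by uniformization.
        """
        Q = _check_Q(Q, mask)
        if n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        rng = np.random.default_rng(seed)
        CL, Pbr, _, dead, prop = self._downpass(Q)
        if dead:
            raise ValueError("data have zero likelihood under this Q")
        tree = self.tree
        sampler = _UniformizationSampler(Q)
        histories = []
        root_w = self.root_prior.probs * CL[tree.root]
        root_w = root_w / root_w.sum()
        for _ in range(n_sims):
            node_state: dict[int, int] = {}
            node_state[tree.root] = int(rng.choice(root_w.size, p=root_w))
            segments: dict[int, list[tuple[int, float]]] = {}
            for v in tree.preorder():
                v = int(v)
                for c in tree.children[v]:
                    i = node_state[v]
                    w = Pbr[c][i, :] * CL[c]
                    tot = w.sum()
                    if tot <= 0:
                        raise RuntimeError(
                            f"no consistent state for node {c} given its parent"
                        )
                    jstate = int(rng.choice(w.size, p=w / tot))
                    node_state[c] = jstate
                    segments[c] = sampler.sample_path(
                        i, jstate, float(tree.branch_length[c]), Pbr[c], rng, branch=c
                    )
            histories.append(
                SimmapHistory(space=self.space, node_state=node_state, segments=segments)
            )
        return histories


@dataclass
class SimmapHistory:
    """One complete trait history: a state per node and, per non-root node,
    the ordered (state_index, duration) segments along its parent branch
    (parent side first)."""

    space: TraitStateSpace
    node_state: dict[int, int]
    segments: dict[int, list[tuple[int, float]]]

    def validate(self, tree: TimeTree, atol: float = 1e-9) -> None:
        for c, segs in self.segments.items():
            if not segs:
                raise ValueError(f"branch {c} has no segments")
            if any(dur <= 0 for _, dur in segs):
                raise ValueError(f"branch {c} has a non-positive segment duration")
            if abs(sum(d for _, d in segs) - tree.branch_length[c]) > atol:
                raise ValueError(f"branch {c} segments do not sum to its length")
            if segs[0][0] != self.node_state[int(tree.parent[c])]:
                raise ValueError(f"branch {c} does not start at the parent state")
            if segs[-1][0] != self.node_state[c]:
                raise ValueError(f"branch {c} does not end at the child state")
            for (a, _), (b, _) in zip(segs, segs[1:]):
                if a == b:
                    raise ValueError(f"branch {c} has adjacent equal-state segments")

    def transitions(self) -> list[tuple[int, int, int]]:
        """All within-branch state changes as (branch_node, from, to)."""
        out = []
        for c, segs in self.segments.items():
            for (a, _), (b, _) in zip(segs, segs[1:]):
                out.append((c, a, b))
        return out

    def n_changes(self) -> int:
        return sum(len(s) - 1 for s in self.segments.values())


class _UniformizationSampler:
    """Endpoint-conditioned CTMC path sampling by uniformization.

    The number of uniformized jumps N given endpoints (i, j) over time t has
    P(N=n) proportional to Poisson(n; Omega t) * R^n[i, j] with
    R = I + Q/Omega; intermediate states form a discrete bridge through the
    powers of R.  Virtual (self) jumps are collapsed afterwards.  The series
    over n is truncated once its partial sum reaches the known normalizer
    P(t)[i, j]; a hard cap guards against pathological inputs.
    """

    MAX_TERMS = 100_000

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        S = Q.shape[0]
        self.omega = float(max(-Q.diagonal().min(), 0.0)) * 1.05 + 1e-12
        self.R = np.eye(S) + Q / self.omega
        self._powers = [np.eye(S), self.R.copy()]

    def _Rpow(self, n: int) -> np.ndarray:
        while len(self._powers) <= n:
            self._powers.append(self._powers[-1] @ self.R)
        return self._powers[n]

    def sample_path(
        self,
        i: int,
        j: int,
        t: float,
        P: np.ndarray | None,
        rng: np.random.Generator,
        branch=None,
    ) -> list[tuple[int, float]]:
        if P is None:
            P = _Propagator(self.Q).P(t)
        pij = float(P[i, j])
        if pij <= 0:
            raise RuntimeError(
                f"impossible endpoint pair ({i}->{j}) on branch {branch}"
            )
        # sample N | endpoints
        u = rng.random() * pij
        lam = self.omega * t
        log_pois = -lam
        acc = 0.0
        n = 0
        while True:
            term = math.exp(log_pois) * float(self._Rpow(n)[i, j])
            acc += term
            if acc >= u or n >= self.MAX_TERMS:
                break
            n += 1
            log_pois += math.log(lam) - math.log(n)
        # bridge states at the n uniformized jumps
        states = [i]
        for k in range(1, n):
            prev = states[-1]
            wvec = self.R[prev, :] * self._Rpow(n - k)[:, j]
            tot = wvec.sum()
            states.append(int(rng.choice(wvec.size, p=wvec / tot)))
        if n > 0:
            states.append(j)
        times = np.sort(rng.random(n)) * t
        # collapse virtual jumps into (state, duration) segments
        segs: list[tuple[int, float]] = []
        cur = i
        last = 0.0
        for k in range(n):
            nxt = states[k + 1]
            if nxt != cur:
                segs.append((cur, float(times[k] - last)))
                last = float(times[k])
                cur = nxt
        segs.append((cur, float(t - last)))
        # numerically-degenerate zero-length segments: merge away
        segs = [(s, d) for s, d in segs if d > 0] or [(j, t)]
        merged: list[tuple[int, float]] = []
        for s, d in segs:
            if merged and merged[-1][0] == s:
                merged[-1] = (s, merged[-1][1] + d)
            else:
                merged.append((s, d))
        if merged[0][0] != i or merged[-1][0] != j:
            raise RuntimeError(f"path sampling failed on branch {branch}")
        return merged


def sample_conditioned_path(
    Q: np.ndarray, t: float, i: int, j: int, rng: np.random.Generator
) -> list[tuple[int, float]]:
    """Sample one endpoint-conditioned CTMC path over a single interval."""
    return _UniformizationSampler(Q).sample_path(i, j, t, None, rng)


# ---------------------------------------------------------------------------
# ARD fitting


def fit_ard(
    tree: TimeTree,
    tip_states: dict[str, object],
    space: TraitStateSpace,
    mask: np.ndarray,
    root_prior: RootPrior,
    rate_bounds: tuple[float, float] = (1e-8, 100.0),
    starts: tuple[float, ...] = (0.02, 0.2, 2.0),
) -> tuple[np.ndarray, float, int, float]:
    """Maximum-likelihood all-rates-different fit under a transition mask.

    Each permitted ordered state pair gets an independent rate; masked
    entries are exactly 0.  Deterministic multi-start (every start
    initializes all free rates to one common value), rates optimized on a
    log scale.  Returns (Q_hat, lnL, k, AICc) with the AICc sample size the
    number of tips.
    """
    model = MkModel(tree, tip_states, space, root_prior)
    S = space.n_states
    mask = np.asarray(mask, dtype=bool)
    free = np.argwhere(mask & ~np.eye(S, dtype=bool))
    k = free.shape[0]
    if k == 0:
        raise ValueError("transition mask permits no transitions")
    observed = set()
    for v in tip_states.values():
        observed.update([v] if isinstance(v, str) else v)
    if len(observed) < 2:
        raise ValueError("need at least two observed states to fit rates")

    def build_Q(logr: np.ndarray) -> np.ndarray:
        Q = np.zeros((S, S))
        Q[free[:, 0], free[:, 1]] = np.exp(logr)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def objective(logr: np.ndarray) -> float:
        ll = model.loglik(build_Q(logr))
        return 1e10 if not math.isfinite(ll) else -ll

    lo, hi = math.log(rate_bounds[0]), math.log(rate_bounds[1])
    best_x, best_f, any_success = None, math.inf, False
    for r0 in starts:
        x0 = np.full(k, math.log(r0))
        res = scipy.optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * k,
            options={"maxiter": 500, "ftol": 1e-10},
        )
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
        any_success = any_success or bool(res.success)
    if best_x is None or not math.isfinite(best_f):
        raise RuntimeError("ARD fit failed from every start")
    Q_hat = build_Q(best_x)
    lnL = -best_f
    if not any_success:
        raise RuntimeError(f"ARD optimizer did not converge; best lnL {lnL:.4f}")
    return Q_hat, lnL, k, aicc(lnL, k, tree.n_tips)


def fit_tied_rates(
    tree: TimeTree,
    tip_states: dict[str, object],
    space: TraitStateSpace,
    mask: np.ndarray,
    root_prior: RootPrior,
    rate_bounds: tuple[float, float] = (1e-8, 100.0),
    starts: tuple[float, ...] = (0.02, 0.2, 2.0),
) -> tuple[np.ndarray, float, int, float]:
    """Like :func:`fit_ard`, but with one rate per (from_class, to_class)
    pair instead of one per state pair.

    On a palaeovalley-structured space the full ARD mask grows linearly in
    the number of valleys (40 free rates at 10 valleys); tying rates by
    habitat class (epigean, interstitial, subterranean) keeps the
    parameter count at the number of permitted class routes, which is what
    tip data at radiation scale can actually inform.  Requires a
    class-structured space.
    """
    if space.classes is None:
        raise ValueError("tied-rate fitting needs a class-structured space")
    model = MkModel(tree, tip_states, space, root_prior)
    S = space.n_states
    mask = np.asarray(mask, dtype=bool)
    free = np.argwhere(mask & ~np.eye(S, dtype=bool))
    if free.shape[0] == 0:
        raise ValueError("transition mask permits no transitions")
    pair_of = [
        (space.class_of(int(i)), space.class_of(int(k))) for i, k in free
    ]
    classes = sorted(set(pair_of))
    col = np.array([classes.index(p) for p in pair_of])
    k = len(classes)

    def build_Q(logr: np.ndarray) -> np.ndarray:
        Q = np.zeros((S, S))
        Q[free[:, 0], free[:, 1]] = np.exp(logr)[col]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def objective(logr: np.ndarray) -> float:
        ll = model.loglik(build_Q(logr))
        return 1e10 if not math.isfinite(ll) else -ll

    lo, hi = math.log(rate_bounds[0]), math.log(rate_bounds[1])
    best_x, best_f, any_success = None, math.inf, False
    for r0 in starts:
        res = scipy.optimize.minimize(
            objective,
            np.full(k, math.log(r0)),
            method="L-BFGS-B",
            bounds=[(lo, hi)] * k,
            options={"maxiter": 500, "ftol": 1e-10},
        )
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
        any_success = any_success or bool(res.success)
    if best_x is None or not math.isfinite(best_f) or not any_success:
        raise RuntimeError("tied-rate fit failed to converge")
    lnL = -best_f
    return build_Q(best_x), lnL, k, aicc(lnL, k, tree.n_tips)


# ---------------------------------------------------------------------------
# module-level convenience wrappers


def mk_loglik(
    tree: TimeTree,
    tip_states: dict[str, object],
    Q: np.ndarray,
    space: TraitStateSpace,
    root_prior: RootPrior,
) -> float:
    return MkModel(tree, tip_states, space, root_prior).loglik(Q)


def marginal_ancestral_states(
    tree: TimeTree,
    tip_states: dict[str, object],
    Q: np.ndarray,
    space: TraitStateSpace,
    root_prior: RootPrior,
) -> dict[int, np.ndarray]:
    return MkModel(tree, tip_states, space, root_prior).marginals(Q)


def simmap_sample(
    tree: TimeTree,
    tip_states: dict[str, object],
    Q: np.ndarray,
    space: TraitStateSpace,
    root_prior: RootPrior,
    n_sims: int = 1000,
    seed=None,
    mask: np.ndarray | None = None,
) -> list[SimmapHistory]:
    """Draw ``n_sims`` stochastic character maps (default 1000)."""
    return MkModel(tree, tip_states, space, root_prior).sample_histories(
        Q, n_sims, seed, mask=mask
    )


# ---------------------------------------------------------------------------
# colonization counting


@dataclass
class ColonizationSummary:
    """Counts across a set of sampled histories.

    Per history: within-branch transitions whose target class is
    subterranean (from any other class) or interstitial; internal nodes
    whose own state and both daughters' initial branch states are
    subterranean ("subterranean speciation"), and of those the count where
    all three share one palaeovalley.  Medians and central 95% intervals
    summarize the per-history counts.
    """

    entries_subterranean: np.ndarray
    entries_interstitial: np.ndarray
    subterranean_speciation: np.ndarray
    within_valley_speciation: np.ndarray

    def _summ(self, x: np.ndarray) -> dict:
        return {
            "median": float(np.median(x)),
            "q2.5": float(np.percentile(x, 2.5)),
            "q97.5": float(np.percentile(x, 97.5)),
        }

    def summary(self) -> dict:
        return {
            "entries_subterranean": self._summ(self.entries_subterranean),
            "entries_interstitial": self._summ(self.entries_interstitial),
            "subterranean_speciation": self._summ(self.subterranean_speciation),
            "within_valley_speciation": self._summ(self.within_valley_speciation),
            "n_histories": int(self.entries_subterranean.size),
        }


def count_colonizations(
    histories: list[SimmapHistory],
    tree: TimeTree,
    space: TraitStateSpace,
    mask: np.ndarray | None = None,
) -> ColonizationSummary:
    """Colonization and subterranean-speciation counts over sampled maps.

    An *entry* is a within-branch transition whose source class is not
    subterranean (resp. interstitial) and whose target class is; inheriting
    a state through a node without change is never an entry.  If ``mask``
    is given, any history containing a masked transition raises (integrity
    check).
    """
    if space.classes is None:
        raise ValueError("colonization counting needs a class-structured space")
    ent_sub, ent_int, spec_sub, spec_valley = [], [], [], []
    internal = [
        int(v) for v in tree.postorder() if not tree.is_tip(int(v))
    ]
    for h in histories:
        n_sub = n_int = 0
        for _, a, b in h.transitions():
            if mask is not None and not mask[a, b]:
                raise ValueError(
                    f"history contains masked transition "
                    f"{space.labels[a]} -> {space.labels[b]}"
                )
            ca, cb = space.class_of(a), space.class_of(b)
            if cb == "subterranean" and ca != "subterranean":
                n_sub += 1
            if cb == "interstitial" and ca != "interstitial":
                n_int += 1
        n_spec = n_wv = 0
        for v in internal:
            s = h.node_state[v]
            if space.class_of(s) != "subterranean":
                continue
            starts = [h.segments[c][0][0] for c in tree.children[v]]
            if all(space.class_of(x) == "subterranean" for x in starts):
                n_spec += 1
                valleys = {space.valley_of(s)} | {space.valley_of(x) for x in starts}
                if len(valleys) == 1:
                    n_wv += 1
        ent_sub.append(n_sub)
        ent_int.append(n_int)
        spec_sub.append(n_spec)
        spec_valley.append(n_wv)
    return ColonizationSummary(
        np.array(ent_sub), np.array(ent_int), np.array(spec_sub), np.array(spec_valley)
    )


# ---------------------------------------------------------------------------
# I/O


def read_trait_table(text: str) -> dict[str, object]:
    """TSV ``tip_label<TAB>state``; multiple states joined by '|' become
    ambiguity sets."""
    out: dict[str, object] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"bad trait row: {line!r}")
        tip, state = parts
        if tip in out:
            raise ValueError(f"duplicate tip {tip!r} in trait table")
        out[tip] = set(state.split("|")) if "|" in state else state
    return out


def write_trait_table(tip_states: dict[str, object]) -> str:
    lines = []
    for tip in sorted(tip_states):
        v = tip_states[tip]
        lines.append(f"{tip}\t{v if isinstance(v, str) else '|'.join(sorted(v))}")
    return "\n".join(lines) + "\n"


def simmap_event_log(histories: list[SimmapHistory], tree: TimeTree) -> str:
    """TSV event log: history, branch (child node id), time from the parent
    node, from_state, to_state."""
    lines = ["history\tbranch\ttime_from_parent\tfrom_state\tto_state"]
    for hi, h in enumerate(histories):
        for c in sorted(h.segments):
            elapsed = 0.0
            segs = h.segments[c]
            for (a, da), (b, _) in zip(segs, segs[1:]):
                elapsed += da
                lines.append(
                    f"{hi}\t{c}\t{elapsed:.6g}\t{h.space.labels[a]}\t{h.space.labels[b]}"
                )
    return "\n".join(lines) + "\n"
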