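"""Maximum-likelihood fitting of DEC-family models and AICc-based comparison
of biogeographic hypotheses.

A *hypothesis* is a dispersal setting: either unguided (all multipliers 1,
single stratum) or a stratified custom multiplier model, optionally with the
multiplier exponent ``w`` free.  Each hypothesis can be fit under every
model family with and without founder-event speciation, and the resulting
grid is ranked by small-sample corrected AIC.

The AICc sample size is the number of tips by default.  The literature is
not unanimous on this choice; it shifts every AICc by the same pattern
within a comparison of models on one tree, so rankings are unaffected, but
``n`` is exposed for users who prefer a different convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .dec import (
    CladogenesisSpec,
    DECModel,
    DECParams,
    GeographyData,
    StratifiedDispersalModel,
)
from .treeio import TimeTree

__all__ = [
    "FitResult",
    "HypothesisSpec",
    "FitError",
    "aicc",
    "fit_model",
    "hypothesis_suite",
    "DEFAULT_BOUNDS",
]

_FAMILY_ORDER = {"DEC": 0, "DIVALIKE": 1, "BAYAREALIKE": 2}

#: optimizer box constraints: d, e in events/Ma; j dimensionless (< 3 under
#: the default cladogenetic weight budget); w a dimensionless exponent
DEFAULT_BOUNDS = {
    "d": (1e-12, 5.0),
    "e": (1e-12, 5.0),
    "j": (0.0, 2.99999),
    "w": (0.0, 10.0),
}

#: deterministic multi-start grid over (d, e) plus optional j starts
_DE_STARTS = (0.01, 0.1, 1.0)
_J_STARTS = (0.0, 0.5)


class FitError(RuntimeError):
    """Optimization failed; carries the best point seen so far."""

    def __init__(self, message: str, best: "FitResult | None" = None):
        super().__init__(message)
        self.best = best


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    family: str
    free_j: bool
    free_w: bool
    params: DECParams
    lnL: float
    k: int
    aicc: float
    n: int
    hypothesis_id: str | None = None
    n_starts: int = 0
    n_evals: int = 0
    root_states: list[str] = field(default_factory=list)
    root_areas: str = ""

    @property
    def model_name(self) -> str:
        return self.family + ("+J" if self.free_j else "")


def aicc(lnL: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: 2k - 2 lnL + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return 2.0 * k - 2.0 * lnL + 2.0 * k * (k + 1) / (n - k - 1)


def _make_model(
    tree: TimeTree,
    geog: GeographyData,
    family: str,
    dispersal: StratifiedDispersalModel | None,
    max_range_size: int | None,
) -> DECModel:
    return DECModel(
        tree,
        geog,
        dispersal=dispersal,
        spec=CladogenesisSpec(family=family),
        max_range_size=max_range_size,
    )


def fit_model(
    tree: TimeTree,
    geog: GeographyData,
    family: str = "DEC",
    dispersal: StratifiedDispersalModel | None = None,
    free_j: bool = False,
    free_w: bool = False,
    max_range_size: int | None = None,
    bounds: dict | None = None,
    hypothesis_id: str | None = None,
    compute_root_areas: bool = True,
) -> FitResult:
    """Maximize the DEC-family likelihood over (d, e[, j][, w]).

    Deterministic: L-BFGS-B from a fixed start grid (3x3 over d, e; two j
    starts when j is free; w started at 1).  d and e are optimized on a log
    scale.  Raises :class:`FitError` carrying the best point if no start
    converges.
    """
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    model = _make_model(tree, geog, family, dispersal, max_range_size)
    n = tree.n_tips
    k = 2 + int(free_j) + int(free_w)

    n_evals = 0

    def unpack(x) -> DECParams:
        d = math.exp(x[0])
        e = math.exp(x[1])
        i = 2
        j = 0.0
        w = 1.0
        if free_j:
            j = x[i]
            i += 1
        if free_w:
            w = x[i]
        return DECParams(d=d, e=e, j=j, w=w)

    def objective(x) -> float:
        nonlocal n_evals
        n_evals += 1
        ll = model.loglik(unpack(x))
        if not math.isfinite(ll):
            return 1e10
        return -ll

    opt_bounds = [
        (math.log(b["d"][0]), math.log(b["d"][1])),
        (math.log(b["e"][0]), math.log(b["e"][1])),
    ]
    if free_j:
        opt_bounds.append(b["j"])
    if free_w:
        opt_bounds.append(b["w"])

    starts = []
    j_starts = _J_STARTS if free_j else (None,)
    for d0, e0, j0 in itertools.product(_DE_STARTS, _DE_STARTS, j_starts):
        x0 = [math.log(d0), math.log(e0)]
        if free_j:
            x0.append(j0)
        if free_w:
            x0.append(1.0)
        starts.append(x0)

    best_x, best_f, any_success = None, math.inf, False
    for x0 in starts:
        res = scipy.optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=opt_bounds,
            options={"maxiter": 200, "ftol": 1e-10},
        )
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
        any_success = any_success or bool(res.success)

    if best_x is None or not math.isfinite(best_f):
        raise FitError(f"no start point yielded a finite likelihood ({family})")
    params = unpack(best_x)
    lnL = -best_f
    result = FitResult(
        family=family,
        free_j=free_j,
        free_w=free_w,
        params=params,
        lnL=lnL,
        k=k,
        aicc=aicc(lnL, k, n),
        n=n,
        hypothesis_id=hypothesis_id,
        n_starts=len(starts),
        n_evals=n_evals,
    )
    if not any_success:
        raise FitError("optimizer did not converge from any start", best=result)
    if compute_root_areas:
        marg = model.marginals(params)
        states, union = model.root_areas_summary(marg[tree.root])
        result.root_states, result.root_areas = states, union
    return result


@dataclass(frozen=True)
class HypothesisSpec:
    """One biogeographic hypothesis: a dispersal setting plus whether the
    multiplier exponent ``w`` is a free parameter.

    ``dispersal=None`` is the unguided setting (all multipliers 1, single
    stratum); in that case ``w`` must stay fixed, since the exponent has no
    effect on an all-ones matrix.
    """

    id: str
    assumption: str = ""
    dispersal: StratifiedDispersalModel | None = None
    w_free: bool = False

    def __post_init__(self):
        if self.dispersal is None and self.w_free:
            raise ValueError(
                f"hypothesis {self.id!r}: w cannot be free without a multiplier matrix"
            )


def hypothesis_suite(
    tree: TimeTree,
    geog: GeographyData,
    hypotheses: list[HypothesisSpec],
    families: tuple[str, ...] = ("DEC", "DIVALIKE", "BAYAREALIKE"),
    free_j_options: tuple[bool, ...] = (False, True),
    max_range_size: int | None = None,
) -> pd.DataFrame:
    """Fit every hypothesis under every family (with/without founder-event
    speciation) and rank by AICc.

    Returns one row per hypothesis, sorted by hypothesis id, with the best
    model's name, AICc, delta-AICc against the overall best, and the
    root-areas summary.  Ties are broken by fewer free parameters, then by
    family order DEC < DIVALIKE < BAYAREALIKE.  A failed fit is recorded in
    the ``error`` column and the suite continues.
    """
    if not hypotheses:
        raise ValueError("need at least one hypothesis")
    rows = []
    fits: dict[str, list[FitResult]] = {}
    errors: dict[str, list[str]] = {}
    for hyp in hypotheses:
        fits[hyp.id] = []
        errors[hyp.id] = []
        for family in families:
            for free_j in free_j_options:
                try:
                    fit = fit_model(
                        tree,
                        geog,
                        family=family,
                        dispersal=hyp.dispersal,
                        free_j=free_j,
                        free_w=hyp.w_free,
                        max_range_size=max_range_size,
                        hypothesis_id=hyp.id,
                    )
                    fits[hyp.id].append(fit)
                except FitError as exc:
                    if exc.best is not None:
                        fits[hyp.id].append(exc.best)
                    else:
                        errors[hyp.id].append(
                            f"{family}{'+J' if free_j else ''}: {exc}"
                        )
    for hyp in sorted(hypotheses, key=lambda h: h.id):
        cand = fits[hyp.id]
        if not cand:
            rows.append(
                {
                    "hypothesis": hyp.id,
                    "assumption": hyp.assumption,
                    "best_model": None,
                    "lnL": np.nan,
                    "k": np.nan,
                    "AICc": np.nan,
                    "root_areas": "",
                    "error": "; ".join(errors[hyp.id]),
                }
            )
            continue
        best = min(
            cand, key=lambda f: (f.aicc, f.k, _FAMILY_ORDER[f.family], f.model_name)
        )
        rows.append(
            {
                "hypothesis": hyp.id,
                "assumption": hyp.assumption,
                "best_model": best.model_name + ("+w" if best.free_w else ""),
                "lnL": best.lnL,
                "k": best.k,
                "AICc": best.aicc,
                "root_areas": best.root_areas,
                "error": "; ".join(errors[hyp.id]),
            }
        )
    table = pd.DataFrame(rows)
    best_aicc = table["AICc"].min()
    table["delta_AICc"] = table["AICc"] - best_aicc
    return table
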