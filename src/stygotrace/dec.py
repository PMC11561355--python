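"""Dispersal-extinction-cladogenesis (DEC) range evolution with founder-event
speciation, time-stratified dispersal multipliers, and a multiplier exponent.

The anagenetic process is a CTMC over subsets of a small set of areas: an
area is gained at rate ``d`` (scaled by dispersal multipliers from the areas
already occupied) and lost at rate ``e``; the empty range is an absorbing
null state.  At each speciation node the ancestral range is partitioned
between the two daughters according to a cladogenetic event model (sympatry,
subset sympatry, vicariance, and optionally founder-event "jump" dispersal
weighted by ``j``).  Three classical families are supported:

``DEC``
    singleton sympatry, subset sympatry, and vicariance in which one
    daughter retains a single area;
``DIVALIKE``
    no subset sympatry; vicariance may split a widespread range into pieces
    of any size; widespread sympatry is forbidden;
``BAYAREALIKE``
    no cladogenetic range change at all — both daughters copy the ancestor.

Dispersal multipliers may vary across time strata (e.g. an area contributing
nothing before its geological emergence), and the exponent ``w`` softens or
sharpens multipliers strictly between 0 and 1; exact zeros stay zero for
every ``w`` so that a forbidden route can never be re-opened by the exponent.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .treeio import Stratification, TimeTree, slice_branch_by_strata

__all__ = [
    "AreaUniverse",
    "RangeStateSpace",
    "GeographyData",
    "StratifiedDispersalModel",
    "DECParams",
    "CladogenesisSpec",
    "DECModel",
    "enumerate_range_states",
    "build_anagenetic_Q",
    "cladogenesis_distribution",
    "dec_loglik",
    "ancestral_range_marginals",
    "read_geography",
    "write_geography",
    "read_dispersal_model",
    "write_dispersal_model",
    "MIOCENE_BASE_MA",
    "OLIGOCENE_BASE_MA",
]

#: conventional epoch-boundary ages (Ma) used as default stratum boundaries
#: for "standard" (Miocene-base) and "relaxed" (Oligocene-base) emergence
#: scenarios of a late-appearing area
MIOCENE_BASE_MA = 23.0
OLIGOCENE_BASE_MA = 34.0

_FAMILIES = ("DEC", "DIVALIKE", "BAYAREALIKE")

# outcome kind codes
_K_SYMPATRY = 0
_K_SUBSET = 1
_K_VICARIANCE = 2
_K_JUMP = 3
_K_NULL = 4  # extinct-range inheritance: both daughters stay null


@dataclass(frozen=True)
class AreaUniverse:
    """Ordered set of area labels.

    The default follows the five-area Australopacific scheme: East Asia (A),
    Australia (B), New Guinea (C), the Pacific archipelagos (D), and
    New Zealand (E).
    """

    labels: tuple[str, ...] = ("A", "B", "C", "D", "E")

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 1:
            raise ValueError("universe needs at least one area")
        if len(set(labels)) != len(labels):
            raise ValueError("area labels must be unique")

    @property
    def n_areas(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def mask_to_set(self, mask: int) -> frozenset[str]:
        return frozenset(l for i, l in enumerate(self.labels) if mask >> i & 1)

    def set_to_mask(self, areas) -> int:
        m = 0
        for a in areas:
            m |= 1 << self.index(a)
        return m

    def mask_to_string(self, mask: int) -> str:
        return "".join(l for i, l in enumerate(self.labels) if mask >> i & 1)


class RangeStateSpace:
    """All ranges of size <= max_range_size over a universe, as bitmasks.

    State 0 is the null range (a valid internal state of the CTMC, never an
    observation); the rest are ordered by range size then lexicographically
    by area order, e.g. for two areas: null, {A}, {B}, {A,B}.
    """

    def __init__(self, universe: AreaUniverse, max_range_size: int | None = None):
        self.universe = universe
        n = universe.n_areas
        if max_range_size is None:
            max_range_size = n
        if not (1 <= max_range_size <= n):
            raise ValueError(
                f"max_range_size must be in [1, {n}], got {max_range_size}"
            )
        self.max_range_size = int(max_range_size)
        states = [0]
        for size in range(1, self.max_range_size + 1):
            for combo in itertools.combinations(range(n), size):
                m = 0
                for i in combo:
                    m |= 1 << i
                states.append(m)
        self.states: tuple[int, ...] = tuple(states)
        self.index: dict[int, int] = {m: i for i, m in enumerate(states)}
        self.sizes = np.array([bin(m).count("1") for m in states])

    @property
    def n_states(self) -> int:
        return len(self.states)

    def as_sets(self) -> list[frozenset[str]]:
        return [self.universe.mask_to_set(m) for m in self.states]

    def labels(self) -> list[str]:
        return ["()" if m == 0 else self.universe.mask_to_string(m) for m in self.states]


def enumerate_range_states(
    universe: AreaUniverse, max_range_size: int
) -> list[frozenset[str]]:
    """Ordered range states (as area-label sets) including the null range."""
    return RangeStateSpace(universe, max_range_size).as_sets()


@dataclass(frozen=True)
class DECParams:
    """Anagenetic and cladogenetic rate parameters.

    d : per-area dispersal (range-gain) rate, events/Ma
    e : per-area range-loss rate, events/Ma
    j : founder-event (jump dispersal) cladogenetic weight
    w : exponent applied to dispersal multipliers strictly inside (0, 1)
    """

    d: float
    e: float
    j: float = 0.0
    w: float = 1.0

    def __post_init__(self):
        for name in ("d", "e", "j", "w"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class CladogenesisSpec:
    """Cladogenetic event model.

    ``y``, ``s``, ``v`` are the base weights of sympatry, subset sympatry
    and vicariance.  When left ``None`` they all default to ``(3 - j) / 3``
    — the usual weight budget under which the jump weight ``j`` is bounded
    by 3.  ``jump_scaled_by_multiplier`` multiplies each jump outcome's
    weight by the mean (effective) dispersal multiplier from the ancestral
    areas to the target area.
    """

    family: str = "DEC"
    y: float | None = None
    s: float | None = None
    v: float | None = None
    jump_scaled_by_multiplier: bool = True

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {_FAMILIES}")
        for name in ("y", "s", "v"):
            val = getattr(self, name)
            if val is not None and (not math.isfinite(val) or val < 0):
                raise ValueError(f"weight {name} must be finite and >= 0")

    def base_weights(self, j: float) -> tuple[float, float, float]:
        default = max(3.0 - j, 0.0) / 3.0
        y = default if self.y is None else self.y
        s = default if self.s is None else self.s
        v = default if self.v is None else self.v
        return y, s, v


class GeographyData:
    """Tip label -> geographic range (bitmask over an area universe)."""

    def __init__(
        self,
        universe: AreaUniverse,
        ranges: dict[str, int],
        allow_null: bool = False,
    ):
        self.universe = universe
        self.ranges = dict(ranges)
        full = (1 << universe.n_areas) - 1
        for label, m in self.ranges.items():
            if not (0 <= m <= full):
                raise ValueError(f"range of tip {label!r} uses areas outside the universe")
            if m == 0 and not allow_null:
                raise ValueError(f"tip {label!r} has an empty range")

    @classmethod
    def from_sets(cls, universe: AreaUniverse, tip_ranges: dict[str, set]) -> "GeographyData":
        return cls(universe, {k: universe.set_to_mask(v) for k, v in tip_ranges.items()})

    def range_set(self, label: str) -> frozenset[str]:
        return self.universe.mask_to_set(self.ranges[label])

    def check_tree(self, tree: TimeTree) -> None:
        tips = set(tree.tip_label.values())
        coded = set(self.ranges)
        if tips != coded:
            missing = sorted(tips - coded)
            extra = sorted(coded - tips)
            raise ValueError(
                f"geography does not match tree tips (missing {missing}, extra {extra})"
            )


def read_geography(text: str) -> GeographyData:
    """Parse the PHYLIP-style geography table.

    Header ``n_tips n_areas (A B C ...)``, then one row per tip:
    ``label<TAB>01001`` with one presence digit per area.
    """
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines:
        raise ValueError("empty geography file")
    head = lines[0].replace("(", " ").replace(")", " ").split()
    if len(head) < 3:
        raise ValueError(f"bad geography header: {lines[0]!r}")
    n_tips, n_areas = int(head[0]), int(head[1])
    labels = tuple(head[2:])
    if len(labels) != n_areas:
        raise ValueError(
            f"header declares {n_areas} areas but names {len(labels)}: {lines[0]!r}"
        )
    universe = AreaUniverse(labels)
    ranges: dict[str, int] = {}
    for line in lines[1:]:
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"bad geography row: {line!r}")
        tip, bits = parts
        if len(bits) != n_areas or set(bits) - {"0", "1"}:
            raise ValueError(f"bad presence string for tip {tip!r}: {bits!r}")
        if tip in ranges:
            raise ValueError(f"duplicate tip {tip!r} in geography file")
        ranges[tip] = sum(1 << i for i, b in enumerate(bits) if b == "1")
    if len(ranges) != n_tips:
        raise ValueError(f"header declares {n_tips} tips, found {len(ranges)}")
    return GeographyData(universe, ranges)


def write_geography(geog: GeographyData) -> str:
    u = geog.universe
    lines = [f"{len(geog.ranges)} {u.n_areas} ({' '.join(u.labels)})"]
    for tip in sorted(geog.ranges):
        bits = "".join("1" if geog.ranges[tip] >> i & 1 else "0" for i in range(u.n_areas))
        lines.append(f"{tip}\t{bits}")
    return "\n".join(lines) + "\n"


class StratifiedDispersalModel:
    """Per-stratum dispersal multiplier matrices (source area -> sink area).

    Entries are in [0, 1]; a value of 0 forbids the route and an area that
    has not yet emerged in a stratum has all incoming multipliers 0 there.
    """

    def __init__(
        self,
        universe: AreaUniverse,
        matrices: list[np.ndarray],
        stratification: Stratification | None = None,
    ):
        self.universe = universe
        self.stratification = stratification or Stratification()
        mats = [np.asarray(m, dtype=float) for m in matrices]
        if len(mats) != self.stratification.n_strata:
            raise ValueError(
                f"need {self.stratification.n_strata} matrices for "
                f"{len(self.stratification.boundary_ages)} boundaries, got {len(mats)}"
            )
        n = universe.n_areas
        for k, m in enumerate(mats):
            if m.shape != (n, n):
                raise ValueError(f"stratum {k} matrix has shape {m.shape}, expected {(n, n)}")
            if np.any(m < 0) or np.any(m > 1):
                raise ValueError(f"stratum {k} multipliers must lie in [0, 1]")
        self.matrices = mats

    @classmethod
    def uniform(cls, universe: AreaUniverse) -> "StratifiedDispersalModel":
        """Single stratum, all multipliers 1 (the 'unguided' setting)."""
        n = universe.n_areas
        return cls(universe, [np.ones((n, n))])

    @property
    def n_strata(self) -> int:
        return self.stratification.n_strata

    def effective(self, w: float) -> list[np.ndarray]:
        """Apply the exponent ``w`` to multipliers strictly inside (0, 1).

        Exact zeros remain zero for every ``w`` (including w=0), so routes
        closed by geology can never be re-opened by the exponent; exact ones
        remain one.
        """
        out = []
        for m in self.matrices:
            eff = m.copy()
            inner = (m > 0) & (m < 1)
            eff[inner] = m[inner] ** w
            out.append(eff)
        return out

    def with_area_unavailable(self, area: str, strata: list[int]) -> "StratifiedDispersalModel":
        """Copy with all incoming multipliers of ``area`` zeroed in the given strata."""
        idx = self.universe.index(area)
        mats = [m.copy() for m in self.matrices]
        for s in strata:
            mats[s][:, idx] = 0.0
        return StratifiedDispersalModel(self.universe, mats, self.stratification)


def read_dispersal_model(text: str, universe: AreaUniverse) -> StratifiedDispersalModel:
    """Parse per-stratum multiplier matrices.

    Each stratum is a header line ``stratum <old_age> <young_age>`` followed
    by ``n_areas`` whitespace-delimited rows; strata are listed oldest
    first, ``inf`` allowed for the oldest bound and the youngest must end at 0.
    """
    lines = [l.strip() for l in text.splitlines() if l.strip()]
    n = universe.n_areas
    strata: list[tuple[float, float, np.ndarray]] = []
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if parts[0].lower() != "stratum" or len(parts) != 3:
            raise ValueError(f"expected 'stratum <old> <young>' header, got {lines[i]!r}")
        old, young = float(parts[1]), float(parts[2])
        rows = lines[i + 1 : i + 1 + n]
        if len(rows) != n:
            raise ValueError(f"stratum starting at {lines[i]!r} has fewer than {n} rows")
        mat = np.array([[float(x) for x in r.split()] for r in rows])
        strata.append((old, young, mat))
        i += 1 + n
    if not strata:
        raise ValueError("no strata found")
    boundaries = [young for old, young, _ in strata[:-1]]
    for (o1, y1, _), (o2, y2, _) in zip(strata, strata[1:]):
        if y1 != o2:
            raise ValueError(f"non-contiguous strata: {y1} followed by {o2}")
    if strata[-1][1] != 0:
        raise ValueError("youngest stratum must extend to the present (young age 0)")
    return StratifiedDispersalModel(
        universe, [m for _, _, m in strata], Stratification(tuple(boundaries))
    )


def write_dispersal_model(model: StratifiedDispersalModel) -> str:
    bounds = [math.inf, *model.stratification.boundary_ages, 0.0]
    out = []
    for k, mat in enumerate(model.matrices):
        out.append(f"stratum {bounds[k]:g} {bounds[k + 1]:g}")
        for row in mat:
            out.append(" ".join(f"{x:g}" for x in row))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# anagenetic rate matrix


def build_anagenetic_Q(
    params: DECParams,
    multipliers: np.ndarray,
    space: RangeStateSpace,
    apply_w: bool = True,
) -> np.ndarray:
    """Dense rate matrix over the range-state space for one stratum.

    Gains: Q[R, R+a] = d * sum_{i in R} m_eff[i, a] for a outside R while
    |R+a| stays within the range-size cap.  Losses: Q[R, R-a] = e for every
    a in R (singletons decay to the absorbing null range).  Rows sum to 0.
    """
    m = np.asarray(multipliers, dtype=float)
    if np.any(m < 0):
        raise ValueError("dispersal multipliers must be >= 0")
    if apply_w:
        eff = m.copy()
        inner = (m > 0) & (m < 1)
        eff[inner] = m[inner] ** params.w
    else:
        eff = m
    S = space.n_states
    n = space.universe.n_areas
    Q = np.zeros((S, S))
    for si, R in enumerate(space.states):
        if R == 0:
            continue  # null range is absorbing
        occupied = [i for i in range(n) if R >> i & 1]
        for a in range(n):
            if R >> a & 1:
                target = R & ~(1 << a)
                Q[si, space.index[target]] += params.e
            else:
                grown = R | (1 << a)
                if grown in space.index:
                    rate = params.d * sum(eff[i, a] for i in occupied)
                    Q[si, space.index[grown]] += rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


# ---------------------------------------------------------------------------
# cladogenesis


class _CladoStructure:
    """Parameter-independent enumeration of cladogenetic outcomes.

    Outcomes are ordered daughter pairs.  Symmetric events and asymmetric
    non-jump events are enumerated in every ordering, each carrying the full
    class weight; jump events are enumerated once as (ancestor, jump
    daughter) carrying weight j (times the optional multiplier scaling).
    The expansion arrays redistribute each outcome's probability over both
    left/right daughter assignments (half-half when asymmetric), which is
    what the pruning merge and the forward simulator consume.
    """

    def __init__(self, space: RangeStateSpace, family: str):
        self.space = space
        self.family = family
        n = space.universe.n_areas
        anc, d1, d2, kind, target = [], [], [], [], []

        def add(a, x, y, k, t=-1):
            anc.append(space.index[a])
            d1.append(space.index[x])
            d2.append(space.index[y])
            kind.append(k)
            target.append(t)

        for R in space.states:
            if R == 0:
                # a lineage whose range has gone extinct passes the null
                # range to both daughters; with nonempty tip data this
                # outcome carries zero conditional likelihood automatically
                add(0, 0, 0, _K_NULL)
                continue
            size = bin(R).count("1")
            areas = [i for i in range(n) if R >> i & 1]
            if family == "BAYAREALIKE":
                add(R, R, R, _K_SYMPATRY)
            elif size == 1:
                add(R, R, R, _K_SYMPATRY)
            else:
                if family == "DEC":
                    for a in areas:
                        single = 1 << a
                        add(R, R, single, _K_SUBSET)
                        add(R, single, R, _K_SUBSET)
                # vicariance: ordered bipartitions (both nonempty); DEC
                # additionally requires one side to be a single area
                for sub_size in range(1, size):
                    if family == "BAYAREALIKE":
                        break
                    for combo in itertools.combinations(areas, sub_size):
                        if family == "DEC" and sub_size != 1 and size - sub_size != 1:
                            continue
                        left = 0
                        for i in combo:
                            left |= 1 << i
                        add(R, left, R & ~left, _K_VICARIANCE)
            # founder-event jumps to any unoccupied single area
            for a in range(n):
                if not R >> a & 1:
                    add(R, R, 1 << a, _K_JUMP, a)

        self.anc = np.array(anc, dtype=int)
        self.d1 = np.array(d1, dtype=int)
        self.d2 = np.array(d2, dtype=int)
        self.kind = np.array(kind, dtype=int)
        self.target = np.array(target, dtype=int)
        # mean-multiplier scaling helper: row-normalized ancestor membership
        memb = np.zeros((len(anc), n))
        for o, si in enumerate(self.anc):
            R = space.states[si]
            areas = [i for i in range(n) if R >> i & 1]
            if areas:
                memb[o, areas] = 1.0 / len(areas)
        self.anc_membership = memb

        # symmetrized expansion over left/right daughter assignments
        eo, e1, e2, ef = [], [], [], []
        for o in range(len(anc)):
            if self.d1[o] == self.d2[o]:
                eo.append(o); e1.append(self.d1[o]); e2.append(self.d2[o]); ef.append(1.0)
            else:
                eo.append(o); e1.append(self.d1[o]); e2.append(self.d2[o]); ef.append(0.5)
                eo.append(o); e1.append(self.d2[o]); e2.append(self.d1[o]); ef.append(0.5)
        self.exp_out = np.array(eo, dtype=int)
        self.exp_d1 = np.array(e1, dtype=int)
        self.exp_d2 = np.array(e2, dtype=int)
        self.exp_factor = np.array(ef)
        self.exp_anc = self.anc[self.exp_out]

    def outcome_probs(
        self, spec: CladogenesisSpec, params: DECParams, eff_multipliers: np.ndarray
    ) -> np.ndarray:
        """Per-outcome probabilities, normalized within each ancestor state."""
        y, s, v = spec.base_weights(params.j)
        w = np.empty(self.anc.size)
        w[self.kind == _K_SYMPATRY] = y
        w[self.kind == _K_SUBSET] = s
        w[self.kind == _K_VICARIANCE] = v
        w[self.kind == _K_NULL] = 1.0
        jmask = self.kind == _K_JUMP
        if jmask.any():
            jw = np.full(jmask.sum(), params.j)
            if spec.jump_scaled_by_multiplier:
                scale = np.einsum(
                    "oa,ao->o",
                    self.anc_membership[jmask],
                    eff_multipliers[:, self.target[jmask]],
                )
                jw = jw * scale
            w[jmask] = jw
        denom = np.bincount(self.anc, weights=w, minlength=self.space.n_states)
        probs = np.zeros_like(w)
        ok = denom[self.anc] > 0
        probs[ok] = w[ok] / denom[self.anc[ok]]
        self._last_denom = denom
        return probs


_structure_cache: dict[tuple[int, int, str], _CladoStructure] = {}


def _get_structure(space: RangeStateSpace, family: str) -> _CladoStructure:
    key = (space.universe.labels, space.max_range_size, family)
    st = _structure_cache.get(key)
    if st is None:
        st = _CladoStructure(space, family)
        _structure_cache[key] = st
    return st


def cladogenesis_distribution(
    ancestor,
    spec: CladogenesisSpec,
    params: DECParams,
    multipliers: np.ndarray,
    space: RangeStateSpace,
) -> dict[tuple[frozenset, frozenset], float]:
    """Distribution over ordered daughter-range pairs for one ancestor range.

    ``ancestor`` may be an area-label set or a bitmask.  Probabilities sum
    to 1 over the outcomes legal for the family; an empty ancestor is an
    error (the null range cannot speciate).
    """
    u = space.universe
    mask = ancestor if isinstance(ancestor, int) else u.set_to_mask(ancestor)
    if mask == 0:
        raise ValueError("the null range has no cladogenetic outcomes")
    if mask not in space.index:
        raise ValueError("ancestor range exceeds max_range_size")
    st = _get_structure(space, spec.family)
    eff = np.asarray(multipliers, dtype=float).copy()
    inner = (eff > 0) & (eff < 1)
    eff[inner] = eff[inner] ** params.w
    probs = st.outcome_probs(spec, params, eff)
    si = space.index[mask]
    sel = st.anc == si
    if probs[sel].sum() <= 0:
        raise ValueError("all cladogenetic outcomes have zero weight for this ancestor")
    out: dict[tuple[frozenset, frozenset], float] = {}
    for o in np.flatnonzero(sel):
        if probs[o] == 0:
            continue
        key = (
            u.mask_to_set(space.states[st.d1[o]]),
            u.mask_to_set(space.states[st.d2[o]]),
        )
        out[key] = out.get(key, 0.0) + float(probs[o])
    return out


# ---------------------------------------------------------------------------
# propagators


class _Propagator:
    """Transition probabilities P(t) = expm(Q t) via eigendecomposition,
    falling back to scaling-and-squaring when Q is ill-conditioned."""

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self._fallback = False
        try:
            w, V = scipy.linalg.eig(Q)
            # repeated eigenvalues (e.g. d or e at 0) make V defective;
            # check conditioning before attempting the inverse
            if not np.all(np.isfinite(V)) or np.linalg.cond(V) > 1e8:
                raise np.linalg.LinAlgError
            Vinv = scipy.linalg.inv(V)
            if not np.all(np.isfinite(Vinv)):
                raise np.linalg.LinAlgError
            self._w, self._V, self._Vinv = w, V, Vinv
        except (np.linalg.LinAlgError, ValueError):
            self._fallback = True

    def P(self, t: float) -> np.ndarray:
        if t == 0:
            return np.eye(self.Q.shape[0])
        if self._fallback:
            P = scipy.linalg.expm(self.Q * t)
        else:
            P = ((self._V * np.exp(self._w * t)) @ self._Vinv).real
        np.clip(P, 0.0, None, out=P)
        return P


# ---------------------------------------------------------------------------
# likelihood engine


class DECModel:
    """Pruning likelihood and marginal ancestral ranges for one dataset.

    Precomputes the traversal order, per-branch stratum segments and tip
    state vectors once, so repeated likelihood evaluations during
    optimization only rebuild the parameter-dependent pieces (rate matrices,
    their propagators and the cladogenetic tables, one set per stratum).

    The root is handled with a flat prior over nonempty ranges within the
    size cap (no cladogenetic event at the root); pass ``root_prior`` to
    override.
    """

    def __init__(
        self,
        tree: TimeTree,
        geog: GeographyData,
        dispersal: StratifiedDispersalModel | None = None,
        spec: CladogenesisSpec | None = None,
        max_range_size: int | None = None,
        root_prior: np.ndarray | None = None,
    ):
        self.tree = tree
        self.geog = geog
        self.universe = geog.universe
        self.dispersal = dispersal or StratifiedDispersalModel.uniform(self.universe)
        if self.dispersal.universe.labels != self.universe.labels:
            raise ValueError("dispersal model and geography use different universes")
        self.spec = spec or CladogenesisSpec()
        if max_range_size is None:
            max_range_size = self.universe.n_areas
        self.space = RangeStateSpace(self.universe, max_range_size)
        self.structure = _get_structure(self.space, self.spec.family)
        geog.check_tree(tree)

        ages = tree.node_ages()
        strat = self.dispersal.stratification
        strat.check_against_root(tree.root_age)
        self._tipvec: dict[int, np.ndarray] = {}
        for nid, label in tree.tip_label.items():
            mask = geog.ranges[label]
            if mask not in self.space.index:
                raise ValueError(
                    f"tip {label!r} has a range of {bin(mask).count('1')} areas, "
                    f"larger than max_range_size={self.space.max_range_size}"
                )
            v = np.zeros(self.space.n_states)
            v[self.space.index[mask]] = 1.0
            self._tipvec[nid] = v
        self._segments: dict[int, list[tuple[int, float]]] = {}
        for v in tree.postorder():
            v = int(v)
            if v == tree.root:
                continue
            self._segments[v] = slice_branch_by_strata(
                (ages[tree.parent[v]], ages[v]), strat
            )
        self._node_stratum = {
            int(v): strat.stratum_of(ages[int(v)])
            for v in tree.postorder()
            if not tree.is_tip(int(v))
        }
        if root_prior is None:
            pi = np.ones(self.space.n_states)
            pi[0] = 0.0
            pi /= pi.sum()
        else:
            pi = np.asarray(root_prior, dtype=float)
            if pi.shape != (self.space.n_states,) or pi.sum() <= 0:
                raise ValueError("root prior must be a nonnegative vector over states")
            pi = pi / pi.sum()
        self.root_prior = pi

    # -- per-parameter machinery ------------------------------------------

    def _prepare(self, params: DECParams):
        eff = self.dispersal.effective(params.w)
        props = [
            _Propagator(build_anagenetic_Q(params, m, self.space, apply_w=False))
            for m in eff
        ]
        st = self.structure
        merge_w = []
        for m in eff:
            probs = st.outcome_probs(self.spec, params, m)
            merge_w.append(probs[st.exp_out] * st.exp_factor)
        return props, merge_w

    def _branch_P(self, node: int, props) -> np.ndarray:
        P = None
        for stratum, dur in self._segments[node]:
            Pk = props[stratum].P(dur)
            P = Pk if P is None else P @ Pk
        return P

    def _downpass(self, params: DECParams):
        props, merge_w = self._prepare(params)
        st = self.structure
        tree = self.tree
        CL: dict[int, np.ndarray] = {}
        D: dict[int, np.ndarray] = {}
        Pbr: dict[int, np.ndarray] = {}
        logscale = 0.0
        dead = False
        for v in tree.postorder():
            v = int(v)
            if tree.is_tip(v):
                CL[v] = self._tipvec[v]
                continue
            c1, c2 = tree.children[v]
            P1 = self._branch_P(c1, props)
            P2 = self._branch_P(c2, props)
            Pbr[c1], Pbr[c2] = P1, P2
            D1 = P1 @ CL[c1]
            D2 = P2 @ CL[c2]
            D[c1], D[c2] = D1, D2
            w = merge_w[self._node_stratum[v]]
            cl = np.bincount(
                st.exp_anc,
                weights=w * D1[st.exp_d1] * D2[st.exp_d2],
                minlength=self.space.n_states,
            )
            mx = cl.max()
            if mx <= 0 or not np.isfinite(mx):
                dead = True
                cl = np.zeros_like(cl)
            else:
                logscale += math.log(mx)
                cl = cl / mx
            CL[v] = cl
        return CL, D, Pbr, logscale, dead, props, merge_w

    def loglik(self, params: DECParams) -> float:
        """Log-likelihood of the tip ranges (<= 0, or -inf if impossible)."""
        CL, _, _, logscale, dead, _, _ = self._downpass(params)
        L = float(self.root_prior @ CL[self.tree.root])
        if dead or L <= 0:
            return -math.inf
        return math.log(L) + logscale

    def marginals(self, params: DECParams) -> dict[int, np.ndarray]:
        """Marginal posterior range distribution at the root and every
        internal node (probability vector over the state space)."""
        CL, D, Pbr, _, dead, props, merge_w = self._downpass(params)
        if dead:
            raise ValueError("data have zero likelihood under these parameters")
        tree = self.tree
        st = self.structure
        O: dict[int, np.ndarray] = {tree.root: self.root_prior.copy()}
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
            w = merge_w[self._node_stratum[v]]
            ww = w * O[v][st.exp_anc]
            Otop1 = np.bincount(
                st.exp_d1, weights=ww * D[c2][st.exp_d2], minlength=self.space.n_states
            )
            Otop2 = np.bincount(
                st.exp_d2, weights=ww * D[c1][st.exp_d1], minlength=self.space.n_states
            )
            for c, Otop in ((c1, Otop1), (c2, Otop2)):
                if not tree.is_tip(c):
                    Oc = Pbr[c].T @ Otop
                    s = Oc.sum()
                    O[c] = Oc / s if s > 0 else Oc
        return out

    def root_areas_summary(
        self, marginal_root: np.ndarray, threshold: float = 0.95
    ) -> tuple[list[str], str]:
        """Smallest set of range states whose cumulative root probability
        reaches ``threshold``, plus the union of their areas as a label."""
        order = np.argsort(-marginal_root, kind="stable")
        total = 0.0
        chosen: list[int] = []
        for i in order:
            chosen.append(int(i))
            total += marginal_root[i]
            if total >= threshold:
                break
        union = 0
        for i in chosen:
            union |= self.space.states[i]
        labels = self.space.labels()
        return [labels[i] for i in chosen], self.universe.mask_to_string(union)


def dec_loglik(
    tree: TimeTree,
    geog: GeographyData,
    params: DECParams,
    dispersal: StratifiedDispersalModel | None = None,
    spec: CladogenesisSpec | None = None,
    max_range_size: int | None = None,
) -> float:
    """One-shot DEC-family log-likelihood (see :class:`DECModel`)."""
    return DECModel(tree, geog, dispersal, spec, max_range_size).loglik(params)


def ancestral_range_marginals(
    tree: TimeTree,
    geog: GeographyData,
    params: DECParams,
    dispersal: StratifiedDispersalModel | None = None,
    spec: CladogenesisSpec | None = None,
    max_range_size: int | None = None,
):
    """Per-internal-node marginal range distributions plus the root-areas
    summary (state labels covering 95% posterior mass and their area union)."""
    model = DECModel(tree, geog, dispersal, spec, max_range_size)
    marg = model.marginals(params)
    states, union = model.root_areas_summary(marg[tree.root])
    return marg, states, union
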