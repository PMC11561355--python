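"""Forward simulators for every data type the inference modules consume.

Each simulator is seeded, reproducible, and returns a :class:`SimTruth`
recording the generating parameters and the complete latent history
(true node states, every anagenetic event with its time), sufficient to
score any downstream inference against the truth.

The :func:`study_mimic` preset assembles a dataset with the statistical
shape of a subterranean diving-beetle radiation: ~95 tips with a crown age
of ~17 Ma, five geographic areas with one area contributing no dispersal
before the Miocene, habitat states structured by palaeovalley with rare
epigean-to-subterranean transitions, and coding alignments carrying
injected frameshift/stop lesions shared within sister pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dec import (
    AreaUniverse,
    CladogenesisSpec,
    DECParams,
    GeographyData,
    RangeStateSpace,
    StratifiedDispersalModel,
    _get_structure,
    build_anagenetic_Q,
    MIOCENE_BASE_MA,
)
from .pseudogene import STANDARD_STOPS, CodingAlignment
from .treeio import Stratification, TimeTree, slice_branch_by_strata
from .trait_mk import TraitStateSpace, build_habitat_space

__all__ = [
    "SimTruth",
    "simulate_bd_tree",
    "simulate_dec_tips",
    "simulate_mk_tips",
    "simulate_coding_alignment",
    "habitat_rate_matrix",
    "study_mimic",
]


@dataclass
class SimTruth:
    """Generating parameters plus the full latent history of one simulation."""

    params: dict
    seed: object
    node_states: dict[int, object] = field(default_factory=dict)
    events: list[tuple] = field(default_factory=list)
    flags: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# birth-death trees


def simulate_bd_tree(
    birth_rate: float,
    death_rate: float,
    n_tips: int,
    seed,
    root_age: float | None = None,
    max_retries: int = 1000,
) -> tuple[TimeTree, SimTruth]:
    """Ultrametric binary tree with exactly ``n_tips`` extant tips.

    Forward (Gillespie) birth-death from a crown of two lineages,
    conditioned on survival by simple rejection; when the extant count
    first reaches ``n_tips`` the clock runs on to the moment the *next*
    event would occur and the tree is cut there, so under pure birth the
    expected crown age is sum_{k=2..n} 1/(lambda k).  Extinct subtrees are
    pruned.  ``root_age`` optionally rescales the crown age (e.g. to 17 Ma).
    """
    if not (birth_rate > death_rate >= 0):
        raise ValueError("need birth_rate > death_rate >= 0")
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    rng = np.random.default_rng(seed)
    total_rate = birth_rate + death_rate

    for attempt in range(max_retries):
        # records: start time, parent record, children records, end time
        recs: list[dict] = [dict(start=0.0, parent=None, children=[], end=0.0)]
        recs.append(dict(start=0.0, parent=0, children=[], end=None))
        recs.append(dict(start=0.0, parent=0, children=[], end=None))
        recs[0]["children"] = [1, 2]
        active = [1, 2]
        t = 0.0
        present = None
        while True:
            k = len(active)
            if k == 0:
                break
            dt = rng.exponential(1.0 / (k * total_rate))
            t += dt
            if k == n_tips:
                present = t
                break
            idx = active[rng.integers(k)]
            if rng.random() < birth_rate / total_rate:
                recs[idx]["end"] = t
                for _ in range(2):
                    recs.append(dict(start=t, parent=idx, children=[], end=None))
                    recs[idx]["children"].append(len(recs) - 1)
                    active.append(len(recs) - 1)
                active.remove(idx)
            else:
                recs[idx]["end"] = t
                active.remove(idx)
        if present is None:
            continue  # total extinction; retry
        for idx in active:
            recs[idx]["end"] = present
            recs[idx]["extant"] = True

        # prune extinct subtrees, merging pass-through (unifurcation) spans
        def prune(i: int, span_start: float):
            r = recs[i]
            if not r["children"]:
                if r.get("extant"):
                    return ("tip", span_start, present)
                return None
            kept = [prune(c, recs[c]["start"]) for c in r["children"]]
            kept = [x for x in kept if x is not None]
            if not kept:
                return None
            if len(kept) == 1:
                kind, _, *rest = kept[0]
                return (kind, span_start, *rest)
            return ("node", span_start, r["end"], kept)

        top = prune(0, 0.0)
        assert top is not None and top[0] == "node"

        # flatten to TimeTree arrays; drop any stem above the crown node
        parent_arr: list[int] = []
        blen: list[float] = []
        tip_label: dict[int, str] = {}
        counter = [0]

        def emit(node, parent_id: int, parent_time: float) -> None:
            my_id = len(parent_arr)
            parent_arr.append(parent_id)
            if node[0] == "tip":
                _, s, e = node
                blen.append(e - parent_time if parent_id >= 0 else math.nan)
                counter[0] += 1
                tip_label[my_id] = f"t{counter[0]}"
            else:
                _, s, e, kids = node
                blen.append(e - parent_time if parent_id >= 0 else math.nan)
                for kid in kids:
                    emit(kid, my_id, e)

        # the crown node is `top` itself (its two kept children split at top[2])
        emit(top, -1, 0.0)
        scale = 1.0
        if root_age is not None:
            crown = present - top[2]  # split time of the emitted root to present
            scale = root_age / crown
        blen_arr = np.array(
            [b * scale if math.isfinite(b) else math.nan for b in blen]
        )
        tree = TimeTree(np.array(parent_arr), blen_arr, tip_label)
        truth = SimTruth(
            params=dict(
                birth_rate=birth_rate,
                death_rate=death_rate,
                n_tips=n_tips,
                root_age=root_age,
            ),
            seed=seed,
            flags=dict(attempts=attempt + 1, rescaled=root_age is not None),
            extras=dict(raw_crown_age=present - top[2]),
        )
        return tree, truth
    raise RuntimeError(f"total extinction in every one of {max_retries} attempts")


# ---------------------------------------------------------------------------
# DEC forward simulation


def _gillespie_segment(
    Q: np.ndarray, state: int, duration: float, rng: np.random.Generator
) -> tuple[int, list[tuple[float, int, int]]]:
    """Exact simulation of a CTMC over one interval; events as
    (elapsed_time, from_state, to_state)."""
    events = []
    t = 0.0
    while True:
        rate = -Q[state, state]
        if rate <= 0:
            return state, events
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            return state, events
        probs = Q[state, :].clip(min=0.0)
        probs[state] = 0.0
        probs /= probs.sum()
        new = int(rng.choice(probs.size, p=probs))
        events.append((t, state, new))
        state = new


def simulate_dec_tips(
    tree: TimeTree,
    params: DECParams,
    dispersal: StratifiedDispersalModel,
    spec: CladogenesisSpec,
    root_range,
    seed,
    max_range_size: int | None = None,
    redraw_on_null: bool = False,
    max_redraws: int = 100,
) -> tuple[GeographyData, SimTruth]:
    """Forward-simulate geographic ranges down a dated tree.

    Anagenesis by exact stochastic simulation of the per-stratum rate
    matrix along branch segments; cladogenesis by drawing a daughter pair
    from the cladogenetic outcome distribution at each node (orientation to
    left/right child randomized).  Lineages absorbed into the null range
    stay null; if any tip ends null the dataset is flagged
    (``truth.flags['has_null_tips']``) and optionally redrawn.
    """
    universe = dispersal.universe
    space = RangeStateSpace(universe, max_range_size)
    structure = _get_structure(space, spec.family)
    root_mask = root_range if isinstance(root_range, int) else universe.set_to_mask(root_range)
    if root_mask == 0 or root_mask not in space.index:
        raise ValueError("root range must be nonempty and within the size cap")
    rng = np.random.default_rng(seed)
    ages = tree.node_ages()
    strat = dispersal.stratification
    strat.check_against_root(tree.root_age)
    eff = dispersal.effective(params.w)
    Qs = [build_anagenetic_Q(params, m, space, apply_w=False) for m in eff]
    probs_by_stratum = [structure.outcome_probs(spec, params, m) for m in eff]
    outcome_ids = {
        si: np.flatnonzero(structure.anc == si) for si in range(space.n_states)
    }

    for attempt in range(max_redraws + 1):
        node_state: dict[int, int] = {tree.root: space.index[root_mask]}
        events: list[tuple] = []
        clado_events: list[tuple] = []
        for v in tree.preorder():
            v = int(v)
            if tree.is_tip(v):
                continue
            si = node_state[v]
            if space.states[si] == 0:
                daughters = (si, si)  # extinct range: nothing to inherit
            else:
                ids = outcome_ids[si]
                p = probs_by_stratum[strat.stratum_of(ages[v])][ids]
                o = int(ids[rng.choice(ids.size, p=p / p.sum())])
                d1, d2 = structure.d1[o], structure.d2[o]
                if d1 != d2 and rng.random() < 0.5:
                    d1, d2 = d2, d1
                daughters = (int(d1), int(d2))
                clado_events.append((v, si, daughters))
            for c, dstate in zip(tree.children[v], daughters):
                state = dstate
                segs = slice_branch_by_strata((ages[v], ages[c]), strat)
                top_age = ages[v]
                for stratum, dur in segs:
                    state, ev = _gillespie_segment(Qs[stratum], state, dur, rng)
                    events.extend(
                        (c, top_age - et, space.states[a], space.states[b])
                        for et, a, b in ev
                    )
                    top_age -= dur
                node_state[c] = state
        tip_ranges = {
            tree.tip_label[i]: space.states[node_state[i]] for i in tree.tip_label
        }
        has_null = any(m == 0 for m in tip_ranges.values())
        if not has_null or not redraw_on_null:
            truth = SimTruth(
                params=dict(
                    d=params.d, e=params.e, j=params.j, w=params.w,
                    family=spec.family, root_range=root_mask,
                ),
                seed=seed,
                node_states={v: space.states[s] for v, s in node_state.items()},
                events=events,
                flags=dict(has_null_tips=has_null, redraws=attempt),
                extras=dict(clado_events=clado_events),
            )
            geog = GeographyData(universe, tip_ranges, allow_null=has_null)
            return geog, truth
    raise RuntimeError(f"null-range tips persisted through {max_redraws} redraws")


# ---------------------------------------------------------------------------
# Mk forward simulation


def simulate_mk_tips(
    tree: TimeTree,
    Q: np.ndarray,
    space: TraitStateSpace,
    root_state: str,
    seed,
) -> tuple[dict[str, str], SimTruth]:
    """Forward-simulate a discrete trait down the tree (Gillespie).

    The truth records every transition as (branch_child_node,
    time_from_parent, from_label, to_label), the true state of every node,
    and per-state total dwell times (for rate-estimator checks).
    """
    Q = np.asarray(Q, dtype=float)
    rng = np.random.default_rng(seed)
    root_idx = space.index(root_state)
    node_state: dict[int, int] = {tree.root: root_idx}
    events: list[tuple] = []
    dwell = np.zeros(space.n_states)
    n_segments = 0
    for v in tree.preorder():
        v = int(v)
        for c in tree.children[v]:
            state = node_state[v]
            bl = float(tree.branch_length[c])
            new_state, ev = _gillespie_segment(Q, state, bl, rng)
            last = 0.0
            for et, a, b in ev:
                events.append((c, et, space.labels[a], space.labels[b]))
                dwell[a] += et - last
                last = et
            dwell[ev[-1][2] if ev else state] += bl - last
            n_segments += len(ev) + 1
            node_state[c] = new_state
    tip_states = {tree.tip_label[i]: space.labels[node_state[i]] for i in tree.tip_label}
    truth = SimTruth(
        params=dict(root_state=root_state),
        seed=seed,
        node_states={v: space.labels[s] for v, s in node_state.items()},
        events=events,
        extras=dict(dwell_times=dwell, n_segments=n_segments),
    )
    return tip_states, truth


def habitat_rate_matrix(
    space: TraitStateSpace,
    mask: np.ndarray,
    rates: dict[tuple[str, str], float] | float,
) -> np.ndarray:
    """Build a rate matrix on a masked space.

    ``rates`` is either one rate for every permitted transition or a map
    from (from_class, to_class) pairs — e.g. ("epigean", "subterranean") —
    to per-route rates.
    """
    S = space.n_states
    Q = np.zeros((S, S))
    for i in range(S):
        for k in range(S):
            if i == k or not mask[i, k]:
                continue
            if isinstance(rates, dict):
                key = (space.class_of(i), space.class_of(k))
                Q[i, k] = rates.get(key, 0.0)
            else:
                Q[i, k] = float(rates)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


# ---------------------------------------------------------------------------
# coding alignments with injected lesions


def simulate_coding_alignment(
    n_seqs: int,
    n_codons: int,
    lesion_plan: list[tuple],
    seed,
    n_substitutions: int = 0,
) -> tuple[CodingAlignment, SimTruth]:
    """Codon alignment: an intact reference ORF plus queries carrying
    exactly the planned lesions.

    ``lesion_plan`` entries are ``(seq_id, kind, codon_index)`` or
    ``(seq_id, kind, codon_index, detail)`` with 1-based codon indices;
    kinds are ``premature_stop`` (detail: the stop triplet) and
    ``frameshift`` (detail: deletion length 1 or 2).  Sequence ids are
    ``ref`` then ``seq2`` .. ``seq<n>``.  Optional neutral substitutions
    are drawn with rejection so they can never create a stop codon; no
    unplanned lesion is ever introduced.
    """
    if n_seqs < 2:
        raise ValueError("need n_seqs >= 2 (a reference plus queries)")
    if n_codons < 3:
        raise ValueError("need n_codons >= 3")
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    stops = sorted(STANDARD_STOPS)

    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(bases[rng.integers(4)] for _ in range(3))
        if c not in STANDARD_STOPS:
            codons.append(c)
    codons.append("TAA")
    ref = "".join(codons)

    ids = ["ref"] + [f"seq{i}" for i in range(2, n_seqs + 1)]
    rows = {sid: list(ref) for sid in ids}

    planned = []
    seen: set[tuple[str, int]] = set()
    for entry in lesion_plan:
        sid, kind, codon_idx = entry[0], entry[1], int(entry[2])
        detail = entry[3] if len(entry) > 3 else None
        if sid not in rows or sid == "ref":
            raise ValueError(f"lesion plan names unknown or reference sequence {sid!r}")
        if not (1 <= codon_idx <= n_codons):
            raise ValueError(f"lesion codon {codon_idx} out of range")
        if (sid, codon_idx) in seen:
            raise ValueError(f"two lesions at codon {codon_idx} of {sid!r}")
        seen.add((sid, codon_idx))
        start = (codon_idx - 1) * 3
        if kind == "premature_stop":
            if codon_idx >= n_codons:
                raise ValueError("cannot plan a premature stop at the terminal codon")
            triplet = detail or stops[rng.integers(len(stops))]
            if triplet not in STANDARD_STOPS:
                raise ValueError(f"{triplet!r} is not a stop codon")
            rows[sid][start : start + 3] = list(triplet)
            planned.append((sid, kind, codon_idx, triplet, start + 1))
        elif kind == "frameshift":
            length = int(detail or 1)
            if length not in (1, 2):
                raise ValueError("frameshift deletion length must be 1 or 2")
            for p in range(start, start + length):
                rows[sid][p] = "-"
            planned.append((sid, kind, codon_idx, str(length), start + 1))
        else:
            raise ValueError(f"unknown lesion kind {kind!r}")

    lesioned = {(sid, ci) for sid, _, ci, _, _ in planned}
    for sid in ids[1:]:
        for _ in range(n_substitutions):
            for _attempt in range(100):
                ci = int(rng.integers(1, n_codons))  # never the terminal codon
                if (sid, ci) in lesioned:
                    continue
                pos = (ci - 1) * 3 + int(rng.integers(3))
                cur = rows[sid][pos]
                if cur == "-":
                    continue
                new = bases[rng.integers(4)]
                if new == cur:
                    continue
                old = rows[sid][pos]
                rows[sid][pos] = new
                codon = "".join(rows[sid][(ci - 1) * 3 : ci * 3])
                if codon in STANDARD_STOPS:
                    rows[sid][pos] = old
                    continue
                break

    aln = CodingAlignment({sid: "".join(r) for sid, r in rows.items()}, "ref")
    truth = SimTruth(
        params=dict(n_seqs=n_seqs, n_codons=n_codons, n_substitutions=n_substitutions),
        seed=seed,
        events=planned,
    )
    return aln, truth


# ---------------------------------------------------------------------------
# study-scale preset


def study_mimic(seed, n_tips: int = 95, crown_age: float = 17.0, n_valleys: int = 10):
    """Assemble a full synthetic dataset at the scale of a subterranean
    beetle radiation: dated tree, five-area ranges under DEC+J with one
    area closed to dispersal before the Miocene, palaeovalley-structured
    habitat states, and vision-gene alignments with shared lesions in four
    sister pairs.

    Returns a dict with keys ``tree``, ``geography``, ``dispersal``,
    ``dec_params``, ``clado_spec``, ``habitat_space``, ``habitat_mask``,
    ``habitat_Q``, ``habitat_states``, ``alignment``, ``pairs``, ``truths``.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=8)

    universe = AreaUniverse()
    n = universe.n_areas
    base = np.ones((n, n))
    # proximity template in the 0.1..1 range (symmetric, diagonal 1)
    prox = np.array(
        [
            [1.0, 0.5, 0.5, 0.1, 0.1],
            [0.5, 1.0, 1.0, 0.5, 0.5],
            [0.5, 1.0, 1.0, 0.5, 0.1],
            [0.1, 0.5, 0.5, 1.0, 0.5],
            [0.1, 0.5, 0.1, 0.5, 1.0],
        ]
    )
    strat = Stratification((MIOCENE_BASE_MA,)) if MIOCENE_BASE_MA < crown_age else Stratification()
    mats = [prox.copy() for _ in range(strat.n_strata)]
    dispersal = StratifiedDispersalModel(universe, mats, strat)
    if strat.n_strata > 1:
        dispersal = dispersal.with_area_unavailable("C", [0])
    dec_params = DECParams(d=0.03, e=0.02, j=0.3)
    spec = CladogenesisSpec("DEC")

    # survivorship: lineages whose range goes locally extinct would never be
    # sampled; simulate a few extra tips and prune null-range lineages
    from .treeio import prune_tips

    n_sim = max(n_tips + 4, int(n_tips * 1.15))
    for attempt in range(50):
        tree, tree_truth = simulate_bd_tree(
            0.3, 0.05, n_sim, int(sub[0]) + attempt, root_age=crown_age
        )
        raw_geog, dec_truth = simulate_dec_tips(
            tree, dec_params, dispersal, spec, {"B", "C"}, int(sub[1]) + attempt
        )
        alive = sorted(t for t, m in raw_geog.ranges.items() if m != 0)
        if len(alive) >= n_tips:
            break
    else:
        raise RuntimeError("could not reach the requested number of surviving tips")
    alive = alive[:n_tips]
    tree = prune_tips(tree, alive)
    geog = GeographyData(universe, {t: raw_geog.ranges[t] for t in alive})

    valleys = [f"P{i}" for i in range(1, n_valleys + 1)]
    hspace, hmask = build_habitat_space(valleys)
    hQ = habitat_rate_matrix(
        hspace,
        hmask,
        {
            ("epigean", "interstitial"): 0.001,
            ("interstitial", "epigean"): 0.02,
            ("epigean", "subterranean"): 0.011,
            ("interstitial", "subterranean"): 0.05,
        },
    )
    habitat_states, mk_truth = simulate_mk_tips(tree, hQ, hspace, "epigean", int(sub[2]))

    subterranean_tips = [t for t, s in habitat_states.items() if s.startswith("subterranean")]
    pair_tips = (subterranean_tips * 2)[:8] if subterranean_tips else list(habitat_states)[:8]
    plan = []
    pairs = []
    seq_ids = [f"seq{i}" for i in range(2, 10)]
    for p in range(4):
        a, b = seq_ids[2 * p], seq_ids[2 * p + 1]
        pairs.append((a, b))
        stop_codon = 20 + 15 * p
        plan += [(a, "premature_stop", stop_codon, "TAA"), (b, "premature_stop", stop_codon, "TAA")]
        fs_codon = 60 + 10 * p
        plan += [(a, "frameshift", fs_codon, 1), (b, "frameshift", fs_codon, 1)]
    aln, aln_truth = simulate_coding_alignment(9, 150, plan, int(sub[3]), n_substitutions=3)

    return dict(
        tree=tree,
        geography=geog,
        dispersal=dispersal,
        dec_params=dec_params,
        clado_spec=spec,
        habitat_space=hspace,
        habitat_mask=hmask,
        habitat_Q=hQ,
        habitat_states=habitat_states,
        alignment=aln,
        pairs=pairs,
        truths=dict(tree=tree_truth, ranges=dec_truth, habitat=mk_truth, alignment=aln_truth),
    )
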