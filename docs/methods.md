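# Methods

This note documents the models implemented in `stygotrace`, the conventions
chosen where the literature leaves room, the numerical machinery, what the
synthetic-data generator does and does not emulate, and known limitations.

## Range evolution (DEC family)

### Anagenesis

The state space is every subset of the area universe up to
`max_range_size`, ordered by size then lexicographically, plus the null
range ∅. The rate matrix has

* gains `Q[R, R∪{a}] = d · Σ_{i∈R} m[i,a]` for `a ∉ R` while the enlarged
  range stays within the cap,
* losses `Q[R, R∖{a}] = e` for each `a ∈ R` (singletons decay to ∅),
* ∅ absorbing.

`d` and `e` are per-area rates in events/Ma (branch lengths are Ma).
Dispersal multipliers `m[i,a] ∈ [0,1]` scale the gain from source `i` into
sink `a` and may differ per time stratum; a stratum in which an area has
not yet emerged has that area's entire incoming column at 0.

**The `w` exponent** is applied elementwise as `m^w`, but only to entries
strictly inside (0, 1). Exact zeros stay zero for every `w`, including
`w = 0`: since `0^w → 1` as `w → 0`, a naive power would silently re-open
routes that geology closed. Exact ones stay one. The same effective
multipliers feed the jump-weight scaling below.

### Cladogenesis

Events at a node partition the ancestral range `R` between the daughters:

* **DEC** — singleton sympatry `(R,R)` for `|R| = 1`; subset sympatry
  `(R,{a})` for `a ∈ R`; vicariance into two disjoint pieces with the
  smaller piece a single area.
* **DIVALIKE** — singleton sympatry; vicariance into any disjoint
  bipartition (unequal splits allowed); no subset sympatry, no widespread
  sympatry.
* **BAYAREALIKE** — no cladogenetic range change: both daughters copy `R`.
  (Only its likelihood is implemented; the original Bayesian sampler is
  not.)
* **Founder-event jumps** (all families) — one daughter keeps `R`, the
  other jumps to a single unoccupied area.

Weights: sympatry `y`, subset `s`, vicariance `v`, jump `j`. By default
`y = s = v = (3 − j)/3`, so `j` is bounded by 3 and `j = 0` recovers equal
unit weights. Jump weights are additionally scaled by the mean effective
multiplier from the ancestral areas into the target (switchable off).
Probabilities are normalized per ancestor over the legal outcomes.

Enumeration convention: symmetric events appear once; asymmetric non-jump
events appear in both orderings, each carrying the full class weight; jump
events appear once as (retained range, jump daughter). At the likelihood
merge and in the forward simulator each asymmetric outcome's probability is
split evenly over the two left/right daughter assignments, so nothing
depends on child orientation.

**Null-range inheritance.** The internal cladogenesis table gives the null
ancestor the single outcome (∅, ∅). With nonempty tip ranges this outcome
carries zero conditional likelihood automatically (∅ is absorbing), so
ordinary fits are unaffected; it matters only when simulated datasets with
locally-extinct lineages are fit as complete data (below).

### Likelihood, root, and reconstructions

Standard pruning with per-node rescaling. Branches are sliced at stratum
boundaries; each segment uses its stratum's rate matrix, composed oldest to
youngest. Transition probabilities come from an eigendecomposition of the
(at most 32 × 32) rate matrix, cached per likelihood evaluation and applied
per branch; if the eigenvector matrix is ill-conditioned (condition number
above 1e8, e.g. at degenerate rates) the code falls back to
scaling-and-squaring `expm`. Tiny negative entries from roundoff are
clipped at zero.

The root is handled by a flat prior over nonempty ranges within the size
cap, with no cladogenetic event above the root; a custom prior vector can
be supplied. Marginal ancestral ranges use the standard outside/inside
product with the cladogenetic kernel in both passes. The "root areas"
summary takes the smallest set of range states whose cumulative root
probability reaches 0.95 (stable tie-break by state order) and reports the
union of their areas.

## Model fitting and hypothesis comparison

`fit_model` maximizes the likelihood over `(d, e[, j][, w])` with L-BFGS-B,
`d` and `e` on a log scale, from a fixed deterministic start grid
(`d, e ∈ {0.01, 0.1, 1}`, two `j` starts `{0, 0.5}` when free, `w` started
at 1). Bounds: `d, e ∈ [1e-12, 5]`, `j ∈ [0, 3)`, `w ∈ [0, 10]`.

AICc uses `n =` number of tips. The field is not unanimous here (tips vs
tips−1 vs other effective sizes); within one tree the choice shifts every
model's AICc by the same pattern and cannot change a ranking, and `aicc()`
takes `n` explicitly for users who prefer another convention.

`hypothesis_suite` fits every declared hypothesis under every requested
family with and without free `j`, ranks by AICc, breaks ties by fewer
parameters then family order DEC < DIVALIKE < BAYAREALIKE, and reports
ΔAICc against the overall best plus the root-areas summary. A hypothesis
whose every fit fails is reported with its error; the suite continues. The
exponent `w` is fitted only for hypotheses that declare it free — it is
meaningless for the unguided (all-ones) setting and fixed at 1 elsewhere.

Stratum-boundary defaults exposed as constants: 23 Ma (Miocene base,
"standard" emergence) and 34 Ma (Oligocene base, "relaxed"); both are
epoch boundaries, configurable per analysis. The repository ships a
template proximity matrix in the study-scale preset; real multiplier
matrices are user input.

## Trait models

### Habitat space and mask

States: `epigean`, plus `interstitial:p` and `subterranean:p` per
palaeovalley `p`. Permitted transitions: epigean ↔ interstitial (any
valley), epigean → subterranean (direct colonization from surface water —
switchable off), interstitial → subterranean within the same valley only.
Everything else is forbidden, in particular subterranean movement between
palaeovalleys (isolated aquifer systems) and — by default — any exit from a
subterranean state: regressive troglomorphic traits (eye and wing loss,
depigmentation) make reversal to surface life implausible. A flag permits
exits for sensitivity analysis. The altitude model uses five
maximum-altitude bands (≤1000, 1001–2000, 2001–3000, 3001–4000, >4000 m)
with an unconstrained ARD mask; the natural root prior there is restricted
to the two bands below 2000 m. Species spanning bands can be coded as
ambiguity sets (conditional likelihood 1 for each listed state);
maximum-altitude point coding is the default in the table format.

### Fitting

`fit_ard` gives every permitted ordered state pair its own rate (log-scale
L-BFGS-B, deterministic common-value starts `{0.02, 0.2, 2}`, bounds
`[1e-8, 100]`/Ma); masked entries are exactly zero by construction.
`fit_tied_rates` instead shares one rate per (from-class, to-class) route —
on a 10-valley habitat space this is 4 parameters instead of 40, which is
what tip data at radiation scale can actually inform; it is the pipeline
default for habitat analyses, with full ARD available by configuration.

### Stochastic character mapping

Node states are drawn from their exact joint conditional distribution
(root from prior × root conditionals, then preorder given the sampled
parent). Branch paths are drawn from the endpoint-conditioned CTMC by
uniformization: with `Ω = 1.05 · max_i |Q_ii|` and `R = I + Q/Ω`, the jump
count `N` given endpoints `(i, j)` over `t` has
`P(N = n) ∝ Pois(n; Ωt) · (R^n)[i,j]`; the inverse-CDF series is truncated
at its known normalizer `P(t)[i,j]` with a hard cap of 1e5 terms;
intermediate states form a bridge through cached powers of `R`; virtual
self-jumps are collapsed. The sampler is exact — no rejection, no retries;
an endpoint pair with zero transition probability raises, naming the
branch. Default number of maps: 1000.

### Colonization counting

Over sampled histories: an *entry* into the subterranean (or interstitial)
class is a within-branch transition whose source class differs; state
inheritance through a node never counts. A *subterranean speciation event*
is an internal node whose state and both daughters' initial branch states
are subterranean (under a CTMC these coincide with the node state; the
definition is kept general), *within-palaeovalley* when all three share one
valley. Reports give the median and central 95% interval across histories.
Any history containing a masked transition fails an integrity check.

## Pseudogene scanning

Codon coordinates are projected from a designated reference sequence:
after skipping the frame offset, the reference's ungapped positions are
grouped in triples, and every query is read in those columns. Insertions
relative to the reference therefore never shift downstream codon indices,
which makes lesion identity robust to realignment. The reference must be a
valid ORF (no internal stop).

* **Premature stops** — any stop triplet (standard nuclear code
  {TAA, TAG, TGA}, configurable) strictly before the reference's terminal
  codon; codons containing gaps or N are never called; only the terminal
  codon is exempt (no percentage-tail heuristic). Stops downstream of an
  earlier frameshift in the same sequence are reported with a
  `post_frameshift` flag, so either reading is derivable from output.
* **Frameshifts** — maximal runs of same-type indel columns (deletion:
  reference base over query gap; insertion: the reverse) whose length mod 3
  is nonzero; one call per run at its first column with the shift (1 or 2).
* **Sharing** — a lesion is shared within a pair when kind and position
  match exactly: reference codon index for stops, (start column, shift)
  for frameshifts.

Strand is assumed pre-normalized; reverse-complement input fails alphabet
or ORF validation by design. Coverage interpretation (partial exons from
degraded specimens) is left to the user: gap/N codons are simply not
callable.

## Synthetic data

All simulators take an integer seed and return the complete latent truth
(node states, every event with its time, per-state dwell times), so any
downstream inference can be scored exactly.

* **Trees** — forward Gillespie birth–death from a crown of two lineages,
  rejected on total extinction; when the extant count first reaches `n`
  the clock runs to the moment the next event would occur and the tree is
  cut there (under pure birth the expected crown age is
  `Σ_{k=2..n} 1/(λk)`). Extinct subtrees are pruned. This simple rejection
  conditioning slightly biases tree shape relative to sampling-conditioned
  simulators; at the package's problem sizes the bias is irrelevant to
  what the tests measure. Optional rescaling to a target crown age.
* **Ranges** — exact stochastic simulation of the per-stratum rate matrix
  along branch segments; cladogenetic outcomes drawn from the same
  normalized table the likelihood uses, with random daughter orientation.
  Lineages absorbed into ∅ are retained and flagged, not silently
  redrawn — degenerate data must be visible to tests; a redraw option
  exists.
* **Traits** — Gillespie on a masked rate matrix; the truth's event list
  and dwell times support rate-estimator consistency checks and
  constraint audits.
* **Alignments** — an intact random ORF (start codon, non-stop interior,
  terminal TAA) copied per sequence with exactly the planned lesions
  injected (stop substitutions, 1–2 nt deletions) plus optional neutral
  substitutions drawn with rejection so they can never create a stop.
  Lesions are injected, not evolved — no substitution model, no indel
  process beyond the planned ones.

The **study-scale preset** (`study_mimic`) bundles all of these at
realistic scale: 95 tips rescaled to a 17 Ma crown, five areas with a
proximity-style multiplier template (0.1–1) and one area closed below the
23 Ma boundary, ten palaeovalleys with habitat rates chosen to yield a few
dozen subterranean tips, and a 150-codon alignment with shared lesions in
four sister pairs. The preset samples survivors: it simulates ~15% extra
tips and prunes lineages whose range went locally extinct, since a real
dataset contains only extant, nonempty-range species.

What the generator does **not** emulate: time-heterogeneous trait rates
(a homogeneous CTMC cannot concentrate groundwater colonizations into the
last few Ma the way aridification did); rate variation across lineages;
phylogenetic error or node-age uncertainty (point trees only); sequence
evolution in the alignments. Passing tests therefore demonstrate
correctness of the inference machinery under its own model assumptions,
not robustness to the ways real data violate them.

## Verification conditions and problem sizes

The statistical checks in `tests/test_acceptance.py` and
`scripts/acceptance.py` run at these sizes, chosen once for
identifiability: oracle equivalence on 100 random instances each (trees of
2–4 tips, 2–3 areas/states, random stratification, weights and exponents)
against full enumeration with independently built rate matrices and
scaling-and-squaring exponentials; DEC rate recovery over 50 replicates of
200-tip pure-birth trees (birth 0.15/Ma, three areas, d = 0.02, e = 0.01);
ARD recovery over 50 replicates of 300-tip trees (two states, rates
0.1/0.05); stochastic-map calibration against the closed-form conditional
change count of the symmetric 2-state chain at 10,000 draws;
constraint integrity over ≥10⁶ simulated branch segments; pseudogene
round-trips over 200 random fixtures; and hypothesis-selection power over
30 replicates at 150 tips with a stratified generating model.

**Complete-data recovery.** Under DEC with nonzero `e`, lineages whose
range is absorbed into ∅ are precisely the carriers of loss evidence.
Conditioning simulated datasets on "no null tips" (or pruning null tips)
therefore biases ê toward zero, and on trees long enough for `e` to be
identifiable such conditioning is also combinatorially infeasible. The
recovery harness instead fits each complete simulated dataset, observing
locally-extinct lineages in the null range — exact full-data maximum
likelihood under the generating process. Real-data analyses are unaffected:
empirical tips are always nonempty, and tip validation enforces this
outside the simulator pathway.

## Known limitations

* No more than ~8 areas: dense matrices over all subsets, no sparse or
  full-log-space machinery.
* Polytomies are rejected, not resolved: the cladogenetic models are
  defined for bifurcations. Zero-length terminal branches are likewise
  rejected (they break path sampling); add an epsilon explicitly if
  needed.
* Point estimates on one tree: no integration over posterior tree samples
  or node-age intervals.
* No hidden-rate or threshold/ordered trait models; marginal (not joint)
  ancestral reconstruction.
* BAYAREALIKE is the likelihood variant only.
* AICc comparisons across non-nested families carry the usual caveats;
  no likelihood-ratio testing or model averaging.
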