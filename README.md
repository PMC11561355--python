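# stygotrace

Inference tools for radiations that span extreme habitat gradients — island
chains, groundwater aquifers, alpine sky islands — where three questions
recur: *where* did lineages move (geographic range evolution), *how* did
they shift habitat (constrained discrete-trait evolution), and *what traces
did habitat specialization leave in their genes* (pseudogenization of, e.g.,
vision genes in obligate subterranean species).

The package is aimed at phylogeneticists working from a time-calibrated
tree: it provides the likelihood machinery, simulators and reporting for a
complete analysis of the kind used on subterranean diving-beetle radiations
in arid Australia, with every stage testable against forward simulations.

## What's inside

**Geographic ranges (DEC family).** A range is a subset of discrete areas.
Anagenesis is a CTMC on ranges: area *a* is gained at rate
`d · Σ_{i∈R} m[i,a]` (with `m` a per-epoch dispersal multiplier matrix) and
lost at rate `e`; the empty range is absorbing. At speciation the range is
partitioned under a cladogenetic model — sympatry, subset sympatry,
vicariance, and founder-event "jump" dispersal weighted by `j`
(DEC, DIVALIKE and BAYAREALIKE families). Multiplier matrices may change
across time strata (an area contributes nothing before its geological
emergence), and an exponent `w` softens or sharpens multipliers strictly
between 0 and 1 (exact zeros stay zero for every `w`). Maximum-likelihood
fits are ranked with AICc = `2k − 2lnL + 2k(k+1)/(n−k−1)` (n = tips) across
a user-declared suite of dispersal hypotheses.

**Habitat and altitude traits (constrained Mk/ARD).** Discrete-trait CTMCs
with a transition mask. The built-in habitat space has one epigean state
plus interstitial and subterranean states per palaeovalley; the mask
forbids subterranean movement between palaeovalleys, allows
interstitial→subterranean shifts only within a palaeovalley, and treats
subterranean life as irreversible by default. Marginal ancestral states,
stochastic character mapping (endpoint-conditioned paths by
uniformization), and colonization/subterranean-speciation counts across
sampled maps are provided; a five-band maximum-altitude model ships with an
unconstrained ARD mask.

**Pseudogene lesions.** A scanner for aligned coding sequences that calls
premature stop codons and out-of-frame indel runs in reference-projected
codon coordinates, and reports lesions shared between designated sister
pairs — the signature of pseudogenization in a common ancestor.

**Simulators.** Seeded forward simulators for dated birth–death trees,
DEC-family ranges, masked trait histories and lesion-bearing codon
alignments, each returning the full latent truth for scoring inference.

## Worked example

Simulate ranges under a stratified truth (area C closed to dispersal before
15 Ma) and ask whether AICc recovers it against an unguided analysis:

```python
import numpy as np
import stygotrace as st
from stygotrace.model_selection import HypothesisSpec, hypothesis_suite
from stygotrace.treeio import Stratification

u = st.AreaUniverse(("A", "B", "C"))
young = np.array([[1.0, 1.0, 0.1], [1.0, 1.0, 1.0], [0.1, 1.0, 1.0]])
old   = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.1, 1.0, 0.0]])
truth = st.StratifiedDispersalModel(u, [old, young], Stratification((15.0,)))

tree, _ = st.simulate_bd_tree(0.3, 0.05, 60, seed=7, root_age=30.0)
geog, _ = st.simulate_dec_tips(tree, st.DECParams(d=0.02, e=0.01), truth,
                               st.CladogenesisSpec("DEC"), {"B"}, seed=8)
table = hypothesis_suite(tree, geog,
                         [HypothesisSpec(id="M0", assumption="unguided"),
                          HypothesisSpec(id="M1", assumption="stratified",
                                         dispersal=truth)],
                         families=("DEC",))
print(table[["hypothesis", "best_model", "AICc", "delta_AICc", "root_areas"]])
```

prints

```
hypothesis best_model       AICc  delta_AICc root_areas
        M0        DEC 136.866343    2.595165        ABC
        M1        DEC 134.271178    0.000000        ABC
```

M1 (the generating hypothesis) wins by ΔAICc ≈ 2.6: the stratified
multipliers explain the same tip ranges with a better likelihood at equal
parameter count. The `root_areas` column is the union of areas in the
smallest set of range states covering 95% of the root's marginal posterior.

On the habitat side (`examples/03_habitat_simmap.py`), fitting class-tied
rates on a simulated 80-tip radiation over 5 palaeovalleys and sampling 200
stochastic maps with the root forced epigean prints, e.g.:

```
entries_subterranean: median 22  [22, 24]
subterranean_speciation: median 32  [30, 32]
```

i.e. ~22 independent groundwater colonizations and ~32 speciation events at
already-subterranean nodes, with 95% intervals across maps.

The `examples/` directory holds one short script per capability;
`examples/05_full_pipeline.py` generates a 95-tip study-scale synthetic
dataset and runs every stage through the `stygotrace` CLI
(`simulate`, `run`, `fit-biogeo`, `fit-trait`, `simmap`,
`scan-pseudogenes`).

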