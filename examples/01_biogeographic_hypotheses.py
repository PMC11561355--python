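"""Compare dispersal hypotheses for a simulated island radiation.

Simulates geographic ranges down a 60-tip dated tree under a stratified
truth — area C closed to dispersal before 15 Ma, weak A<->C exchange after —
then asks the hypothesis suite whether AICc can tell that truth (M1) apart
from an unguided analysis with all multipliers equal (M0).
"""

import numpy as np

import stygotrace as st
from stygotrace.model_selection import HypothesisSpec, hypothesis_suite
from stygotrace.treeio import Stratification

universe = st.AreaUniverse(("A", "B", "C"))
young = np.array([[1.0, 1.0, 0.1], [1.0, 1.0, 1.0], [0.1, 1.0, 1.0]])
old = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.1, 1.0, 0.0]])
truth = st.StratifiedDispersalModel(universe, [old, young], Stratification((15.0,)))

tree, _ = st.simulate_bd_tree(0.3, 0.05, 60, seed=7, root_age=30.0)
geog, sim_truth = st.simulate_dec_tips(
    tree, st.DECParams(d=0.02, e=0.01), truth, st.CladogenesisSpec("DEC"),
    root_range={"B"}, seed=8,
)
print(f"simulated {tree.n_tips} tips, {len(sim_truth.events)} anagenetic events")

table = hypothesis_suite(
    tree, geog,
    [
        HypothesisSpec(id="M0", assumption="unguided"),
        HypothesisSpec(id="M1", assumption="stratified custom matrix", dispersal=truth),
    ],
    families=("DEC",),
)
print(table[["hypothesis", "assumption", "best_model", "AICc", "delta_AICc",
             "root_areas"]].to_string(index=False))
print(
    "\nThe hypothesis with delta_AICc = 0 is preferred; when the generating"
    "\nmodel is stratified, M1 should usually win and its root-areas summary"
    "\nshould include the true root area B."
)
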