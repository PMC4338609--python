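"""Phosphotyrosine gradient around a receptor in the interaction network.

Simulates phosphosites whose tyrosine fraction decays with hop distance
from a hub "receptor" node (25% at 1 hop down to 5% at 3+ hops), then
recovers the gradient as cumulative per-band composition — the analysis
that shows receptor-proximal signalling is tyrosine-biased.
"""

import numpy as np

from phosphoadhesome import (
    SimulationDesign,
    hop_composition,
    hop_distances,
    simulate_interactome,
    simulate_phosphosites,
)

profile = {
    0: (0.60, 0.15, 0.25),
    1: (0.60, 0.15, 0.25),
    2: (0.73, 0.12, 0.15),
    -1: (0.84, 0.11, 0.05),
}
design = SimulationDesign(seed=7, residue_profile_by_hop=profile)
graph = simulate_interactome(400, seed=7)
receptor = max(graph.degree, key=lambda kv: kv[1])[0]
records, _ = simulate_phosphosites(
    design, graph, receptor, n_sites=3000, rng=np.random.default_rng(7)
)

decomp = hop_distances(graph, receptor)
comps = hop_composition(decomp, records, max_hop=3)
for k in (1, 2, 3):
    band = comps["cumulative"][k]
    pS, pT, pY = band.percentages()
    print(
        f"within {k} interaction(s) of {receptor}: "
        f"{len(decomp.neighbourhood(k)):4d} proteins, {band.total:5d} sites, "
        f"pY = {pY}%"
    )
# pY% falls monotonically with distance from the receptor, recovering the
# designed gradient: tyrosine phosphorylation concentrates at the receptor.
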