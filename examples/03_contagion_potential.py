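"""Contagion potential and homophily.

Contagion potential (CP) scores each node's likelihood of being a
spreader on a 0-1 scale: infected nodes carry 1, and everyone else
accumulates potential from infected-adjacent contacts over time.  The
CP objective minimizes |Z(u) - Z(v)| across ties, which groups nodes of
similar potential together (homophily).  The E-I index on one-decimal
CP groups measures that: -1 is complete homophily, +1 complete
heterophily.
"""

import numpy as np

import socdist as sd
from socdist.simulation import SimulationState, run_epoch

region = sd.RegionSpec(X=100, Y=50, d=6, tau=25)
cfg = sd.SimulationConfig(
    region=region,
    strategy=sd.StrategyConfig(
        kind="sampling", pi=0.4, objective=sd.ObjectiveKind.CONTAGION_POTENTIAL
    ),
    n=75,
    T=30,
    seed=0,
)

state = SimulationState.initialize(cfg)
before, after = [], []
for _ in range(cfg.T):
    pop = state.population
    ids = [ind.id for ind in pop]
    pre = pop.positions_array().copy()
    state, _ = run_epoch(state, cfg)
    groups = sd.discretize_cp({ind.id: ind.overall_cp for ind in pop}, 1)
    try:
        before.append(sd.ei_index(sd.ContactNetwork.from_positions(ids, pre, region.d), groups))
        after.append(sd.ei_index(sd.build_contact_network(pop, region.d), groups))
    except ValueError:
        pass

print(f"mean E-I index before relocation: {np.mean(before):+.3f}")
print(f"mean E-I index after relocation:  {np.mean(after):+.3f}")
print(
    "The optimized network is more homophilic (lower E-I): ties increasingly\n"
    "join nodes of similar contagion potential, isolating likely spreaders."
)
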