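"""Perturb a healthy network: vein occlusion and progressive arteriolar loss.

RVO: a major vein is narrowed by 80% at an artery-vein crossover and the
drainage-territory flow deficit measured.  DR: arterioles below 35 µm are
occluded in batches of five, periphery first, pruning whatever loses
perfusion.
"""

import numpy as np

import retvasc as rv
import retvasc.pathology as pa

net, domain, params, _ = rv.generate_retina(
    seed=7, preset="mini",
    stages=("seed", "leaves", "growth", "optimize", "trim", "topology",
            "intersections", "macula", "capillaries"))
bc, sol = rv.solve_flow(net, params)
print(f"healthy total flow: {sol.total_inlet_flow_ul_min:.3f} uL/min")

rng = np.random.default_rng(0)
occluded, rvo_sol, deficit = pa.apply_rvo(net, sol, bc, rng)
print(f"RVO deficit:        {deficit:.3f} uL/min "
      f"({100 * deficit / sol.total_inlet_flow_ul_min:.0f}% of total) "
      "summed over the occluded vein's drainage territory")

states = pa.apply_dr_progression(net, bc, domain, rng,
                                 schedule_mm=(3.0, 2.0, 1.0))
print("DR progression:")
for i, (state, state_sol) in enumerate(states):
    print(f"  batch {i + 1}: {len(state.segments)} segments survive, "
          f"total flow {state_sol.total_inlet_flow_ul_min:.3f} uL/min")
# Flow decreases monotonically as arterioles occlude and their dependent
# capillary territories become ischaemic and are pruned.
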