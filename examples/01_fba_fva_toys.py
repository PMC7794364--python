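"""Flux balance and flux variability analysis on small toy networks.

The built-in toys ship with hand-derived analytic truths, so you can
see exactly what the LP layer is supposed to return:

* ``chain``   A -> B -> C straight pathway; every reaction carries the
  same flux, capped at 10 by the uptake bound.
* ``branch``  A splits into B and C; the objective prefers the B route,
  so at optimality the C route is forced to zero.
"""

import gbmflux as g

# ---------------------------------------------------------------- FBA
model, truth = g.make_toy_network("chain")
solution = g.fba(model)
print(f"chain: status={solution.status.name}, "
      f"objective={solution.objective_value:.3f} "
      f"(analytic optimum {truth['optimum']})")
for rid in model.reaction_ids:
    print(f"  {rid:8s} v = {solution[rid]:7.3f}")

# ---------------------------------------------------------------- FVA
# gamma is the fraction of the optimal objective that must be retained:
# gamma=0 explores the whole feasible polytope, gamma=1 only the
# optimal face.
model, truth = g.make_toy_network("branch")
for gamma in (0.0, 0.5, 1.0):
    result = g.fva(model, g.FVAConfig(gamma=gamma))
    print(f"\nbranch FVA at gamma={gamma}:")
    for rid, (lo, hi) in sorted(result.ranges.items()):
        print(f"  {rid:8s} [{lo:7.3f}, {hi:7.3f}]")

# At gamma=1 the flexible C route collapses to zero width -- the
# objective pins it -- while at gamma=0 both routes span [0, 10].
r = g.fva(model, g.FVAConfig(gamma=1.0))
print(f"\nR_AC width at optimality: {r.width('R_AC'):.3f} (expected 0)")

# Largest achievable uptake through one exchange, all else free:
print(f"max A uptake: {g.maximal_exchange(model, 'EX_A', 'uptake'):.3f}")
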