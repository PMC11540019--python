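"""Compare foraging policies: acting on need directly vs. on accumulated need.

Both agents face the same 1-D track with food 300 steps away.  The
direct-need agent's predicted gain is tied to its own motion ("prediction
changes when the agent stops"), so moving collapses its need below the
action threshold and it dithers in short go/stop bouts.  The
accumulated-need agent integrates need into motivation and, once over
threshold, approaches in a single sustained bout — acquiring food earlier.
"""

import needmot as nm
from needmot.foraging import AgentParams, run_simulation

params = AgentParams()  # gamma 0.99, e 0.1, a 0.0015, leak 0.001, threshold 0.5

direct = run_simulation(
    "direct_need", "pred_changes_on_stop", "ID", params, n_steps=4000, seed=0
)
accum = run_simulation(
    "accumulated_need", "pred_changes_on_stop", "ID", params, n_steps=4000, seed=0
)

print(f"{'policy':18s} {'acquired at':>12s} {'go bouts':>9s} {'go steps':>9s}")
for name, traj in (("direct need", direct), ("accumulated need", accum)):
    print(f"{name:18s} {traj.acquisition_time:>12d} {traj.n_go_bouts:>9d} "
          f"{traj.total_go_steps:>9d}")

delay = direct.acquisition_time - accum.acquisition_time
print(f"\nacting on need directly delays acquisition by {delay} steps:")
print("the direct agent alternates 10-step go bouts with 50-step holds")
print("(its own movement keeps cancelling the need that drives it), while")
print("the accumulated agent crosses threshold once and walks straight in.")
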