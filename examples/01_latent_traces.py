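"""Build the need and motivation latents for a multi-event foraging trial.

The need latent steps down at each predicted-gain event (seeking, proximity,
contact, consumption end) and rebounds at the predicted loss
(inaccessibility); the motivation latent accumulates need from the
accessibility moment, declines after consumption, and freezes once the food
becomes inaccessible.
"""

import numpy as np

import needmot as nm

schedule = nm.TEMPLATE_SCHEDULES["multi_gain_loss"]
params = nm.default_true_params("multi_gain_loss")

need = nm.build_test_model(
    "multi_gain_loss", schedule, "need", params["need"], params["motivation"]
)
motivation = nm.build_test_model(
    "multi_gain_loss", schedule, "motivation", params["need"], params["motivation"]
)

print("event schedule:")
for event in schedule.events:
    print(f"  {event.time:5.1f} s  {event.kind.value:16s} {event.label}")

print("\nlatent values at event times (need / motivation):")
for event in schedule.events:
    i = need.index_of(event.time)
    print(
        f"  t={event.time:5.1f} s   N={need.values[i]:+6.2f}   "
        f"M={motivation.values[i]:+6.2f}"
    )

# The need staircase descends 2.0 -> -2.0 across the gains and consumption
# end, then rebounds by 1.5 at inaccessibility; motivation rises while need
# is positive, falls after consumption (need < 0), and freezes at the loss.
i_loss = need.index_of(schedule.first_loss_time)
assert np.all(motivation.values[i_loss:] == motivation.values[i_loss])
print("\nmotivation is frozen from the inaccessibility event onward.")
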