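"""Expose HR-proportional bias with a criterion-ranked decile table.

A tracker whose underestimation grows with heart rate looks acceptable on
pooled statistics but shows a widening per-decile difference: decile 1 holds
the lowest 10% of criterion HR, decile 10 the highest.
"""

from hrconcord import (
    DeviceErrorModel,
    LabProtocol,
    Participant,
    apply_device_error,
    decile_table,
    match_pairs,
    to_epochs,
    true_hr_trajectory,
)

participant = Participant(id="P001", age=30, resting_hr=65)
truth = true_hr_trajectory(participant, LabProtocol(), seed=3)
tracker = apply_device_error(
    truth,
    DeviceErrorModel(proportional_bias=-0.10, noise_sd_base=2.0,
                     sampling_period=1, seed=5),
    resting_hr=participant.resting_hr,
    device_id="wrist_1hz",
)

tab = decile_table(match_pairs(to_epochs(truth), to_epochs(tracker)))
cols = ["decile", "n_epochs", "criterion_mean", "tracker_mean", "mean_diff_bpm"]
print(tab[cols].round(1).to_string(index=False))

# mean_diff_bpm grows more negative from decile 1 to decile 10: the −10%
# HR-proportional bias costs almost nothing at rest but ~8 bpm at the top
# cycling stage — the signature pattern of optical trackers during exercise.
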