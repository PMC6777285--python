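"""Agreement statistics for one laboratory session.

Builds a ground-truth cycling trajectory for a 30-year-old, corrupts it with
a wrist-sensor error model (−6 bpm bias, heteroscedastic noise, 3% dropout),
matches tracker to criterion on the 10-second grid, and prints the full
agreement battery.
"""

from hrconcord import (
    DeviceErrorModel,
    LabProtocol,
    Participant,
    apply_device_error,
    compute_agreement,
    match_pairs,
    to_epochs,
    true_hr_trajectory,
)

participant = Participant(id="P001", age=30, resting_hr=65)
truth = true_hr_trajectory(participant, LabProtocol(), seed=7)

tracker = apply_device_error(
    truth,
    DeviceErrorModel(additive_bias=-6.0, noise_sd_base=3.0, noise_sd_slope=0.02,
                     dropout_prob=0.03, sampling_period=1, seed=1),
    resting_hr=participant.resting_hr,
    device_id="wrist_1hz",
)

pairs = match_pairs(to_epochs(truth), to_epochs(tracker))
result = compute_agreement(pairs)

for key, value in result.summary().items():
    print(f"{key:22s} {value}")

# icc near 0.9+ with this mild error model ("strong"/"very strong" band);
# mean_diff_bpm recovers the injected −6 bpm bias; the Bland–Altman limits
# of agreement span ≈ ±1.96 SD of the per-epoch differences; MAPE below the
# 10% cutoff means the simulated tracker would pass the validity criterion.
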