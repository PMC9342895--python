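"""Forward-simulate an oscillating fluorescence trace and compare it with
a noisy observation.

With KaiA and KaiB present, KaiC's phosphostates cycle with a ~24.7 h
period.  Given per-state intensities F_i (from a KaiC-alone relaxation)
and the state abundances A_i(t), the model predicts
F_app(t) = sum_i F_i A_i(t) + offset, the offset being the constant KaiA
fluorescence background.  Because abundances sum to 1, that offset is
not separable within a single fit — it is estimated with the F_i pinned.
"""

import numpy as np

import kaifluor as kf

model = kf.OscillationModel(period=24.7, n_cycles=4)
abund = kf.generate_oscillation_abundances(model)

truth = kf.StateFluorescence(
    f_values=dict(zip(kf.STATES, (40.0, 8.0, 20.0, 38.0))),
    offset=16.0, construct="F419W", condition="KaiA+KaiB+KaiC",
)
observed = kf.compose_fapp(truth, abund, noise_sigma=0.5, rng_seed=42)

# F_i assumed known from the relaxation experiment; estimate the offset
pinned = kf.StateFluorescence(f_values=dict(truth.f_values))
offset, offset_se = kf.estimate_offset(observed, pinned, abund)
print(f"estimated KaiA background offset: {offset:.2f} ± {offset_se:.2f} "
      f"(true 16.0)")

simulated = kf.simulate_fapp(
    kf.StateFluorescence(f_values=dict(truth.f_values), offset=offset), abund
)
comp = kf.compare_fit(observed, simulated)
print(f"observed vs simulated: RMSD = {comp.rmsd:.3f}, r = {comp.pearson_r:.4f}")

amp = kf.amplitude_minmax(observed.times, observed.f_app)
fit = kf.fit_period(observed.times, observed.f_app, n_harmonics=3)
print(f"oscillation amplitude (max - min): {amp:.2f}")
print(f"fitted period: {fit.period:.2f} ± {fit.period_se:.2f} h (true 24.7)")
print("RMSD near the injected noise SD and r ~ 1 mean the 4-state linear")
print("model explains the whole rhythmic fluorescence change.")
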