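"""Characterize phosphostate emission spectra: band intensity F,
emission maximum lambda_max, and probe-isolating difference spectra.

Phospho-mimicking mutants freeze KaiC in each of the four states.
Comparing each mutant with and without the F419W substitution isolates
the engineered probe: the difference spectrum is the probe's own
emission band.  lambda_max reports the polarity of the probe's
environment (red-shift = more solvent-exposed).
"""

import numpy as np

import kaifluor as kf

# with-probe model: strong, state-dependent bands; base model: weak,
# nearly state-independent intrinsic emission
probe_model = kf.SpectralStateModel(noise_sigma=0.002, rng_seed=1)
base_model = kf.SpectralStateModel(
    band_lambda_max=(336.0, 336.5, 336.0, 335.5),
    band_amplitude=(0.30, 0.28, 0.29, 0.31),
    noise_sigma=0.002, rng_seed=2,
)

mimic_names = {"SpT": "CE", "pSpT": "EE", "pST": "EV", "ST": "CV"}
groups = {}
for i, state in enumerate(kf.STATES):
    pure = np.eye(4)[i]
    with_probe = kf.synthesize_spectrum(probe_model, pure)
    without = kf.synthesize_spectrum(base_model, pure)
    diff = kf.difference_spectrum(with_probe, without)
    f_w419 = kf.integrate_band(diff)
    lam = kf.find_lambda_max(diff)
    name = mimic_names[state]
    print(f"{name} ({state}): F^W419 = {f_w419:6.2f}, "
          f"lambda_max = {lam.lambda_max:.1f} nm")
    groups[name] = [with_probe]

print("\nF vs lambda_max summary (with-probe mutants):")
for summ in kf.summarize_f_lambda(groups):
    print(f"  {summ.label}: F = {summ.f:6.2f}, "
          f"lambda_max = {summ.lambda_max:.1f} nm")
print("Low F with blue-shifted lambda_max marks a quenched, buried probe")
print("(pSpT); high F marks the dequenched SpT/ST states.")
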