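"""Run the end-to-end simulate-and-recover pipeline.

One call generates a KaiC-alone relaxation (fixing the per-state
intensities F_i), circadian oscillations at 30/35/40 deg C with a known
Arrhenius law, adds measurement noise, and then recovers every
generating parameter: F_i, the KaiA offset, the period at each
temperature, and E_a / Q10.  The recovery table lists true vs estimated
values; the run report embeds the full config so the run is exactly
reproducible.
"""

from pathlib import Path

from kaifluor import RunConfig, run_pipeline

out = Path("scratch/pipeline_demo")
cfg = RunConfig(rng_seed=11, noise_sigma=0.5, n_harmonics=3)
report = run_pipeline(cfg, mode="simulate-and-recover", out_dir=out)

print((out / "recovery_table.csv").read_text())
print(f"full report: {report.outputs['run_report']}")
print("abs_error/rel_error columns show each parameter's recovery: periods,")
print("E_a and Q10 land within a fraction of a percent; the offset and the")
print("partially collinear SpT/pSpT intensities carry a few percent of")
print("noise-propagated error.")
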