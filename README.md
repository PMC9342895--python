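# kaifluor

Analysis toolkit for phosphostate-resolved tryptophan fluorescence of the
cyanobacterial circadian clock protein KaiC.

KaiC cycles through four phosphorylation states of Ser431/Thr432
(ST → SpT → pSpT → pST → ST) with a ~24 h period when mixed with KaiA and
KaiB, and relaxes toward ST when incubated alone.  The apparent Trp
fluorescence of such a solution — emission integrated over 320–370 nm,
normalized to protein concentration and an NATA standard — is modelled as a
linear mix of intrinsic per-state intensities:

```
F_app(t) = F_SpT·A_SpT(t) + F_pSpT·A_pSpT(t) + F_pST·A_pST(t) + F_ST·A_ST(t)  [+ offset]
```

where the A_i(t) are the measured relative state abundances and the optional
constant offset is the fluorescence background of KaiA.  `kaifluor` is for
spectroscopists and clock biologists who want to

* deconvolve F_app(t) into the F_i by least squares, with standard errors
  and identifiability diagnostics (`fit_state_fluorescence`);
* isolate an engineered Trp probe's per-state signal by construct
  subtraction, F^W419_i = F_i(F419W) − F_i(base) (`extract_w419`);
* process emission spectra: NATA/concentration normalization, 320–370 nm
  band integration, sub-nm λmax estimation, difference spectra
  (`kaifluor.spectra`);
* quantify rhythms: cosine/Fourier period fits (1–3 harmonics), min–max
  amplitudes, and temperature compensation through the Arrhenius plot of
  cycle frequency 24/period, giving E_a and Q10 (`kaifluor.rhythm`);
* generate fully synthetic datasets with the same statistical structure
  (first-order relaxation kinetics, phase-staggered periodic abundance
  pulses, skew-normal emission bands, additive Gaussian noise), so every
  stage is testable without instrument data (`kaifluor.synthetic`).

## Worked example

Temperature-compensation analysis on synthetic rhythms
(`examples/04_temperature_compensation.py`):

```sh
$ python examples/04_temperature_compensation.py
30 deg C: period = 24.70 h
35 deg C: period = 23.00 h
40 deg C: period = 21.49 h

E_a = 2.63 ± 0.01 kcal/mol (true 2.64)
Q10 = 1.149 (true 1.15)
reference uncompensated reaction: Q10 = 2 -> E_a = 13.1 kcal/mol
```

Oscillations are simulated at three temperatures with a weakly
temperature-dependent period (Q10 = 1.15); the fitted periods are regressed
on an Arrhenius plot, recovering the generating activation energy and Q10.
Q10 ≈ 1.15 — far below the Q10 = 2 (E_a = 13.1 kcal/mol) of an ordinary
chemical reaction — is the signature of a temperature-compensated clock.

The other example scripts cover the remaining capabilities: relaxation
deconvolution and W419 extraction (`01`), forward simulation of an
oscillating F_app with offset estimation (`02`), spectra and the F–λmax
summary (`03`), and the end-to-end pipeline (`05`).

A thin CLI wraps the same functions:

```sh
kaifluor pipeline --seed 3 --out run/     # simulate-and-recover run
kaifluor deconvolve --fluor fapp.csv --abund abundances.csv
kaifluor rhythm --input fapp_30C.csv --input fapp_35C.csv --input fapp_40C.csv
```

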