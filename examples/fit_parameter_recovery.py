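"""Recovering (R, A) and tau_PIN from noisy synthetic measurements.

Generates sine-law and dose-response data with the model's own laws
plus Gaussian noise (sigma = 0.05, the typical scatter of coleoptile
response measurements), then fits them back the way the experimental
datasets are fit: the steady curve fixes (R, A); the dose-response
curve then yields tau_PIN as the single remaining parameter.
"""

from gravipin import (
    fit_memory_time,
    fit_sine_law,
    synth_dose_data,
    synth_steady_data,
)

R_TRUE, A_TRUE, TAU_TRUE = 25.0, 1.3, 13.0

steady = synth_steady_data(R=R_TRUE, A=A_TRUE, sigma=0.05, n_angles=100,
                           seed=2026)
sine = fit_sine_law(steady)
print(f"sine-law fit:   R_hat = {sine.R_hat:8.2f} (true {R_TRUE}), "
      f"A_hat = {sine.A_hat:.3f} (true {A_TRUE})")
if sine.plateau:
    print(f"  note: R profile is flat above ~{sine.plateau_R_lower:.0f} — "
          "the data constrain the curve shape, not R itself")

dose = synth_dose_data(tau_pin=TAU_TRUE, sigma=0.05, seed=2026)
mem = fit_memory_time(dose, R=R_TRUE, A=A_TRUE, polish=False)
print(f"memory-time fit: tau_PIN_hat = {mem.tau_pin_hat:.2f} min "
      f"(true {TAU_TRUE}); unidentifiable flag = {mem.unidentifiable}")
print("\nA is the amplitude of the steady curve and is tightly "
      "constrained; R shapes it and saturates for strong coupling; "
      "tau_PIN is read off the dose-response crossover.")
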