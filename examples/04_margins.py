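"""Population errors and van Herk margins from the packaged study tables.

Aggregates the per-patient deviation tables into systematic (Sigma) and
random (sigma) error components and evaluates the CTV-to-PTV margin recipe
2.5 Sigma + 0.7 sigma, combining the diaphragm-vs-marker surrogate error
with the 3D tracking-verification error in quadrature.
"""

from mdtt.margins import (combine_error_sources, load_table, round_half_up,
                          table_population_errors, van_herk_margin)

t2 = load_table(2)  # diaphragm-vs-marker deviations, per axis
t4 = load_table(4)  # detected-vs-predicted 3D tracking deviations
tracking = table_population_errors(t4, "3d")
print(f"tracking: mean {round_half_up(tracking.mean_of_means):.2f} mm, "
      f"Sigma {round_half_up(tracking.sigma_systematic):.2f}, "
      f"sigma {round_half_up(tracking.sigma_random):.2f}")

for axis in ("ml", "si", "ap"):
    surrogate = table_population_errors(t2, axis)
    combined = combine_error_sources([surrogate, tracking])
    margin = van_herk_margin(combined)  # 2.5*Sigma + 0.7*sigma
    print(f"{axis.upper()}: surrogate Sigma/sigma "
          f"{round_half_up(surrogate.sigma_systematic):.2f}/"
          f"{round_half_up(surrogate.sigma_random):.2f} mm -> "
          f"margin {round_half_up(margin.margin_mm, 1):.1f} mm")
# The margin combines a preparation-type error (Sigma, shifts the dose
# distribution) and an execution-type error (sigma, blurs it); the
# coefficients and combination rule are configurable and echoed in the
# MarginResult.
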