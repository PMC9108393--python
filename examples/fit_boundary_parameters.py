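"""Fit the boundary-influx parameters to synthetic binned counts.

Generates one noise-free control experiment, then uses the Kriging /
expected-improvement optimiser to fit the PBMC reservoir density
(rho_tilde) and the cytokine outflux coefficient (zeta) to the binned
counts.  Individually the two are unidentifiable from count data, but
their product — which sets the boundary influx — is recovered accurately.
"""

import numpy as np

from chemofit import FitSpec, StudyDesign, bin_counts, make_objective, optimize
from chemofit.synth import CONTROL_LABEL, _align_times, control_params, generate_experiment

truth = control_params()
design = StudyDesign(noise="none", seed=3, n_cells=200)
table = generate_experiment(design, CONTROL_LABEL, 3)
data = _align_times(bin_counts(table, design.roi_length_um, design.n_bins),
                    design)

spec = FitSpec(free_names=["rho_tilde", "zeta"],
               bounds={"rho_tilde": (10.0, 250.0), "zeta": (0.05, 1.0)},
               baseline=truth, roi_length_um=700.0,
               output_times=design.times, n_cells=200)
f = make_objective(data, spec)
res = optimize(f, spec.transformed_bounds(), budget=120, q=4, seed=0)

best = spec.theta_to_params(res.x)
print(f"fitted objective (SSR over {len(design.times)}x{design.n_bins} "
      f"time-bin cells): {res.fun:.2f}")
print(f"fitted rho_tilde = {best.rho_tilde:7.1f}   (truth {truth.rho_tilde})")
print(f"fitted zeta      = {best.zeta:7.3f}   (truth {truth.zeta})")
print(f"influx product zeta*rho_tilde = {best.zeta * best.rho_tilde:.1f} "
      f"(truth {truth.zeta * truth.rho_tilde:.1f})")
print("The SSR is at the count-rounding floor and the product is recovered "
      "even when the individual parameters drift along the ridge.")
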