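"""Fit the chain model to a synthetic dose-response experiment.

Generates noiseless dose-response data for a cytostatic G1-targeting
drug, then recovers the drug-free rates, the initial G1 fraction and
the drug's Hill parameters by differential evolution.  A deliberately
small optimizer budget keeps the example quick; see the fitting module
docstring for production settings.
"""

import numpy as np

import lctcycle as lc
from lctcycle.fitting import FitSpec, fit

control = lc.RateSet(alpha=8 / 22.3, beta=20 / 22.3)
truth = lc.DrugResponseProfile("g1_blocker", control, ec50=50.0,
                               steepness=2.0, e_max={"alpha": 0.05})
doses = [0.0, 10.0, 50.0, 250.0]
times = np.arange(0.0, 96.5, 1.0)

data = lc.mean_field_dose_response(truth, doses, times, initial_g1_fraction=0.75)
datasets = {("g1_blocker", c): v for c, v in data.items()}

spec = FitSpec(drug_doses={"g1_blocker": doses},
               free_emax={"g1_blocker": {"alpha": [True] * 4}},
               times=times,
               optimizer={"popsize": 6, "maxiter": 40, "seed": 0})
result = fit(spec, datasets)

g1_fit, sg2_fit = lc.average_phase_durations(result.control_rates)
print(f"SSE                  : {result.sse:.3e} (converged={result.converged})")
print(f"fitted G1 duration   : {g1_fit:.1f} h (true 22.3)")
print(f"fitted S-G2 duration : {sg2_fit:.1f} h (true 22.3)")
print(f"fitted EC50          : {result.profiles['g1_blocker'].ec50:.1f} nM (true 50)")
print(f"fitted G1 fraction   : {result.initial_g1_fraction:.2f} (true 0.75)")
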