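"""Round trip through the file interface: simulate, write, read, fit, test.

The same workflow is available from the shell:
    mrdoc simulate --config scenario.yaml --out twins.tsv
    mrdoc fit twins.tsv --model mrdoc_re0 --test g1
"""

import tempfile
from pathlib import Path

from mrdoc import fit_ml, lrt, mrdoc_spec, simulate_twin_study, recovery_scenario, \
    theta_from_scenario, wald
from mrdoc.io import read_twin_table, write_scenario, write_twin_table

tmp = Path(tempfile.mkdtemp())
scenario = recovery_scenario(2)
theta = theta_from_scenario(scenario)
write_scenario(scenario, tmp / "scenario.yaml")

data = simulate_twin_study(theta, 1000, 1000, mode="random", seed=3)
write_twin_table(data, tmp / "twins.tsv")
data_back = read_twin_table(tmp / "twins.tsv")
print(f"wrote and re-read {data_back.n_mz} MZ + {data_back.n_dz} DZ pairs")

spec = mrdoc_spec(re_zero=True)
fit = fit_ml(data_back, spec)
e = fit.estimates
print(f"estimates: b1={e.b1:.3f} (true {theta.b1:.3f})  "
      f"b2={e.b2:.3f} (true {theta.b2:.3f})  g1={e.g1:.3f} (true {theta.g1:.3f})")

null = fit_ml(data_back, spec.constrain(g1=0.0),
              starts=fit.estimates.replace(g1=0.0), compute_se=False)
delta, df, p_lrt = lrt(fit, null)
z, p_wald = wald(fit, "g1")
print(f"causal-effect tests: LRT chi2({df}) = {delta:.2f} (p = {p_lrt:.2g}), "
      f"Wald z = {z:.2f} (p = {p_wald:.2g})")
print("\nWith 2000 random-sampled pairs the estimates scatter around the")
print("generating values and both tests detect the causal path.")
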