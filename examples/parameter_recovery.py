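"""Standard MR vs MR-DoC under instrument pleiotropy.

Builds the three generating scenarios (valid instrument; pleiotropic
instrument with a causal effect; pleiotropic instrument without one),
simulates exact data, and compares the causal-effect estimates.  Standard
MR is biased by b2/b1 whenever the instrument has a direct effect on the
outcome; the twin-integrated model estimates b2 and stays unbiased.
"""

from mrdoc import (
    exact_mvn_sample,
    fit_ml,
    implied_moments_unrelated,
    mrdoc_spec,
    simulate_twin_study,
    recovery_scenario,
    theta_from_scenario,
    tsls,
)

for sid, label in (
    (1, "valid instrument, g1 > 0"),
    (2, "pleiotropic instrument, g1 > 0"),
    (3, "pleiotropic instrument, g1 = 0"),
):
    theta = theta_from_scenario(recovery_scenario(sid))
    print(f"scenario {sid} ({label}):")
    print(f"  generating: b1={theta.b1:.4f}  b2={theta.b2:.4f}  g1={theta.g1:.4f}")

    # standard MR on 4000 exact-data unrelated individuals
    arr = exact_mvn_sample(implied_moments_unrelated(theta), 4000, seed=sid)
    est, se = tsls(arr[:, 2], arr[:, 1], arr[:, 0])
    print(f"  standard MR (2SLS, 4000 unrelateds): g1_hat = {est:.4f} (se {se:.4f})")

    # MR-DoC on 1000 MZ + 1000 DZ exact twin pairs
    data = simulate_twin_study(theta, 1000, 1000, mode="exact", seed=sid)
    fit = fit_ml(data, mrdoc_spec(re_zero=True), compute_se=False)
    e = fit.estimates
    print(f"  MR-DoC (2000 twin pairs):            g1_hat = {e.g1:.4f}  "
          f"b2_hat = {e.b2:.4f}\n")

print("Standard MR recovers g1 only in scenario 1; in scenarios 2-3 its")
print("estimate equals g1 + b2/b1 (0.63 and 1.00 here) while MR-DoC stays")
print("on the generating values because the pleiotropy path is estimated.")
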