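"""Estimate dG by thermodynamic integration from surrogate dH/dlambda series.

Generates an AR(1) surrogate study (25 lambda points x 9 replicas x 500 ps)
whose true mean curve g(lambda) = 15 - 12 lambda + 6 lambda^2 has a known
integral, then runs the full estimator: equilibration discard, replica
pooling with block-averaged errors, and generalized Simpson integration.
"""

from ticycle.synthetic_data import SurrogateSpec, gen_ar1_dhdl, true_integral
from ticycle.ti_core import (
    build_lambda_schedule,
    combine_replicas,
    discard_equilibration,
    estimate_free_energy,
)

spec = SurrogateSpec(
    coeffs=(15.0, -12.0, 6.0), sigma_n=8.0, phi=0.8,
    n_steps=500, n_replicas=9, seed=42,
)
schedule = build_lambda_schedule()  # 21 uniform + 2 extra nodes per end

points = []
for lam in schedule:
    replicas = [discard_equilibration(s) for s in gen_ar1_dhdl(spec, float(lam))]
    points.append(combine_replicas(replicas))

est = estimate_free_energy(points, schedule)
truth = true_integral(spec)

print(f"dG (TI estimate) = {est.delta_g:.3f} +/- {est.sigma:.3f} kJ/mol")
print(f"true integral of g(lambda) = {truth:.3f} kJ/mol")
print(f"deviation = {abs(est.delta_g - truth) / est.sigma:.2f} sigma")
# The estimate should agree with the planted truth within ~3 sigma; the
# sigma is propagated from per-lambda block-averaged standard errors.
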