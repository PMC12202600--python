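"""Closed-form telegraph stationary laws vs the brute-force CME oracle.

Builds the partial mass functions p (promoter ON) and q (promoter OFF) for a
bursty parameter set, compares them to the stationary solution of the
truncated chemical master equation, and shows the polyploid (K=3) joint law
of (active alleles, total count).
"""

import numpy as np

from burstfish import (
    TelegraphParams,
    active_fraction,
    cme_stationary_oracle,
    marginal_pmf,
    partial_pmf_off,
    partial_pmf_on,
    polyploid_joint_pmf,
)

params = TelegraphParams(lam=1.0, gam=1.0, mu=10.0, delta=1.0, beta=0.2)
f = active_fraction(params)
p, q = partial_pmf_on(params), partial_pmf_off(params)
print(f"active fraction f = {f:.3f}")
print(f"sum p = {p.sum():.6f} (= f), sum q = {q.sum():.6f} (= 1-f)")

P = marginal_pmf(params)
mean = (np.arange(len(P)) * P).sum()
print(f"stationary mean count = {mean:.4f} (closed form f*mu/delta = {f * params.mu / params.delta:.4f})")

oracle = cme_stationary_oracle(params, K=1, m_max=150)
n = min(len(p), 151)
err = max(np.abs(p[:n] - oracle[1, :n]).max(), np.abs(q[:n] - oracle[0, :n]).max())
print(f"max |closed form - CME oracle| = {err:.2e}  (agreement of two independent routes)")

joint = polyploid_joint_pmf(params, K=3, full_support=True)
print("P(k active alleles) =", np.round(joint.sum(axis=1), 4), "(binomial(3, f))")
# Each row k is C(3,k) * p^{*k} conv q^{*(3-k)}: the count law given k active alleles.
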