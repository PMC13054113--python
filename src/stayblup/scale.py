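"""Liability/observed scale conversion for binary traits (Dempster-Lerner,
as extended by Gianola for categorical traits).

With success incidence ``alpha``, threshold ``t = Phi^-1(1 - alpha)`` and
``z = phi(t)`` the normal density at the threshold:

    h2_obs      = z^2 h2_lia / (alpha (1 - alpha))
    sigma_u2_obs = z^2 h2_lia
    sigma_p2_obs = alpha (1 - alpha)
    sigma_e2_obs = sigma_p2_obs - (sigma_u2_obs + sigma_pe2 + sigma_cg2)

The permanent-environment and contemporary-group variances are zero for the
single-record stayability model; they are kept as explicit arguments because
the residual formula subtracts all non-residual components together.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm


@dataclass
class ScaleConversion:
    alpha: float
    t: float
    z: float
    h2_liability: float
    h2_observed: float
    sigma_u2_obs: float
    sigma_p2_obs: float
    sigma_e2_obs: float


def liability_to_observed(
    h2_liability: float, alpha: float, sigma_pe2: float = 0.0, sigma_cg2: float = 0.0
) -> ScaleConversion:
    """Convert a liability-scale heritability to the observed (0/1) scale.

    ``alpha`` is the incidence of the success category; the conversion is
    symmetric in ``alpha`` and ``1 - alpha``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not 0.0 < h2_liability < 1.0:
        raise ValueError("h2_liability must be in (0, 1)")
    t = norm.ppf(1.0 - alpha)
    z = norm.pdf(t)
    sigma_u2 = z * z * h2_liability
    sigma_p2 = alpha * (1.0 - alpha)
    sigma_e2 = sigma_p2 - (sigma_u2 + sigma_pe2 + sigma_cg2)
    return ScaleConversion(
        alpha=alpha,
        t=float(t),
        z=float(z),
        h2_liability=h2_liability,
        h2_observed=sigma_u2 / sigma_p2,
        sigma_u2_obs=float(sigma_u2),
        sigma_p2_obs=float(sigma_p2),
        sigma_e2_obs=float(sigma_e2),
    )


def observed_to_liability(h2_observed: float, alpha: float) -> float:
    """Inverse map: ``h2_lia = h2_obs alpha (1 - alpha) / z^2``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    z = norm.pdf(norm.ppf(1.0 - alpha))
    h2_l = h2_observed * alpha * (1.0 - alpha) / (z * z)
    if not 0.0 < h2_l < 1.0:
        raise ValueError(f"resulting liability heritability {h2_l:.4g} outside (0, 1)")
    return float(h2_l)
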