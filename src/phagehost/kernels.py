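"""Infection kernels: trade-off based and random compatibility and virulence.

Compatibility ``C`` is the probability that a virus recognizes/attaches a
host; virulence ``V`` is the probability that a compatible encounter ends in
lysis.  The trade-off forms couple the host's competitive trait (nutrient
affinity gene ``g_alpha``) to the virus's defense-relevant traits (adsorption
gene ``g_beta`` and host-range gene ``g_nu``):

    C_t = exp(-|g_alpha - g_beta| / g_nu)        broad range => compatible
    V_t = min(1, beta_n * g_beta / g_nu)         narrow range => virulent

so a broad host range (large ``g_nu``) buys compatibility at the price of
per-infection efficiency.  The random variants draw a fresh Uniform(0, 1)
per call and ignore the genotypes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "compat_tradeoff",
    "compat_random",
    "virulence_tradeoff",
    "virulence_random",
    "GENE_FLOOR_EPS",
]

#: Default numerical floor for g_nu in denominators.
GENE_FLOOR_EPS = 1e-9


def _check_unit(name: str, x) -> None:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {x!r}")


def compat_tradeoff(g_alpha, g_nu, g_beta, gene_floor_eps: float = GENE_FLOOR_EPS):
    """Trade-off based compatibility exp(-|g_alpha - g_beta| / g_nu).

    Equals 1 when host and virus genes match exactly (regardless of g_nu),
    decays with gene distance, and increases with the virus host range g_nu.
    Accepts scalars or broadcastable arrays; scalar inputs give a float.
    """
    _check_unit("g_alpha", g_alpha)
    _check_unit("g_nu", g_nu)
    _check_unit("g_beta", g_beta)
    d = np.abs(np.asarray(g_alpha, float) - np.asarray(g_beta, float))
    denom = np.maximum(np.asarray(g_nu, float), gene_floor_eps)
    out = np.exp(-d / denom)
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def virulence_tradeoff(g_nu, g_beta, beta_n, gene_floor_eps: float = GENE_FLOOR_EPS):
    """Trade-off based virulence min(1, beta_n * g_beta / g_nu).

    Linear in the adsorption gene below the clamp and inversely related to
    host range; the clamp keeps the value interpretable as a probability.
    """
    _check_unit("g_nu", g_nu)
    _check_unit("g_beta", g_beta)
    if np.any(np.asarray(beta_n, float) < 0):
        raise ValueError(f"beta_n must be >= 0, got {beta_n!r}")
    denom = np.maximum(np.asarray(g_nu, float), gene_floor_eps)
    out = np.minimum(1.0, np.asarray(beta_n, float) * np.asarray(g_beta, float) / denom)
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def compat_random(rng: np.random.Generator) -> float:
    """Random compatibility: one independent Uniform(0, 1) draw per call."""
    return float(rng.random())


def virulence_random(rng: np.random.Generator) -> float:
    """Random virulence: one independent Uniform(0, 1) draw per call."""
    return float(rng.random())
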