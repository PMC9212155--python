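"""Model parameters, individual/state types, unit normalization and validation.

The simulator tracks a phosphorus budget in "host-equivalent" units: one unit
equals the maximum phosphorus content ``P_h`` of a single host cell.  The
total phosphorus in the simulated volume is therefore ``P_units = P * V / P_h``
host-equivalents, and the per-individual rate constants ``alpha`` (host
nutrient affinity, L/h) and ``beta`` (virus adsorption coefficient, L/h) are
normalized by the simulated volume ``V`` so that they act on per-volume
abundances directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "SimulationParams",
    "NormalizedParams",
    "HostIndividual",
    "VirusIndividual",
    "ChemostatState",
    "InvalidConfigError",
    "normalize",
    "validate",
]

MODES = ("tradeoff", "random")


class InvalidConfigError(ValueError):
    """Raised for configurations that cannot be simulated."""


@dataclass(frozen=True)
class SimulationParams:
    """Full parameter set of the individual-based chemostat model.

    Defaults are the standard short-horizon scenario: a 1 μL chemostat at
    71 μmol-P/L total phosphorus, diluted at 0.2/h, inoculated with 46 hosts
    and 810 virions (virus-to-host ratio 17.6), run for 36 one-hour steps
    with trade-off based compatibility and virulence.
    """

    T: int = 36                  # simulation duration, hours
    t_step: float = 1.0          # time step, hours (only 1 h supported)
    V: float = 1e-6              # chemostat volume, litres
    P: float = 71.0              # total phosphorus concentration, μmol-P/L
    P_h: float = 8.3e-8          # maximum phosphorus content of one host, μmol-P
    omega: float = 0.2           # dilution (washout) rate, 1/h; 0 = closed system
    N_h0: int = 46               # initial host count
    N_v0: int = 810              # initial virus count
    alpha: float = 1.6e-7        # host nutrient affinity, L/h
    mu_h: float = 0.738          # maximum host growth rate, 1/h
    g_alpha0: float = 0.1        # initial nutrient-affinity gene, in [0, 1]
    pi_h: float = 6e-2           # host mutation probability per division
    sigma_h: float = 5e-2        # host mutation standard deviation
    delta_h: float = 1.4e-2      # host mortality rate, 1/h
    eps_h: float = 1.4e-2        # host metabolic loss rate, 1/h
    beta: float = 6.2e-11        # virus adsorption coefficient, L/h
    g_nu0: float = 0.1           # initial virus host-range ("memory") gene
    g_beta0: float = 0.1         # initial virus adsorption gene
    pi_v: float = 6e-3           # virus mutation probability per progeny virion
    sigma_v: float = 5e-3        # virus mutation standard deviation
    kappa: int = 10              # burst size, virions per lysed host
    delta_v: float = 1.4e-2      # virus decay rate, 1/h
    compatibility_mode: str = "tradeoff"
    virulence_mode: str = "tradeoff"
    gene_floor_eps: float = 1e-9  # floor for g_nu in kernel denominators

    @property
    def vhr(self) -> float:
        """Initial virus-to-host ratio N_v0 / N_h0."""
        if self.N_h0 == 0:
            return math.inf if self.N_v0 else math.nan
        return self.N_v0 / self.N_h0

    def with_(self, **overrides) -> "SimulationParams":
        """A copy with the given fields replaced."""
        return replace(self, **overrides)


def validate(params: SimulationParams) -> list[str]:
    """Check all parameter invariants; return human-readable violations.

    An empty list means the configuration is valid.  Rates interpreted as
    per-step probabilities (1 h steps) must lie in [0, 1]; counts must be
    non-negative integers; the volume and per-host phosphorus quota must be
    positive.
    """
    v: list[str] = []
    if params.t_step != 1.0:
        v.append("t_step: only 1 h time steps are supported (got %r)" % (params.t_step,))
    if not (isinstance(params.T, int) and params.T >= 0):
        v.append("T: must be a non-negative integer number of hours")
    for name in ("omega", "delta_h", "eps_h", "delta_v", "mu_h"):
        x = getattr(params, name)
        if not 0.0 <= x <= 1.0:
            v.append(f"{name}: rate {x!r} outside [0, 1] (per-step probability)")
    for name in ("pi_h", "pi_v"):
        x = getattr(params, name)
        if not 0.0 <= x <= 1.0:
            v.append(f"{name}: probability {x!r} outside [0, 1]")
    for name in ("sigma_h", "sigma_v"):
        x = getattr(params, name)
        if not x >= 0.0:
            v.append(f"{name}: standard deviation {x!r} must be >= 0")
    for name in ("N_h0", "N_v0", "kappa"):
        x = getattr(params, name)
        if not (isinstance(x, int) and x >= 0):
            v.append(f"{name}: must be a non-negative integer (got {x!r})")
    if not params.V > 0:
        v.append(f"V: volume must be positive (got {params.V!r})")
    if not params.P_h > 0:
        v.append(f"P_h: per-host phosphorus quota must be positive (got {params.P_h!r})")
    if not params.P >= 0:
        v.append(f"P: total phosphorus must be >= 0 (got {params.P!r})")
    for name in ("g_alpha0", "g_nu0", "g_beta0"):
        x = getattr(params, name)
        if not 0.0 <= x <= 1.0:
            v.append(f"{name}: gene value {x!r} outside [0, 1]")
    for name in ("compatibility_mode", "virulence_mode"):
        x = getattr(params, name)
        if x not in MODES:
            v.append(f"{name}: {x!r} not one of {MODES}")
    if not params.gene_floor_eps > 0:
        v.append(f"gene_floor_eps: must be positive (got {params.gene_floor_eps!r})")
    return v


@dataclass(frozen=True)
class NormalizedParams:
    """Parameters in simulation units (host-equivalents per simulated volume).

    ``P_units = P * V / P_h`` is the total phosphorus expressed as a number of
    host individuals; ``alpha_n = alpha / V`` and ``beta_n = beta / V`` act on
    abundances within the simulated volume.  All other fields of the source
    :class:`SimulationParams` are reachable as attributes.
    """

    P_units: float
    alpha_n: float
    beta_n: float
    base: SimulationParams = field(repr=False)

    def __getattr__(self, name):
        # delegate pass-through fields to the underlying SimulationParams
        try:
            return getattr(self.base, name)
        except AttributeError:
            raise AttributeError(name) from None


def normalize(params: SimulationParams) -> NormalizedParams:
    """Convert physical units to host-equivalent simulation units."""
    problems = validate(params)
    if problems:
        raise InvalidConfigError("invalid configuration: " + "; ".join(problems))
    return NormalizedParams(
        P_units=params.P * params.V / params.P_h,
        alpha_n=params.alpha / params.V,
        beta_n=params.beta / params.V,
        base=params,
    )


@dataclass
class HostIndividual:
    """One bacterium: biomass ``m`` (host-equivalent P units, in (0, 1]) and
    nutrient-affinity gene ``g_alpha`` in [0, 1]."""

    m: float
    g_alpha: float


@dataclass
class VirusIndividual:
    """One phage: host-range ("memory") gene ``g_nu`` and adsorption gene
    ``g_beta``, both in [0, 1]."""

    g_nu: float
    g_beta: float


@dataclass
class ChemostatState:
    """Snapshot of the chemostat: dissolved phosphorus plus both populations.

    Populations are held as parallel numpy arrays (structure-of-arrays) for
    speed; ``hosts`` / ``viruses`` expose object views for inspection.
    ``cumulative_inflow`` / ``cumulative_outflow`` keep the phosphorus ledger:
    at every step ``P_d + sum(m) == P_units + inflow - outflow`` and, in a
    closed system (omega = 0), ``P_d + sum(m) == P_units`` exactly.
    """

    time: int
    P_d: float
    P_d0: float
    host_m: "np.ndarray"
    host_g_alpha: "np.ndarray"
    virus_g_nu: "np.ndarray"
    virus_g_beta: "np.ndarray"
    cumulative_inflow: float = 0.0
    cumulative_outflow: float = 0.0

    @property
    def N_h(self) -> int:
        return int(self.host_m.size)

    @property
    def N_v(self) -> int:
        return int(self.virus_g_nu.size)

    @property
    def hosts(self) -> list[HostIndividual]:
        return [HostIndividual(float(m), float(g))
                for m, g in zip(self.host_m, self.host_g_alpha)]

    @property
    def viruses(self) -> list[VirusIndividual]:
        return [VirusIndividual(float(n), float(b))
                for n, b in zip(self.virus_g_nu, self.virus_g_beta)]


# only needed for type resolution of the array annotations above
import numpy as np  # noqa: E402  (kept at bottom to avoid polluting __all__)
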