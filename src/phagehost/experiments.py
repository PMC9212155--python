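"""Ensemble replication, parameter sweeps and long-term factorial runs.

Replicate ``r`` of an ensemble with master seed ``s`` uses the generator
seeded by ``numpy.random.SeedSequence((s, r))``; any replicate can therefore
be re-run in isolation, and ensembles with the same master seed are
bit-reproducible regardless of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .engine import Trajectory, run
from .params import SimulationParams

__all__ = [
    "EnsembleSummary",
    "SweepSpec",
    "run_ensemble",
    "run_sweep",
    "run_factorial_longterm",
    "classify_outcome",
    "second_peak",
    "DEFAULT_VHR_GRID",
    "DEFAULT_P_FACTORS",
    "DEFAULT_OMEGA_GRID",
    "DEFAULT_MUTATION_FACTORS",
]

# default sweep grids bracketing the standard parameter set
DEFAULT_VHR_GRID = (1.76, 8.8, 17.6, 88.0, 176.0)
DEFAULT_P_FACTORS = (0.5, 1.0, 5.0, 10.0, 20.0)
DEFAULT_OMEGA_GRID = (0.0, 0.1, 0.2, 0.3, 0.4)
DEFAULT_MUTATION_FACTORS = (0.01, 0.1, 1.0, 10.0)


@dataclass
class EnsembleSummary:
    """Cross-replicate mean and standard deviation of the main time series."""

    params: SimulationParams
    n_reps: int
    master_seed: int
    time: np.ndarray
    mean_Nh: np.ndarray
    sd_Nh: np.ndarray
    mean_Nv: np.ndarray
    sd_Nv: np.ndarray
    mean_Pd: np.ndarray
    sd_Pd: np.ndarray
    trajectories: list[Trajectory] | None = None

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "t": self.time,
            "mean_Nh": self.mean_Nh, "sd_Nh": self.sd_Nh,
            "mean_Nv": self.mean_Nv, "sd_Nv": self.sd_Nv,
            "mean_Pd": self.mean_Pd, "sd_Pd": self.sd_Pd,
        })


def replicate_seed(master_seed: int, rep: int) -> np.random.SeedSequence:
    """Seed of replicate ``rep``: SeedSequence((master_seed, rep))."""
    return np.random.SeedSequence((int(master_seed), int(rep)))


def run_ensemble(params: SimulationParams, n_reps: int, master_seed: int,
                 *, keep_trajectories: bool = False, n_bins: int = 50,
                 snapshot_times: tuple = ()) -> EnsembleSummary:
    """Run ``n_reps`` independent replicates and summarize them per step.

    Standard deviations are population standard deviations across replicates
    (a single replicate yields sd = 0 everywhere).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    trajs = []
    for r in range(n_reps):
        trajs.append(run(params, replicate_seed(master_seed, r),
                         n_bins=n_bins, snapshot_times=snapshot_times))
    Nh = np.stack([t.N_h for t in trajs]).astype(float)
    Nv = np.stack([t.N_v for t in trajs]).astype(float)
    Pd = np.stack([t.P_d for t in trajs])
    return EnsembleSummary(
        params=params, n_reps=n_reps, master_seed=int(master_seed),
        time=trajs[0].time.copy(),
        mean_Nh=Nh.mean(axis=0), sd_Nh=Nh.std(axis=0),
        mean_Nv=Nv.mean(axis=0), sd_Nv=Nv.std(axis=0),
        mean_Pd=Pd.mean(axis=0), sd_Pd=Pd.std(axis=0),
        trajectories=trajs if keep_trajectories else None,
    )


@dataclass
class SweepSpec:
    """One-dimensional parameter sweep.

    ``param`` may be any :class:`SimulationParams` field, or the virtual
    parameter ``"VHR"`` which scales ``N_v0`` at fixed ``N_h0``.
    """

    param: str
    values: tuple
    n_reps: int
    base: SimulationParams = field(default_factory=SimulationParams)
    master_seed: int = 0


def _apply_sweep_value(base: SimulationParams, param: str, value) -> SimulationParams:
    if param == "VHR":
        return replace(base, N_v0=int(round(value * base.N_h0)))
    if param not in {f.name for f in base.__dataclass_fields__.values()}:
        raise ValueError(f"unknown sweep parameter {param!r}")
    if param in ("N_h0", "N_v0", "kappa", "T"):
        value = int(value)
    return replace(base, **{param: value})


def run_sweep(spec: SweepSpec, **ensemble_kwargs) -> dict:
    """One ensemble per swept value, keyed by the value.

    Every grid point uses the same master seed (common random numbers), so a
    single-value sweep reproduces :func:`run_ensemble` exactly and results do
    not depend on the order in which grid points are executed.
    """
    out = {}
    for value in spec.values:
        params = _apply_sweep_value(spec.base, spec.param, value)
        out[value] = run_ensemble(params, spec.n_reps, spec.master_seed,
                                  **ensemble_kwargs)
    return out


def run_factorial_longterm(base_params: SimulationParams, n_reps: int,
                           master_seed: int, *, T: int = 720,
                           open_omega: float | None = None) -> dict:
    """All 8 combinations of {closed, open} x {Ct, Cr} x {Vt, Vr}.

    "closed" sets the washout rate to 0; "open" keeps the base washout rate
    (or ``open_omega`` if given).  Returns a dict keyed by
    ``(system, compatibility_mode, virulence_mode)``.
    """
    omega_open = base_params.omega if open_omega is None else open_omega
    out = {}
    for system, omega in (("closed", 0.0), ("open", omega_open)):
        for cmode in ("tradeoff", "random"):
            for vmode in ("tradeoff", "random"):
                params = replace(base_params, T=T, omega=omega,
                                 compatibility_mode=cmode, virulence_mode=vmode)
                out[(system, cmode, vmode)] = run_ensemble(
                    params, n_reps, master_seed)
    return out


def classify_outcome(summary: EnsembleSummary, threshold: float = 1.0) -> str:
    """Qualitative fate from ensemble-mean final abundances.

    Both populations above the threshold (one individual) -> "coexistence";
    hosts only -> "host_only"; otherwise "double_extinction".  A host-free
    vessel with straggling virions is a collapse in progress (virions decay
    with nothing left to infect) and counts as double extinction.
    """
    hosts = summary.mean_Nh[-1] >= threshold
    viruses = summary.mean_Nv[-1] >= threshold
    if hosts and viruses:
        return "coexistence"
    if hosts:
        return "host_only"
    return "double_extinction"


def second_peak(series: np.ndarray) -> tuple[int, float]:
    """Locate the post-crash recovery peak of a host abundance series.

    Finds the global (first) bloom peak, the trough that follows it, and
    returns (index, height) of the maximum after that trough.  If the series
    never recovers the final value is returned.
    """
    series = np.asarray(series, dtype=float)
    i_peak1 = int(np.argmax(series))
    if i_peak1 >= series.size - 1:
        return series.size - 1, float(series[-1])
    i_trough = i_peak1 + int(np.argmin(series[i_peak1:]))
    if i_trough >= series.size - 1:
        return series.size - 1, float(series[-1])
    i_peak2 = i_trough + int(np.argmax(series[i_trough:]))
    return i_peak2, float(series[i_peak2])


def sweep_to_dataframe(results: dict, param: str):
    """Tidy long-format table of a sweep result:
    {swept_param, value, t, mean_Nh, sd_Nh, mean_Nv, sd_Nv, mean_Pd}."""
    import pandas as pd
    frames = []
    for value, summary in results.items():
        df = summary.to_dataframe()[["t", "mean_Nh", "sd_Nh",
                                     "mean_Nv", "sd_Nv", "mean_Pd"]]
        df.insert(0, "swept_param", param)
        df.insert(1, "value", value)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def factorial_to_dataframe(results: dict):
    """Tidy table of factorial outcomes with per-combination classification."""
    import pandas as pd
    frames = []
    for (system, cmode, vmode), summary in results.items():
        df = summary.to_dataframe()[["t", "mean_Nh", "sd_Nh",
                                     "mean_Nv", "sd_Nv", "mean_Pd"]]
        df.insert(0, "system", system)
        df.insert(1, "compat_mode", cmode)
        df.insert(2, "virulence_mode", vmode)
        df.insert(3, "outcome_class", classify_outcome(summary))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
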