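"""Stochastic simulation engine: one chemostat run, step by step.

Each one-hour step applies, in order:

1. nutrient update -- dissolved phosphorus relaxes toward its initial value,
   ``P_d += omega * (P_d0 - P_d)``, modelling in/outflow of medium;
2. host round -- every host, in random order, faces washout (prob ``omega``)
   then death (prob ``delta_h``, biomass recycled to ``P_d``), pays metabolic
   losses ``eps_h * m``, takes up Monod growth
   ``min(P_d, mu_h * a g P_d / (1 + a g P_d))`` from the running nutrient
   pool, and divides into two daughters when its mass exceeds 1 (daughters
   share one mutation draw of the nutrient-affinity gene);
3. virus round -- every virion, in random order, faces washout then decay,
   and otherwise scans the surviving hosts in random order; each virus-host
   pair succeeds with probability C * V (compatibility times virulence,
   trade-off based or random per configuration).  The first success lyses the
   host (biomass recycled to ``P_d``), removes the virion, and buffers
   ``kappa`` progeny that join the population only after the round.

The virus round is implemented as an exact sparse equivalent of that per-pair
scan: scanning hosts in random order and taking the first per-pair Bernoulli
success selects a uniformly random element of the success set, and the
success set over the currently alive hosts is sampled by drawing a
``Binomial(n, p_max)`` candidate count per virus and thinning candidates by
``p_ij / p_max``.  Random kernels enter as their exact per-pair marginal: a
Bernoulli whose success probability is itself Uniform(0, 1) is a
Bernoulli(1/2).  All randomness is pre-drawn from one per-run generator, so
a given (parameters, seed) pair always yields a bit-identical trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np

from .params import (
    ChemostatState,
    InvalidConfigError,
    NormalizedParams,
    SimulationParams,
    normalize,
)

__all__ = [
    "Trajectory",
    "init_simulation",
    "nutrient_update",
    "host_round",
    "virus_round",
    "step",
    "run",
]


# --------------------------------------------------------------------------
# jitted sequential kernels (all random numbers are pre-drawn outside)

@numba.njit(cache=False)
def _host_round_kernel(m, g, order, u_wash, u_death, u_mut, z_mut,
                       P_d, omega, delta_h, eps_h, mu_h, alpha_n, pi_h,
                       out_m, out_g):
    """Sequential host dynamics; returns (n_out, P_d, outflow)."""
    n = order.size
    n_out = 0
    outflow = 0.0
    for k in range(n):
        i = order[k]
        mi = m[i]
        gi = g[i]
        if u_wash[k] < omega:          # washed out of the vessel
            outflow += mi
            continue
        if u_death[k] < delta_h:       # death: biomass recycled
            P_d += mi
            continue
        loss = eps_h * mi              # metabolic loss
        mi -= loss
        P_d += loss
        x = alpha_n * gi * P_d         # Monod uptake from the running pool
        gain = mu_h * x / (1.0 + x)
        if gain > P_d:
            gain = P_d
        P_d -= gain
        mi += gain
        if mi > 1.0:                   # division; daughters share one draw
            g2 = gi
            if u_mut[k] < pi_h:
                g2 = gi + z_mut[k]
                if g2 < 0.0:
                    g2 = 0.0
                elif g2 > 1.0:
                    g2 = 1.0
            half = 0.5 * mi
            out_m[n_out] = half
            out_g[n_out] = g2
            out_m[n_out + 1] = half
            out_g[n_out + 1] = g2
            n_out += 2
        else:
            out_m[n_out] = mi
            out_g[n_out] = gi
            n_out += 1
    return n_out, P_d, outflow


@numba.njit(cache=False)
def _infection_walk(offsets, cand_host, accepted, u_sel, alive, inf_host):
    """Resolve candidate infections sequentially over the shuffled viruses.

    For candidate virus c, its accepted hosts still alive form the success
    set; one of them, chosen uniformly (``u_sel``), is lysed and removed.
    ``inf_host[c]`` is set to the lysed host index, or -1 for no infection.
    """
    n_c = offsets.size - 1
    for c in range(n_c):
        lo = offsets[c]
        hi = offsets[c + 1]
        navail = 0
        for q in range(lo, hi):
            if accepted[q] and alive[cand_host[q]]:
                navail += 1
        if navail == 0:
            inf_host[c] = -1
            continue
        target = int(u_sel[c] * navail)
        if target >= navail:
            target = navail - 1
        seen = 0
        for q in range(lo, hi):
            j = cand_host[q]
            if accepted[q] and alive[j]:
                if seen == target:
                    alive[j] = False
                    inf_host[c] = j
                    break
                seen += 1
    return inf_host


# --------------------------------------------------------------------------
# simulation operations

def init_simulation(nparams: NormalizedParams,
                    rng: np.random.Generator) -> ChemostatState:
    """Inoculate the vessel: N_h0 hosts with gene g_alpha0 and mass drawn
    Uniform[1/2, 1], N_v0 virions with genes (g_nu0, g_beta0); the dissolved
    pool starts at P_units minus the inoculated host biomass."""
    p = nparams
    m = rng.uniform(0.5, 1.0, p.N_h0)
    total_m = float(m.sum())
    P_d0 = p.P_units - total_m
    if P_d0 < 0:
        raise InvalidConfigError(
            f"initial host biomass {total_m:.3f} exceeds the total phosphorus "
            f"budget {p.P_units:.3f} host-equivalents")
    return ChemostatState(
        time=0,
        P_d=P_d0,
        P_d0=P_d0,
        host_m=m,
        host_g_alpha=np.full(p.N_h0, float(p.g_alpha0)),
        virus_g_nu=np.full(p.N_v0, float(p.g_nu0)),
        virus_g_beta=np.full(p.N_v0, float(p.g_beta0)),
    )


def nutrient_update(state: ChemostatState, nparams: NormalizedParams) -> ChemostatState:
    """Relax the dissolved pool toward its initial value at rate omega."""
    inflow = nparams.omega * (state.P_d0 - state.P_d)
    state.P_d += inflow
    state.cumulative_inflow += inflow
    return state


def host_round(state: ChemostatState, nparams: NormalizedParams,
               rng: np.random.Generator) -> ChemostatState:
    """One round of host dynamics (washout, death, metabolism, growth,
    division with mutation), processed in a fresh random order."""
    n = state.N_h
    if n == 0:
        return state
    p = nparams
    order = rng.permutation(n)
    u_wash = rng.random(n)
    u_death = rng.random(n)
    u_mut = rng.random(n)
    z_mut = rng.normal(0.0, p.sigma_h, n) if p.sigma_h > 0 else np.zeros(n)
    out_m = np.empty(2 * n)
    out_g = np.empty(2 * n)
    n_out, P_d, outflow = _host_round_kernel(
        state.host_m, state.host_g_alpha, order, u_wash, u_death, u_mut, z_mut,
        state.P_d, p.omega, p.delta_h, p.eps_h, p.mu_h, p.alpha_n, p.pi_h,
        out_m, out_g)
    state.host_m = out_m[:n_out].copy()
    state.host_g_alpha = out_g[:n_out].copy()
    state.P_d = float(P_d)
    state.cumulative_outflow += outflow
    return state


def _distinct_within_rows(counts, cand_host, offsets, n0, rng):
    """Make candidate host indices distinct within each virus's row.

    A Binomial(n0, p) success count corresponds to a uniformly random subset
    of that size, so multi-candidate viruses need distinct host slots; rows
    of size 1 (the common case) are already uniform."""
    for c in np.flatnonzero(counts > 1):
        lo, hi = offsets[c], offsets[c + 1]
        cand_host[lo:hi] = rng.choice(n0, size=hi - lo, replace=False)


def virus_round(state: ChemostatState, nparams: NormalizedParams,
                rng: np.random.Generator) -> ChemostatState:
    """One round of virus dynamics: washout/decay, then per-pair infection
    attempts against the surviving hosts; progeny join after the round."""
    p = nparams
    nv = state.N_v
    if nv == 0:
        return state

    # washout (prob omega) then decay (prob delta_v), one uniform per virion
    u = rng.random(nv)
    removal = p.omega + (1.0 - p.omega) * p.delta_v
    surv_idx = np.flatnonzero(u >= removal)
    # survivors are processed in a fresh random order
    surv = surv_idx[rng.permutation(surv_idx.size)]
    g_nu = state.virus_g_nu[surv]
    g_beta = state.virus_g_beta[surv]

    n0 = state.N_h
    if n0 == 0 or surv.size == 0:
        state.virus_g_nu = np.ascontiguousarray(g_nu)
        state.virus_g_beta = np.ascontiguousarray(g_beta)
        return state

    eps = p.gene_floor_eps
    denom = np.maximum(g_nu, eps)

    # per-virus virulence factor (host-independent)
    if p.virulence_mode == "tradeoff":
        v_factor = np.minimum(1.0, p.beta_n * g_beta / denom)
    else:  # random: per-pair Bernoulli(U) == Bernoulli(1/2)
        v_factor = np.full(surv.size, 0.5)

    ga = state.host_g_alpha
    if p.compatibility_mode == "tradeoff":
        # upper bound on compatibility via nearest host gene (round-start pool)
        hs = np.sort(ga)
        pos = np.searchsorted(hs, g_beta)
        d_lo = np.where(pos > 0, np.abs(g_beta - hs[np.maximum(pos - 1, 0)]), np.inf)
        d_hi = np.where(pos < n0, np.abs(hs[np.minimum(pos, n0 - 1)] - g_beta), np.inf)
        dmin = np.minimum(d_lo, d_hi)
        c_max = np.exp(-dmin / denom)
    else:
        c_max = np.full(surv.size, 0.5)

    p_max = v_factor * c_max
    k = rng.binomial(n0, p_max)
    cand = np.flatnonzero(k > 0)

    inf_virus_rows = np.empty(0, dtype=np.int64)
    inf_hosts = np.empty(0, dtype=np.int64)
    if cand.size:
        counts = k[cand]
        offsets = np.concatenate(([0], np.cumsum(counts)))
        K = int(offsets[-1])
        cand_host = rng.integers(0, n0, K)
        _distinct_within_rows(counts, cand_host, offsets, n0, rng)

        if p.compatibility_mode == "tradeoff":
            gb_rep = np.repeat(g_beta[cand], counts)
            dn_rep = np.repeat(denom[cand], counts)
            cmax_rep = np.repeat(c_max[cand], counts)
            c_pair = np.exp(-np.abs(ga[cand_host] - gb_rep) / dn_rep)
            accepted = rng.random(K) < c_pair / cmax_rep
        else:
            accepted = np.ones(K, dtype=bool)  # c == c_max == 1/2 exactly

        u_sel = rng.random(cand.size)
        alive = np.ones(n0, dtype=bool)
        inf_host = np.empty(cand.size, dtype=np.int64)
        _infection_walk(offsets.astype(np.int64), cand_host.astype(np.int64),
                        accepted, u_sel, alive, inf_host)
        hit = inf_host >= 0
        inf_virus_rows = cand[hit]
        inf_hosts = inf_host[hit]

    # lysed hosts: biomass recycled into the dissolved pool
    if inf_hosts.size:
        state.P_d += float(state.host_m[inf_hosts].sum())
        keep_hosts = np.ones(n0, dtype=bool)
        keep_hosts[inf_hosts] = False
        state.host_m = state.host_m[keep_hosts]
        state.host_g_alpha = state.host_g_alpha[keep_hosts]

    # burst: kappa progeny per infection, joining after the round
    n_inf = inf_virus_rows.size
    n_prog = n_inf * p.kappa
    if n_prog:
        prog_nu = np.repeat(g_nu[inf_virus_rows], p.kappa)
        prog_beta = np.repeat(g_beta[inf_virus_rows], p.kappa)
        mutate = rng.random(n_prog) < p.pi_v
        n_mut = int(mutate.sum())
        if n_mut:
            prog_nu[mutate] = np.clip(
                prog_nu[mutate] + rng.normal(0.0, p.sigma_v, n_mut), 0.0, 1.0)
            prog_beta[mutate] = np.clip(
                prog_beta[mutate] + rng.normal(0.0, p.sigma_v, n_mut), 0.0, 1.0)
    else:
        prog_nu = np.empty(0)
        prog_beta = np.empty(0)

    if n_inf:
        keep = np.ones(surv.size, dtype=bool)
        keep[inf_virus_rows] = False
        g_nu = g_nu[keep]
        g_beta = g_beta[keep]
    state.virus_g_nu = np.concatenate((g_nu, prog_nu))
    state.virus_g_beta = np.concatenate((g_beta, prog_beta))
    return state


def step(state: ChemostatState, nparams: NormalizedParams,
         rng: np.random.Generator) -> ChemostatState:
    """Advance the chemostat by one hour."""
    nutrient_update(state, nparams)
    host_round(state, nparams, rng)
    virus_round(state, nparams, rng)
    state.time += 1
    return state


# --------------------------------------------------------------------------
# trajectory recording

@dataclass
class Trajectory:
    """Per-step record of one run.

    Abundance and nutrient series have ``T + 1`` entries (including t = 0).
    Gene distributions are stored as per-step histograms over ``n_bins``
    equal-width bins on [0, 1] (sufficient for binned Shannon diversity);
    raw per-individual gene samples can be kept at selected ``snapshots``.
    """

    params: SimulationParams
    seed: int
    n_bins: int
    time: np.ndarray
    N_h: np.ndarray
    N_v: np.ndarray
    P_d: np.ndarray
    host_mass: np.ndarray
    mean_g_alpha: np.ndarray
    mean_g_nu: np.ndarray
    mean_g_beta: np.ndarray
    hist_g_alpha: np.ndarray
    hist_g_nu: np.ndarray
    hist_g_beta: np.ndarray
    snapshots: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.time.size

    def to_dataframe(self):
        """Tidy per-step table: {seed, t, N_h, N_v, P_d, mean genes}."""
        import pandas as pd
        return pd.DataFrame({
            "seed": np.full(self.time.size, self.seed, dtype=np.int64),
            "t": self.time,
            "N_h": self.N_h,
            "N_v": self.N_v,
            "P_d": self.P_d,
            "mean_g_alpha": self.mean_g_alpha,
            "mean_g_nu": self.mean_g_nu,
            "mean_g_beta": self.mean_g_beta,
        })


def _mean_or_nan(x: np.ndarray) -> float:
    return float(x.mean()) if x.size else np.nan


def run(params: SimulationParams, seed: int, *, n_bins: int = 50,
        snapshot_times: tuple = ()) -> Trajectory:
    """Run one full simulation of ``params.T`` hourly steps.

    ``seed`` feeds a single PCG64 generator that supplies every stochastic
    draw of the run; identical (params, seed) give identical trajectories.
    """
    nparams = normalize(params)
    rng = np.random.default_rng(seed)
    state = init_simulation(nparams, rng)

    T = params.T
    n_rec = T + 1
    time = np.arange(n_rec, dtype=np.int64)
    N_h = np.empty(n_rec, dtype=np.int64)
    N_v = np.empty(n_rec, dtype=np.int64)
    P_d = np.empty(n_rec)
    host_mass = np.empty(n_rec)
    mga = np.empty(n_rec)
    mgn = np.empty(n_rec)
    mgb = np.empty(n_rec)
    h_ga = np.zeros((n_rec, n_bins), dtype=np.int64)
    h_gn = np.zeros((n_rec, n_bins), dtype=np.int64)
    h_gb = np.zeros((n_rec, n_bins), dtype=np.int64)
    snapshots: dict = {}
    snap = set(int(t) for t in snapshot_times)

    def record(i: int) -> None:
        N_h[i] = state.N_h
        N_v[i] = state.N_v
        P_d[i] = state.P_d
        host_mass[i] = state.host_m.sum()
        mga[i] = _mean_or_nan(state.host_g_alpha)
        mgn[i] = _mean_or_nan(state.virus_g_nu)
        mgb[i] = _mean_or_nan(state.virus_g_beta)
        h_ga[i] = np.histogram(state.host_g_alpha, bins=n_bins, range=(0.0, 1.0))[0]
        h_gn[i] = np.histogram(state.virus_g_nu, bins=n_bins, range=(0.0, 1.0))[0]
        h_gb[i] = np.histogram(state.virus_g_beta, bins=n_bins, range=(0.0, 1.0))[0]
        if i in snap:
            snapshots[i] = {
                "g_alpha": state.host_g_alpha.copy(),
                "g_nu": state.virus_g_nu.copy(),
                "g_beta": state.virus_g_beta.copy(),
                "m": state.host_m.copy(),
            }

    record(0)
    for t in range(1, T + 1):
        step(state, nparams, rng)
        record(t)

    return Trajectory(params=params, seed=int(seed) if np.isscalar(seed) else -1,
                      n_bins=n_bins, time=time, N_h=N_h, N_v=N_v, P_d=P_d,
                      host_mass=host_mass, mean_g_alpha=mga, mean_g_nu=mgn,
                      mean_g_beta=mgb, hist_g_alpha=h_ga, hist_g_nu=h_gn,
                      hist_g_beta=h_gb, snapshots=snapshots)
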