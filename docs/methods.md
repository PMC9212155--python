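# Methods

## Model and assumptions

The simulator is a discrete-time (1 h steps), well-mixed, individual-based
model of lytic phage–bacteria coevolution in a chemostat limited by a single
elemental resource, phosphorus. All phosphorus bookkeeping is done in
host-equivalent units: one unit equals the maximum phosphorus content of one
cell (P_h), so the total budget is `P_units = P·V/P_h` and the per-volume
rate constants are `alpha_n = alpha/V`, `beta_n = beta/V`. At the default
1 μL volume and 71 μmol-P/L this gives 855.4 host-equivalents, which is why
host plateaus sit near 1,000–1,300 cells/μL (each cell carries mass in
(0.5, 1]). Note that the literal algebra "P/(P_h·V)" sometimes quoted for
this normalization is dimensionally inconsistent; `P·V/P_h` is the quantity
with the intended meaning (total μmol in the vessel over μmol per cell).

Assumptions worth keeping in mind:

- rates in h⁻¹ are used directly as per-step probabilities (valid only for
  1 h steps; configurations with any other step size are rejected, not
  rescaled);
- viruses are massless in the phosphorus budget — lysed host biomass is
  recycled instantly to the dissolved pool, so a closed system conserves
  `P_d + Σm` exactly;
- no spatial structure, no lysogeny, no multiple infection; a virus infects
  at most one host per step and is consumed by the infection;
- washed-out host biomass leaves the budget (tracked in a cumulative
  outflow ledger); death and lysis recycle biomass.

## Infection kernels

Trait-based compatibility `C_t = exp(-|g_alpha - g_beta|/g_nu)` and
virulence `V_t = min(1, beta_n·g_beta/g_nu)` put the host-range gene in the
denominator of both: broad host range raises compatibility and lowers
per-infection virulence. Orientation follows the monotonicity the model's
phenomenology requires (compatibility increasing, virulence decreasing in
g_nu). `V_t` is clamped to 1 so it remains a probability; `g_nu` is floored
at `gene_floor_eps` (default 1e-9) in both denominators, chosen so that the
identical-genotype limit `C_t = 1` is preserved exactly while `g_nu -> 0`
yields vanishing compatibility for any gene mismatch. The random kernels
draw a fresh Uniform(0,1) per encounter; because a Bernoulli trial whose
success probability is itself U(0,1) is marginally Bernoulli(1/2), the
engine treats random kernels as exact per-pair factors of 1/2.

## Exact sparse virus round

The defining per-pair algorithm — each virion scans surviving hosts in
random order and lyses the first per-pair success — is quadratic in
population sizes if done literally (10⁵ virions × 10³ hosts). The engine
uses an equivalent-in-distribution sparse form:

1. scanning in random order and stopping at the first success selects a
   uniformly random member of the per-pair Bernoulli success set;
2. the success set itself is sampled by drawing, per virion, a candidate
   count `k ~ Binomial(n, p_max)` with `p_max = V_i · C_max,i` an upper
   bound over the round-start host pool (`C_max` from the nearest host gene
   by binary search), then thinning each candidate by `p_ij / p_max`;
3. candidates referring to hosts already lysed earlier in the round are
   discarded, which restricts the Bernoulli field to the hosts actually
   alive at that virion's turn (the bound stays valid because the
   round-start pool is a superset).

Washout/decay are collapsed into one uniform draw per virion
(`u < omega` → washout, else `u < omega + (1-omega)·delta_v` → decay),
exactly equivalent to two sequential Bernoullis. The two sequential inner
loops (host round; infection walk) are numba-compiled with all random
numbers pre-drawn from the single per-run PCG64 generator, so a
(parameters, seed) pair yields a bit-identical trajectory.

## Parameters

Defaults are the standard scenario of the study system: T = 36 h (720 h for
long-term runs), V = 1 μL, P = 71 μmol-P/L, omega = 0.2/h (0 for closed
systems), 46 hosts and 810 virions (VHR 17.6), alpha = 1.6e-7 L/h,
mu_h = 0.738/h, delta_h = eps_h = delta_v = 0.014/h, beta = 6.2e-11 L/h,
kappa = 10, all initial genes at 0.1, host mutation (pi_h, sigma_h) =
(0.06, 0.05), virus mutation (pi_v, sigma_v) = (0.006, 0.005). Mutations
are Gaussian perturbations clamped to [0, 1]; clamping (rather than
reflection or resampling) is a deliberate, documented choice and matters
only for mutation scales approaching the interval width. Both daughters of
a division share a single mutation draw; each progeny virion mutates
independently, with both virus genes redrawn jointly on a mutation event.

Sweep grids default to brackets around the standard values (VHR
{1.76, 8.8, 17.6, 88, 176}; P multipliers {0.5, 1, 5, 10, 20}; omega
{0…0.4}; mutation factors {0.01, 0.1, 1, 10}); all are overridable.

## Ensembles, seeds, problem sizes

Replicate r of an ensemble uses `SeedSequence((master_seed, r))`, so any
replicate can be re-run in isolation and sweep grid points are independent
of execution order (each grid point reuses the master seed — common random
numbers). Ensemble mean/sd are per-step population statistics across
replicates.

The packaged experiments run at desk scale: 30 replicates for the 36 h
sweeps and mutation scenarios, 20 replicates × 720 h for the factorial
(closed/open × kernel modes), 10 replicates for the long-term diversity
series; these sizes give ensemble means stable to a few percent for the
short-horizon quantities while keeping a full reproduction in the
few-minutes range on one core.

## Trait diversity

Shannon entropy (natural log) of a gene's distribution over `n_bins = 50`
equal-width bins on [0, 1]. Trajectories record per-step histograms at the
run's bin count — binned entropy from counts is identical to entropy of the
raw values at the same binning, so nothing is lost while avoiding storing
~10⁵ virus genes per step over 720 steps; raw samples can be retained at
chosen times via `run(snapshot_times=...)`. Entropies are comparable only
at a fixed bin count. Empty populations yield NaN (undefined), never 0
(monomorphic).

## Numerical and degenerate-input choices

- Growth uptake is capped at the currently available `P_d`, processed
  sequentially in the shuffled host order, so the pool cannot go negative.
- Division threshold is strict (`m > 1`); since `mu_h <= 1`, a host divides
  at most once per step and daughter masses stay in (0, 1].
- The initial inoculum is rejected if its biomass exceeds the phosphorus
  budget (negative initial `P_d`).
- `classify_outcome` compares ensemble-mean final abundances against an
  absolute threshold of one individual: both above → coexistence, hosts
  only → host_only, anything else → double_extinction (a host-free vessel
  with straggling, strictly decaying virions is a collapse in progress).
- The "recovery peak" of a host series is located as: global bloom maximum,
  then the minimum after it (the crash trough), then the maximum after the
  trough; a series that never recovers reports its final value.

## What the simulator does and does not emulate

The generator reproduces the study conditions themselves (the model *is*
the object of study; no external data are consumed). Against real
plate-reader infection experiments it shares the qualitative infection
cycle — bloom, virus-driven crash, resistance-mediated recovery, faster
cycles at higher VHR — but not absolute scales: OD600 is only a proxy for
abundance, all simulated virions are infectious whereas a fraction of real
lysate is not, and the wet system is a closed microplate well rather than a
chemostat. The CSV reader for such experiments deliberately performs no
unit conversion.

Known limitations: outcomes under *random* kernels are sensitive to the
per-pair encounter structure. With 810 virions scanning every host at
per-pair success ~0.25–0.5, the initial host population is eliminated in
the first step, so all random-virulence cells and the open
random-compatibility cell collapse; trait-based kernels (per-pair success
~6e-5 initially) are the regime the model is designed for. Long-horizon
open systems wash the phage population out entirely well before 720 h, so
30-day "coexistence" in an open vessel is not reachable under the default
washout rate.
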