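# phagehost

An individual-based (agent-based) simulator of lytic bacteriophage–bacteria
coevolution in a phosphorus-limited chemostat, built for studying how
trade-offs between competitive host traits and defensive/offensive virus
traits shape population dynamics and long-term coexistence.

It is aimed at microbial ecologists and modellers who want a small,
reproducible in-silico system for questions such as: when does a phage
population persist alongside its evolving host; how do virus-to-host ratio
(VHR), nutrient load and dilution rate change the infection cycle; and what
do random (trait-blind) infection rules do to long-term fates compared with
trait-based ones?

## The model

Every bacterium carries a nutrient-affinity gene g<sub>α</sub> ∈ [0, 1] and a
biomass m ∈ (0, 1], measured in "host-equivalent" phosphorus units (one unit
= the maximum phosphorus content P<sub>h</sub> of a cell). Every virion
carries a host-range ("memory") gene g<sub>ν</sub> and an adsorption gene
g<sub>β</sub>. The vessel holds dissolved phosphorus P<sub>d</sub>; the total
budget is P·V/P<sub>h</sub> host-equivalents (≈ 855 at defaults), and it is
exactly conserved when the system is closed.

Each one-hour step:

1. **Nutrient exchange** — P<sub>d</sub> ← P<sub>d</sub> + ω(P<sub>d0</sub> − P<sub>d</sub>),
   with dilution rate ω (h⁻¹).
2. **Host round** — each host, in random order: washout (prob ω); death
   (prob δ<sub>h</sub>, biomass recycled); metabolic loss ε<sub>h</sub>m;
   Monod growth Δm = μ<sub>h</sub>·αg<sub>α</sub>P<sub>d</sub>/(1 + αg<sub>α</sub>P<sub>d</sub>)
   drawn from the running nutrient pool; division at m > 1 into two daughters,
   whose shared genotype mutates with probability π<sub>h</sub> by a
   N(0, σ<sub>h</sub>²) perturbation clamped to [0, 1].
3. **Virus round** — each virion, in random order: washout (ω), decay
   (δ<sub>v</sub>), then a scan of the surviving hosts in random order. A
   virus–host pair leads to lysis with probability C·V, where the
   **compatibility** and **virulence** kernels are either trait-based,

   &nbsp;&nbsp;C<sub>t</sub> = exp(−|g<sub>α</sub> − g<sub>β</sub>| / g<sub>ν</sub>),&nbsp;&nbsp;
   V<sub>t</sub> = min(1, β·g<sub>β</sub> / g<sub>ν</sub>),

   or random (a fresh Uniform(0, 1) per encounter). A broad host range
   (large g<sub>ν</sub>) buys compatibility at the price of per-infection
   virulence — the competition–defense trade-off at the core of the model.
   Lysis removes host and virion, recycles the host biomass, and buffers κ
   progeny (genotype mutating with probability π<sub>v</sub>) that join the
   population after the round.

Defaults (1 μL vessel, 71 μmol-P/L, ω = 0.2/h, 46 hosts, 810 virions,
κ = 10, …) are the standard scenario; see
`phagehost.SimulationParams` for the full annotated set. Because the vessel
is 1 μL, abundances are per-μL values. The virus round is executed as an
exact sparse-sampling equivalent of the per-pair scan (see
`docs/methods.md`), which keeps 30-day runs with ~10⁵ virions tractable.

## Worked example

```bash
phagehost run --seed 1 --out traj.csv
```

writes a tidy per-hour table. Selected rows:

```
 t  N_h  N_v     P_d  mean_g_alpha
 0   46  810 820.545         0.100
 8 1291  606  18.016         0.100
18 1052 4736 105.316         0.122
28 1023 8838 125.880         0.204
36 1166 6107  69.160         0.244
```

Hosts bloom to ~1,300 cells/μL by hour 8, exhausting the dissolved pool
(P_d ≈ 18); the phage population, initially decaying, amplifies on the dense
host lawn and suppresses it (hour 18–28) while the mean host nutrient-affinity
gene climbs from 0.10 toward 0.24 — hosts evolving away from the phage
adsorption gene, trading growth for resistance — after which the host
population recovers.

The same machinery is available programmatically:

```python
from phagehost import SimulationParams, run_ensemble

summary = run_ensemble(SimulationParams(omega=0.0), n_reps=30, master_seed=1)
print(summary.mean_Nv.max())   # peak ensemble-mean virus abundance
```

Other CLI verbs: `ensemble`, `sweep` (any parameter, or the virtual
parameter `VHR`), `factorial` (closed/open × trait-based/random kernels over
30 days) and `entropy` (Shannon trait-diversity time series). All accept
`--config` (TOML, one key per parameter), `--seed` and `--out`.

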