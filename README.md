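# hexpassage

A stochastic lattice model of 2D cell culture for studying how **passaging**
(repeatedly growing a culture to near-confluence and splitting it into a
fresh flask) reshapes a cell line's proliferative character, and how that in
turn changes the outcome of **scratch (wound-healing) assays**.

Cells are agents on a hexagonal lattice with spacing Δ equal to one cell
diameter, at most one cell per site. Per time step τ, with N(t) the current
population, N(t) motility attempts are made (move to a uniformly chosen
nearest-neighbour site with probability P_m; moves into occupied or
off-lattice sites are aborted), then N(t) proliferation attempts (place a
daughter on a uniformly chosen neighbour site with per-cell probability
P_p; aborted the same way). Each cell's P_p is drawn initially from
N(μ_p, σ) clipped to [0, 1] and is inherited *exactly* by daughters. The
defaults P_m = 0.35, μ_p = 0.004, Δ = 24 μm, τ = 1/12 h give a cell
diffusivity D = P_m Δ²/(4τ) ≈ 600 μm²/h and growth rate λ = μ_p/τ ≈ 0.05 /h.

The passaging protocol seeds 15% of sites, grows to 85% confluence, samples
a 15%-of-sites subpopulation uniformly, applies stochastic damage
P_p ← max(P_p − max(ε, 0), 0) with ε ~ N(μ_ε, σ_ε), and reseeds — for 30
passages. The trade-off between initial heterogeneity (σ = 1e-4 vs 1e-3)
and damage (none / small / large) makes the population median P_p stay
flat, rise, fall, or rise-then-fall with passage number. The scratch assay
seeds an 80×68 field of view at 30%, vacates a centred 23-column (~550 μm)
strip, and tracks column-averaged density profiles ⟨C_i⟩ = (1/J) Σ_j C_{i,j},
ensemble-averaged over identically prepared realisations.

The package is for computational biologists and modellers who want to
reproduce, probe, or extend these in silico experiments: all stochastic
update rules are numba-accelerated, every run is bit-reproducible from a
seed, and both experiments are scriptable from Python or the command line.

## Worked example

```python
import numpy as np
import hexpassage as hp

# 1. Passage a heterogeneous cell line with large damage on a scaled lattice
records = hp.run_passaging_experiment(
    hp.PassagingProtocol(damage=hp.DamageModel.large(), n_passages=30),
    hp.ModelParameters.heterogeneous(),     # sigma = 1e-3
    hp.LatticeConfig(200, 174),
    seed=11,
)
med = np.array([r.pp_median for r in records])
print(f"median Pp: passage 0 {med[0]:.5f}, peak {med.max():.5f} "
      f"at passage {med.argmax()}, passage 30 {med[-1]:.5f}")

# 2. Scratch assay with the baseline Pp distribution
config = hp.ScratchConfig(n_realisations=20,
                          record_times_h=(0., 24., 48., 72., 96., 120.))
closure = hp.ensemble_closure_times(config, base_seed=5)
print(f"mean closure time {np.nanmean(closure):.1f} h "
      f"({np.isnan(closure).sum()} of {closure.size} not closed)")
```

prints

```
median Pp: passage 0 0.00439, peak 0.00599 at passage 12, passage 30 0.00508
mean closure time 80.8 h (0 of 20 not closed)
```

The first block shows the rise-then-fall signature of the heterogeneity vs
damage trade-off: selection amplifies fast-proliferating lineages (median
P_p climbs from 0.0044 to 0.0060), until the upper tail of the initial
distribution is exhausted and the per-passage damage (mean effective
decrement 1.083×10⁻⁴) takes over. The second block runs twenty independent
scratch assays and reports when the density inside the scratched columns
first reaches 90% of the density outside — a strict quantitative criterion
that is crossed a few hours after the wound already *looks* closed in
snapshots.

The same experiments are available from the shell:

```
hexpassage passage --preset heterogeneous --damage large --passages 30 \
    --lattice 200x174 --seed 11 --out runs/het_large --dump-pp
hexpassage scratch --pp-table runs/het_large/pp_values_p30.csv --reps 100 \
    --seed 5 --out runs/scratch_p30
hexpassage msd-check --seed 1
```

`passage` writes `passage_records.csv` (per-passage population size, growth
duration, and mean/sd/median/quartiles of P_p) plus optional per-passage
P_p tables that can seed a scratch assay; `scratch` writes
`density_profiles.csv` and a closure summary; `msd-check` verifies the
diffusivity calibration against the exact lattice value 604.8 μm²/h.

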