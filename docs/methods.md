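# Methods

## The model

`hexpassage` simulates a population of cells as an exclusion-process random
walk on an `I x J` hexagonal lattice with spacing `Δ` equal to one cell
diameter (default 24 μm). Site `(i, j)` (columns `1..I`, rows `1..J`) has
position

    x = (i − 1)Δ   (even rows),   x = (i − ½)Δ   (odd rows),
    y = √3 (j − 1) Δ / 2,

so every interior site has six nearest neighbours at distance `Δ`. Each site
holds at most one cell (volume exclusion). Each cell carries a heritable
per-step proliferation probability `Pp`; motility `Pm` is a single global
constant (assumption of the model: passaging affects proliferation, not
migration).

One time step of duration `τ` (default 1/12 h) performs, with `N(t)` the
population at the start of the step:

1. `N(t)` *motility attempts*: a cell is selected uniformly at random with
   replacement; with probability `Pm` a target is drawn uniformly from the
   six geometric directions; the move happens only if the target is inside
   the domain and vacant, otherwise the event is aborted.
2. `N(t)` *proliferation attempts*: same selection rule; with probability
   equal to the cell's own `Pp` a daughter site is drawn from the six
   directions; if in-domain and vacant, a daughter is placed there carrying
   the mother's `Pp` **bit-for-bit**.

Aborting off-domain targets realises zero-net-flux boundaries with the same
semantics as crowding. Directions are always drawn from all six geometric
directions (probability 1/6 each) and validity-checked afterwards, never from
a truncated in-domain list, so the per-direction probability is uniform
everywhere including boundaries. There is no death process, so `N(t)` never
decreases during a step.

Macroscopic calibration: a free agent performs an unbiased hexagonal walk
with diffusivity `D = Pm Δ² / (4τ)`; at the defaults `Pm = 0.35`, `Δ = 24 μm`,
`τ = 1/12 h` this is 604.8 μm²/h (≈600). The low-density per-capita growth
rate is `λ = μp/τ = 0.048 /h` (≈0.05) at `μp = 0.004`.

### Selection pool during the proliferation sweep

The number of proliferation attempts is fixed at `N(t)`, but each draw is
uniform over the population *at the moment of the draw*, so daughters born
earlier in the sweep are eligible — the natural reading of selection "with
replacement, one at a time", and standard random-sequential-update practice.
A `daughters_selectable=False` switch freezes the pool at the sweep start for
sensitivity checks; at the default parameters (`Pp ≈ 0.004`) the difference
is far below statistical resolution.

## Initial conditions and passaging

A culture cycle seeds `round(0.15·I·J)` cells on distinct uniformly chosen
sites, grows to 85% confluence (`N/(I·J) ≥ 0.85`, checked after each
completed step), then splits: `round(0.15·I·J)` cells are sampled uniformly
*without replacement* (a physical cell transfers at most once), their `Pp`
values receive stochastic damage, and they are reseeded on an empty lattice.
Passage number counts the splits; "passage 0" is the first growth cycle from
fresh draws. Every record is taken at the moment 85% confluence is reached.

Initial `Pp` values are i.i.d. `N(μp, σ)` draws clipped to `[0, 1]`
(`Pp` is a probability; at `μp = 0.004, σ = 1e-3` a negative draw occurs with
probability ≈3×10⁻⁵ per cell, so clipping matters at scale). `σ` is a
*standard deviation*: 1e-4 defines the near-homogeneous prototype line,
1e-3 the heterogeneous one.

Damage: per transferred cell and per passage an independent
`ε ~ N(μ_ε, σ_ε)` is drawn and clipped to `max(ε, 0)` — damage never
increases `Pp` — and subtracted, flooring at 0. Presets: none (`ε ≡ 0`),
small (`μ_ε = σ_ε = 2e-5`), large (`μ_ε = σ_ε = 1e-4`). The mean effective
decrement has the closed form `μΦ(μ/σ) + σφ(μ/σ)` (1.083e-4 per passage for
the large preset), used as a test oracle. Damage is applied to the selected
subpopulation at split time; since selection is blind to `Pp` this is
equivalent to damaging before selection.

The qualitative outcome is a competition: inheritance plus growth
preferentially amplifies high-`Pp` lineages (a lineage with probability `p`
amplifies roughly like `e^{c·p}` per cycle, where `c ≈ ln(0.85/0.15)/p̄`),
while damage shifts every cell down by ~`E[max(ε,0)]` per split. For the
near-homogeneous line selection is negligible (`c σ²` is tiny), so damage
sets the trend; for the heterogeneous line selection initially wins, and
under large damage the median rises and then falls once the upper tail of
the initial `Pp` distribution is exhausted.

### Finite-size effect on the peak passage

The passage at which the heterogeneous/large-damage median peaks depends on
the *population size*, not only on the density fractions: the selection gain
per passage stalls when the tilted distribution reaches the sample maximum
of the initial draws, which grows like `σ√(2 ln N₀)`. Desk-scale lattices
(10⁴–10⁵ cells at split) therefore peak several passages earlier than a
flask-scale population (2.26 million cells at split). The trend *direction*
(rise then fall) is scale-invariant and is what the qualitative tests
assert; the peak location reported by the acceptance script is computed at
the 300×260 desk scale (three averaged replicates) and sits near passage
11–13 there, whereas an independent mean-field branching oracle places the
flask-scale peak near 16–17. This finite-size behaviour is a property of the
protocol itself, not of the implementation.

## Scratch assay

The assay runs on a small field-of-view lattice (default 80 columns × 68
rows ≈ 1900 μm × 1400 μm): every site is independently occupied with
probability 0.30, `Pp` is assigned per cell (clipped-normal draws, or uniform
resampling with replacement from an empirical `Pp` table dumped by a
passaging run — resampling preserves skewness that refitting a normal would
destroy), and all cells in 23 contiguous columns (≈550 μm; centred by
default, first column `⌊(I−w)/2⌋+1 = 29`) are removed at `t = 0`.

The spatial summary is the column-averaged density
`⟨C_i⟩ = (1/J) Σ_j C_{i,j}`, recorded at 0, 24, 48, 72 h (plus an optional
fine cadence, default hourly, for closure timing), and ensemble-averaged
over `n_realisations` independent realisations (default 100) with RNG
streams derived from `(base_seed, realisation_index)`.

Closure is operationalised as the first recorded time at which the mean
density inside the originally scratched columns reaches `threshold` (default
0.9) times the mean density outside them; a NaN sentinel marks realisations
that never close within the recorded horizon. At the baseline parameters
(`Pp ~ N(0.004, 1e-4)`) both the lattice model and the mean-field
Fisher–KPP PDE (`∂C/∂t = D∇²C + λC(1−C)` with the calibrated `D` and `λ`)
put the inside/outside ratio at ≈0.84–0.86 at 72 h and cross 0.9 near 80 h:
under this strict criterion the measured mean closure time is ≈80 h, later
than the 48–72 h window suggested by visual inspection of snapshots, which
judges a wound "closed" well before the density deficit fully equilibrates.
The closure-time routine therefore records hourly out to 120 h by default in
the acceptance script so the statistic always exists.

## Numerical and design choices

- **RNG.** One `numpy.random.Generator` (PCG64) per realisation drives every
  stochastic choice — placement, selection, Bernoulli trials, directions,
  damage draws. The generator object is passed directly into the
  numba-compiled sweep kernels, so runs are bit-reproducible given a seed and
  independent states can be interleaved. Ensemble members use
  `SeedSequence([base_seed, index])` streams.
- **Kernels.** The per-step sweeps are `numba.njit`-compiled loops over flat
  occupancy/`Pp` arrays plus a live-cell index list; a move updates the
  cell's entry in place, a birth appends. This keeps one attempt at ~0.1 μs,
  making 30-passage desk-scale experiments take minutes on one core.
- **Confluence target.** `N ≥ ⌈fraction·I·J⌉` checked after each completed
  step; `grow_to_confluence` raises a non-convergence error naming the
  density reached if a step cap (default 200 000) is hit, e.g. when `Pp ≡ 0`.
- **Quartiles and spread.** Passage records use numpy's default linear
  interpolation for quartiles and the population convention (`ddof=0`) for
  the standard deviation; a constant `Pp` list reports exactly `sd = 0`
  (guarding the degenerate σ = 0 control against float summation noise).
  Histograms use fixed bins (60 bins over `[0, 0.012]`).
- **Column coordinates.** A column's density is plotted at the mean `x` of
  its sites, `(i − ¾)Δ` (odd rows sit `Δ/2` right of even rows).
- **Lattice sizes.** The flask-scale lattice `I = 4168, J = 3610`
  (~15 M sites, 10 cm × 7.5 cm) is accepted as a configuration default and
  fully supported (a flask passage runs in hours, not seconds). Tests and
  the acceptance script use proportionally scaled lattices (100×87 to
  300×260) with the same 15%/85% fractions; the trend-direction results are
  scale-invariant, with the peak-passage caveat described above. Problem
  sizes used: trends at 100×87, logistic/growth checks at 200×174, peak
  passage at 300×260 (3 replicates) and 200×174 (2 replicates, test suite),
  scratch ensembles of 20–100 realisations on the 80×68 default.

## What the synthetic conditions do and do not show

The generator reproduces the study conditions themselves (random uniform
seeding, clipped-normal `Pp`, exact inheritance, uniform splits, clipped
normal damage); it does not emulate real-culture features such as cell
death, adhesion, age-structured or noisy inheritance, motility
heterogeneity, or trypsin chemistry. Passing tests therefore validate the
model's internal consistency and its stated calibrations (`D`, `λ`, exact
one-step distribution, logistic growth at low correlation), not biological
accuracy of any particular cell line.

## Known limitations

- The mean-field logistic ODE is only an upper-bound-style reference for
  lattice growth (spatial correlations slow the lattice slightly); the
  growth test uses a deliberately generous 15% tolerance.
- Single-realisation boxplot statistics at desk scale carry visible
  sampling noise in the far upper tail; replicate averaging is available
  and used where a location estimate (peak passage) is extracted.
- No mean-field PDE of the heterogeneous model is provided; the Fisher–KPP
  comparison above uses the homogeneous approximation.
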