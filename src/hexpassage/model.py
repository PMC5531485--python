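"""Stochastic hexagonal-lattice model of 2D cell culture, passaging and scratch assays.

The model is an exclusion-process random walk on a hexagonal lattice: each
agent (cell) occupies one site, attempts nearest-neighbour moves with a global
per-step probability ``Pm``, and attempts divisions with a heritable per-cell
per-step probability ``Pp``. Moves and daughter placements into occupied or
off-lattice sites are aborted, which realises both crowding and zero-net-flux
boundaries. Time advances in steps of duration ``tau``; during one step,
``N(t)`` motility attempts are made (agents selected uniformly with
replacement), then ``N(t)`` proliferation attempts.

On top of the lattice dynamics sit two experiment protocols:

* **Passaging** — seed 15% of sites, grow to 85% confluence, transfer a
  uniformly sampled 15%-of-sites subpopulation to a fresh lattice, apply a
  stochastic non-negative decrement ("damage") to each transferred cell's
  ``Pp``, repeat. The trade-off between initial ``Pp`` heterogeneity and
  damage drives the median ``Pp`` up, down, or up-then-down with passage
  number.
* **Scratch assay** — seed a small field of view at 30% per-site probability,
  vacate a vertical strip of columns, and track re-colonisation through
  column-averaged density profiles, optionally ensemble-averaged over many
  identically prepared realisations.

Default parameters describe a generic motile, proliferative cell line:
``Pm = 0.35``, ``Pp ~ N(0.004, sigma)`` with sigma 1e-4 (near-homogeneous) or
1e-3 (heterogeneous), ``delta = 24`` micrometres (one cell diameter) and
``tau = 1/12`` h, giving a free-agent diffusivity ``D = Pm*delta^2/(4*tau)``
of about 600 um^2/h and a low-density growth rate ``lambda = mu_p/tau`` of
about 0.05 /h.

All stochastic choices of a realisation flow from a single
``numpy.random.Generator``, which is also passed into the numba-compiled
update kernels, so runs are bit-reproducible given a seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from numba import njit

__all__ = [
    # geometry / core
    "LatticeConfig",
    "ModelParameters",
    "HexLatticeState",
    "site_position",
    "neighbours",
    "attempt_move",
    "attempt_proliferation",
    "step",
    "grow_to_confluence",
    "isolated_diffusivity",
    # passaging
    "DamageModel",
    "PassagingProtocol",
    "PassageRecord",
    "draw_initial_pp",
    "seed_random",
    "apply_damage",
    "passage_once",
    "summarise_pp",
    "run_passaging_experiment",
    # scratch assay
    "ScratchConfig",
    "DensityProfile",
    "ScratchEnsembleResult",
    "scratch_width_sites",
    "scratch_columns",
    "init_scratch_population",
    "make_scratch",
    "column_density",
    "run_scratch_ensemble",
    "ensemble_closure_times",
    "closure_time",
    "NOT_CLOSED",
    # reporting / io
    "ScenarioConfig",
    "load_config",
    "save_config",
    "render_snapshot",
    "export_boxplot_table",
    "export_density_profiles",
    "write_manifest",
    "ConfigError",
    "GeometryError",
    "NonConvergenceError",
    "realisation_rng",
]

logger = logging.getLogger("hexpassage")
logger.addHandler(logging.NullHandler())

#: Default step duration tau in hours.
DEFAULT_TAU = 1.0 / 12.0
#: Default motility probability per step.
DEFAULT_PM = 0.35
#: Default mean of the initial proliferation-probability distribution.
DEFAULT_MU_P = 0.004
#: Default lattice spacing (average cell diameter) in micrometres.
DEFAULT_DELTA = 24.0

SQRT3 = math.sqrt(3.0)


class ConfigError(ValueError):
    """Invalid or inconsistent scenario configuration."""


class GeometryError(ValueError):
    """Requested geometry (window, strip, site) lies outside the lattice."""


class NonConvergenceError(RuntimeError):
    """A growth phase failed to reach its target confluence within the step cap."""


def realisation_rng(base_seed: int, *stream: int) -> np.random.Generator:
    """Derive an independent Generator for a (base seed, stream indices) pair."""
    return np.random.default_rng(np.random.SeedSequence([int(base_seed), *map(int, stream)]))


# ---------------------------------------------------------------------------
# Hexagonal lattice geometry
# ---------------------------------------------------------------------------
#
# Sites are indexed (i, j) with column 1 <= i <= I and row 1 <= j <= J.
# Odd rows are shifted half a spacing to the right, rows are sqrt(3)/2 apart,
# so the six nearest neighbours of every interior site sit at distance delta.

# Neighbour offsets (di, dj), indexed by row parity of the 0-based row:
# parity 0 <=> 1-based odd row, parity 1 <=> 1-based even row.
_OFFSETS = np.array(
    [
        [[1, 0], [-1, 0], [0, 1], [0, -1], [1, 1], [1, -1]],
        [[1, 0], [-1, 0], [0, 1], [0, -1], [-1, 1], [-1, -1]],
    ],
    dtype=np.int64,
)


@dataclass(frozen=True)
class LatticeConfig:
    """Rectangular hexagonal lattice: ``I`` columns, ``J`` rows, spacing ``delta`` (um).

    ``I * J`` is the maximum population (100% confluence). Boundaries are
    zero-net-flux: any event targeting an off-lattice site is aborted.
    """

    I: int
    J: int
    delta: float = DEFAULT_DELTA

    def __post_init__(self) -> None:
        if self.I < 2 or self.J < 2:
            raise ConfigError(f"lattice must be at least 2x2, got {self.I}x{self.J}")
        if self.delta <= 0:
            raise ConfigError(f"lattice spacing must be positive, got {self.delta}")

    @property
    def n_sites(self) -> int:
        return self.I * self.J


def site_position(i, j, delta: float = DEFAULT_DELTA):
    """Physical position (x, y) in micrometres of site (i, j), 1-based indices.

    Even rows have x = (i-1)*delta, odd rows are shifted right by delta/2;
    rows are sqrt(3)*delta/2 apart. Accepts scalars or numpy arrays.
    """
    i = np.asarray(i)
    j = np.asarray(j)
    if np.any(i < 1) or np.any(j < 1):
        raise IndexError("site indices are 1-based and must be >= 1")
    x = np.where(j % 2 == 0, (i - 1.0) * delta, (i - 0.5) * delta)
    y = SQRT3 * (j - 1.0) * delta / 2.0
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


def neighbours(i: int, j: int, config: LatticeConfig) -> list[tuple[int, int]]:
    """In-domain subset of the six hexagonal neighbours of site (i, j)."""
    if not (1 <= i <= config.I and 1 <= j <= config.J):
        raise IndexError(f"site ({i}, {j}) outside {config.I}x{config.J} lattice")
    out = []
    for di, dj in _OFFSETS[(j - 1) & 1]:
        ti, tj = i + int(di), j + int(dj)
        if 1 <= ti <= config.I and 1 <= tj <= config.J:
            out.append((ti, tj))
    return out


# ---------------------------------------------------------------------------
# Model parameters and derived macroscopic rates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelParameters:
    """Agent parameters and the macroscopic rates they imply.

    ``pm`` is the global per-step motility probability; initial per-cell
    proliferation probabilities are drawn from N(``mu_p``, ``sigma``) clipped
    to [0, 1] and inherited exactly by daughters. The free-agent diffusivity
    is ``D = pm * delta^2 / (4 tau)`` and the low-density per-capita growth
    rate is ``lambda = mu_p / tau``.
    """

    pm: float = DEFAULT_PM
    mu_p: float = DEFAULT_MU_P
    sigma: float = 1e-4
    delta: float = DEFAULT_DELTA
    tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        if not (0.0 <= self.pm <= 1.0):
            raise ConfigError(f"pm must be a probability, got {self.pm}")
        if not (0.0 <= self.mu_p <= 1.0):
            raise ConfigError(f"mu_p must be a probability, got {self.mu_p}")
        if self.sigma < 0:
            raise ConfigError(f"sigma must be non-negative, got {self.sigma}")
        if self.tau <= 0 or self.delta <= 0:
            raise ConfigError("tau and delta must be positive")

    @property
    def derived_diffusivity(self) -> float:
        """Free-agent diffusivity D = pm * delta^2 / (4 tau), in um^2/h."""
        return self.pm * self.delta**2 / (4.0 * self.tau)

    @property
    def derived_growth_rate(self) -> float:
        """Low-density per-capita growth rate lambda = mu_p / tau, in /h."""
        return self.mu_p / self.tau

    @classmethod
    def near_homogeneous(cls, **kw) -> "ModelParameters":
        """Prototype population with almost constant Pp (sigma = 1e-4)."""
        return cls(sigma=1e-4, **kw)

    @classmethod
    def heterogeneous(cls, **kw) -> "ModelParameters":
        """Prototype population with distinctly variable Pp (sigma = 1e-3)."""
        return cls(sigma=1e-3, **kw)


# ---------------------------------------------------------------------------
# Lattice state and the numba update kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sweep(occ, pp, cells, n0, I, J, pm, daughters_selectable, rng):  # pragma: no cover
    """One full step: n0 motility attempts then n0 proliferation attempts.

    occ/pp are flat site arrays (site = (j-1)*I + (i-1)); cells[:n] holds the
    flat site of each live cell. Returns the new population size.
    """
    # motility sweep: population is constant, selection uniform over it
    for _ in range(n0):
        k = np.intp(rng.integers(0, n0))
        s = cells[k]
        if rng.random() >= pm:
            continue
        d = np.intp(rng.integers(0, 6))
        i = s % I
        j = s // I
        par = j & 1  # 0-based row parity; parity 0 is a 1-based odd row
        ti = i + _OFFSETS[par, d, 0]
        tj = j + _OFFSETS[par, d, 1]
        if ti < 0 or ti >= I or tj < 0 or tj >= J:
            continue  # off-lattice target: event aborted (no-flux boundary)
        t = tj * I + ti
        if occ[t] == 1:
            continue  # crowding: move aborted
        occ[t] = 1
        occ[s] = 0
        pp[t] = pp[s]
        pp[s] = np.nan
        cells[k] = t
    # proliferation sweep: n0 attempts; the selection pool optionally includes
    # daughters born earlier in this sweep
    n = n0
    for _ in range(n0):
        pool = n if daughters_selectable else n0
        k = np.intp(rng.integers(0, pool))
        s = cells[k]
        if rng.random() >= pp[s]:
            continue
        d = np.intp(rng.integers(0, 6))
        i = s % I
        j = s // I
        par = j & 1
        ti = i + _OFFSETS[par, d, 0]
        tj = j + _OFFSETS[par, d, 1]
        if ti < 0 or ti >= I or tj < 0 or tj >= J:
            continue
        t = tj * I + ti
        if occ[t] == 1:
            continue
        occ[t] = 1
        pp[t] = pp[s]  # daughter inherits the mother's Pp exactly
        cells[n] = t
        n += 1
    return n


@njit(cache=True)
def _grow(occ, pp, cells, n, I, J, pm, target_n, max_steps, daughters_selectable, rng):  # pragma: no cover
    steps = 0
    while n < target_n and steps < max_steps:
        n = _sweep(occ, pp, cells, n, I, J, pm, daughters_selectable, rng)
        steps += 1
    return n, steps


@njit(cache=True)
def _msd_total(n_walkers, n_steps, half, pm, rng):  # pragma: no cover
    """Total squared displacement (unit spacing) of isolated agents.

    Each walker runs through the full step kernel with Pp = 0 on an empty
    lattice of side 2*half+1, starting at the centre, so it can never reach
    the boundary while n_steps <= half.
    """
    I = 2 * half + 1
    J = 2 * half + 1
    occ = np.zeros(I * J, dtype=np.uint8)
    pp = np.zeros(I * J, dtype=np.float64)
    cells = np.zeros(1, dtype=np.int64)
    s0 = half * I + half
    x0 = s0 % I + 0.5 * ((s0 // I) % 2 == 0)  # parity 0 => 1-based odd row
    y0 = SQRT3 * (s0 // I) / 2.0
    total = 0.0
    for _ in range(n_walkers):
        occ[s0] = 1
        pp[s0] = 0.0
        cells[0] = s0
        n = 1
        for _ in range(n_steps):
            n = _sweep(occ, pp, cells, n, I, J, pm, True, rng)
        s = cells[0]
        occ[s] = 0
        x = s % I + 0.5 * ((s // I) % 2 == 0)
        y = SQRT3 * (s // I) / 2.0
        total += (x - x0) ** 2 + (y - y0) ** 2
    return total


class HexLatticeState:
    """Occupancy and per-cell proliferation probabilities on a hexagonal lattice.

    Invariants: at most one cell per site; every occupied site carries exactly
    one Pp value in [0, 1]; the population never shrinks during a step.
    """

    def __init__(
        self,
        config: LatticeConfig,
        pm: float = DEFAULT_PM,
        tau: float = DEFAULT_TAU,
        rng: np.random.Generator | None = None,
        seed: int | None = None,
        daughters_selectable: bool = True,
    ) -> None:
        if not (0.0 <= pm <= 1.0):
            raise ConfigError(f"pm must be a probability, got {pm}")
        if tau <= 0:
            raise ConfigError(f"tau must be positive, got {tau}")
        self.config = config
        self.pm = float(pm)
        self.tau = float(tau)
        self.t = 0.0
        self.passage = 0
        self.daughters_selectable = bool(daughters_selectable)
        self.rng_seed = seed
        self.rng = rng if rng is not None else np.random.default_rng(seed)
        n_sites = config.n_sites
        self._occ = np.zeros(n_sites, dtype=np.uint8)
        self._pp = np.full(n_sites, np.nan)
        self._cells = np.zeros(n_sites, dtype=np.int64)
        self._n = 0

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_cells(self) -> int:
        """Current population N(t)."""
        return self._n

    @property
    def confluence(self) -> float:
        """Occupied fraction N / (I*J)."""
        return self._n / self.config.n_sites

    @property
    def occupancy(self) -> np.ndarray:
        """Binary occupancy as a (J, I) array; element [j-1, i-1] is C_{i,j}."""
        return self._occ.reshape(self.config.J, self.config.I).copy()

    @property
    def pp_values(self) -> np.ndarray:
        """Pp of every live cell (one entry per cell, arbitrary stable order)."""
        return self._pp[self._cells[: self._n]].copy()

    def pp_at(self, i: int, j: int) -> float:
        s = self._flat(i, j)
        if self._occ[s] == 0:
            raise ValueError(f"site ({i}, {j}) is vacant")
        return float(self._pp[s])

    def is_occupied(self, i: int, j: int) -> bool:
        return bool(self._occ[self._flat(i, j)])

    def _flat(self, i: int, j: int) -> int:
        if not (1 <= i <= self.config.I and 1 <= j <= self.config.J):
            raise IndexError(f"site ({i}, {j}) outside {self.config.I}x{self.config.J} lattice")
        return (j - 1) * self.config.I + (i - 1)

    def _populate(self, sites: np.ndarray, pp: np.ndarray) -> None:
        """Place cells on flat site indices (internal; sites must be vacant)."""
        if np.any(self._occ[sites]):
            raise ValueError("attempt to place a cell on an occupied site")
        self._occ[sites] = 1
        self._pp[sites] = pp
        self._cells[self._n : self._n + sites.size] = sites
        self._n += sites.size

    def validate(self) -> None:
        """Assert the exclusion and bookkeeping invariants (used by tests)."""
        occ = self._occ
        cells = self._cells[: self._n]
        assert occ.max(initial=0) <= 1, "site occupancy exceeds 1"
        assert int(occ.sum()) == self._n, "cell count disagrees with occupancy"
        assert np.unique(cells).size == self._n, "duplicate cell bookkeeping entry"
        assert np.all(occ[cells] == 1), "cell list points at a vacant site"
        live = self._pp[cells]
        assert np.all(np.isfinite(live)), "occupied site without a Pp value"
        assert np.all((live >= 0) & (live <= 1)), "Pp outside [0, 1]"
        vacant = self._pp[occ == 0]
        assert np.all(np.isnan(vacant)), "vacant site carries a Pp value"


# ---------------------------------------------------------------------------
# Elementary update operations
# ---------------------------------------------------------------------------


def _draw_target(i: int, j: int, config: LatticeConfig, rng: np.random.Generator):
    """Draw one of the six geometric directions; return the target or None.

    Targets are always drawn from all six directions (probability 1/6 each)
    and validity-checked afterwards, so boundary sites keep the same
    per-direction probability as interior sites.
    """
    di, dj = _OFFSETS[(j - 1) & 1, int(rng.integers(0, 6))]
    ti, tj = i + int(di), j + int(dj)
    if 1 <= ti <= config.I and 1 <= tj <= config.J:
        return ti, tj
    return None


def attempt_move(state: HexLatticeState, site: tuple[int, int], rng: np.random.Generator | None = None) -> HexLatticeState:
    """One motility attempt for the cell at ``site`` (must be occupied).

    With probability ``pm`` a target direction is drawn uniformly from the six
    hexagonal directions; the move happens only if the target is in-domain and
    vacant, carrying the cell's Pp along. Population size is conserved.
    """
    rng = rng if rng is not None else state.rng
    i, j = site
    s = state._flat(i, j)
    if state._occ[s] == 0:
        raise ValueError(f"attempt_move on vacant site ({i}, {j})")
    if rng.random() >= state.pm:
        return state
    target = _draw_target(i, j, state.config, rng)
    if target is None:
        return state
    t = state._flat(*target)
    if state._occ[t] == 1:
        return state
    state._occ[t] = 1
    state._occ[s] = 0
    state._pp[t] = state._pp[s]
    state._pp[s] = np.nan
    k = int(np.nonzero(state._cells[: state._n] == s)[0][0])
    state._cells[k] = t
    return state


def attempt_proliferation(state: HexLatticeState, site: tuple[int, int], rng: np.random.Generator | None = None) -> HexLatticeState:
    """One proliferation attempt for the cell at ``site`` (must be occupied).

    With probability equal to the cell's own Pp a daughter site is drawn
    uniformly from the six directions; if in-domain and vacant, a daughter is
    placed there with exactly the mother's Pp. Otherwise nothing changes.
    """
    rng = rng if rng is not None else state.rng
    i, j = site
    s = state._flat(i, j)
    if state._occ[s] == 0:
        raise ValueError(f"attempt_proliferation on vacant site ({i}, {j})")
    if rng.random() >= state._pp[s]:
        return state
    target = _draw_target(i, j, state.config, rng)
    if target is None:
        return state
    t = state._flat(*target)
    if state._occ[t] == 1:
        return state
    state._occ[t] = 1
    state._pp[t] = state._pp[s]
    state._cells[state._n] = t
    state._n += 1
    return state


def step(state: HexLatticeState, rng: np.random.Generator | None = None) -> HexLatticeState:
    """Advance the state by one step of duration tau.

    Performs N(t) motility attempts then N(t) proliferation attempts, each on
    a cell selected uniformly with replacement (daughters born during the
    proliferation sweep join the selection pool unless the state was built
    with ``daughters_selectable=False``), then advances t by tau.
    """
    if state._n == 0:
        raise ValueError("cannot step an empty population")
    rng = rng if rng is not None else state.rng
    state._n = _sweep(
        state._occ,
        state._pp,
        state._cells,
        state._n,
        state.config.I,
        state.config.J,
        state.pm,
        state.daughters_selectable,
        rng,
    )
    state.t += state.tau
    return state


def grow_to_confluence(
    state: HexLatticeState,
    confluence_fraction: float,
    max_steps: int = 200_000,
) -> tuple[HexLatticeState, float]:
    """Step the state until N/(I*J) >= confluence_fraction.

    Returns the first such state and the elapsed simulated time in hours.
    Raises :class:`NonConvergenceError` (naming the density reached) if the
    target is not met within ``max_steps`` steps.
    """
    if not (0.0 < confluence_fraction <= 1.0):
        raise ConfigError(f"confluence fraction must be in (0, 1], got {confluence_fraction}")
    n_sites = state.config.n_sites
    target_n = int(math.ceil(confluence_fraction * n_sites - 1e-9))
    if state._n >= target_n:
        return state, 0.0
    if state._n == 0:
        raise ValueError("cannot grow an empty population")
    state._n, steps = _grow(
        state._occ,
        state._pp,
        state._cells,
        state._n,
        state.config.I,
        state.config.J,
        state.pm,
        target_n,
        max_steps,
        state.daughters_selectable,
        state.rng,
    )
    state.t += steps * state.tau
    if state._n < target_n:
        raise NonConvergenceError(
            f"density {state.confluence:.4f} after {steps} steps, "
            f"target {confluence_fraction} not reached"
        )
    return state, steps * state.tau


def isolated_diffusivity(
    n_walkers: int = 20_000,
    n_steps: int = 100,
    params: ModelParameters | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> float:
    """Estimate the free-agent diffusivity D = MSD/(4t) by simulation, in um^2/h.

    Runs ``n_walkers`` independent single-agent realisations of the full step
    kernel (proliferation disabled) and converts the mean squared displacement
    at ``t = n_steps * tau``. The exact lattice value is
    ``pm * delta^2 / (4 tau)``.
    """
    params = params if params is not None else ModelParameters()
    rng = rng if rng is not None else np.random.default_rng(seed)
    half = n_steps + 1  # walker can displace at most one site per step
    total = _msd_total(n_walkers, n_steps, half, params.pm, rng)
    msd = total / n_walkers * params.delta**2
    return msd / (4.0 * n_steps * params.tau)


# ---------------------------------------------------------------------------
# Passaging: seed -> grow -> split -> damage -> repeat
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DamageModel:
    """Per-passage stochastic decrement applied to each transferred cell's Pp.

    One independent epsilon ~ N(mu_eps, sigma_eps) is drawn per cell per
    passage; negative draws are set to zero before subtracting, so damage can
    never increase Pp, and the damaged Pp is floored at 0.
    """

    mu_eps: float = 0.0
    sigma_eps: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_eps < 0:
            raise ConfigError(f"sigma_eps must be non-negative, got {self.sigma_eps}")

    @classmethod
    def none(cls) -> "DamageModel":
        return cls(0.0, 0.0)

    @classmethod
    def small(cls) -> "DamageModel":
        return cls(2e-5, 2e-5)

    @classmethod
    def large(cls) -> "DamageModel":
        return cls(1e-4, 1e-4)

    @classmethod
    def from_preset(cls, name: str) -> "DamageModel":
        try:
            return {"none": cls.none, "small": cls.small, "large": cls.large}[name]()
        except KeyError:
            raise ConfigError(f"unknown damage preset {name!r}; expected none/small/large") from None

    @property
    def preset_name(self) -> str | None:
        for name in ("none", "small", "large"):
            if self == DamageModel.from_preset(name):
                return name
        return None

    def mean_effective_decrement(self) -> float:
        """E[max(eps, 0)] = mu*Phi(mu/sigma) + sigma*phi(mu/sigma), closed form."""
        if self.sigma_eps == 0:
            return max(self.mu_eps, 0.0)
        z = self.mu_eps / self.sigma_eps
        return self.mu_eps * _norm_cdf(z) + self.sigma_eps * _norm_pdf(z)


def _norm_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def _norm_pdf(z: float) -> float:
    return math.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class PassagingProtocol:
    """The culture-split cycle: seed at ``seed_fraction``, grow to
    ``confluence_fraction``, transfer a ``seed_fraction``-of-sites sample with
    ``damage`` applied, for ``n_passages`` splits."""

    seed_fraction: float = 0.15
    confluence_fraction: float = 0.85
    n_passages: int = 30
    damage: DamageModel = field(default_factory=DamageModel.none)
    max_steps_per_passage: int = 200_000

    def __post_init__(self) -> None:
        if not (0.0 < self.seed_fraction < self.confluence_fraction <= 1.0):
            raise ConfigError(
                "need 0 < seed_fraction < confluence_fraction <= 1, got "
                f"{self.seed_fraction} and {self.confluence_fraction}"
            )
        if self.n_passages < 0:
            raise ConfigError("n_passages must be >= 0")


#: Bin edges used for the fixed-bin Pp histograms in passage records.
PP_HISTOGRAM_EDGES = np.linspace(0.0, 0.012, 61)


@dataclass
class PassageRecord:
    """Summary of the whole-population Pp distribution at 85% confluence.

    ``pp_sd`` uses the population convention (ddof=0); quartiles use numpy's
    default linear interpolation.
    """

    passage_number: int
    n_cells: int
    duration_h: float
    pp_mean: float
    pp_sd: float
    pp_median: float
    pp_q1: float
    pp_q3: float
    pp_histogram: np.ndarray = field(repr=False)
    bin_edges: np.ndarray = field(repr=False)


def draw_initial_pp(n: int, mu_p: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. draws from N(mu_p, sigma) clipped to [0, 1]."""
    if n < 1:
        raise ValueError(f"need at least one draw, got n={n}")
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    return np.clip(rng.normal(mu_p, sigma, size=n), 0.0, 1.0)


def seed_random(
    config: LatticeConfig,
    fraction: float,
    rng: np.random.Generator,
    pp_values: np.ndarray | None = None,
    mu_p: float = DEFAULT_MU_P,
    sigma: float = 1e-4,
    pm: float = DEFAULT_PM,
    tau: float = DEFAULT_TAU,
    daughters_selectable: bool = True,
) -> HexLatticeState:
    """Occupy round(fraction * I * J) distinct sites chosen uniformly at random.

    Pp values are either carried over (``pp_values``, e.g. after a split) or
    freshly drawn from N(mu_p, sigma) clipped to [0, 1].
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"seed fraction must be in (0, 1], got {fraction}")
    n_seed = int(round(fraction * config.n_sites))
    if pp_values is not None:
        pp_values = np.asarray(pp_values, dtype=float)
        if pp_values.size != n_seed:
            raise ValueError(
                f"{pp_values.size} pp values supplied for {n_seed} seeded cells"
            )
    else:
        pp_values = draw_initial_pp(n_seed, mu_p, sigma, rng)
    state = HexLatticeState(config, pm=pm, tau=tau, rng=rng, daughters_selectable=daughters_selectable)
    sites = rng.choice(config.n_sites, size=n_seed, replace=False)
    state._populate(sites, pp_values)
    return state


def apply_damage(pp_values: np.ndarray, damage: DamageModel, rng: np.random.Generator) -> np.ndarray:
    """Subtract an independent clipped decrement max(eps, 0) from each Pp.

    eps ~ N(mu_eps, sigma_eps) per cell; the result is floored at 0 and the
    output order matches the input order.
    """
    pp_values = np.asarray(pp_values, dtype=float)
    if pp_values.size and (pp_values.min() < 0 or pp_values.max() > 1):
        raise ValueError("pp values must lie in [0, 1]")
    eps = rng.normal(damage.mu_eps, damage.sigma_eps, size=pp_values.size)
    np.maximum(eps, 0.0, out=eps)
    return np.maximum(pp_values - eps, 0.0)


def passage_once(
    state: HexLatticeState,
    protocol: PassagingProtocol,
    rng: np.random.Generator | None = None,
) -> HexLatticeState:
    """Split a confluent culture: sample, damage, reseed on an empty lattice.

    round(seed_fraction * I * J) cells are sampled uniformly without
    replacement (a physical cell transfers at most once); their Pp values pass
    through :func:`apply_damage`; the survivors are placed uniformly at random
    on an empty lattice. The passage counter increments by one.
    """
    rng = rng if rng is not None else state.rng
    n_keep = int(round(protocol.seed_fraction * state.config.n_sites))
    if state.confluence < protocol.confluence_fraction - 1e-12:
        raise ValueError(
            f"passage requested at {state.confluence:.3f} confluence, "
            f"below the {protocol.confluence_fraction} threshold"
        )
    if state._n < n_keep:
        raise ValueError(f"population {state._n} smaller than split size {n_keep}")
    idx = rng.choice(state._n, size=n_keep, replace=False)
    selected = state._pp[state._cells[idx]]
    damaged = apply_damage(selected, protocol.damage, rng)
    new = seed_random(
        state.config,
        protocol.seed_fraction,
        rng,
        pp_values=damaged,
        pm=state.pm,
        tau=state.tau,
        daughters_selectable=state.daughters_selectable,
    )
    new.t = state.t
    new.passage = state.passage + 1
    return new


def summarise_pp(values: Iterable[float], bin_edges: np.ndarray | None = None) -> dict:
    """Mean, sd (population, ddof=0), median, quartiles and a fixed-bin histogram."""
    values = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarise an empty Pp list")
    edges = PP_HISTOGRAM_EDGES if bin_edges is None else np.asarray(bin_edges, dtype=float)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    hist, _ = np.histogram(values, bins=edges)
    constant = values.min() == values.max()  # exact stats for a degenerate list
    return {
        "pp_mean": float(values[0]) if constant else float(values.mean()),
        "pp_sd": 0.0 if constant else float(values.std(ddof=0)),
        "pp_median": float(med),
        "pp_q1": float(q1),
        "pp_q3": float(q3),
        "pp_histogram": hist,
        "bin_edges": edges,
    }


def run_passaging_experiment(
    protocol: PassagingProtocol,
    model: ModelParameters,
    lattice: LatticeConfig,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    return_pp: bool = False,
):
    """Run passage 0 (fresh Pp draws) through passage ``n_passages``.

    Each :class:`PassageRecord` summarises the whole-population Pp
    distribution at the moment the culture reaches the confluence threshold.
    With ``return_pp=True`` also returns the full per-passage Pp arrays
    (e.g. to seed a scratch assay from a chosen passage).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    state = seed_random(
        lattice,
        protocol.seed_fraction,
        rng,
        mu_p=model.mu_p,
        sigma=model.sigma,
        pm=model.pm,
        tau=model.tau,
    )
    records: list[PassageRecord] = []
    pp_dumps: list[np.ndarray] = []
    for k in range(protocol.n_passages + 1):
        if k > 0:
            state = passage_once(state, protocol, rng)
        state, duration = grow_to_confluence(
            state, protocol.confluence_fraction, protocol.max_steps_per_passage
        )
        values = state.pp_values
        stats = summarise_pp(values)
        records.append(PassageRecord(passage_number=k, n_cells=state.n_cells, duration_h=duration, **stats))
        if return_pp:
            pp_dumps.append(values)
        logger.info(
            "passage %d: N=%d, %.1f h to confluence, median Pp=%.5g",
            k, state.n_cells, duration, stats["pp_median"],
        )
    if return_pp:
        return records, pp_dumps
    return records


# ---------------------------------------------------------------------------
# In silico scratch assay
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScratchConfig:
    """Geometry, seeding and ensemble settings for the in silico scratch assay.

    The default field of view is an 80-column x 68-row lattice (about
    1900 um x 1400 um at 24 um spacing), seeded with independent per-site
    probability 0.30 and scratched over 23 centred columns (about 550 um).
    Pp is drawn either from a clipped normal (``pp_normal = (mu, sigma)``) or
    by uniform resampling with replacement from an empirical table of Pp
    values (``pp_table``), e.g. the dump of a passaging run — resampling
    preserves the skewness that refitting a normal would destroy.
    """

    lattice: LatticeConfig = field(default_factory=lambda: LatticeConfig(80, 68, DEFAULT_DELTA))
    seed_probability: float = 0.30
    scratch_width_sites: int = 23
    scratch_position: int | None = None  # first removed column; None = centred
    record_times_h: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0)
    n_realisations: int = 100
    pm: float = DEFAULT_PM
    tau: float = DEFAULT_TAU
    pp_normal: tuple[float, float] | None = (DEFAULT_MU_P, 1e-4)
    pp_table: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.seed_probability <= 1.0):
            raise ConfigError(f"seed probability must be in [0, 1], got {self.seed_probability}")
        if not (0 <= self.scratch_width_sites < self.lattice.I):
            raise ConfigError(
                f"scratch width {self.scratch_width_sites} must be < I={self.lattice.I}"
            )
        times = np.asarray(self.record_times_h, dtype=float)
        if times.size == 0 or np.any(times < 0) or np.any(np.diff(times) <= 0):
            raise ConfigError("record times must be non-negative and strictly increasing")
        if (self.pp_normal is None) == (self.pp_table is None):
            raise ConfigError("exactly one of pp_normal and pp_table must be given")
        if self.pp_table is not None and np.asarray(self.pp_table).size == 0:
            raise ConfigError("empirical pp table is empty")
        if self.n_realisations < 1:
            raise ConfigError("need at least one realisation")


def scratch_width_sites(width_um: float, delta: float = DEFAULT_DELTA) -> int:
    """Number of whole columns spanning a scratch of the given physical width."""
    return int(round(width_um / delta))


def scratch_columns(config: ScratchConfig) -> tuple[int, int]:
    """First and last removed column (1-based, inclusive) of the scratch."""
    w = config.scratch_width_sites
    first = config.scratch_position
    if first is None:
        first = (config.lattice.I - w) // 2 + 1
    last = first + w - 1
    if w > 0 and not (1 <= first and last <= config.lattice.I):
        raise GeometryError(f"scratch columns {first}..{last} outside 1..{config.lattice.I}")
    return first, last


def init_scratch_population(config: ScratchConfig, rng: np.random.Generator) -> HexLatticeState:
    """Seed every site independently with probability ``seed_probability``.

    Pp per cell comes from the configured source: clipped-normal draws or
    uniform resampling with replacement from the empirical table.
    """
    lattice = config.lattice
    state = HexLatticeState(lattice, pm=config.pm, tau=config.tau, rng=rng)
    sites = np.flatnonzero(rng.random(lattice.n_sites) < config.seed_probability)
    if sites.size == 0:
        return state
    if config.pp_table is not None:
        table = np.asarray(config.pp_table, dtype=float)
        pp = rng.choice(table, size=sites.size, replace=True)
    else:
        mu, sigma = config.pp_normal
        pp = draw_initial_pp(sites.size, mu, sigma, rng)
    state._populate(sites, pp)
    return state


def make_scratch(state: HexLatticeState, width_sites: int, position: int | None = None) -> HexLatticeState:
    """Remove every cell in ``width_sites`` contiguous columns (the scratch).

    ``position`` is the first removed column (1-based); by default the strip
    is centred. Pp values of removed cells are discarded; other sites are
    untouched.
    """
    I = state.config.I
    if width_sites == 0:
        return state
    first = position if position is not None else (I - width_sites) // 2 + 1
    last = first + width_sites - 1
    if not (1 <= first and last <= I and width_sites >= 0):
        raise GeometryError(f"scratch columns {first}..{last} outside 1..{I}")
    cells = state._cells[: state._n]
    cols = cells % I + 1  # 1-based column of each cell
    doomed = (cols >= first) & (cols <= last)
    gone = cells[doomed]
    state._occ[gone] = 0
    state._pp[gone] = np.nan
    survivors = cells[~doomed]
    state._cells[: survivors.size] = survivors
    state._n = survivors.size
    return state


@dataclass
class DensityProfile:
    """Column-averaged occupancy <C_i> = (1/J) sum_j C_{i,j} at one time."""

    column_density: np.ndarray
    x_positions: np.ndarray
    time_h: float
    n_averaged: int = 1


def _column_x_positions(config: LatticeConfig) -> np.ndarray:
    # mean x over the rows of a column (odd rows sit delta/2 right of even rows)
    i = np.arange(1, config.I + 1, dtype=float)
    return (i - 0.75) * config.delta


def column_density(state: HexLatticeState) -> DensityProfile:
    """Per-column mean occupancy of a single state."""
    occ = state._occ.reshape(state.config.J, state.config.I)
    return DensityProfile(
        column_density=occ.mean(axis=0),
        x_positions=_column_x_positions(state.config),
        time_h=state.t,
        n_averaged=1,
    )


@dataclass
class ScratchEnsembleResult:
    """Ensemble-averaged (and optionally per-realisation) density profiles."""

    config: ScratchConfig
    record_times_h: np.ndarray
    mean_profiles: np.ndarray  # (n_times, I)
    sd_profiles: np.ndarray  # (n_times, I), sd across realisations
    x_positions: np.ndarray
    scratch_cols: tuple[int, int]
    n_realisations: int
    per_realisation: np.ndarray | None = None  # (R, n_times, I)

    def profile_at(self, time_h: float) -> DensityProfile:
        k = int(np.argmin(np.abs(self.record_times_h - time_h)))
        if not math.isclose(self.record_times_h[k], time_h, abs_tol=1e-9):
            raise KeyError(f"time {time_h} h was not recorded")
        return DensityProfile(
            column_density=self.mean_profiles[k],
            x_positions=self.x_positions,
            time_h=float(time_h),
            n_averaged=self.n_realisations,
        )


def _run_scratch_realisation(config: ScratchConfig, rng: np.random.Generator, times: np.ndarray) -> np.ndarray:
    """One realisation; returns column densities at each requested time."""
    state = init_scratch_population(config, rng)
    make_scratch(state, config.scratch_width_sites, config.scratch_position)
    out = np.empty((times.size, config.lattice.I))
    for k, t in enumerate(times):
        n_steps = int(round((t - state.t) / config.tau))
        for _ in range(n_steps):
            if state.n_cells == 0:
                state.t += config.tau
            else:
                step(state)
        out[k] = column_density(state).column_density
    return out


def run_scratch_ensemble(
    config: ScratchConfig,
    base_seed: int,
    keep_realisations: bool = False,
    record_times_h: Sequence[float] | None = None,
) -> ScratchEnsembleResult:
    """Run ``n_realisations`` identically prepared scratch assays and average.

    Realisation ``r`` uses an independent RNG stream derived from
    ``(base_seed, r)``; the returned mean profile is the pointwise average of
    the per-realisation column densities at each recorded time.
    """
    times = np.asarray(
        config.record_times_h if record_times_h is None else record_times_h, dtype=float
    )
    R = config.n_realisations
    profiles = np.empty((R, times.size, config.lattice.I))
    for r in range(R):
        rng = realisation_rng(base_seed, r)
        profiles[r] = _run_scratch_realisation(config, rng, times)
    return ScratchEnsembleResult(
        config=config,
        record_times_h=times,
        mean_profiles=profiles.mean(axis=0),
        sd_profiles=profiles.std(axis=0, ddof=0),
        x_positions=_column_x_positions(config.lattice),
        scratch_cols=scratch_columns(config),
        n_realisations=R,
        per_realisation=profiles if keep_realisations else None,
    )


#: Sentinel returned by :func:`closure_time` when the scratch never closes.
NOT_CLOSED = float("nan")


def closure_time(
    profiles: Sequence[DensityProfile] | Mapping[float, np.ndarray],
    scratch_cols: tuple[int, int],
    threshold: float = 0.9,
) -> float:
    """First recorded time at which the scratch counts as closed.

    Closed means: mean density over the originally scratched columns is at
    least ``threshold`` times the mean density over all other columns (and the
    outside density is positive). Returns :data:`NOT_CLOSED` (NaN) if no
    recorded profile satisfies the criterion.
    """
    if isinstance(profiles, Mapping):
        items = sorted((float(t), np.asarray(p)) for t, p in profiles.items())
    else:
        items = sorted((float(p.time_h), np.asarray(p.column_density)) for p in profiles)
    first, last = scratch_cols
    for t, prof in items:
        if not (1 <= first <= last <= prof.size):
            raise GeometryError(
                f"scratch columns {first}..{last} incompatible with a {prof.size}-column profile"
            )
        inside = prof[first - 1 : last]
        outside = np.concatenate([prof[: first - 1], prof[last:]])
        if outside.size == 0 or inside.size == 0:
            raise GeometryError("closure criterion needs columns on both sides of the comparison")
        out_mean = outside.mean()
        if out_mean > 0 and inside.mean() >= threshold * out_mean:
            return t
    return NOT_CLOSED


def ensemble_closure_times(
    config: ScratchConfig,
    base_seed: int,
    threshold: float = 0.9,
    record_every_h: float = 1.0,
) -> np.ndarray:
    """Per-realisation closure times under the relative-density criterion.

    Each realisation is recorded on a fine time grid (default hourly) up to
    the last configured record time; entries are NaN where a realisation never
    closes within that horizon.
    """
    t_max = max(config.record_times_h)
    times = np.arange(0.0, t_max + record_every_h / 2, record_every_h)
    result = run_scratch_ensemble(config, base_seed, keep_realisations=True, record_times_h=times)
    first, last = result.scratch_cols
    out = np.empty(config.n_realisations)
    for r in range(config.n_realisations):
        profs = [
            DensityProfile(result.per_realisation[r, k], result.x_positions, float(t))
            for k, t in enumerate(times)
        ]
        out[r] = closure_time(profs, (first, last), threshold)
    return out


# ---------------------------------------------------------------------------
# Reporting and I/O: scenario configs, snapshots, tables, manifests
# ---------------------------------------------------------------------------


@dataclass
class ScenarioConfig:
    """Flat, serialisable description of one experiment run.

    ``kind`` selects the experiment: ``passage``, ``scratch`` or
    ``msd-check``. Unknown keys in a config file are rejected; missing keys
    take the defaults below, which are the model's standard study conditions.
    """

    kind: str = "passage"
    # lattice
    I: int = 4168
    J: int = 3610
    delta: float = DEFAULT_DELTA
    # agent parameters
    pm: float = DEFAULT_PM
    mu_p: float = DEFAULT_MU_P
    sigma: float = 1e-4
    tau: float = DEFAULT_TAU
    # passaging protocol
    damage: str = "none"
    seed_fraction: float = 0.15
    confluence_fraction: float = 0.85
    n_passages: int = 30
    max_steps_per_passage: int = 200_000
    # scratch assay
    scratch_seed_probability: float = 0.30
    scratch_width_sites: int = 23
    scratch_position: int | None = None
    record_times_h: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0)
    n_realisations: int = 100
    pp_table_path: str | None = None
    # msd check
    msd_walkers: int = 20_000
    msd_steps: int = 100
    # bookkeeping
    seed: int = 0
    outdir: str = "hexpassage_out"
    fov_um: tuple[float, float] | None = None  # (width, height) of snapshot window

    def __post_init__(self) -> None:
        if self.kind not in ("passage", "scratch", "msd-check"):
            raise ConfigError(f"unknown experiment kind {self.kind!r}")
        self.record_times_h = tuple(float(t) for t in self.record_times_h)
        if self.fov_um is not None:
            self.fov_um = tuple(float(v) for v in self.fov_um)
        DamageModel.from_preset(self.damage)  # validate early

    # -- views onto the module-level parameter objects ---------------------

    def lattice_config(self) -> LatticeConfig:
        return LatticeConfig(self.I, self.J, self.delta)

    def model_parameters(self) -> ModelParameters:
        return ModelParameters(pm=self.pm, mu_p=self.mu_p, sigma=self.sigma, delta=self.delta, tau=self.tau)

    def protocol(self) -> PassagingProtocol:
        return PassagingProtocol(
            seed_fraction=self.seed_fraction,
            confluence_fraction=self.confluence_fraction,
            n_passages=self.n_passages,
            damage=DamageModel.from_preset(self.damage),
            max_steps_per_passage=self.max_steps_per_passage,
        )

    def scratch_config(self, pp_table: np.ndarray | None = None) -> ScratchConfig:
        if pp_table is None and self.pp_table_path is not None:
            pp_table = read_pp_table(self.pp_table_path)
        return ScratchConfig(
            lattice=LatticeConfig(self.I, self.J, self.delta),
            seed_probability=self.scratch_seed_probability,
            scratch_width_sites=self.scratch_width_sites,
            scratch_position=self.scratch_position,
            record_times_h=self.record_times_h,
            n_realisations=self.n_realisations,
            pm=self.pm,
            tau=self.tau,
            pp_normal=None if pp_table is not None else (self.mu_p, self.sigma),
            pp_table=pp_table,
        )

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out


def load_config(path: str | Path) -> ScenarioConfig:
    """Read a YAML scenario config, rejecting unknown keys and filling defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    known = {f.name for f in fields(ScenarioConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    return ScenarioConfig(**raw)


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario config as YAML (round-trips losslessly)."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def read_pp_table(path: str | Path) -> np.ndarray:
    """Read an empirical Pp table (CSV with a ``pp`` column, or one column)."""
    df = pd.read_csv(path)
    col = "pp" if "pp" in df.columns else df.columns[0]
    values = df[col].to_numpy(dtype=float)
    if values.size == 0:
        raise ConfigError(f"pp table {path} is empty")
    return values


def write_pp_table(values: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"pp": np.asarray(values, dtype=float)}).to_csv(path, index=False)


def render_snapshot(
    state: HexLatticeState,
    field_of_view_um: tuple[float, float, float, float] | None = None,
    colour_range: tuple[float, float] | None = None,
    path: str | Path | None = None,
    dpi: int = 150,
):
    """Raster snapshot of a rectangular window, cells coloured by Pp.

    ``field_of_view_um`` is (x0, x1, y0, y1); by default a centred square of
    side 2000 um, shrunk to the domain if the lattice is smaller. The colour
    scale is fixed by ``colour_range`` (pass the same range across snapshots
    to make them comparable); the range is printed on the colour bar. The
    raster is deterministic: identical state and arguments give identical
    bytes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    cfg = state.config
    x_max = (cfg.I - 0.5) * cfg.delta
    y_max = SQRT3 * (cfg.J - 1) * cfg.delta / 2.0
    if field_of_view_um is None:
        side = min(2000.0, x_max, y_max)
        x0 = (x_max - side) / 2.0
        y0 = (y_max - side) / 2.0
        field_of_view_um = (x0, x0 + side, y0, y0 + side)
    x0, x1, y0, y1 = field_of_view_um
    if not (0.0 <= x0 < x1 <= x_max + 1e-9 and 0.0 <= y0 < y1 <= y_max + 1e-9):
        raise GeometryError(
            f"window ({x0}, {x1}) x ({y0}, {y1}) outside domain [0, {x_max:.1f}] x [0, {y_max:.1f}]"
        )
    cells = state._cells[: state._n]
    ii = cells % cfg.I + 1
    jj = cells // cfg.I + 1
    x, y = site_position(ii, jj, cfg.delta) if cells.size else (np.array([]), np.array([]))
    if cells.size:
        inside = (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
        x, y = x[inside], y[inside]
        pp = state._pp[cells[inside]]
    else:
        pp = np.array([])
    if colour_range is None:
        colour_range = (0.0, float(pp.max()) if pp.size else 1.0)
    fig, ax = plt.subplots(figsize=(6, 6 * (y1 - y0) / (x1 - x0)), dpi=dpi)
    marker_pts = 0.8 * cfg.delta / (x1 - x0) * 6 * 72  # disc about one spacing wide
    sc = ax.scatter(x, y, c=pp, s=marker_pts**2, vmin=colour_range[0], vmax=colour_range[1], cmap="jet", linewidths=0)
    ax.set_xlim(x0, x1)
    ax.set_ylim(y0, y1)
    ax.set_aspect("equal")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title(f"t = {state.t:.1f} h, N = {state.n_cells}")
    cb = fig.colorbar(sc, ax=ax, label=f"Pp  [{colour_range[0]:.4g}, {colour_range[1]:.4g}]")
    if path is not None:
        fig.savefig(path, metadata={"Software": "hexpassage"})
        plt.close(fig)
        return None
    return fig


def export_boxplot_table(records: Sequence[PassageRecord], path: str | Path) -> None:
    """One CSV row per passage with the Pp summary statistics, full precision."""
    if not records:
        raise ValueError("no passage records to export")
    df = pd.DataFrame(
        {
            "passage": [r.passage_number for r in records],
            "n_cells": [r.n_cells for r in records],
            "duration_h": [r.duration_h for r in records],
            "pp_mean": [r.pp_mean for r in records],
            "pp_sd": [r.pp_sd for r in records],
            "pp_median": [r.pp_median for r in records],
            "pp_q1": [r.pp_q1 for r in records],
            "pp_q3": [r.pp_q3 for r in records],
        }
    )
    df.to_csv(path, index=False)


def export_density_profiles(result: ScratchEnsembleResult, path: str | Path) -> None:
    """Long-format CSV of the ensemble profiles: time, column, x, mean, sd."""
    T, I = result.mean_profiles.shape
    df = pd.DataFrame(
        {
            "time_h": np.repeat(result.record_times_h, I),
            "column": np.tile(np.arange(1, I + 1), T),
            "x_um": np.tile(result.x_positions, T),
            "mean_density": result.mean_profiles.ravel(),
            "sd_density": result.sd_profiles.ravel(),
        }
    )
    df.to_csv(path, index=False)


def write_manifest(path: str | Path, config: ScenarioConfig, extra: dict | None = None) -> None:
    """Config echo + seed + code version: enough to reproduce a run bit-for-bit."""
    from . import __version__

    manifest = {"version": __version__, "config": config.to_dict()}
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
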