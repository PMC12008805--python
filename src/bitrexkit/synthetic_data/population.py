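"""Stochastic expansion/contraction dynamics of a tandem array population.

Models nick-induced break-induced replication (BIR) at an array flank: each
cell division, the collapsed fork can re-invade an upstream repeat unit, so
the array either stays the same or expands; the donor chromatid is inherited
unchanged by one daughter (asymmetric inheritance).  Expansion requires at
least two units — a single-copy array has no upstream unit to invade.
Independently, inter-unit homologous recombination contracts the array with
per-generation hazard 1 - exp(-k X^2).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_ORIGIN_MODES = ("internal", "external")
_MAGNITUDE_MODES = ("uniform", "single")


@dataclass(frozen=True)
class SimParams:
    """Per-division event model.

    p_exp              expansion-event probability per division when the
                       nick-proximal fork wins the race (internal mode uses
                       it directly).
    step_mean          mean of the geometric expansion step (copies gained).
    k                  contraction rate constant, per copy^2 per generation.
    origin_mode        'internal': replication initiates inside the repeat
                       unit, success independent of array length.
                       'external': the fork covering the array starts at an
                       origin beyond it, and races an opposite-side fork;
                       success probability shrinks as the array grows.
    d_internal_side    nick-to-same-side-origin distance (bp).
    d_external         nick-to-opposite-side-origin distance (bp).
    unit_length_bp     repeat-unit length used to convert copies to bp.
    population_cap     multinomial resampling target per generation
                       (``None`` = unbounded, exact lineage tree).
    contraction_magnitude  'uniform': a contraction event removes
                       Uniform[1, X-1] copies (recombination between two
                       random units); 'single': exactly one copy, the regime
                       in which mean dynamics follow dX/dt = -kX^2.
    """

    p_exp: float = 0.05
    step_mean: float = 1.5
    k: float = 0.0
    origin_mode: str = "internal"
    d_external: float = 10000.0
    d_internal_side: float = 500.0
    unit_length_bp: float = 2000.0
    population_cap: int | None = 1000
    contraction_magnitude: str = "uniform"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_exp <= 1.0:
            raise ValueError("p_exp must be in [0, 1]")
        if self.step_mean < 1.0:
            raise ValueError("step_mean must be >= 1")
        if self.k < 0.0:
            raise ValueError("k must be >= 0")
        if self.origin_mode not in _ORIGIN_MODES:
            raise ValueError(f"origin_mode must be one of {_ORIGIN_MODES}")
        if self.contraction_magnitude not in _MAGNITUDE_MODES:
            raise ValueError(f"contraction_magnitude must be one of {_MAGNITUDE_MODES}")
        if self.d_external < 0 or self.d_internal_side <= 0:
            raise ValueError("origin distances must be positive")
        if self.population_cap is not None and self.population_cap < 1:
            raise ValueError("population_cap must be >= 1")


def effective_expansion_probability(params: SimParams, copies) -> np.ndarray:
    """Per-division expansion probability for arrays of ``copies`` units.

    In external mode two constant-speed forks race toward the nick: the
    same-side fork travels d_internal_side, the opposite one travels
    d_external plus the whole array, giving
    ``p_exp * d_int / (d_int + d_ext + array_bp)`` — strictly decreasing in
    array length, hence the expansion-rate plateau for long arrays.
    """
    x = np.asarray(copies, dtype=float)
    if params.origin_mode == "internal":
        return np.broadcast_to(np.float64(params.p_exp), x.shape).copy()
    array_bp = x * params.unit_length_bp
    d_i = params.d_internal_side
    return params.p_exp * d_i / (d_i + params.d_external + array_bp)


@dataclass
class PopulationTrajectory:
    """Per-generation summary plus the final copy-number multiset."""

    generations: np.ndarray
    mean_copy: np.ndarray
    sd_copy: np.ndarray
    population_size: np.ndarray
    final_population: np.ndarray
    x0: int
    params: SimParams = field(repr=False)

    @property
    def cna_per_generation(self) -> float:
        g = self.generations[-1] - self.generations[0]
        if g == 0:
            return 0.0
        return float((self.mean_copy[-1] - self.mean_copy[0]) / g)

    def to_kinetics_trajectory(self, g_per_day: float = 6.0):
        from .. import kinetics

        return kinetics.Trajectory(
            times=np.asarray(self.generations, dtype=float) / g_per_day,
            mean_copy=self.mean_copy.astype(float),
            sd_copy=self.sd_copy.astype(float),
            n_replicates=1,
        )


def simulate_population(
    x0: int, params: SimParams, n_generations: int, *, n_initial: int = 1
) -> PopulationTrajectory:
    """Evolve a clonal population for ``n_generations`` synchronous divisions.

    Each division, a cell of X units produces one daughter with X (the donor
    chromatid) and one with X + step on an expansion event (eligible only
    when X >= 2).  Every resulting lineage then contracts with hazard
    1 - exp(-k X^2).  When the population exceeds ``population_cap`` it is
    diluted by multinomial resampling.
    """
    if x0 < 1:
        raise ValueError("x0 must be >= 1")
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    if n_initial < 1:
        raise ValueError("n_initial must be >= 1")

    rng = np.random.default_rng(params.seed)
    pop = np.full(n_initial, x0, dtype=np.int64)
    gens = [0]
    means = [float(pop.mean())]
    sds = [float(pop.std())]
    sizes = [pop.size]

    p_geom = 1.0 / params.step_mean
    for g in range(1, n_generations + 1):
        n = pop.size
        p_eff = effective_expansion_probability(params, pop)
        event = (rng.random(n) < p_eff) & (pop >= 2)
        steps = rng.geometric(p_geom, size=n)
        daughters = pop + np.where(event, steps, 0)
        pop = np.concatenate([pop, daughters])

        if params.k > 0:
            hazard = 1.0 - np.exp(-params.k * pop.astype(float) ** 2)
            contract = (rng.random(pop.size) < hazard) & (pop >= 2)
            idx = np.nonzero(contract)[0]
            if idx.size:
                if params.contraction_magnitude == "uniform":
                    mag = rng.integers(1, pop[idx])  # uniform on [1, X-1]
                else:
                    mag = np.ones(idx.size, dtype=np.int64)
                pop[idx] -= mag

        cap = params.population_cap
        if cap is not None and pop.size > cap:
            pop = rng.choice(pop, size=cap, replace=True)

        gens.append(g)
        means.append(float(pop.mean()))
        sds.append(float(pop.std()))
        sizes.append(pop.size)

    return PopulationTrajectory(
        generations=np.array(gens),
        mean_copy=np.array(means),
        sd_copy=np.array(sds),
        population_size=np.array(sizes),
        final_population=np.sort(pop),
        x0=x0,
        params=params,
    )
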