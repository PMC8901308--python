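"""Particle swarm optimizers.

Three variants share one configuration and driver:

* ``continuous`` — canonical PSO with linearly decaying inertia weight,
  per-dimension random acceleration toward the personal best (pbest) and the
  swarm best (gbest), and additive position updates.
* ``standard_binary`` — binary PSO: the same velocity recursion, but positions
  live in {0,1}^dims and are resampled each step with per-bit probability
  sigmoid(v).
* ``modified_binary`` — a velocity-free binary variant for subset search:
  each particle's new position is built by mutating its pbest and the gbest
  (with mutation counts that decay over the run) and recombining the two
  bit-by-bit, taking the gbest bit with a fixed probability on disagreement.

All variants maximize the supplied fitness; minimize by negating at the call
site.  Every stochastic draw flows through one seeded ``numpy`` generator in a
fixed order, so a run is bit-reproducible from its seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import expit

logger = logging.getLogger(__name__)

VARIANTS = ("continuous", "standard_binary", "modified_binary")

#: default velocity clamp for the sigmoid-transfer binary variant; |v| = 6
#: already saturates the transfer function to within 2.5e-3 of 0/1.
DEFAULT_BINARY_V_CLAMP = 6.0


@dataclass
class SwarmConfig:
    """Hyperparameters of a swarm run.

    Parameters
    ----------
    n_particles : population size.
    dims : dimension of the search space (number of bits for binary variants).
    n_iterations : iteration budget T.
    variant : one of ``continuous``, ``standard_binary``, ``modified_binary``.
    w_max, w_min : inertia-weight bounds; w decays linearly from w_max to
        w_min over the run.
    d1, d2 : acceleration coefficients toward pbest and gbest.
    m1_base, m2_base : mutation-count bases of the modified variant (applied
        to pbest and gbest respectively); both decay linearly to 0 over the
        run.  ``None`` selects ``dims / 4``.
    v_clamp : velocity bound; ``"auto"`` resolves to 6 for standard_binary
        and to no clamp otherwise; ``None`` disables clamping.
    combine_threshold : probability of adopting the gbest bit when the two
        mutated parents disagree (modified variant).
    seed : RNG seed for the run.
    """

    n_particles: int
    dims: int
    n_iterations: int = 100
    variant: str = "modified_binary"
    w_max: float = 0.9
    w_min: float = 0.4
    d1: float = 2.0
    d2: float = 2.0
    m1_base: Optional[float] = None
    m2_base: Optional[float] = None
    v_clamp: object = "auto"
    combine_threshold: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.n_particles < 1:
            raise ValueError("n_particles must be a positive integer")
        if self.dims < 1:
            raise ValueError("dims must be a positive integer")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be a positive integer")
        if not (self.w_max >= self.w_min > 0):
            raise ValueError("inertia bounds must satisfy w_max >= w_min > 0")
        if self.d1 < 0 or self.d2 < 0:
            raise ValueError("acceleration coefficients must be >= 0")
        if self.m1_base is None:
            self.m1_base = self.dims / 4.0
        if self.m2_base is None:
            self.m2_base = self.dims / 4.0
        if not (0 <= self.m1_base < self.dims):
            raise ValueError("m1_base must satisfy 0 <= m1_base < dims")
        if not (0 <= self.m2_base < self.dims):
            raise ValueError("m2_base must satisfy 0 <= m2_base < dims")
        if self.v_clamp == "auto":
            self.v_clamp = DEFAULT_BINARY_V_CLAMP if self.variant == "standard_binary" else None
        if self.v_clamp is not None and not self.v_clamp > 0:
            raise ValueError("v_clamp must be positive or None")
        if not (0.0 <= self.combine_threshold <= 1.0):
            raise ValueError("combine_threshold must lie in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "SwarmConfig":
        return cls(**d)


@dataclass
class ParticleState:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float


@dataclass
class SwarmState:
    particles: list
    gbest_position: np.ndarray
    gbest_fitness: float
    t: int = 0


@dataclass
class OptimizationResult:
    """Outcome of a swarm run: the best position/fitness found, the
    per-iteration gbest trace, and the total number of fitness calls."""

    best_position: np.ndarray
    best_fitness: float
    fitness_history: np.ndarray = field(repr=False)
    evaluations: int = 0


def inertia_weight(t: int, config: SwarmConfig) -> float:
    """Linearly decaying inertia weight: w_max at t=0 down to w_min at t=T."""
    if not (0 <= t <= config.n_iterations):
        raise ValueError(f"iteration index {t} outside [0, {config.n_iterations}]")
    frac = t / config.n_iterations
    return config.w_max - (config.w_max - config.w_min) * frac


def velocity_update(
    p: ParticleState,
    gbest: np.ndarray,
    w: float,
    config: SwarmConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One velocity step: w·v + d1·r1·(pbest − x) + d2·r2·(gbest − x).

    r1, r2 are fresh per-dimension uniforms (r1 drawn first).  The result is
    clamped to ±v_clamp when the config sets one.
    """
    x = np.asarray(p.position, dtype=float)
    if x.shape != np.shape(gbest) or x.shape != p.velocity.shape:
        raise ValueError("position/velocity/gbest dimension mismatch")
    r1 = rng.random(x.shape[0])
    r2 = rng.random(x.shape[0])
    v = (
        w * np.asarray(p.velocity, dtype=float)
        + config.d1 * r1 * (np.asarray(p.pbest_position, dtype=float) - x)
        + config.d2 * r2 * (np.asarray(gbest, dtype=float) - x)
    )
    if config.v_clamp is not None:
        v = np.clip(v, -config.v_clamp, config.v_clamp)
    return v


def position_update_continuous(x: np.ndarray, v: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    if x.shape != v.shape:
        raise ValueError("position/velocity dimension mismatch")
    return x + v


def sigmoid(v):
    """Logistic transfer S(v) = 1 / (1 + e^{−v}); maps velocity to a bit
    probability.  Saturates gracefully for large |v|."""
    return expit(v)


def sample_binary_position(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw a bit vector with independent per-bit probability sigmoid(v_i)."""
    v = np.asarray(v, dtype=float)
    u = rng.random(v.shape[0])
    return (u < sigmoid(v)).astype(np.int64)


def decay_schedule(m_base: float, t: int, horizon: int = 100) -> float:
    """Linearly decaying mutation count m(t) = m_base·(horizon − t)/horizon.

    Clamped at zero for t past the horizon.  The default horizon of 100
    iterations is the canonical schedule; swarm steps pass their own
    iteration budget as the horizon.
    """
    if t < 0:
        raise ValueError("iteration index must be >= 0")
    if m_base < 0:
        raise ValueError("m_base must be >= 0")
    return m_base * max(horizon - t, 0) / horizon


def mutate_bits(bits: np.ndarray, m_t: float, rng: np.random.Generator) -> np.ndarray:
    """Flip k = round(m_t·u) distinct uniformly chosen bits (u ~ U[0,1)).

    One uniform draw decides the count; the flip positions are sampled
    without replacement, so the Hamming distance from the input is exactly k
    (capped at the vector length).
    """
    bits = np.asarray(bits)
    d = bits.shape[0]
    if m_t < 0:
        raise ValueError("mutation count must be >= 0")
    out = bits.copy()
    u = rng.random()
    k = min(int(math.floor(m_t * u + 0.5)), d)
    if k > 0:
        idx = rng.choice(d, size=k, replace=False)
        out[idx] = 1 - out[idx]
    return out


def combine_bits(
    p_bit: int, g_bit: int, rng: np.random.Generator, threshold: float = 1.0 / 3.0
) -> int:
    """Recombine one bit: agreement is kept; on disagreement the gbest bit is
    adopted with probability ``threshold`` (else the pbest bit)."""
    if p_bit not in (0, 1) or g_bit not in (0, 1):
        raise ValueError("combine_bits operates on bits in {0, 1}")
    if p_bit == g_bit:
        return int(p_bit)
    take_g = rng.random() < threshold
    # round(p + (g − p)·[u < threshold]); a no-op on bit operands
    return int(round(p_bit + (g_bit - p_bit) * take_g))


def _combine_vectors(
    ptmp: np.ndarray, gtmp: np.ndarray, rng: np.random.Generator, threshold: float
) -> np.ndarray:
    """Vectorized bitwise recombination; draws one uniform per dimension
    (agreeing positions consume a draw too, keeping the draw order fixed)."""
    u = rng.random(ptmp.shape[0])
    take_g = (ptmp != gtmp) & (u < threshold)
    out = ptmp.copy()
    out[take_g] = gtmp[take_g]
    return out


def _check_fitness(value: float, index: int) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"fitness returned non-finite value {value!r} for particle {index}")
    return value


def _update_bests(state: SwarmState, fitnesses: Sequence[float]) -> None:
    """Strict-improvement pbest/gbest update (ties keep the incumbent)."""
    for p, f in zip(state.particles, fitnesses):
        if f > p.pbest_fitness:
            p.pbest_fitness = f
            p.pbest_position = p.position.copy()
    for p in state.particles:
        if p.pbest_fitness > state.gbest_fitness:
            state.gbest_fitness = p.pbest_fitness
            state.gbest_position = p.pbest_position.copy()


def modified_bpso_step(
    state: SwarmState,
    config: SwarmConfig,
    fitness: Callable[[np.ndarray], float],
    rng: np.random.Generator,
    repair: Optional[Callable[[np.ndarray, np.random.Generator], np.ndarray]] = None,
) -> SwarmState:
    """One synchronous step of the mutation/recombination binary variant.

    Per particle (in index order): Ptmp = mutated pbest, Gtmp = mutated
    gbest, new position = bitwise recombination of the two; all particles are
    then evaluated once and the bests updated by strict improvement.
    """
    m1_t = decay_schedule(config.m1_base, state.t, horizon=config.n_iterations)
    m2_t = decay_schedule(config.m2_base, state.t, horizon=config.n_iterations)
    new_positions = []
    for p in state.particles:
        ptmp = mutate_bits(p.pbest_position, m1_t, rng)
        gtmp = mutate_bits(state.gbest_position, m2_t, rng)
        pos = _combine_vectors(ptmp, gtmp, rng, config.combine_threshold)
        if repair is not None:
            pos = repair(pos, rng)
        new_positions.append(pos)
    fitnesses = []
    for i, (p, pos) in enumerate(zip(state.particles, new_positions)):
        p.position = pos
        fitnesses.append(_check_fitness(fitness(pos), i))
    _update_bests(state, fitnesses)
    state.t += 1
    return state


def standard_binary_step(
    state: SwarmState,
    config: SwarmConfig,
    fitness: Callable[[np.ndarray], float],
    rng: np.random.Generator,
    repair: Optional[Callable[[np.ndarray, np.random.Generator], np.ndarray]] = None,
) -> SwarmState:
    """One synchronous step of sigmoid-transfer binary PSO."""
    w = inertia_weight(state.t, config)
    new_v, new_x = [], []
    for p in state.particles:
        v = velocity_update(p, state.gbest_position, w, config, rng)
        x = sample_binary_position(v, rng)
        if repair is not None:
            x = repair(x, rng)
        new_v.append(v)
        new_x.append(x)
    fitnesses = []
    for i, (p, v, x) in enumerate(zip(state.particles, new_v, new_x)):
        p.velocity = v
        p.position = x
        fitnesses.append(_check_fitness(fitness(x), i))
    _update_bests(state, fitnesses)
    state.t += 1
    return state


def continuous_step(
    state: SwarmState,
    config: SwarmConfig,
    fitness: Callable[[np.ndarray], float],
    rng: np.random.Generator,
) -> SwarmState:
    """One synchronous step of continuous PSO."""
    w = inertia_weight(state.t, config)
    new_v, new_x = [], []
    for p in state.particles:
        v = velocity_update(p, state.gbest_position, w, config, rng)
        new_v.append(v)
        new_x.append(position_update_continuous(p.position, v))
    fitnesses = []
    for i, (p, v, x) in enumerate(zip(state.particles, new_v, new_x)):
        p.velocity = v
        p.position = x
        fitnesses.append(_check_fitness(fitness(x), i))
    _update_bests(state, fitnesses)
    state.t += 1
    return state


def _init_state(
    config: SwarmConfig,
    fitness: Callable[[np.ndarray], float],
    rng: np.random.Generator,
    bounds: tuple,
    repair,
) -> SwarmState:
    n, d = config.n_particles, config.dims
    if config.variant == "continuous":
        lo, hi = bounds
        positions = rng.uniform(lo, hi, size=(n, d))
    else:
        positions = rng.integers(0, 2, size=(n, d))
        if repair is not None:
            positions = np.stack([repair(row, rng) for row in positions])
    velocities = np.zeros((n, d), dtype=float)
    particles = []
    for i in range(n):
        f = _check_fitness(fitness(positions[i]), i)
        particles.append(
            ParticleState(
                position=positions[i].copy(),
                velocity=velocities[i].copy(),
                pbest_position=positions[i].copy(),
                pbest_fitness=f,
            )
        )
    best = max(range(n), key=lambda i: particles[i].pbest_fitness)
    return SwarmState(
        particles=particles,
        gbest_position=particles[best].pbest_position.copy(),
        gbest_fitness=particles[best].pbest_fitness,
        t=0,
    )


_STEPPERS = {
    "continuous": lambda s, c, f, r, rep: continuous_step(s, c, f, r),
    "standard_binary": standard_binary_step,
    "modified_binary": modified_bpso_step,
}


def run_optimizer(
    fitness: Callable[[np.ndarray], float],
    config: SwarmConfig,
    bounds: tuple = (-5.0, 5.0),
    repair: Optional[Callable[[np.ndarray, np.random.Generator], np.ndarray]] = None,
) -> OptimizationResult:
    """Run the configured variant for ``config.n_iterations`` steps.

    ``bounds`` seeds the initial positions of the continuous variant only.
    ``repair`` (binary variants) maps a freshly generated position to an
    admissible one before evaluation; the repaired position is what the
    particle keeps.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    state = _init_state(config, fitness, rng, bounds, repair)
    evaluations = config.n_particles
    history = np.empty(config.n_iterations, dtype=float)
    stepper = _STEPPERS[config.variant]
    for it in range(config.n_iterations):
        stepper(state, config, fitness, rng, repair)
        evaluations += config.n_particles
        history[it] = state.gbest_fitness
        logger.debug(
            "iter=%d gbest=%.6f evaluations=%d", state.t, state.gbest_fitness, evaluations
        )
    return OptimizationResult(
        best_position=state.gbest_position.copy(),
        best_fitness=state.gbest_fitness,
        fitness_history=history,
        evaluations=evaluations,
    )


def _mantegna_sigma(alpha: float) -> float:
    num = math.gamma(1 + alpha) * math.sin(math.pi * alpha / 2)
    den = math.gamma((1 + alpha) / 2) * alpha * 2 ** ((alpha - 1) / 2)
    return (num / den) ** (1 / alpha)


def run_levy_optimizer(
    fitness: Callable[[np.ndarray], float],
    config: SwarmConfig,
    alpha: float = 1.5,
    repair: Optional[Callable[[np.ndarray, np.random.Generator], np.ndarray]] = None,
) -> OptimizationResult:
    """Binary PSO with heavy-tailed post-sampling bit flips (experimental).

    Each particle follows the standard sigmoid-transfer update, then flips
    ``k`` random bits where ``k = floor(|step|)`` and ``step`` is a
    Mantegna-style Levy(alpha) draw.  Occasional large flips give long jumps.
    This is a stand-in construction for a heavy-tailed baseline, not an
    implementation of any published "Levy algorithm".
    """
    if not (1.0 < alpha <= 2.0):
        raise ValueError("alpha must lie in (1, 2]")
    cfg = SwarmConfig(
        n_particles=config.n_particles,
        dims=config.dims,
        n_iterations=config.n_iterations,
        variant="standard_binary",
        w_max=config.w_max,
        w_min=config.w_min,
        d1=config.d1,
        d2=config.d2,
        v_clamp=config.v_clamp if config.v_clamp is not None else "auto",
        seed=config.seed,
    )
    sigma = _mantegna_sigma(alpha)
    rng = np.random.default_rng(cfg.seed)
    state = _init_state(cfg, fitness, rng, (0, 1), repair)
    evaluations = cfg.n_particles
    history = np.empty(cfg.n_iterations, dtype=float)
    for it in range(cfg.n_iterations):
        w = inertia_weight(state.t, cfg)
        new_v, new_x = [], []
        for p in state.particles:
            v = velocity_update(p, state.gbest_position, w, cfg, rng)
            x = sample_binary_position(v, rng)
            u = rng.normal(0.0, sigma)
            vv = rng.normal(0.0, 1.0)
            step = u / abs(vv) ** (1 / alpha)
            k = min(int(abs(step)), cfg.dims)
            if k > 0:
                idx = rng.choice(cfg.dims, size=k, replace=False)
                x = x.copy()
                x[idx] = 1 - x[idx]
            if repair is not None:
                x = repair(x, rng)
            new_v.append(v)
            new_x.append(x)
        fitnesses = []
        for i, (p, v, x) in enumerate(zip(state.particles, new_v, new_x)):
            p.velocity = v
            p.position = x
            fitnesses.append(_check_fitness(fitness(x), i))
        _update_bests(state, fitnesses)
        state.t += 1
        evaluations += cfg.n_particles
        history[it] = state.gbest_fitness
    return OptimizationResult(
        best_position=state.gbest_position.copy(),
        best_fitness=state.gbest_fitness,
        fitness_history=history,
        evaluations=evaluations,
    )
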