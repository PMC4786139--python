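"""Antlion optimizer (ALO) and its chaotic variant (CALO).

The optimizer evolves two populations over a box-bounded continuous space:
antlions (trap builders, holding the incumbent solutions) and ants
(candidate solutions performing random walks).  Each iteration every ant
walks inside bounds that are shrunk by the exploration ratio ``I`` and
centred on a roulette-selected antlion and on the elite; the ant's new
position is the average of the two walks.  Ants that out-perform their
antlion replace it, and the best antlion ever seen (the elite) is returned.

In the chaotic variant the shrink ratio is modulated every iteration by a
chaotic-map value x in (0, 1) via ``I_hat = max(1, I ** x)``, alternating
the search between near-full exploration (x -> 0) and the base
exploitation envelope (x -> 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chaos import ChaosState, ChaoticMap

# Step thresholds (fraction of T) -> accuracy exponent w; below the first
# threshold no shrinking is applied (I = 1).
DEFAULT_W_TABLE = ((0.1, 2), (0.5, 3), (0.75, 4), (0.9, 5), (0.95, 6))

ROULETTE_EPS = 1e-12


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box ``[lower, upper]^D``; for feature selection [0, 1]^D."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if lower.shape != upper.shape or lower.ndim != 1:
            raise ValueError("lower and upper must be 1-D arrays of equal length")
        if not np.all(lower < upper):
            raise ValueError("lower bounds must be strictly below upper bounds")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def dim(self) -> int:
        return self.lower.shape[0]

    @classmethod
    def unit(cls, dim: int) -> "SearchSpace":
        return cls(np.zeros(dim), np.ones(dim))


@dataclass(frozen=True)
class Schedule:
    """Exploration-ratio schedule: plain quasi-linear or chaos-modulated.

    ``coupling`` selects how a chaotic value x couples to the base ratio I:
    ``power`` (default) uses I_hat = max(1, I**x); ``replace`` uses
    I_hat = 1/x, discarding the base envelope entirely (sensitivity mode).
    """

    mode: str = "base"
    map_spec: ChaoticMap | None = None
    coupling: str = "power"
    w_table: tuple = DEFAULT_W_TABLE

    def __post_init__(self):
        if self.mode not in ("base", "chaotic"):
            raise ValueError(f"mode must be 'base' or 'chaotic', got {self.mode!r}")
        if self.coupling not in ("power", "replace"):
            raise ValueError(f"coupling must be 'power' or 'replace', got {self.coupling!r}")
        if self.mode == "chaotic" and self.map_spec is None:
            raise ValueError("chaotic schedule requires a map_spec")


@dataclass
class RunResult:
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray  # elite fitness after init and after each iteration
    n_evaluations: int


def exploration_ratio(t: int, T: int, w_table=DEFAULT_W_TABLE) -> float:
    """Shrink ratio ``I = 10^w * t / T`` with the stepped exponent table.

    For t at or below the first threshold (t <= 0.1 T) no shrinking is
    applied and I = 1.  The ratio is non-decreasing in t.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if not 0 <= t <= T:
        raise ValueError(f"iteration t={t} outside [0, {T}]")
    frac = t / T
    w = None
    for threshold, exponent in w_table:
        if frac > threshold:
            w = exponent
    if w is None:
        return 1.0
    return max(1.0, 10.0**w * frac)


def chaotic_exploration_ratio(I: float, x: float, coupling: str = "power") -> float:
    """Chaos-modulated ratio, bounded in [1, I] for the power coupling."""
    if coupling == "power":
        return max(1.0, I**x)
    # 'replace': ratio set directly from the chaos value, no envelope
    return max(1.0, 1.0 / x) if x > 0 else 1.0


def shrink_bounds(space: SearchSpace, I: float):
    """Divide both bound vectors by I, shrinking interval widths by 1/I."""
    if I < 1.0:
        raise ValueError(f"shrink ratio must be >= 1, got {I}")
    return space.lower / I, space.upper / I


def center_bounds(c_t: np.ndarray, d_t: np.ndarray, antlion_pos: np.ndarray):
    """Translate shrunk bounds onto an antlion's position (width preserved)."""
    if not (c_t.shape == d_t.shape == np.shape(antlion_pos)):
        raise ValueError("bound vectors and antlion position must share a shape")
    return c_t + antlion_pos, d_t + antlion_pos


def random_walk(T: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-step random walk of length T+1 starting at 0.

    Each step is +1 when a uniform draw exceeds 0.5, else -1.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    steps = np.where(rng.random(T) > 0.5, 1.0, -1.0)
    walk = np.empty(T + 1)
    walk[0] = 0.0
    np.cumsum(steps, out=walk[1:])
    return walk


def normalize_walk(walk: np.ndarray, c: float, d: float) -> np.ndarray:
    """Affine min-max rescale of a walk into [c, d].

    A constant walk (no spread to rescale) maps to the midpoint (c+d)/2.
    """
    if d <= c:
        raise ValueError(f"need c < d, got c={c}, d={d}")
    a, b = walk.min(), walk.max()
    if a == b:
        return np.full_like(walk, 0.5 * (c + d))
    return (walk - a) * (d - c) / (b - a) + c


def roulette_select(fitness: np.ndarray, rng: np.random.Generator) -> int:
    """Fitness-proportional selection under minimization.

    Weights are max-shifted, w_j = (max f - f_j) + eps, so lower fitness
    means strictly higher selection probability; all-equal fitness gives a
    uniform draw.
    """
    fitness = np.asarray(fitness, dtype=float)
    if fitness.size == 0:
        raise ValueError("cannot select from an empty fitness vector")
    weights = (fitness.max() - fitness) + ROULETTE_EPS
    probs = weights / weights.sum()
    return int(rng.choice(fitness.size, p=probs))


def greedy_replacement(
    antlions: np.ndarray,
    antlion_fitness: np.ndarray,
    ants: np.ndarray,
    ant_fitness: np.ndarray,
):
    """Antlion i takes ant i's position when the ant is strictly fitter."""
    better = ant_fitness < antlion_fitness
    antlions[better] = ants[better]
    antlion_fitness[better] = ant_fitness[better]
    return antlions, antlion_fitness


def _evaluate(objective, positions: np.ndarray) -> np.ndarray:
    fit = np.array([float(objective(p)) for p in positions])
    if not np.all(np.isfinite(fit)):
        bad = int(np.flatnonzero(~np.isfinite(fit))[0])
        raise RuntimeError(
            f"objective returned a non-finite value at position {positions[bad]}"
        )
    return fit


def run(
    space: SearchSpace,
    objective,
    n_agents: int = 8,
    n_iterations: int = 70,
    schedule: Schedule = Schedule(),
    seed: int | None = None,
    forced_positions=None,
) -> RunResult:
    """Run the (C)ALO loop for ``n_iterations`` and return the elite.

    ``forced_positions`` (list of D-vectors) overwrite the first antlion
    rows at initialization, guaranteeing their fitness is visible to the
    elite from the start — used to seed the all-features solution in
    feature selection.
    """
    if n_agents < 2:
        raise ValueError(f"need at least 2 agents, got {n_agents}")
    rng = np.random.default_rng(seed)
    D = space.dim
    T = n_iterations

    ants = rng.uniform(space.lower, space.upper, size=(n_agents, D))
    antlions = rng.uniform(space.lower, space.upper, size=(n_agents, D))
    if forced_positions is not None:
        forced = np.atleast_2d(np.asarray(forced_positions, dtype=float))
        if forced.shape[0] > n_agents or forced.shape[1] != D:
            raise ValueError("forced_positions must be at most n_agents D-vectors")
        antlions[: forced.shape[0]] = forced

    ant_fitness = _evaluate(objective, ants)
    antlion_fitness = _evaluate(objective, antlions)
    n_evals = 2 * n_agents

    elite_idx = int(np.argmin(antlion_fitness))
    elite = antlions[elite_idx].copy()
    elite_fitness = float(antlion_fitness[elite_idx])
    trace = [elite_fitness]

    chaos = ChaosState(schedule.map_spec) if schedule.mode == "chaotic" else None

    for t in range(1, T + 1):
        I = exploration_ratio(t, T, schedule.w_table)
        if chaos is not None:
            # one map step per optimizer iteration, shared by all ants
            I = chaotic_exploration_ratio(I, chaos.step(), schedule.coupling)
        c_t, d_t = shrink_bounds(space, I)

        for i in range(n_agents):
            j = roulette_select(antlion_fitness, rng)
            guides = (antlions[j], elite)
            # fresh T-step walk per guide per dimension; position read at index t
            steps = np.where(rng.random((2, D, T)) > 0.5, 1.0, -1.0)
            walks = np.concatenate(
                [np.zeros((2, D, 1)), np.cumsum(steps, axis=2)], axis=2
            )
            lo = walks.min(axis=2)
            hi = walks.max(axis=2)
            vals = np.empty((2, D))
            for g, guide in enumerate(guides):
                # the walk happens *around* the guide: the shrunk interval is
                # attached per-dimension to a randomly chosen side, so each
                # coordinate can move both up and down even when the global
                # lower bound is 0 and c_t collapses onto the guide itself
                side = rng.random(D) < 0.5
                c_i = np.where(side, c_t, -d_t) + guide
                d_i = np.where(side, d_t, -c_t) + guide
                span = hi[g] - lo[g]
                with np.errstate(invalid="ignore", divide="ignore"):
                    scaled = (walks[g, :, t] - lo[g]) * (d_i - c_i) / span + c_i
                # constant walk -> midpoint (cannot occur for T>=1 unit steps,
                # kept for contract completeness)
                vals[g] = np.where(span == 0.0, 0.5 * (c_i + d_i), scaled)
            ants[i] = np.clip(vals.mean(axis=0), space.lower, space.upper)

        ant_fitness = _evaluate(objective, ants)
        n_evals += n_agents
        greedy_replacement(antlions, antlion_fitness, ants, ant_fitness)

        best = int(np.argmin(antlion_fitness))
        if antlion_fitness[best] < elite_fitness:
            elite = antlions[best].copy()
            elite_fitness = float(antlion_fitness[best])
        trace.append(elite_fitness)

    return RunResult(
        best_position=elite,
        best_fitness=elite_fitness,
        trace=np.asarray(trace),
        n_evaluations=n_evals,
    )
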