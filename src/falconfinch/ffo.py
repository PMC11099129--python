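"""Falcon finch optimization: a bound-constrained swarm metaheuristic.

The algorithm maintains a population ("swarm") of candidate positions in a
box. Each iteration runs up to three stages:

1. **Foraging** — the fittest ``producer_fraction`` of individuals (the
   producers) explore: below the alarm threshold they contract their
   position by a per-dimension exponential factor, above it they take a
   multiplicative normal jump.
2. **Accumulation / besiege** — the remaining individuals (scroungers)
   either follow the sparrow-search scrounger rule, or — when the alarm
   draw signals a predator — escalate to Harris-hawk style soft or hard
   besiege moves, optionally replaced by a "rapid dive" move when the dive
   improves fitness.
3. **Perching** — every individual blends its position with the global
   best (the "falcon"), conditioned on an alarm draw and a perching
   selector.

Greedy acceptance after every stage (an individual keeps its old position
whenever the proposed one is worse) makes the best-so-far fitness
non-increasing across iterations. Minimization convention throughout;
negate the objective to maximize.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

Objective = Callable[[np.ndarray], float]

#: sentinel for not-yet-evaluated fitness
UNEVALUATED = np.inf

_DENOM_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# configuration


@dataclass
class BesiegeParams:
    """Constants of the soft/hard besiege stage.

    ``E`` (escape energy) decays as ``E = 2 * E0 * (1 - k / iter_max)`` with
    ``E0`` drawn uniformly from ``e0_range`` per individual per iteration, so
    ``|E|`` reaches 0 exactly at the final iteration. ``V`` (jump strength)
    is uniform on ``(0, v_max)``; ``Q`` is standard normal.
    """

    e0_range: tuple[float, float] = (-1.0, 1.0)
    v_max: float = 2.0

    def validate(self) -> None:
        lo, hi = self.e0_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"invalid e0_range {self.e0_range!r}")
        if not self.v_max > 0:
            raise ValueError("v_max must be positive")


@dataclass
class FFOConfig:
    """All knobs of the optimizer.

    Parameters
    ----------
    l : population size.
    s : decision dimension.
    iter_max : iteration budget (the only stopping rule).
    lower, upper : box bounds, broadcastable to length ``s``.
    p_alarm : safety threshold; alarm draws below it mean "no predator".
    lam : besiege mixing constant (the dive moves' λ).
    x1, x2, x3 : soft-besiege mixture weights.
    producer_fraction : share of the population acting as producers.
    ssa_compat : if True the high-alarm producer move is the additive
        sparrow-search original (``Y + N_rand``) instead of the
        multiplicative ``Y * N_rand`` form.
    enable_besiege, enable_perching : stage switches; disabling both
        reduces the algorithm to plain sparrow-search dynamics.
    perch_producers_only : restrict the perching stage to producers.
    """

    l: int = 30
    s: int = 2
    iter_max: int = 100
    lower: Sequence[float] | float = -1.0
    upper: Sequence[float] | float = 1.0
    p_alarm: float = 0.5
    lam: float = 0.5
    x1: float = 1.0 / 3.0
    x2: float = 1.0 / 3.0
    x3: float = 1.0 / 3.0
    producer_fraction: float = 0.2
    seed: int = 0
    ssa_compat: bool = False
    enable_besiege: bool = True
    enable_perching: bool = True
    perch_producers_only: bool = False
    besiege: BesiegeParams = field(default_factory=BesiegeParams)

    @property
    def lb(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.lower, dtype=float), (self.s,)).copy()

    @property
    def ub(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.upper, dtype=float), (self.s,)).copy()

    @property
    def n_producers(self) -> int:
        return min(self.l, max(1, int(round(self.producer_fraction * self.l))))

    def validate(self) -> None:
        if self.l < 1 or self.s < 1:
            raise ValueError("population size and dimension must be >= 1")
        if self.iter_max < 0:
            raise ValueError("iter_max must be >= 0")
        lb, ub = self.lb, self.ub
        if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
            raise ValueError("bounds must be finite")
        if np.any(lb > ub):
            raise ValueError("lower bound exceeds upper bound")
        if not 0.0 < self.producer_fraction <= 1.0:
            raise ValueError("producer_fraction must lie in (0, 1]")
        if not 0.0 < self.p_alarm < 1.0:
            raise ValueError("p_alarm must lie in (0, 1)")
        self.besiege.validate()

    # -- flat key/value round-trip ------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["lower"] = self.lb.tolist()
        d["upper"] = self.ub.tolist()
        d["e0_range"] = list(d.pop("besiege")["e0_range"])
        d["v_max"] = self.besiege.v_max
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "FFOConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        bes = BesiegeParams(
            e0_range=tuple(d.pop("e0_range", (-1.0, 1.0))),
            v_max=d.pop("v_max", 2.0),
        )
        cfg = cls(besiege=bes, **d)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# per-individual random draws


@dataclass
class StageDraws:
    """One individual's random draws for one iteration.

    The sampling order in :meth:`sample` is the reproducibility contract:
    any consumer drawing from the same seeded generator in this order sees
    the same stream.
    """

    T: float
    z: float
    p: float
    beta: float  # in (0, 1]
    n_rand: float
    n1: float
    n2: float
    n3: float
    n4: float
    e0: float
    v: float
    q: float
    b: np.ndarray  # ±1 row vector, length s

    @classmethod
    def sample(
        cls,
        rng: np.random.Generator,
        s: int,
        e0_range: tuple[float, float] = (-1.0, 1.0),
        v_max: float = 2.0,
    ) -> "StageDraws":
        T = rng.random()
        z = rng.random()
        p = rng.random()
        beta = 1.0 - rng.random()  # (0, 1]: guards the Eq-15 exponent
        n_rand = rng.standard_normal()
        n1, n2, n3, n4 = rng.random(4)
        e0 = rng.uniform(*e0_range)
        v = rng.uniform(0.0, v_max)
        q = rng.standard_normal()
        b = np.where(rng.random(s) < 0.5, -1.0, 1.0)
        return cls(T, z, p, beta, n_rand, n1, n2, n3, n4, e0, v, q, b)


def pinv_sign_row(b: np.ndarray) -> np.ndarray:
    """Pseudo-inverse ``B⁺ = Bᵀ(BBᵀ)⁻¹`` of a ±1 row vector: entries b_j / s."""
    b = np.asarray(b, dtype=float)
    return b / b.size


# ---------------------------------------------------------------------------
# swarm container


@dataclass
class FinchSwarm:
    """Population state: positions sorted by fitness, global bookkeeping.

    After :func:`evaluate_fitness`, row ``r`` holds the individual of
    fitness rank ``r`` (0-based; ties keep their pre-sort order), so the
    producers are exactly the first ``n_producers`` rows.
    """

    positions: np.ndarray  # (l, s)
    fitnesses: np.ndarray  # (l,)
    best_position: np.ndarray
    best_fitness: float
    worst_position: np.ndarray
    worst_fitness: float
    iteration: int = 0
    evaluations: int = 0

    @property
    def l(self) -> int:
        return self.positions.shape[0]

    @property
    def s(self) -> int:
        return self.positions.shape[1]

    @property
    def mean_position(self) -> np.ndarray:
        """Column-wise arithmetic mean of the current positions (Y_avg)."""
        return self.positions.mean(axis=0)


def initialize_swarm(config: FFOConfig, rng: np.random.Generator) -> FinchSwarm:
    """Draw an l×s population uniformly within the box; fitnesses unevaluated."""
    config.validate()
    lb, ub = config.lb, config.ub
    positions = lb + (ub - lb) * rng.random((config.l, config.s))
    fitnesses = np.full(config.l, UNEVALUATED)
    return FinchSwarm(
        positions=positions,
        fitnesses=fitnesses,
        best_position=positions[0].copy(),
        best_fitness=UNEVALUATED,
        worst_position=positions[0].copy(),
        worst_fitness=-np.inf,
    )


def _safe_eval(objective: Objective, x: np.ndarray) -> float:
    val = float(objective(x))
    if not np.isfinite(val):
        logger.warning("objective returned non-finite value %r; assigning +inf", val)
        return np.inf
    return val


def evaluate_fitness(swarm: FinchSwarm, objective: Objective) -> FinchSwarm:
    """Evaluate all rows, sort by fitness (stable), refresh best/worst.

    The elitist best never worsens across calls; the worst reflects the
    current population only.
    """
    fits = np.empty(swarm.l)
    for r in range(swarm.l):
        fits[r] = _safe_eval(objective, swarm.positions[r])
    swarm.evaluations += swarm.l
    order = np.argsort(fits, kind="stable")
    swarm.positions = swarm.positions[order]
    swarm.fitnesses = fits[order]
    _refresh_best(swarm)
    _refresh_worst(swarm)
    return swarm


def _refresh_best(swarm: FinchSwarm) -> None:
    r = int(np.argmin(swarm.fitnesses))
    if swarm.fitnesses[r] <= swarm.best_fitness:
        swarm.best_fitness = float(swarm.fitnesses[r])
        swarm.best_position = swarm.positions[r].copy()


def _refresh_worst(swarm: FinchSwarm) -> None:
    r = int(np.argmax(np.where(np.isfinite(swarm.fitnesses), swarm.fitnesses, -np.inf)))
    swarm.worst_fitness = float(swarm.fitnesses[r])
    swarm.worst_position = swarm.positions[r].copy()


def _clip(x: np.ndarray, config: FFOConfig) -> np.ndarray:
    return np.clip(x, config.lb, config.ub)


# ---------------------------------------------------------------------------
# stage moves


def producer_update(
    position: np.ndarray, draws: StageDraws, config: FFOConfig
) -> np.ndarray:
    """Foraging move of a producer.

    Below the alarm threshold each component i (1-based) contracts by
    ``exp(-i / (beta * iter_max))``; at or above it the whole position takes
    a multiplicative standard-normal jump (or the additive sparrow-search
    original when ``ssa_compat`` is set).
    """
    y = np.asarray(position, dtype=float)
    s = y.size
    if draws.T < config.p_alarm:
        i = np.arange(1, s + 1, dtype=float)
        denom = draws.beta * max(config.iter_max, 1)
        new = y * np.exp(-i / denom)
    else:
        if config.ssa_compat:
            new = y + draws.n_rand
        else:
            new = y * draws.n_rand  # times the all-ones row M
    return _clip(new, config)


def scrounger_update(
    swarm: FinchSwarm, rank: int, draws: StageDraws, config: FFOConfig
) -> np.ndarray:
    """Accumulation move of a scrounger of 1-based fitness ``rank``.

    The worse (starving) half flies off following a normal draw scaled by
    ``exp((Y_worst - Y) / rank²)``; the better half moves to the optimum
    plus a signed spread ``|Y - Y_opt| · B⁺ · M``.
    """
    if rank < 1:
        raise IndexError("rank is 1-based and must be >= 1")
    y = swarm.positions[rank - 1]
    if rank > swarm.l / 2:  # starving
        new = draws.n_rand * np.exp((swarm.worst_position - y) / rank**2)
    else:
        spread = float(np.abs(y - swarm.best_position) @ pinv_sign_row(draws.b))
        new = swarm.best_position + spread  # times all-ones row M
    return _clip(new, config)


def _escape_energy(draws: StageDraws, iteration: int, iter_max: int) -> float:
    frac = iteration / iter_max if iter_max > 0 else 1.0
    return 2.0 * draws.e0 * (1.0 - min(frac, 1.0))


def soft_besiege_move(
    swarm: FinchSwarm, rank: int, draws: StageDraws, config: FFOConfig
) -> np.ndarray:
    """Soft besiege: the x1/x2/x3 mixture (starving) or the spread move."""
    y = swarm.positions[rank - 1]
    y_scr = best_scrounger_position(swarm, config)
    if rank > swarm.l / 2:
        kernel = draws.n_rand * np.exp((swarm.worst_position - y) / rank**2)
        new = (
            config.x1 * kernel
            + config.x2 * (y_scr - y)
            + config.x3 * (y - swarm.best_position)
        )
    else:
        spread = float(np.abs(y - swarm.best_position) @ pinv_sign_row(draws.b))
        new = swarm.best_position + spread
    return new


def soft_dive_move(
    swarm: FinchSwarm, rank: int, draws: StageDraws, config: FFOConfig
) -> np.ndarray:
    """Rapid progressive dive of the soft besiege."""
    y = swarm.positions[rank - 1]
    y_scr = best_scrounger_position(swarm, config)
    return 0.5 * (
        y_scr
        + draws.T * np.abs(draws.v * y_scr - y)
        + swarm.mean_position
        + config.lam * (y - swarm.best_position)
    )


def hard_besiege_move(
    swarm: FinchSwarm, rank: int, draws: StageDraws, config: FFOConfig
) -> np.ndarray:
    """Hard besiege: low-energy convergence toward the best scrounger."""
    y = swarm.positions[rank - 1]
    y_scr = best_scrounger_position(swarm, config)
    e = _escape_energy(draws, swarm.iteration, config.iter_max)
    denom = swarm.best_fitness - swarm.worst_fitness
    if not np.isfinite(denom) or abs(denom) < _DENOM_FLOOR:
        logger.debug("besiege fitness spread ~0; flooring denominator")
        denom = -_DENOM_FLOOR if denom <= 0 else _DENOM_FLOOR
    return 0.5 * (
        y_scr
        - e * np.abs(y_scr - y)
        + y
        + draws.q * (np.abs(y - swarm.worst_position) / denom)
    )


def hard_dive_move(
    swarm: FinchSwarm, rank: int, draws: StageDraws, config: FFOConfig
) -> np.ndarray:
    """Rapid progressive dive of the hard besiege."""
    y = swarm.positions[rank - 1]
    y_scr = best_scrounger_position(swarm, config)
    e = _escape_energy(draws, swarm.iteration, config.iter_max)
    return 0.5 * (
        y_scr
        + (1.0 + e * draws.v)
        + y * (config.lam - e)
        + swarm.mean_position
        - swarm.best_position
    )


def best_scrounger_position(swarm: FinchSwarm, config: FFOConfig) -> np.ndarray:
    """Position of the best-ranked scrounger (first non-producer row)."""
    idx = min(config.n_producers, swarm.l - 1)
    return swarm.positions[idx]


def besiege_update(
    swarm: FinchSwarm,
    rank: int,
    draws: StageDraws,
    config: FFOConfig,
    objective: Optional[Objective] = None,
) -> np.ndarray:
    """Soft (z >= 0.5) or hard (z < 0.5) besiege move for one scrounger.

    When ``objective`` is given, the corresponding rapid-dive move replaces
    the base move if (and only if) it has better fitness.
    """
    if draws.z >= 0.5:
        base = soft_besiege_move(swarm, rank, draws, config)
        dive = soft_dive_move(swarm, rank, draws, config)
    else:
        base = hard_besiege_move(swarm, rank, draws, config)
        dive = hard_dive_move(swarm, rank, draws, config)
    base = _clip(base, config)
    if objective is None:
        return base
    dive = _clip(dive, config)
    f_base = _safe_eval(objective, base)
    f_dive = _safe_eval(objective, dive)
    swarm.evaluations += 2
    return dive if f_dive < f_base else base


def perching_update(
    swarm: FinchSwarm, rank: int, draws: StageDraws, config: FFOConfig
) -> np.ndarray:
    """Perching move: blend with the falcon (current global best).

    Safe regime with the falcon near family (T below alarm, p >= 0.5):
    contract toward the falcon with an attack correction. Otherwise: mix a
    normal jump with attraction to the prey (the best) relative to the
    swarm mean, repelled from a random point of the box.
    """
    y = swarm.positions[rank - 1]
    s = y.size
    y_fal = swarm.best_position  # falcon == prey == global best
    if draws.T < config.p_alarm and draws.p >= 0.5:
        i = np.arange(1, s + 1, dtype=float)
        new = (
            0.5 * y * np.exp(-i / max(config.iter_max, 1))
            + 0.5 * y_fal
            - draws.n1 * np.abs(y_fal - 2.0 * draws.n2 * y)
        )
    else:
        lb, ub = config.lb, config.ub
        new = 0.5 * (y + draws.n_rand) + 0.5 * (
            y_fal - swarm.mean_position - draws.n3 * (lb + draws.n4 * (ub - lb))
        )
    return _clip(new, config)


# ---------------------------------------------------------------------------
# iteration and outer loop


def _greedy_accept(
    swarm: FinchSwarm, row: int, candidate: np.ndarray, objective: Objective
) -> None:
    f_new = _safe_eval(objective, candidate)
    swarm.evaluations += 1
    if f_new < swarm.fitnesses[row]:
        swarm.positions[row] = candidate
        swarm.fitnesses[row] = f_new


def step(
    swarm: FinchSwarm,
    objective: Objective,
    config: FFOConfig,
    rng: np.random.Generator,
) -> FinchSwarm:
    """One full iteration: foraging -> accumulation/besiege -> perching.

    Requires an evaluated swarm. Greedy acceptance after every stage keeps
    each individual's fitness non-increasing within the iteration, which
    makes the global best elitist. The global best is refreshed after each
    stage (scroungers chase the producers' updated optimum); the worst is
    the snapshot from the start of the iteration.
    """
    if not np.all(np.isfinite(swarm.fitnesses) | np.isinf(swarm.fitnesses)):
        raise ValueError("swarm must be evaluated before stepping")
    e0_range = config.besiege.e0_range
    v_max = config.besiege.v_max
    n_prod = config.n_producers

    for r in range(n_prod):
        d = StageDraws.sample(rng, config.s, e0_range, v_max)
        cand = producer_update(swarm.positions[r], d, config)
        _greedy_accept(swarm, r, cand, objective)
    _refresh_best(swarm)

    for r in range(n_prod, swarm.l):
        d = StageDraws.sample(rng, config.s, e0_range, v_max)
        if config.enable_besiege and d.T >= 0.5:
            cand = besiege_update(swarm, r + 1, d, config, objective)
        else:
            cand = scrounger_update(swarm, r + 1, d, config)
        _greedy_accept(swarm, r, cand, objective)
    _refresh_best(swarm)

    if config.enable_perching:
        rows = range(n_prod) if config.perch_producers_only else range(swarm.l)
        for r in rows:
            d = StageDraws.sample(rng, config.s, e0_range, v_max)
            cand = perching_update(swarm, r + 1, d, config)
            _greedy_accept(swarm, r, cand, objective)
        _refresh_best(swarm)

    order = np.argsort(swarm.fitnesses, kind="stable")
    swarm.positions = swarm.positions[order]
    swarm.fitnesses = swarm.fitnesses[order]
    _refresh_worst(swarm)
    swarm.iteration += 1
    return swarm


@dataclass
class OptimizationResult:
    """Outcome of a full run: elitist best plus per-iteration history."""

    best_position: np.ndarray
    best_fitness: float
    convergence_history: np.ndarray  # best fitness after each iteration
    evaluations: int
    seed: int
    config: FFOConfig

    def to_json(self, path) -> None:
        payload = {
            "best_position": self.best_position.tolist(),
            "best_fitness": self.best_fitness,
            "convergence_history": self.convergence_history.tolist(),
            "evaluations": self.evaluations,
            "seed": self.seed,
            "config": {
                **{
                    k: v
                    for k, v in asdict(self.config).items()
                    if k not in ("lower", "upper", "besiege")
                },
                "lower": self.config.lb.tolist(),
                "upper": self.config.ub.tolist(),
                "e0_range": list(self.config.besiege.e0_range),
                "v_max": self.config.besiege.v_max,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def history_to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "iteration": np.arange(1, len(self.convergence_history) + 1),
                "best_fitness": self.convergence_history,
            }
        ).to_csv(path, index=False)


def optimize(
    objective: Objective,
    config: FFOConfig,
    initial_guess: Optional[np.ndarray] = None,
) -> OptimizationResult:
    """Run the optimizer for ``iter_max`` iterations under ``config.seed``.

    ``initial_guess`` (if given) replaces the first initial individual, so
    the elitist best can never be worse than the guess.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    swarm = initialize_swarm(config, rng)
    if initial_guess is not None:
        guess = np.asarray(initial_guess, dtype=float)
        if guess.shape != (config.s,):
            raise ValueError(f"initial_guess must have shape ({config.s},)")
        swarm.positions[0] = _clip(guess, config)
    evaluate_fitness(swarm, objective)
    history = np.empty(config.iter_max)
    for k in range(config.iter_max):
        step(swarm, objective, config, rng)
        history[k] = swarm.best_fitness
    return OptimizationResult(
        best_position=swarm.best_position.copy(),
        best_fitness=swarm.best_fitness,
        convergence_history=history,
        evaluations=swarm.evaluations,
        seed=config.seed,
        config=config,
    )
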