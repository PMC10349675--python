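"""Global-best particle swarm optimization with an inertia weight.

Minimization convention. Velocity update:
``v' = w*v + R1*c1*(pbest - x) + R2*c2*(gbest - x)`` with per-dimension
uniform draws R1, R2; positions are clipped to the search box and the
velocity component is zeroed on any clipped dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np


@dataclass(frozen=True)
class PSOParams:
    bounds: tuple[tuple[float, float], ...]  # (lower, upper) per dimension
    c1: float = 2.0
    c2: float = 2.0
    w: float | None = None      # None = linear 0.9 -> 0.4 schedule
    w_start: float = 0.9
    w_end: float = 0.4
    swarm_size: int = 30
    max_iter: int = 200
    v_max_frac: float = 0.2     # v_max = frac * (upper - lower)

    def __post_init__(self) -> None:
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("c1 and c2 must be >= 0")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"invalid bound ({lo}, {hi})")
        if self.swarm_size < 1 or self.max_iter < 0:
            raise ValueError("swarm_size must be >= 1 and max_iter >= 0")

    @property
    def dim(self) -> int:
        return len(self.bounds)

    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])

    def v_max(self) -> np.ndarray:
        return self.v_max_frac * (self.upper() - self.lower())

    def inertia(self, iteration: int) -> float:
        """Inertia weight at a given (0-based) iteration."""
        if self.w is not None:
            return self.w
        if self.max_iter <= 1:
            return self.w_start
        frac = iteration / (self.max_iter - 1)
        return self.w_start + (self.w_end - self.w_start) * frac


@dataclass
class Particle:
    x: np.ndarray
    v: np.ndarray
    pbest_x: np.ndarray
    pbest_f: float


def update_velocity(particle: Particle, gbest_x: np.ndarray,
                    params: PSOParams, w: float,
                    r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """Inertia-weighted velocity update, clamped to +/- v_max."""
    if r1.shape != particle.x.shape or r2.shape != particle.x.shape:
        raise ValueError("R1/R2 draws must match the particle dimension")
    if gbest_x.shape != particle.x.shape:
        raise ValueError("gbest dimension mismatch")
    v_new = (w * particle.v
             + r1 * params.c1 * (particle.pbest_x - particle.x)
             + r2 * params.c2 * (gbest_x - particle.x))
    v_max = params.v_max()
    return np.clip(v_new, -v_max, v_max)


def update_position(particle: Particle, params: PSOParams) -> np.ndarray:
    """``x' = x + v`` clipped to bounds; velocity zeroed where clipped."""
    x_new = particle.x + particle.v
    lo, hi = params.lower(), params.upper()
    clipped = np.clip(x_new, lo, hi)
    particle.v = np.where(clipped != x_new, 0.0, particle.v)
    return clipped


@dataclass
class PSOResult:
    gbest_x: np.ndarray
    gbest_f: float
    history: list[float] = field(default_factory=list)
    n_evaluations: int = 0


def run_pso(objective: Callable[[np.ndarray], float], params: PSOParams,
            rng: np.random.Generator | int | None = None,
            init_positions: Sequence[np.ndarray] | None = None) -> PSOResult:
    """Minimize ``objective`` over the box; returns global best + history.

    ``init_positions`` may seed some or all particles (extra slots are
    filled uniformly at random); velocities always start at zero draws
    within +/- v_max.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lo, hi = params.lower(), params.upper()
    d = params.dim

    def evaluate(x: np.ndarray) -> float:
        f = float(objective(x))
        if not np.isfinite(f):
            raise ValueError(f"objective returned non-finite value at {x!r}")
        return f

    particles: list[Particle] = []
    n_eval = 0
    for k in range(params.swarm_size):
        if init_positions is not None and k < len(init_positions):
            x = np.clip(np.asarray(init_positions[k], dtype=float), lo, hi)
        else:
            x = rng.uniform(lo, hi, size=d)
        v = rng.uniform(-params.v_max(), params.v_max())
        f = evaluate(x)
        n_eval += 1
        particles.append(Particle(x=x, v=v, pbest_x=x.copy(), pbest_f=f))

    gbest = min(particles, key=lambda p: p.pbest_f)
    gbest_x, gbest_f = gbest.pbest_x.copy(), gbest.pbest_f
    history = [gbest_f]

    for it in range(params.max_iter):
        w = params.inertia(it)
        for p in particles:
            r1 = rng.uniform(size=d)
            r2 = rng.uniform(size=d)
            p.v = update_velocity(p, gbest_x, params, w, r1, r2)
            p.x = update_position(p, params)
            f = evaluate(p.x)
            n_eval += 1
            if f < p.pbest_f:
                p.pbest_f = f
                p.pbest_x = p.x.copy()
                if f < gbest_f:
                    gbest_f = f
                    gbest_x = p.x.copy()
        history.append(gbest_f)
    return PSOResult(gbest_x=gbest_x, gbest_f=gbest_f, history=history,
                     n_evaluations=n_eval)
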