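"""Stochastic cell-proliferation simulator with a fluctuating phenotype.

Each cell carries a phenotype ``y_t`` whose logarithm follows a discretized
Ornstein–Uhlenbeck process: given ``ln y_t``, the next state is drawn from

    Normal( mu + exp(-gamma*dt) * (ln y_t - mu),  sigma2 * (1 - exp(-2*gamma*dt)) ).

At every frame a cell divides with probability ``f(y_t) * dt``; on division
the two daughters start at the next frame from independent OU draws
conditioned on the mother's last state.  The default parameters give a
stationary log-normal phenotype with mean 1.0 and standard deviation 0.3,
a per-generation autocorrelation ``r_g = exp(-gamma / f0)`` of 0.8, frames
every 5 minutes and a 250-minute window from 100 ancestors.

Division-rate families:

``hill``      f(y) = fmax * y^n / (1 + y^n)       (n = 0: constant fmax/2)
``gaussian``  f(y) = f0 * (1 + s^-2 * exp(-(y-1)^2 / (2*(0.3 s)^2)))
``constant``  f(y) = f0

Each cell owns an RNG stream derived deterministically from the root seed,
the ancestor index and the cell's left/right path in its tree, so results
are independent of traversal order and bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import yaml

from .genealogy import CellRecord, LineageEnsemble

__all__ = ["SimulationConfig", "ou_step", "division_rate", "simulate_ensemble"]

_LN109 = math.log(1.09)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the proliferation model (times in minutes, rates in 1/h)."""

    dt: float = 5.0  # frame interval, min
    mu: float = -0.5 * _LN109  # stationary mean of ln y
    sigma2: float = _LN109  # stationary variance of ln y
    r_g: float | None = 0.8  # per-generation autocorrelation of ln y
    gamma: float | None = None  # OU reversion rate, 1/h; derived from r_g if None
    fitness_kind: str = "hill"  # hill | gaussian | constant
    fmax: float = 1.2  # maximal division rate (hill), 1/h
    hill_n: float = 0.0  # Hill coefficient
    f0: float = 0.6  # baseline division rate (gaussian/constant), 1/h
    s: float = 1.0  # width parameter of the gaussian rate
    N0: int = 100  # number of ancestor cells
    tau: float = 250.0  # window duration, min
    seed: int = 0
    gamma_h: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.gamma is not None:
            g = float(self.gamma)
        elif self.r_g is not None:
            if not 0 < self.r_g < 1:
                raise ValueError("r_g must lie in (0, 1)")
            # gamma = -0.6 ln(r_g) per hour: r_g is the autocorrelation of
            # ln y after one mean generation 1/f0 = (1/0.6) h
            g = -0.6 * math.log(self.r_g)
        else:
            raise ValueError("either gamma or r_g must be given")
        if g <= 0:
            raise ValueError("gamma must be positive")
        object.__setattr__(self, "gamma_h", g)
        if self.fitness_kind not in ("hill", "gaussian", "constant"):
            raise ValueError(f"unknown fitness_kind {self.fitness_kind!r}")
        if self.N0 < 1 or self.tau <= 0 or self.dt <= 0:
            raise ValueError("N0 >= 1 and tau, dt > 0 required")
        # the per-step division probability must be a probability
        fcap = {"hill": self.fmax, "gaussian": self.f0 * (1 + self.s**-2), "constant": self.f0}[
            self.fitness_kind
        ]
        if fcap * self.dt_h >= 1:
            raise ValueError("f(y)*dt reaches 1; decrease dt or the division rate")

    @property
    def dt_h(self) -> float:
        return self.dt / 60.0

    @property
    def tau_h(self) -> float:
        return self.tau / 60.0

    @property
    def n_steps(self) -> int:
        n = self.tau / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("tau must be a whole number of frames")
        return int(round(n))

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls) if f.init}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown simulator config key(s): {sorted(bad)}")
        return cls(**raw)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


def ou_step(ln_y: float, config: SimulationConfig, rng: np.random.Generator) -> float:
    """One OU transition of ln y over a frame interval."""
    a = math.exp(-config.gamma_h * config.dt_h)
    sd = math.sqrt(config.sigma2 * (1.0 - a * a))
    return config.mu + a * (ln_y - config.mu) + sd * rng.standard_normal()


def division_rate(y: float, config: SimulationConfig) -> float:
    """Instantaneous division rate f(y) in 1/h for the configured family."""
    if y <= 0:
        raise ValueError("phenotype y must be positive")
    if config.fitness_kind == "hill":
        yn = y**config.hill_n
        return config.fmax * yn / (1.0 + yn)
    if config.fitness_kind == "gaussian":
        return config.f0 * (
            1.0 + config.s**-2 * math.exp(-((y - 1.0) ** 2) / (2.0 * (0.3 * config.s) ** 2))
        )
    return config.f0


def _cell_rng(seed: int, ancestor: int, path: tuple[int, ...]) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(ancestor, *path))
    )


def simulate_ensemble(config: SimulationConfig) -> LineageEnsemble:
    """Simulate the branching process and return it as a lineage ensemble.

    The phenotype ``y_t`` is stored in the fluorescence channel of each
    cell's samples (cell size is the constant 1; the model has no size
    variable).  Ancestors start at ``t0 = 0`` with ``ln y`` drawn from the
    stationary normal; a division at frame step ``k`` ends the mother at
    frame ``k+1`` where both daughters start.  Divisions may land exactly on
    ``t1``, in which case the daughters are degenerate single-frame leaves.
    """
    n_steps = config.n_steps
    dt_h = config.dt_h
    times = dt_h * np.arange(n_steps + 1)
    t1 = float(times[-1])
    records: dict[str, CellRecord] = {}

    for anc in range(config.N0):
        # stack of cells to simulate: (path, birth step, initial ln y, own rng)
        root_rng = _cell_rng(config.seed, anc, ())
        ln_y0 = config.mu + math.sqrt(config.sigma2) * root_rng.standard_normal()
        stack: list[tuple[tuple[int, ...], int, float, np.random.Generator]] = [
            ((), 0, ln_y0, root_rng)
        ]
        while stack:
            path, k_birth, ln_y, rng = stack.pop()
            traj = [ln_y]
            k = k_birth
            divided = False
            while k < n_steps:
                y = math.exp(traj[-1])
                if rng.random() < division_rate(y, config) * dt_h:
                    divided = True
                    break
                traj.append(ou_step(traj[-1], config, rng))
                k += 1
            cid = f"a{anc}" + ("." + "".join(map(str, path)) if path else "")
            k_end = k + 1 if divided else n_steps
            y_arr = np.exp(traj)
            records[cid] = CellRecord(
                cell_id=cid,
                parent_id=(f"a{anc}" + ("." + "".join(map(str, path[:-1])) if path[:-1] else ""))
                if path
                else None,
                birth_time=times[k_birth],
                end_time=times[k_end] if divided else t1,
                fate="divided" if divided else "extant",
                samples=np.column_stack(
                    [times[k_birth : k_birth + len(traj)], np.ones(len(traj)), y_arr]
                ),
            )
            if divided:
                mother_ln_y = traj[-1]
                for branch in (0, 1):
                    child_path = path + (branch,)
                    child_rng = _cell_rng(config.seed, anc, child_path)
                    ln_child = ou_step(mother_ln_y, config, child_rng)
                    stack.append((child_path, k_end, ln_child, child_rng))

    return LineageEnsemble(records, t0=0.0, t1=t1)
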