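"""Exact stochastic simulation (Gillespie direct method).

Simulates the base IP/DP surface chains and their open extensions with
receptor synthesis and internalization.  The state vector tracks the
five species ``(R, L, M, D, P)`` -- free receptors, free ligands, bound
monomers, non-phosphorylated dimers (DP only) and phosphorylated
dimers.  In the base models ``R`` and ``L`` are redundant through
conservation and serve as an online invariant check.

Extended-model bookkeeping: internalizing a complex removes its ligand
from the surface pool (``recycle_ligand=False`` by default); free
receptors internalize at ``k_int``, monomers and non-phosphorylated
dimers at ``k_int``, phosphorylated dimers at ``q * k_int``, and new
free receptors appear at the constant rate ``k_syn`` (balance with the
basal receptor count requires ``k_syn = n_R * k_int``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import ModelKind, ModelSpec
from .params import KineticRates

SPECIES = ("R", "L", "M", "D", "P")


@dataclass(frozen=True)
class ReactionChannel:
    name: str
    change: np.ndarray                       # length-5 state-change vector
    propensity: Callable[[np.ndarray], float]


def reaction_channels(spec: ModelSpec, rates: KineticRates,
                      extended: bool = False,
                      recycle_ligand: bool = False) -> list[ReactionChannel]:
    """Reaction channels for the requested model variant."""
    kind = spec.kind
    ch: list[ReactionChannel] = []

    def add(name, dR=0, dL=0, dM=0, dD=0, dP=0, prop=None):
        ch.append(ReactionChannel(name, np.array([dR, dL, dM, dD, dP]), prop))

    add("bind", dR=-1, dL=-1, dM=+1,
        prop=lambda x: 2.0 * rates.alpha_plus * x[1] * x[0])
    add("unbind", dR=+1, dL=+1, dM=-1,
        prop=lambda x: rates.alpha_minus * x[2])
    if kind is ModelKind.IP:
        add("crosslink", dR=-1, dM=-1, dP=+1,
            prop=lambda x: rates.beta_plus * x[2] * x[0])
        add("dimer_dissoc", dR=+1, dM=+1, dP=-1,
            prop=lambda x: 2.0 * rates.beta_minus * x[4])
    else:
        add("crosslink", dR=-1, dM=-1, dD=+1,
            prop=lambda x: rates.beta_plus * x[2] * x[0])
        add("dimer_dissoc", dR=+1, dM=+1, dD=-1,
            prop=lambda x: 2.0 * rates.beta_minus * x[3])
        add("phosphorylate", dD=-1, dP=+1,
            prop=lambda x: rates.gamma_plus * x[3])
        add("dephosphorylate", dD=+1, dP=-1,
            prop=lambda x: rates.gamma_minus * x[4])
    if extended:
        dL_int = +1 if recycle_ligand else 0
        add("synthesis", dR=+1, prop=lambda x: rates.k_syn)
        add("int_R", dR=-1, prop=lambda x: rates.k_int * x[0])
        add("int_M", dM=-1, dL=dL_int, prop=lambda x: rates.k_int * x[2])
        if kind is ModelKind.DP:
            add("int_D", dD=-1, dL=dL_int, prop=lambda x: rates.k_int * x[3])
        add("int_P", dP=-1, dL=dL_int, prop=lambda x: rates.k_int_P * x[4])
    return ch


@dataclass(frozen=True)
class Trajectory:
    """One exact SSA sample path (event times and post-event states)."""

    times: np.ndarray = field(repr=False)    # strictly increasing, starts at 0
    states: np.ndarray = field(repr=False)   # (n_events+1, 5), row 0 = initial
    channels: tuple                          # channel index per event (-1 none)

    def sample(self, grid: np.ndarray) -> np.ndarray:
        """Piecewise-constant interpolation onto a time grid -> (len(grid), 5)."""
        idx = np.searchsorted(self.times, grid, side="right") - 1
        return self.states[np.clip(idx, 0, len(self.times) - 1)]


def initial_state(spec: ModelSpec) -> np.ndarray:
    return np.array([spec.n_R, spec.n_L, 0, 0, 0], dtype=np.int64)


def simulate(spec: ModelSpec, rates: KineticRates, t_max: float,
             seed=None, extended: bool = False,
             recycle_ligand: bool = False,
             stop_when: Callable[[np.ndarray], bool] | None = None) -> Trajectory:
    """Direct-method SSA trajectory over ``[0, t_max]``.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`; the
    trajectory is reproducible given the same seed and inputs.
    ``stop_when`` optionally halts the simulation early (e.g. a hitting
    time); the final recorded time is then the stopping event time.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if extended and rates.k_int > 0 and rates.k_syn == 0:
        raise ValueError("extended model with internalization needs k_syn "
                         "(basal balance: k_syn = n_R * k_int)")
    rng = np.random.default_rng(seed)
    channels = reaction_channels(spec, rates, extended=extended,
                                 recycle_ligand=recycle_ligand)
    changes = np.stack([c.change for c in channels])
    x = initial_state(spec)
    t = 0.0
    times = [0.0]
    states = [x.copy()]
    fired: list[int] = []
    props = np.empty(len(channels))
    while True:
        for k, c in enumerate(channels):
            props[k] = c.propensity(x)
        total = props.sum()
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t > t_max:
            break
        cum = np.cumsum(props)
        k = min(int(np.searchsorted(cum, rng.random() * total, side="right")),
                len(channels) - 1)
        x = x + changes[k]
        if x.min() < 0:
            raise AssertionError(
                f"channel {channels[k].name} drove a count negative: {x}")
        times.append(t)
        states.append(x.copy())
        fired.append(k)
        if stop_when is not None and stop_when(x):
            break
    return Trajectory(times=np.asarray(times),
                      states=np.stack(states),
                      channels=tuple(fired))


def hitting_time(spec: ModelSpec, rates: KineticRates, threshold: int,
                 t_max: float, seed=None) -> float:
    """First time the phosphorylated-dimer count reaches ``threshold``.

    Returns ``nan`` if the threshold is not reached before ``t_max``.
    """
    traj = simulate(spec, rates, t_max, seed=seed,
                    stop_when=lambda x: x[4] >= threshold)
    if traj.states[-1, 4] >= threshold:
        return float(traj.times[-1])
    return float("nan")


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Per-species mean and SD over replicates on a fixed time grid."""

    spec: ModelSpec
    replicates: int
    seed: int
    grid: np.ndarray = field(repr=False)
    mean: np.ndarray = field(repr=False)   # (len(grid), 5)
    sd: np.ndarray = field(repr=False)

    def species_mean(self, species: str) -> np.ndarray:
        return self.mean[:, SPECIES.index(species)]

    def species_sd(self, species: str) -> np.ndarray:
        return self.sd[:, SPECIES.index(species)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(SPECIES):
            for i, t in enumerate(self.grid):
                rows.append({"time_s": t, "species": name,
                             "mean": self.mean[i, j], "sd": self.sd[i, j]})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def ensemble_summary(spec: ModelSpec, rates: KineticRates, replicates: int,
                     t_max: float, grid_dt: float, seed: int = 0,
                     extended: bool = False,
                     recycle_ligand: bool = False) -> TrajectoryEnsemble:
    """Mean/SD time courses over independent replicates.

    Each replicate runs on its own RNG substream spawned from the master
    seed, so the ensemble is deterministic for fixed ``(seed, inputs)``
    and individual replicates are independent.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    grid = np.arange(0.0, t_max + 0.5 * grid_dt, grid_dt)
    streams = np.random.SeedSequence(seed).spawn(replicates)
    acc = np.zeros((len(grid), 5))
    acc2 = np.zeros((len(grid), 5))
    for ss in streams:
        traj = simulate(spec, rates, t_max, seed=ss, extended=extended,
                        recycle_ligand=recycle_ligand)
        vals = traj.sample(grid).astype(float)
        acc += vals
        acc2 += vals ** 2
    mean = acc / replicates
    var = np.maximum(acc2 / replicates - mean ** 2, 0.0)
    return TrajectoryEnsemble(spec=spec, replicates=replicates, seed=seed,
                              grid=grid, mean=mean, sd=np.sqrt(var))
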