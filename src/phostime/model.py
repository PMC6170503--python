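"""State-space enumeration and infinitesimal generators.

Two continuous-time Markov chain (CTMC) models of bivalent-ligand /
receptor-monomer binding on a cell-surface patch:

* **IP** (instantaneous phosphorylation): state ``(n1, n2)`` counts bound
  monomers ``M`` and phosphorylated bound dimers ``P``; dimers are
  phosphorylated the instant they form.
* **DP** (delayed phosphorylation): state ``(n1, n2, n3)`` counts bound
  monomers ``M``, non-phosphorylated dimers ``D`` and phosphorylated
  dimers ``P``; phosphorylation/de-phosphorylation are explicit
  reactions with rates ``gamma_plus`` / ``gamma_minus``.

Free receptor and ligand counts are implicit through conservation:
``R = n_R - M - 2*(D + P)`` and ``L = n_L - M - D - P``.

Grouping states by their phosphorylated-dimer count (the *level*) gives
each generator a block-tridiagonal, quasi-birth-and-death (QBD)
structure: a single reaction changes the level by at most one.  The
level choice means that making "at least N phosphorylated dimers"
absorbing truncates whole levels.

Mass-action transition rates, with ``fR`` / ``fL`` the free receptor and
ligand counts of the current state (the factors of 2 reflect the two
equivalent binding sites of the bivalent ligand):

====================  =============================  ============
reaction              rate                           level change
====================  =============================  ============
monomer binding       ``2*alpha_plus * fL * fR``     0
monomer unbinding     ``alpha_minus * n1``           0
cross-linking         ``beta_plus * n1 * fR``        +1 (IP) / 0 (DP)
dimer dissociation    ``2*beta_minus * n_dimer``     -1 (IP) / 0 (DP)
phosphorylation       ``gamma_plus * n2`` (DP)       +1
de-phosphorylation    ``gamma_minus * n3`` (DP)      -1
====================  =============================  ============
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .params import KineticRates


class ModelKind(str, enum.Enum):
    IP = "IP"
    DP = "DP"

    @classmethod
    def coerce(cls, value: "ModelKind | str") -> "ModelKind":
        if isinstance(value, cls):
            return value
        return cls(str(value).upper())


class Regime(str, enum.Enum):
    """Which of the three state-space cases the (n_R, n_L) pair falls in."""

    LIGAND_LIMITED = "2nL<=nR"        # 2*n_L <= n_R
    INTERMEDIATE = "nR<2nL<2nR"       # n_R < 2*n_L < 2*n_R
    RECEPTOR_LIMITED = "nR<=nL"       # n_R <= n_L


@dataclass(frozen=True)
class ModelSpec:
    """Model kind plus copy numbers on the analysed surface patch."""

    kind: ModelKind
    n_R: int
    n_L: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ModelKind.coerce(self.kind))
        if self.n_R < 1 or self.n_L < 1:
            raise ValueError("n_R and n_L must both be >= 1")

    @property
    def regime(self) -> Regime:
        if 2 * self.n_L <= self.n_R:
            return Regime.LIGAND_LIMITED
        if self.n_R <= self.n_L:
            return Regime.RECEPTOR_LIMITED
        return Regime.INTERMEDIATE

    @property
    def n_species(self) -> int:
        return 2 if self.kind is ModelKind.IP else 3


def _admissible(spec: ModelSpec, counts: tuple[int, ...]) -> bool:
    n1 = counts[0]
    dimers = sum(counts[1:])
    return (min(counts) >= 0
            and n1 + dimers <= spec.n_L
            and n1 + 2 * dimers <= spec.n_R)


@dataclass(frozen=True)
class StateSpace:
    """Ordered enumeration of the CTMC states with QBD level indexing.

    States are ordered level-major (ascending phosphorylated-dimer
    count); within a level, lexicographically by ``(n1, n2)``.  The
    ordering is deterministic and stable across runs.
    """

    spec: ModelSpec
    states: tuple[tuple[int, ...], ...]
    index: dict = field(repr=False)

    @classmethod
    def enumerate(cls, spec: ModelSpec) -> "StateSpace":
        """Enumerate all and only the admissible states of ``spec``.

        The constraint set ``n1 + dimers <= n_L`` and
        ``n1 + 2*dimers <= n_R`` covers all three (n_R, n_L) regimes
        simultaneously (whichever constraint binds is regime-dependent).
        """
        nL, nR = spec.n_L, spec.n_R
        out: list[tuple[int, ...]] = []
        if spec.kind is ModelKind.IP:
            for level in range(min(nL, nR // 2) + 1):
                for n1 in range(min(nL - level, nR - 2 * level) + 1):
                    out.append((n1, level))
        else:
            for level in range(min(nL, nR // 2) + 1):
                pairs = [(n1, n2)
                         for n1 in range(nL + 1) for n2 in range(nL + 1)
                         if _admissible(spec, (n1, n2, level))]
                out.extend((n1, n2, level) for n1, n2 in sorted(pairs))
        states = tuple(out)
        return cls(spec=spec, states=states,
                   index={s: i for i, s in enumerate(states)})

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[tuple[int, ...]]:
        return iter(self.states)

    def level_of(self, state: tuple[int, ...]) -> int:
        return state[-1]

    @property
    def levels(self) -> np.ndarray:
        """Level (phosphorylated-dimer count) of every state, in order."""
        return np.array([s[-1] for s in self.states], dtype=np.int64)

    @property
    def max_level(self) -> int:
        return int(self.levels.max())

    def level_slices(self) -> list[np.ndarray]:
        """Ordinal index arrays of each level, ascending."""
        lv = self.levels
        return [np.flatnonzero(lv == l) for l in range(self.max_level + 1)]

    def ordinal(self, state: tuple[int, ...]) -> int:
        return self.index[state]

    def free_counts(self, state: tuple[int, ...]) -> tuple[int, int]:
        """Free receptor and ligand counts ``(R, L)`` of ``state``."""
        n1 = state[0]
        dimers = sum(state[1:])
        return self.spec.n_R - n1 - 2 * dimers, self.spec.n_L - n1 - dimers

    def to_csv(self, path: str | Path) -> None:
        cols = ("n1", "n2") if self.spec.kind is ModelKind.IP else ("n1", "n2", "n3")
        lines = ["ordinal," + ",".join(cols) + ",level,phase"]
        phase = 0
        prev_level = 0
        for i, s in enumerate(self.states):
            level = s[-1]
            phase = phase + 1 if level == prev_level and i else 0
            prev_level = level
            lines.append(",".join(map(str, (i, *s, level, phase))))
        Path(path).write_text("\n".join(lines) + "\n")


def state_count(kind: ModelKind | str, n_L: int) -> int:
    """Closed-form state count in the ligand-limited regime (2*n_L <= n_R)."""
    kind = ModelKind.coerce(kind)
    if kind is ModelKind.IP:
        return (n_L + 1) * (n_L + 2) // 2
    return (n_L + 1) * (n_L + 2) * (n_L + 3) // 6


def _channels(spec: ModelSpec, state: tuple[int, ...]):
    """Yield ``(rate_name, combinatorial_coefficient, target_state)``.

    The generator is linear in every individual rate constant; the
    coefficient returned here multiplies that constant.
    """
    nR, nL = spec.n_R, spec.n_L
    if spec.kind is ModelKind.IP:
        n1, n2 = state
        fR, fL = nR - n1 - 2 * n2, nL - n1 - n2
        yield "alpha_plus", 2 * fL * fR, (n1 + 1, n2)
        yield "alpha_minus", n1, (n1 - 1, n2)
        yield "beta_plus", n1 * fR, (n1 - 1, n2 + 1)
        yield "beta_minus", 2 * n2, (n1 + 1, n2 - 1)
    else:
        n1, n2, n3 = state
        fR, fL = nR - n1 - 2 * (n2 + n3), nL - n1 - n2 - n3
        yield "alpha_plus", 2 * fL * fR, (n1 + 1, n2, n3)
        yield "alpha_minus", n1, (n1 - 1, n2, n3)
        yield "beta_plus", n1 * fR, (n1 - 1, n2 + 1, n3)
        yield "beta_minus", 2 * n2, (n1 + 1, n2 - 1, n3)
        yield "gamma_plus", n2, (n1, n2 - 1, n3 + 1)
        yield "gamma_minus", n3, (n1, n2 + 1, n3 - 1)


@dataclass(frozen=True)
class Generator:
    """Infinitesimal generator Q over a :class:`StateSpace`.

    ``matrix`` is sparse CSR with non-negative off-diagonal entries and
    zero row sums (diagonal = minus the off-diagonal row sum).
    """

    space: StateSpace
    rates: KineticRates
    matrix: sp.csr_matrix = field(repr=False)

    @property
    def spec(self) -> ModelSpec:
        return self.space.spec

    def level_blocks(self):
        """Dense per-level blocks ``(diag, up, down)`` of the QBD structure.

        ``diag[l]`` is the within-level block of level ``l``, ``up[l]``
        the block ``l -> l+1`` and ``down[l]`` the block ``l -> l-1``
        (``up[-1]`` and ``down[0]`` are ``None``).
        """
        slices = self.space.level_slices()
        A = self.matrix
        diag, up, down = [], [], []
        for l, rows in enumerate(slices):
            diag.append(A[np.ix_(rows, rows)].toarray())
            up.append(A[np.ix_(rows, slices[l + 1])].toarray()
                      if l + 1 < len(slices) else None)
            down.append(A[np.ix_(rows, slices[l - 1])].toarray()
                        if l > 0 else None)
        return diag, up, down

    def is_irreducible(self) -> bool:
        """True when the chain forms a single communicating class."""
        n_comp, _ = connected_components(self.matrix, directed=True,
                                         connection="strong")
        return n_comp == 1

    def to_coo_text(self, path: str | Path) -> None:
        """Write (row, col, rate) triplets, one per line, for debugging."""
        coo = self.matrix.tocoo()
        lines = [f"{i},{j},{v!r}" for i, j, v in zip(coo.row, coo.col, coo.data)]
        Path(path).write_text("\n".join(lines) + "\n")


def _rate_value(rates: KineticRates, name: str) -> float:
    return getattr(rates, name)


def _assemble(space: StateSpace, weight) -> sp.csr_matrix:
    """Assemble a generator-shaped matrix with per-rate weights.

    ``weight(rate_name)`` returns the scalar multiplying each reaction
    channel's combinatorial coefficient.  The diagonal is set to minus
    the row sum, so the result is a conservative generator whenever the
    weights are the actual rates, and a pattern matrix ``B_theta`` when
    the weight is an indicator.
    """
    rows, cols, vals = [], [], []
    for i, state in enumerate(space.states):
        for name, coeff, target in _channels(space.spec, state):
            w = weight(name)
            if coeff == 0 or w == 0.0:
                continue
            j = space.index.get(target)
            if j is None:
                continue
            rows.append(i)
            cols.append(j)
            vals.append(w * coeff)
    n = len(space)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    A = A - sp.diags(np.asarray(A.sum(axis=1)).ravel())
    return A.tocsr()


def build_generator(spec: ModelSpec, rates: KineticRates,
                    space: StateSpace | None = None) -> Generator:
    """Build the infinitesimal generator of the base IP or DP model.

    Raises
    ------
    ValueError
        If the DP model is requested with zero phosphorylation rate
        (the chain would be reducible: level 0 could never be left).
    """
    if space is None:
        space = StateSpace.enumerate(spec)
    if spec.kind is ModelKind.DP and rates.gamma_plus == 0.0:
        raise ValueError("DP model requires a positive gamma_plus rate")
    matrix = _assemble(space, lambda name: _rate_value(rates, name))
    return Generator(space=space, rates=rates, matrix=matrix)


def generator_derivative(spec: ModelSpec, rate_name: str,
                         space: StateSpace | None = None) -> sp.csr_matrix:
    """Pattern matrix ``B_theta = dQ/d theta`` for one kinetic rate.

    Because Q is linear in each rate constant, ``Q = sum_theta theta *
    B_theta`` exactly, and perturbing a single rate by ``delta`` changes
    Q by ``delta * B_theta``.  The diagonal of ``B_theta`` carries the
    derivative of the row-sum term.
    """
    valid = ({"alpha_plus", "alpha_minus", "beta_plus", "beta_minus"}
             if ModelKind.coerce(spec.kind) is ModelKind.IP else
             set(KineticRates.SENSITIVITY_RATES))
    if rate_name not in valid:
        raise KeyError(f"unknown rate {rate_name!r} for {spec.kind} model; "
                       f"valid: {sorted(valid)}")
    if space is None:
        space = StateSpace.enumerate(spec)
    return _assemble(space, lambda name: 1.0 if name == rate_name else 0.0)
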