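"""Stationary distribution of the base IP/DP chains.

The base chains are finite and irreducible, so the stationary
probability vector is the unique normalized solution of ``pi Q = 0``.
Two routes are provided: QBD level censoring (highest level censored
first) and a generic sparse direct solve in which one redundant balance
equation is replaced by the normalization constraint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .model import Generator, ModelKind
from . import qbd


@dataclass(frozen=True)
class StationaryDistribution:
    generator: Generator
    probabilities: np.ndarray = field(repr=False)

    @property
    def space(self):
        return self.generator.space

    def marginal(self, species: str) -> np.ndarray:
        """Exact marginal distribution of one species count.

        ``species`` is ``'M'``, ``'P'`` or (DP only) ``'D'``.  Entry
        ``k`` is the stationary probability of holding exactly ``k``
        copies.
        """
        kind = self.space.spec.kind
        pos = {"M": 0}
        if kind is ModelKind.IP:
            pos["P"] = 1
        else:
            pos.update({"D": 1, "P": 2})
        if species not in pos:
            raise KeyError(f"species {species!r} not tracked by the {kind} model")
        j = pos[species]
        counts = np.array([s[j] for s in self.space.states])
        out = np.zeros(counts.max() + 1)
        np.add.at(out, counts, self.probabilities)
        return out

    def mean(self, species: str) -> float:
        """Stationary mean copy number E_pi[species]."""
        m = self.marginal(species)
        return float(np.arange(len(m)) @ m)

    def means(self) -> dict:
        kind = self.space.spec.kind
        names = ("M", "P") if kind is ModelKind.IP else ("M", "D", "P")
        return {s: self.mean(s) for s in names}

    def residual(self) -> float:
        """Infinity-norm of pi Q (should be ~0)."""
        return float(np.abs(self.probabilities @ self.generator.matrix).max())

    def to_csv(self, path: str | Path) -> None:
        states = self.space.states
        cols = {"n1": [s[0] for s in states], "n2": [s[1] for s in states]}
        if self.space.spec.kind is ModelKind.DP:
            cols["n3"] = [s[2] for s in states]
        cols["probability"] = self.probabilities
        pd.DataFrame(cols).to_csv(path, index=False)

    def marginals_to_csv(self, path: str | Path) -> None:
        kind = self.space.spec.kind
        names = ("M", "P") if kind is ModelKind.IP else ("M", "D", "P")
        rows = []
        for s in names:
            for k, p in enumerate(self.marginal(s)):
                rows.append({"species": s, "count": k, "probability": p})
        pd.DataFrame(rows).to_csv(path, index=False)

    def means_to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.means(), indent=2) + "\n")


def stationary_distribution(gen: Generator,
                            method: str = "qbd") -> StationaryDistribution:
    """Stationary probability vector of a base-model generator.

    ``method='qbd'`` censors levels top-down via
    :func:`phostime.qbd.censored_stationary`; ``method='sparse'``
    replaces the last balance equation with normalization and solves the
    transposed sparse system.
    """
    if gen.rates.k_int > 0 or gen.rates.k_syn > 0:
        raise ValueError("stationary analysis applies to the closed base "
                         "models only (k_int = k_syn = 0)")
    Q = gen.matrix
    n = Q.shape[0]
    if method == "sparse":
        M = Q.tolil(copy=True)
        M[:, n - 1] = 1.0
        e = np.zeros(n)
        e[n - 1] = 1.0
        pi = splu(sp.csc_matrix(M.T)).solve(e)
    elif method == "qbd":
        diag, up, down = gen.level_blocks()
        pi = qbd.censored_stationary(diag, up, down)
    else:
        raise ValueError(f"unknown method {method!r}; use 'qbd' or 'sparse'")
    pi = np.maximum(pi, 0.0)
    pi = pi / pi.sum()
    return StationaryDistribution(generator=gen, probabilities=pi)


def dimer_marginals(dist: StationaryDistribution) -> dict:
    """Marginal distributions of the dimer species (Fig 7-style summary)."""
    if dist.space.spec.kind is ModelKind.IP:
        return {"P": dist.marginal("P")}
    return {"D": dist.marginal("D"), "P": dist.marginal("P")}
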