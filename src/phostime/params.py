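"""Physiological parameters and kinetic rate containers.

The default physiological parameter set describes the VEGF-A / VEGFR2
system on a human umbilical vein endothelial cell (HUVEC): measured
biophysical constants (surface area, diffusion coefficients, receptor
radius, membrane thickness, equilibrium and dissociation constants,
phosphorylation rates) together with the fraction ``f`` of the cell
surface analysed and the total receptor count per cell.

Units are fixed internally to millimetres, seconds and moles; all
lengths are mm, areas mm^2, diffusion coefficients mm^2/s, volumetric
concentrations mol/mm^3.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

#: Avogadro's number (mol^-1), 2019 SI exact value.
AVOGADRO = 6.02214076e23

#: mol/mm^3 per picomolar (1 pM = 1e-12 mol/L = 1e-18 mol/mm^3).
MOL_PER_MM3_PER_PM = 1e-18


@dataclass(frozen=True)
class PhysiologicalParameters:
    """Measured biophysical constants of the receptor-ligand system.

    Attributes
    ----------
    s_c : float
        Cell surface area (mm^2).
    D_L : float
        Ligand diffusion coefficient in the medium (mm^2/s).
    D_R : float
        Receptor diffusion coefficient on the membrane (mm^2/s).  The
        bound-monomer diffusivity is assumed equal to ``D_R``.
    b : float
        Receptor radius (mm).
    delta : float
        Membrane thickness (mm); converts the intrinsic 3D binding rate
        into its 2D membrane analogue.
    h : float
        Characteristic length of the experimental volume (mm).
    k_off : float
        Ligand-receptor dissociation rate (1/s).
    K_d : float
        Equilibrium dissociation constant (mol/mm^3).
    gamma_plus, gamma_minus : float
        Phosphorylation and de-phosphorylation rates of bound dimers
        (1/s).  The defaults correspond to 0.22/min and 0.055/min.
    f : float
        Fraction of the cell surface analysed, 0 < f < 1.
    n_R_total : int
        Total number of receptors on the whole cell surface.
    """

    s_c: float = 1e-3
    D_L: float = 5.2e-5
    D_R: float = 1e-8
    b: float = 5e-7
    delta: float = 1e-4
    h: float = 1.0
    k_off: float = 1.32e-3
    K_d: float = 1.5e-16
    gamma_plus: float = 0.22 / 60.0
    gamma_minus: float = 0.055 / 60.0
    f: float = 0.04
    n_R_total: int = 5800

    def __post_init__(self) -> None:
        for name in ("s_c", "D_L", "D_R", "b", "delta", "h", "k_off", "K_d",
                     "gamma_plus", "gamma_minus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"physiological parameter {name!r} must be positive")
        if not 0.0 < self.f < 1.0:
            raise ValueError("surface fraction f must lie strictly in (0, 1)")
        if self.n_R_total < 1:
            raise ValueError("n_R_total must be a positive integer")

    @property
    def n_R(self) -> int:
        """Receptor count on the analysed surface patch, round(f * n_R_total)."""
        return int(round(self.f * self.n_R_total))

    def replace(self, **overrides) -> "PhysiologicalParameters":
        return dataclasses.replace(self, **overrides)

    @classmethod
    def from_file(cls, path: str | Path) -> "PhysiologicalParameters":
        """Load parameters from a flat key-value (YAML) config file.

        Unknown keys are rejected; missing keys fall back to defaults.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw is None:
            raw = {}
        if not isinstance(raw, Mapping):
            raise ValueError(f"config file {path} must contain a flat key-value mapping")
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "PhysiologicalParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}; "
                             f"valid keys are {sorted(known)}")
        kwargs = {k: (int(v) if k == "n_R_total" else float(v)) for k, v in raw.items()}
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class KineticRates:
    """Per-event stochastic rate constants of the surface reaction models.

    ``alpha`` rates govern bound-monomer formation/dissociation, ``beta``
    rates dimer cross-linking/dissociation and ``gamma`` rates
    phosphorylation/de-phosphorylation (used by the delayed-
    phosphorylation model only).  ``k_int``/``k_syn`` extend the base
    models with internalization and receptor synthesis (zero for the
    closed base models); ``q`` multiplies the internalization rate of
    phosphorylated dimers, ``k_int_P = q * k_int``.
    All rates in 1/s.
    """

    alpha_plus: float
    alpha_minus: float
    beta_plus: float
    beta_minus: float
    gamma_plus: float = 0.0
    gamma_minus: float = 0.0
    k_int: float = 0.0
    k_syn: float = 0.0
    q: float = 1.0

    #: names of the kinetic rates subject to sensitivity analysis
    SENSITIVITY_RATES = ("alpha_plus", "alpha_minus", "beta_plus",
                         "beta_minus", "gamma_plus", "gamma_minus")

    def __post_init__(self) -> None:
        for name in ("alpha_plus", "alpha_minus", "beta_plus", "beta_minus",
                     "gamma_plus", "gamma_minus", "k_int", "k_syn", "q"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name!r} must be non-negative")

    @property
    def k_int_P(self) -> float:
        """Internalization rate of phosphorylated dimers (1/s)."""
        return self.q * self.k_int

    def replace(self, **overrides) -> "KineticRates":
        return dataclasses.replace(self, **overrides)

    def scaled(self, c: float) -> "KineticRates":
        """All rates multiplied by ``c`` (a pure change of time unit)."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return KineticRates(
            alpha_plus=c * self.alpha_plus, alpha_minus=c * self.alpha_minus,
            beta_plus=c * self.beta_plus, beta_minus=c * self.beta_minus,
            gamma_plus=c * self.gamma_plus, gamma_minus=c * self.gamma_minus,
            k_int=c * self.k_int, k_syn=c * self.k_syn, q=self.q)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
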