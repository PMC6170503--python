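"""Physiological-to-kinetic rate estimation.

Maps measured biophysical constants to the per-event stochastic rates of
the surface CTMC models through the classical two-step (transport +
intrinsic reaction) picture of diffusion-limited receptor-ligand
binding:

1.  A ligand reaches the surface patch of radius ``r`` by 3D diffusion
    at transport rate ``k_dL = 4 pi D_L r`` and then reacts with a free
    receptor at intrinsic rate ``k+3D``; the observed per-receptor pair
    ``(q_on, q_off)`` composes the two steps in series,

        1/q_on = 1/k+3D + n_R/k_dL,
        q_off  = k_minus * k_dL / (k_dL + n_R * k+3D),

    with ``q_on = k_on / N_A`` and ``q_off = k_off`` fixed by the
    equilibrium constant ``K_d = k_off/k_on``.
2.  On the membrane, a free receptor reaches a bound monomer by 2D
    diffusion at ``k_dR = 2 pi (D_R + D_M) / log(w/b)`` (``w`` the
    radius of the per-receptor area disc, i.e. one-half the mean
    inter-receptor distance) and cross-links at the 2D intrinsic rate
    ``k+2D = k+3D / delta``; the composed cross-linking rates are

        k_c = k_dR * k+2D / (k_dR + k+2D),
        k_u = k_minus * k_dR / (k_dR + k+2D).

Finally the per-event CTMC rates are the area-normalized versions:
``alpha+ = q_on/(f s_c h)``, ``alpha- = q_off``, ``beta+ = k_c/(f s_c)``
and ``beta- = k_u``; phosphorylation rates pass through unchanged.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

from .params import AVOGADRO, MOL_PER_MM3_PER_PM, KineticRates, PhysiologicalParameters

#: concentration unit factors to mol/mm^3
_UNIT_TO_MOL_PER_MM3 = {
    "pM": MOL_PER_MM3_PER_PM,
    "nM": 1e3 * MOL_PER_MM3_PER_PM,
    "M": 1e12 * MOL_PER_MM3_PER_PM,
}

#: canonical concentration -> ligand-count pairs used throughout the
#: VEGF-A/VEGFR2 analyses (10 / 25 / 50 % of the 232 patch receptors).
CANONICAL_LIGAND_COUNTS = {1.0: 23, 2.5: 58, 5.0: 116}


class GeometryError(ValueError):
    """Receptor geometry inconsistent (e.g. receptors denser than their radius)."""


class TransportLimitError(ValueError):
    """Requested q_on unreachable: transport alone is slower than q_on."""


@dataclass(frozen=True)
class RateDerivation:
    """All intermediate quantities of the two-step rate derivation."""

    k_on: float        # mm^3 mol^-1 s^-1
    q_on: float        # mm^3 s^-1, per-receptor association constant
    q_off: float       # s^-1
    r: float           # mm, analysed-patch radius
    w: float           # mm, half mean inter-receptor distance
    k_dL: float        # mm^3 s^-1, ligand 3D transport rate
    k_dR: float        # mm^2 s^-1, receptor 2D transport rate
    k_plus_3D: float   # mm^3 s^-1, intrinsic 3D binding rate
    k_plus_2D: float   # mm^2 s^-1, intrinsic 2D binding rate
    k_minus: float     # s^-1, intrinsic dissociation rate
    k_c: float         # mm^2 s^-1, cross-linking rate
    k_u: float         # s^-1, cross-link dissociation rate
    n_R: int           # receptors on the analysed patch

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def derive_rates(phys: PhysiologicalParameters) -> tuple[RateDerivation, KineticRates]:
    """Derive the stochastic kinetic rates from physiological parameters.

    Raises
    ------
    TransportLimitError
        If ligand transport alone cannot sustain the observed ``q_on``
        (``1/q_on - n_R/k_dL <= 0``), i.e. the binding would have to be
        faster than diffusion allows.
    GeometryError
        If the per-receptor disc radius ``w`` does not exceed the
        receptor radius ``b``.
    """
    n_R = phys.n_R
    area = phys.f * phys.s_c
    r = math.sqrt(area / math.pi)
    k_dL = 4.0 * math.pi * phys.D_L * r
    k_on = phys.k_off / phys.K_d
    q_on = k_on / AVOGADRO
    q_off = phys.k_off
    inv_k3 = 1.0 / q_on - n_R / k_dL
    if inv_k3 <= 0:
        raise TransportLimitError(
            "ligand transport is rate limiting: 1/q_on - n_R/k_dL <= 0; "
            "no finite intrinsic rate k+3D reproduces q_on")
    k_plus_3D = 1.0 / inv_k3
    k_minus = q_off * (k_dL + n_R * k_plus_3D) / k_dL
    k_plus_2D = k_plus_3D / phys.delta
    w = math.sqrt(area / (math.pi * n_R))
    if w <= phys.b:
        raise GeometryError(
            f"half mean inter-receptor distance w={w:.3e} mm does not "
            f"exceed the receptor radius b={phys.b:.3e} mm")
    D = 2.0 * phys.D_R   # receptor + bound-monomer diffusivities, assumed equal
    k_dR = 2.0 * math.pi * D / math.log(w / phys.b)
    k_c = k_dR * k_plus_2D / (k_dR + k_plus_2D)
    k_u = k_minus * k_dR / (k_dR + k_plus_2D)
    derivation = RateDerivation(
        k_on=k_on, q_on=q_on, q_off=q_off, r=r, w=w, k_dL=k_dL, k_dR=k_dR,
        k_plus_3D=k_plus_3D, k_plus_2D=k_plus_2D, k_minus=k_minus,
        k_c=k_c, k_u=k_u, n_R=n_R)
    rates = KineticRates(
        alpha_plus=q_on / (area * phys.h),
        alpha_minus=q_off,
        beta_plus=k_c / area,
        beta_minus=k_u,
        gamma_plus=phys.gamma_plus,
        gamma_minus=phys.gamma_minus)
    return derivation, rates


def ligand_count_from_concentration(c_L: float, phys: PhysiologicalParameters,
                                    unit: str = "pM",
                                    use_lookup: bool = True) -> int:
    """Ligand count on the analysed volume for a molar concentration.

    ``n_L = round(c_L * N_A * f * s_c * h)`` with ``c_L`` converted to
    mol/mm^3.  The canonical pairs 1 pM -> 23, 2.5 pM -> 58 and
    5 pM -> 116 (10/25/50 % of the 232 patch receptors at the default
    parameters) take precedence over the formula when ``use_lookup`` is
    true and the parameters are at their defaults.
    """
    if c_L < 0:
        raise ValueError("concentration must be >= 0")
    try:
        factor = _UNIT_TO_MOL_PER_MM3[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}; "
                         f"use one of {sorted(_UNIT_TO_MOL_PER_MM3)}") from None
    c_pm = c_L * factor / MOL_PER_MM3_PER_PM
    if use_lookup and phys == PhysiologicalParameters():
        for key, n_L in CANONICAL_LIGAND_COUNTS.items():
            if math.isclose(c_pm, key, rel_tol=1e-9):
                return n_L
    volume = phys.f * phys.s_c * phys.h
    return int(round(c_L * factor * AVOGADRO * volume))
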