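"""Closed-form energetics of transient-dwell formation and proton transfer.

All energies are in units of kBT at 298 K. Three terms recur in the
bookkeeping of what powers a synthase-direction sub-step against the
F1-ATPase torque:

* elastic (torsional) energy of the rotor mismatch, U = kappa*theta^2/2;
* the free energy stored in the pKa gap between the proton input and
  output half-channels, U = ln(10) * dpKa per proton;
* the screened Coulomb attraction between the essential stator arginine
  and an unprotonated c-subunit carboxylate, U = |qi*qj| * 561 / (eps * r)
  with r in Angstroms and eps the local dielectric constant (2 for the
  lipid bilayer, up to 80 for bulk water).

The 561 kBT*Angstrom constant is e^2/(4 pi eps0) expressed in kBT at
298 K; it is exposed as a module constant (not a temperature-dependent
parameter) and cross-checked against CODATA values in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "COULOMB_CONSTANT_KBT_ANGSTROM",
    "DEFAULT_TORSIONAL_KAPPA",
    "TorsionalSpring",
    "CoulombPair",
    "EnergyLedger",
    "torsional_energy",
    "coulomb_energy",
    "pka_gap_energy",
    "build_ledger",
]

#: e^2 / (4 pi eps0) in kBT * Angstrom at 298 K.
COULOMB_CONSTANT_KBT_ANGSTROM = 561.0

#: Torsional spring constant of the E. coli rotor, kBT per radian^2.
DEFAULT_TORSIONAL_KAPPA = 12.6


@dataclass(frozen=True)
class TorsionalSpring:
    """Harmonic torsional spring; ``kappa`` in kBT/radian^2."""

    kappa: float = DEFAULT_TORSIONAL_KAPPA

    def __post_init__(self):
        if not self.kappa > 0:
            raise ValueError("kappa must be positive")

    def energy(self, theta_rad: float | None = None, theta_deg: float | None = None) -> float:
        if (theta_rad is None) == (theta_deg is None):
            raise ValueError("give exactly one of theta_rad or theta_deg")
        if theta_deg is not None:
            theta_rad = math.radians(theta_deg)
        return torsional_energy(self.kappa, theta_rad)


@dataclass(frozen=True)
class CoulombPair:
    """Two point charges screened by a uniform dielectric.

    ``qi``/``qj`` in elementary charges (signed), ``r`` in Angstroms,
    ``epsilon`` dimensionless (physically 2-80; accepted range 1-100).
    """

    qi: int
    qj: int
    r: float
    epsilon: float
    coulomb_constant: float = COULOMB_CONSTANT_KBT_ANGSTROM

    def __post_init__(self):
        if not self.r > 0:
            raise ValueError("separation r must be positive")
        if not 1.0 <= self.epsilon <= 100.0:
            raise ValueError("epsilon must lie in [1, 100]")


@dataclass(frozen=True)
class EnergyLedger:
    """Named energy components (kBT) with their rounded-then-summed total.

    ``total`` follows the convention of summing each component after
    rounding to ``rounding`` decimals; ``total_raw`` sums the unrounded
    values.
    """

    components: dict
    rounding: int
    total: float
    total_raw: float


def torsional_energy(kappa: float, theta_rad: float) -> float:
    """Elastic energy kappa*theta^2/2 (kBT) for a rotation of theta radians."""
    if not (math.isfinite(kappa) and math.isfinite(theta_rad)):
        raise ValueError("inputs must be finite")
    return 0.5 * kappa * theta_rad * theta_rad


def coulomb_energy(pair: CoulombPair) -> float:
    """Magnitude of the screened Coulomb interaction energy in kBT.

    U = |qi*qj| * coulomb_constant / (epsilon * r). The sign convention
    (attraction vs repulsion) is carried by the charge signs on the pair,
    not by the returned magnitude.
    """
    return abs(pair.qi * pair.qj) * pair.coulomb_constant / (pair.epsilon * pair.r)


def pka_gap_energy(delta_pka: float) -> float:
    """Free energy ln(10)*dpKa (kBT) of moving one proton across a pKa gap."""
    if delta_pka < 0:
        raise ValueError("delta_pka must be >= 0")
    return math.log(10.0) * delta_pka


def build_ledger(components: dict, rounding: int = 1) -> EnergyLedger:
    """Sum named energy components, rounding each before summation.

    Rounding each term to ``rounding`` decimals before adding matches how
    such ledgers are quoted term-by-term; the unrounded total is reported
    alongside.
    """
    if not components:
        raise ValueError("ledger needs at least one component")
    rounded = {k: round(float(v), rounding) for k, v in components.items()}
    return EnergyLedger(
        components=dict(components),
        rounding=rounding,
        total=round(sum(rounded.values()), rounding),
        total_raw=float(sum(float(v) for v in components.values())),
    )
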