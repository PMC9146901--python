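"""Total energy of a chain configuration.

Elastic energy is the sum of harmonic step energies over all base-pair
steps.  Screened electrostatics between base-pair centers uses a
Debye-Huckel term: each center carries the lumped effective charge of its
two phosphates (counterion-condensed to a fraction of the bare charge), and
pairs closer along the contour than an exclusion separation do not
interact (near-neighbor repulsion is already encoded in the elastic term).

    E_DH = sum_{|i-j| >= exclusion} q_eff^2 * l_B * exp(-kappa r_ij) / r_ij   [kT]

with l_B the Bjerrum length and kappa the inverse Debye length of the
monovalent salt solution, both computed from physical constants.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import constants as const

from .geometry import ChainPath, build_chain
from .potentials import PotentialSet

__all__ = [
    "ElectrostaticsParams",
    "EnergyBreakdown",
    "debye_huckel_energy",
    "chain_energy",
    "bjerrum_length",
    "debye_kappa",
]

#: cap (kT) substituted for a coincident-center pair so the optimizer backs off
CONTACT_CAP = 1e6


def bjerrum_length(epsilon: float = 78.5, temperature: float = 300.0) -> float:
    """Bjerrum length in angstroms at the given dielectric and temperature."""
    lb_m = const.e**2 / (
        4.0 * np.pi * const.epsilon_0 * epsilon * const.k * temperature
    )
    return lb_m * 1e10


def debye_kappa(
    ionic_strength: float, epsilon: float = 78.5, temperature: float = 300.0
) -> float:
    """Inverse Debye screening length (1/angstrom) of a 1:1 salt solution.

    kappa^2 = 8 pi l_B n with n the number density of each ion species;
    100 mM at 300 K and epsilon 78.5 gives kappa^-1 of about 9.6 A.
    """
    if ionic_strength <= 0:
        raise ValueError("ionic strength must be positive")
    n_per_A3 = const.N_A * ionic_strength * 1e-27  # mol/L -> 1/A^3
    lb = bjerrum_length(epsilon, temperature)
    return float(np.sqrt(8.0 * np.pi * lb * n_per_A3))


@dataclass
class ElectrostaticsParams:
    """Debye-Huckel parameters for the screened base-pair-center charges."""

    charge_per_phosphate: float = -0.24  # elementary charges after condensation
    phosphates_per_bp: int = 2  # both strands lumped at the bp center
    ionic_strength: float = 0.1  # mol/L monovalent salt
    epsilon: float = 78.5
    temperature: float = 300.0  # K
    exclusion: int = 11  # bp; pairs at contour separation >= this interact

    def __post_init__(self):
        if self.exclusion < 1:
            raise ValueError("exclusion separation must be >= 1 bp")

    @property
    def q_eff(self) -> float:
        return self.charge_per_phosphate * self.phosphates_per_bp

    @property
    def kappa(self) -> float:
        return debye_kappa(self.ionic_strength, self.epsilon, self.temperature)

    @property
    def bjerrum(self) -> float:
        return bjerrum_length(self.epsilon, self.temperature)


@dataclass
class EnergyBreakdown:
    """Elastic-per-step and electrostatic contributions, in kT."""

    elastic_per_step: np.ndarray
    electrostatic: float = 0.0
    contact_flag: bool = False

    @property
    def elastic(self) -> float:
        return float(np.sum(self.elastic_per_step))

    @property
    def total(self) -> float:
        return self.elastic + self.electrostatic


def _contour_separation(n: int, closed: bool) -> np.ndarray:
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    if closed:
        sep = np.minimum(sep, n - sep)
    return sep


def debye_huckel_pairs(
    origins: np.ndarray, ep: ElectrostaticsParams, closed: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index pairs (i, j), i<j, included in the DH sum, and their distances."""
    origins = np.asarray(origins, dtype=float)
    n = origins.shape[0]
    sep = _contour_separation(n, closed)
    ii, jj = np.where(np.triu(sep >= ep.exclusion))
    diff = origins[ii] - origins[jj]
    return ii, jj, np.linalg.norm(diff, axis=1)


def debye_huckel_energy(
    path: ChainPath | np.ndarray,
    ep: ElectrostaticsParams,
    closed: bool | None = None,
) -> float:
    """Screened Coulomb energy (kT) over included base-pair-center pairs."""
    if isinstance(path, ChainPath):
        origins = path.origins
        if closed is None:
            closed = path.closed
    else:
        origins = np.asarray(path, dtype=float)
        closed = bool(closed)
    _, _, r = debye_huckel_pairs(origins, ep, closed)
    pref = ep.q_eff**2 * ep.bjerrum
    kappa = ep.kappa
    with np.errstate(divide="ignore"):
        terms = np.where(r > 0, pref * np.exp(-kappa * r) / np.where(r > 0, r, 1.0), CONTACT_CAP)
    return float(np.sum(terms))


def chain_energy(
    steps: Sequence | np.ndarray,
    potentials: PotentialSet,
    sequence: str,
    ep: ElectrostaticsParams | None = None,
    closed: bool = True,
) -> EnergyBreakdown:
    """Elastic + electrostatic energy of a configuration.

    ``steps`` holds one row of six parameters per step (n steps for a
    closed chain over n bp, n-1 for an open chain).
    """
    arr = np.asarray(
        [s.as_array() if hasattr(s, "as_array") else s for s in steps], dtype=float
    ).reshape(-1, 6)
    n_steps = arr.shape[0]
    elastic = np.empty(n_steps)
    for i in range(n_steps):
        pot = potentials.potential_for_step(sequence, i, circular=closed)
        elastic[i] = pot.energy(arr[i])
    electro = 0.0
    contact = False
    if ep is not None:
        path = build_chain(sequence, arr, closed=closed)
        electro = debye_huckel_energy(path, ep, closed=closed)
        contact = electro >= CONTACT_CAP
    return EnergyBreakdown(elastic, electro, contact)
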