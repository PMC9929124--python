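"""Equilibrium site-occupancy frequencies of the colonization model.

With hierarchical displacement competition the equilibrium of the
patch-occupancy dynamics decouples rank by rank: the equilibrium frequency
of species ``i`` depends only on its own fecundity and on the frequencies of
the species that outcompete it.  A single forward pass over ranks therefore
yields the full equilibrium,

    p_i* = 1 - sum_{j<i} p_j* - (1/f_i) (sum_{j<i} f_j p_j* + m/q)

if that quantity is positive, and 0 otherwise.  A species can only attain a
positive frequency (even with all better competitors absent) when
``f_i > m/q``, the persistence floor.

This recursion is for the immigration-free model; equilibria under
immigration are obtained by long integration in :mod:`levinsfert.dynamics`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .tradeoff import FecundityProfile

__all__ = [
    "CommunityParams",
    "EquilibriumState",
    "solve_equilibrium",
    "persistence_floor",
    "first_persistent_index",
    "occupied_fraction",
]

logger = logging.getLogger(__name__)

# Frequencies below this are indistinguishable from 0 at double precision
# relative to any reported threshold (1e-5); zeroed to stop denormal noise
# from propagating through the running sums.
_ZERO_GUARD = 1e-15


@dataclass(frozen=True)
class CommunityParams:
    """Site-level rates shared by all species.

    Parameters
    ----------
    q : float
        Basal colonization rate: probability that a propagule reaches a
        site and attains the colony growth stage, ``0 < q <= 1``.
    m : float
        Extinction (disturbance) rate: probability per unit time that an
        occupied site is emptied, ``m > 0``.
    immigration : float
        External propagule inflow added to every species' dynamics
        (default 0; used only by the ODE integrator, never by the
        equilibrium recursion).
    """

    q: float
    m: float
    immigration: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.q <= 1:
            raise ValueError(f"q must be in (0, 1], got {self.q}")
        if not self.m > 0:
            raise ValueError(f"m must be > 0, got {self.m}")
        if self.immigration < 0:
            raise ValueError(f"immigration must be >= 0, got {self.immigration}")


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrium occupancy frequencies ``p_1*..p_n*`` with their inputs."""

    frequencies: np.ndarray
    profile: FecundityProfile
    params: CommunityParams

    @property
    def occupied_fraction(self) -> float:
        """Total fraction of occupied sites, the community biomass proxy."""
        return float(self.frequencies.sum())


def persistence_floor(params: CommunityParams) -> float:
    """Minimum fecundity ``m/q`` a species needs to persist alone."""
    return params.m / params.q


def first_persistent_index(
    profile: FecundityProfile, params: CommunityParams
) -> int | None:
    """Smallest competitive rank whose fecundity clears the persistence floor.

    Returns the 1-based rank of the best competitor that could maintain a
    population in the absence of superior species, or ``None`` if no species
    in the pool satisfies ``f_i > m/q``.
    """
    floor = persistence_floor(params)
    above = np.flatnonzero(profile.values > floor)
    return int(above[0]) + 1 if above.size else None


def solve_equilibrium(
    profile: FecundityProfile, params: CommunityParams
) -> EquilibriumState:
    """Solve for the equilibrium by a forward pass over competitive ranks.

    Species are visited in order of decreasing competitive ability; each is
    assigned the positive branch of the fixed-point expression or 0.  Only
    species already assigned a positive frequency contribute to the running
    sums (species at 0 contribute nothing in either sum).  The immigration
    rate in ``params`` is ignored: the recursion describes the closed
    community.

    Returns
    -------
    EquilibriumState
        Frequencies satisfying ``0 <= p_i* <= 1``, ``sum p_i* <= 1``, and
        ``p_i* = 0`` wherever ``f_i <= m/q``.
    """
    f = profile.values
    n = f.size
    floor = params.m / params.q
    p = np.zeros(n)
    sum_p = 0.0  # running sum of p_j* over persisting j < i
    sum_fp = 0.0  # running sum of f_j * p_j*
    for i in range(n):
        if f[i] <= 0:
            logger.debug("species %d has nonpositive fecundity; set to 0", i + 1)
            continue
        val = 1.0 - sum_p - (sum_fp + floor) / f[i]
        if val > _ZERO_GUARD:
            p[i] = val
            sum_p += val
            sum_fp += f[i] * val
    return EquilibriumState(frequencies=p, profile=profile, params=params)


def occupied_fraction(state: EquilibriumState) -> float:
    """Sum of occupancy frequencies (1 minus the empty-site frequency)."""
    return state.occupied_fraction
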