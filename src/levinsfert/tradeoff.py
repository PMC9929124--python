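"""Competition-fecundity trade-off functions.

Species are indexed by competitive rank ``i = 1..n`` where ``i = 1`` is the
best competitor.  The trade-off assigns each rank a reproductive rate

    f_i = alpha * (1 - exp(-beta*i/n)) / (1 + exp(-beta*i/n))
        = alpha * tanh(beta*i / (2*n)),

so competitively inferior species (large ``i``) are more fecund, saturating
towards the ceiling ``alpha``.  ``beta`` controls how fast fecundity
saturates along the rank axis.  Fertilization is modelled as a switch to a
trade-off with larger ``alpha`` (overall fecundity gain) and/or larger
``beta`` (stronger saturation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

__all__ = [
    "TradeoffParams",
    "FecundityProfile",
    "PRESETS",
    "fecundity_value",
    "build_profile",
    "preset_params",
    "preset_profile",
    "perturb_profile",
    "perturb_pair",
]

#: Named trade-off parameterizations: the unfertilized baseline ``f0`` and
#: two fertilization scenarios ``f1`` (strong saturation) and ``f2``
#: (slightly stronger saturation), all for an 80-species pool.
PRESETS: Mapping[str, tuple[float, float]] = {
    "f0": (2.0, 4.0),
    "f1": (3.0, 16.0),
    "f2": (3.0, 18.0),
}


@dataclass(frozen=True)
class TradeoffParams:
    """Parameters of the saturating competition-fecundity trade-off.

    Parameters
    ----------
    alpha : float
        Maximum fecundity (reproductive-rate ceiling), > 0.
    beta : float
        Magnitude of saturation along the competitive-rank axis
        (dimensionless), > 0.
    n : int
        Number of potential species in the pool, >= 1.
    """

    alpha: float
    beta: float
    n: int = 80

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"n must be a positive integer, got {self.n}")


@dataclass(frozen=True)
class FecundityProfile:
    """An ordered vector of reproductive rates ``f_1..f_n``.

    ``values[i-1]`` is the fecundity of the species with competitive rank
    ``i``.  Built unperturbed from :class:`TradeoffParams` the vector is
    strictly increasing and bounded by ``alpha``; perturbed profiles may
    violate monotonicity and downstream code must not assume sortedness.

    ``provenance`` records how the profile was built (parameters, seed and
    multipliers of any perturbation) so that runs are reproducible.
    """

    values: np.ndarray
    provenance: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("values must be a non-empty 1-D vector")
        if not np.all(v > 0):
            raise ValueError("all fecundities must be strictly positive")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n


def fecundity_value(i: int, params: TradeoffParams) -> float:
    """Fecundity of the species with competitive rank ``i``.

    ``i = 0`` is accepted for limit checks and yields 0; species ranks are
    otherwise 1-based.
    """
    if i < 0 or i > params.n:
        raise ValueError(f"species index {i} outside [0, {params.n}]")
    # tanh form of alpha*(1-e^(-b i/n))/(1+e^(-b i/n)); identical, stabler.
    return float(params.alpha * np.tanh(params.beta * i / (2.0 * params.n)))


def build_profile(params: TradeoffParams) -> FecundityProfile:
    """Evaluate the trade-off at every rank ``i = 1..n``."""
    i = np.arange(1, params.n + 1, dtype=float)
    values = params.alpha * np.tanh(params.beta * i / (2.0 * params.n))
    prov = {"kind": "tradeoff", "alpha": params.alpha, "beta": params.beta,
            "n": params.n}
    return FecundityProfile(values=values, provenance=prov)


def preset_params(name: str, n: int = 80) -> TradeoffParams:
    """Look up a named trade-off (``f0``, ``f1`` or ``f2``)."""
    try:
        alpha, beta = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
    return TradeoffParams(alpha=alpha, beta=beta, n=n)


def preset_profile(name: str, n: int = 80) -> FecundityProfile:
    profile = build_profile(preset_params(name, n=n))
    profile.provenance["preset"] = name  # type: ignore[index]
    return profile


def perturb_profile(
    profile: FecundityProfile,
    relative_magnitude: float,
    seed: int | np.random.Generator | None = None,
    multipliers: np.ndarray | None = None,
) -> FecundityProfile:
    """Multiply each fecundity by an independent uniform factor.

    Each species' rate is scaled by a draw from
    ``U[1 - relative_magnitude, 1 + relative_magnitude]``; the draws are
    deterministic given ``seed``.  Pass ``multipliers`` to reuse a previous
    draw (e.g. to apply identical fluctuations to a pre/post pair).

    Raises
    ------
    ValueError
        If ``relative_magnitude`` is not in ``[0, 1)`` (a magnitude >= 1
        could produce nonpositive fecundities).
    """
    if not 0 <= relative_magnitude < 1:
        raise ValueError(
            f"relative_magnitude must be in [0, 1), got {relative_magnitude}"
        )
    if multipliers is None:
        rng = np.random.default_rng(seed)
        multipliers = rng.uniform(
            1.0 - relative_magnitude, 1.0 + relative_magnitude, size=profile.n
        )
    else:
        multipliers = np.asarray(multipliers, dtype=float)
        if multipliers.shape != (profile.n,):
            raise ValueError("multipliers must match the profile length")
    prov = dict(profile.provenance)
    prov["perturbation"] = {
        "relative_magnitude": relative_magnitude,
        "seed": seed if isinstance(seed, (int, type(None))) else "generator",
        "multipliers": multipliers.tolist(),
    }
    return FecundityProfile(values=profile.values * multipliers, provenance=prov)


def perturb_pair(
    before: FecundityProfile,
    after: FecundityProfile,
    relative_magnitude: float,
    seed: int | None = None,
    share_multipliers: bool = False,
) -> tuple[FecundityProfile, FecundityProfile]:
    """Fluctuate a pre/post-fertilization pair of profiles.

    By default the two profiles get independent draws; with
    ``share_multipliers=True`` the same per-species factors are applied to
    both, modelling species-level fecundity quirks that persist through
    fertilization.
    """
    rng = np.random.default_rng(seed)
    pre = perturb_profile(before, relative_magnitude, seed=rng)
    if share_multipliers:
        mult = np.asarray(pre.provenance["perturbation"]["multipliers"])
        post = perturb_profile(after, relative_magnitude, multipliers=mult)
    else:
        post = perturb_profile(after, relative_magnitude, seed=rng)
    return pre, post
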