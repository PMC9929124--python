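"""Rank abundance diagrams (RADs) and labeled-SAD community comparisons.

A RAD lists the detectable species of a community ordered by decreasing
abundance.  Detection uses the 1e-5 exclusion threshold by default, applied
either to the raw site frequency (``convention="raw"``) or to the relative
abundance ``p_i / sum(p)`` (``convention="relative"``, the default).  Because
species keep their identity (their competitive rank), pre/post-treatment
RADs can be compared species by species: which appeared, which were lost,
and how the dominant ranks were reshuffled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_THRESHOLD",
    "RankAbundance",
    "CommunityComparison",
    "build_rad",
    "richness",
    "compare_communities",
    "rad_slope",
    "evenness",
]

DEFAULT_THRESHOLD = 1e-5


@dataclass(frozen=True)
class RankAbundance:
    """Detectable species sorted by decreasing abundance.

    ``species[r]`` is the 1-based competitive rank of the species holding
    abundance rank ``r + 1``; ``abundances`` is non-increasing and strictly
    above ``threshold`` minus detection (>= threshold).  Ties are broken in
    favour of the better competitor (smaller species index).
    """

    species: np.ndarray  # 1-based competitive indices, ordered by abundance
    abundances: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    convention: str = "relative"

    @property
    def entries(self) -> list[tuple[int, float]]:
        return [(int(s), float(a)) for s, a in zip(self.species, self.abundances)]

    @property
    def richness(self) -> int:
        return int(self.species.size)

    def rank_of(self, species_index: int) -> int | None:
        """1-based abundance rank of a species, or None if undetected."""
        hit = np.flatnonzero(self.species == species_index)
        return int(hit[0]) + 1 if hit.size else None

    def __len__(self) -> int:
        return self.richness


@dataclass(frozen=True)
class CommunityComparison:
    """Species bookkeeping between a pre- and post-treatment RAD.

    ``new``, ``lost`` and ``retained`` partition the union of the two
    detectable sets.  ``top_k_tracking`` maps each of the ``k`` most
    abundant pre-treatment species to its post-treatment abundance rank
    (``None`` if it dropped below the detection threshold).
    """

    before: RankAbundance
    after: RankAbundance
    new: frozenset[int]
    lost: frozenset[int]
    retained: frozenset[int]
    top_k_tracking: dict[int, int | None]
    k: int


def _detectable(frequencies: np.ndarray, threshold: float, convention: str
                ) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(frequencies, dtype=float)
    if np.any(p < 0):
        raise ValueError("frequencies must be nonnegative")
    if convention == "relative":
        total = p.sum()
        abundance = p / total if total > 0 else p
    elif convention == "raw":
        abundance = p
    else:
        raise ValueError(f"unknown convention {convention!r}")
    keep = np.flatnonzero(abundance >= threshold)
    return keep, abundance[keep]


def build_rad(
    frequencies: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    convention: str = "relative",
) -> RankAbundance:
    """Threshold and sort a frequency vector into a RAD.

    Species with abundance below ``threshold`` (under the chosen
    convention) are excluded; the rest are sorted by decreasing abundance,
    ties going to the smaller competitive index.
    """
    keep, abundance = _detectable(frequencies, threshold, convention)
    # stable sort on -abundance keeps index order within ties
    order = np.argsort(-abundance, kind="stable")
    return RankAbundance(
        species=keep[order] + 1,
        abundances=abundance[order],
        threshold=threshold,
        convention=convention,
    )


def richness(
    frequencies: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    convention: str = "relative",
) -> int:
    """Number of detectable species."""
    keep, _ = _detectable(frequencies, threshold, convention)
    return int(keep.size)


def compare_communities(
    before: np.ndarray,
    after: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    k: int = 8,
    convention: str = "relative",
) -> CommunityComparison:
    """Labeled-SAD comparison of two frequency vectors."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after vectors must have equal length")
    rad_before = build_rad(before, threshold, convention)
    rad_after = build_rad(after, threshold, convention)
    set_before = frozenset(int(s) for s in rad_before.species)
    set_after = frozenset(int(s) for s in rad_after.species)
    tracking = {
        int(s): rad_after.rank_of(int(s)) for s in rad_before.species[:k]
    }
    return CommunityComparison(
        before=rad_before,
        after=rad_after,
        new=set_after - set_before,
        lost=set_before - set_after,
        retained=set_before & set_after,
        top_k_tracking=tracking,
        k=k,
    )


def rad_slope(rad: RankAbundance) -> float:
    """Least-squares slope of log10(abundance) against abundance rank.

    More negative means a steeper, less even RAD.  Undefined for fewer
    than two detectable species.
    """
    if rad.richness < 2:
        raise ValueError("RAD slope needs at least 2 detectable species")
    ranks = np.arange(1, rad.richness + 1, dtype=float)
    slope, _ = np.polyfit(ranks, np.log10(rad.abundances), 1)
    return float(slope)


def evenness(rad: RankAbundance) -> float:
    """Pielou-style evenness of the detectable abundances.

    Shannon entropy of the normalized detectable abundances divided by
    ``log(richness)``; 1 for a perfectly even community.
    """
    if rad.richness < 2:
        raise ValueError("evenness needs at least 2 detectable species")
    w = rad.abundances / rad.abundances.sum()
    h = -np.sum(w * np.log(w))
    return float(h / np.log(rad.richness))
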