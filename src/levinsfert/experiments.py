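"""End-to-end computational experiments: fertilization scenarios, parameter
sweeps, the alpha/beta decomposition and trade-off fluctuation robustness.

A *fertilization scenario* assembles a community under a baseline trade-off,
switches to a fertilized trade-off at a scheduled time, and records the
equilibria, the transient trajectory (with a small immigration term so every
species can respond), snapshot RADs during the transition, and the
richness/biomass time series.  The sweep maps equilibrium richness and
occupied fraction over a grid of trade-off parameters; the decomposition
separates the effect of raising the fecundity ceiling (alpha) from
intensifying saturation (beta); the fluctuation experiment checks robustness
of the fertilization trends to ±5% species-level noise in the trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import SimulationSchedule, Trajectory, simulate
from .equilibrium import CommunityParams, EquilibriumState, solve_equilibrium
from .rad import (
    DEFAULT_THRESHOLD,
    CommunityComparison,
    RankAbundance,
    build_rad,
    compare_communities,
    evenness,
    rad_slope,
    richness,
)
from .tradeoff import (
    FecundityProfile,
    TradeoffParams,
    build_profile,
    perturb_pair,
    preset_profile,
)

__all__ = [
    "ScenarioConfig",
    "ScenarioBundle",
    "SweepConfig",
    "SweepResult",
    "DecompositionResult",
    "FluctuationResult",
    "run_fertilization_scenario",
    "sweep_alpha_beta",
    "decomposition_experiment",
    "fluctuation_experiment",
]


def _as_profile(spec: str | TradeoffParams | FecundityProfile, n: int
                ) -> FecundityProfile:
    if isinstance(spec, FecundityProfile):
        return spec
    if isinstance(spec, TradeoffParams):
        return build_profile(spec)
    return preset_profile(spec, n=n)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a fertilization scenario; defaults are the standard run
    (n=80 species, q=0.3, m=0.2, immigration 1e-10, fertilization at
    t=10,000, horizon 90,000, 1e-5 detection threshold, top-8 tracking)."""

    before: str | TradeoffParams | FecundityProfile = "f0"
    after: str | TradeoffParams | FecundityProfile = "f1"
    n: int = 80
    q: float = 0.3
    m: float = 0.2
    immigration: float = 1e-10
    switch_time: float = 10_000.0
    end_time: float = 90_000.0
    snapshot_interval: float = 1_000.0
    sample_interval: float = 100.0
    threshold: float = DEFAULT_THRESHOLD
    top_k: int = 8
    convention: str = "relative"
    initial_frequency: float = 1e-3
    seed: int | None = None

    @property
    def community_params(self) -> CommunityParams:
        return CommunityParams(q=self.q, m=self.m, immigration=self.immigration)

    def resolved(self) -> dict:
        """JSON-serializable copy of every resolved field."""
        def enc(v):
            if isinstance(v, TradeoffParams):
                return {"alpha": v.alpha, "beta": v.beta, "n": v.n}
            if isinstance(v, FecundityProfile):
                return dict(v.provenance) or {"kind": "explicit"}
            return v
        return {k: enc(getattr(self, k)) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class ScenarioBundle:
    """Everything one fertilization scenario produces."""

    config: ScenarioConfig
    profile_before: FecundityProfile
    profile_after: FecundityProfile
    eq_before: EquilibriumState
    eq_after: EquilibriumState
    rad_before: RankAbundance
    rad_after: RankAbundance
    comparison: CommunityComparison
    trajectory: Trajectory
    snapshots: dict[float, RankAbundance]
    timeseries: pd.DataFrame  # time, occupied_fraction, richness_{raw,relative}


def run_fertilization_scenario(config: ScenarioConfig) -> ScenarioBundle:
    """Run one fertilization experiment end to end.

    Computes the closed-community equilibria and their RAD comparison, then
    integrates the dynamics with immigration through the fertilization
    switch, taking a snapshot RAD every ``snapshot_interval`` after the
    switch and recording occupied fraction and richness (both threshold
    conventions) at every sample.
    """
    pf_before = _as_profile(config.before, config.n)
    pf_after = _as_profile(config.after, config.n)
    params = config.community_params

    eq_before = solve_equilibrium(pf_before, params)
    eq_after = solve_equilibrium(pf_after, params)
    rad_before = build_rad(eq_before.frequencies, config.threshold,
                           config.convention)
    rad_after = build_rad(eq_after.frequencies, config.threshold,
                          config.convention)
    comparison = compare_communities(
        eq_before.frequencies, eq_after.frequencies,
        threshold=config.threshold, k=config.top_k,
        convention=config.convention,
    )

    schedule = SimulationSchedule(
        profile_before=pf_before,
        profile_after=pf_after,
        switch_time=config.switch_time,
        end_time=config.end_time,
        sample_interval=config.sample_interval,
        initial_frequencies=np.full(config.n, config.initial_frequency),
    )
    traj = simulate(schedule, params)

    snapshots: dict[float, RankAbundance] = {}
    t_snap = config.switch_time + config.snapshot_interval
    while t_snap <= config.end_time + 1e-9:
        t_rec, state = traj.state_at(min(t_snap, config.end_time))
        snapshots[t_rec] = build_rad(state, config.threshold, config.convention)
        t_snap += config.snapshot_interval

    timeseries = pd.DataFrame({
        "time": traj.times,
        "occupied_fraction": traj.states.sum(axis=1),
        "richness_raw": [
            richness(s, config.threshold, "raw") for s in traj.states
        ],
        "richness_relative": [
            richness(s, config.threshold, "relative") for s in traj.states
        ],
    })

    return ScenarioBundle(
        config=config,
        profile_before=pf_before,
        profile_after=pf_after,
        eq_before=eq_before,
        eq_after=eq_after,
        rad_before=rad_before,
        rad_after=rad_after,
        comparison=comparison,
        trajectory=traj,
        snapshots=snapshots,
        timeseries=timeseries,
    )


@dataclass(frozen=True)
class SweepConfig:
    """Grid of trade-off parameters for the richness/biomass response
    surfaces.  The default grid brackets all preset values with margin."""

    alphas: np.ndarray = field(
        default_factory=lambda: np.linspace(1.5, 4.0, 26))
    betas: np.ndarray = field(
        default_factory=lambda: np.linspace(2.0, 24.0, 45))
    n: int = 80
    q: float = 0.3
    m: float = 0.2
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.alphas, dtype=float))
        b = np.atleast_1d(np.asarray(self.betas, dtype=float))
        if a.size == 0 or b.size == 0:
            raise ValueError("alpha/beta grids must be nonempty")
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("alpha/beta grid values must be positive")
        object.__setattr__(self, "alphas", a)
        object.__setattr__(self, "betas", b)


@dataclass(frozen=True)
class SweepResult:
    """Response surfaces over the (alpha, beta) grid.

    2-D arrays are indexed ``[alpha_index, beta_index]``, aligned with the
    input grids.  Richness is reported under both threshold conventions.
    """

    alphas: np.ndarray
    betas: np.ndarray
    richness_raw: np.ndarray
    richness_relative: np.ndarray
    biomass: np.ndarray
    config: SweepConfig

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: alpha, beta, richness (both), biomass."""
        aa, bb = np.meshgrid(self.alphas, self.betas, indexing="ij")
        return pd.DataFrame({
            "alpha": aa.ravel(),
            "beta": bb.ravel(),
            "richness_raw": self.richness_raw.ravel().astype(int),
            "richness_relative": self.richness_relative.ravel().astype(int),
            "biomass": self.biomass.ravel(),
        })


def sweep_alpha_beta(config: SweepConfig) -> SweepResult:
    """Equilibrium richness and occupied fraction over the parameter grid."""
    params = CommunityParams(q=config.q, m=config.m)
    shape = (config.alphas.size, config.betas.size)
    rich_raw = np.zeros(shape, dtype=int)
    rich_rel = np.zeros(shape, dtype=int)
    biomass = np.zeros(shape)
    for ia, alpha in enumerate(config.alphas):
        for ib, beta in enumerate(config.betas):
            profile = build_profile(TradeoffParams(alpha, beta, config.n))
            state = solve_equilibrium(profile, params)
            rich_raw[ia, ib] = richness(state.frequencies, config.threshold, "raw")
            rich_rel[ia, ib] = richness(
                state.frequencies, config.threshold, "relative")
            biomass[ia, ib] = state.occupied_fraction
    return SweepResult(config.alphas, config.betas, rich_raw, rich_rel,
                       biomass, config)


def _cell_summary(state: EquilibriumState, threshold: float, convention: str
                  ) -> dict:
    rad = build_rad(state.frequencies, threshold, convention)
    return {
        "richness": rad.richness,
        "slope": rad_slope(rad) if rad.richness >= 2 else np.nan,
        "evenness": evenness(rad) if rad.richness >= 2 else np.nan,
        "biomass": state.occupied_fraction,
    }


@dataclass(frozen=True)
class DecompositionResult:
    """Equilibria for the four (alpha, beta) combinations of a baseline and
    a fertilized trade-off, isolating each factor's contribution."""

    cells: dict[str, EquilibriumState]  # keys: base, alpha_only, beta_only, both
    rads: dict[str, RankAbundance]
    summary: pd.DataFrame  # one row per cell: richness, slope, evenness, biomass


def decomposition_experiment(
    base: TradeoffParams,
    fert: TradeoffParams,
    params: CommunityParams,
    threshold: float = DEFAULT_THRESHOLD,
    convention: str = "relative",
) -> DecompositionResult:
    """Factor the fertilization response into its alpha and beta parts.

    Solves the equilibrium for the baseline, the fertilized trade-off, and
    the two mixed cells (fertilized alpha with baseline beta and vice
    versa), so the richness/slope/evenness/biomass changes attributable to
    the fecundity increment and to the saturation increase can be compared.
    """
    n = base.n
    combos = {
        "base": TradeoffParams(base.alpha, base.beta, n),
        "alpha_only": TradeoffParams(fert.alpha, base.beta, n),
        "beta_only": TradeoffParams(base.alpha, fert.beta, n),
        "both": TradeoffParams(fert.alpha, fert.beta, n),
    }
    cells, rads, rows = {}, {}, []
    for name, tp in combos.items():
        state = solve_equilibrium(build_profile(tp), params)
        cells[name] = state
        rads[name] = build_rad(state.frequencies, threshold, convention)
        rows.append({"cell": name, "alpha": tp.alpha, "beta": tp.beta,
                     **_cell_summary(state, threshold, convention)})
    return DecompositionResult(cells, rads, pd.DataFrame(rows))


@dataclass(frozen=True)
class FluctuationResult:
    """Replicate table and summary of the trade-off fluctuation experiment."""

    replicates: pd.DataFrame
    summary: dict
    baseline: dict  # unperturbed before/after summaries


def fluctuation_experiment(
    before: str | TradeoffParams | FecundityProfile = "f0",
    after: str | TradeoffParams | FecundityProfile = "f1",
    magnitude: float = 0.05,
    replicates: int = 50,
    seed: int | None = None,
    params: CommunityParams | None = None,
    n: int = 80,
    threshold: float = DEFAULT_THRESHOLD,
    convention: str = "relative",
    share_multipliers: bool = False,
) -> FluctuationResult:
    """Robustness of the fertilization trends to species-level noise.

    Each replicate multiplies both trade-off curves by independent ±magnitude
    uniform factors per species, recomputes the pre/post equilibria, and
    records richness, slope, evenness and biomass.  The summary reports the
    medians and the fraction of replicates in which richness and evenness
    both decline after fertilization.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    params = params or CommunityParams(q=0.3, m=0.2)
    pf_before = _as_profile(before, n)
    pf_after = _as_profile(after, n)
    base_before = solve_equilibrium(pf_before, params)
    base_after = solve_equilibrium(pf_after, params)
    baseline = {
        "before": _cell_summary(base_before, threshold, convention),
        "after": _cell_summary(base_after, threshold, convention),
    }

    seeds = np.random.SeedSequence(seed).spawn(replicates)
    rows = []
    for r, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        pre = perturb_pair(pf_before, pf_after, magnitude,
                           seed=int(rng.integers(2**31)),
                           share_multipliers=share_multipliers)
        s_pre = _cell_summary(solve_equilibrium(pre[0], params),
                              threshold, convention)
        s_post = _cell_summary(solve_equilibrium(pre[1], params),
                               threshold, convention)
        rows.append({
            "replicate": r,
            **{f"{k}_before": v for k, v in s_pre.items()},
            **{f"{k}_after": v for k, v in s_post.items()},
            "richness_declines": s_post["richness"] < s_pre["richness"],
            "evenness_declines": s_post["evenness"] < s_pre["evenness"],
        })
    table = pd.DataFrame(rows)
    table["both_decline"] = (table["richness_declines"]
                             & table["evenness_declines"])
    summary = {
        "replicates": replicates,
        "magnitude": magnitude,
        "median_richness_before": float(table["richness_before"].median()),
        "median_richness_after": float(table["richness_after"].median()),
        "median_evenness_before": float(table["evenness_before"].median()),
        "median_evenness_after": float(table["evenness_after"].median()),
        "median_biomass_before": float(table["biomass_before"].median()),
        "median_biomass_after": float(table["biomass_after"].median()),
        "fraction_both_decline": float(table["both_decline"].mean()),
    }
    return FluctuationResult(replicates=table, summary=summary,
                             baseline=baseline)
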