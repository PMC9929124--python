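"""Continuous-time patch-occupancy dynamics with an optional fertilization event.

The frequency ``p_i`` of sites occupied by the ``i``-th ranked species obeys

    dp_i/dt = q f_i p_i (1 - sum_{j<=i} p_j)
            - q (sum_{j<i} f_j p_j) p_i
            - m p_i  (+ immigration),

i.e. colonization of sites not held by equal-or-better competitors, minus
displacement by superior colonizers, minus disturbance.  A fertilization
event swaps the fecundity profile at a scheduled time; the integration is
restarted there so the switch is exact.

Immigration (default form: a constant added to every derivative) rescues
species from complete extinction so that the whole pool can respond to
fertilization.  The alternative form scales the inflow by the sites
actually available to the species, ``eps * (1 - sum_{j<=i} p_j)``; at the
rates used here (1e-10) the two are numerically indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

from .equilibrium import CommunityParams
from .tradeoff import FecundityProfile

__all__ = ["SimulationSchedule", "Trajectory", "rate_of_change", "simulate"]

ImmigrationMode = Literal["additive", "available_sites"]


@dataclass(frozen=True)
class SimulationSchedule:
    """What to integrate: profiles, event time, horizon and sampling.

    ``initial_frequencies`` defaults to a uniform ``1e-3`` for every
    species — a sparse, even inoculum from which the pre-fertilization
    community assembles.  ``profile_after=None`` means no event: the run
    uses ``profile_before`` throughout.
    """

    profile_before: FecundityProfile
    profile_after: FecundityProfile | None = None
    switch_time: float = 10_000.0
    end_time: float = 90_000.0
    sample_interval: float = 100.0
    initial_frequencies: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.profile_after is not None:
            if self.profile_after.n != self.profile_before.n:
                raise ValueError("before/after profiles must have equal length")
            if not 0 <= self.switch_time <= self.end_time:
                raise ValueError("need 0 <= switch_time <= end_time")
        if not self.end_time > 0:
            raise ValueError("end_time must be > 0")
        if not self.sample_interval > 0:
            raise ValueError("sample_interval must be > 0")
        p0 = self.initial_frequencies
        if p0 is not None:
            p0 = np.asarray(p0, dtype=float)
            if p0.shape != (self.profile_before.n,):
                raise ValueError("initial_frequencies length must match profile")
            if np.any(p0 < 0) or p0.sum() > 1 + 1e-12:
                raise ValueError("initial frequencies must be >= 0 with sum <= 1")
            object.__setattr__(self, "initial_frequencies", p0)

    def initial_state(self, default: float = 1e-3) -> np.ndarray:
        if self.initial_frequencies is not None:
            return self.initial_frequencies.copy()
        return np.full(self.profile_before.n, default)


@dataclass(frozen=True)
class Trajectory:
    """Sampled states ``states[k] = p(times[k])`` of one simulation run."""

    times: np.ndarray
    states: np.ndarray
    schedule: SimulationSchedule
    params: CommunityParams

    def state_at(self, t: float) -> tuple[float, np.ndarray]:
        """State at the nearest recorded time at or before ``t``.

        Returns the ``(timestamp, frequencies)`` pair actually sampled, so
        callers can see how far from ``t`` the record is.  Exact at sample
        points.
        """
        if t < self.times[0] or t > self.times[-1] + 1e-9:
            raise ValueError(
                f"t={t} outside sampled range [{self.times[0]}, {self.times[-1]}]"
            )
        k = int(np.searchsorted(self.times, t + 1e-9) - 1)
        k = max(k, 0)
        return float(self.times[k]), self.states[k].copy()

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()


def rate_of_change(
    p: np.ndarray,
    profile: FecundityProfile,
    params: CommunityParams,
    immigration_mode: ImmigrationMode = "additive",
) -> np.ndarray:
    """Time derivatives ``dp_i/dt`` of the occupancy frequencies."""
    p = np.asarray(p, dtype=float)
    f = profile.values
    if p.shape != f.shape:
        raise ValueError(f"state length {p.shape} != profile length {f.shape}")
    cum_p = np.cumsum(p)  # sum_{j<=i} p_j
    cum_fp_below = np.cumsum(f * p) - f * p  # sum_{j<i} f_j p_j
    dp = params.q * f * p * (1.0 - cum_p) - params.q * cum_fp_below * p - params.m * p
    if params.immigration:
        if immigration_mode == "additive":
            dp += params.immigration
        elif immigration_mode == "available_sites":
            dp += params.immigration * (1.0 - cum_p)
        else:
            raise ValueError(f"unknown immigration mode {immigration_mode!r}")
    return dp


def _integrate_leg(
    f: np.ndarray,
    params: CommunityParams,
    immigration_mode: ImmigrationMode,
    t0: float,
    t1: float,
    p0: np.ndarray,
    t_eval: np.ndarray,
    method: str,
    rtol: float,
    atol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    q, m, eps = params.q, params.m, params.immigration

    def rhs(t: float, p: np.ndarray) -> np.ndarray:
        cum_p = np.cumsum(p)
        cum_fp_below = np.cumsum(f * p) - f * p
        dp = q * f * p * (1.0 - cum_p) - q * cum_fp_below * p - m * p
        if eps:
            dp = dp + (eps if immigration_mode == "additive" else eps * (1.0 - cum_p))
        return dp

    if t_eval.size == 0 or t_eval[-1] != t1:
        t_eval = np.append(t_eval, t1)  # always record the leg endpoint
    sol = solve_ivp(
        rhs, (t0, t1), p0, method=method, rtol=rtol, atol=atol, t_eval=t_eval
    )
    if not sol.success:
        reached = sol.t[-1] if sol.t.size else t0
        raise RuntimeError(
            f"integration failed at t={reached}: {sol.message}"
        )
    return sol.t, sol.y.T, sol.y[:, -1].copy()


def simulate(
    schedule: SimulationSchedule,
    params: CommunityParams,
    method: str = "LSODA",
    rtol: float = 1e-9,
    atol: float = 1e-13,
    immigration_mode: ImmigrationMode = "additive",
) -> Trajectory:
    """Integrate the occupancy dynamics over the schedule.

    Integrates with ``profile_before`` on ``[0, switch_time)`` and
    ``profile_after`` from ``switch_time`` on (restarting the integrator at
    the switch), sampling every ``sample_interval``.  Tolerances default
    tight enough to resolve frequencies near the 1e-10 immigration floor.
    Negative values (integrator noise) are clipped to 0 in the recorded
    samples and at the restart.

    Raises
    ------
    RuntimeError
        If the integrator fails; the message reports the time reached.
    """
    p0 = schedule.initial_state()
    t_end = schedule.end_time
    samples = np.arange(0.0, t_end + schedule.sample_interval / 2,
                        schedule.sample_interval)
    if samples[-1] < t_end:
        samples = np.append(samples, t_end)

    two_legs = (
        schedule.profile_after is not None
        and 0 < schedule.switch_time < t_end
    )
    if not two_legs:
        f = (schedule.profile_after.values
             if schedule.profile_after is not None and schedule.switch_time == 0
             else schedule.profile_before.values)
        t, y, _ = _integrate_leg(
            f, params, immigration_mode, 0.0, t_end, p0, samples,
            method, rtol, atol,
        )
        return Trajectory(t, np.clip(y, 0.0, None), schedule, params)

    t_sw = schedule.switch_time
    t1, y1, p_sw = _integrate_leg(
        schedule.profile_before.values, params, immigration_mode,
        0.0, t_sw, p0, samples[samples <= t_sw], method, rtol, atol,
    )
    p_sw = np.clip(p_sw, 0.0, None)
    t2, y2, _ = _integrate_leg(
        schedule.profile_after.values, params, immigration_mode,
        t_sw, t_end, p_sw, samples[samples > t_sw], method, rtol, atol,
    )
    times = np.concatenate([t1, t2])
    states = np.clip(np.vstack([y1, y2]), 0.0, None)
    return Trajectory(times, states, schedule, params)
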