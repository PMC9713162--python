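"""Three-state cohort model of surgical delay.

A cohort of mean age ``a`` starts in the *preoperative* state and is followed
in weekly cycles until age 100.  At the scheduled surgery week the surviving
preoperative occupancy moves to the *postoperative* state in full; each week
a state-specific death probability moves occupancy to the absorbing *dead*
state.  Comparing cumulative (quality-adjusted) life years between a 2-week
and a 52-week delay yields the health loss per 50 weeks of delay, which is
converted to loss per month (one month = 52/12 weeks).

Survival inputs are survival probabilities over a declared horizon (default
one year) converted to a constant weekly death probability; time-to-no-effect
parameters remove the survival and/or quality-of-life benefit of surgery for
delays at or beyond their threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConsistencyError, DomainError

HORIZON_AGE = 100.0
WEEKS_PER_YEAR = 52
WEEKS_PER_MONTH = 52.0 / 12.0

#: Delay grid (weeks): two weeks up to one year in ten-week intervals.
DELAY_GRID_WEEKS = (2, 12, 22, 32, 42, 52)

__all__ = [
    "SurgeryParams",
    "DelayScenario",
    "CohortTrace",
    "HealthOutcome",
    "DelayLossResult",
    "EffectiveParams",
    "weekly_death_prob",
    "effective_params",
    "run_cohort",
    "outcome_from_trace",
    "delay_loss",
    "scenario_grid",
    "cancellation_loss",
    "DELAY_GRID_WEEKS",
]


@dataclass(frozen=True)
class SurgeryParams:
    """The seven model inputs (plus metadata) for one surgical procedure.

    Parameters
    ----------
    surgery_id : str
        Short unique label used as the key everywhere.
    name : str
        Display name (never used as a key).
    mean_age : float
        Cohort age in years at model start, in [0, 100).
    surv_pre, surv_post : float
        Probability of surviving ``surv_horizon_years`` while awaiting
        surgery / after surgery, in (0, 1].
    qol_pre, qol_post : float
        Health-state utilities in [0, 1] (1 = full health, 0 = death).
    surv_horizon_years : float
        Horizon of the survival inputs in years (default 1).
    t_no_effect_surv, t_no_effect_qol : float or None
        Delay (weeks) at or beyond which surgery no longer confers its
        survival / quality-of-life benefit.  ``None`` means no limit.
    evidence : dict
        Parameter-name -> evidence class in {I, IIa, IIb, III}; metadata
        only, never used in computation.
    """

    surgery_id: str
    name: str
    mean_age: float
    surv_pre: float
    surv_post: float
    qol_pre: float
    qol_post: float
    surv_horizon_years: float = 1.0
    t_no_effect_surv: float | None = None
    t_no_effect_qol: float | None = None
    evidence: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.qol_pre <= 1.0 and 0.0 <= self.qol_post <= 1.0):
            raise DomainError(
                f"{self.surgery_id}: utilities must be in [0, 1] "
                f"(qol_pre={self.qol_pre}, qol_post={self.qol_post})"
            )
        if not (0.0 < self.surv_pre <= 1.0 and 0.0 < self.surv_post <= 1.0):
            raise DomainError(
                f"{self.surgery_id}: survival probabilities must be in (0, 1] "
                f"(surv_pre={self.surv_pre}, surv_post={self.surv_post})"
            )
        if not (0.0 <= self.mean_age < HORIZON_AGE):
            raise DomainError(
                f"{self.surgery_id}: mean_age must be in [0, 100), got {self.mean_age}"
            )
        if self.surv_horizon_years <= 0:
            raise DomainError(f"{self.surgery_id}: surv_horizon_years must be > 0")
        for label, t in (("t_no_effect_surv", self.t_no_effect_surv),
                         ("t_no_effect_qol", self.t_no_effect_qol)):
            if t is not None and t <= 0:
                raise DomainError(f"{self.surgery_id}: {label} must be > 0 when present")

    @property
    def n_cycles(self) -> int:
        """Whole weekly cycles from ``mean_age`` to age 100."""
        return int(math.floor(WEEKS_PER_YEAR * (HORIZON_AGE - self.mean_age) + 1e-9))


@dataclass(frozen=True)
class DelayScenario:
    """A delay of ``delay_weeks`` weeks, or definitive cancellation."""

    cancelled: bool = False
    delay_weeks: int = 0

    def __post_init__(self):
        if not self.cancelled and self.delay_weeks < 0:
            raise DomainError("delay_weeks must be non-negative")

    def validate_for(self, params: SurgeryParams) -> None:
        if not self.cancelled and self.delay_weeks > params.n_cycles:
            raise DomainError(
                f"delay of {self.delay_weeks} weeks exceeds the remaining "
                f"{params.n_cycles} weekly cycles to age 100 for "
                f"{params.surgery_id} (mean_age={params.mean_age})"
            )


@dataclass(frozen=True)
class EffectiveParams:
    """Weekly death probabilities and utilities applicable to each alive
    state under a given scenario, after the time-to-no-effect rule.

    With a constant-hazard conversion these do not vary over cycles; the
    object therefore carries one value per state, valid at every cycle.
    """

    p_die_pre: float
    p_die_post: float
    u_pre: float
    u_post: float


@dataclass(frozen=True)
class CohortTrace:
    """Weekly state-occupancy proportions from ``start_age`` to age 100.

    ``occupancy`` has shape (n_cycles + 1, 3) with columns
    (preoperative, postoperative, dead); row ``k`` is the state after
    ``k`` completed cycles, so row 0 is (1, 0, 0).
    """

    start_age: float
    occupancy: np.ndarray
    cycle_length: int = 1

    def validate(self) -> None:
        occ = self.occupancy
        if occ.ndim != 2 or occ.shape[1] != 3:
            raise ConsistencyError("occupancy must have shape (n+1, 3)")
        if np.any(occ < -1e-12):
            raise ConsistencyError("negative occupancy")
        if np.max(np.abs(occ.sum(axis=1) - 1.0)) > 1e-9:
            raise ConsistencyError("occupancy rows must sum to 1")
        if np.any(np.diff(occ[:, 2]) < -1e-12):
            raise ConsistencyError("dead-state occupancy must be non-decreasing")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1


@dataclass(frozen=True)
class HealthOutcome:
    """Expected undiscounted life years and QALYs to the age-100 horizon."""

    life_years: float
    qalys: float


@dataclass(frozen=True)
class DelayLossResult:
    """Health loss per month of surgical delay for one procedure."""

    surgery_id: str
    daly_per_month: float
    yll_per_month: float


@dataclass(frozen=True)
class CancellationLossResult:
    """Total (not per-month) health loss of definitive cancellation,
    relative to surgery after a two-week delay."""

    surgery_id: str
    daly_total: float
    yll_total: float


def weekly_death_prob(annual_survival: float, horizon_years: float = 1.0) -> float:
    """Convert a survival probability over ``horizon_years`` to a constant
    weekly death probability, ``1 - s**(1 / (52 * h))``.

    Raises
    ------
    DomainError
        If ``annual_survival`` is outside (0, 1] (a survival of 0 implies an
        infinite hazard) or the horizon is not positive.
    """
    if not (0.0 < annual_survival <= 1.0):
        raise DomainError(f"survival probability must be in (0, 1], got {annual_survival}")
    if horizon_years <= 0:
        raise DomainError("horizon must be positive")
    return 1.0 - annual_survival ** (1.0 / (WEEKS_PER_YEAR * horizon_years))


def effective_params(params: SurgeryParams, scenario: DelayScenario) -> EffectiveParams:
    """Per-cycle death probabilities and utilities under a scenario.

    Before surgery the pre-surgery values apply; after surgery the
    post-surgery values apply, except that a delay at or beyond
    ``t_no_effect_surv`` (``t_no_effect_qol``) replaces the post-surgery
    death probability (utility) with the pre-surgery one: the surgery came
    too late to confer that benefit.  A cancelled scenario behaves as an
    infinite delay (the post-state values are never reached).
    """
    scenario.validate_for(params)
    p_pre = weekly_death_prob(params.surv_pre, params.surv_horizon_years)
    p_post = weekly_death_prob(params.surv_post, params.surv_horizon_years)
    u_post = params.qol_post
    if scenario.cancelled:
        delay = math.inf
    else:
        delay = scenario.delay_weeks
    if params.t_no_effect_surv is not None and delay >= params.t_no_effect_surv:
        p_post = p_pre
    if params.t_no_effect_qol is not None and delay >= params.t_no_effect_qol:
        u_post = params.qol_pre
    return EffectiveParams(p_die_pre=p_pre, p_die_post=p_post,
                           u_pre=params.qol_pre, u_post=u_post)


def _weekly_schedule(params: SurgeryParams, scenario: DelayScenario):
    """Survival and utility applying during each of the ``n_cycles`` weeks,
    plus the surgery week index (``None`` when cancelled)."""
    eff = effective_params(params, scenario)
    n = params.n_cycles
    if scenario.cancelled:
        surv = np.full(n, 1.0 - eff.p_die_pre)
        util = np.full(n, eff.u_pre)
        return surv, util, None
    d = min(scenario.delay_weeks, n)
    surv = np.empty(n)
    surv[:d] = 1.0 - eff.p_die_pre
    surv[d:] = 1.0 - eff.p_die_post
    util = np.empty(n)
    util[:d] = eff.u_pre
    util[d:] = eff.u_post
    return surv, util, d


def run_cohort(params: SurgeryParams, scenario: DelayScenario) -> CohortTrace:
    """Simulate the cohort week by week from ``mean_age`` to age 100.

    The whole cohort starts preoperative; at week ``delay_weeks`` all
    surviving preoperative occupancy transitions to postoperative (no
    perioperative excess risk); cancelled scenarios never transition.
    """
    surv, _, d = _weekly_schedule(params, scenario)
    n = surv.shape[0]
    alive = np.empty(n + 1)
    alive[0] = 1.0
    np.cumprod(surv, out=alive[1:])
    occ = np.zeros((n + 1, 3))
    if d is None:
        occ[:, 0] = alive
    else:
        occ[:d, 0] = alive[:d]
        occ[d:, 1] = alive[d:]
    occ[:, 2] = 1.0 - alive
    trace = CohortTrace(start_age=params.mean_age, occupancy=occ)
    trace.validate()
    return trace


def _outcomes(params: SurgeryParams, scenario: DelayScenario) -> HealthOutcome:
    """Life years and QALYs without materialising the trace.

    Occupancy alive at the start of week ``k`` contributes 1/52 years for
    that week, weighted by the utility of the state occupied during it.
    """
    surv, util, _ = _weekly_schedule(params, scenario)
    n = surv.shape[0]
    if n == 0:
        return HealthOutcome(0.0, 0.0)
    alive = np.empty(n)
    alive[0] = 1.0
    np.cumprod(surv[:-1], out=alive[1:])
    life_years = float(alive.sum()) / WEEKS_PER_YEAR
    qalys = float(alive @ util) / WEEKS_PER_YEAR
    return HealthOutcome(life_years=life_years, qalys=qalys)


def outcome_from_trace(trace: CohortTrace, params: SurgeryParams,
                       scenario: DelayScenario) -> HealthOutcome:
    """Accumulate life years and QALYs from a trace produced by
    :func:`run_cohort` on the same ``(params, scenario)`` pair."""
    if trace.n_cycles != params.n_cycles:
        raise ConsistencyError(
            f"trace has {trace.n_cycles} cycles but params imply {params.n_cycles}"
        )
    eff = effective_params(params, scenario)
    occ = trace.occupancy[:-1]  # state at the start of each week
    life_years = float((occ[:, 0] + occ[:, 1]).sum()) / WEEKS_PER_YEAR
    qalys = float((occ[:, 0] * eff.u_pre + occ[:, 1] * eff.u_post).sum()) / WEEKS_PER_YEAR
    return HealthOutcome(life_years=life_years, qalys=qalys)


def delay_loss(params: SurgeryParams) -> DelayLossResult:
    """DALYs and life years lost per month of surgical delay.

    The expected outcome after a 52-week delay is compared with the outcome
    after a two-week delay; the difference is the loss per 50 weeks of
    delay, converted to a monthly loss with one month = 52/12 weeks.
    DALY loss is the QALY difference (disability weight = 1 - utility over a
    common horizon); YLL loss is the life-year difference.
    """
    early = _outcomes(params, DelayScenario(delay_weeks=2))
    late = _outcomes(params, DelayScenario(delay_weeks=52))
    factor = WEEKS_PER_MONTH / 50.0
    return DelayLossResult(
        surgery_id=params.surgery_id,
        daly_per_month=(early.qalys - late.qalys) * factor,
        yll_per_month=(early.life_years - late.life_years) * factor,
    )


def scenario_grid(params: SurgeryParams) -> list[DelayScenario]:
    """The reporting grid: delays of 2, 12, ..., 52 weeks plus cancellation."""
    scenarios = [DelayScenario(delay_weeks=d) for d in DELAY_GRID_WEEKS]
    for s in scenarios:
        s.validate_for(params)
    scenarios.append(DelayScenario(cancelled=True))
    return scenarios


def cancellation_loss(params: SurgeryParams) -> CancellationLossResult:
    """Total QALYs and life years lost by definitive cancellation, relative
    to surgery after a two-week delay.  Not a per-month quantity."""
    early = _outcomes(params, DelayScenario(delay_weeks=2))
    never = _outcomes(params, DelayScenario(cancelled=True))
    return CancellationLossResult(
        surgery_id=params.surgery_id,
        daly_total=early.qalys - never.qalys,
        yll_total=early.life_years - never.life_years,
    )


def with_qol(params: SurgeryParams, qol_pre: float, qol_post: float) -> SurgeryParams:
    """Copy of ``params`` with replaced utilities (used when swapping in
    alternative panel estimates)."""
    return replace(params, qol_pre=qol_pre, qol_post=qol_post)
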