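"""Probabilistic sensitivity analysis (PSA) and urgency ranking.

Each model input is given an uncertainty distribution — Beta for
probabilities and utilities, Gamma for positive durations, standard
practice in health-economic PSA — and the delay-loss model is re-evaluated
over repeated draws.  Per procedure the mean and the 2.5th/97.5th
percentiles of DALY/month and YLL/month summarise the draws, and procedures
are ranked by descending mean DALY/month (ties broken alphabetically by
``surgery_id``).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from . import model_core
from .errors import DomainError
from .model_core import SurgeryParams, delay_loss

__all__ = [
    "ParamUncertainty",
    "PSAConfig",
    "UrgencyResult",
    "beta_from_mean_bounds",
    "beta_from_mean_rse",
    "gamma_from_mean_rse",
    "sample_params",
    "run_psa",
    "rank_surgeries",
    "compare_rankings",
]

#: Parameters the PSA varies by default (mean_age is held fixed unless an
#: uncertainty spec names it).
DEFAULT_VARIED = ("surv_pre", "surv_post", "qol_pre", "qol_post",
                  "t_no_effect_surv", "t_no_effect_qol")


@dataclass(frozen=True)
class ParamUncertainty:
    """Uncertainty specification for one parameter.

    ``kind`` is one of:

    - ``"point"``  — no uncertainty, the deterministic value is used;
    - ``"rse"``    — relative standard error: sd = rse * mean;
    - ``"bounds"`` — 95% bounds (lo, hi) to which the distribution's
      2.5th/97.5th percentiles are fitted.
    """

    kind: str = "rse"
    rse: float = 0.1
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self):
        if self.kind not in ("point", "rse", "bounds"):
            raise DomainError(f"unknown uncertainty kind {self.kind!r}")
        if self.kind == "rse" and self.rse <= 0:
            raise DomainError("relative standard error must be > 0")
        if self.kind == "bounds" and (self.lo is None or self.hi is None):
            raise DomainError("bounds uncertainty requires lo and hi")


@dataclass(frozen=True)
class PSAConfig:
    """PSA run configuration.

    ``uncertainty`` maps parameter names (``surv_pre``, ``qol_post``,
    ``t_no_effect_surv``, ``mean_age``, ...) to :class:`ParamUncertainty`;
    unlisted varied parameters default to a relative standard error of
    ``default_rse``.
    """

    n_draws: int = 1000
    seed: int = 0
    default_rse: float = 0.1
    uncertainty: dict[str, ParamUncertainty] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_draws < 1:
            raise DomainError("n_draws must be >= 1")
        if self.default_rse <= 0:
            raise DomainError("default_rse must be > 0")

    def spec_for(self, param: str) -> ParamUncertainty:
        if param in self.uncertainty:
            return self.uncertainty[param]
        if param in DEFAULT_VARIED:
            return ParamUncertainty(kind="rse", rse=self.default_rse)
        return ParamUncertainty(kind="point")


@dataclass(frozen=True)
class UrgencyResult:
    """PSA summary for one procedure, with its 1-based urgency rank."""

    surgery_id: str
    daly_per_month_mean: float
    daly_ci: tuple[float, float]
    yll_per_month_mean: float
    yll_ci: tuple[float, float]
    rank: int = 0


# Cap on how concentrated / diffuse a fitted Beta may be (log10 of the
# concentration alpha+beta); 1e8 is numerically a point mass.
_LOG_KAPPA_RANGE = (-0.5, 8.0)

# A Beta with concentration below this is bimodally piled at 0 and 1; when a
# relative-SE request implies something more diffuse the sd is capped here
# instead of aborting (matters for utilities close to 1).
_MIN_KAPPA = 3.0


def beta_from_mean_bounds(mean: float, lo: float, hi: float) -> tuple[float, float] | None:
    """Fit Beta shape parameters with the given mean whose 2.5th/97.5th
    percentiles best match ``(lo, hi)`` (least squares on the two
    percentiles over the concentration).

    Returns ``None`` as a point-mass marker when ``lo == hi == mean``.
    """
    if not (0.0 <= lo <= hi <= 1.0):
        raise DomainError(f"bounds must satisfy 0 <= lo <= hi <= 1, got ({lo}, {hi})")
    if lo == hi == mean:
        return None
    if not (0.0 < mean < 1.0):
        raise DomainError(f"mean must be in (0, 1) for a Beta fit, got {mean}")
    if not (lo <= mean <= hi):
        raise DomainError(f"bounds ({lo}, {hi}) do not bracket the mean {mean}")

    def loss(log_kappa: float) -> float:
        kappa = 10.0 ** log_kappa
        a, b = mean * kappa, (1.0 - mean) * kappa
        q = stats.beta.ppf([0.025, 0.975], a, b)
        return float((q[0] - lo) ** 2 + (q[1] - hi) ** 2)

    res = optimize.minimize_scalar(loss, bounds=_LOG_KAPPA_RANGE, method="bounded",
                                   options={"xatol": 1e-10})
    kappa = 10.0 ** float(res.x)
    return mean * kappa, (1.0 - mean) * kappa


def beta_from_mean_rse(mean: float, rse: float) -> tuple[float, float] | None:
    """Beta shape parameters matching a mean and a relative standard error.

    For a Beta(a, b), var = m(1-m)/(kappa+1) with kappa = a+b, so
    kappa = m(1-m)/var - 1.  When the requested sd is infeasible or would
    leave kappa below 3 (a U-shaped pile-up at the endpoints), the sd is
    capped at the value giving kappa = 3.  Means of exactly 0 or 1 are
    point masses (no Beta has them).
    """
    if mean in (0.0, 1.0):
        return None
    if not (0.0 < mean < 1.0):
        raise DomainError(f"mean must be in [0, 1], got {mean}")
    var = (rse * mean) ** 2
    var_cap = mean * (1.0 - mean) / (_MIN_KAPPA + 1.0)
    var = min(var, var_cap)
    kappa = mean * (1.0 - mean) / var - 1.0
    return mean * kappa, (1.0 - mean) * kappa


def gamma_from_mean_rse(mean: float, rse: float) -> tuple[float, float]:
    """Gamma (shape, scale) matching a mean and relative standard error:
    shape = 1/rse**2, scale = mean * rse**2."""
    if mean <= 0:
        raise DomainError(f"Gamma mean must be > 0, got {mean}")
    shape = 1.0 / rse ** 2
    return shape, mean * rse ** 2


def _draw_beta(mean: float, spec: ParamUncertainty, rng: np.random.Generator) -> float:
    if spec.kind == "point":
        return mean
    if spec.kind == "bounds":
        shapes = beta_from_mean_bounds(mean, spec.lo, spec.hi)
    else:
        shapes = beta_from_mean_rse(mean, spec.rse)
    if shapes is None:
        return mean
    return float(rng.beta(*shapes))


def _draw_gamma(mean: float, spec: ParamUncertainty, rng: np.random.Generator) -> float:
    if spec.kind == "point":
        return mean
    if spec.kind == "bounds":
        # fit a Gamma by matching the mean and taking the rse implied by the
        # bound half-width relative to 1.96 sd
        sd = (spec.hi - spec.lo) / (2 * 1.96)
        rse = sd / mean if mean > 0 else 0.0
        if rse <= 0:
            return mean
    else:
        rse = spec.rse
    shape, scale = gamma_from_mean_rse(mean, rse)
    return float(rng.gamma(shape, scale))


def sample_params(params: SurgeryParams, config: PSAConfig,
                  rng: np.random.Generator) -> SurgeryParams:
    """One PSA draw of the input parameters.

    Survival probabilities and utilities are drawn from fitted Beta
    distributions, time-to-no-effect parameters from a Gamma matched to
    mean and relative SE; ``mean_age`` is held fixed unless the config
    names it.  Draws violating the type invariants are rejected and
    redrawn.
    """
    for _ in range(1000):
        kw: dict = {}
        for p in ("surv_pre", "surv_post", "qol_pre", "qol_post"):
            spec = config.spec_for(p)
            mean = getattr(params, p)
            if p.startswith("surv") and mean == 1.0 and spec.kind == "rse":
                kw[p] = mean  # survival of exactly 1 has no Beta; point mass
            else:
                kw[p] = _draw_beta(mean, spec, rng)
        for p in ("t_no_effect_surv", "t_no_effect_qol"):
            mean = getattr(params, p)
            if mean is not None:
                kw[p] = _draw_gamma(mean, config.spec_for(p), rng)
        age_spec = config.spec_for("mean_age")
        if age_spec.kind != "point" and params.mean_age > 0:
            kw["mean_age"] = _draw_gamma(params.mean_age, age_spec, rng)
        try:
            drawn = replace(params, **kw)
        except DomainError:
            continue  # e.g. an age draw beyond the horizon: reject, redraw
        if kw.get("surv_pre", 1.0) <= 0 or kw.get("surv_post", 1.0) <= 0:
            continue
        return drawn
    raise DomainError(
        f"{params.surgery_id}: could not draw parameters satisfying the "
        f"type invariants after 1000 attempts"
    )


def _stream_for(surgery_id: str, seed: int) -> np.random.Generator:
    """An independent, order-insensitive random stream per surgery, derived
    from the master seed and a stable hash of the surgery id."""
    digest = hashlib.sha256(surgery_id.encode("utf-8")).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def run_psa(params_table: list[SurgeryParams], config: PSAConfig) -> list[UrgencyResult]:
    """Run the PSA for every procedure and rank them.

    Per surgery: ``n_draws`` sampled parameter sets are pushed through
    :func:`surgdelay.model_core.delay_loss`; the mean and (2.5, 97.5)
    percentiles summarise DALY/month and YLL/month.  Ranks are assigned by
    descending mean DALY/month.
    """
    if not params_table:
        raise DomainError("params_table must be non-empty")
    results = []
    for params in params_table:
        rng = _stream_for(params.surgery_id, config.seed)
        daly = np.empty(config.n_draws)
        yll = np.empty(config.n_draws)
        for i in range(config.n_draws):
            loss = delay_loss(sample_params(params, config, rng))
            if not (np.isfinite(loss.daly_per_month) and np.isfinite(loss.yll_per_month)):
                raise ArithmeticError(
                    f"non-finite delay loss for surgery {params.surgery_id!r} "
                    f"at draw {i}"
                )
            daly[i] = loss.daly_per_month
            yll[i] = loss.yll_per_month
        d_lo, d_hi = np.percentile(daly, [2.5, 97.5])
        y_lo, y_hi = np.percentile(yll, [2.5, 97.5])

        def exact_mean(x: np.ndarray) -> float:
            # constant draws (point-mass PSA) must reproduce the
            # deterministic loss bit-exactly, so skip the averaging
            return float(x[0]) if x.min() == x.max() else float(x.mean())

        results.append(UrgencyResult(
            surgery_id=params.surgery_id,
            daly_per_month_mean=exact_mean(daly),
            daly_ci=(float(d_lo), float(d_hi)),
            yll_per_month_mean=exact_mean(yll),
            yll_ci=(float(y_lo), float(y_hi)),
        ))
    return rank_surgeries(results)


def rank_surgeries(results: list[UrgencyResult]) -> list[UrgencyResult]:
    """Order by descending mean DALY/month, ties broken by ``surgery_id``
    ascending, and assign 1-based ranks."""
    if not results:
        raise DomainError("results must be non-empty")
    ordered = sorted(results, key=lambda r: (-r.daly_per_month_mean, r.surgery_id))
    return [replace(r, rank=i + 1) for i, r in enumerate(ordered)]


def compare_rankings(ranks_a: dict[str, int], ranks_b: dict[str, int]) -> float:
    """Spearman's rank correlation between two urgency rankings over the
    same set of surgeries (average-rank tie handling)."""
    if set(ranks_a) != set(ranks_b):
        missing = set(ranks_a) ^ set(ranks_b)
        raise DomainError(f"rankings cover different surgeries: {sorted(missing)}")
    if len(ranks_a) < 2:
        raise DomainError("need at least two surgeries to correlate rankings")
    keys = sorted(ranks_a)
    a = [ranks_a[k] for k in keys]
    b = [ranks_b[k] for k in keys]
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def ranking_dict(results: list[UrgencyResult]) -> dict[str, int]:
    """surgery_id -> rank mapping from a ranked result list."""
    return {r.surgery_id: r.rank for r in results}


def deterministic_ranking(params_table: list[SurgeryParams]) -> list[UrgencyResult]:
    """Ranking from the deterministic model alone (no PSA): each mean is the
    deterministic delay loss and the intervals are degenerate."""
    results = []
    for p in params_table:
        loss = model_core.delay_loss(p)
        results.append(UrgencyResult(
            surgery_id=p.surgery_id,
            daly_per_month_mean=loss.daly_per_month,
            daly_ci=(loss.daly_per_month, loss.daly_per_month),
            yll_per_month_mean=loss.yll_per_month,
            yll_ci=(loss.yll_per_month, loss.yll_per_month),
        ))
    return rank_surgeries(results)
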