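"""Delphi quality-of-life elicitation and two-panel validation.

Experts rate each surgery's pre- and postoperative health state on a 0-100
visual analogue scale (VAS) over two rounds, with the group median and
interquartile range fed back between rounds.  VAS scores map linearly to
utilities (VAS/100).  Two independent expert panels are compared with a
Bland-Altman agreement analysis per health state, a linear mixed-effects
model of the overall panel difference (random intercept per rated item),
and the Spearman correlation between the urgency rankings each panel's
estimates induce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import psa_engine
from .errors import ConvergenceError, DomainError
from .model_core import SurgeryParams, with_qol
from .psa_engine import PSAConfig

__all__ = [
    "DelphiRating",
    "PanelEstimate",
    "BlandAltman",
    "MixedDifference",
    "PanelComparison",
    "vas_to_utility",
    "round_feedback",
    "panel_estimate",
    "combine_panels",
    "bland_altman",
    "mixed_model_difference",
    "validate_panels",
]

STATES = ("pre", "post")


@dataclass(frozen=True)
class DelphiRating:
    """One rater's VAS score for one surgery, health state and round."""

    rater_id: str
    panel: str
    surgery_id: str
    state: str
    round: int
    vas: float

    def __post_init__(self):
        if self.state not in STATES:
            raise DomainError(f"state must be one of {STATES}, got {self.state!r}")
        if self.round not in (1, 2):
            raise DomainError(f"round must be 1 or 2, got {self.round}")
        if not (0.0 <= self.vas <= 100.0):
            raise DomainError(
                f"VAS must be in [0, 100], got {self.vas} "
                f"({self.rater_id}/{self.surgery_id}/{self.state}/round {self.round})"
            )


@dataclass(frozen=True)
class PanelEstimate:
    """Aggregated utility for one (surgery, state) item.

    ``utility`` is the panel point estimate (mean of final-round individual
    utilities by default); the median and IQR are retained as the Delphi
    feedback statistics.
    """

    surgery_id: str
    state: str
    utility: float
    median: float
    iqr: tuple[float, float]
    n_raters: int


@dataclass(frozen=True)
class BlandAltman:
    """Agreement between two panels for one health state: mean paired
    difference (bias) and bias +/- 1.96 sd limits of agreement."""

    state: str
    bias: float
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class MixedDifference:
    """Overall mean panel difference from the mixed-effects model, with its
    Wald 95% confidence interval.  Direction: reference panel minus
    comparison panel (the reference is the first panel named)."""

    estimate: float
    ci: tuple[float, float]
    reference_panel: str
    comparison_panel: str


@dataclass(frozen=True)
class PanelComparison:
    """Full two-panel validation: per-state Bland-Altman, the mixed-model
    overall difference, and the Spearman rho of the induced rankings."""

    bland_altman: dict[str, BlandAltman]
    mixed: MixedDifference
    spearman_rho: float
    panel_a: str
    panel_b: str


def vas_to_utility(vas: float) -> float:
    """Map a 0-100 VAS score linearly to a utility in [0, 1]."""
    if not (0.0 <= vas <= 100.0):
        raise DomainError(f"VAS must be in [0, 100], got {vas}")
    return vas / 100.0


def _frame(ratings) -> pd.DataFrame:
    rows = [(r.rater_id, r.panel, r.surgery_id, r.state, r.round, r.vas)
            for r in ratings]
    df = pd.DataFrame(rows, columns=["rater_id", "panel", "surgery_id",
                                     "state", "round", "vas"])
    dup = df.duplicated(["rater_id", "surgery_id", "state", "round"])
    if dup.any():
        keys = df.loc[dup, ["rater_id", "surgery_id", "state", "round"]]
        raise DomainError(f"duplicate ratings: {keys.to_dict('records')}")
    return df


def _final_round(df: pd.DataFrame) -> pd.DataFrame:
    """Per rater and item, the round-2 score, falling back to round 1 for
    raters who skipped round 2.  Adds a ``utility`` column."""
    df = df.sort_values("round")
    final = df.groupby(["rater_id", "panel", "surgery_id", "state"],
                       as_index=False).last()
    final["utility"] = final["vas"] / 100.0
    return final


def round_feedback(ratings, round: int = 1) -> dict[tuple[str, str], dict]:
    """Median and interquartile range of VAS scores per (surgery, state) for
    the given round — the feedback displayed to raters before the next
    round.  Percentiles use linear interpolation.
    """
    df = _frame(ratings)
    df = df[df["round"] == round]
    if df.empty:
        raise DomainError(f"no ratings for round {round}")
    out: dict[tuple[str, str], dict] = {}
    for (sid, state), grp in df.groupby(["surgery_id", "state"]):
        v = grp["vas"].to_numpy()
        q25, med, q75 = np.percentile(v, [25, 50, 75])
        out[(sid, state)] = {"median": float(med),
                             "iqr": (float(q25), float(q75)),
                             "n": int(v.size)}
    return out


def _estimates_from(final: pd.DataFrame, aggregate: str) -> list[PanelEstimate]:
    if aggregate not in ("mean", "median"):
        raise DomainError(f"aggregate must be 'mean' or 'median', got {aggregate!r}")
    out = []
    for (sid, state), grp in final.groupby(["surgery_id", "state"]):
        u = grp["utility"].to_numpy()
        q25, med, q75 = np.percentile(u, [25, 50, 75])
        point = float(np.mean(u)) if aggregate == "mean" else float(med)
        out.append(PanelEstimate(surgery_id=sid, state=state, utility=point,
                                 median=float(med), iqr=(float(q25), float(q75)),
                                 n_raters=int(u.size)))
    return out


def panel_estimate(ratings, panel: str, aggregate: str = "mean") -> list[PanelEstimate]:
    """Per-item utility estimates for one panel: the mean (or median) of its
    raters' final-round utilities, with the median/IQR feedback statistics.
    """
    df = _frame(ratings)
    if panel not in set(df["panel"]):
        raise DomainError(f"unknown panel {panel!r}; panels present: "
                          f"{sorted(set(df['panel']))}")
    return _estimates_from(_final_round(df[df["panel"] == panel]), aggregate)


def combine_panels(ratings, aggregate: str = "mean") -> list[PanelEstimate]:
    """Pooled per-item estimates over all raters of all panels, each rater
    carrying equal weight (not an average of panel means)."""
    df = _frame(ratings)
    return _estimates_from(_final_round(df), aggregate)


def estimates_dict(estimates: list[PanelEstimate]) -> dict[tuple[str, str], PanelEstimate]:
    return {(e.surgery_id, e.state): e for e in estimates}


def bland_altman(est_a: list[PanelEstimate], est_b: list[PanelEstimate],
                 state: str) -> BlandAltman:
    """Bland-Altman agreement for one health state.

    Differences are first-listed panel minus second (A is the reference);
    bias is their mean and the limits are bias +/- 1.96 times the sample
    (n-1) standard deviation.
    """
    a = {e.surgery_id: e.utility for e in est_a if e.state == state}
    b = {e.surgery_id: e.utility for e in est_b if e.state == state}
    if set(a) != set(b):
        raise DomainError(f"unmatched items for state {state!r}: "
                          f"{sorted(set(a) ^ set(b))}")
    if len(a) < 2:
        raise DomainError("Bland-Altman needs at least two matched items")
    d = np.array([a[k] - b[k] for k in sorted(a)])
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(state=state, bias=bias, loa_low=bias - 1.96 * sd,
                       loa_high=bias + 1.96 * sd, n=d.size)


def mixed_model_difference(ratings, grouping: str = "item",
                           reference_panel: str | None = None) -> MixedDifference:
    """Overall mean panel difference in final-round utilities.

    Fits, by restricted maximum likelihood, a linear mixed model with a
    fixed intercept, a fixed indicator for the comparison panel, and a
    random intercept per rated item ((surgery, state) by default, or per
    surgery with ``grouping="surgery"``).  Returns the panel effect as
    reference minus comparison, with its Wald 95% interval.

    When the within-cell residual noise is numerically zero REML is
    singular; the panel difference is then deterministic and is returned
    exactly, with a degenerate interval.
    """
    if grouping not in ("item", "surgery"):
        raise DomainError(f"grouping must be 'item' or 'surgery', got {grouping!r}")
    df = _frame(ratings)
    panels = sorted(set(df["panel"]))
    if len(panels) != 2:
        raise DomainError(f"need exactly two panels, found {panels}")
    if reference_panel is None:
        reference_panel = panels[0]
    if reference_panel not in panels:
        raise DomainError(f"reference panel {reference_panel!r} not in {panels}")
    comparison = next(p for p in panels if p != reference_panel)
    if df["surgery_id"].nunique() < 2:
        raise DomainError("need at least two surgeries for a random intercept")

    final = _final_round(df)
    if grouping == "item":
        final["group"] = final["surgery_id"] + ":" + final["state"]
    else:
        final["group"] = final["surgery_id"]
    final["is_comparison"] = (final["panel"] == comparison).astype(float)

    # Degenerate path: all raters of a panel agree exactly on every item and
    # every item shows the same panel gap -> the difference is deterministic.
    cell = final.groupby(["group", "panel"])["utility"]
    resid = final["utility"] - cell.transform("mean")
    gaps = (final.pivot_table(index="group", columns="panel", values="utility",
                              aggfunc="mean"))
    if gaps.notna().all().all():
        item_gap = gaps[reference_panel] - gaps[comparison]
        if resid.abs().max() < 1e-12 and (item_gap - item_gap.mean()).abs().max() < 1e-12:
            est = float(item_gap.mean())
            return MixedDifference(estimate=est, ci=(est, est),
                                   reference_panel=reference_panel,
                                   comparison_panel=comparison)

    import warnings

    import statsmodels.formula.api as smf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("utility ~ is_comparison", data=final,
                            groups=final["group"])
        try:
            fit = model.fit(reml=True)
        except Exception as exc:  # pragma: no cover - numerical failure path
            raise ConvergenceError(f"mixed model failed to converge: {exc}") from exc
    # the coefficient is comparison-minus-reference; flip to the package's
    # reference-minus-comparison convention
    est = -float(fit.params["is_comparison"])
    se = float(fit.bse["is_comparison"])
    if not np.isfinite(est) or not np.isfinite(se):
        raise ConvergenceError("mixed model produced non-finite estimates")
    ci = (est - 1.96 * se, est + 1.96 * se)
    return MixedDifference(estimate=est, ci=ci, reference_panel=reference_panel,
                           comparison_panel=comparison)


def validate_panels(ratings, params_table: list[SurgeryParams],
                    psa_config: PSAConfig, reference_panel: str | None = None,
                    aggregate: str = "mean", grouping: str = "item") -> PanelComparison:
    """Run the whole validation chain between two expert panels.

    The delay-loss model is evaluated twice, once with each panel's utility
    estimates substituted for ``qol_pre``/``qol_post``, through the full
    PSA; the two urgency rankings are compared by Spearman's rho.  The
    panel estimates themselves are compared by per-state Bland-Altman and
    the mixed-effects overall difference.
    """
    df = _frame(ratings)
    panels = sorted(set(df["panel"]))
    if len(panels) != 2:
        raise DomainError(f"need exactly two panels, found {panels}")
    if reference_panel is None:
        reference_panel = panels[0]
    comparison = next(p for p in panels if p != reference_panel)

    est_a = panel_estimate(ratings, reference_panel, aggregate)
    est_b = panel_estimate(ratings, comparison, aggregate)
    ba = {state: bland_altman(est_a, est_b, state) for state in STATES}
    mixed = mixed_model_difference(ratings, grouping=grouping,
                                   reference_panel=reference_panel)

    ranks = []
    for est in (est_a, est_b):
        lut = estimates_dict(est)
        table = []
        for p in params_table:
            try:
                pre = lut[(p.surgery_id, "pre")].utility
                post = lut[(p.surgery_id, "post")].utility
            except KeyError as exc:
                raise DomainError(
                    f"no panel estimate for surgery {p.surgery_id!r} "
                    f"state {exc.args[0][1]!r}") from exc
            table.append(with_qol(p, qol_pre=pre, qol_post=post))
        results = psa_engine.run_psa(table, psa_config)
        ranks.append(psa_engine.ranking_dict(results))
    rho = psa_engine.compare_rankings(ranks[0], ranks[1])

    return PanelComparison(bland_altman=ba, mixed=mixed, spearman_rho=rho,
                           panel_a=reference_panel, panel_b=comparison)
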