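"""Wald-ratio instrumental-variable estimation with delta-method errors.

With a genetic score G, exposure X and outcome Y, and summary-level
score effects beta_GX (score on exposure) and beta_GY (score on
outcome), the causal effect of X on Y is estimated by the Wald ratio

    beta_IV = beta_GY / beta_GX,

interpretable as the outcome change per SD-increase of the (ln-scale,
SD-standardized) exposure.  Its standard error comes from the
first-order delta method for a ratio of independent estimators:

    se_IV = |beta_IV| * sqrt( (se_GX/beta_GX)^2 + (se_GY/beta_GY)^2 ).

That expression is singular at beta_GY = 0 although its value is not:
the beta_GY inside the sqrt cancels against |beta_IV|.  The
implementation therefore uses the algebraically identical form

    se_IV = sqrt( beta_GY^2 se_GX^2 / beta_GX^4 + se_GY^2 / beta_GX^2 ),

finite for any beta_GX != 0 and reducing to se_GY/|beta_GX| in the
null-outcome limit.  The approximation is accurate for strong
instruments (|beta_GX/se_GX| large); no weak-instrument correction is
applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .score import OddsRatioView, ScoreEffect, Z95, _z_p
from .summary_data import LNOR


class WeakInstrumentError(ValueError):
    """The score-exposure effect is zero; the Wald ratio is undefined."""


def delta_se(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> float:
    """Delta-method SE of the ratio ``beta_out / beta_exp``.

    Uses the everywhere-finite algebraic form; see the module docstring.
    """
    if se_exp < 0 or se_out < 0:
        raise ValueError("standard errors must be non-negative")
    if beta_exp == 0:
        raise WeakInstrumentError("exposure effect is zero; ratio SE undefined")
    be2 = beta_exp * beta_exp
    return math.sqrt(
        (beta_out * beta_out) * (se_exp * se_exp) / (be2 * be2)
        + (se_out * se_out) / be2
    )


@dataclass(frozen=True)
class CausalEstimate:
    """Wald-ratio causal estimate of exposure on outcome.

    ``beta_iv`` is per SD-increase of the exposure, on the outcome's
    scale; ``or_view`` is present exactly when that scale is lnOR.
    """

    beta_iv: float
    se_iv: float
    ci_low: float
    ci_high: float
    p: float
    scale: str
    or_view: OddsRatioView | None = None
    exposure_effect: ScoreEffect | None = None
    outcome_effect: ScoreEffect | None = None


def wald_ratio(
    exposure_effect: ScoreEffect, outcome_effect: ScoreEffect
) -> CausalEstimate:
    """Causal effect of the exposure on the outcome via the Wald ratio."""
    if exposure_effect.beta == 0:
        raise WeakInstrumentError(
            "score-exposure effect is zero; the Wald ratio is undefined"
        )
    beta_iv = outcome_effect.beta / exposure_effect.beta
    se_iv = delta_se(
        exposure_effect.beta, exposure_effect.se, outcome_effect.beta, outcome_effect.se
    )
    _, p = _z_p(beta_iv, se_iv)
    ci_low = beta_iv - Z95 * se_iv
    ci_high = beta_iv + Z95 * se_iv
    or_view = None
    if outcome_effect.scale == LNOR:
        or_view = OddsRatioView(
            or_=math.exp(beta_iv),
            ci_low=math.exp(ci_low),
            ci_high=math.exp(ci_high),
        )
    return CausalEstimate(
        beta_iv=beta_iv,
        se_iv=se_iv,
        ci_low=ci_low,
        ci_high=ci_high,
        p=p,
        scale=outcome_effect.scale,
        or_view=or_view,
        exposure_effect=exposure_effect,
        outcome_effect=outcome_effect,
    )
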