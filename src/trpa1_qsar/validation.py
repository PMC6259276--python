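"""External (test-set) validation statistics for QSAR models.

Implements the predictive r-squared and the Golbraikh-Tropsha criteria
battery: regression-through-origin slopes k and k', their determination
coefficients r0^2 and r0'^2, Roy's rm^2 = r^2 (1 - sqrt(|r^2 - r0^2|)), and
the acceptance thresholds

    r2cv > 0.5,  r2 > 0.6,  (r2 - r0^2)/r2 < 0.1,  0.85 <= k <= 1.15,
    rm^2 > 0.5.

Both slope conventions are always reported: k = sum(y yhat)/sum(yhat^2) is
the headline value, k' = sum(y yhat)/sum(y^2) its counterpart with actual
and predicted roles swapped.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ExternalValidationReport",
    "r2_pred",
    "slope_k",
    "r0_squared",
    "rm_squared",
    "criteria_check",
    "residual_table",
    "external_validation",
]


def r2_pred(test_actual, test_pred, train_mean: float) -> float:
    """Predictive r2 = (SD - PRESS) / SD over a held-out test set.

    PRESS is the sum of squared prediction errors; SD the sum of squared
    deviations of the test actuals from the training-set mean activity.
    """
    y = np.asarray(test_actual, float)
    yhat = np.asarray(test_pred, float)
    if len(y) < 2:
        raise ValueError("need at least 2 test compounds")
    sd = ((y - train_mean) ** 2).sum()
    if sd == 0:
        raise ValueError("SD is zero: test activities all equal the training mean")
    press = ((yhat - y) ** 2).sum()
    return float((sd - press) / sd)


def slope_k(actual, pred) -> tuple[float, float]:
    """Regression-through-origin slopes (k, k').

    k = sum(y*yhat)/sum(yhat^2); k' = sum(y*yhat)/sum(y^2).
    """
    y = np.asarray(actual, float)
    yhat = np.asarray(pred, float)
    if len(y) < 2:
        raise ValueError("need at least 2 points")
    d1, d2 = (yhat**2).sum(), (y**2).sum()
    if d1 == 0 or d2 == 0:
        raise ValueError("zero denominator in through-origin slope")
    num = (y * yhat).sum()
    return float(num / d1), float(num / d2)


def r0_squared(actual, pred) -> tuple[float, float]:
    """Determination coefficients of the regressions through the origin.

    r0^2 regresses predicted on actual (yhat ~ k'*y):
    r0^2 = 1 - sum((yhat - k'*y)^2) / sum((yhat - mean(yhat))^2); the primed
    variant swaps the roles. Negative values are legitimate.
    """
    y = np.asarray(actual, float)
    yhat = np.asarray(pred, float)
    k, k_prime = slope_k(actual, pred)
    var_hat = ((yhat - yhat.mean()) ** 2).sum()
    var_y = ((y - y.mean()) ** 2).sum()
    if var_hat == 0 or var_y == 0:
        raise ValueError("zero variance in through-origin correlation")
    r0 = 1.0 - ((yhat - k_prime * y) ** 2).sum() / var_hat
    r0p = 1.0 - ((y - k * yhat) ** 2).sum() / var_y
    return float(r0), float(r0p)


def rm_squared(r2: float, r0_sq: float) -> float:
    """Roy's rm^2 = r^2 * (1 - sqrt(|r^2 - r0^2|)).

    The absolute value covers the case r0^2 > r2 (a negative gap), which
    occurs for the CoMSIA model of this series.
    """
    if not (-1.0 <= r2 <= 1.0 and -1.0 <= r0_sq <= 1.0):
        raise ValueError("r2 and r0^2 must lie in [-1, 1]")
    return float(r2 * (1.0 - np.sqrt(abs(r2 - r0_sq))))


@dataclass(frozen=True)
class ExternalValidationReport:
    """Test-set validation summary (one model)."""

    r2_pred: float
    press: float
    sd: float
    slope_k: float
    slope_k_prime: float
    r0_sq: float
    r0_sq_prime: float
    rm_sq: float
    ratio: float                    # (r2 - r0_sq) / r2
    criteria: dict[str, bool]

    def to_dict(self) -> dict:
        return asdict(self)


def criteria_check(
    q2: float, r2: float, ratio: float, k: float, rm_sq: float
) -> dict[str, bool]:
    """The acceptance battery; overall pass is the AND of all criteria."""
    crit = {
        "q2_gt_0.5": q2 > 0.5,
        "r2_gt_0.6": r2 > 0.6,
        "ratio_lt_0.1": ratio < 0.1,
        "k_in_0.85_1.15": 0.85 <= k <= 1.15,
        "rm_sq_gt_0.5": rm_sq > 0.5,
    }
    crit["overall"] = all(crit.values())
    return crit


def residual_table(actual, pred) -> pd.DataFrame:
    """(actual, predicted, residual) rows with residual = actual - predicted."""
    y = np.asarray(actual, float)
    yhat = np.asarray(pred, float)
    if len(y) != len(yhat):
        raise ValueError(f"length mismatch: {len(y)} actuals vs {len(yhat)} predictions")
    return pd.DataFrame({"actual": y, "predicted": yhat, "residual": y - yhat})


def external_validation(
    test_actual,
    test_pred,
    train_mean: float,
    *,
    q2: float,
    training_r2: float,
) -> ExternalValidationReport:
    """Full test-set report for one model.

    ``training_r2`` is the non-cross-validated r2 of the training fit; rm^2
    and the (r2 - r0^2)/r2 ratio combine it with the test-set r0^2, matching
    the arithmetic that reproduces the published constants.
    """
    y = np.asarray(test_actual, float)
    yhat = np.asarray(test_pred, float)
    press = float(((yhat - y) ** 2).sum())
    sd = float(((y - train_mean) ** 2).sum())
    r2p = r2_pred(y, yhat, train_mean)
    k, kp = slope_k(y, yhat)
    r0, r0p = r0_squared(y, yhat)
    rm = rm_squared(training_r2, r0)
    ratio = (training_r2 - r0) / training_r2
    crit = criteria_check(q2, training_r2, ratio, k, rm)
    return ExternalValidationReport(
        r2_pred=r2p,
        press=press,
        sd=sd,
        slope_k=k,
        slope_k_prime=kp,
        r0_sq=r0,
        r0_sq_prime=r0p,
        rm_sq=rm,
        ratio=float(ratio),
        criteria=crit,
    )
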