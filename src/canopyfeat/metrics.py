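"""Prediction-evaluation statistics for regression and classification.

Regression: RMSE, coefficient of determination R² in the 1 − SSE/SST form,
and Bias (mean of prediction − observation).  Note this R² is *not* a
squared correlation: on validation data it can be negative whenever the
model does worse than predicting the observation mean.

Classification: Accuracy c/n and Cohen's kappa
(Accuracy − E)/(1 − E), where the chance agreement E is computed from the
predicted and observed class marginals, E = (1/n²) Σ_k np_k · no_k.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Hashable, Sequence

import numpy as np

__all__ = ["regression_metrics", "classification_metrics", "chance_agreement"]


def _paired(observations, predictions) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(observations)
    p = np.asarray(predictions)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observations and predictions must be equal-length 1-D sequences")
    if o.size == 0:
        raise ValueError("need at least one observation")
    return o, p


def regression_metrics(observations: Sequence[float], predictions: Sequence[float]) -> dict[str, float]:
    """RMSE, R² and Bias of predictions against observations.

    R² is NaN when the observations are constant (zero total sum of
    squares); it may be negative for poor predictions.
    """
    o, p = _paired(observations, predictions)
    o = o.astype(np.float64)
    p = p.astype(np.float64)
    resid = p - o
    rmse = float(np.sqrt(np.mean(resid**2)))
    bias = float(np.mean(resid))
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0.0:
        r2 = math.nan
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / sst
    return {"RMSE": rmse, "R2": r2, "Bias": bias}


def chance_agreement(observations: Sequence[Hashable], predictions: Sequence[Hashable]) -> float:
    """Expected chance agreement E from the two class marginals.

    The class universe is the union of observed and predicted labels, so a
    class present on only one side contributes zero to the sum.
    """
    o, p = _paired(list(observations), list(predictions))
    n = o.size
    no = Counter(o.tolist())
    np_ = Counter(p.tolist())
    classes = set(no) | set(np_)
    return sum(np_.get(k, 0) * no.get(k, 0) for k in classes) / n**2


def classification_metrics(observations: Sequence[Hashable], predictions: Sequence[Hashable]) -> dict[str, float]:
    """Accuracy and Cohen's kappa of predicted against observed classes.

    Kappa is NaN when E = 1 (both marginals concentrated on a single
    class — there is no disagreement left to correct for).
    """
    o, p = _paired(list(observations), list(predictions))
    n = o.size
    accuracy = float(np.mean(o == p))
    e = chance_agreement(o, p)
    kappa = math.nan if e == 1.0 else (accuracy - e) / (1.0 - e)
    return {"Accuracy": accuracy, "Kappa": kappa, "E": e}
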