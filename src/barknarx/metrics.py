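"""Model-comparison statistics for bark-thickness predictions.

All error metrics are in the units of the series (cm here).  The sign
convention of the mean error is ``observed - predicted``: a positive ME
means the model underestimates on average.

The model-efficiency coefficient EF comes in two variants.  The conventional
(Nash–Sutcliffe) form references the residual sum of squares to the spread
of the *observations*:

    EF = 1 - sum((obs - pred)^2) / sum((obs - mean(obs))^2)

and is bounded above by 1, equal to 0 for the constant predictor at the
observed mean.  The second, ``printed_form``, normalizes by the spread of
the *predictions* instead; it is kept selectable so reports can be matched
against either convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetricsReport", "evaluate"]


@dataclass(frozen=True)
class MetricsReport:
    """RMSE/ME/EF/MAE summary of one model on one evaluation set."""

    RMSE: float
    ME: float
    EF: float
    MAE: float
    MEAN: float
    K: int
    ef_variant: str
    EF_observed_mean: float
    EF_printed_form: float

    def as_dict(self) -> dict[str, float]:
        return {
            "RMSE": self.RMSE,
            "ME": self.ME,
            "EF": self.EF,
            "MAE": self.MAE,
            "MEAN": self.MEAN,
        }


def evaluate(observed, predicted, ef_variant: str = "observed_mean") -> MetricsReport:
    """Compute RMSE, ME, EF, MAE and the prediction mean.

    NaN pairs (e.g. recurrent-model priming positions) are dropped before
    computing anything.  A zero EF denominator yields EF = NaN while the
    other metrics are still returned.
    """
    if ef_variant not in ("observed_mean", "printed_form"):
        raise ValueError(f"unknown EF variant {ef_variant!r}")
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    ok = np.isfinite(obs) & np.isfinite(pred)
    obs, pred = obs[ok], pred[ok]
    K = obs.size
    if K < 2:
        raise ValueError("need at least 2 finite pairs")

    err = obs - pred
    sse = float(err @ err)
    rmse = float(np.sqrt(sse / K))
    me = float(err.mean())
    mae = float(np.abs(err).mean())
    mean_pred = float(pred.mean())

    def _ef(reference: np.ndarray) -> float:
        denom = float(((reference - reference.mean()) ** 2).sum())
        return 1.0 - sse / denom if denom > 0 else float("nan")

    ef_obs = _ef(obs)
    ef_printed = _ef(pred)
    return MetricsReport(
        RMSE=rmse,
        ME=me,
        EF=ef_obs if ef_variant == "observed_mean" else ef_printed,
        MAE=mae,
        MEAN=mean_pred,
        K=K,
        ef_variant=ef_variant,
        EF_observed_mean=ef_obs,
        EF_printed_form=ef_printed,
    )
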