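"""Forecast-quality metrics: SMAPE and logarithmic deviation.

SMAPE here is ``(100/n) * sum |y_i - x_i| / (|y_i| + |x_i|)`` — note the
denominator is the plain sum of magnitudes (not halved), so the score is
bounded by 100%.  Pairs with both values zero contribute 0.

The logarithmic deviation of a pair is ``ld_i = log(y_i / x_i)`` (natural
log by default): positive values flag overestimation, negative values
underestimation; the summary statistic is the plain sum over pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["smape", "log_deviation", "evaluation_report", "EvalReport"]


def smape(predicted, measured) -> float:
    """Symmetric mean absolute percentage error in percent (0-100)."""
    y = np.asarray(predicted, dtype=np.float64)
    x = np.asarray(measured, dtype=np.float64)
    if y.shape != x.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {x.shape}")
    if y.size < 1:
        raise ValueError("smape needs at least one pair")
    if (y < 0).any() or (x < 0).any():
        raise ValueError("smape expects non-negative values")
    denom = np.abs(y) + np.abs(x)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(denom > 0, np.abs(y - x) / denom, 0.0)
    return float(100.0 / y.size * terms.sum())


def log_deviation(predicted, measured, base: str = "e") -> tuple[np.ndarray, float]:
    """Per-pair log deviations ``log(y_i/x_i)`` and their sum.

    ``base`` is ``'e'`` (natural, default) or ``'10'``.  All values must be
    strictly positive.
    """
    y = np.asarray(predicted, dtype=np.float64)
    x = np.asarray(measured, dtype=np.float64)
    if y.shape != x.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {x.shape}")
    if (y <= 0).any() or (x <= 0).any():
        raise ValueError("log deviation requires strictly positive values")
    ratio = y / x
    ld = np.log(ratio) if base == "e" else np.log10(ratio) if base == "10" else None
    if ld is None:
        raise ValueError("base must be 'e' or '10'")
    return ld, float(ld.sum())


@dataclass
class EvalReport:
    """Aggregated SMAPE and per-pair log deviations for one parameter."""

    parameter: str
    n_pairs: int
    smape_percent: float
    ld_pairs: np.ndarray
    ld_sum: float
    over_count: int
    under_count: int
    zero_count: int
    plant_ids: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "n_pairs": self.n_pairs,
            "smape_percent": self.smape_percent,
            "ld_sum": self.ld_sum,
            "over_count": self.over_count,
            "under_count": self.under_count,
            "zero_count": self.zero_count,
            "ld_pairs": [float(v) for v in self.ld_pairs],
            "plant_ids": self.plant_ids,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def ld_to_csv(self, path) -> None:
        """Per-pair deviations (and their cumulative sum) for plotting."""
        import pandas as pd

        pd.DataFrame(
            {
                "plant_id": self.plant_ids,
                "ld": self.ld_pairs,
                "ld_cumsum": np.cumsum(self.ld_pairs),
            }
        ).to_csv(path, index=False)


def evaluation_report(pred, truth, parameter: str = "height") -> EvalReport:
    """Compare predicted vs measured :class:`PlantRecord` lists.

    Records are matched on (plant_id, date_index); unmatched records are
    excluded with a logged warning.
    """
    import logging

    if parameter not in ("height", "crown_area"):
        raise ValueError("parameter must be 'height' or 'crown_area'")
    logger = logging.getLogger(__name__)
    truth_map = {(r.plant_id, r.date_index): r for r in truth}
    pairs = []
    ids = []
    unmatched = 0
    for r in pred:
        key = (r.plant_id, r.date_index)
        if key in truth_map:
            pairs.append((getattr(r, parameter), getattr(truth_map[key], parameter)))
            ids.append(r.plant_id)
        else:
            unmatched += 1
    if unmatched:
        logger.warning("%d predicted records had no matching measurement", unmatched)
    if not pairs:
        raise ValueError("no matched (plant_id, date_index) pairs to evaluate")
    y = np.array([p[0] for p in pairs])
    x = np.array([p[1] for p in pairs])
    ld, ld_sum = log_deviation(y, x)
    return EvalReport(
        parameter=parameter,
        n_pairs=len(pairs),
        smape_percent=smape(y, x),
        ld_pairs=ld,
        ld_sum=ld_sum,
        over_count=int((ld > 0).sum()),
        under_count=int((ld < 0).sum()),
        zero_count=int((ld == 0).sum()),
        plant_ids=ids,
    )
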