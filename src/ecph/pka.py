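"""Reconciling model pKa values with trajectory-ensemble pKa predictions.

Per-residue pKa predictions sampled along an MD trajectory (e.g. PROPKAtraj
output) form a distribution whose median and spread decide whether the
residue keeps its model pKa or is assigned an individual value:

* if the median deviates from the model value by more than 1 pKa unit, the
  model value is replaced by the median;
* but if the standard deviation of the predictions itself exceeds 1 pKa
  unit, that standard deviation is used as the deviation threshold instead
  (a broad, uncertain prediction should not override the model value).

The predictor's own accuracy constant (RMSD 0.89 pKa units for PROPKA) is
recorded as :data:`PREDICTOR_RMSD` for reference; it does not enter the rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError

__all__ = ["PREDICTOR_RMSD", "PkaSampleSet", "summarize_samples", "adjust_model_pka"]

#: Reported accuracy (RMSD, pKa units) of the upstream PROPKA predictor.
#: Metadata only — the adjustment rule does not use it.
PREDICTOR_RMSD = 0.89


def summarize_samples(samples: list[float] | np.ndarray) -> tuple[float, float]:
    """Median and population standard deviation of per-frame pKa predictions.

    The median is the conventional middle-order statistic (mean of the two
    central values for even counts); the standard deviation is the
    population form (ddof=0), appropriate since the frames exhaust the
    prediction set rather than subsample a larger one.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("cannot summarize an empty pKa sample list")
    return float(np.median(arr)), float(np.std(arr))


@dataclass
class PkaSampleSet:
    """Per-frame pKa predictions for one residue, with live summaries.

    ``median`` and ``std`` are properties recomputed from ``samples`` on
    access, so they can never go stale.
    """

    chain_id: str
    residue_number: int
    residue_type: str
    samples: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def median(self) -> float:
        return summarize_samples(self.samples)[0]

    @property
    def std(self) -> float:
        return summarize_samples(self.samples)[1]


def adjust_model_pka(model_pka: float, sample_set: PkaSampleSet) -> tuple[float, bool]:
    """Apply the median-vs-model reconciliation rule for one residue.

    Returns ``(assigned_pka, altered)`` where ``assigned_pka`` is the sample
    median when the rule fires and the model value otherwise. The deviation
    threshold is 1 pKa unit, widened to the prediction standard deviation
    when that exceeds 1.
    """
    median, std = summarize_samples(sample_set.samples)
    threshold = std if std > 1.0 else 1.0
    if abs(median - model_pka) > threshold:
        return median, True
    return model_pka, False
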