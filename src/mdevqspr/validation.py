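"""Model validation: leave-one-out CV, external validation, RMSRE.

Prediction quality is summarised by signed percent relative errors

    RE_i = 100 * (predicted_i - experimental_i) / experimental_i

and their quadratic mean, the root mean square relative error

    RMSRE = sqrt( sum RE_i^2 / n )        (in percent),

plus the least-squares line and Pearson correlation of predicted versus
experimental values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import QsprRecord
from .errors import DatasetError, DegenerateRegressionError, ProtocolError
from .lann import predict_lann, train_lann
from .regression import fit_mlr, predict

__all__ = [
    "ValidationReport",
    "relative_error_percent",
    "rmsre",
    "loo_cv",
    "external_validation",
    "pred_vs_exp_line",
]

_MODELERS = ("mlr", "lann")


def relative_error_percent(predicted: float, experimental: float) -> float:
    """Signed percent relative error 100*(pred - exp)/exp."""
    if experimental == 0:
        raise ZeroDivisionError("relative error undefined for experimental value 0")
    return 100.0 * (predicted - experimental) / experimental


def rmsre(relative_errors) -> float:
    """Root mean square of percent relative errors, in percent."""
    re = np.asarray(list(relative_errors), dtype=float)
    if re.size == 0:
        raise DatasetError("rmsre of an empty list")
    return float(np.sqrt(np.mean(re**2)))


@dataclass(frozen=True)
class PveLine:
    """Least-squares line of predicted on experimental values."""

    slope: float
    intercept: float
    correlation: float


@dataclass(frozen=True)
class ValidationReport:
    per_sample: pd.DataFrame  # columns: name, experimental, predicted, re_percent
    rmsre: float
    pve_line: PveLine
    n: int
    protocol: str  # "loo" | "external"
    modeler: str   # "mlr" | "lann"

    def recomputed_rmsre(self) -> float:
        return rmsre(self.per_sample["re_percent"])


def pred_vs_exp_line(predicted, experimental) -> PveLine:
    """Fit predicted = slope*experimental + intercept; report Pearson r."""
    pred = np.asarray(list(predicted), dtype=float)
    exp = np.asarray(list(experimental), dtype=float)
    if pred.size < 3:
        raise DatasetError("need >= 3 points for a predicted-vs-experimental line")
    if np.ptp(exp) == 0:
        raise DegenerateRegressionError("experimental values are constant")
    fit = stats.linregress(exp, pred)
    return PveLine(float(fit.slope), float(fit.intercept), float(fit.rvalue))


def _fit_and_predict(train, test, modeler: str, seed: int | None):
    if modeler == "mlr":
        model = fit_mlr(train)
        return predict(model, test)
    if modeler == "lann":
        model = train_lann(train, seed=seed)
        return predict_lann(model, test)
    raise ValueError(f"unknown modeler {modeler!r}; expected one of {_MODELERS}")


def _report(records, predictions, protocol: str, modeler: str) -> ValidationReport:
    rows = pd.DataFrame(
        {
            "name": [r.name for r in records],
            "experimental": [r.lgkoa_exp for r in records],
            "predicted": np.asarray(predictions, dtype=float),
        }
    )
    rows["re_percent"] = [
        relative_error_percent(p, e)
        for p, e in zip(rows["predicted"], rows["experimental"])
    ]
    return ValidationReport(
        per_sample=rows,
        rmsre=rmsre(rows["re_percent"]),
        pve_line=pred_vs_exp_line(rows["predicted"], rows["experimental"]),
        n=len(rows),
        protocol=protocol,
        modeler=modeler,
    )


def loo_cv(
    records: list[QsprRecord], modeler: str = "mlr", seed: int | None = 0
) -> ValidationReport:
    """Leave-one-out cross-validation.

    Each record is predicted by a model refitted on the other n-1.  With
    the ``mlr`` modeler the procedure is fully deterministic; with ``lann``
    each fold draws a fresh seeded calibration split (the fold index
    offsets the seed so runs are reproducible).
    """
    if len(records) < 5:
        raise DatasetError(f"need >= 5 records for LOO CV, got {len(records)}")
    predictions = []
    for i, held_out in enumerate(records):
        rest = records[:i] + records[i + 1:]
        fold_seed = None if seed is None else seed + i
        try:
            pred = _fit_and_predict(rest, [held_out], modeler, fold_seed)
        except Exception as exc:
            raise type(exc)(f"LOO fold {i} ({held_out.name}): {exc}") from exc
        predictions.append(float(pred[0]))
    return _report(records, predictions, "loo", modeler)


def external_validation(
    train_records: list[QsprRecord],
    test_records: list[QsprRecord],
    modeler: str = "mlr",
    seed: int | None = 0,
) -> ValidationReport:
    """Single fit on a calibration set, error statistics on a disjoint test set."""
    if not train_records or not test_records:
        raise ProtocolError("train and test sets must both be nonempty")
    train_keys = {r.congener.canonical() for r in train_records}
    test_keys = {r.congener.canonical() for r in test_records}
    overlap = train_keys & test_keys
    if overlap:
        names = sorted(s.name for s in overlap)
        raise ProtocolError(f"train and test sets overlap: {names}")
    predictions = _fit_and_predict(train_records, test_records, modeler, seed)
    return _report(test_records, predictions, "external", modeler)
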