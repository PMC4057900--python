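"""Ordinary least-squares QSPR regression of lgK_OA on (mu1, mu2).

The calibration model is the two-descriptor linear form

    lgK_OA = b1 * mu1 + b2 * mu2 + b0

fitted by OLS on raw (unstandardised) descriptors.  Diagnostics follow the
conventions of classical regression output: the multiple correlation
coefficient R = sqrt(SS_reg / SS_tot), the standard error of the estimate
sqrt(SS_res / (n - 3)), and the overall F statistic on (2, n - 3) degrees
of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .dataset import QsprRecord
from .errors import SampleSizeError, SingularDesignError

__all__ = ["LinearQsprModel", "fit_mlr", "predict", "design_matrix"]


def design_matrix(records: list[QsprRecord]) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) arrays with X columns (mu1, mu2)."""
    X = np.array([[r.mu1, r.mu2] for r in records], dtype=float)
    y = np.array([r.lgkoa_exp for r in records], dtype=float)
    return X, y


@dataclass(frozen=True)
class LinearQsprModel:
    """Fitted linear QSPR model with its training diagnostics.

    Coefficients are in lgK_OA units per descriptor unit; ``se_estimate``
    is the residual standard deviation in lgK_OA units.
    """

    coef_mu1: float
    coef_mu2: float
    intercept: float
    n_train: int
    r: float
    se_estimate: float
    f_value: float

    def predict_xy(self, mu1: np.ndarray, mu2: np.ndarray) -> np.ndarray:
        return self.coef_mu1 * np.asarray(mu1) + self.coef_mu2 * np.asarray(mu2) + self.intercept


def fit_mlr(records: list[QsprRecord]) -> LinearQsprModel:
    """Fit lgK_OA ~ mu1 + mu2 by OLS.

    Requires at least 4 records (one more than the parameter count) and a
    full-rank design.
    """
    if len(records) < 4:
        raise SampleSizeError(
            f"need >= 4 records to fit a 3-parameter model, got {len(records)}"
        )
    X, y = design_matrix(records)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")
    fit = sm.OLS(y, design).fit()
    n = len(records)
    return LinearQsprModel(
        coef_mu1=float(fit.params[1]),
        coef_mu2=float(fit.params[2]),
        intercept=float(fit.params[0]),
        n_train=n,
        r=float(np.sqrt(fit.rsquared)),
        se_estimate=float(np.sqrt(fit.ssr / (n - 3))),
        f_value=float(fit.fvalue),
    )


def predict(model: LinearQsprModel, records: list[QsprRecord]) -> np.ndarray:
    """Predicted lgK_OA for each record."""
    X, _ = design_matrix(records)
    return model.predict_xy(X[:, 0], X[:, 1])
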