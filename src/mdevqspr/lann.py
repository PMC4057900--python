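"""Linear artificial neural network (L-ANN) trained by SVD pseudo-inverse.

An L-ANN has no hidden layer: the output neuron computes the post-synaptic
potential v = sum_i x_i w_i + b with a linear (identity) activation, so the
network is an affine map of its inputs.  Inputs and the output are z-score
normalised before training.  Training is one-shot: the weights solving the
least-squares problem on the training set are obtained from the singular
value decomposition of the (normalised) design matrix.

Model selection uses a held-out verification set drawn from the calibration
records: candidate networks are generated by truncating trailing singular
values (ranks full, full-1, ..., 1) and the candidate with the smallest
verification RMSE is kept, which is how "stop training before over-fitting"
translates to a one-shot pseudo-inverse solver.  With well-conditioned
inputs this selects the full-rank solution, whose de-normalised weights
coincide with the OLS coefficients.  ``verification_fraction=0`` disables
the split and returns the full least-squares solution directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import QsprRecord
from .errors import ConfigurationError, SampleSizeError, SingularDesignError
from .regression import design_matrix

__all__ = ["LannModel", "train_lann", "predict_lann"]


@dataclass(frozen=True)
class LannModel:
    """Trained linear network with its normalisation and split metadata."""

    weights: tuple[float, ...]      # per-input weights, normalised scale
    bias: float                     # bias, normalised scale
    x_mean: tuple[float, ...]
    x_scale: tuple[float, ...]
    y_mean: float
    y_scale: float
    seed: int | None
    train_indices: tuple[int, ...]
    verification_indices: tuple[int, ...]
    verification_rmse: float | None
    rank: int

    @property
    def coefficients(self) -> tuple[float, ...]:
        """De-normalised input coefficients (lgK_OA per descriptor unit)."""
        w = np.asarray(self.weights)
        return tuple(float(v) for v in w * self.y_scale / np.asarray(self.x_scale))

    @property
    def intercept(self) -> float:
        """De-normalised intercept."""
        w = np.asarray(self.weights)
        shift = float(np.sum(w * np.asarray(self.x_mean) / np.asarray(self.x_scale)))
        return self.y_mean + self.y_scale * (self.bias - shift)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Forward pass: normalise, affine map, de-normalise."""
        xn = (np.asarray(x, dtype=float) - np.asarray(self.x_mean)) / np.asarray(self.x_scale)
        v = xn @ np.asarray(self.weights) + self.bias
        return self.y_mean + self.y_scale * v


def _truncated_solution(u, s, vt, yn, rank: int) -> np.ndarray:
    """Minimum-norm least-squares solution keeping the top ``rank`` singular values."""
    coeffs = (u.T @ yn)[:rank] / s[:rank]
    return vt[:rank].T @ coeffs


def train_lann(
    calibration: list[QsprRecord],
    seed: int | None = 0,
    verification_fraction: float = 0.2,
) -> LannModel:
    """Train the linear network on calibration records.

    The calibration set is randomly split (seeded) into a training set used
    to solve the weights and a verification set used only to pick among the
    SVD-truncation candidates.  For the 15-sample folds of the study's
    leave-one-out protocol, the default fraction gives the 12/3 split used
    there.
    """
    if len(calibration) < 5:
        raise SampleSizeError(
            f"need >= 5 calibration records, got {len(calibration)}"
        )
    X, y = design_matrix(calibration)
    n = len(calibration)

    if verification_fraction < 0 or verification_fraction >= 1:
        raise ConfigurationError("verification_fraction must be in [0, 1)")
    n_verif = int(round(verification_fraction * n)) if verification_fraction else 0
    if verification_fraction > 0 and n_verif == 0:
        raise ConfigurationError(
            f"verification_fraction {verification_fraction} leaves an empty "
            f"verification set at n={n}"
        )
    if n - n_verif < 3:
        raise SampleSizeError(
            f"split leaves {n - n_verif} training records; need >= 3"
        )

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    verif_idx = np.sort(perm[:n_verif])
    train_idx = np.sort(perm[n_verif:])

    x_mean = X[train_idx].mean(axis=0)
    x_scale = X[train_idx].std(axis=0, ddof=0)
    if np.any(x_scale == 0):
        raise SingularDesignError("a descriptor is constant on the training set")
    y_mean = float(y[train_idx].mean())
    y_scale = float(y[train_idx].std(ddof=0))
    if y_scale == 0:
        y_scale = 1.0

    xn = (X[train_idx] - x_mean) / x_scale
    yn = (y[train_idx] - y_mean) / y_scale
    design = np.column_stack([xn, np.ones(len(train_idx))])
    u, s, vt = np.linalg.svd(design, full_matrices=False)
    full_rank = int(np.sum(s > s[0] * np.finfo(float).eps * max(design.shape)))
    if full_rank == 0:
        raise SingularDesignError("zero design matrix")

    if n_verif == 0:
        w = _truncated_solution(u, s, vt, yn, full_rank)
        best = (w, None, full_rank)
    else:
        xv = (X[verif_idx] - x_mean) / x_scale
        dv = np.column_stack([xv, np.ones(len(verif_idx))])
        yv = y[verif_idx]
        best = None
        for rank in range(full_rank, 0, -1):  # prefer full rank on ties
            w = _truncated_solution(u, s, vt, yn, rank)
            pred = y_mean + y_scale * (dv @ w)
            rmse = float(np.sqrt(np.mean((pred - yv) ** 2)))
            if best is None or rmse < best[1]:
                best = (w, rmse, rank)
        w, rmse, rank = best
        best = (w, rmse, rank)

    w, verif_rmse, rank = best
    return LannModel(
        weights=tuple(float(v) for v in w[:-1]),
        bias=float(w[-1]),
        x_mean=tuple(float(v) for v in x_mean),
        x_scale=tuple(float(v) for v in x_scale),
        y_mean=y_mean,
        y_scale=y_scale,
        seed=seed,
        train_indices=tuple(int(i) for i in train_idx),
        verification_indices=tuple(int(i) for i in verif_idx),
        verification_rmse=verif_rmse,
        rank=rank,
    )


def predict_lann(model: LannModel, records: list[QsprRecord]) -> np.ndarray:
    """Predicted lgK_OA for each record."""
    X, _ = design_matrix(records)
    return model.forward(X)
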