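"""Synthetic congener datasets with the linear response structure the
QSPR models assume.

The generator draws random PBDE substitution patterns and simulates
lgK_OA as a linear function of the (mu1, mu2) descriptors plus additive
Gaussian noise:

    lgK_OA = b1*mu1 + b2*mu2 + b0 + N(0, noise_sd)

Defaults mirror the study conditions: the generating coefficients are the
calibration-fit values (-0.7598, 0.9883, 6.3470), the noise level is the
fitted residual standard deviation (0.234 lgK_OA units), and the default
sample size is the 16-congener calibration group.  This gives fully
reproducible, download-free data for parameter-recovery and protocol
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .congener_graph import CongenerSpec, enumerate_canonical_congeners
from .dataset import QsprRecord
from .errors import ConfigurationError, ExhaustionError
from .mdev import compute_mdev

__all__ = ["SyntheticConfig", "sample_congeners", "simulate_lgkoa", "N_CONGENERS"]

#: Number of distinct canonical PBDE congeners with at least one bromine.
N_CONGENERS = 209

_POSITIONS = (2, 3, 4, 5, 6)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating model for synthetic (congener, lgK_OA) datasets."""

    n_samples: int = 16
    true_coef_mu1: float = -0.7598
    true_coef_mu2: float = 0.9883
    true_intercept: float = 6.3470
    noise_sd: float = 0.234
    seed: int | None = 0
    allow_duplicates: bool = False

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not self.allow_duplicates and self.n_samples > N_CONGENERS:
            raise ExhaustionError(
                f"only {N_CONGENERS} distinct congeners exist; "
                f"cannot draw {self.n_samples} without duplicates"
            )


def sample_congeners(
    n: int, seed: int | None = 0, allow_duplicates: bool = False
) -> list[CongenerSpec]:
    """Draw random canonical congeners with at least one bromine.

    Each of the 10 ring positions carries a bromine independently with
    probability 1/2; all-empty draws are rejected and every draw is
    canonicalised.  Without duplicates at most 209 distinct congeners
    exist; requesting more raises :class:`ExhaustionError`.
    """
    if not allow_duplicates and n > N_CONGENERS:
        raise ExhaustionError(
            f"only {N_CONGENERS} distinct congeners exist; cannot draw {n}"
        )
    rng = np.random.default_rng(seed)
    out: list[CongenerSpec] = []
    seen: set[CongenerSpec] = set()
    # Rejection sampling is fast until the distinct pool is nearly
    # exhausted; fall back to a shuffled exhaustive enumeration there.
    max_attempts = 200 * max(n, 1) + 10_000
    attempts = 0
    while len(out) < n and attempts < max_attempts:
        attempts += 1
        mask = rng.random(10) < 0.5
        if not mask.any():
            continue
        ring_a = frozenset(p for p, hit in zip(_POSITIONS, mask[:5]) if hit)
        ring_b = frozenset(p for p, hit in zip(_POSITIONS, mask[5:]) if hit)
        spec = CongenerSpec(ring_a, ring_b).canonical()
        if allow_duplicates:
            out.append(spec)
        elif spec not in seen:
            seen.add(spec)
            out.append(spec)
    if len(out) < n:
        pool = [s for s in enumerate_canonical_congeners() if s not in seen]
        rng.shuffle(pool)
        out.extend(pool[: n - len(out)])
    return out


def simulate_lgkoa(
    specs: list[CongenerSpec], config: SyntheticConfig
) -> list[QsprRecord]:
    """Simulate lgK_OA for given congeners under the linear generating model."""
    rng = np.random.default_rng(config.seed)
    records = []
    noise = rng.normal(0.0, config.noise_sd, size=len(specs)) if config.noise_sd else np.zeros(len(specs))
    for spec, eps in zip(specs, noise):
        idx = compute_mdev(spec)
        lgkoa = (
            config.true_coef_mu1 * idx.mu1
            + config.true_coef_mu2 * idx.mu2
            + config.true_intercept
            + float(eps)
        )
        records.append(QsprRecord(spec, idx.mu1, idx.mu2, lgkoa, None))
    return records


def generate_dataset(config: SyntheticConfig) -> list[QsprRecord]:
    """Convenience: sample congeners and simulate responses in one call.

    Congener sampling and noise use decorrelated streams derived from the
    configured seed, so datasets of different sizes share no structure.
    """
    spec_seed = None if config.seed is None else (config.seed * 2 + 1) % (2**31)
    specs = sample_congeners(config.n_samples, spec_seed, config.allow_duplicates)
    return simulate_lgkoa(specs, config)
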