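"""Evaluation metrics for affinity regression: MSE, CI, rm², Pearson.

The concordance index (CI) scores, over all ordered pairs whose true labels
differ, whether the predictions preserve the order: 1 for a concordant
pair, 0.5 for a prediction tie, 0 for a discordant pair, normalized by the
number of such pairs.  Pairs with tied labels are excluded.

rm² penalizes the gap between the squared correlation with an intercept
(r²) and the squared correlation through the origin (r₀², Roy's
external-validation form with observed-vs-predicted orientation:
r₀² = 1 − Σ(yᵢ − k·pᵢ)² / Σ(yᵢ − ȳ)², k = Σyᵢpᵢ / Σpᵢ²).  Two variants
are provided: the default ``r²·(1 − (r² − r₀²))`` and the classical
``r²·(1 − √(r² − r₀²))`` behind ``sqrt_variant=True``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np


@dataclass
class MetricsReport:
    mse: float
    ci: float
    rm2: float
    pearson: float
    n: int
    rm2_clamped: bool = False  # true when r² < r₀² forced a clamp at 0

    def to_json(self, **kw) -> str:
        return json.dumps(asdict(self), **kw)


def _check_pair(y, p, min_len=1):
    y = np.asarray(y, dtype=np.float64).ravel()
    p = np.asarray(p, dtype=np.float64).ravel()
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape[0]} labels vs {p.shape[0]} predictions")
    if y.shape[0] < min_len:
        raise ValueError(f"need at least {min_len} observations, got {y.shape[0]}")
    return y, p


def mse(y, p) -> float:
    y, p = _check_pair(y, p)
    return float(np.mean((y - p) ** 2))


def concordance_index(y, p) -> float:
    y, p = _check_pair(y, p, min_len=2)
    dy = y[:, None] - y[None, :]
    dp = p[:, None] - p[None, :]
    comparable = dy > 0  # ordered pairs with y_i > y_j; label ties excluded
    z = comparable.sum()
    if z == 0:
        raise ValueError("concordance index undefined: all labels identical")
    score = np.where(dp > 0, 1.0, np.where(dp == 0, 0.5, 0.0))
    return float(score[comparable].sum() / z)


def pearson(y, p) -> float:
    y, p = _check_pair(y, p, min_len=2)
    if np.all(y == y[0]) or np.all(p == p[0]):
        raise ValueError("Pearson undefined for a constant vector")
    return float(np.corrcoef(p, y)[0, 1])


def rm2(y, p, sqrt_variant: bool = False) -> float:
    value, _ = rm2_with_flag(y, p, sqrt_variant=sqrt_variant)
    return value


def rm2_with_flag(y, p, sqrt_variant: bool = False) -> tuple[float, bool]:
    """rm² plus a flag marking whether r² − r₀² was clamped at zero."""
    y, p = _check_pair(y, p, min_len=3)
    if np.all(y == y[0]) or np.all(p == p[0]):
        raise ValueError("rm2 undefined for a constant vector")
    r2 = pearson(y, p) ** 2
    k = float(np.sum(y * p) / np.sum(p * p))
    ss_res = float(np.sum((y - k * p) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r02 = 1.0 - ss_res / ss_tot
    diff = r2 - r02
    clamped = diff < 0
    diff = max(diff, 0.0)
    if sqrt_variant:
        return float(r2 * (1.0 - np.sqrt(diff))), clamped
    return float(r2 * (1.0 - diff)), clamped


def evaluate(y, p, sqrt_variant: bool = False) -> MetricsReport:
    """Full report over a set of (true, predicted) pairs."""
    y, p = _check_pair(y, p, min_len=2)
    rm2_value, clamped = rm2_with_flag(y, p, sqrt_variant=sqrt_variant)
    return MetricsReport(
        mse=mse(y, p),
        ci=concordance_index(y, p),
        rm2=rm2_value,
        pearson=pearson(y, p),
        n=int(y.shape[0]),
        rm2_clamped=clamped,
    )
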