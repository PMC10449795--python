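"""Agreement statistics between paired percent-change PLR traces.

Device-comparison studies summarise how well a new pupillometer tracks a
clinical reference using mean absolute error (in percentage points of the
percent-change-from-mean traces), Pearson's product-moment correlation, and
Bland-Altman bias with 1.96-SD limits of agreement.  Cohort summaries are the
arithmetic mean (and SD, for MAE) of the per-subject statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .plr import AlignedTracePair

__all__ = [
    "ConstantInputError",
    "mae",
    "pearson",
    "bland_altman",
    "BlandAltmanResult",
    "AgreementResult",
    "ValidationSummary",
    "agreement",
    "summarize_cohort",
]


class ConstantInputError(ValueError):
    """Pearson correlation is undefined for a constant input vector."""


def _paired(a, b, min_len: int = 1) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("inputs must be 1-D")
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) < min_len:
        raise ValueError(f"need at least {min_len} paired samples, got {len(a)}")
    return a, b


def mae(a, b) -> float:
    """Mean absolute error between paired samples."""
    a, b = _paired(a, b, min_len=1)
    return float(np.mean(np.abs(a - b)))


def pearson(a, b) -> float:
    """Pearson product-moment correlation; rejects constant inputs."""
    a, b = _paired(a, b, min_len=3)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ConstantInputError("Pearson correlation undefined for a constant input")
    return float(sstats.pearsonr(a, b).statistic)


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 1.96-SD limits of agreement, with per-pair points for plotting."""

    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland-Altman agreement: differences a - b, bias, bias +/- 1.96 * SD.

    SD uses the sample (n-1) denominator.
    """
    a, b = _paired(a, b, min_len=2)
    diffs = a - b
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=(a + b) / 2.0,
        diffs=diffs,
    )


@dataclass(frozen=True)
class AgreementResult:
    """Per-subject agreement between two percent-change traces."""

    mae_pct: float
    pearson_r: float
    bland_altman_bias: float
    loa_low: float
    loa_high: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.mae_pct < 0:
            raise ValueError("MAE must be non-negative")
        if not self.loa_low <= self.bland_altman_bias <= self.loa_high:
            raise ValueError("limits of agreement must bracket the bias")


def agreement(pair: AlignedTracePair) -> AgreementResult:
    """Compute all agreement statistics on the jointly valid samples of a pair."""
    a, b = pair.valid_pairs()
    ba = bland_altman(a, b)
    return AgreementResult(
        mae_pct=mae(a, b),
        pearson_r=pearson(a, b),
        bland_altman_bias=ba.bias,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        n_samples=len(a),
    )


@dataclass(frozen=True)
class ValidationSummary:
    """Cohort roll-up of per-subject agreement results."""

    per_subject: tuple[AgreementResult, ...]
    cohort_mean_mae_pct: float
    cohort_sd_mae_pct: float
    cohort_mean_pearson_r: float

    @property
    def n_subjects(self) -> int:
        return len(self.per_subject)


def summarize_cohort(results) -> ValidationSummary:
    """Cohort mean and SD of per-subject MAE, and cohort mean Pearson r."""
    results = tuple(results)
    if not results:
        raise ValueError("no per-subject results to summarise")
    maes = np.array([r.mae_pct for r in results])
    rs = np.array([r.pearson_r for r in results])
    sd = float(maes.std(ddof=1)) if len(maes) > 1 else float("nan")
    return ValidationSummary(
        per_subject=results,
        cohort_mean_mae_pct=float(maes.mean()),
        cohort_sd_mae_pct=sd,
        cohort_mean_pearson_r=float(rs.mean()),
    )
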