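"""Observer-agreement statistics over paired case scores and statuses.

MSE uses 1/n normalization; Pearson is the sample correlation; Cohen's
kappa is the unweighted two-rater statistic with marginal-product chance
agreement. When both raters are constant and identical, chance agreement is
1 and kappa is defined as 1 by convention (logged).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .her2_grading import status_from_score

__all__ = [
    "AgreementReport",
    "PairedScores",
    "ZeroVarianceError",
    "agreement_report",
    "cohens_kappa",
    "mse",
    "pearson",
    "round_half_up_to",
]

logger = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    pass


def round_half_up_to(x: float, decimals: int) -> float:
    """Display rounding: half-up at a fixed number of decimals."""
    factor = 10**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class PairedScores:
    x: list[float]
    y: list[float]
    case_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValueError(f"length mismatch: {len(self.x)} vs {len(self.y)}")
        if any(v is None or not math.isfinite(v) for v in list(self.x) + list(self.y)):
            raise ValueError("missing or non-finite values")

    @property
    def n(self) -> int:
        return len(self.x)


def mse(pairs: PairedScores) -> float:
    """Mean squared difference, 1/n normalization."""
    if pairs.n < 1:
        raise ValueError("need at least one pair")
    dx = np.asarray(pairs.x, dtype=float) - np.asarray(pairs.y, dtype=float)
    return float(np.mean(dx**2))


def pearson(pairs: PairedScores) -> float:
    """Sample Pearson correlation (normalization-invariant form)."""
    if pairs.n < 2:
        raise ValueError("need at least two pairs for correlation")
    x = np.asarray(pairs.x, dtype=float)
    y = np.asarray(pairs.y, dtype=float)
    dx = x - x.mean()
    dy = y - y.mean()
    denom = math.sqrt(float(dx @ dx) * float(dy @ dy))
    if denom == 0.0:
        raise ZeroVarianceError("undefined correlation: a vector has zero variance")
    return float(dx @ dy) / denom


def _contingency(status_x: Sequence[str], status_y: Sequence[str]) -> np.ndarray:
    labels = sorted(set(status_x) | set(status_y))
    idx = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)), dtype=int)
    for a, b in zip(status_x, status_y):
        table[idx[a], idx[b]] += 1
    return table


def cohens_kappa(status_x: Sequence[str], status_y: Sequence[str]) -> float:
    """Unweighted two-rater kappa: (p_o - p_e) / (1 - p_e)."""
    if len(status_x) != len(status_y):
        raise ValueError("status vectors must have equal length")
    if len(status_x) == 0:
        raise ValueError("empty status vectors")
    n = len(status_x)
    table = _contingency(status_x, status_y)
    p_o = np.trace(table) / n
    p_e = float(table.sum(axis=1) @ table.sum(axis=0)) / (n * n)
    if p_e == 1.0:
        logger.info("both raters constant and equal: kappa = 1 by convention")
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass
class AgreementReport:
    n: int
    mse: float
    pcc: float
    kappa: float
    contingency: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mse": self.mse,
            "pcc": self.pcc,
            "kappa": self.kappa,
            "contingency": self.contingency.tolist(),
        }

    def __str__(self) -> str:
        return (
            f"n={self.n}  MSE={self.mse:.4f}  PCC={self.pcc:.4f}  "
            f"kappa={self.kappa:.4f}"
        )


def agreement_report(
    pairs: PairedScores,
    status_x: Sequence[str] | None = None,
    status_y: Sequence[str] | None = None,
) -> AgreementReport:
    """Bundle MSE, Pearson and kappa; statuses derived from the scores by the
    positivity rule when not supplied.
    """
    if status_x is None:
        status_x = [status_from_score(v) for v in pairs.x]
    if status_y is None:
        status_y = [status_from_score(v) for v in pairs.y]
    return AgreementReport(
        n=pairs.n,
        mse=mse(pairs),
        pcc=pearson(pairs),
        kappa=cohens_kappa(status_x, status_y),
        contingency=_contingency(status_x, status_y),
    )
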