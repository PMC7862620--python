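"""Affinity-accuracy and virtual-screening evaluation metrics.

Score polarity: lower score = better (more negative predicted binding
energy).  Pass ``higher_is_better=True`` to invert.  Ranking ties: AUC uses
average ranks; EF and BEDROC use stable input order (a warning is emitted
when ties straddle the relevant boundary behavior is ambiguous only for EF).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = ["ScreeningTable", "pearson_r", "rmse", "roc_auc",
           "enrichment_factor", "max_enrichment_factor", "bedroc"]


@dataclass
class ScreeningTable:
    ids: List[str]
    scores: np.ndarray
    labels: np.ndarray  # boolean, True = active

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if not (len(self.ids) == len(self.scores) == len(self.labels)):
            raise ValueError("ids, scores and labels must have equal length")

    @property
    def n(self) -> int:
        return len(self.scores)

    @property
    def n_active(self) -> int:
        return int(self.labels.sum())

    def require_both_classes(self) -> None:
        if self.n_active == 0 or self.n_active == self.n:
            raise ValueError("need at least one active and one inactive")


def _ranking(table: ScreeningTable, higher_is_better: bool) -> np.ndarray:
    """Indices sorted best-first; ties broken by stable input order."""
    s = -table.scores if higher_is_better else table.scores
    return np.argsort(s, kind="stable")


def pearson_r(pred: Sequence[float], exp: Sequence[float]) -> float:
    """Pearson correlation coefficient between predictions and experiment."""
    y = np.asarray(pred, dtype=float)
    t = np.asarray(exp, dtype=float)
    if len(y) != len(t):
        raise ValueError("length mismatch")
    if len(y) < 3:
        raise ValueError("need at least 3 points")
    dy = y - y.mean()
    dt = t - t.mean()
    denom = math.sqrt(float(dy @ dy)) * math.sqrt(float(dt @ dt))
    if denom == 0:
        raise ValueError("zero variance in one of the inputs")
    return float(np.clip((dy @ dt) / denom, -1.0, 1.0))


def rmse(pred: Sequence[float], exp: Sequence[float]) -> float:
    y = np.asarray(pred, dtype=float)
    t = np.asarray(exp, dtype=float)
    if len(y) != len(t):
        raise ValueError("length mismatch")
    if len(y) == 0:
        raise ValueError("need at least one point")
    return float(np.sqrt(np.mean((y - t) ** 2)))


def roc_auc(table: ScreeningTable, higher_is_better: bool = False) -> float:
    """Rank-based ROC AUC; tied scores contribute 1/2 (Mann-Whitney)."""
    table.require_both_classes()
    s = -table.scores if higher_is_better else table.scores
    # low score = predicted active, so rank ascending and compare to labels
    ranks = rankdata(s, method="average")
    n_act = table.n_active
    n_inact = table.n - n_act
    rank_sum = ranks[table.labels].sum()
    u = rank_sum - n_act * (n_act + 1) / 2.0
    return float(1.0 - u / (n_act * n_inact))


def enrichment_factor(table: ScreeningTable, fraction: float,
                      higher_is_better: bool = False,
                      fractional: bool = True) -> float:
    """Enrichment factor at the given screened fraction.

    With ``fractional=True`` (default) the compound straddling the
    ``fraction * N`` boundary contributes proportionally, which makes the
    theoretical maximum equal ``min(1/fraction, N/n_active)``.  With
    ``fractional=False`` the conventional integer cutoff
    ``floor(fraction * N)`` is used.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    table.require_both_classes()
    order = _ranking(table, higher_is_better)
    act = table.labels[order].astype(float)
    n = table.n
    n_act = table.n_active
    depth = fraction * n
    if fractional:
        whole = int(math.floor(depth))
        found = act[:whole].sum()
        if whole < n:
            found += (depth - whole) * act[whole]
    else:
        whole = int(math.floor(depth))
        found = act[:whole].sum()
    return float(found / (n_act * fraction))


def max_enrichment_factor(n_active: int, n_total: int, fraction: float) -> float:
    """Best achievable EF: min(1/fraction, n_total/n_active)."""
    if not 0 < n_active <= n_total:
        raise ValueError("require 0 < n_active <= n_total")
    return float(min(1.0 / fraction, n_total / n_active))


def bedroc(table: ScreeningTable, alpha: float,
           higher_is_better: bool = False) -> float:
    """Boltzmann-enhanced discrimination of ROC (exponentially weighted
    early recognition), normalized to [0, 1].

    Computed as the min-max-normalized exponential rank sum
    ``(S - S_min) / (S_max - S_min)`` with ``S = sum_actives exp(-alpha r/N)``,
    the exact discrete form of the RIE normalization: 1 for a perfect
    ranking, 0 for the worst.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    table.require_both_classes()
    order = _ranking(table, higher_is_better)
    n = table.n
    n_act = table.n_active
    ranks = np.flatnonzero(table.labels[order]) + 1  # 1-based best-first
    s = np.exp(-alpha * ranks / n).sum()
    i = np.arange(1, n_act + 1)
    s_max = np.exp(-alpha * i / n).sum()
    s_min = np.exp(-alpha * (n - n_act + i) / n).sum()
    return float((s - s_min) / (s_max - s_min))
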