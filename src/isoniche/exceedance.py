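"""Posterior exceedance probabilities between groups.

The evidence measure for "niche expansion": the percentage of posterior
draws in which one group's metric exceeds another's,

    P(a > b) = 100 * (1/n) * sum_i 1[X_a,i > X_b,i]

over paired draw indices (the default: group posteriors are computed from
disjoint data, so draws are independent and index pairing is just a
Monte Carlo coupling), or over all n^2 cross pairs.  Ties are counted
separately, never split, so P(a>b) + P(b>a) + P(tie) = 100 exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .records import ConfigurationError, logger

PAIRING_MODES = ("by-index", "all-pairs")


@dataclass(frozen=True, slots=True)
class ExceedanceResult:
    """P(a > b) in percent, with tie mass reported separately."""

    label_a: str
    label_b: str
    metric: str
    p_exceed: float
    p_tie: float
    n: int
    pairing: str

    @property
    def p_less(self) -> float:
        return 100.0 - self.p_exceed - self.p_tie


def prob_exceed(draws_a, draws_b,
                pairing: str = "by-index",
                label_a: str = "a", label_b: str = "b",
                metric: str = "") -> ExceedanceResult:
    """Exceedance probability (percent) between two posterior draw vectors.

    ``by-index`` compares draws at matching indices and requires equal
    lengths; ``all-pairs`` compares every draw of a with every draw of b.
    Strict inequality; ties are reported, not split.  Draw vectors shorter
    than 100 carry large Monte Carlo error and trigger a warning.
    """
    if pairing not in PAIRING_MODES:
        raise ConfigurationError(f"pairing must be one of {PAIRING_MODES}")
    a = np.asarray(draws_a, dtype=float).ravel()
    b = np.asarray(draws_b, dtype=float).ravel()
    if min(len(a), len(b)) < 100:
        logger.warning("exceedance computed on < 100 draws; Monte Carlo error is large")
    if pairing == "by-index":
        if len(a) != len(b):
            raise ConfigurationError(
                f"by-index pairing requires equal lengths, got {len(a)} and {len(b)}")
        n = len(a)
        p = 100.0 * np.count_nonzero(a > b) / n
        t = 100.0 * np.count_nonzero(a == b) / n
    else:
        n = len(a) * len(b)
        gt = np.count_nonzero(a[:, None] > b[None, :])
        eq = np.count_nonzero(a[:, None] == b[None, :])
        p = 100.0 * gt / n
        t = 100.0 * eq / n
    return ExceedanceResult(label_a, label_b, metric, p, t, n, pairing)


def comparison_matrix(metric_draws: Mapping[str, Mapping[str, np.ndarray | None]],
                      pairing: str = "by-index") -> pd.DataFrame:
    """Full pairwise exceedance table across groups, per metric.

    ``metric_draws`` maps metric name -> {group label -> draw vector or
    None}.  Both directions of every pair are emitted so report layers can
    pick an orientation (e.g. protected-over-fished).  A group whose draws
    are None (metric unavailable, e.g. a species absent from an area)
    yields rows with NaN probability marked unavailable.
    """
    rows = []
    for metric, groups in metric_draws.items():
        labels = sorted(groups)
        if len(labels) < 2:
            raise ConfigurationError(f"metric {metric}: need >= 2 groups")
        for la, lb in itertools.permutations(labels, 2):
            da, db = groups[la], groups[lb]
            if da is None or db is None:
                rows.append({"metric": metric, "group_a": la, "group_b": lb,
                             "p_exceed_percent": np.nan, "p_tie_percent": np.nan,
                             "n_draws": 0, "mode": pairing, "available": False})
                continue
            r = prob_exceed(da, db, pairing, la, lb, metric)
            rows.append({"metric": metric, "group_a": la, "group_b": lb,
                         "p_exceed_percent": r.p_exceed, "p_tie_percent": r.p_tie,
                         "n_draws": r.n, "mode": pairing, "available": True})
    return pd.DataFrame(rows)
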