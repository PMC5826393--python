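"""Loading-volume correlations against a pseudo-topic resampling null.

A positive correlation between an author's loading on a topic and the
(log) total length of their contributions means the topic becomes more
important the more an author writes.  Because loadings share a general
association with length across all topics, observed per-topic
correlations are judged against pseudo-topics: synthetic loading vectors
formed by giving every author one of their own t loadings chosen
uniformly at random.  The mean and 95% interval of the pseudo-topic
correlations describe what "a generic topic" correlates at; real topics
outside the interval are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from authortopics._seeds import child_seed

__all__ = [
    "log_lengths",
    "topic_length_correlations",
    "PseudoTopicNull",
    "pseudo_topic_null",
    "flag_correlations",
]


@dataclass
class PseudoTopicNull:
    """Summary of the pseudo-topic correlation distribution."""

    n_pseudo: int
    mean_r: float
    ci_low: float
    ci_high: float
    seed: int

    def __post_init__(self) -> None:
        # small slack: on degenerate (constant) null distributions the
        # quantiles and mean differ only by floating-point accumulation
        tol = 1e-9 * max(1.0, abs(self.mean_r))
        if not (self.ci_low - tol <= self.mean_r <= self.ci_high + tol):
            raise ValueError("null interval must bracket its mean")


def log_lengths(char_counts: Sequence[int], base: float = 10.0) -> np.ndarray:
    """Log of per-author combined comment length (characters), default base 10.

    Correlations are invariant to the base (a positive affine transform),
    so the choice only affects display scales.
    """
    counts = np.asarray(char_counts, dtype=float)
    if (counts < 1).any():
        raise ValueError("char counts must be >= 1 for log lengths")
    return np.log(counts) / np.log(base)


def _pearson_columns(M: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Product-moment correlation of each column of M with y; NaN if degenerate."""
    M = np.asarray(M, dtype=float)
    y = np.asarray(y, dtype=float)
    mc = M - M.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((mc**2).sum(axis=0)) * np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mc * yc[:, None]).sum(axis=0) / denom
    r[denom == 0] = np.nan
    return r


def topic_length_correlations(
    W: np.ndarray,
    lengths: Sequence[float],
    assignments: Mapping[str, int] | Sequence[int] | None = None,
    min_group: int = 3,
) -> pd.DataFrame:
    """Per-topic correlation between loading and log length, overall and by subgroup.

    Returns a DataFrame indexed by group ("overall" plus each subgroup
    id) with one column per topic.  Zero-variance loading columns yield
    NaN (undefined, not zero); groups smaller than ``min_group`` are
    skipped with a NaN row.
    """
    W = np.asarray(W, dtype=float)
    y = np.asarray(lengths, dtype=float)
    if W.shape[0] != y.shape[0]:
        raise ValueError("loadings and lengths must cover the same authors")
    rows = {"overall": _pearson_columns(W, y)}
    if assignments is not None:
        labels = np.asarray(
            list(assignments.values()) if isinstance(assignments, Mapping) else assignments
        )
        for g in np.unique(labels):
            mask = labels == g
            if mask.sum() < min_group:
                rows[str(g)] = np.full(W.shape[1], np.nan)
            else:
                rows[str(g)] = _pearson_columns(W[mask], y[mask])
    return pd.DataFrame.from_dict(rows, orient="index")


def pseudo_topic_null(
    W: np.ndarray,
    lengths: Sequence[float],
    n_pseudo: int = 10000,
    seed: int = 0,
) -> PseudoTopicNull:
    """Null distribution of loading-length correlation from pseudo-topics.

    Each pseudo-topic gives every author one of their own t loadings,
    chosen uniformly at random; its correlation with log length is
    recorded.  Returns the mean and the empirical 2.5% / 97.5% quantiles
    over ``n_pseudo`` pseudo-topics.
    """
    W = np.asarray(W, dtype=float)
    y = np.asarray(lengths, dtype=float)
    if n_pseudo < 100:
        raise ValueError("pseudo_topic_null needs at least 100 pseudo-topics")
    n, t = W.shape
    rng = np.random.default_rng(child_seed(seed, "pseudo-topic"))
    rs = np.empty(n_pseudo)
    rows = np.arange(n)
    for i in range(n_pseudo):
        pseudo = W[rows, rng.integers(0, t, size=n)]
        r = _pearson_columns(pseudo[:, None], y)[0]
        rs[i] = 0.0 if np.isnan(r) else r
    return PseudoTopicNull(
        n_pseudo=n_pseudo,
        mean_r=float(rs.mean()),
        ci_low=float(np.quantile(rs, 0.025)),
        ci_high=float(np.quantile(rs, 0.975)),
        seed=seed,
    )


def flag_correlations(
    matrix: pd.DataFrame, null: PseudoTopicNull
) -> pd.DataFrame:
    """Flag each (group, topic) correlation against the pseudo-topic interval.

    "above" iff r > ci_high, "below" iff r < ci_low (strict); undefined
    correlations flag "none".
    """
    flags = pd.DataFrame("none", index=matrix.index, columns=matrix.columns)
    flags[matrix > null.ci_high] = "above"
    flags[matrix < null.ci_low] = "below"
    return flags
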