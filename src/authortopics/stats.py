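"""Subgroup descriptive statistics and Monte Carlo loading significance.

The descriptive table mirrors the posting-pattern summary used to
characterize subgroups: per subgroup the post count, its share of all
posts, the author count, its share of all authors, and posts per author.
A small subgroup whose posts-per-author ratio towers over the forum
average is the signature of a "monological" core — few authors, a large
share of the content.

Significance of a subgroup's mean loading on a topic is judged against a
Monte Carlo null: each topic's loading column is shuffled across authors,
a random pseudo-subgroup the size of the smallest real subgroup is drawn,
and its mean loading recorded; the empirical alpha/2 and 1-alpha/2
quantiles over replicates bound what mean loadings random subgroups
produce.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from authortopics._seeds import child_seed
from authortopics.preprocess import AuthorDocument

__all__ = [
    "subgroup_table",
    "descriptive_stats",
    "select_variable_topics",
    "mc_loading_null",
    "flag_loadings",
    "normalize_loadings_for_display",
]


def subgroup_table(
    posts: Mapping[str, int],
    authors: Mapping[str, int],
    total_posts: int | None = None,
    total_authors: int | None = None,
) -> pd.DataFrame:
    """Build the descriptive table from per-subgroup post and author counts.

    ``total_posts`` / ``total_authors`` default to the sums over
    subgroups; pass them explicitly when the subgroup rows do not cover
    the whole forum.  Returns one row per subgroup plus a leading
    whole-forum row, with columns posts, posts_share, authors,
    authors_share, posts_per_author.
    """
    if set(posts) != set(authors):
        raise ValueError("posts and authors must cover the same subgroups")
    tp = int(total_posts) if total_posts is not None else sum(posts.values())
    ta = int(total_authors) if total_authors is not None else sum(authors.values())
    rows = []
    for name in posts:
        p, a = int(posts[name]), int(authors[name])
        rows.append(
            {
                "group": name,
                "posts": p,
                "posts_share": p / tp if tp else np.nan,
                "authors": a,
                "authors_share": a / ta if ta else np.nan,
                "posts_per_author": p / a if a else np.nan,
            }
        )
    forum = {
        "group": "all",
        "posts": tp,
        "posts_share": 1.0,
        "authors": ta,
        "authors_share": 1.0,
        "posts_per_author": tp / ta if ta else np.nan,
    }
    return pd.DataFrame([forum] + rows).set_index("group")


def descriptive_stats(
    assignments: Mapping[str, int | str],
    docs: Sequence[AuthorDocument],
) -> pd.DataFrame:
    """Per-subgroup posting statistics from author-level metadata.

    ``assignments`` maps author name to subgroup id; every assigned
    author must appear in ``docs``.  Unassigned authors are collected
    into an ``uncategorized`` remainder row so that the share columns sum
    to 1 across subgroups.
    """
    meta = {d.author: d for d in docs}
    missing = [a for a in assignments if a not in meta]
    if missing:
        raise ValueError(f"assigned authors without metadata: {missing[:5]}")
    posts: dict[str, int] = {}
    authors: dict[str, int] = {}
    for d in docs:
        group = assignments.get(d.author, "uncategorized")
        key = str(group)
        posts[key] = posts.get(key, 0) + d.n_comments
        authors[key] = authors.get(key, 0) + 1
    return subgroup_table(posts, authors)


def select_variable_topics(
    W: np.ndarray,
    assignments: Sequence[int],
    n_select: int = 15,
) -> list[int]:
    """Topics ranked by the SD of subgroup mean loadings, most variable first.

    Per topic, the mean loading within each subgroup is computed and the
    population SD of those means taken across subgroups; the ``n_select``
    topics with the largest SD are returned (ties broken by topic id).
    """
    W = np.asarray(W, dtype=float)
    labels = np.asarray(assignments)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("topic variability needs at least two subgroups")
    means = np.vstack([W[labels == g].mean(axis=0) for g in groups])
    sd = means.std(axis=0, ddof=0)
    order = sorted(range(W.shape[1]), key=lambda j: (-sd[j], j))
    return order[: min(n_select, W.shape[1])]


def mc_loading_null(
    W: np.ndarray,
    group_size: int,
    n_reps: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    shuffle: str = "within_topic",
) -> np.ndarray:
    """Monte Carlo null bounds for subgroup mean loadings, per topic.

    Each replicate shuffles the document-topic mapping — by default every
    topic column is permuted independently across authors, destroying
    author-level loading correlations while preserving each topic's
    marginal (``shuffle="rows"`` instead permutes whole author rows) —
    then draws ``group_size`` authors without replacement and records
    their mean loading per topic.  Returns an array of shape (2, t):
    row 0 the alpha/2 quantile, row 1 the 1 - alpha/2 quantile.
    """
    W = np.asarray(W, dtype=float)
    n, t = W.shape
    if group_size > n:
        raise ValueError(f"group_size={group_size} exceeds author count {n}")
    if n_reps < 100:
        raise ValueError("mc_loading_null needs at least 100 replicates")
    if shuffle not in ("within_topic", "rows"):
        raise ValueError(f"unknown shuffle mode: {shuffle!r}")
    rng = np.random.default_rng(child_seed(seed, "mc-null"))
    means = np.empty((n_reps, t))
    for r in range(n_reps):
        if shuffle == "within_topic":
            shuffled = np.column_stack(
                [W[rng.permutation(n), j] for j in range(t)]
            )
        else:
            shuffled = W[rng.permutation(n)]
        pick = rng.choice(n, size=group_size, replace=False)
        means[r] = shuffled[pick].mean(axis=0)
    lo = np.quantile(means, alpha / 2.0, axis=0)
    hi = np.quantile(means, 1.0 - alpha / 2.0, axis=0)
    return np.vstack([lo, hi])


def flag_loadings(
    group_means: np.ndarray, bounds: np.ndarray, atol: float = 1e-12
) -> np.ndarray:
    """Flag each (subgroup, topic) mean against the Monte Carlo bounds.

    Returns an object array of "above", "below" or "none"; a mean equal
    to a bound is not flagged (strict inequalities, with ``atol`` slack
    so a degenerate constant-column null flags nothing).
    """
    gm = np.atleast_2d(np.asarray(group_means, dtype=float))
    lo, hi = bounds[0], bounds[1]
    flags = np.full(gm.shape, "none", dtype=object)
    flags[gm > hi + atol] = "above"
    flags[gm < lo - atol] = "below"
    return flags


def normalize_loadings_for_display(group_means: np.ndarray) -> np.ndarray:
    """Divide each topic column by its maximum over subgroups (0-columns kept)."""
    gm = np.asarray(group_means, dtype=float)
    col_max = gm.max(axis=0)
    out = gm.copy()
    nz = col_max > 0
    out[:, nz] = gm[:, nz] / col_max[nz]
    return out
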