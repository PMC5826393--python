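"""K-means subgroup discovery in topic space and its validation battery.

Authors are partitioned on their complete (unnormalized) topic-loading
rows.  Because k-means always returns a partition, four independent
checks establish that a solution tracks real structure:

* the gap statistic (Tibshirani et al.) — log within-cluster sum of
  squares compared against uniform reference data drawn in the bounding
  box of the loadings;
* percent variance explained (PVE), inspected for an elbow;
* the mean clusterwise silhouette score, whose local maxima mark
  candidate k;
* repeated split-half linear-discriminant classification, whose accuracy
  against chance measures cluster discriminability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import silhouette_samples
from sklearn.model_selection import StratifiedShuffleSplit

from authortopics._seeds import child_seed

__all__ = [
    "ClusterSolution",
    "GapCurve",
    "kmeans",
    "gap_statistic",
    "select_k_gap",
    "select_k_compound",
    "pve",
    "silhouette_mean",
    "split_half_validation",
]


@dataclass
class ClusterSolution:
    """A k-means partition: assignments, centroids, and within-cluster SS."""

    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    within_ss: float


@dataclass
class GapCurve:
    """Gap values and reference-dispersion SDs over a range of k."""

    ks: list[int]
    gap: list[float]
    null_sd: list[float]
    B: int

    def __post_init__(self) -> None:
        if not (len(self.ks) == len(self.gap) == len(self.null_sd)):
            raise ValueError("gap curve fields must have equal length")


def kmeans(
    W: np.ndarray, k: int, n_restarts: int = 10, seed: int = 0
) -> ClusterSolution:
    """Best-of-``n_restarts`` Lloyd k-means on author loading rows."""
    W = np.asarray(W, dtype=float)
    if k > W.shape[0]:
        raise ValueError(f"k={k} exceeds the number of points ({W.shape[0]})")
    km = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        algorithm="lloyd",
        random_state=child_seed(seed, "kmeans", k),
    ).fit(W)
    return ClusterSolution(
        k=k,
        assignments=km.labels_.copy(),
        centroids=km.cluster_centers_.copy(),
        within_ss=float(km.inertia_),
    )


def _log_wss(W: np.ndarray, k: int, n_restarts: int, seed: int) -> float:
    return float(np.log(max(kmeans(W, k, n_restarts=n_restarts, seed=seed).within_ss,
                            1e-300)))


def gap_statistic(
    W: np.ndarray,
    ks: Sequence[int] | None = None,
    B: int = 20,
    seed: int = 0,
    n_restarts: int = 10,
) -> GapCurve:
    """Gap statistic over candidate k against a uniform-box reference.

    For each of B reference replicates, points are drawn uniformly within
    the per-dimension bounds of the data (a zero-range dimension stays
    constant).  gap(k) is the mean reference log within-SS minus the data
    log within-SS; ``null_sd`` carries the (1 + 1/B)^0.5 simulation
    correction of Tibshirani et al.
    """
    W = np.asarray(W, dtype=float)
    if B < 2:
        raise ValueError("gap statistic needs at least B=2 reference replicates")
    if ks is None:
        ks = list(range(2, 31))
    ks = list(ks)
    lo, hi = W.min(axis=0), W.max(axis=0)
    rng = np.random.default_rng(child_seed(seed, "gap-ref"))
    refs = [lo + (hi - lo) * rng.random(W.shape) for _ in range(B)]
    gaps, sds = [], []
    for k in ks:
        log_w = _log_wss(W, k, n_restarts, seed=child_seed(seed, "gap-data", k))
        ref_log_w = np.array(
            [
                _log_wss(refs[b], k, n_restarts, seed=child_seed(seed, "gap-b", k, b))
                for b in range(B)
            ]
        )
        gaps.append(float(ref_log_w.mean() - log_w))
        sds.append(float(ref_log_w.std(ddof=0) * np.sqrt(1.0 + 1.0 / B)))
    return GapCurve(ks=ks, gap=gaps, null_sd=sds, B=B)


def select_k_gap(curve: GapCurve) -> int:
    """Smallest k with gap(k) >= gap(k+1) - sd(k+1) (the standard gap rule)."""
    for i in range(len(curve.ks) - 1):
        if curve.gap[i] >= curve.gap[i + 1] - curve.null_sd[i + 1]:
            return curve.ks[i]
    return curve.ks[-1]


def select_k_compound(
    ks: Sequence[int],
    gap_curve: GapCurve,
    pves: Sequence[float],
    silhouettes: Sequence[float],
    gap_margin_sd: float = 0.0,
    pve_floor_frac: float = 0.5,
    sil_tie_tol: float = 0.01,
) -> tuple[int, dict]:
    """Compound cluster-number rule: gap screen, PVE floor, silhouette maxima.

    Candidates are silhouette local maxima among k whose gap exceeds
    ``gap_margin_sd`` reference SDs above zero (evidence of real
    structure) and whose PVE is at least ``pve_floor_frac`` of the best
    PVE on the scan (dropping low-k maxima that explain little
    variance).  Among candidates, silhouettes within ``sil_tie_tol`` of
    the best are near-ties and the largest such k wins.  Returns the
    chosen k and a decision log.
    """
    ks = list(ks)
    if ks != list(gap_curve.ks):
        raise ValueError("gap curve was computed on a different k range")
    sil = np.asarray(silhouettes, dtype=float)
    pv = np.asarray(pves, dtype=float)
    gap_ok = [
        g > gap_margin_sd * s for g, s in zip(gap_curve.gap, gap_curve.null_sd)
    ]
    maxima = [
        i
        for i in range(len(ks))
        if (i == 0 or sil[i] >= sil[i - 1])
        and (i == len(ks) - 1 or sil[i] >= sil[i + 1])
    ]
    pve_floor = pve_floor_frac * pv.max()
    candidates = [i for i in maxima if gap_ok[i] and pv[i] >= pve_floor]
    log = {
        "silhouette_maxima": [ks[i] for i in maxima],
        "gap_screen_passed": [ks[i] for i in range(len(ks)) if gap_ok[i]],
        "pve_floor": float(pve_floor),
    }
    if not candidates:
        candidates = [int(np.argmax(sil))]
        log["fallback"] = "no candidate passed all screens; best silhouette used"
    best = max(sil[i] for i in candidates)
    near = [i for i in candidates if sil[i] >= best - sil_tie_tol]
    choice = ks[max(near)]
    log["candidates"] = [ks[i] for i in candidates]
    log["near_ties"] = [ks[i] for i in near]
    log["chosen_k"] = choice
    return choice, log


def pve(solution: ClusterSolution, W: np.ndarray) -> float:
    """Fraction of total sum of squares explained by the partition."""
    W = np.asarray(W, dtype=float)
    total_ss = float(((W - W.mean(axis=0)) ** 2).sum())
    if total_ss == 0.0:
        raise ValueError("total sum of squares is zero; variance undefined")
    return float((total_ss - solution.within_ss) / total_ss)


def silhouette_mean(solution: ClusterSolution, W: np.ndarray) -> float:
    """Mean clusterwise silhouette: per-cluster means, then their grand mean.

    Singleton clusters and points with degenerate (all-zero) distances
    score 0 by convention.
    """
    if solution.k < 2:
        raise ValueError("silhouette requires at least two clusters")
    W = np.asarray(W, dtype=float)
    labels = np.asarray(solution.assignments)
    s = silhouette_samples(W, labels)
    s = np.nan_to_num(s, nan=0.0)
    cluster_means = [float(s[labels == c].mean()) for c in np.unique(labels)]
    return float(np.mean(cluster_means))


def split_half_validation(
    W: np.ndarray,
    labels: Sequence[int],
    n_reps: int = 100,
    seed: int = 0,
    chance: str = "sum_squared",
) -> tuple[float, float, float]:
    """Repeated split-half linear-discriminant cluster discriminability.

    Per repetition the authors are split at random into stratified
    halves; a linear discriminant classifier trained on each half
    predicts the other and the two accuracies are averaged.  Returns
    (mean accuracy, sd over repetitions, chance level).  ``chance`` is
    the sum of squared label proportions by default (the accuracy of
    proportional random assignment) or ``"largest_class"``.
    """
    W = np.asarray(W, dtype=float)
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        raise ValueError("every cluster needs at least 2 members for stratified halves")
    props = counts / counts.sum()
    if chance == "sum_squared":
        chance_level = float((props**2).sum())
    elif chance == "largest_class":
        chance_level = float(props.max())
    else:
        raise ValueError(f"unknown chance definition: {chance!r}")
    splitter = StratifiedShuffleSplit(
        n_splits=n_reps, test_size=0.5, random_state=child_seed(seed, "split-half")
    )
    accs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinear loadings are routine
        for idx_a, idx_b in splitter.split(W, y):
            acc = 0.0
            for tr, te in ((idx_a, idx_b), (idx_b, idx_a)):
                clf = LinearDiscriminantAnalysis()
                clf.fit(W[tr], y[tr])
                acc += float((clf.predict(W[te]) == y[te]).mean())
            accs.append(acc / 2.0)
    accs = np.asarray(accs)
    return float(accs.mean()), float(accs.std(ddof=1)), chance_level
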