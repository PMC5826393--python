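"""Topic extraction by non-negative matrix factorization.

The author-term tf-idf matrix ``X`` (a authors x v terms) is factored as
``X ~ W H`` with ``W`` (a x t) the document-topic mapping — ``W[a, t]`` is
author a's loading on topic t — and ``H`` (t x v) the topic-word mapping,
both non-negative.  Optimization is by multiplicative updates on the
squared Frobenius objective, seeded with NNDSVD (the SVD-based
initialization that is the de-facto default for NMF); structural zeros
are filled with the matrix average ("nndsvda", the deterministic
default) or with small random values ("nndsvdar") so that no entry is
locked at zero.

The number of topics t is scanned over a grid; for each fit the mean
pairwise cosine similarity between topic rows of ``H`` measures topic
overlap, and t is chosen where that curve flattens out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.utils.extmath import randomized_svd

from authortopics._seeds import child_seed
from authortopics.vectorize import DocTermMatrix

__all__ = [
    "TopicModel",
    "TopicScanResult",
    "nmf_fit",
    "mean_topic_cosine",
    "scan_topic_numbers",
    "select_topic_number",
    "top_words",
]

_EPS = 1e-10


@dataclass
class TopicModel:
    """An NMF factor pair with its optimization trace."""

    W: np.ndarray
    H: np.ndarray
    t: int
    objective: float
    seed: int
    n_iter: int
    objective_trace: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if (self.W < 0).any() or (self.H < 0).any():
            raise ValueError("NMF factors must be non-negative")


@dataclass
class TopicScanResult:
    """Mean pairwise topic cosine similarity per candidate topic number."""

    grid: list[int]
    mean_cos: list[float]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError("grid must be strictly increasing")


def _as_csr(X: DocTermMatrix | sp.spmatrix | np.ndarray) -> sp.csr_matrix:
    if isinstance(X, DocTermMatrix):
        return X.values.tocsr()
    return sp.csr_matrix(X)


def _nndsvd(X: sp.csr_matrix, t: int, rng: np.random.Generator, variant: str):
    """NNDSVD initialization, zeros filled by the matrix average ("nndsvda",
    deterministic) or by small random values ("nndsvdar")."""
    U, S, Vt = randomized_svd(
        X, n_components=t, random_state=np.random.RandomState(rng.integers(2**31))
    )
    a, v = X.shape
    W = np.zeros((a, t))
    H = np.zeros((t, v))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, t):
        x, y = U[:, j], Vt[j, :]
        xp, xn = np.maximum(x, 0), np.maximum(-x, 0)
        yp, yn = np.maximum(y, 0), np.maximum(-y, 0)
        xp_n, yp_n = np.linalg.norm(xp), np.linalg.norm(yp)
        xn_n, yn_n = np.linalg.norm(xn), np.linalg.norm(yn)
        mp, mn = xp_n * yp_n, xn_n * yn_n
        if mp >= mn and mp > 0:
            u, vv, sigma = xp / xp_n, yp / yp_n, mp
        elif mn > 0:
            u, vv, sigma = xn / xn_n, yn / yn_n, mn
        else:
            continue
        lam = np.sqrt(S[j] * sigma)
        W[:, j] = lam * u
        H[j, :] = lam * vv
    if variant == "nndsvda":
        avg = X.mean()
        W[W == 0] = avg
        H[H == 0] = avg
    elif variant == "nndsvdar":
        avg = X.mean() / 100.0
        W[W == 0] = avg * rng.random(int((W == 0).sum()))
        H[H == 0] = avg * rng.random(int((H == 0).sum()))
    else:
        raise ValueError(f"unknown init variant: {variant!r}")
    return W, H


def _frobenius_error(X: sp.csr_matrix, W: np.ndarray, H: np.ndarray, x_sq: float) -> float:
    # ||X - WH||_F via the trace expansion; avoids densifying X.
    WtX = np.asarray((X.T @ W).T)  # sparse @ dense -> ndarray
    cross = float(np.sum(WtX * H))
    wh_sq = float(np.sum((W.T @ W) * (H @ H.T)))
    return float(np.sqrt(max(x_sq - 2.0 * cross + wh_sq, 0.0)))


def nmf_fit(
    X: DocTermMatrix | sp.spmatrix | np.ndarray,
    t: int,
    max_iter: int = 400,
    tol: float = 1e-4,
    seed: int = 0,
    init: str = "nndsvda",
) -> TopicModel:
    """Factor a non-negative matrix into t topics by multiplicative updates.

    Iterations stop when the relative change of the Frobenius
    reconstruction error between successive sweeps drops below ``tol`` or
    at ``max_iter``.  The per-iteration error trace is retained on the
    returned model; multiplicative updates guarantee it is non-increasing.
    """
    Xc = _as_csr(X)
    a, v = Xc.shape
    if t < 1 or t > min(a, v):
        raise ValueError(f"topic number t={t} out of range for a {a}x{v} matrix")
    if (Xc.data < 0).any():
        raise ValueError("input matrix must be non-negative")
    rng = np.random.default_rng(seed)
    x_sq = float(Xc.multiply(Xc).sum())
    if x_sq == 0.0:  # zero matrix: W = 0 is an exact factorization
        W = np.zeros((a, t))
        H = np.zeros((t, v))
        return TopicModel(W=W, H=H, t=t, objective=0.0, seed=seed, n_iter=0,
                          objective_trace=[0.0])
    W, H = _nndsvd(Xc, t, rng, init)
    err = _frobenius_error(Xc, W, H, x_sq)
    trace = [err]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # Lee-Seung multiplicative updates for the Frobenius objective
        WtX = np.asarray((Xc.T @ W).T)
        H *= WtX / (W.T @ W @ H + _EPS)
        XHt = np.asarray(Xc @ H.T)
        W *= XHt / (W @ (H @ H.T) + _EPS)
        prev, err = err, _frobenius_error(Xc, W, H, x_sq)
        trace.append(err)
        if prev > 0 and abs(prev - err) / prev < tol:
            break
    return TopicModel(
        W=W, H=H, t=t, objective=err, seed=seed, n_iter=n_iter, objective_trace=trace
    )


def mean_topic_cosine(H: np.ndarray) -> float:
    """Mean cosine similarity over all unordered pairs of topic rows of H."""
    H = np.asarray(H, dtype=float)
    t = H.shape[0]
    if t < 2:
        raise ValueError("mean_topic_cosine needs at least two topics")
    norms = np.linalg.norm(H, axis=1)
    if (norms == 0).any():
        raise ValueError("degenerate topic: an all-zero topic row has no direction")
    U = H / norms[:, None]
    G = U @ U.T
    iu = np.triu_indices(t, k=1)
    return float(np.clip(G[iu].mean(), 0.0, 1.0))


def scan_topic_numbers(
    X: DocTermMatrix | sp.spmatrix | np.ndarray,
    grid: Sequence[int] | None = None,
    seed: int = 0,
    max_iter: int = 400,
    tol: float = 1e-4,
    init: str = "nndsvda",
) -> TopicScanResult:
    """Fit one NMF model per grid point and record mean topic cosine.

    The default grid is t = 12, 15, ..., 90 (step 3).  Per-point seeds are
    derived deterministically from the master seed so individual points
    can be re-fit in isolation.
    """
    if grid is None:
        grid = list(range(12, 91, 3))
    grid = list(grid)
    mean_cos = []
    for t in grid:
        model = nmf_fit(X, t, max_iter=max_iter, tol=tol,
                        seed=child_seed(seed, "scan", t), init=init)
        mean_cos.append(mean_topic_cosine(model.H))
    return TopicScanResult(grid=grid, mean_cos=mean_cos)


def select_topic_number(scan: TopicScanResult, flatten_threshold: float = 0.25) -> int:
    """Pick the topic number where the cosine curve flattens out.

    "Flattening" is formalized as a corridor rule: the chosen t is the
    smallest grid point from which the remaining curve stays within a
    corridor whose width is ``flatten_threshold`` times the curve's full
    range (so a perfectly flat curve selects the smallest grid value,
    and a curve that is exactly constant from some point selects that
    point).  The corridor must contain at least three grid points; if no
    tail of that length is flat — e.g. the curve is still changing
    steeply at the end of the grid — the last grid point is returned
    with a warning.
    """
    if len(scan.grid) < 3:
        raise ValueError("topic-number selection needs at least three grid points")
    m = np.asarray(scan.mean_cos, dtype=float)
    corridor = flatten_threshold * (m.max() - m.min())
    for j in range(len(scan.grid) - 2):
        tail = m[j:]
        if tail.max() - tail.min() <= corridor:
            return scan.grid[j]
    warnings.warn(
        "mean topic cosine never flattens on this grid; returning the last grid point",
        stacklevel=2,
    )
    return scan.grid[-1]


def top_words(
    H: np.ndarray, terms: Sequence[str], k: int = 15
) -> list[list[tuple[str, float]]]:
    """Per topic, the k heaviest terms in descending weight, ties lexicographic."""
    H = np.asarray(H, dtype=float)
    if k > len(terms):
        raise ValueError("k exceeds vocabulary size")
    out = []
    for row in H:
        order = sorted(range(len(terms)), key=lambda i: (-row[i], terms[i]))
        out.append([(terms[i], float(row[i])) for i in order[:k]])
    return out
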