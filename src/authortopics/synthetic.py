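"""Synthetic forum corpora with planted topics, subgroups and volume structure.

The generator emulates the statistical features of a real conspiracy-forum
comment dump that the downstream pipeline keys on, with exported ground
truth so that recovery can be scored:

* latent topics as word-emission distributions (optionally with disjoint
  dominant-word support, the well-separated regime);
* author subgroups with distinct topic-loading profiles, including a
  small "monological" subgroup loading highly on every topic while
  posting far more than the rest;
* heavy-tailed (log-normal) comments-per-author and tokens-per-comment
  counts;
* an optional planted positive coupling between an author's posting
  volume and one designated topic loading.

Comments are emitted in the same JSON-lines record schema as real input
(author, body, created_utc, subreddit), so downstream stages cannot
distinguish synthetic from real data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from authortopics._seeds import child_seed

__all__ = [
    "TopicDictionary",
    "SubgroupProfile",
    "GroundTruth",
    "generate_topics",
    "generate_corpus",
    "default_profiles",
    "write_corpus",
]


def _term_name(i: int) -> str:
    """Purely alphabetic synthetic term ("q" + base-26 code), immune to cleaning."""
    letters = []
    i, rem = divmod(i, 26)
    letters.append(chr(ord("a") + rem))
    while i:
        i, rem = divmod(i, 26)
        letters.append(chr(ord("a") + rem))
    return "q" + "".join(reversed(letters))


@dataclass
class TopicDictionary:
    """Ground-truth topics: per-topic word emission probabilities."""

    n_topics_true: int
    vocabulary: list[str]
    word_probs: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValueError("vocabulary terms must be unique")
        wp = np.asarray(self.word_probs, dtype=float)
        if wp.shape != (self.n_topics_true, len(self.vocabulary)):
            raise ValueError("word_probs shape must be n_topics x vocab size")
        if (wp < 0).any():
            raise ValueError("word probabilities must be non-negative")
        if not np.allclose(wp.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each topic row must sum to 1")
        self.word_probs = wp


@dataclass
class SubgroupProfile:
    """One planted author subgroup: loading profile and posting-volume law."""

    name: str
    mean_loading: np.ndarray
    loading_dispersion: float
    n_authors: int
    volume_log_mean: float
    volume_log_sd: float

    def __post_init__(self) -> None:
        ml = np.asarray(self.mean_loading, dtype=float)
        if (ml < 0).any() or not (ml > 0).any():
            raise ValueError("mean_loading must be non-negative with a positive entry")
        if self.n_authors < 1:
            raise ValueError("a subgroup needs at least one author")
        if self.loading_dispersion < 0 or self.volume_log_sd < 0:
            raise ValueError("dispersions must be non-negative")
        self.mean_loading = ml


@dataclass
class GroundTruth:
    """Exported generation truth: labels and the loadings actually used."""

    author_labels: dict[str, str]
    true_loadings: np.ndarray
    authors: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.author_labels) != self.true_loadings.shape[0]:
            raise ValueError("one loading row per labeled author required")


def generate_topics(
    vocab_size: int,
    n_topics_true: int,
    concentration: float = 0.1,
    seed: int = 0,
    disjoint_support: bool = False,
) -> TopicDictionary:
    """Draw topic word-emission rows from a symmetric Dirichlet.

    With ``disjoint_support`` the vocabulary is split into contiguous
    blocks, one per topic, and each topic's Dirichlet is supported only
    on its own block — the limiting well-separated regime in which
    topics share no words at all.
    """
    if concentration <= 0:
        raise ValueError("Dirichlet concentration must be positive")
    if not (2 <= n_topics_true <= vocab_size):
        raise ValueError("need vocab_size >= n_topics_true >= 2")
    rng = np.random.default_rng(child_seed(seed, "topics"))
    vocabulary = [_term_name(i) for i in range(vocab_size)]
    if disjoint_support:
        word_probs = np.zeros((n_topics_true, vocab_size))
        bounds = np.linspace(0, vocab_size, n_topics_true + 1).astype(int)
        for k in range(n_topics_true):
            lo, hi = bounds[k], bounds[k + 1]
            word_probs[k, lo:hi] = rng.dirichlet(np.full(hi - lo, concentration))
    else:
        word_probs = rng.dirichlet(
            np.full(vocab_size, concentration), size=n_topics_true
        )
    return TopicDictionary(
        n_topics_true=n_topics_true, vocabulary=vocabulary, word_probs=word_probs
    )


def generate_corpus(
    topics: TopicDictionary,
    profiles: Sequence[SubgroupProfile],
    seed: int = 0,
    volume_topic: int | None = None,
    volume_coef: float = 0.0,
    comment_log_mean: float = 3.0,
    comment_log_sd: float = 0.7,
    noise_word_prob: float = 0.0,
    subreddit: str = "synthetic",
) -> tuple[list[dict], GroundTruth]:
    """Generate comment records and ground truth for the given subgroups.

    Per author: the loading vector is the profile mean perturbed by
    multiplicative gamma noise (mean 1, coefficient of variation equal
    to ``loading_dispersion``; zero dispersion leaves the mean exact);
    the comment count is log-normal (rounded up, minimum 1) from the
    profile's volume parameters; token counts per comment are log-normal
    (default log-mean 3.0, log-sd 0.7 — lengths spanning orders of
    magnitude).  If ``volume_topic`` is set, ``volume_coef *
    log(total tokens)`` is added to that loading before normalization,
    planting a volume-topic correlation.  Each comment's words are drawn
    i.i.d. from the author's normalized topic mixture times the topic
    word-emission matrix, blended with a uniform distribution over the
    whole vocabulary at weight ``noise_word_prob`` (residual non-topical
    words: cleaning leftovers, typos, idiosyncratic vocabulary).
    """
    if not profiles:
        raise ValueError("at least one subgroup profile is required")
    if len(topics.vocabulary) == 0:
        raise ValueError("topic dictionary has an empty vocabulary")
    t = topics.n_topics_true
    for p in profiles:
        if p.mean_loading.shape != (t,):
            raise ValueError(f"profile {p.name!r} loading length != {t}")
    if volume_topic is not None and not (0 <= volume_topic < t):
        raise ValueError("volume_topic out of range")

    rng = np.random.default_rng(child_seed(seed, "corpus"))
    records: list[dict] = []
    labels: dict[str, str] = {}
    loadings_rows: list[np.ndarray] = []
    authors: list[str] = []
    author_no = 0
    ts = 1_400_000_000  # arbitrary epoch origin for synthetic timestamps
    for prof in profiles:
        for _ in range(prof.n_authors):
            author = f"author_{author_no:05d}"
            author_no += 1
            n_comments = max(
                1,
                math.ceil(
                    float(
                        rng.lognormal(prof.volume_log_mean, prof.volume_log_sd)
                    )
                ),
            )
            lengths = np.maximum(
                1,
                np.ceil(
                    rng.lognormal(comment_log_mean, comment_log_sd, size=n_comments)
                ).astype(int),
            )
            total_tokens = int(lengths.sum())
            if prof.loading_dispersion > 0:
                shape = 1.0 / prof.loading_dispersion**2
                noise = rng.gamma(shape, scale=1.0 / shape, size=t)
            else:
                noise = np.ones(t)
            loading = prof.mean_loading * noise
            if volume_topic is not None and volume_coef != 0.0:
                loading = loading.copy()
                loading[volume_topic] += volume_coef * math.log(total_tokens)
            mixture = loading / loading.sum()
            word_dist = mixture @ topics.word_probs
            if noise_word_prob > 0:
                uniform = np.full(len(topics.vocabulary), 1.0 / len(topics.vocabulary))
                word_dist = (1.0 - noise_word_prob) * word_dist + noise_word_prob * uniform
            word_dist = word_dist / word_dist.sum()
            tokens = rng.choice(
                len(topics.vocabulary), size=total_tokens, p=word_dist
            )
            offset = 0
            for ln in lengths:
                body = " ".join(topics.vocabulary[i] for i in tokens[offset : offset + ln])
                offset += ln
                records.append(
                    {
                        "author": author,
                        "body": body,
                        "created_utc": ts,
                        "subreddit": subreddit,
                    }
                )
                ts += 60
            labels[author] = prof.name
            loadings_rows.append(loading)
            authors.append(author)
    truth = GroundTruth(
        author_labels=labels,
        true_loadings=np.vstack(loadings_rows),
        authors=authors,
        seed=seed,
    )
    return records, truth


def default_profiles(
    n_topics: int = 6,
    n_authors: int = 600,
    monological_frac: float = 0.1,
    baseline: float = 0.2,
    background: float = 0.7,
    dominant: float = 3.0,
    monological_loading: float = 2.4,
    loading_dispersion: float = 0.3,
    thematic_log_mean: float = 1.2,
    thematic_log_sd: float = 0.6,
    monological_log_mean: float = 3.8,
    monological_log_sd: float = 0.5,
) -> list[SubgroupProfile]:
    """Study-condition subgroup layout: thematic groups plus a monological core.

    Topic 0 is a shared background topic every author loads on
    moderately (the natural designee for the planted volume coupling,
    like a general evidence-and-argument topic); topics 1 to
    ``n_topics - 2`` each anchor one thematic subgroup that loads
    dominantly on it; the last topic is a niche theme carried mainly by
    the final subgroup, which loads highly on *every* topic while
    posting at a log-mean volume high enough to contribute a
    disproportionate share of comments — the "small but vocal"
    monological pattern.  The default layout is therefore 6 topics /
    5 subgroups / 600 authors.
    """
    n_mono = max(1, round(n_authors * monological_frac))
    n_thematic_groups = n_topics - 2
    if n_thematic_groups < 1:
        raise ValueError("need at least three topics")
    per_group = (n_authors - n_mono) // n_thematic_groups
    profiles = []
    base = np.full(n_topics, baseline)
    base[0] = background
    for g in range(n_thematic_groups):
        ml = base.copy()
        ml[1 + g] = dominant
        profiles.append(
            SubgroupProfile(
                name=f"thematic_{g}",
                mean_loading=ml,
                loading_dispersion=loading_dispersion,
                n_authors=per_group,
                volume_log_mean=thematic_log_mean,
                volume_log_sd=thematic_log_sd,
            )
        )
    profiles.append(
        SubgroupProfile(
            name="monological",
            mean_loading=np.full(n_topics, monological_loading),
            loading_dispersion=loading_dispersion,
            n_authors=n_authors - per_group * n_thematic_groups,
            volume_log_mean=monological_log_mean,
            volume_log_sd=monological_log_sd,
        )
    )
    return profiles


def write_corpus(
    records: Sequence[dict],
    truth: GroundTruth,
    out_dir: str | Path,
    manifest: dict | None = None,
) -> None:
    """Persist comments (JSON lines), ground truth (TSV) and a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "comments.jsonl", "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")
    t = truth.true_loadings.shape[1]
    with open(out / "ground_truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("author\tsubgroup\t" + "\t".join(f"loading_{j}" for j in range(t)) + "\n")
        for i, author in enumerate(truth.authors):
            row = "\t".join(f"{x:.8g}" for x in truth.true_loadings[i])
            fh.write(f"{author}\t{truth.author_labels[author]}\t{row}\n")
    if manifest is not None:
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
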