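"""End-to-end orchestration: comments in, validated subgroup report out.

Stages: preprocess (clean, de-bot, aggregate, median filter) -> tf-idf
vectorize -> topic-number scan and NMF fit -> k-means clustering with the
validation battery -> subgroup descriptive statistics and Monte Carlo
loading significance -> loading-length correlations against the
pseudo-topic null.  Every intermediate is persisted under the output
directory and every random procedure draws its seed deterministically
from the single master seed, so the run is a pure function of (input
bytes, config) and any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from authortopics._version import __version__
from authortopics._seeds import child_seed
from authortopics import cluster as _cluster
from authortopics import correlate as _correlate
from authortopics import stats as _stats
from authortopics import topics as _topics
from authortopics import vectorize as _vectorize
from authortopics.preprocess import (
    aggregate_authors,
    clean_comment,
    load_stopwords,
    median_filter,
    read_jsonl,
    remove_bots,
    write_author_documents,
)

logger = logging.getLogger("authortopics")

__all__ = ["RunConfig", "RunReport", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults.

    Defaults follow the study conditions where stated (median filter,
    topic grid 12..90 step 3, gap k = 2..30 with B = 20, 1,000-replicate
    loading null at alpha 0.01, 15 most-variable topics, 10,000
    pseudo-topics); the rest are the package's documented choices.
    """

    input_path: str = ""
    output_dir: str = "run_output"
    seed: int = 0
    # preprocessing
    bot_list: str | None = None
    stopword_file: str | None = None
    # vectorizing
    min_doc_freq: int = 2
    max_doc_prop: float = 0.5
    # topic model
    topic_grid: list[int] = field(default_factory=lambda: list(range(12, 91, 3)))
    flatten_threshold: float = 0.25  # corridor width as a fraction of curve range
    nmf_max_iter: int = 400
    nmf_tol: float = 1e-4
    n_topics: int | None = None  # override: skip the scan
    top_k_words: int = 15
    # clustering
    cluster_ks: list[int] = field(default_factory=lambda: list(range(2, 31)))
    gap_B: int = 20
    kmeans_restarts: int = 10
    n_clusters: int | None = None  # override: skip k selection
    split_half_reps: int = 100
    chance_definition: str = "sum_squared"
    # subgroup statistics
    n_variable_topics: int = 15
    mc_reps: int = 1000
    mc_alpha: float = 0.01
    mc_shuffle: str = "within_topic"
    # correlations
    n_pseudo: int = 10000
    log_base: float = 10.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True),
            encoding="utf-8",
        )


@dataclass
class RunReport:
    """Headline results plus pointers to the persisted intermediates."""

    chosen_t: int
    chosen_k: int
    n_authors: int
    n_terms: int
    nmf_objective: float
    scan: pd.DataFrame
    validation: pd.DataFrame
    split_half: tuple[float, float, float]
    k_decision: dict
    subgroup_table: pd.DataFrame
    variable_topics: list[int]
    loading_flags: pd.DataFrame
    correlations: pd.DataFrame
    correlation_flags: pd.DataFrame
    pseudo_null: _correlate.PseudoTopicNull
    output_dir: Path


def _stage_seed(cfg: RunConfig, name: str) -> int:
    return child_seed(cfg.seed, "stage", name)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages; persist intermediates; return the report."""
    inp = Path(config.input_path)
    if not inp.exists():
        raise FileNotFoundError(f"input not found: {inp}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    # --- preprocess -----------------------------------------------------
    logger.info("reading comments from %s", inp)
    comments = read_jsonl(inp)
    if config.bot_list:
        bots = {
            b.strip()
            for b in Path(config.bot_list).read_text(encoding="utf-8").splitlines()
            if b.strip()
        }
        comments = remove_bots(comments, bots)
    stopwords = load_stopwords(config.stopword_file)
    cleaned = [
        dataclasses.replace(c, body=clean_comment(c.body, stopwords))
        for c in comments
    ]
    docs = median_filter(aggregate_authors(cleaned))
    docs = [d for d in docs if d.char_count > 0]
    logger.info("%d authors retained after median filter", len(docs))
    write_author_documents(docs, out / "author_documents.tsv")

    # --- vectorize ------------------------------------------------------
    vocab = _vectorize.build_vocabulary(
        docs, min_doc_freq=config.min_doc_freq, max_doc_prop=config.max_doc_prop
    )
    X = _vectorize.tfidf(docs, vocab)
    _vectorize.save_matrix(X, out / "tfidf")
    logger.info("tf-idf matrix: %d authors x %d terms", *X.values.shape)

    # --- topic model ----------------------------------------------------
    tm_seed = _stage_seed(config, "topics")
    if config.n_topics is None:
        scan = _topics.scan_topic_numbers(
            X,
            grid=config.topic_grid,
            seed=tm_seed,
            max_iter=config.nmf_max_iter,
            tol=config.nmf_tol,
        )
        chosen_t = _topics.select_topic_number(scan, config.flatten_threshold)
    else:
        chosen_t = config.n_topics
        scan = _topics.TopicScanResult(grid=[chosen_t], mean_cos=[np.nan])
    scan_df = pd.DataFrame({"t": scan.grid, "mean_cosine": scan.mean_cos})
    scan_df.to_csv(out / "topic_scan.tsv", sep="\t", index=False)
    model = _topics.nmf_fit(
        X,
        chosen_t,
        max_iter=config.nmf_max_iter,
        tol=config.nmf_tol,
        seed=child_seed(tm_seed, "final", chosen_t),
    )
    logger.info("fitted t=%d topics (objective %.4f)", chosen_t, model.objective)
    ranked = _topics.top_words(model.H, X.col_labels, k=config.top_k_words)
    with open(out / "topic_words.tsv", "w", encoding="utf-8") as fh:
        fh.write("topic\trank\tterm\tweight\n")
        for ti, words in enumerate(ranked):
            for rank, (term, weight) in enumerate(words, 1):
                fh.write(f"{ti}\t{rank}\t{term}\t{weight:.6g}\n")
    pd.DataFrame(
        model.W, index=X.row_labels, columns=[f"topic_{j}" for j in range(chosen_t)]
    ).to_csv(out / "loadings.tsv", sep="\t")

    # --- clustering -----------------------------------------------------
    cl_seed = _stage_seed(config, "cluster")
    W = model.W
    ks = [k for k in config.cluster_ks if k <= W.shape[0]]
    gap_curve = _cluster.gap_statistic(
        W, ks=ks, B=config.gap_B, seed=cl_seed, n_restarts=config.kmeans_restarts
    )
    pves, sils = [], []
    for k in ks:
        sol = _cluster.kmeans(
            W, k, n_restarts=config.kmeans_restarts, seed=child_seed(cl_seed, "scan", k)
        )
        pves.append(_cluster.pve(sol, W))
        sils.append(_cluster.silhouette_mean(sol, W))
    if config.n_clusters is None:
        chosen_k, k_log = _cluster.select_k_compound(ks, gap_curve, pves, sils)
    else:
        chosen_k, k_log = config.n_clusters, {"chosen_k": config.n_clusters,
                                              "override": True}
    validation = pd.DataFrame(
        {
            "k": ks,
            "gap": gap_curve.gap,
            "gap_null_sd": gap_curve.null_sd,
            "pve": pves,
            "silhouette": sils,
        }
    )
    validation.to_csv(out / "cluster_validation.tsv", sep="\t", index=False)
    solution = _cluster.kmeans(
        W, chosen_k, n_restarts=config.kmeans_restarts,
        seed=child_seed(cl_seed, "final", chosen_k),
    )
    logger.info("chose k=%d clusters", chosen_k)
    pd.DataFrame(
        {"author": X.row_labels, "cluster": solution.assignments}
    ).to_csv(out / "assignments.tsv", sep="\t", index=False)
    split_half = _cluster.split_half_validation(
        W,
        solution.assignments,
        n_reps=config.split_half_reps,
        seed=child_seed(cl_seed, "split"),
        chance=config.chance_definition,
    )

    # --- subgroup statistics -------------------------------------------
    assignments = {a: int(c) for a, c in zip(X.row_labels, solution.assignments)}
    table = _stats.descriptive_stats(assignments, docs)
    table.to_csv(out / "subgroup_table.tsv", sep="\t")
    variable = _stats.select_variable_topics(
        W, solution.assignments, n_select=config.n_variable_topics
    )
    sizes = np.bincount(solution.assignments)
    bounds = _stats.mc_loading_null(
        W,
        group_size=int(sizes[sizes > 0].min()),
        n_reps=config.mc_reps,
        alpha=config.mc_alpha,
        seed=_stage_seed(config, "mc-null"),
        shuffle=config.mc_shuffle,
    )
    group_ids = np.unique(solution.assignments)
    group_means = np.vstack(
        [W[solution.assignments == g].mean(axis=0) for g in group_ids]
    )
    flags = _stats.flag_loadings(group_means, bounds)
    flag_df = pd.DataFrame(
        flags, index=[f"cluster_{g}" for g in group_ids],
        columns=[f"topic_{j}" for j in range(W.shape[1])],
    )
    flag_df.to_csv(out / "loading_flags.tsv", sep="\t")
    display = _stats.normalize_loadings_for_display(group_means[:, variable])
    pd.DataFrame(
        display, index=[f"cluster_{g}" for g in group_ids],
        columns=[f"topic_{j}" for j in variable],
    ).to_csv(out / "loading_display.tsv", sep="\t")

    # --- correlations ---------------------------------------------------
    lengths = _correlate.log_lengths(
        [d.char_count for d in docs], base=config.log_base
    )
    corr = _correlate.topic_length_correlations(W, lengths, solution.assignments)
    null = _correlate.pseudo_topic_null(
        W, lengths, n_pseudo=config.n_pseudo, seed=_stage_seed(config, "pseudo"),
    )
    corr_flags = _correlate.flag_correlations(corr, null)
    corr.to_csv(out / "correlations.tsv", sep="\t")
    corr_flags.to_csv(out / "correlation_flags.tsv", sep="\t")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            s: _stage_seed(config, s) for s in ("topics", "cluster", "mc-null", "pseudo")
        },
        "chosen_t": int(chosen_t),
        "chosen_k": int(chosen_k),
        "k_decision": k_log,
        "n_authors": len(docs),
        "n_terms": len(X.col_labels),
        "nmf_objective": float(model.objective),
        "split_half": {
            "mean_accuracy": split_half[0],
            "sd": split_half[1],
            "chance_level": split_half[2],
        },
        "pseudo_null": {
            "mean_r": null.mean_r,
            "ci_low": null.ci_low,
            "ci_high": null.ci_high,
            "n_pseudo": null.n_pseudo,
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return RunReport(
        chosen_t=int(chosen_t),
        chosen_k=int(chosen_k),
        n_authors=len(docs),
        n_terms=len(X.col_labels),
        nmf_objective=float(model.objective),
        scan=scan_df,
        validation=validation,
        split_half=split_half,
        k_decision=k_log,
        subgroup_table=table,
        variable_topics=variable,
        loading_flags=flag_df,
        correlations=corr,
        correlation_flags=corr_flags,
        pseudo_null=null,
        output_dir=out,
    )
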