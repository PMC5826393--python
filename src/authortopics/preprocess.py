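"""Comment cleaning, bot removal, author aggregation and the median filter.

Raw forum comments are cleaned to a lower-case stream of alphabetic tokens
(quotes, URLs, markdown, punctuation, digits and stopwords removed), then
concatenated into a single document per author.  Authors who contributed
fewer than the median number of comments are dropped: low-posting authors
carry little information about their interests, and the median gives a
corpus-adaptive cutoff.
"""

from __future__ import annotations

import html
import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "RawComment",
    "AuthorDocument",
    "load_stopwords",
    "clean_comment",
    "remove_bots",
    "aggregate_authors",
    "median_filter",
    "read_jsonl",
    "write_author_documents",
    "read_author_documents",
]


@dataclass(frozen=True)
class RawComment:
    """One forum comment as ingested from a JSON-lines dump."""

    author: str
    body: str
    created_utc: int
    subreddit: str = ""

    def __post_init__(self) -> None:
        if not self.author:
            raise ValueError("comment author must be non-empty")


@dataclass
class AuthorDocument:
    """One author's concatenated cleaned comments.

    ``char_count`` is measured on the cleaned text, so the tf-idf input and
    the length covariate used downstream share one text representation.
    """

    author: str
    text: str
    n_comments: int
    char_count: int

    def __post_init__(self) -> None:
        if self.n_comments < 1:
            raise ValueError("an AuthorDocument needs at least one comment")
        if self.char_count != len(self.text):
            raise ValueError("char_count must equal len(text)")


def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """Load the stopword list (packaged English list by default).

    The packaged list stores contractions with the apostrophe removed
    ("dont", "im") to match the cleaning rules, which strip punctuation
    inside tokens.
    """
    if path is None:
        text = (
            resources.files("authortopics.data")
            .joinpath("stopwords_en.txt")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    return frozenset(w.strip().lower() for w in text.splitlines() if w.strip())


_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MD_LINK_RE = re.compile(r"\[([^\]]*)\]\([^)]*\)")
_NON_ALPHA_RE = re.compile(r"[^a-z\s]+")
_APOSTROPHE_RE = re.compile(r"[’']")


def clean_comment(body: str, stopword_list: Iterable[str] | None = None) -> str:
    """Clean one comment body to a whitespace-joined token stream.

    Applied in order: HTML entities unescaped; quoted lines (markdown
    ``>`` prefix) dropped; URLs dropped; markdown links reduced to their
    anchor text; lower-cased; apostrophes deleted (so contractions collapse
    to one token); every remaining non-letter character replaced by a
    space; stopwords removed; whitespace normalized.  Cleaning is
    idempotent: a cleaned text passes through unchanged.
    """
    if stopword_list is None:
        stopword_list = load_stopwords()
    stopwords = stopword_list if isinstance(stopword_list, (set, frozenset)) else set(stopword_list)

    text = html.unescape(body)
    lines = [ln for ln in text.split("\n") if not ln.lstrip().startswith(">")]
    text = " ".join(lines)
    text = _URL_RE.sub(" ", text)
    text = _MD_LINK_RE.sub(r"\1", text)
    text = text.lower()
    text = _APOSTROPHE_RE.sub("", text)
    text = _NON_ALPHA_RE.sub(" ", text)
    tokens = [t for t in text.split() if t not in stopwords]
    return " ".join(tokens)


def remove_bots(
    comments: Sequence[RawComment], bot_authors: Iterable[str]
) -> list[RawComment]:
    """Drop all comments whose author is on the bot list; order preserved."""
    bots = set(bot_authors)
    return [c for c in comments if c.author not in bots]


def aggregate_authors(comments: Sequence[RawComment]) -> list[AuthorDocument]:
    """Combine each author's (already cleaned) comments into one document.

    Comments are concatenated in ascending ``created_utc`` order.  A
    comment whose cleaned body is empty still counts toward
    ``n_comments``.  Output is sorted by author name.
    """
    by_author: dict[str, list[RawComment]] = {}
    for c in comments:
        by_author.setdefault(c.author, []).append(c)
    docs = []
    for author in sorted(by_author):
        cs = sorted(by_author[author], key=lambda c: c.created_utc)
        text = " ".join(c.body for c in cs if c.body)
        docs.append(
            AuthorDocument(
                author=author, text=text, n_comments=len(cs), char_count=len(text)
            )
        )
    return docs


def median_filter(docs: Sequence[AuthorDocument]) -> list[AuthorDocument]:
    """Keep authors whose comment count is at least the corpus median.

    The median uses the lower-interpolation convention on even counts, so
    the threshold is always an observed integer; authors exactly at the
    median are retained.
    """
    if not docs:
        raise ValueError("median_filter requires a non-empty document list")
    counts = sorted(d.n_comments for d in docs)
    median = counts[(len(counts) - 1) // 2]
    return [d for d in docs if d.n_comments >= median]


def read_jsonl(path: str | Path) -> list[RawComment]:
    """Read comment records from a JSON-lines file."""
    comments = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            comments.append(
                RawComment(
                    author=rec["author"],
                    body=rec["body"],
                    created_utc=int(rec["created_utc"]),
                    subreddit=rec.get("subreddit", ""),
                )
            )
    return comments


def write_author_documents(docs: Sequence[AuthorDocument], path: str | Path) -> None:
    """Persist author documents as a UTF-8 TSV (author, n_comments, char_count, text)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("author\tn_comments\tchar_count\ttext\n")
        for d in docs:
            fh.write(f"{d.author}\t{d.n_comments}\t{d.char_count}\t{d.text}\n")


def read_author_documents(path: str | Path) -> list[AuthorDocument]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("author\t"):
            raise ValueError(f"not an author-document TSV: {path}")
        for line in fh:
            author, n_comments, char_count, text = line.rstrip("\n").split("\t", 3)
            docs.append(
                AuthorDocument(
                    author=author,
                    text=text,
                    n_comments=int(n_comments),
                    char_count=int(char_count),
                )
            )
    return docs
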