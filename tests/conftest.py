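import numpy as np
import pytest

from authortopics.preprocess import AuthorDocument, RawComment


@pytest.fixture
def toy_comments():
    """Four authors with known comment counts and timestamps."""
    mk = RawComment
    return [
        mk("alice", "apple banana", 100),
        mk("bob", "banana cherry", 101),
        mk("alice", "apple apple", 102),
        mk("carol", "date", 103),
        mk("alice", "banana", 104),
        mk("bob", "cherry cherry cherry", 105),
        mk("dave", "", 106),
    ]


@pytest.fixture
def toy_docs():
    def doc(author, text, n_comments=1):
        return AuthorDocument(
            author=author, text=text, n_comments=n_comments, char_count=len(text)
        )

    return [
        doc("a", "apple banana apple"),
        doc("b", "banana banana banana"),
        doc("c", "apple cherry"),
        doc("d", "cherry date banana"),
        doc("e", "fig"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
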