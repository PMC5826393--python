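"""The synthetic-corpus generator and its exported ground truth."""

import numpy as np
import pytest

from authortopics.synthetic import (
    SubgroupProfile,
    default_profiles,
    generate_corpus,
    generate_topics,
)


class TestGenerateTopics:
    def test_rows_are_distributions(self):
        topics = generate_topics(50, 5, concentration=0.1, seed=1)
        np.testing.assert_allclose(topics.word_probs.sum(axis=1), 1.0, atol=1e-9)
        assert topics.word_probs.min() >= 0

    def test_disjoint_support_option(self):
        topics = generate_topics(10, 2, concentration=0.5, seed=0,
                                 disjoint_support=True)
        support = topics.word_probs > 0
        assert not np.any(support[0] & support[1])

    def test_deterministic_given_seed(self):
        a = generate_topics(30, 4, seed=7)
        b = generate_topics(30, 4, seed=7)
        np.testing.assert_array_equal(a.word_probs, b.word_probs)
        assert a.vocabulary == b.vocabulary

    def test_vocabulary_unique_and_alphabetic(self):
        topics = generate_topics(700, 3, seed=2)
        assert len(set(topics.vocabulary)) == 700
        assert all(term.isalpha() and term.islower() for term in topics.vocabulary)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_concentration_raises(self, bad):
        with pytest.raises(ValueError):
            generate_topics(10, 2, concentration=bad, seed=0)


class TestGenerateCorpus:
    @staticmethod
    def _profile(**kw):
        defaults = dict(
            name="g",
            mean_loading=np.array([1.0, 1.0]),
            loading_dispersion=0.0,
            n_authors=5,
            volume_log_mean=1.0,
            volume_log_sd=0.3,
        )
        defaults.update(kw)
        return SubgroupProfile(**defaults)

    def test_zero_dispersion_keeps_mean_loading_exact(self):
        topics = generate_topics(10, 2, seed=0)
        prof = self._profile(mean_loading=np.array([0.3, 0.7]))
        _, truth = generate_corpus(topics, [prof], seed=1)
        np.testing.assert_allclose(
            truth.true_loadings, np.tile([0.3, 0.7], (5, 1)), atol=1e-12
        )

    def test_deterministic_given_seed(self):
        topics = generate_topics(20, 3, seed=0)
        profs = [self._profile(mean_loading=np.array([1.0, 0.5, 0.2]))]
        r1, t1 = generate_corpus(topics, profs, seed=9)
        r2, t2 = generate_corpus(topics, profs, seed=9)
        assert r1 == r2
        np.testing.assert_array_equal(t1.true_loadings, t2.true_loadings)

    def test_word_frequencies_converge_to_topic_distribution(self):
        """One topic at weight 1, many tokens: empirical TV distance small."""
        topics = generate_topics(40, 2, concentration=1.0, seed=3)
        prof = self._profile(
            mean_loading=np.array([1.0, 0.0]),
            n_authors=1,
            volume_log_mean=4.0,
            volume_log_sd=0.0,
        )
        records, _ = generate_corpus(
            topics, [prof], seed=4, comment_log_mean=6.0, comment_log_sd=0.0
        )
        tokens = " ".join(r["body"] for r in records).split()
        assert len(tokens) > 20_000
        counts = np.zeros(40)
        index = {w: i for i, w in enumerate(topics.vocabulary)}
        for tok in tokens:
            counts[index[tok]] += 1
        tv = 0.5 * np.abs(counts / counts.sum() - topics.word_probs[0]).sum()
        assert tv < 0.05

    def test_tv_distance_decreases_with_token_count(self):
        topics = generate_topics(30, 2, concentration=1.0, seed=5)
        tvs = []
        for log_len in (2.0, 6.0):
            prof = self._profile(
                mean_loading=np.array([1.0, 0.0]),
                n_authors=1,
                volume_log_mean=3.0,
                volume_log_sd=0.0,
            )
            records, _ = generate_corpus(
                topics, [prof], seed=6, comment_log_mean=log_len, comment_log_sd=0.0
            )
            tokens = " ".join(r["body"] for r in records).split()
            counts = np.zeros(30)
            index = {w: i for i, w in enumerate(topics.vocabulary)}
            for tok in tokens:
                counts[index[tok]] += 1
            tvs.append(0.5 * np.abs(counts / counts.sum() - topics.word_probs[0]).sum())
        assert tvs[1] < tvs[0]

    def test_records_follow_input_schema(self):
        topics = generate_topics(10, 2, seed=0)
        records, _ = generate_corpus(topics, [self._profile()], seed=0)
        assert {"author", "body", "created_utc", "subreddit"} == set(records[0])
        assert all(r["body"] for r in records)

    def test_high_volume_subgroup_overrepresented_in_posts(self):
        """Planted volume: comment share far exceeds author share."""
        topics = generate_topics(30, 2, seed=1)
        quiet = self._profile(name="quiet", n_authors=90, volume_log_mean=1.0)
        loud = self._profile(name="loud", n_authors=10, volume_log_mean=3.5)
        records, truth = generate_corpus(topics, [quiet, loud], seed=2)
        loud_authors = {a for a, g in truth.author_labels.items() if g == "loud"}
        loud_posts = sum(r["author"] in loud_authors for r in records)
        posts_share = loud_posts / len(records)
        authors_share = len(loud_authors) / 100
        assert posts_share / authors_share >= 5

    def test_volume_coupling_raises_designated_loading(self):
        topics = generate_topics(20, 3, seed=2)
        prof = self._profile(
            mean_loading=np.array([1.0, 1.0, 1.0]),
            n_authors=100,
            volume_log_sd=1.0,
        )
        _, truth = generate_corpus(
            topics, [prof], seed=3, volume_topic=1, volume_coef=1.0
        )
        # designated loading exceeds the others and tracks volume
        assert truth.true_loadings[:, 1].mean() > truth.true_loadings[:, 0].mean()

    def test_planted_share_correlation_monotone_in_coefficient(self):
        """The designated topic's true mixture share tracks volume more
        strongly as the coupling coefficient grows."""
        topics = generate_topics(20, 3, seed=4)
        prof = self._profile(
            mean_loading=np.array([1.0, 1.0, 1.0]),
            n_authors=150,
            volume_log_sd=1.0,
            loading_dispersion=0.3,
        )
        rs = []
        for c in (0.0, 0.5, 2.0):
            records, truth = generate_corpus(
                topics, [prof], seed=5, volume_topic=1, volume_coef=c
            )
            tokens = {}
            for r in records:
                tokens[r["author"]] = tokens.get(r["author"], 0) + len(r["body"].split())
            share = truth.true_loadings[:, 1] / truth.true_loadings.sum(axis=1)
            logv = np.log([tokens[a] for a in truth.authors])
            rs.append(np.corrcoef(share, logv)[0, 1])
        assert rs[0] < rs[1] < rs[2]

    def test_empty_profiles_raise(self):
        topics = generate_topics(10, 2, seed=0)
        with pytest.raises(ValueError):
            generate_corpus(topics, [], seed=0)


class TestDefaultProfiles:
    def test_five_subgroups_for_six_topics(self):
        profs = default_profiles()
        assert len(profs) == 5
        assert sum(p.n_authors for p in profs) == 600
        assert profs[-1].name == "monological"

    def test_monological_group_loads_on_every_topic(self):
        profs = default_profiles()
        assert np.all(profs[-1].mean_loading > 1.0)
        for p in profs[:-1]:
            assert (p.mean_loading > 1.0).sum() == 1
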