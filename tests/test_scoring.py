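import math

import numpy as np
import pytest

from mirmix.scoring import (
    Grouping,
    enrichment,
    group_frequency_profile,
    group_summaries,
    hamming,
    hierarchical_grouping,
    match_score,
    random_grouping,
    silhouette_score,
    silhouette_scores,
)

from conftest import brute_match_score, brute_silhouette


def make_grouping(seeds, labels, k=None):
    k = k if k is not None else max(labels) + 1
    return Grouping(
        ids=[f"s{i}" for i in range(len(seeds))],
        labels=np.asarray(labels),
        k=k,
        seeds=list(seeds),
    )


class TestHamming:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("AUACAA", "AUACAA", 0),
            ("AUACAA", "AUACAC", 1),
            ("AAAAAA", "UUUUUU", 6),
        ],
    )
    def test_values(self, a, b, expected):
        assert hamming(a, b) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            hamming("ACG", "ACGU")


class TestSilhouette:
    def test_perfectly_separated_identical_clusters(self):
        seeds = ["AAAAAA", "AAAAAA", "CCCCCC", "CCCCCC"]
        g = make_grouping(seeds, [0, 0, 1, 1])
        assert np.allclose(silhouette_scores(g, seeds), 1.0)

    def test_singleton_scores_zero(self):
        seeds = ["AAAAAA", "CCCCCC", "CCCCCC"]
        g = make_grouping(seeds, [0, 1, 1])
        assert silhouette_score("s0", g, seeds) == 0.0

    def test_single_group_is_error(self):
        seeds = ["AAAAAA", "CCCCCC"]
        g = make_grouping(seeds, [0, 0], k=2)
        with pytest.raises(ValueError, match="2 non-empty"):
            silhouette_scores(g, seeds)

    def test_matches_brute_force(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 21))
            seeds = ["".join(rng.choice(list("ACGU"), size=6)) for _ in range(n)]
            labels = rng.integers(0, int(rng.integers(2, 5)), size=n)
            if len(set(labels.tolist())) < 2:
                continue
            g = make_grouping(seeds, labels, k=int(labels.max()) + 1)
            mine = silhouette_scores(g, seeds)
            assert np.allclose(mine, brute_silhouette(seeds, labels), atol=1e-12)
            assert np.all(mine >= -1 - 1e-12) and np.all(mine <= 1 + 1e-12)

    def test_matches_sklearn_on_precomputed_hamming(self, rng):
        """Cross-check against sklearn's silhouette on a Hamming matrix."""
        from sklearn.metrics import silhouette_samples

        from mirmix.scoring import hamming_matrix

        n = 30
        seeds = ["".join(rng.choice(list("ACGU"), size=6)) for _ in range(n)]
        labels = rng.integers(0, 3, size=n)
        g = make_grouping(seeds, labels, k=3)
        ours = silhouette_scores(g, seeds)
        ref = silhouette_samples(
            hamming_matrix(seeds).astype(float), labels, metric="precomputed"
        )
        assert np.allclose(ours, ref, atol=1e-10)


class TestMatchScore:
    def test_identical_group_scores_one(self):
        profile = group_frequency_profile(["AUACAA"] * 10)
        assert match_score("AUACAA", profile) == 1.0

    def test_uniform_profile_degenerate(self):
        profile = group_frequency_profile(["AAAAAA", "CCCCCC", "GGGGGG", "UUUUUU"])
        score, degenerate = match_score("AAAAAA", profile, return_degenerate=True)
        assert score == 0.0 and degenerate

    def test_against_formula_oracle(self):
        members = ["AAAAAA", "AAAAAC", "AAAACC"]
        profile = group_frequency_profile(members)
        assert match_score("AAAAAA", profile) == pytest.approx(
            brute_match_score("AAAAAA", members), abs=1e-12
        )

    def test_random_instances_match_oracle_and_range(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 15))
            members = ["".join(rng.choice(list("ACGU"), size=6)) for _ in range(n)]
            probe = "".join(rng.choice(list("ACGU"), size=6))
            profile = group_frequency_profile(members)
            val = match_score(probe, profile)
            assert val == pytest.approx(brute_match_score(probe, members), abs=1e-12)
            assert -1e-12 <= val <= 1 + 1e-12

    def test_consensus_scores_one_when_not_uniform(self, rng):
        from mirmix.pwm import consensus

        for _ in range(20):
            members = ["".join(rng.choice(list("ACGU"), size=6)) for _ in range(5)]
            profile = group_frequency_profile(members)
            score, degenerate = match_score(
                consensus(profile.freqs), profile, return_degenerate=True
            )
            if not degenerate:
                assert score == pytest.approx(1.0, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            match_score("ACG", group_frequency_profile(["AAAAAA"]))


class TestGroupSummaries:
    def test_perfect_clusters(self):
        seeds = ["AAAAAA", "AAAAAA", "CCCCCC", "CCCCCC"]
        table, global_means = group_summaries(make_grouping(seeds, [0, 0, 1, 1]), seeds)
        assert np.allclose(table.mean_score_S, 1.0)
        assert np.allclose(table.mean_score_M, 1.0)
        assert global_means == {"n": 4, "mean_score_S": 1.0, "mean_score_M": 1.0}

    def test_single_group_silhouette_is_na(self):
        seeds = ["AAAAAA", "AAAAAC"]
        table, global_means = group_summaries(make_grouping(seeds, [0, 0]), seeds)
        assert math.isnan(table.mean_score_S.iloc[0])
        assert math.isnan(global_means["mean_score_S"])
        assert table.n_members.iloc[0] == 2

    def test_means_match_brute_force(self, rng):
        seeds = ["".join(rng.choice(list("ACGU"), size=6)) for _ in range(12)]
        labels = rng.integers(0, 2, size=12)
        if len(set(labels.tolist())) < 2:
            labels[0] = 1 - labels[0]
        g = make_grouping(seeds, labels, k=2)
        table, global_means = group_summaries(g, seeds)
        sil = brute_silhouette(seeds, labels)
        match = np.array(
            [
                brute_match_score(
                    s, [seeds[j] for j in range(12) if labels[j] == labels[i]]
                )
                for i, s in enumerate(seeds)
            ]
        )
        assert global_means["mean_score_S"] == pytest.approx(sil.mean(), abs=1e-12)
        assert global_means["mean_score_M"] == pytest.approx(match.mean(), abs=1e-12)
        for row in table.itertuples(index=False):
            members = labels == row.group_index
            assert row.mean_score_S == pytest.approx(sil[members].mean(), abs=1e-12)


class TestBaselines:
    def test_random_grouping_k1_and_determinism(self):
        ids = [f"s{i}" for i in range(100)]
        assert set(random_grouping(ids, 1, 0).labels.tolist()) == {0}
        a = random_grouping(ids, 4, 7)
        b = random_grouping(ids, 4, 7)
        assert np.array_equal(a.labels, b.labels)

    def test_random_grouping_sizes_concentrate(self):
        ids = [f"s{i}" for i in range(4000)]
        g = random_grouping(ids, 4, 1)
        counts = np.bincount(g.labels, minlength=4)
        assert np.all(np.abs(counts - 1000) < 4 * math.sqrt(4000))

    def test_hierarchical_recovers_identical_blocks(self):
        seeds = ["AAAAAA"] * 3 + ["CCCCCC"] * 4
        g = hierarchical_grouping(seeds, 2)
        assert len(set(g.labels[:3].tolist())) == 1
        assert len(set(g.labels[3:].tolist())) == 1
        assert g.labels[0] != g.labels[3]

    def test_hierarchical_k_equals_n(self):
        seeds = ["AAAAAA", "CCCCCC", "GGGGGG"]
        g = hierarchical_grouping(seeds, 3)
        assert sorted(g.labels.tolist()) == [0, 1, 2]

    def test_hierarchical_hand_worked_dendrogram(self):
        # within-block distances 0, 1, 3; all across-block distances are >= 5,
        # so average linkage must merge the three blocks first
        seeds = ["AAAAAA", "AAAAAA", "CCCCCC", "CCCCCU", "GGGGGG", "GGGUUU"]
        g = hierarchical_grouping(seeds, 3)
        blocks = [g.labels[:2], g.labels[2:4], g.labels[4:]]
        assert all(len(set(b.tolist())) == 1 for b in blocks)
        assert len({b[0] for b in blocks}) == 3

    def test_hierarchical_too_few_records(self):
        with pytest.raises(ValueError):
            hierarchical_grouping(["AAAAAA"], 2)


def test_mixture_grouping_beats_random_on_silhouette():
    """On well-separated simulated data, the EM grouping's mean silhouette
    strictly exceeds a random grouping's at the same k (20 seeded trials)."""
    from mirmix.mixture import PWMMixture
    from mirmix.simulate import sample_mixture

    for trial in range(20):
        t = sample_mixture(
            k=3, n=120, separation="planted_consensus", rng_seed=40_000 + trial
        )
        model = PWMMixture(3, random_state=trial).fit(t.seeds)
        seeds = [s.seed for s in t.seeds]
        ids = [s.id for s in t.seeds]
        em = Grouping(ids=ids, labels=model.labels_, k=3, seeds=seeds)
        rand = random_grouping(ids, 3, rng_seed=trial, seeds=seeds)
        assert (
            silhouette_scores(em, seeds).mean()
            > silhouette_scores(rand, seeds).mean()
        )


class TestEnrichment:
    def test_whole_family_in_one_group(self):
        seeds = ["AAAAAA"] * 5
        g = make_grouping(seeds, [2] * 5, k=3)
        table = enrichment(g, {"let-7": {f"s{i}" for i in range(5)}})
        row = table.iloc[0]
        assert (row.best_group, row.enrichment) == (2, "5/5")

    def test_split_family_best_overlap(self):
        g = make_grouping(["AAAAAA"] * 3, [0, 0, 1], k=2)
        row = enrichment(g, {"f": {"s0", "s1", "s2"}}).iloc[0]
        assert (row.best_group, row.enrichment) == (0, "2/3")

    def test_tie_goes_to_lowest_group(self):
        g = make_grouping(["AAAAAA"] * 4, [1, 1, 0, 0], k=2)
        row = enrichment(g, {"f": {"s0", "s1", "s2", "s3"}}).iloc[0]
        assert row.best_group == 0

    def test_missing_members_counted_in_size(self):
        g = make_grouping(["AAAAAA"] * 2, [0, 0], k=1)
        row = enrichment(g, {"f": {"s0", "s1", "ghost"}}).iloc[0]
        assert (row.enrichment, row.n_missing) == ("2/3", 1)

    def test_fully_absent_family_is_error(self):
        g = make_grouping(["AAAAAA"], [0], k=1)
        with pytest.raises(ValueError, match="ghost"):
            enrichment(g, {"f": {"ghost"}})
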