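"""KS connectivity scoring: closed forms, brute-force oracle and selection rules."""

import numpy as np
import pytest

import organodx as ox
from organodx import connectivity as cx


def brute_force_ks(tags, ranking):
    """Literal loop implementation of the signed KS enrichment statistic."""
    n = len(ranking)
    pos = sorted(i + 1 for i, f in enumerate(ranking) if f in set(tags))
    t = len(pos)
    a = max((j + 1) / t - pos[j] / n for j in range(t))
    b = max(pos[j] / n - j / t for j in range(t))
    return a if a > b else -b


def brute_force_raw(up, down, ranking):
    a = brute_force_ks(up, ranking)
    b = brute_force_ks(down, ranking)
    if (a > 0) == (b > 0):
        return 0.0
    return (a - b) / 2.0


FEATURES = [f"g{i:03d}" for i in range(60)]


def make_profile(pid, order):
    return cx.ReferenceProfile(pid, tuple(order))


class TestKsEnrichment:
    def test_tags_on_top_closed_form(self):
        tags = set(FEATURES[:4])
        stat = ox.ks_enrichment(tags, make_profile("p", FEATURES))
        assert stat == pytest.approx(1 - 4 / 60)

    def test_tags_on_bottom_negative_mirror(self):
        tags = set(FEATURES[-4:])
        stat = ox.ks_enrichment(tags, make_profile("p", FEATURES))
        assert stat == pytest.approx(-(60 - 4 + 1) / 60)
        assert abs(abs(stat) - (1 - 4 / 60)) <= 1 / 60  # mirror up to rank discreteness

    def test_interleaved_tags_near_zero(self):
        tags = set(FEATURES[::10])  # evenly spread
        stat = ox.ks_enrichment(tags, make_profile("p", FEATURES))
        assert abs(stat) < 0.2

    def test_empty_tags_rejected(self):
        with pytest.raises(ValueError):
            ox.ks_enrichment(set(), make_profile("p", FEATURES))

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            order = list(FEATURES)
            rng.shuffle(order)
            tags = set(rng.choice(FEATURES, size=5, replace=False))
            assert ox.ks_enrichment(tags, make_profile("p", order)) == pytest.approx(
                brute_force_ks(tags, order)
            )


class TestConnectivityScore:
    def query(self):
        return cx.QuerySignature(frozenset(FEATURES[:5]), frozenset(FEATURES[5:10]))

    def test_maximal_reversal_and_mirror(self):
        q = self.query()
        up, down = sorted(q.up_set), sorted(q.down_set)
        rest = [f for f in FEATURES if f not in q.up_set | q.down_set]
        reverser = make_profile("rev", down + rest + up)
        mimic = make_profile("mim", up + rest + down)
        hits = {h.perturbagen_id: h.score for h in ox.score_profiles(q, [reverser, mimic])}
        assert hits["rev"] == pytest.approx(-100.0)
        assert hits["mim"] == pytest.approx(100.0)

    def test_single_profile_normalizes_to_extremes(self):
        q = self.query()
        up, down = sorted(q.up_set), sorted(q.down_set)
        rest = [f for f in FEATURES if f not in q.up_set | q.down_set]
        hit = cx.connectivity_score(q, make_profile("rev", down + rest + up))
        assert hit.score == -100.0

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(1)
        q = self.query()
        profiles = []
        for i in range(20):
            order = list(FEATURES)
            rng.shuffle(order)
            profiles.append(make_profile(f"p{i:02d}", order))
        hits = {h.perturbagen_id: h.score for h in ox.score_profiles(q, profiles)}
        raws = {p.perturbagen_id: brute_force_raw(q.up_set, q.down_set, p.ranking)
                for p in profiles}
        scale = max(abs(v) for v in raws.values())
        for pid, raw in raws.items():
            assert hits[pid] == pytest.approx(100.0 * raw / scale)

    def test_swapping_up_down_negates_scores(self):
        rng = np.random.default_rng(2)
        q = self.query()
        profiles = []
        for i in range(10):
            order = list(FEATURES)
            rng.shuffle(order)
            profiles.append(make_profile(f"p{i}", order))
        direct = {h.perturbagen_id: h.score for h in ox.score_profiles(q, profiles)}
        swapped = {h.perturbagen_id: h.score for h in ox.score_profiles(q.swapped(), profiles)}
        for pid in direct:
            assert swapped[pid] == pytest.approx(-direct[pid])

    def test_reversing_profiles_negates_scores(self):
        rng = np.random.default_rng(3)
        q = self.query()
        profiles = []
        for i in range(10):
            order = list(FEATURES)
            rng.shuffle(order)
            profiles.append(make_profile(f"p{i}", order))
        direct = {h.perturbagen_id: h.score for h in ox.score_profiles(q, profiles)}
        rev = {h.perturbagen_id: h.score
               for h in ox.score_profiles(q, [p.reversed_profile() for p in profiles])}
        for pid in direct:
            assert rev[pid] == pytest.approx(-direct[pid])

    def test_invariant_to_nontag_relabeling(self):
        q = self.query()
        order = list(FEATURES)
        base = cx.raw_connectivity(q, make_profile("p", order))
        relabeled = [f if f in q.up_set | q.down_set else f"x_{f}" for f in order]
        assert cx.raw_connectivity(q, make_profile("p", relabeled)) == pytest.approx(base)

    def test_multi_instance_averaging(self):
        q = self.query()
        up, down = sorted(q.up_set), sorted(q.down_set)
        rest = [f for f in FEATURES if f not in q.up_set | q.down_set]
        inst1 = make_profile("drugA", down + rest + up)
        inst2 = make_profile("drugA", down + rest[::-1] + up)
        hits = ox.score_profiles(q, [inst1, inst2])
        assert hits[0].n_instances == 2

    def test_low_coverage_profile_excluded_with_warning(self):
        q = self.query()
        partial = make_profile("partial", FEATURES[3:])  # misses 3/5 of up set
        full = make_profile("full", FEATURES)
        with pytest.warns(UserWarning, match="50%"):
            hits = ox.score_profiles(q, [partial, full])
        assert [h.perturbagen_id for h in hits] == ["full"]


class TestSelectCandidates:
    def hit(self, pid, score):
        return cx.ConnectivityHit(pid, score, 1, 0.0)

    def test_disjoint_passing_sets_empty(self):
        a = [self.hit("x", -99.0), self.hit("y", -10.0)]
        b = [self.hit("x", -10.0), self.hit("y", -99.0)]
        assert len(ox.select_candidates(a, b, -95.0)) == 0

    def test_shared_strong_reverser_returned(self):
        a = [self.hit("x", -98.0), self.hit("y", -99.0)]
        b = [self.hit("x", -98.0), self.hit("z", -99.0)]
        result = ox.select_candidates(a, b, -95.0)
        assert result["perturbagen_id"].tolist() == ["x"]
        assert result["mean_score"].iloc[0] == -98.0

    def test_threshold_minus_100_boundary(self):
        a = [self.hit("x", -100.0), self.hit("y", -99.9)]
        b = [self.hit("x", -100.0), self.hit("y", -100.0)]
        result = ox.select_candidates(a, b, -100.0)
        assert result["perturbagen_id"].tolist() == ["x"]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        a = [self.hit(f"p{i}", rng.uniform(-100, 0)) for i in range(30)]
        b = [self.hit(f"p{i}", rng.uniform(-100, 0)) for i in range(30)]
        prev: set = set()
        for thr in (-99.0, -90.0, -50.0, 0.0):
            cur = set(ox.select_candidates(a, b, thr)["perturbagen_id"])
            assert prev <= cur
            prev = cur

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            ox.select_candidates([], [], 5.0)


class TestProfileIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        profiles = []
        for i in range(3):
            order = list(FEATURES)
            rng.shuffle(order)
            profiles.append(make_profile(f"p{i}", order))
        path = tmp_path / "profiles.tsv"
        cx.write_profiles(profiles, path)
        back = {p.perturbagen_id: p.ranking for p in cx.read_profiles(path)}
        for p in profiles:
            assert back[p.perturbagen_id] == p.ranking
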