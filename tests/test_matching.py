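"""Trimmed-distance matching: hand examples, oracle equivalence, enrollment."""

import numpy as np
import pytest

from finprint import matching as M
from finprint.types import DotPattern as DP


def brute_force_distance(q, t, cfg):
    """Independent O(n*m*grid) reimplementation used as the oracle."""
    best = (np.inf, None)
    steps = np.arange(-cfg.max_shift, cfg.max_shift + cfg.shift_step / 2,
                      cfg.shift_step)
    for dx in steps:
        for dy in steps:
            ds = sorted(
                min(np.hypot(qq[0] - (tt[0] + dx), qq[1] - (tt[1] + dy))
                    for tt in t)
                for qq in q)
            k = max(int(np.ceil(cfg.trim_fraction * len(q))), 1)
            v = float(np.mean(ds[:k]))
            if v < best[0] - 1e-15:
                best = (v, (dx, dy))
    return best


class TestPatternDistanceAtShift:
    def test_outlier_trimming_hand_example(self):
        q = DP([(0, 0), (10, 0), (20, 0), (100, 50)])
        t = DP([(0, 0), (10, 0), (20, 0)])
        # NN distances {0,0,0,sqrt(80^2+50^2)}; keep ceil(3/4*4)=3 smallest
        assert M.pattern_distance_at_shift(q, t, (0, 0)) == 0.0

    def test_identity_zero(self):
        p = DP([(3, 4), (100, 60), (400, 10)])
        assert M.pattern_distance_at_shift(p, p, (0, 0)) == 0.0

    def test_single_point_euclidean(self):
        assert M.pattern_distance_at_shift(DP([(0, 0)]), DP([(3, 4)]),
                                           (0, 0)) == 5.0

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            M.pattern_distance_at_shift(DP(np.empty((0, 2))), DP([(0, 0)]),
                                        (0, 0))


class TestPatternDistance:
    def test_grid_shift_recovered(self):
        base = np.array([(0.0, 0), (10, 5), (30, 7), (80, 40)])
        d, s = M.pattern_distance(DP(base), DP(base + [15, -10]))
        assert d == pytest.approx(0.0, abs=1e-9)
        assert s == (-15.0, 10.0)

    def test_off_grid_shift_leaves_residual(self):
        base = np.array([(0.0, 0), (10, 5), (30, 7)])
        d, s = M.pattern_distance(DP(base), DP(base + [17, 0]))
        assert d <= 2.0 + 1e-9
        assert s == (-15.0, 0.0)

    def test_oracle_equivalence_random_patterns(self, rng):
        """Exact agreement (distance and tie-break) with the brute force."""
        for _ in range(25):
            q = rng.uniform(0, 300, (int(rng.integers(1, 11)), 2))
            t = rng.uniform(0, 300, (int(rng.integers(1, 11)), 2))
            got = M.pattern_distance(DP(q), DP(t))
            exp = brute_force_distance(q, t, M.SHORT_TERM)
            assert got[0] == pytest.approx(exp[0], abs=1e-9)
            assert got[1] == exp[1]

    def test_self_distance_zero_at_origin_shift(self, rng):
        for _ in range(10):
            p = DP(rng.uniform(0, 800, (int(rng.integers(1, 25)), 2)))
            d, s = M.pattern_distance(p, p)
            assert d == 0.0 and s == (0.0, 0.0)

    def test_trim_monotonicity(self, rng):
        p = DP(rng.uniform(0, 300, (12, 2)))
        t = DP(rng.uniform(0, 300, (12, 2)))
        dists = [M.pattern_distance(
            p, t, M.MatchConfig(trim_fraction=f))[0]
            for f in (0.25, 0.5, 0.75, 1.0)]
        assert dists == sorted(dists)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            M.MatchConfig(max_shift=32.0, shift_step=5.0)
        with pytest.raises(ValueError):
            M.MatchConfig(trim_fraction=0.0)

    def test_scale_grid_helps_under_uniform_scaling(self):
        base = np.array([(350.0, 20), (500, 100), (700, 60), (900, 150)])
        centroid = base.mean(axis=0)
        scaled = centroid + 1.1 * (base - centroid)
        plain, _ = M.pattern_distance(DP(base), DP(scaled))
        cfg = M.MatchConfig(scale_grid=(0.9, 0.95, 1.0, 1.05, 1.1))
        with_scale, _ = M.pattern_distance(DP(base), DP(scaled), cfg)
        assert with_scale <= plain


class TestComparable:
    @pytest.mark.parametrize("na,nb,expected", [
        (10, 20, True),    # boundary is inclusive
        (10, 21, False),   # ratio 2.1
        (7, 7, True),
        (20, 10, True),
    ])
    def test_count_ratio(self, na, nb, expected, rng):
        a = DP(rng.uniform(0, 100, (na, 2)))
        b = DP(rng.uniform(0, 100, (nb, 2)))
        assert M.comparable(a, b) is expected


class TestIdentifyShortTerm:
    def test_cohort_separability(self, patterns_by_fish):
        """Every third detected pattern identifies its own fish."""
        gallery = {fid: pats[:2] for fid, pats in patterns_by_fish.items()}
        for fid, pats in patterns_by_fish.items():
            res = M.identify_short_term(pats[2], gallery)
            assert res.predicted_id == fid
            assert res.distances[res.predicted_id] == min(res.distances.values())

    def test_single_fish_gallery(self, rng):
        q = DP(rng.uniform(0, 500, (8, 2)), fish_id=3)
        res = M.identify_short_term(q, {7: [DP(rng.uniform(0, 500, (8, 2)))]})
        assert res.predicted_id == 7

    def test_tie_breaks_to_smaller_id(self, rng):
        tpl = DP(rng.uniform(0, 500, (8, 2)))
        res = M.identify_short_term(tpl, {5: [tpl], 2: [tpl]})
        assert res.predicted_id == 2

    def test_empty_gallery_rejected(self, rng):
        with pytest.raises(ValueError):
            M.identify_short_term(DP(rng.uniform(0, 10, (4, 2))), {})

    def test_count_heuristic_fallback(self, rng):
        # gallery patterns all non-comparable -> heuristic relaxed
        q = DP(rng.uniform(0, 500, (4, 2)))
        g = {1: [DP(rng.uniform(0, 500, (30, 2)))]}
        res = M.identify_short_term(q, g)
        assert res.predicted_id == 1

    def test_heuristic_never_changes_prediction(self, patterns_by_fish):
        gallery = {fid: pats[:2] for fid, pats in patterns_by_fish.items()}
        loose = M.MatchConfig(count_ratio_max=np.inf)
        for fid, pats in patterns_by_fish.items():
            with_h = M.identify_short_term(pats[2], gallery)
            without_h = M.identify_short_term(pats[2], gallery, loose)
            assert with_h.predicted_id == without_h.predicted_id


class TestBuildRepresentative:
    def test_identical_copies_full_support(self, rng):
        p = rng.uniform(0, 500, (9, 2))
        rep = M.build_representative([DP(p) for _ in range(6)])
        assert len(rep) == 9
        assert np.all(rep.support == 6)
        assert np.allclose(np.sort(rep.points, axis=0), np.sort(p, axis=0))

    def test_support_rule_arithmetic(self, rng):
        """N=6: a dot present in 4 patterns is kept, one in 2 is dropped."""
        base = np.array([(400.0, 50), (500, 100), (600, 150), (700, 60),
                         (800, 120)])
        extra = np.array([[900.0, 30]])    # only in reference + 1 other
        sets = []
        for i in range(6):
            pts = base.copy()
            if i < 4:
                pts = np.vstack([pts, [350.0, 180]])  # in 4 of 6
            if i < 2:
                pts = np.vstack([pts, extra])
            sets.append(DP(pts + rng.normal(0, 1, pts.shape)))
        rep = M.build_representative(sets)
        # base dots (support 6) and the 4-pattern dot survive; extra dies
        assert len(rep) == 6
        assert not np.any(np.hypot(*(rep.points - extra[0]).T) < 20)

    def test_jittered_patterns_recover_truth(self, rng):
        truth = rng.uniform((340, 30), (960, 240), (14, 2))
        pats = [DP(truth + rng.normal(0, 3, truth.shape)) for _ in range(6)]
        rep = M.build_representative(pats)
        d = np.sqrt(((rep.points[:, None] - truth[None]) ** 2).sum(-1)).min(1)
        assert np.mean(d < 6) >= 0.9          # recovers >= 90% of true dots
        assert len(rep) <= len(truth) + 1      # and adds (almost) nothing

    def test_single_pattern_passthrough_warns(self, rng):
        p = DP(rng.uniform(0, 100, (5, 2)))
        with pytest.warns(UserWarning):
            rep = M.build_representative([p])
        assert np.array_equal(rep.points, p.points)


class TestIdentifyLongTerm:
    def test_self_query_zero_distance(self, rng):
        from finprint.types import RepresentativePattern as RP
        reps = {fid: RP(points=rng.uniform((340, 30), (960, 240), (10, 2)),
                        support=np.full(10, 6), n_source_patterns=6,
                        fish_id=fid) for fid in range(4)}
        for fid in range(4):
            res = M.identify_long_term(reps[fid], reps)
            assert res.predicted_id == fid
            assert res.distances[fid] == 0.0

    def test_drifted_sessions_identified(self, rng):
        from finprint.types import RepresentativePattern as RP
        truths = [rng.uniform((340, 30), (960, 240), (12, 2))
                  for _ in range(6)]
        s1 = {fid: RP(points=t, support=np.full(12, 6), n_source_patterns=6,
                      fish_id=fid, session="SL1")
              for fid, t in enumerate(truths)}
        s2 = {fid: RP(points=t + rng.normal(0, 4.5, t.shape) + [20, -10],
                      support=np.full(12, 6), n_source_patterns=6,
                      fish_id=fid, session="SL2")
              for fid, t in enumerate(truths)}
        for fid in range(6):
            assert M.identify_long_term(s2[fid], s1).predicted_id == fid
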