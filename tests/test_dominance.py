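"""Dominance ranks, style measures and the species composite index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vocalstyle import dominance
from vocalstyle.dominance import (RankTable, build_win_matrix, composite_index,
                                  dyad_dii, feeding_proximity,
                                  modified_davids_score, tolerance_profile)
from vocalstyle.tables import (AggressionBout, GroupMeta, ProximityScan,
                               ValidationError)


def make_bout(agg, vic, k=0, decided=True, winner=None, counter=False,
              contact=False, group="g"):
    return AggressionBout(group_id=group, bout_id=f"b{k}", time=float(k),
                          aggressor_id=agg, victim_id=vic, contact=contact,
                          counter=counter, decided=decided,
                          winner_id=(winner or agg) if decided else None)


def random_bouts(rng, inds, n, p_decided=0.8):
    bouts = []
    for k in range(n):
        a, v = rng.choice(inds, size=2, replace=False)
        decided = rng.random() < p_decided
        winner = (a if rng.random() < 0.7 else v) if decided else None
        bouts.append(make_bout(a, v, k, decided=decided, winner=winner,
                               counter=rng.random() < 0.3,
                               contact=rng.random() < 0.4))
    return bouts


class TestWinMatrix:
    def test_simple_tally(self):
        bouts = [make_bout("A", "B", k) for k in range(4)]
        w = build_win_matrix(bouts)
        i, j = w.index("A"), w.index("B")
        assert w.s[i, j] == 4 and w.s[j, i] == 0 and w.n[i, j] == 4

    def test_undecided_excluded(self):
        bouts = ([make_bout("A", "B", k) for k in range(3)]
                 + [make_bout("A", "B", 9, decided=False)])
        w = build_win_matrix(bouts)
        assert w.n[w.index("A"), w.index("B")] == 3

    def test_no_decided_bouts_is_error(self):
        with pytest.raises(ValidationError, match="rank undeterminable"):
            build_win_matrix([make_bout("A", "B", decided=False)])

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(7)
        inds = list("ABCDE")
        bouts = random_bouts(rng, inds, 120)
        w = build_win_matrix(bouts)
        for b in bouts:
            if not b.decided:
                continue
        # independent tally with a dict
        tally = {}
        for b in bouts:
            if b.decided:
                loser = b.victim_id if b.winner_id == b.aggressor_id else b.aggressor_id
                tally[(b.winner_id, loser)] = tally.get((b.winner_id, loser), 0) + 1
        for (x, y), c in tally.items():
            assert w.s[w.index(x), w.index(y)] == c
        assert w.s.sum() == sum(tally.values())

    def test_min_decided_filter_drops_rare_individuals(self):
        bouts = ([make_bout("A", "B", k) for k in range(5)]
                 + [make_bout("A", "C", 10)])
        w = build_win_matrix(bouts, min_decided=3)
        assert "C" not in w.individuals


class TestModifiedDavidsScore:
    def test_two_individual_hand_case(self):
        """A beats B 4-0: DS = +/-0.8, normDS = 0.9 / 0.1."""
        w = build_win_matrix([make_bout("A", "B", k) for k in range(4)])
        rt = modified_davids_score(w)
        np.testing.assert_allclose(sorted(rt.ds), [-0.8, 0.8], atol=1e-12)
        np.testing.assert_allclose(sorted(rt.norm_ds), [0.1, 0.9], atol=1e-12)
        assert rt.rank[rt.individuals.index("A")] == 1

    def test_scores_sum_to_zero_and_norm_mean(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n_ind = rng.integers(2, 9)
            inds = [f"i{k}" for k in range(n_ind)]
            bouts = random_bouts(rng, inds, int(rng.integers(n_ind, 120)),
                                 p_decided=1.0)
            rt = modified_davids_score(build_win_matrix(bouts))
            n = len(rt.individuals)
            assert abs(rt.ds.sum()) < 1e-9
            assert abs(rt.norm_ds.mean() - (n - 1) / 2) < 1e-9
            assert (rt.norm_ds >= -1e-9).all() and (rt.norm_ds <= n - 1 + 1e-9).all()

    def test_symmetric_matrix_gives_zero_scores(self):
        bouts = []
        k = 0
        for a, b in [("A", "B"), ("A", "C"), ("B", "C")]:
            for _ in range(3):
                bouts.append(make_bout(a, b, k)); k += 1
                bouts.append(make_bout(b, a, k)); k += 1
        rt = modified_davids_score(build_win_matrix(bouts))
        np.testing.assert_allclose(rt.ds, 0.0, atol=1e-9)

    def test_single_individual_pair_required(self):
        w = build_win_matrix([make_bout("A", "B")])
        w.individuals, w.s, w.n = ["A"], np.zeros((1, 1)), np.zeros((1, 1))
        with pytest.raises(ValidationError):
            modified_davids_score(w)


class TestAssignRanks:
    def test_rank_is_sort_permutation(self):
        rng = np.random.default_rng(3)
        norm = rng.uniform(0, 5, size=8)
        rt = RankTable(individuals=[f"i{k}" for k in range(8)],
                       ds=norm - norm.mean(), norm_ds=norm,
                       rank=np.zeros(8, int), tied=np.zeros(8, bool))
        rt = dominance.assign_ranks(rt)
        order = np.argsort(-norm, kind="stable")
        assert sorted(rt.rank) == list(range(1, 9))
        assert all(rt.rank[order[k]] == k + 1 for k in range(8))

    def test_ties_broken_lexicographically_and_flagged(self):
        rt = RankTable(individuals=["b", "a", "c"], ds=np.zeros(3),
                       norm_ds=np.array([1.0, 1.0, 2.0]),
                       rank=np.zeros(3, int), tied=np.zeros(3, bool))
        rt = dominance.assign_ranks(rt)
        assert list(rt.rank) == [3, 2, 1]        # c first, then a before b
        assert list(rt.tied) == [True, True, False]


class TestDyadDii:
    @pytest.mark.parametrize("a,b,expected", [(7, 3, 0.3), (5, 0, 0.0),
                                              (3, 3, 0.5), (1, 1, 0.5)])
    def test_direct_proportions(self, a, b, expected):
        bouts = ([make_bout("A", "B", k) for k in range(a)]
                 + [make_bout("B", "A", 100 + k) for k in range(b)])
        assert dyad_dii(bouts) == pytest.approx(expected)

    def test_undecided_bouts_count(self):
        bouts = ([make_bout("A", "B", k, decided=False) for k in range(7)]
                 + [make_bout("B", "A", 100 + k) for k in range(3)])
        assert dyad_dii(bouts) == pytest.approx(0.3)

    def test_empty_is_error(self):
        with pytest.raises(ValidationError):
            dyad_dii([])

    @given(st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=60, deadline=None)
    def test_bounded_and_relabel_invariant(self, a, b):
        if a + b == 0:
            return
        bouts = ([make_bout("A", "B", k) for k in range(a)]
                 + [make_bout("B", "A", 100 + k) for k in range(b)])
        flipped = ([make_bout("B", "A", k) for k in range(a)]
                   + [make_bout("A", "B", 100 + k) for k in range(b)])
        v = dyad_dii(bouts)
        assert 0.0 <= v <= 0.5
        assert v == dyad_dii(flipped)


def _ranked(inds_desc):
    """Rank table with norm_ds descending in the given order."""
    n = len(inds_desc)
    return dominance.assign_ranks(RankTable(
        individuals=list(inds_desc), ds=np.zeros(n),
        norm_ds=np.arange(n, 0, -1, dtype=float),
        rank=np.zeros(n, int), tied=np.zeros(n, bool)))


class TestToleranceProfile:
    def test_top_ranked_has_no_received_profile(self):
        ranks = _ranked(["A", "B", "C"])
        bouts = [make_bout("A", "B", k) for k in range(12)]
        prof = tolerance_profile(bouts, ranks, "received", min_bouts=1)
        assert prof["A"].dii is None and prof["A"].n_bouts == 0

    def test_single_dyad_direct_proportions(self):
        ranks = _ranked(["A", "B"])
        bouts = ([make_bout("A", "B", k, counter=k < 4, contact=k < 2)
                  for k in range(7)]
                 + [make_bout("B", "A", 100 + k) for k in range(3)])
        prof = tolerance_profile(bouts, ranks, "given", min_bouts=10)
        assert prof["A"].dii == pytest.approx(0.3)
        assert prof["A"].counter_pct == pytest.approx(40.0)
        assert prof["A"].intensity_pct == pytest.approx(20.0)
        # B's received profile uses exactly the same bouts
        rec = tolerance_profile(bouts, ranks, "received", min_bouts=10)
        assert rec["B"].dii == pytest.approx(0.3)
        assert rec["B"].n_bouts == prof["A"].n_bouts == 10

    def test_below_minimum_is_missing(self):
        ranks = _ranked(["A", "B"])
        bouts = [make_bout("A", "B", k) for k in range(5)]
        prof = tolerance_profile(bouts, ranks, "given", min_bouts=10)
        assert prof["A"].dii is None and prof["A"].n_bouts == 5

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(23)
        inds = list("ABCDEF")
        ranks = _ranked(inds)
        bouts = random_bouts(rng, inds, 200)
        for direction in ("given", "received", "all"):
            prof = tolerance_profile(bouts, ranks, direction, min_bouts=1)
            for focal in inds:
                nf = ranks.norm_of(focal)
                sel = []
                for b in bouts:
                    if focal not in (b.aggressor_id, b.victim_id):
                        continue
                    other = (b.victim_id if b.aggressor_id == focal
                             else b.aggressor_id)
                    keep = {"given": ranks.norm_of(other) < nf,
                            "received": ranks.norm_of(other) > nf,
                            "all": True}[direction]
                    if keep:
                        sel.append(b)
                if not sel:
                    assert prof[focal].dii is None
                    continue
                least = 0
                partners = {tuple(sorted((b.aggressor_id, b.victim_id)))
                            for b in sel}
                for pair in partners:
                    fwd = sum(1 for b in sel
                              if (b.aggressor_id, b.victim_id) == pair)
                    bwd = sum(1 for b in sel
                              if (b.victim_id, b.aggressor_id) == pair)
                    least += min(fwd, bwd)
                assert prof[focal].dii == pytest.approx(least / len(sel))
                assert prof[focal].counter_pct == pytest.approx(
                    100 * sum(b.counter for b in sel) / len(sel))
                assert prof[focal].intensity_pct == pytest.approx(
                    100 * sum(b.contact for b in sel) / len(sel))

    def test_every_bout_partitioned_once_per_participant(self):
        """Each bout appears in exactly one direction-profile of each
        participant when ranks are distinct."""
        rng = np.random.default_rng(5)
        inds = list("ABCDE")
        ranks = _ranked(inds)
        bouts = random_bouts(rng, inds, 150)
        given = tolerance_profile(bouts, ranks, "given", min_bouts=1)
        received = tolerance_profile(bouts, ranks, "received", min_bouts=1)
        for focal in inds:
            n_total = sum(1 for b in bouts
                          if focal in (b.aggressor_id, b.victim_id))
            assert given[focal].n_bouts + received[focal].n_bouts == n_total


class TestFeedingProximity:
    def test_direct_percentage(self):
        scans = [ProximityScan("g", "A", float(k), True, k < 5)
                 for k in range(20)]
        assert feeding_proximity(scans, "A", min_scans=10) == pytest.approx(25.0)

    def test_no_feeding_scans_is_missing(self):
        scans = [ProximityScan("g", "A", 0.0, False, True)] * 5
        assert feeding_proximity(scans, "A", min_scans=1) is None

    def test_non_feeding_scans_never_counted(self):
        rng = np.random.default_rng(9)
        scans = [ProximityScan("g", "A", float(k), bool(rng.random() < 0.5),
                               bool(rng.random() < 0.5)) for k in range(200)]
        feeding = [s for s in scans if s.feeding]
        expected = 100 * sum(s.neighbor_within_1m for s in feeding) / len(feeding)
        assert feeding_proximity(scans, "A", min_scans=1) == pytest.approx(expected)


def _profile(ind, dii, counter, intensity):
    return dominance.ToleranceProfile(ind, "all", dii, counter, intensity, 50)


class TestCompositeIndex:
    meta = [GroupMeta(f"sp{k}_g1", f"sp{k}", 10) for k in range(1, 5)]

    def _profiles(self, values):
        # one group per species, one individual per group
        return {f"sp{k}_g1": [_profile(f"i{k}", *vals)]
                for k, vals in enumerate(values, start=1)}

    def test_z_columns_standardized(self):
        profiles = self._profiles([(0.1, 10, 40), (0.2, 20, 30),
                                   (0.3, 30, 20), (0.4, 50, 10)])
        idx = composite_index(profiles, self.meta)
        for attr in ("z_dii", "z_counter", "z_intensity"):
            z = np.array([getattr(s, attr) for s in idx])
            assert abs(z.mean()) < 1e-9
            assert abs(z.std(ddof=1) - 1) < 1e-9
        for s in idx:
            assert s.composite == pytest.approx(
                (s.z_dii + s.z_counter + s.z_intensity) / 3)

    def test_three_species_unit_spacing(self):
        """Means {0,1,2} have sample SD 1, so z = {-1, 0, 1}."""
        meta = [GroupMeta(f"sp{k}_g1", f"sp{k}", 10) for k in range(1, 4)]
        profiles = {f"sp{k}_g1": [_profile(f"i{k}", float(k - 1), k - 1.0,
                                           float(k - 1))]
                    for k in range(1, 4)}
        idx = composite_index(profiles, meta)
        assert [s.z_dii for s in idx] == pytest.approx([-1.0, 0.0, 1.0])
        # intensity is negated before z-scoring: rising raw intensity
        # means falling z
        assert [s.z_intensity for s in idx] == pytest.approx([1.0, 0.0, -1.0])

    def test_affine_rescaling_invariance(self):
        base = [(0.1, 10, 40), (0.2, 20, 30), (0.3, 30, 20), (0.4, 50, 10)]
        idx1 = composite_index(self._profiles(base), self.meta)
        scaled = [(7 * d + 2, c, i) for d, c, i in base]
        idx2 = composite_index(self._profiles(scaled), self.meta)
        for a, b in zip(idx1, idx2):
            assert a.composite == pytest.approx(b.composite, abs=1e-9)

    def test_zero_sd_is_error(self):
        profiles = self._profiles([(0.2, 10, 40), (0.2, 20, 30),
                                   (0.2, 30, 20), (0.2, 50, 10)])
        with pytest.raises(ValidationError, match="zero cross-species SD"):
            composite_index(profiles, self.meta)

    def test_species_missing_measure_excluded_and_logged(self):
        profiles = self._profiles([(0.1, 10, 40), (0.2, 20, 30),
                                   (0.3, 30, 20), (0.4, 50, 10)])
        profiles["sp4_g1"] = [_profile("i4", 0.4, None, 10)]
        log = []
        idx = composite_index(profiles, self.meta, log)
        assert len(idx) == 3
        assert any("sp4" in line and "counter" in line for line in log)

    def test_fewer_than_two_species_is_error(self):
        profiles = {"sp1_g1": [_profile("i1", 0.1, 10, 40)]}
        with pytest.raises(ValidationError, match=">= 2"):
            composite_index(profiles, self.meta)

    def test_group_then_species_averaging_matches_spreadsheet(self):
        """Hand-computed two-stage means for a 2-species, 2-group layout."""
        meta = [GroupMeta("a_g1", "a", 5), GroupMeta("a_g2", "a", 5),
                GroupMeta("b_g1", "b", 5)]
        profiles = {
            "a_g1": [_profile("x", 0.1, 10, 20), _profile("y", 0.3, 30, 40)],
            "a_g2": [_profile("z", 0.4, 20, 10)],
            "b_g1": [_profile("w", 0.2, 50, 60)],
        }
        idx = {s.species_id: s for s in composite_index(profiles, meta)}
        # species a: group means (0.2, 20, 30) and (0.4, 20, 10) -> (0.3, 20, 20)
        assert idx["a"].mean_dii == pytest.approx(0.3)
        assert idx["a"].mean_counter == pytest.approx(20.0)
        assert idx["a"].mean_intensity == pytest.approx(20.0)
        assert idx["b"].mean_dii == pytest.approx(0.2)
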