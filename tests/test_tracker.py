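import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import myobarcode as mb
from myobarcode import tracker


def _frame(ids, xs, ys, colors=None, time=0.0, **extra):
    n = len(ids)
    colors = colors or [(0.5, 0.3, 0.2)] * n
    df = pd.DataFrame({
        "fiber_id": ids, "x": xs, "y": ys,
        "c1": [c[0] for c in colors], "c2": [c[1] for c in colors],
        "c3": [c[2] for c in colors],
        "compartment": extra.get("compartment", ["dorsal"] * n),
        "medial_edge": extra.get("medial_edge", [False] * n),
        "time": time,
    })
    return df


def _tagged_frames(frames):
    return {t: df[df.tagged].reset_index(drop=True)
            for t, df in frames.items()}


class TestMatchFibers:
    def test_identical_frames_identity_matching(self):
        f = _frame([1, 2, 3], [10.0, 50.0, 90.0], [10.0, 50.0, 90.0])
        matches, la, lb = tracker.match_fibers(f, f)
        assert matches == {1: 1, 2: 2, 3: 3}
        assert not la and not lb

    def test_permuted_ids_with_jitter_recovered(self, rng):
        n = 20
        xs = rng.uniform(5, 115, n)
        ys = rng.uniform(5, 155, n)
        colors = [tuple(rng.dirichlet(np.ones(3))) for _ in range(n)]
        a = _frame(list(range(n)), xs, ys, colors)
        perm = rng.permutation(n)
        b = _frame([int(p) for p in perm], xs[perm] + rng.uniform(-2, 2, n),
                   ys[perm] + rng.uniform(-2, 2, n),
                   [colors[p] for p in perm])
        matches, la, lb = tracker.match_fibers(a, b)
        assert matches == {i: i for i in range(n)}

    def test_removed_fiber_left_unmatched(self):
        a = _frame([1, 2], [10.0, 100.0], [10.0, 100.0],
                   [(1.0, 0.0, 0.0), (0.0, 1.0, 0.0)])
        b = _frame([2], [100.0], [100.0], [(0.0, 1.0, 0.0)])
        matches, la, lb = tracker.match_fibers(a, b)
        assert matches == {2: 2}
        assert la == {1} and lb == set()

    def test_empty_inputs_give_empty_assignment(self):
        e = _frame([], [], [])
        f = _frame([1], [0.0], [0.0])
        m, la, lb = tracker.match_fibers(e, f)
        assert m == {} and la == set() and lb == {1}

    def test_duplicate_ids_rejected(self):
        f = _frame([1, 1], [0.0, 5.0], [0.0, 5.0])
        with pytest.raises(ValueError):
            tracker.match_fibers(f, f)

    @pytest.mark.parametrize("shape", [(3, 3), (5, 5), (6, 6), (5, 7), (7, 4)])
    def test_assignment_optimality_vs_brute_force(self, shape, rng):
        # the Hungarian step must match exhaustive enumeration on small
        # rectangular cost matrices
        from scipy.optimize import linear_sum_assignment
        n, m = shape
        cost = rng.random((n, m))
        rows, cols = linear_sum_assignment(cost)
        best = cost[rows, cols].sum()
        k = min(n, m)
        brute = min(
            sum(cost[i, p[i]] if n <= m else cost[p[i], i] for i in range(k))
            for p in itertools.permutations(range(max(n, m)), k))
        assert best == pytest.approx(brute, abs=1e-12)


class TestClassifyFates:
    def test_no_unmatched_all_persist(self):
        f0 = _frame([1, 2, 3], [10.0, 50.0, 90.0], [10.0, 50.0, 90.0],
                    time=0.0)
        f1 = f0.assign(time=1.0)
        tt = tracker.classify_fates({0.0: f0, 1.0: f1})
        assert all(tr.fate == "persist" for tr in tt.tracks)
        assert len(tt.tracks) == 3

    def test_all_lost_at_final_interval(self):
        f0 = _frame([1, 2], [10.0, 100.0], [10.0, 100.0],
                    [(1.0, 0.0, 0.0), (0.0, 1.0, 0.0)], time=0.0)
        f1 = _frame([], [], [], time=1.0)
        tt = tracker.classify_fates({0.0: f0, 1.0: f1})
        assert all(tr.fate == "eliminated" and tr.eliminated_at == 1.0
                   for tr in tt.tracks)

    def test_every_fiber_in_exactly_one_track(self):
        cfg = mb.SimulationConfig(seed=13, n_myotomes=2,
                                  initial_fibers_per_myotome=20,
                                  t_grid=(14.0, 14.5, 15.0, 15.5))
        frames, _ = mb.simulate_population(cfg)
        tagged = _tagged_frames(frames)
        tt = tracker.classify_fates(tagged)
        seen = set()
        for tr in tt.tracks:
            for t, fid in tr.points:
                key = (t, fid)
                assert key not in seen
                seen.add(key)
        total = sum(len(df) for df in tagged.values())
        assert len(seen) == total

    def test_duplicate_ids_in_frame_rejected(self):
        f = _frame([1, 1], [0.0, 50.0], [0.0, 50.0])
        with pytest.raises(ValueError):
            tracker.classify_fates({0.0: f, 1.0: f})

    def test_fate_accuracy_on_tagged_cohort(self):
        # tagged fibers tracked over 12-h frames: fate calls must agree with
        # the generative truth in >= 98% of tracks
        cfg = mb.SimulationConfig(seed=7, n_myotomes=4,
                                  initial_fibers_per_myotome=25,
                                  t_grid=(14.0, 14.5, 15.0, 15.5, 16.0),
                                  growth_condition="FG", hyperplasia_rate=1.0)
        frames, gt = mb.simulate_population(cfg)
        tt = tracker.classify_fates(_tagged_frames(frames))
        correct = 0
        for tr in tt.tracks:
            f = gt.fibers[tr.points[0][1]]
            if tr.fate == "eliminated":
                correct += (f.death_time is not None
                            and f.death_time == tr.eliminated_at)
            else:
                correct += f.death_time is None
        assert correct / len(tt.tracks) >= 0.98


class TestDissolutionEvents:
    def _table_with_event(self, replacements):
        f0 = _frame([1], [50.0], [50.0], [(1.0, 0.0, 0.0)], time=0.0)
        ids = list(range(10, 10 + replacements))
        f1 = _frame(ids, [51.0 + i for i in range(replacements)],
                    [50.0] * replacements,
                    [(0.0, 0.0, 1.0)] * replacements, time=1.0)
        tt = tracker.classify_fates({0.0: f0, 1.0: f1},
                                    tracker.TrackerConfig(max_cost=0.0))
        frames = {0.0: f0, 1.0: f1}
        footprints = {1: (50.0, 50.0, 10.0)}
        return tt, frames, footprints

    def test_no_nearby_births_count_zero(self):
        tt, frames, fp = self._table_with_event(0)
        events = tracker.detect_dissolution_events(tt, frames, fp)
        assert len(events) == 1 and events[0].replacement_count == 0

    def test_three_planted_replacements_counted(self):
        tt, frames, fp = self._table_with_event(3)
        events = tracker.detect_dissolution_events(tt, frames, fp)
        assert events[0].replacement_count == 3

    def test_interleaved_births_assigned_to_nearest_parent(self):
        # two parents die; births sit between them, nearer one or the other
        f0 = _frame([1, 2], [20.0, 80.0], [50.0, 50.0],
                    [(1.0, 0.0, 0.0), (0.0, 1.0, 0.0)], time=0.0)
        f1 = _frame([10, 11, 12], [25.0, 75.0, 45.0], [50.0, 50.0, 50.0],
                    [(0.0, 0.0, 1.0)] * 3, time=1.0)
        tt = tracker.classify_fates({0.0: f0, 1.0: f1},
                                    tracker.TrackerConfig(max_cost=0.0))
        footprints = {1: (20.0, 80.0, 30.0), 2: (80.0, 50.0, 30.0)}
        footprints = {1: (20.0, 50.0, 30.0), 2: (80.0, 50.0, 30.0)}
        events = tracker.detect_dissolution_events(
            tt, {0.0: f0, 1.0: f1}, footprints)
        by_parent = {e.parent_track_id: e for e in events}
        # no double counting even where dilated footprints overlap
        all_ids = [i for e in events for i in e.replacement_ids]
        assert len(all_ids) == len(set(all_ids)) == 3
        counts = sorted(e.replacement_count for e in events)
        assert counts == [1, 2]  # birth at x=45 goes to the nearer parent

    def test_missing_footprint_skips_event_with_warning(self):
        tt, frames, _ = self._table_with_event(1)
        with pytest.warns(UserWarning):
            events = tracker.detect_dissolution_events(tt, frames, {})
        assert events == []


class TestCategorizeEvents:
    @staticmethod
    def _events(counts_by_category):
        events = []
        tid = 0
        for cat, n in counts_by_category.items():
            k = 5 if cat == ">=5" else int(cat)
            for _ in range(n):
                events.append(tracker.DissolutionEvent(
                    parent_track_id=tid, time=1.0,
                    replacement_ids=tuple(range(k)),
                    compartment="dorsal", medial_edge=False))
                tid += 1
        return events

    def test_printed_category_proportions_give_89_percent_with_birth(self):
        # 98 events split 11 / 28 / 21 / 18 / 13 / 7 over {0,1,2,3,4,>=5}
        events = self._events({"0": 11, "1": 28, "2": 21, "3": 18,
                               "4": 13, ">=5": 7})
        dist, ge1 = tracker.categorize_events(events)
        assert len(events) == 98
        assert round(ge1) == 89
        assert round(dist["1"]) == 29 and round(dist["2"]) == 21
        assert round(dist["3"]) == 18 and round(dist["4"]) == 13

    def test_all_zero_category(self):
        events = self._events({"0": 10})
        dist, ge1 = tracker.categorize_events(events)
        assert dist["0"] == 100.0 and ge1 == 0.0

    def test_uniform_categories_binomial_ci(self, rng):
        # 500 events uniform over {0..4}: share with >= 1 birth is Binomial
        # (500, 0.8); the estimate must fall in the exact 99% CI
        cats = rng.integers(0, 5, size=500)
        events = self._events({str(c): int((cats == c).sum())
                               for c in range(5)})
        _, ge1 = tracker.categorize_events(events)
        lo, hi = sps.binom.interval(0.99, 500, 0.8)
        assert lo / 5 <= ge1 <= hi / 5  # percent scale: /500*100 = /5

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            tracker.categorize_events([])


class TestCompartmentBias:
    def test_all_medial_and_none(self):
        mk = lambda medial, comp: tracker.DissolutionEvent(
            0, 1.0, (), comp, medial)
        evs = [mk(True, "dorsal"), mk(True, "ventral")]
        assert tracker.compartment_bias(evs) == {"dorsal": 100.0,
                                                 "ventral": 100.0}
        evs = [mk(False, "dorsal"), mk(False, "ventral")]
        assert tracker.compartment_bias(evs) == {"dorsal": 0.0,
                                                 "ventral": 0.0}

    def test_simulated_bias_recovered_within_ci(self):
        cfg = mb.SimulationConfig(seed=11, n_myotomes=40,
                                  initial_fibers_per_myotome=60,
                                  t_grid=(14.0, 15.0),
                                  elimination_hazard=0.3,
                                  hyperplasia_rate=0.0)
        _, gt = mb.simulate_population(cfg)
        assert len(gt.events) >= 500
        events = [tracker.DissolutionEvent(
            e["parent"], e["time"], tuple(e["children"]),
            e["compartment"], e["medial_edge"]) for e in gt.events]
        bias = tracker.compartment_bias(events)
        for comp in ("dorsal", "ventral"):
            n = sum(1 for e in events if e.compartment == comp)
            p = cfg.medial_edge_bias[comp]
            lo, hi = sps.binom.interval(0.99, n, p)
            assert 100 * lo / n <= bias[comp] <= 100 * hi / n


class TestEliminationFraction:
    def _table(self, n, n_gone):
        tracks = []
        for i in range(n):
            tr = tracker.Track(track_id=i, points=[(0.0, i)])
            if i < n_gone:
                tr.fate = "eliminated"
                tr.eliminated_at = 1.0
            else:
                tr.points.append((1.0, i))
            tracks.append(tr)
        return tracker.TrackTable(tracks=tracks, times=(0.0, 1.0))

    def test_full_cohort_elimination_is_100(self):
        tt = self._table(328, 328)
        assert tracker.elimination_fraction(tt, 0.0, 1.0) == 100.0

    def test_none_eliminated_is_0(self):
        tt = self._table(10, 0)
        assert tracker.elimination_fraction(tt, 0.0, 1.0) == 0.0

    def test_half_eliminated_is_50(self):
        tt = self._table(10, 5)
        assert tracker.elimination_fraction(tt, 0.0, 1.0) == 50.0

    def test_empty_cohort_rejected(self):
        tt = tracker.TrackTable(tracks=[], times=(0.0,))
        with pytest.raises(ValueError):
            tracker.elimination_fraction(tt, 0.0, 1.0)

    def test_monotone_in_time_for_fixed_cohort(self):
        cfg = mb.SimulationConfig(seed=17, n_myotomes=2,
                                  initial_fibers_per_myotome=25,
                                  t_grid=(14.0, 15.0, 16.0, 17.0, 18.0),
                                  growth_condition="FG")
        frames, _ = mb.simulate_population(cfg)
        tt = tracker.classify_fates(_tagged_frames(frames))
        vals = [tracker.elimination_fraction(tt, 14.0, t)
                for t in cfg.t_grid]
        assert all(a <= b for a, b in zip(vals, vals[1:]))
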