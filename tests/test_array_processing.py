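"""Spot-to-ratio processing, spike normalization and replicate QC."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trnatempo import (
    ArrayExperiment,
    ks_similarity,
    median_ratio,
    normalize_to_spikes,
    process_experiment,
    replicate_cv,
    select_representative,
)
from .conftest import make_ratios


def experiment_from_spots(spots_by_probe, model="m", rep=1):
    return ArrayExperiment(model_id=model, bio_replicate=rep, signals=spots_by_probe)


class TestMedianRatio:
    def test_median_of_per_spot_ratios(self, tiny_panel):
        spots = {pid: [(1.0, 1.0)] for pid in tiny_panel.probe_ids}
        spots["t1"] = [(2.0, 1.0), (4.0, 1.0), (8.0, 1.0)]
        raw = median_ratio(experiment_from_spots(spots), tiny_panel)
        assert raw["t1"] == 4.0

    def test_identical_spots_give_that_ratio(self, tiny_panel):
        spots = {pid: [(3.5, 1.0)] * 4 for pid in tiny_panel.probe_ids}
        raw = median_ratio(experiment_from_spots(spots), tiny_panel)
        assert all(v == 3.5 for v in raw.values())

    def test_zero_reference_spot_dropped_and_logged(self, tiny_panel):
        spots = {pid: [(1.0, 1.0)] for pid in tiny_panel.probe_ids}
        spots["t2"] = [(1.0, 0.0), (3.0, 1.0)]
        drops = {}
        raw = median_ratio(experiment_from_spots(spots), tiny_panel, drop_log=drops)
        assert raw["t2"] == 3.0
        assert drops == {"t2": 1}

    def test_probe_without_usable_spot_is_an_error_naming_it(self, tiny_panel):
        spots = {pid: [(1.0, 1.0)] for pid in tiny_panel.probe_ids}
        spots["t3"] = [(1.0, 0.0)]
        with pytest.raises(ValueError, match="t3"):
            median_ratio(experiment_from_spots(spots), tiny_panel)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_invariant_to_common_rescaling_of_both_channels(self, scale):
        from trnatempo import Probe, ProbePanel

        panel = ProbePanel(
            (Probe("a", ("AGU",), "T", ("ACU",)), Probe("spike_1", is_spike=True))
        )
        base = [(2.0, 1.0), (5.0, 2.0), (7.0, 3.0)]
        spots = {"a": base, "spike_1": [(1.0, 1.0)]}
        scaled = {
            "a": [(s * scale, r * scale) for s, r in base],
            "spike_1": [(1.0, 1.0)],
        }
        r1 = median_ratio(experiment_from_spots(spots), panel)
        r2 = median_ratio(experiment_from_spots(scaled), panel)
        assert r2["a"] == pytest.approx(r1["a"], rel=1e-12)


class TestSpikeNormalization:
    def test_division_by_spike_median(self, tiny_panel):
        raw = {"t1": 6.0, "t2": 1.0, "t3": 1.0, "spike_1": 2.0, "spike_2": 2.0}
        nr = normalize_to_spikes(raw, tiny_panel)
        assert nr.ratio["t1"] == pytest.approx(3.0)
        assert nr.ratio["spike_1"] == pytest.approx(1.0)

    def test_identity_when_spikes_already_at_one(self, tiny_panel):
        raw = {"t1": 0.4, "t2": 2.0, "t3": 5.0, "spike_1": 1.0, "spike_2": 1.0}
        nr = normalize_to_spikes(raw, tiny_panel)
        assert nr.ratio == pytest.approx(raw)

    def test_no_positive_spike_is_an_error(self, tiny_panel):
        raw = {"t1": 1.0, "t2": 1.0, "t3": 1.0, "spike_1": 0.0, "spike_2": 0.0}
        with pytest.raises(ValueError, match="spike"):
            normalize_to_spikes(raw, tiny_panel)

    @given(
        ratios=st.lists(
            st.floats(min_value=1e-3, max_value=1e3), min_size=5, max_size=5
        )
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_idempotent_and_spike_median_is_one(self, tiny_panel, ratios):
        raw = dict(zip(["t1", "t2", "t3", "spike_1", "spike_2"], ratios))
        once = normalize_to_spikes(raw, tiny_panel)
        spike_median = float(
            np.median([once.ratio[p] for p in tiny_panel.spike_ids])
        )
        assert spike_median == pytest.approx(1.0, abs=1e-9)
        twice = normalize_to_spikes(once.ratio, tiny_panel)
        assert twice.ratio == pytest.approx(once.ratio, rel=1e-12)


class TestReplicateCV:
    def test_identical_replicates_have_zero_cv(self):
        a = make_ratios({"p1": 1.0, "p2": 2.0})
        assert all(v == 0.0 for v in replicate_cv(a, a).values())

    def test_two_point_cv_matches_hand_value(self):
        # sd(n-1) of {1, 3} is sqrt(2), mean is 2
        a, b = make_ratios({"p": 1.0}), make_ratios({"p": 3.0})
        assert replicate_cv(a, b)["p"] == pytest.approx(math.sqrt(2) / 2)

    @given(k=st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_scale_invariance(self, k):
        a, b = make_ratios({"p": 1.3}), make_ratios({"p": 2.9})
        ka, kb = make_ratios({"p": 1.3 * k}), make_ratios({"p": 2.9 * k})
        assert replicate_cv(ka, kb)["p"] == pytest.approx(
            replicate_cv(a, b)["p"], rel=1e-9
        )

    def test_nonpositive_mean_is_error(self):
        a, b = make_ratios({"p": 0.0}), make_ratios({"p": 0.0})
        with pytest.raises(ValueError):
            replicate_cv(a, b)


def exact_ks_two_sample(a, b):
    """Brute-force two-sample KS: D over the pooled grid, exact p by
    enumerating all assignments of pooled ranks to the two samples."""
    a, b = sorted(a), sorted(b)

    def d_stat(x, y):
        pooled = sorted(set(x) | set(y))
        d = 0.0
        for v in pooled:
            fa = sum(1 for t in x if t <= v) / len(x)
            fb = sum(1 for t in y if t <= v) / len(y)
            d = max(d, abs(fa - fb))
        return d

    d_obs = d_stat(a, b)
    pooled = a + b
    n = len(a)
    count = total = 0
    for idx in combinations(range(len(pooled)), n):
        xa = [pooled[i] for i in idx]
        xb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if d_stat(xa, xb) >= d_obs - 1e-12:
            count += 1
    return d_obs, count / total


class TestKSSimilarity:
    def test_replicate_against_itself(self, tiny_panel):
        vals = {"t1": 0.5, "t2": 1.5, "t3": 3.0, "spike_1": 1.0, "spike_2": 1.0}
        d, p = ks_similarity(make_ratios(vals), make_ratios(vals), tiny_panel)
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_samples_match_enumeration_oracle(self, tiny_panel):
        from trnatempo import Probe, ProbePanel

        panel = ProbePanel(
            tuple(Probe(f"t{i}", ("AGU",), "T", ("ACU",)) for i in range(4))
            + (Probe("spike_1", is_spike=True),)
        )
        a = make_ratios({f"t{i}": v for i, v in enumerate([1, 2, 3, 4])})
        b = make_ratios({f"t{i}": v for i, v in enumerate([10, 20, 30, 40])})
        d, p = ks_similarity(a, b, panel)
        d_oracle, p_oracle = exact_ks_two_sample([1, 2, 3, 4], [10, 20, 30, 40])
        assert d == pytest.approx(d_oracle)  # 1.0: the samples are disjoint
        assert p == pytest.approx(p_oracle, rel=1e-9)  # 2 / C(8,4)

    def test_symmetric(self, tiny_panel):
        a = make_ratios({"t1": 0.5, "t2": 1.5, "t3": 3.0})
        b = make_ratios({"t1": 0.7, "t2": 1.0, "t3": 9.0})
        assert ks_similarity(a, b, tiny_panel) == ks_similarity(b, a, tiny_panel)

    def test_spikes_are_excluded(self, tiny_panel):
        a = make_ratios({"t1": 1, "t2": 2, "t3": 3, "spike_1": 1, "spike_2": 1})
        b = make_ratios({"t1": 1, "t2": 2, "t3": 3, "spike_1": 50, "spike_2": 50})
        d, p = ks_similarity(a, b, tiny_panel)
        assert d == 0.0


class TestSelectRepresentative:
    def test_single_replicate(self):
        assert select_representative([make_ratios({"p": 1.0})]) == 0

    def test_middle_replicate_wins(self):
        # replicate 1 is the average of 0 and 2, so its mean pairwise CV is lowest
        reps = [
            make_ratios({"p1": 1.0, "p2": 4.0}),
            make_ratios({"p1": 2.0, "p2": 5.0}),
            make_ratios({"p1": 3.0, "p2": 6.0}),
        ]
        # independent hand computation of the selection score
        def cv(x, y):
            return abs(x - y) / math.sqrt(2) / ((x + y) / 2)

        scores = []
        for i in range(3):
            cvs = []
            for j in range(3):
                if i == j:
                    continue
                for pid in ("p1", "p2"):
                    cvs.append(cv(reps[i].ratio[pid], reps[j].ratio[pid]))
            scores.append(sum(cvs) / len(cvs))
        assert scores.index(min(scores)) == 1
        assert select_representative(reps) == 1

    def test_tie_breaks_to_lowest_index(self):
        a = make_ratios({"p": 1.0})
        assert select_representative([a, a, a]) == 0

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            select_representative([])


def test_process_experiment_chains_median_and_spikes(tiny_panel):
    spots = {
        "t1": [(4.0, 1.0)],
        "t2": [(2.0, 1.0)],
        "t3": [(1.0, 1.0)],
        "spike_1": [(2.0, 1.0)],
        "spike_2": [(2.0, 1.0)],
    }
    nr = process_experiment(experiment_from_spots(spots), tiny_panel)
    assert nr.ratio["t1"] == pytest.approx(2.0)
    assert nr.ratio["spike_1"] == pytest.approx(1.0)
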