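import numpy as np
import pytest

from socnet import (Avalanche, ConfigError, EmptyResultError, ExhaustConfig,
                    NonQuiescentError, SignedNetwork, bfs_avalanche,
                    make_random_network, mean_profile, run_avalanche,
                    run_ensemble)
from socnet.avalanche import read_summaries, write_event_log, write_summaries


BIG_TE = ExhaustConfig(t_e=10 ** 6)


class TestHandTraces:
    @pytest.mark.parametrize("name, trigger, s, t, profile", [
        ("isolated", 2, 1, 1, [1]),
        ("chain3", 0, 3, 3, [1, 1, 1]),
        ("tree_d3", 0, 15, 4, [1, 2, 4, 8]),
        ("cancel", 0, 2, 2, [1, 1]),   # +1 route activates the sink
        ("cancel", 1, 1, 1, [1]),      # -1 route cannot
    ])
    def test_exact_avalanche(self, toys, name, trigger, s, t, profile):
        av = run_avalanche(toys[name], trigger, BIG_TE, seed=0)
        assert (av.size, av.duration) == (s, t)
        assert av.profile.tolist() == profile
        assert av.terminated_by == "natural"

    def test_event_list_matches_profile(self, toys):
        av = run_avalanche(toys["tree_d3"], 0, BIG_TE, seed=0)
        assert len(av.events) == int(av.profile.sum())
        counts = np.bincount([t for t, _ in av.events])
        assert counts.tolist() == av.profile.tolist()


class TestExhaustTermination:
    @pytest.mark.parametrize("t_e", [2, 5, 50])
    def test_two_cycle_always_terminates(self, toys, t_e):
        av = run_avalanche(toys["cycle2"], 0, ExhaustConfig(t_e=t_e), seed=3)
        assert av.terminated_by == "exhaust"
        assert av.size == 2

    def test_supercritical_cap_truncation(self):
        net = make_random_network(64, 4.0, 1.0, seed=3)
        av = run_avalanche(net, 0, ExhaustConfig(t_e=10, max_steps=200),
                           seed=4, on_cap="truncate")
        assert av.terminated_by == "cap"
        with pytest.raises(RuntimeError):
            run_avalanche(net, 0, ExhaustConfig(t_e=10, max_steps=200),
                          seed=4)

    def test_elevation_is_single_level(self, toys):
        # theta=1 network on the 2-cycle analog: thresholds rise to at
        # most theta+1, so a theta=0 cycle node needs f > 1 to refire
        av = run_avalanche(toys["cycle2"], 0, ExhaustConfig(t_e=3), seed=5)
        assert av.duration >= 2  # the cycle completes at least one loop


class TestOracleEquality:
    def test_acyclic_matches_bfs_oracle(self, rng):
        # with exhaust effectively disabled (t_e -> inf), avalanches on
        # feedforward nets terminate naturally and match breadth-first
        # propagation exactly; note a finite t_e CAN shorten them, since
        # a DAG may re-activate a node via a longer parallel path
        for _ in range(20):
            n = int(rng.integers(4, 30))
            net = SignedNetwork(n)
            for tgt in range(1, n):
                srcs = rng.choice(tgt, size=min(tgt, 2), replace=False)
                for s in srcs:
                    if rng.random() < 0.8:
                        net.set_link(int(s), tgt, 1 if rng.random() < 0.8 else -1)
            av = run_avalanche(net, 0, ExhaustConfig(t_e=10 ** 9),
                               seed=int(rng.integers(2 ** 31)))
            assert av.terminated_by == "natural"
            assert (av.size, av.duration) == bfs_avalanche(net, 0)

    def test_toys_match_bfs_oracle(self, toys):
        for name in ("isolated", "chain3", "tree_d3", "cancel"):
            av = run_avalanche(toys[name], 0, BIG_TE, seed=0)
            assert (av.size, av.duration) == bfs_avalanche(toys[name], 0)


class TestContracts:
    def test_non_quiescent_start_rejected(self, toys):
        with pytest.raises(NonQuiescentError):
            run_avalanche(toys["chain3"], 0, BIG_TE, seed=0,
                          initial_states=np.array([False, True, False]))

    def test_bad_trigger_rejected(self, toys):
        with pytest.raises(ConfigError):
            run_avalanche(toys["chain3"], 7, BIG_TE, seed=0)

    def test_invariants_on_random_ensemble(self):
        net = make_random_network(64, 1.2, 0.9, seed=9)
        avs = run_ensemble(net, 300, ExhaustConfig(t_e=10), seed=10)
        for av in avs:
            assert 1 <= av.size <= 64
            assert av.duration == len(av.profile)
            assert av.size <= int(av.profile.sum())
            assert np.all(av.profile >= 1)

    def test_ensemble_bit_reproducible(self):
        net = make_random_network(64, 1.2, 0.9, seed=9)
        runs = [run_ensemble(net, 200, ExhaustConfig(t_e=10), seed=11)
                for _ in range(2)]
        assert [(a.size, a.duration) for a in runs[0]] == \
               [(a.size, a.duration) for a in runs[1]]

    def test_thresholds_reset_between_avalanches(self, toys):
        net = toys["cycle2"]
        avs = run_ensemble(net, 50, ExhaustConfig(t_e=3), seed=12)
        # if effective thresholds leaked across avalanches the cycle
        # could never re-enter; every avalanche still recruits both nodes
        # whenever the trigger has an out-link
        assert all(a.size == 2 for a in avs)
        assert np.all(net.thresholds == 0)


class TestMeanProfile:
    def _flat(self, height, duration, n=5):
        prof = np.full(duration, height, dtype=np.int64)
        return [Avalanche(size=height * duration, duration=duration,
                          profile=prof, trigger=0, terminated_by="natural")
                for _ in range(n)]

    def test_identical_profiles_average_to_themselves(self):
        avs = self._flat(3, 4)
        grid, prof = mean_profile(avs, 4, n_bins=4, gamma=1.0)
        assert prof.tolist() == [3.0, 3.0, 3.0, 3.0]

    def test_duration_one_single_point(self):
        avs = self._flat(1, 1)
        _, prof = mean_profile(avs, 1, n_bins=5, gamma=2.0)
        assert np.allclose(prof, 1.0)

    def test_amplitude_rescaling(self):
        avs = self._flat(8, 4)
        _, prof = mean_profile(avs, 4, n_bins=3, gamma=2.0)
        assert np.allclose(prof, 8.0 / 4.0)

    def test_missing_duration_signalled(self):
        with pytest.raises(EmptyResultError):
            mean_profile(self._flat(1, 2), 9)


class TestSummaryIO:
    def test_roundtrip(self, tmp_path):
        net = make_random_network(32, 1.0, 0.9, seed=13)
        avs = run_ensemble(net, 50, ExhaustConfig(t_e=10), seed=14,
                           record_events=True)
        spath = tmp_path / "summary.tsv"
        write_summaries(avs, spath, n_nodes=32)
        back, n_nodes = read_summaries(spath)
        assert n_nodes == 32
        assert [(a.size, a.duration, a.terminated_by) for a in back] == \
               [(a.size, a.duration, a.terminated_by) for a in avs]
        assert all(np.array_equal(a.profile, b.profile)
                   for a, b in zip(avs, back))
        epath = tmp_path / "events.tsv"
        write_event_log(avs, epath)
        lines = epath.read_text().strip().split("\n")
        assert len(lines) == 1 + sum(len(a.events) for a in avs)

    def test_event_log_requires_recorded_events(self, tmp_path):
        net = make_random_network(16, 1.0, 0.9, seed=15)
        avs = run_ensemble(net, 5, ExhaustConfig(t_e=10), seed=16)
        with pytest.raises(ConfigError):
            write_event_log(avs, tmp_path / "events.tsv")
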