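"""Myotome chart handling and weighted-mean segmental mapping."""

import numpy as np
import pytest

from emgsyn import (CANONICAL_MUSCLES, ValidationError, compute_segment_output,
                    load_myotome_chart, scale_by_mn_count)
from emgsyn.spinal import MyotomeChart, SpinalMapper


def tiny_chart(k, muscles=None, segments=("A", "B"), mn=None):
    k = np.asarray(k, dtype=float)
    muscles = muscles or tuple(f"m{i}" for i in range(k.shape[0]))
    mn = mn or {s: 1.0 for s in segments}
    return MyotomeChart(segments=segments, muscles=muscles, k=k, mn_counts=mn)


class TestChart:
    def test_default_chart_covers_all_canonical_muscles(self):
        chart = load_myotome_chart()
        assert chart.muscles == tuple(CANONICAL_MUSCLES)
        assert np.all(chart.n_i >= 1)
        assert np.all(chart.mn_vector > 0)

    def test_chart_missing_muscle_named(self, tmp_path):
        chart = load_myotome_chart()
        import pandas as pd
        df = pd.DataFrame(chart.k, index=list(chart.muscles),
                          columns=list(chart.segments))
        df = df.drop(index="L-TA")
        df.index.name = "muscle"
        df.to_csv(tmp_path / "c.csv")
        with pytest.raises(ValidationError, match="L-TA"):
            load_myotome_chart(tmp_path / "c.csv")

    def test_round_trip_unchanged(self, tmp_path):
        chart = load_myotome_chart()
        chart.write(tmp_path / "k.csv", tmp_path / "mn.json")
        back = load_myotome_chart(tmp_path / "k.csv", tmp_path / "mn.json")
        np.testing.assert_array_equal(back.k, chart.k)
        assert back.segments == chart.segments
        assert back.mn_counts == {s: chart.mn_counts[s] for s in chart.segments}

    def test_all_zero_muscle_rejected(self):
        with pytest.raises(ValidationError, match="m1"):
            tiny_chart([[1.0, 0.0], [0.0, 0.0]])


class TestSegmentOutput:
    def test_single_muscle_segment_returns_its_envelope(self, rng):
        chart = tiny_chart([[1.0, 0.0], [0.0, 1.0]])
        env = rng.uniform(size=(2, 50))
        out = compute_segment_output(env, chart)
        np.testing.assert_allclose(out, env)

    def test_identical_envelopes_give_identical_outputs(self, rng):
        k = rng.uniform(0.1, 1.0, size=(5, 3))
        chart = tiny_chart(k, segments=("A", "B", "C"))
        e = rng.uniform(size=50)
        out = compute_segment_output(np.tile(e, (5, 1)), chart)
        for row in out:
            np.testing.assert_allclose(row, e, rtol=1e-12)

    @pytest.mark.parametrize("variant", ["printed", "literature"])
    def test_matches_brute_force_weighted_mean(self, rng, variant):
        k = np.array([[1.0, 0.5], [0.0, 1.0], [0.7, 0.0]])
        chart = tiny_chart(k)
        env = rng.uniform(size=(3, 1))
        n = (k > 0).sum(axis=1)
        out = compute_segment_output(env, chart, variant=variant)
        for j in range(2):
            num = den = 0.0
            for i in range(3):
                w = k[i, j] * n[i] if variant == "printed" else k[i, j] / n[i]
                num += w * env[i, 0]
                den += w
            assert out[j, 0] == pytest.approx(num / den, abs=1e-12)

    def test_zero_weight_segment_warns_and_zeros(self, rng):
        chart = tiny_chart([[1.0, 0.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="zero total weight"):
            out = compute_segment_output(rng.uniform(size=(2, 5)), chart)
        np.testing.assert_array_equal(out[1], 0.0)

    def test_weighted_mean_bounded_on_random_fixtures(self):
        """min_i EMG_i(t) ≤ S_j(t) ≤ max_i EMG_i(t) over 1000 random charts."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            m, s, t = rng.integers(2, 6), rng.integers(1, 4), rng.integers(1, 6)
            k = rng.uniform(size=(m, s)) * (rng.random(size=(m, s)) < 0.7)
            k[k.sum(axis=1) == 0, 0] = 1.0   # keep every muscle mapped
            chart = tiny_chart(k, segments=tuple(f"s{i}" for i in range(s)),
                               mn={f"s{i}": 1.0 for i in range(s)})
            env = rng.uniform(size=(m, t))
            out = compute_segment_output(env, chart)
            lo, hi = env.min(axis=0), env.max(axis=0)
            nonzero = k.sum(axis=0) > 0
            assert np.all(out[nonzero] >= lo - 1e-12)
            assert np.all(out[nonzero] <= hi + 1e-12)

    def test_muscle_permutation_invariance(self, rng):
        chart = load_myotome_chart()
        env = rng.uniform(size=(14, 30))
        out = compute_segment_output(env, chart)
        perm = rng.permutation(14)
        chart_p = MyotomeChart(chart.segments,
                               tuple(chart.muscles[i] for i in perm),
                               chart.k[perm], dict(chart.mn_counts))
        np.testing.assert_allclose(compute_segment_output(env[perm], chart_p),
                                   out, rtol=1e-12)


class TestMnScaling:
    def test_unit_counts_leave_raw_unchanged(self, rng):
        chart = tiny_chart([[1.0, 0.2], [0.3, 1.0]])
        raw = rng.uniform(size=(2, 8))
        np.testing.assert_array_equal(scale_by_mn_count(raw, chart), raw)

    def test_doubling_one_count_doubles_that_row_only(self, rng):
        chart = tiny_chart([[1.0, 0.2], [0.3, 1.0]], mn={"A": 2.0, "B": 1.0})
        raw = rng.uniform(size=(2, 8))
        out = scale_by_mn_count(raw, chart)
        np.testing.assert_allclose(out[0], 2.0 * raw[0])
        np.testing.assert_allclose(out[1], raw[1])

    def test_hand_example_elementwise_product(self):
        chart = tiny_chart([[1.0, 1.0], [1.0, 1.0]], mn={"A": 3.0, "B": 5.0})
        raw = np.array([[1.0, 2.0], [4.0, 0.5]])
        np.testing.assert_array_equal(scale_by_mn_count(raw, chart),
                                      raw * np.array([[3.0], [5.0]]))


def test_mapper_transformer_end_to_end(noisy_envelope):
    out = SpinalMapper().fit().map_output(noisy_envelope)
    assert out.raw.shape == (7, noisy_envelope.shape[1])
    assert np.all(out.raw >= 0) and np.all(out.scaled >= 0)
    np.testing.assert_allclose(
        out.scaled, out.raw * load_myotome_chart().mn_vector[:, None])
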