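"""The nine prosodic features against hand values and brute-force oracles."""

import math

import numpy as np
import pytest

from szspeech.frames import segment
from szspeech.prosody import (
    JitterParams,
    extract_all,
    fpc,
    jitter,
    mgd,
    mp,
    msr,
    msrs,
    mud,
    pitch_range,
    ps,
)
from conftest import make_sequence


def jitter_oracle(p, K=5, denominator="sum"):
    """Direct summation of the jitter definition (written before the
    vectorized implementation; kept deliberately naive)."""
    R = len(p)
    if R <= K:
        return float("nan")
    h = (K - 1) // 2
    total = 0.0
    for v in range(h, R - h):
        s = sum(p[v + k] for k in range(-h, h + 1))
        num = p[v] - s / K
        den = s if denominator == "sum" else s / K
        total += num / den
    return total / (R - K)


def fpc_oracle(p):
    """Naive lag-1 Pearson autocorrelation."""
    x, y = p[:-1], p[1:]
    mx, my = np.mean(x), np.mean(y)
    num = np.sum((x - mx) * (y - my))
    den = math.sqrt(np.sum((x - mx) ** 2) * np.sum((y - my) ** 2))
    return num / den


def seq_with_speech(pitches, pad_silence=0):
    f0 = [0.0] * pad_silence + list(pitches) + [0.0] * pad_silence
    return make_sequence(f0)


class TestDurationFeatures:
    def test_mud_examples(self):
        f0 = [100.0] * 50 + [0.0] * 10 + [100.0] * 70
        seg = segment(make_sequence(f0))
        assert mud(seg) == pytest.approx(0.6)

        f0 = [100.0] * 50
        assert mud(segment(make_sequence(f0))) == pytest.approx(0.5)

        f0 = [100.0] * 50 + [0.0] * 5 + [100.0] * 50 + [0.0] * 5 + [100.0] * 80
        assert mud(segment(make_sequence(f0))) == pytest.approx(0.6)

    def test_mud_undefined_without_utterances(self):
        assert math.isnan(mud(segment(make_sequence([100.0] * 49))))

    def test_mgd_examples(self):
        f0 = [0.0] * 20 + [100.0] * 50 + [0.0] * 40
        assert mgd(segment(make_sequence(f0))) == pytest.approx(0.3)
        f0 = [100.0] * 50 + [0.0] * 1 + [100.0] * 50
        assert mgd(segment(make_sequence(f0))) == pytest.approx(0.01)
        f0 = (
            [0.0] * 10 + [100.0] * 50 + [0.0] * 10 + [100.0] * 50 + [0.0] * 40
        )
        assert mgd(segment(make_sequence(f0))) == pytest.approx(0.2)

    def test_mgd_undefined_without_gaps(self):
        assert math.isnan(mgd(segment(make_sequence([100.0] * 60))))

    def test_msr_msrs_examples(self):
        f0 = [100.0] * 50 + [0.0] * 50
        seg = segment(make_sequence(f0))
        assert msr(seg) == pytest.approx(0.5)
        assert msrs(seg) == pytest.approx(0.5)

        # sub-threshold speech counts for MSRS but not MSR
        f0 = [100.0] * 30 + [0.0] * 70
        seg = segment(make_sequence(f0))
        assert msr(seg) == 0.0
        assert msrs(seg) == pytest.approx(0.3)

        f0 = [100.0] * 60 + [0.0] * 55 + [100.0] * 50 + [0.0] * 55
        seg = segment(make_sequence(f0))
        assert msr(seg) == pytest.approx(110 / 220)

    def test_msrs_bounds_msr(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            n = rng.integers(1, 150)
            f0 = np.where(rng.random(n) < 0.5, 100.0, 0.0)
            seg = segment(make_sequence(f0))
            assert msrs(seg) >= msr(seg)


class TestPitchFeatures:
    def test_mp_ps_examples(self):
        seq = seq_with_speech([100.0, 150.0], pad_silence=3)
        assert mp(seq) == pytest.approx(125.0)
        seq = seq_with_speech([100.0] * 10)
        assert ps(seq) == 0.0
        seq = seq_with_speech([100.0, 110.0, 120.0])
        assert mp(seq) == pytest.approx(110.0)
        assert ps(seq) == pytest.approx(10.0)  # sample SD

    def test_pitch_range_modes(self):
        seq = seq_with_speech([100.0, 150.0])
        assert pitch_range(seq, "mean") == pytest.approx(50 / 125)
        assert pitch_range(seq, "min") == pytest.approx(0.5)
        const = seq_with_speech([120.0] * 5)
        assert pitch_range(const, "mean") == 0.0
        assert pitch_range(const, "min") == 0.0

    def test_undefined_without_speech(self):
        silent = make_sequence([0.0] * 20)
        assert math.isnan(mp(silent))
        assert math.isnan(pitch_range(silent))


class TestFPC:
    def test_linear_sequence_is_one(self):
        seq = seq_with_speech(np.linspace(100, 150, 30))
        assert fpc(seq) == pytest.approx(1.0)

    def test_alternating_sequence(self):
        seq = seq_with_speech([100.0, 200.0] * 10)
        assert fpc(seq) == pytest.approx(-1.0)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(5, 100)
            p = rng.uniform(80, 240, n)
            seq = seq_with_speech(p, pad_silence=2)
            assert fpc(seq) == pytest.approx(fpc_oracle(p), abs=1e-12)
            assert abs(fpc(seq)) <= 1.0 + 1e-12

    def test_bridges_gaps_by_default(self):
        # identical speech pitches whether or not a silence splits them
        p = np.array([100, 150, 110, 190, 120, 180], float)
        joined = seq_with_speech(p)
        split = make_sequence(list(p[:3]) + [0.0] * 10 + list(p[3:]))
        assert fpc(split) == pytest.approx(fpc(joined))
        # gap-respecting mode drops the pair straddling the silence
        assert fpc(split, bridge_gaps=False) != pytest.approx(fpc(joined))

    def test_undefined_cases(self):
        assert math.isnan(fpc(seq_with_speech([100.0, 120.0])))  # < 3 frames
        assert math.isnan(fpc(seq_with_speech([100.0] * 10)))  # zero variance


class TestJitter:
    def test_constant_pitch_is_zero(self):
        assert jitter(seq_with_speech([150.0] * 20)) == pytest.approx(0.0)

    def test_spike_matches_oracle(self):
        p = [100.0] * 5 + [200.0] + [100.0] * 4
        seq = seq_with_speech(p)
        assert jitter(seq) == pytest.approx(jitter_oracle(p), abs=1e-15)

    def test_random_sequences_match_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(6, 100)
            p = rng.uniform(80, 240, n)
            seq = seq_with_speech(p, pad_silence=1)
            assert jitter(seq) == pytest.approx(jitter_oracle(list(p)), abs=1e-14)

    def test_scale_invariance(self):
        # invariance of the statistic itself: hold the speech mask fixed
        # so rescaling cannot move frames out of the pitch band
        from dataclasses import replace

        rng = np.random.default_rng(5)
        p = rng.uniform(80, 240, 60)

        def as_speech(values):
            seq = make_sequence(values, classify=False)
            return replace(seq, speech_mask=np.ones(len(values), dtype=bool))

        base = jitter(as_speech(p))
        for c in (0.5, 2.0, 10.0):
            assert jitter(as_speech(c * p)) == pytest.approx(base, abs=1e-12)

    def test_mean_denominator_scales_by_k(self):
        p = list(np.random.default_rng(9).uniform(80, 240, 40))
        seq = seq_with_speech(p)
        j_sum = jitter(seq, JitterParams(K=5, denominator="sum"))
        j_mean = jitter(seq, JitterParams(K=5, denominator="mean"))
        assert j_mean == pytest.approx(5 * j_sum, abs=1e-12)

    def test_undefined_when_too_short(self):
        assert math.isnan(jitter(seq_with_speech([100.0] * 5)))

    def test_k_must_be_odd(self):
        with pytest.raises(ValueError):
            JitterParams(K=4)


class TestExtractAll:
    def test_control_like_sequence_all_finite(self, small_cohort):
        seq = small_cohort.frame_sequences[0]
        from szspeech.frames import classify_speech_frames

        vec = extract_all(classify_speech_frames(seq))
        values = vec.as_dict(include_variant=True)
        assert all(np.isfinite(v) for v in values.values()), values

    def test_all_silent_sequence(self):
        vec = extract_all(make_sequence([0.0] * 100))
        assert vec.MSR == 0.0 and vec.MSRS == 0.0
        for name in ("MUD", "MP", "PS", "PR", "FPC", "J"):
            assert math.isnan(getattr(vec, name))

    def test_msr_le_msrs_property(self):
        rng = np.random.default_rng(21)
        for _ in range(500):
            n = int(rng.integers(10, 300))
            f0 = np.where(rng.random(n) < 0.6, rng.uniform(80, 240, n), 0.0)
            vec = extract_all(make_sequence(f0))
            assert vec.MSR <= vec.MSRS + 1e-12

    def test_deterministic(self):
        f0 = np.random.default_rng(2).uniform(0, 300, 500)
        a = extract_all(make_sequence(f0))
        b = extract_all(make_sequence(f0))
        assert a == b
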