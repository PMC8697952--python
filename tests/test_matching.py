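"""Fractional Hamming matching: exact values, shift search, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from noseprint import (
    ComparabilityError,
    ParameterError,
    Template,
    hamming_distance,
    match,
    match_all,
    read_distances,
    write_distances,
)
from conftest import random_template


def _toy(bits_str: str, sid="S", cap=0, fp=1):
    bits = np.array([[list(map(int, bits_str))]], dtype=np.uint8)
    return Template(
        subject_id=sid,
        capture_index=cap,
        bits=bits,
        sample_stride=1,
        origin=(0, 0),
        bank_fingerprint=fp,
    )


class TestHammingDistance:
    def test_toy_five_bit_example(self):
        # 10110 vs 10011 differ in 2 of 5 positions
        assert hamming_distance(_toy("10110"), _toy("10011")) == pytest.approx(0.4)

    def test_self_distance_zero(self):
        t = random_template(np.random.default_rng(0))
        assert hamming_distance(t, t) == 0.0

    def test_complement_distance_one(self):
        t = random_template(np.random.default_rng(1))
        comp = Template(
            subject_id="C",
            capture_index=0,
            bits=(1 - t.bits).astype(np.uint8),
            sample_stride=t.sample_stride,
            origin=t.origin,
            bank_fingerprint=t.bank_fingerprint,
        )
        assert hamming_distance(t, comp) == 1.0

    def test_incomparable_templates_rejected(self):
        rng = np.random.default_rng(2)
        a = random_template(rng, fingerprint=1)
        b = random_template(rng, fingerprint=2)
        with pytest.raises(ComparabilityError):
            hamming_distance(a, b)
        c = random_template(rng, shape=(4, 8, 10), fingerprint=1)
        with pytest.raises(ComparabilityError):
            hamming_distance(a, c)

    @given(st.integers(0, 256), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_flipping_k_bits_gives_k_over_n(self, k, seed):
        rng = np.random.default_rng(seed)
        t = random_template(rng)
        n = t.bits.size
        k = min(k, n)
        flat = t.bits.copy().reshape(-1)
        idx = rng.choice(n, size=k, replace=False)
        flat[idx] = 1 - flat[idx]
        flipped = Template(
            subject_id="F",
            capture_index=0,
            bits=flat.reshape(t.bits.shape),
            sample_stride=t.sample_stride,
            origin=t.origin,
            bank_fingerprint=t.bank_fingerprint,
        )
        assert hamming_distance(t, flipped) == pytest.approx(k / n)


def _brute_force_min(ta, tb, max_shift):
    """Independent oracle: enumerate every shift, recompute overlap
    distance with plain slicing, smallest-shift tie-break.  Shift (dx, dy)
    hypothesises that b[y+dy, x+dx] overlays a[y, x]."""
    _, h, w = ta.bits.shape
    best = None
    shifts = sorted(
        (
            (dx, dy)
            for dx in range(-max_shift, max_shift + 1)
            for dy in range(-max_shift, max_shift + 1)
        ),
        key=lambda s: (abs(s[0]) + abs(s[1]), s),
    )
    for dx, dy in shifts:
        oh, ow = h - abs(dy), w - abs(dx)
        if oh * ow < 0.5 * h * w:
            continue
        a = ta.bits[:, max(-dy, 0) : max(-dy, 0) + oh, max(-dx, 0) : max(-dx, 0) + ow]
        b = tb.bits[:, max(dy, 0) : max(dy, 0) + oh, max(dx, 0) : max(dx, 0) + ow]
        d = int((a != b).sum()) / a.size
        if best is None or d < best[0]:
            best = (d, (dx, dy))
    return best


class TestMatch:
    def test_self_match_zero_at_origin(self):
        t = random_template(np.random.default_rng(3), shape=(4, 12, 12))
        r = match(t, t, max_shift=3)
        assert r.distance == 0.0 and r.best_shift == (0, 0)

    def test_recovers_pure_translation(self):
        rng = np.random.default_rng(4)
        ta = random_template(rng, shape=(2, 10, 10))
        shifted = np.zeros_like(ta.bits)
        shifted[:, :, 1:] = ta.bits[:, :, :-1]  # content moved +1 in x
        tb = Template(
            subject_id="B",
            capture_index=0,
            bits=shifted,
            sample_stride=2,
            origin=(0, 0),
            bank_fingerprint=ta.bank_fingerprint,
        )
        r = match(ta, tb, max_shift=2)
        assert r.distance == 0.0 and r.best_shift == (1, 0)

    def test_zero_shift_reduces_to_hamming(self):
        rng = np.random.default_rng(5)
        ta, tb = random_template(rng), random_template(rng)
        assert match(ta, tb, max_shift=0).distance == hamming_distance(ta, tb)

    def test_equals_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            ta = random_template(rng, shape=(16, 32, 32))
            tb = random_template(rng, shape=(16, 32, 32))
            r = match(ta, tb, max_shift=2)
            d, shift = _brute_force_min(ta, tb, 2)
            assert r.distance == pytest.approx(d, abs=0)
            assert r.best_shift == shift

    def test_symmetry_of_distance(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            ta = random_template(rng, shape=(4, 16, 16))
            tb = random_template(rng, shape=(4, 16, 16))
            assert match(ta, tb, 3).distance == pytest.approx(match(tb, ta, 3).distance)

    def test_distance_never_increases_with_max_shift(self):
        rng = np.random.default_rng(8)
        ta = random_template(rng, shape=(4, 16, 16))
        tb = random_template(rng, shape=(4, 16, 16))
        dists = [match(ta, tb, s).distance for s in range(5)]
        assert all(d2 <= d1 + 1e-12 for d1, d2 in zip(dists, dists[1:]))

    def test_distances_stay_in_unit_interval(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            ta = random_template(rng, shape=(2, 8, 8))
            tb = random_template(rng, shape=(2, 8, 8))
            assert 0.0 <= match(ta, tb, 2).distance <= 1.0

    def test_shifts_below_overlap_floor_are_excluded(self):
        # on an 8x8 grid a shift of 5+ cells keeps < 50% of the area and
        # must never be selected however favourable its overlap distance
        rng = np.random.default_rng(10)
        for _ in range(10):
            ta = random_template(rng, shape=(2, 8, 8))
            tb = random_template(rng, shape=(2, 8, 8))
            r = match(ta, tb, max_shift=7)
            assert max(abs(r.best_shift[0]), abs(r.best_shift[1])) <= 4

    def test_negative_max_shift_rejected(self):
        rng = np.random.default_rng(11)
        with pytest.raises(ParameterError):
            match(random_template(rng), random_template(rng), max_shift=-1)


class TestMatchAll:
    def _gallery(self, rng, n, n_subjects=3):
        return [
            random_template(
                rng, shape=(4, 12, 12), subject_id=f"S{i % n_subjects}", capture_index=i
            )
            for i in range(n)
        ]

    def test_pair_count(self):
        rng = np.random.default_rng(12)
        assert len(match_all(self._gallery(rng, 9), 2)) == 36
        assert len(match_all(self._gallery(rng, 2), 2)) == 1

    def test_agrees_with_pairwise_match(self):
        rng = np.random.default_rng(13)
        gallery = self._gallery(rng, 7)
        results = match_all(gallery, 2)
        k = 0
        for i in range(7):
            for j in range(i + 1, 7):
                ref = match(gallery[i], gallery[j], 2)
                assert results[k].distance == pytest.approx(ref.distance, abs=0)
                assert results[k].best_shift == ref.best_shift
                assert results[k].pair_type == ref.pair_type
                k += 1

    def test_pair_type_labels(self):
        rng = np.random.default_rng(14)
        results = match_all(self._gallery(rng, 6, n_subjects=2), 1)
        for r in results:
            assert r.pair_type == ("genuine" if r.subject_a == r.subject_b else "impostor")


def test_distances_csv_round_trip(tmp_path):
    rng = np.random.default_rng(15)
    gallery = [
        random_template(rng, shape=(4, 12, 12), subject_id=f"S{i % 2}", capture_index=i)
        for i in range(4)
    ]
    results = match_all(gallery, 1)
    path = tmp_path / "distances.csv"
    write_distances(results, path)
    back = read_distances(path)
    assert len(back) == len(results)
    for a, b in zip(results, back):
        assert (a.subject_a, a.capture_a, a.subject_b, a.capture_b) == (
            b.subject_a,
            b.capture_a,
            b.subject_b,
            b.capture_b,
        )
        assert b.distance == pytest.approx(a.distance, abs=5e-5)  # 4-decimal CSV
        assert a.best_shift == b.best_shift
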