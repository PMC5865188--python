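"""Ka/Ks estimation and neutral-time dating."""

import itertools
from math import log

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genoloss.loss_dating import (
    CodonAlignmentPair,
    date_loss,
    kaks,
    neutral_time,
)
from genoloss.synthetic import evolve_codon_sequence, random_cds

# ---------------------------------------------------------------------------
# independent brute-force Nei-Gojobori oracle (kept deliberately naive)

_CODE = {}


def _aa(codon):
    if not _CODE:
        from Bio.Seq import Seq

        for c in map("".join, itertools.product("ACGT", repeat=3)):
            _CODE[c] = str(Seq(c).translate())
    return _CODE[codon]


def oracle_ng86(seq1: str, seq2: str):
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        if _aa(c1) == "*" or _aa(c2) == "*":
            continue
        for c in (c1, c2):
            s = 0.0
            for pos in range(3):
                for b in "ACGT":
                    if b == c[pos]:
                        continue
                    alt = c[:pos] + b + c[pos + 1:]
                    if _aa(alt) == _aa(c) and _aa(alt) != "*":
                        s += 1 / 3
            S += s / 2
            N += (3 - s) / 2
        diffs = [p for p in range(3) if c1[p] != c2[p]]
        if diffs:
            sd = nd = 0.0
            paths = list(itertools.permutations(diffs))
            for path in paths:
                cur = c1
                for p in path:
                    nxt = cur[:p] + c2[p] + cur[p + 1:]
                    if _aa(cur) == _aa(nxt):
                        sd += 1
                    else:
                        nd += 1
                    cur = nxt
            Sd += sd / len(paths)
            Nd += nd / len(paths)
    pS, pN = Sd / S, Nd / N
    jc = lambda p: -0.75 * log(1 - 4 * p / 3)  # noqa: E731
    return jc(pN), jc(pS)


class TestKaKs:
    def test_identical_sequences_undefined_ratio(self):
        pair = CodonAlignmentPair("ATGCGT" * 20, "ATGCGT" * 20)
        res = kaks(pair)
        assert res.ka == 0.0 and res.ks == 0.0
        assert res.ratio is None and "ks_zero" in res.flags

    def test_single_synonymous_change(self):
        s1 = "TTT" + "ATGCGT" * 20
        s2 = "TTC" + "ATGCGT" * 20
        res = kaks(CodonAlignmentPair(s1, s2))
        assert res.ka == 0.0
        assert res.ks > 0.0

    def test_single_nonsynonymous_change(self):
        s1 = "TTT" + "ATGCGT" * 20
        s2 = "TGT" + "ATGCGT" * 20  # Phe -> Cys
        res = kaks(CodonAlignmentPair(s1, s2))
        assert res.ks == 0.0 and res.ka > 0.0

    def test_matches_bruteforce_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            s1 = random_cds(100, rng)
            s2 = evolve_codon_sequence(s1, 0.15, 1.0, rng, forbid_stops=True)
            res = kaks(CodonAlignmentPair(s1, s2))
            if res.ratio is None:
                continue
            ka, ks = oracle_ng86(s1.upper(), s2.upper())
            assert res.ka == pytest.approx(ka, abs=1e-10)
            assert res.ks == pytest.approx(ks, abs=1e-10)

    def test_saturated_proportion_flagged(self):
        # maximally diverged third positions: force pS towards saturation
        s1 = "GGA" * 40
        s2 = "CCT" * 40
        res = kaks(CodonAlignmentPair(s1, s2))
        assert res.ratio is None and res.flags


class TestNeutralTime:
    def test_limit_no_relaxation(self):
        assert neutral_time(0.2, 0.2, 10.0) == 0.0

    def test_limit_fully_neutral(self):
        assert neutral_time(1.0, 0.2, 10.0) == 10.0

    def test_hand_example(self):
        assert neutral_time(0.6, 0.2, 10.0) == pytest.approx(5.0)

    def test_clamped_to_physical_range(self):
        assert neutral_time(0.1, 0.2, 10.0) == 0.0
        assert neutral_time(1.5, 0.2, 10.0) == 10.0

    def test_selected_rate_at_neutral_rejected(self):
        with pytest.raises(ValueError):
            neutral_time(0.6, 1.0, 10.0)

    @settings(max_examples=80, derandomize=True)
    @given(
        st.floats(0.01, 0.95), st.floats(0.01, 0.95), st.floats(0.1, 100),
    )
    def test_monotone_in_k_and_t(self, k, ks, t):
        if ks >= 0.9:
            ks = 0.89
        tn = neutral_time(k, ks, t)
        assert 0.0 <= tn <= t
        assert neutral_time(min(1.0, k + 0.01), ks, t) >= tn
        assert neutral_time(k, ks, t * 1.5) >= tn * 0.999

    @settings(max_examples=60, derandomize=True)
    @given(st.floats(0.05, 0.9), st.floats(0.3, 1.0), st.floats(1.0, 50.0))
    def test_mixture_equation_inverse(self, ks, k, t):
        """Substituting Tn back into K = Ks*Ts/T + 1*Tn/T recovers K."""
        if ks >= k:
            k = min(1.0, ks + 0.05)
        tn = neutral_time(k, ks, t)
        k_back = ks * (t - tn) / t + 1.0 * tn / t
        assert k_back == pytest.approx(k, abs=1e-9)


class TestDateLoss:
    def _pairs(self, rng, omega_loss_half=True):
        anc = random_cds(1000, rng)
        a = evolve_codon_sequence(anc, 0.05, 0.2, rng)
        b = evolve_codon_sequence(anc, 0.05, 0.2, rng)
        mid = evolve_codon_sequence(anc, 0.05, 0.2, rng)
        lost = evolve_codon_sequence(mid, 0.05, 1.0, rng, forbid_stops=False)
        return CodonAlignmentPair(anc, lost), [CodonAlignmentPair(a, b)]

    def test_bounds_scale_linearly_with_t(self):
        rng = np.random.default_rng(7)
        loss_pair, intact = self._pairs(rng)
        d1 = date_loss("g", "br", loss_pair, intact, (20.0, 30.0))
        assert d1.Tn_upper == pytest.approx(d1.Tn_lower * 30.0 / 20.0, rel=1e-9)
        assert 0.0 <= d1.Tn_lower <= 20.0
        assert d1.Ts_lower == pytest.approx(d1.T_lower - d1.Tn_lower)

    def test_half_neutral_branch_recovers_half_time(self):
        rng = np.random.default_rng(11)
        loss_pair, intact = self._pairs(rng)
        d = date_loss("g", "br", loss_pair, intact, (10.0, 10.0))
        assert 0.25 <= d.Tn_lower / 10.0 <= 0.75

    def test_requires_intact_baseline(self):
        rng = np.random.default_rng(3)
        loss_pair, _ = self._pairs(rng)
        with pytest.raises(ValueError):
            date_loss("g", "br", loss_pair, [], (10.0, 20.0))
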