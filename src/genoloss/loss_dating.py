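"""Dating gene losses from the Ka/Ks signature of relaxed selection.

A gene on its loss branch evolves under purifying selection (Ka/Ks =
Ks_sel < 1) until inactivation and neutrally (Ka/Ks = 1) afterwards, so
the whole-branch ratio K is the time-weighted mixture

    K = Ks_sel * Ts/T + 1 * Tn/T,

where T is the branch's divergence time and Ts + Tn = T.  Inverting
gives the time the gene has been evolving neutrally:

    Tn = T * (K - Ks_sel) / (1 - Ks_sel).

Applying the inversion to the lower and upper bounds of the divergence
time yields bounds on Tn.  Ka/Ks itself is estimated with the
Nei-Gojobori (1986) counting method with Jukes-Cantor correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import log
from typing import Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "CodonAlignmentPair",
    "KaKsResult",
    "LossDating",
    "kaks",
    "neutral_time",
    "date_loss",
]

_BASES = "ACGT"
_STOPS = set(standard_dna_table.stop_codons)
_CODON_AA = dict(standard_dna_table.forward_table)
for _stop in _STOPS:
    _CODON_AA[_stop] = "*"


def _syn_site_count(codon: str) -> float:
    """Fraction-of-site count of synonymous positions in one codon.

    Each position contributes the fraction of its three possible
    changes that leave the amino acid unchanged; changes to or from a
    stop codon count as non-synonymous.
    """
    aa = _CODON_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if _CODON_AA[alt] == aa and alt not in _STOPS and codon not in _STOPS:
                syn += 1
        s += syn / 3.0
    return s


_SYN_SITES = {
    "".join(c): _syn_site_count("".join(c))
    for c in itertools.product(_BASES, repeat=3)
}


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/non-synonymous difference counts between two codons,
    averaged over all orderings of the mutational pathway."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_tot = nsyn_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = nsyn = 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _CODON_AA[cur] == _CODON_AA[nxt]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        syn_tot += syn
        nsyn_tot += nsyn
        n_paths += 1
    return syn_tot / n_paths, nsyn_tot / n_paths


@dataclass
class CodonAlignmentPair:
    """Two in-frame, gap-free codon sequences of equal length."""

    seq1: str
    seq2: str

    def __post_init__(self) -> None:
        self.seq1 = self.seq1.upper()
        self.seq2 = self.seq2.upper()
        if len(self.seq1) != len(self.seq2):
            raise ValueError("sequences differ in length")
        if len(self.seq1) % 3:
            raise ValueError("length not divisible by 3")

    def codons(self):
        for i in range(0, len(self.seq1), 3):
            c1, c2 = self.seq1[i:i + 3], self.seq2[i:i + 3]
            if set(c1) <= set(_BASES) and set(c2) <= set(_BASES):
                yield c1, c2


@dataclass
class KaKsResult:
    ka: float
    ks: float
    ratio: Optional[float]          # None when undefined (Ks = 0)
    n_codons: int
    flags: tuple[str, ...] = ()


def kaks(pair: CodonAlignmentPair) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

    Synonymous and non-synonymous site counts are averaged over the two
    sequences; difference counts are averaged over mutational pathways;
    both proportions are corrected with d = -3/4 ln(1 - 4p/3).  The
    ratio is flagged undefined when Ks = 0 or a proportion reaches the
    correction's divergence (p >= 3/4).
    """
    S = N = 0.0
    Sd = Nd = 0.0
    n_codons = 0
    for c1, c2 in pair.codons():
        if c1 in _STOPS or c2 in _STOPS:
            continue
        n_codons += 1
        s1, s2 = _SYN_SITES[c1], _SYN_SITES[c2]
        S += 0.5 * (s1 + s2)
        N += 3.0 - 0.5 * (s1 + s2)
        sd, nd = _pathway_diffs(c1, c2)
        Sd += sd
        Nd += nd
    if n_codons < 30:
        warnings.warn("fewer than 30 codons: Ka/Ks estimate is unstable")
    flags: list[str] = []
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    ks = _jukes_cantor(pS, flags, "ks_saturated")
    ka = _jukes_cantor(pN, flags, "ka_saturated")
    if ks is None or ka is None:
        return KaKsResult(float("nan"), float("nan"), None, n_codons, tuple(flags))
    if ks == 0.0:
        flags.append("ks_zero")
        return KaKsResult(ka, ks, None, n_codons, tuple(flags))
    return KaKsResult(ka, ks, ka / ks, n_codons, tuple(flags))


def _jukes_cantor(p: float, flags: list[str], flag: str) -> Optional[float]:
    if p >= 0.75:
        flags.append(flag)
        return None
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def neutral_time(K: float, Ks_sel: float, T: float) -> float:
    """Time the gene evolved neutrally: Tn = T (K - Ks) / (1 - Ks).

    Clamped to the physical range [0, T]: sampling noise can push the
    branch ratio K outside [Ks_sel, 1], but Tn is a time.
    """
    if Ks_sel >= 1.0:
        raise ValueError("Ks_sel must be < 1 (selection below neutral rate)")
    if T <= 0:
        raise ValueError("divergence time must be positive")
    tn = T * (K - Ks_sel) / (1.0 - Ks_sel)
    return min(T, max(0.0, tn))


@dataclass
class LossDating:
    """Dating of one lost gene on one branch.

    ``K`` is the whole-loss-branch Ka/Ks; ``Ks_sel`` the ratio under
    selection pooled from intact species; times in the units of the
    divergence-time bounds (typically My).
    """

    gene_id: str
    branch: str
    K: float
    Ks_sel: float
    T_lower: float
    T_upper: float
    Tn_lower: float
    Tn_upper: float

    @property
    def Ts_lower(self) -> float:
        return self.T_lower - self.Tn_lower

    @property
    def Ts_upper(self) -> float:
        return self.T_upper - self.Tn_upper


def date_loss(
    gene_id: str,
    branch: str,
    loss_pair: CodonAlignmentPair,
    intact_pairs: Sequence[CodonAlignmentPair],
    T_bounds: tuple[float, float],
) -> LossDating:
    """Date one loss from codon alignments and divergence-time bounds.

    ``loss_pair`` aligns the lost species against its closest intact
    relative (a proxy for the branch's ancestral sequence);
    ``intact_pairs`` are alignments among species with the functional
    gene, pooled to estimate Ks_sel.  Both bounds of the divergence
    time are propagated through the Tn inversion.
    """
    if not intact_pairs:
        raise ValueError("no intact species to estimate the selected rate from")
    ka_sum = ks_sum = 0.0
    for p in intact_pairs:
        r = kaks(p)
        if r.ratio is None:
            continue
        ka_sum += r.ka
        ks_sum += r.ks
    if ks_sum == 0.0:
        raise ValueError("selected-rate Ka/Ks undefined (no synonymous divergence)")
    ks_sel = ka_sum / ks_sum
    if ks_sel >= 1.0:
        raise ValueError("selected-rate Ka/Ks not below 1; cannot date relaxation")

    r = kaks(loss_pair)
    if r.ratio is None:
        raise ValueError(f"loss-branch Ka/Ks undefined: {r.flags}")
    K = min(1.0, max(ks_sel, r.ratio))

    t_lo, t_hi = sorted(T_bounds)
    return LossDating(
        gene_id=gene_id,
        branch=branch,
        K=K,
        Ks_sel=ks_sel,
        T_lower=t_lo,
        T_upper=t_hi,
        Tn_lower=neutral_time(K, ks_sel, t_lo),
        Tn_upper=neutral_time(K, ks_sel, t_hi),
    )
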