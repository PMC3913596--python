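"""Molecular diversity indices: pairwise differences and NG86 dN/dS.

Site counting follows the stop-excluded convention: at each codon
position the three possible single-nucleotide changes are classified as
synonymous, nonsynonymous or stop-creating; stop-creating changes are
dropped from both numerator and denominator, so every counted codon
still contributes exactly 3 sites.  Differences between two codons are
averaged over all minimal mutational paths with equal weights, skipping
paths that pass through a stop codon (if every path does, all paths are
used).  The distance correction is Jukes-Cantor; proportions >= 3/4 give
NaN ("saturated").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .codons import CODON_TO_AA, NUCS, STOP_CODONS
from .seq_model import Alignment

_GAPLIKE = set("-NRYSWKMBDHV?.")


def pairwise_differences(aln: Alignment) -> np.ndarray:
    """Symmetric matrix of mismatching columns, gap columns skipped pairwise."""
    n = len(aln)
    seqs = [s.upper() for _, s in aln.records]
    out = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            d = sum(
                1
                for a, b in zip(seqs[i], seqs[j])
                if a != b and a not in _GAPLIKE and b not in _GAPLIKE
            )
            out[i, j] = out[j, i] = d
    return out


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) fractional site counts of one codon."""
    if codon in STOP_CODONS or any(b not in NUCS for b in codon):
        raise ValueError(f"cannot count sites of {codon!r}")
    syn = nonsyn = 0.0
    for pos in range(3):
        s = n = 0
        for alt in NUCS:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            if CODON_TO_AA[mutant] == CODON_TO_AA[codon]:
                s += 1
            else:
                n += 1
        total = s + n
        if total:
            syn += s / total
            nonsyn += n / total
    # positions whose every change creates a stop contribute no sites of
    # either class; rescale so the codon still carries 3 sites overall
    scale = 3.0 / (syn + nonsyn) if (syn + nonsyn) else 0.0
    return syn * scale, nonsyn * scale


@lru_cache(maxsize=None)
def codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Equal-weight average over all orderings of the differing positions,
    excluding paths through stop codons when any stop-free path exists.
    """
    diff_pos = [k for k in range(3) if c1[k] != c2[k]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        current = c1
        steps = []
        through_stop = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            steps.append((current, nxt))
            current = nxt
        paths.append((through_stop, steps))
    usable = [steps for through, steps in paths if not through]
    if not usable:
        usable = [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in usable:
        for a, b in steps:
            if a in STOP_CODONS or b in STOP_CODONS:
                continue
            if CODON_TO_AA[a] == CODON_TO_AA[b]:
                sd += 1
            else:
                nd += 1
    return sd / len(usable), nd / len(usable)


def jukes_cantor(p: float) -> float:
    """JC-corrected distance; NaN when p >= 3/4 (saturated)."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class PairwiseDnDs:
    seq_a: str
    seq_b: str
    sd: float
    nd: float
    S_sites: float
    N_sites: float

    @property
    def pS(self) -> float:
        return self.sd / self.S_sites if self.S_sites else float("nan")

    @property
    def pN(self) -> float:
        return self.nd / self.N_sites if self.N_sites else float("nan")

    @property
    def dS(self) -> float:
        return jukes_cantor(self.pS)

    @property
    def dN(self) -> float:
        return jukes_cantor(self.pN)


def _usable_codon(codon: str) -> bool:
    return (
        all(b in NUCS for b in codon) and codon not in STOP_CODONS
    )


def nei_gojobori_pair(seq_a: str, seq_b: str,
                      name_a: str = "a", name_b: str = "b",
                      codon_subset: list[int] | None = None) -> PairwiseDnDs:
    """NG86 counts for one aligned codon-sequence pair.

    Codons containing gaps, ambiguity or stops in either sequence are
    skipped pairwise.  ``codon_subset`` restricts counting to the given
    1-based codon columns.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    if len(a) % 3:
        raise ValueError("length not divisible by 3")
    n_codons = len(a) // 3
    sites = codon_subset if codon_subset is not None else range(1, n_codons + 1)
    sd = nd = S = N = 0.0
    for c in sites:
        ca, cb = a[3 * (c - 1) : 3 * c], b[3 * (c - 1) : 3 * c]
        if not (_usable_codon(ca) and _usable_codon(cb)):
            continue
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        ds, dn = codon_pair_differences(ca, cb)
        sd += ds
        nd += dn
    return PairwiseDnDs(name_a, name_b, sd=sd, nd=nd, S_sites=S, N_sites=N)


def nei_gojobori(aln: Alignment,
                 codon_subset: list[int] | None = None) -> list[PairwiseDnDs]:
    """NG86 over all sequence pairs of a codon alignment."""
    if aln.kind != "codon" and aln.n_sites % 3:
        raise ValueError("codon alignment required")
    out = []
    for i in range(len(aln)):
        for j in range(i + 1, len(aln)):
            na, sa = aln.records[i]
            nb, sb = aln.records[j]
            out.append(nei_gojobori_pair(sa, sb, na, nb, codon_subset=codon_subset))
    return out


def mean_dn_ds(pairs: list[PairwiseDnDs]) -> tuple[float, float]:
    """Means of dN and dS over pairs, ignoring saturated (NaN) entries."""
    dn = np.array([p.dN for p in pairs], dtype=float)
    ds = np.array([p.dS for p in pairs], dtype=float)
    return float(np.nanmean(dn)), float(np.nanmean(ds))
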