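"""Genetic-code tables and codon substitution-model building blocks.

The 61 sense codons of the standard code are indexed 0..60 in
lexicographic order (TCAG base order is *not* used; plain ACGT sorting
keeps the mapping obvious).  Rate matrices follow the NY98
parameterisation: single-nucleotide codon exchanges with a transition
multiplier ``kappa`` and a nonsynonymous multiplier ``omega``, equal
codon frequencies (1/61).  With equal frequencies the matrix is
symmetric, so spectral decompositions use ``numpy.linalg.eigh``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCS = "ACGT"
NUC_INDEX = {b: i for i, b in enumerate(NUCS)}

_standard = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid letter, stops mapped to '*'
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_standard.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in CODON_TO_AA if c not in STOP_CODONS)
)
N_SENSE = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

IUPAC_NUC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def is_transition(a: str, b: str) -> bool:
    """True if a<->b is a purine-purine or pyrimidine-pyrimidine change."""
    return frozenset((a, b)) in _TRANSITIONS


def translate_codon(codon: str) -> str:
    """Translate one codon; any ambiguity yields 'X', stops yield '*'."""
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3:
        raise ValueError(f"not a codon: {codon!r}")
    if any(b not in "ACGT" for b in codon):
        return "X"
    return CODON_TO_AA[codon]


@lru_cache(maxsize=1)
def _single_step_structure() -> tuple[np.ndarray, np.ndarray]:
    """Masks over 61x61 pairs: (is_transition, is_nonsynonymous).

    Entries are zero where codons differ at !=1 positions.  Returned as
    float arrays so they can be combined arithmetically.
    """
    ts = np.zeros((N_SENSE, N_SENSE))
    nonsyn = np.zeros((N_SENSE, N_SENSE))
    step = np.zeros((N_SENSE, N_SENSE))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            step[i, j] = 1.0
            if is_transition(*diffs[0]):
                ts[i, j] = 1.0
            if CODON_TO_AA[ci] != CODON_TO_AA[cj]:
                nonsyn[i, j] = 1.0
    return step * ts, step * (1 - ts), nonsyn


def ny98_rate_matrix(kappa: float, omega: float, normalise: bool = False) -> np.ndarray:
    """NY98 codon rate matrix with equal codon frequencies.

    Off-diagonal rate for a single-nucleotide exchange is
    ``kappa^[transition] * omega^[nonsynonymous]``; multi-step exchanges
    are zero.  ``normalise`` rescales so one unit of time gives one
    expected substitution per codon *at omega = 1*; the neutral reference
    keeps omega > 1 sites genuinely faster, matching the NY98 convention
    where omega multiplies the nonsynonymous rate.
    """
    ts, tv, nonsyn = _single_step_structure()
    rates = (kappa * ts + tv) * np.where(nonsyn > 0, omega, 1.0)
    q = rates.copy()
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if normalise:
        neutral = kappa * ts + tv
        rate = float(np.mean(neutral.sum(axis=1)))  # pi_i = 1/61
        if rate > 0:
            q = q / rate
    return q


def transition_probabilities(q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t) via symmetric eigendecomposition (equal-frequency Q)."""
    w, v = np.linalg.eigh(q)
    p = (v * np.exp(w * t)) @ v.T
    np.clip(p, 1e-300, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def codon_indices(seq: str) -> np.ndarray:
    """Encode a nucleotide string as sense-codon indices; -1 marks codons
    containing gaps, ambiguity or stops (treated as missing downstream)."""
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for k in range(len(out)):
        codon = seq[3 * k : 3 * k + 3]
        out[k] = CODON_INDEX.get(codon, -1)
    return out


def indices_to_seq(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)
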