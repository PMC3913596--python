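"""Clone-sampling coverage model.

How many clones must be sequenced to observe all of an individual's
distinct variants, given per-variant sampling frequencies (equal by
default).  ``prob_all_detected`` is the inclusion-exclusion probability
that ``n`` clones hit every one of ``m`` variants; ``expected_fraction_
detected`` is the mean fraction of variants seen at least once.
"""

from __future__ import annotations

import itertools

import numpy as np


def _check_freqs(m: int, p=None) -> np.ndarray:
    if m < 1:
        raise ValueError("m must be >= 1")
    if p is None:
        return np.full(m, 1.0 / m)
    p = np.asarray(p, dtype=float)
    if len(p) != m:
        raise ValueError(f"expected {m} frequencies, got {len(p)}")
    if (p <= 0).any() or not np.isclose(p.sum(), 1.0):
        raise ValueError("frequencies must be positive and sum to 1")
    return p


def prob_all_detected(m: int, n: int, p=None) -> float:
    """P(all m variants observed in n clones), by inclusion-exclusion:
    sum over subsets S of (-1)^|S| (1 - sum_{i in S} p_i)^n."""
    p = _check_freqs(m, p)
    if n < 0:
        raise ValueError("n must be >= 0")
    if n < m:
        return 0.0
    total = 0.0
    for size in range(m + 1):
        for subset in itertools.combinations(range(m), size):
            miss = p[list(subset)].sum() if subset else 0.0
            total += (-1.0) ** size * (1.0 - miss) ** n
    return float(min(max(total, 0.0), 1.0))


def expected_fraction_detected(m: int, n: int, p=None) -> float:
    """E[fraction of variants seen at least once in n clones]."""
    p = _check_freqs(m, p)
    if n < 0:
        raise ValueError("n must be >= 0")
    return float(np.mean(1.0 - (1.0 - p) ** n))


def min_clones_for_confidence(m: int, confidence: float, p=None,
                              n_max: int = 100000) -> int:
    """Smallest n with prob_all_detected(m, n, p) >= confidence."""
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    _check_freqs(m, p)
    n = m
    while n <= n_max:
        if prob_all_detected(m, n, p) >= confidence:
            return n
        n += 1
    raise RuntimeError(f"confidence {confidence} not reached by n={n_max}")


def diploid_two_locus_freqs() -> np.ndarray:
    """Equal-frequency preset for 4 haplotypes (diploid, two loci)."""
    return np.full(4, 0.25)


def monte_carlo_prob_all(m: int, n: int, p=None, draws: int = 100000,
                         seed: int = 0) -> tuple[float, float]:
    """Simulation estimate of prob_all_detected with its standard error."""
    p = _check_freqs(m, p)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(draws):
        seen = np.unique(rng.choice(m, size=n, p=p))
        hits += len(seen) == m
    est = hits / draws
    se = float(np.sqrt(est * (1 - est) / draws))
    return est, se
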