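"""Recombination screening: breakpoint detectors, consensus calls, rho/theta.

Three detectors are shipped:

* ``maxchi_scan`` — pairwise maximum chi-square contrast of discordance
  left/right of candidate breakpoints, permutation null over polymorphic
  columns, Bonferroni over pairs;
* ``triplet_scan`` — for each (child; parent1, parent2) triplet, the same
  contrast on informative sites (parents differ), which also yields the
  putative recombinant and parents;
* ``composition_scan`` — exact single-crossover composition test
  (generalised from the within-individual clone screen).

Calls are accepted only when >= 2 detectors agree and the consensus
score exceeds 60 (score = 100 * detector fraction * median permutation
support of the supporting detectors).

``estimate_rho_theta`` pairs the Watterson estimator with a grid-based
pairwise composite likelihood for rho built on four-gamete-violation
probabilities calibrated by coalescent simulation (msprime).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations

import numpy as np

from .clone_validation import find_single_crossover
from .seq_model import Alignment


@dataclass(frozen=True)
class BreakpointCandidate:
    sequences: tuple[str, ...]       # pair or (child, parent1, parent2)
    breakpoint: tuple[int, int]      # 1-based column interval
    statistic: float
    p_value: float                   # Bonferroni-adjusted permutation p
    detector: str


@dataclass(frozen=True)
class RecombinationCall:
    recombinant: str
    parents: tuple[str, str]
    breakpoint: tuple[int, int]
    detectors: frozenset
    consensus_score: float
    p_values: dict = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self):
        if len(self.detectors) < 2:
            raise ValueError("an accepted call needs >= 2 detectors")
        if self.consensus_score <= 60:
            raise ValueError("an accepted call needs consensus score > 60")


@dataclass(frozen=True)
class RecombEstimates:
    rho: float
    theta: float
    ratio_note: str

    def __post_init__(self):
        if self.rho < 0 or self.theta < 0:
            raise ValueError("rho and theta must be >= 0")


def _max_chi_with_null(binary: np.ndarray, positions: np.ndarray,
                       permutations_n: int, rng: np.random.Generator,
                       min_flank: int = 2) -> tuple[float, int, float]:
    """Max chi-square of a binary discordance vector split left/right.

    Returns (statistic, best index into ``positions`` marking the last
    left-side site, permutation p-value).  ``binary`` holds 1 where the
    compared sequences disagree at the polymorphic column.
    """
    m = len(binary)
    if m < 2 * min_flank:
        return 0.0, -1, 1.0
    total = binary.sum()

    def scan(vec: np.ndarray) -> tuple[float, int]:
        left = np.cumsum(vec)[:-1]
        k = np.arange(1, m)
        right = total - left
        n_left, n_right = k, m - k
        p_left = left / n_left
        p_right = right / n_right
        p_all = total / m
        with np.errstate(divide="ignore", invalid="ignore"):
            chi = (n_left * (p_left - p_all) ** 2 + n_right * (p_right - p_all) ** 2)
            denom = p_all * (1 - p_all)
            chi = np.where(denom > 0, chi / denom, 0.0)
        valid = (k >= min_flank) & (m - k >= min_flank)
        chi = np.where(valid, chi, -1.0)
        best = int(np.argmax(chi))
        return float(chi[best]), best

    stat, best = scan(binary)
    if stat <= 0:
        return 0.0, -1, 1.0
    exceed = 0
    for _ in range(permutations_n):
        perm_stat, _ = scan(rng.permutation(binary))
        if perm_stat >= stat:
            exceed += 1
    p = (exceed + 1) / (permutations_n + 1)
    return stat, best, p


def _polymorphic_columns(aln: Alignment) -> np.ndarray:
    """1-based columns with >= 2 distinct non-gap residues."""
    cols = []
    for pos in range(1, aln.n_sites + 1):
        column = {c for c in aln.column(pos) if c not in "-NX?"}
        if len(column) >= 2:
            cols.append(pos)
    return np.array(cols, dtype=np.int64)


def maxchi_scan(aln: Alignment, window: int | None = None,
                permutations: int = 1000, seed: int = 0,
                alpha: float = 0.05) -> list[BreakpointCandidate]:
    """Pairwise MaxChi over all sequence pairs; Bonferroni over pairs.

    ``window``, when given, restricts candidate breakpoints to have at
    least that many polymorphic sites on each flank.
    """
    if len(aln) < 3:
        raise ValueError("maxchi_scan needs >= 3 sequences")
    positions = _polymorphic_columns(aln)
    if len(positions) == 0:
        return []
    rng = np.random.default_rng(seed)
    names = aln.names
    seqs = {n: s for n, s in aln.records}
    pairs = list(combinations(names, 2))
    n_tests = len(pairs)
    min_flank = window if window is not None else 2
    out = []
    for a, b in pairs:
        sa, sb = seqs[a], seqs[b]
        binary = np.array([sa[p - 1] != sb[p - 1] for p in positions], dtype=float)
        if binary.sum() in (0, len(binary)):
            continue
        stat, best, p_raw = _max_chi_with_null(binary, positions, permutations,
                                               rng, min_flank=min_flank)
        if best < 0:
            continue
        p_adj = min(1.0, p_raw * n_tests)
        if p_adj <= alpha:
            bp = (int(positions[best]), int(positions[best + 1]))
            out.append(BreakpointCandidate(
                sequences=(a, b), breakpoint=bp, statistic=stat,
                p_value=p_adj, detector="maxchi"))
    return out


def triplet_scan(aln: Alignment, permutations: int = 1000, seed: int = 0,
                 alpha: float = 0.05) -> list[BreakpointCandidate]:
    """Triplet incongruence scan identifying recombinant and parents.

    For each candidate child and unordered parent pair, sites where the
    parents differ are coded by which parent the child matches; a
    breakpoint shows as a left/right contrast of that coding.
    """
    if len(aln) < 3:
        raise ValueError("triplet_scan needs >= 3 sequences")
    rng = np.random.default_rng(seed)
    names = aln.names
    seqs = {n: s for n, s in aln.records}
    triplets = [(c, p1, p2) for c in names
                for p1, p2 in combinations([n for n in names if n != c], 2)]
    n_tests = len(triplets)
    out = []
    for child, p1, p2 in triplets:
        sc, s1, s2 = seqs[child], seqs[p1], seqs[p2]
        informative, coding = [], []
        for pos in range(1, aln.n_sites + 1):
            c, a, b = sc[pos - 1], s1[pos - 1], s2[pos - 1]
            if "-" in (c, a, b) or a == b:
                continue
            if c == a:
                informative.append(pos)
                coding.append(0.0)
            elif c == b:
                informative.append(pos)
                coding.append(1.0)
        binary = np.array(coding)
        if len(binary) < 4 or binary.sum() in (0, len(binary)):
            continue
        positions = np.array(informative, dtype=np.int64)
        stat, best, p_raw = _max_chi_with_null(binary, positions, permutations, rng)
        if best < 0:
            continue
        p_adj = min(1.0, p_raw * n_tests)
        if p_adj <= alpha:
            bp = (int(positions[best]), int(positions[best + 1]))
            out.append(BreakpointCandidate(
                sequences=(child, p1, p2), breakpoint=bp, statistic=stat,
                p_value=p_adj, detector="triplet"))
    return out


def composition_scan(aln: Alignment) -> list[BreakpointCandidate]:
    """Exact single-crossover composition test across all triplets."""
    names = aln.names
    seqs = {n: s for n, s in aln.records}
    out = []
    for child in names:
        for p1, p2 in permutations([n for n in names if n != child], 2):
            if seqs[child] in (seqs[p1], seqs[p2]):
                continue
            k = find_single_crossover(seqs[child], seqs[p1], seqs[p2])
            if k is not None:
                out.append(BreakpointCandidate(
                    sequences=(child, p1, p2), breakpoint=(k, k + 1),
                    statistic=float("inf"), p_value=0.0, detector="composition"))
                break
        else:
            continue
    return out


def consensus_recombination_call(detector_outputs: dict[str, list[BreakpointCandidate]],
                                 min_detectors: int = 2,
                                 min_score: float = 60.0) -> list[RecombinationCall]:
    """Combine per-detector candidates into accepted calls.

    A call survives when >= ``min_detectors`` detectors implicate the
    same recombinant sequence and the consensus score (detector fraction
    times median permutation support, on a 0-100 scale) exceeds
    ``min_score``.
    """
    if len(detector_outputs) < 2:
        raise ValueError("consensus requires >= 2 detectors run")
    n_run = len(detector_outputs)
    per_seq: dict[str, list[BreakpointCandidate]] = {}
    for detector, cands in detector_outputs.items():
        for cand in cands:
            # pairwise detectors implicate both sequences; triplet-style
            # detectors implicate the child only
            implicated = cand.sequences if len(cand.sequences) == 2 else cand.sequences[:1]
            for name in implicated:
                per_seq.setdefault(name, []).append(cand)
    calls = []
    for name in sorted(per_seq):
        cands = per_seq[name]
        detectors = frozenset(c.detector for c in cands)
        if len(detectors) < min_detectors:
            continue
        support = float(np.median([1.0 - c.p_value for c in cands]))
        score = 100.0 * (len(detectors) / n_run) * support
        if score <= min_score:
            continue
        with_parents = [c for c in cands if len(c.sequences) == 3]
        if with_parents:
            best = min(with_parents, key=lambda c: c.p_value)
            parents = (best.sequences[1], best.sequences[2])
            bp = best.breakpoint
        else:
            best = min(cands, key=lambda c: c.p_value)
            other = [s for s in best.sequences if s != name]
            parents = (other[0], other[0]) if other else (name, name)
            bp = best.breakpoint
        calls.append(RecombinationCall(
            recombinant=name, parents=parents, breakpoint=bp,
            detectors=detectors, consensus_score=score,
            p_values={c.detector: c.p_value for c in cands}))
    return calls


def watterson_theta(n_sequences: int, n_segregating: int) -> float:
    """theta_W = S / a_n, per alignment."""
    if n_sequences < 2:
        raise ValueError("need >= 2 sequences")
    a_n = sum(1.0 / i for i in range(1, n_sequences))
    return n_segregating / a_n


def count_segregating(aln: Alignment) -> int:
    return len(_polymorphic_columns(aln))


@lru_cache(maxsize=8)
def _violation_curve(n: int, table_seed: int = 1234, reps: int = 400
                     ) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """P(four-gamete violation | C) on a grid of two-locus rho values C,
    estimated by two-locus coalescent simulation with one mutation per
    marginal tree.  Monotonised and clipped away from 0/1 for use as a
    Bernoulli likelihood."""
    import msprime

    c_grid = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 100.0)
    rng = np.random.default_rng(table_seed)
    probs = []
    for c in c_grid:
        hits = 0
        for rep in range(reps):
            ts = msprime.sim_ancestry(
                samples=n, ploidy=1, sequence_length=2,
                recombination_rate=c / 4.0 / 1.0,  # rho = 4*N*r*L with N=1/4 scaling
                population_size=0.5,
                random_seed=int(rng.integers(1, 2**31)),
            )
            trees = [t.copy() for t in ts.trees()]
            first, last = trees[0], trees[-1]
            sets = []
            for tree in (first, last):
                nodes = [u for u in tree.nodes()
                         if tree.parent(u) != -1 and tree.num_samples(u) < n]
                lengths = np.array([tree.branch_length(u) for u in nodes])
                if lengths.sum() == 0:
                    sets.append(frozenset())
                    continue
                u = nodes[rng.choice(len(nodes), p=lengths / lengths.sum())]
                sets.append(frozenset(tree.samples(u)))
            s1, s2 = sets
            if not s1 or not s2:
                continue
            gametes = {(int(i in s1), int(i in s2)) for i in range(n)}
            hits += len(gametes) == 4
        probs.append(hits / reps)
    probs = np.maximum.accumulate(np.clip(probs, 1e-4, 1 - 1e-4))
    return c_grid, tuple(float(p) for p in probs)


def _four_gamete_matrix(aln: Alignment, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairs of biallelic columns and their four-gamete indicator."""
    biallelic = []
    for pos in positions:
        col = [c for c in aln.column(int(pos)) if c not in "-NX?"]
        if len(set(col)) == 2 and len(col) == len(aln):
            biallelic.append(int(pos))
    viol, dists = [], []
    seqs = [s for _, s in aln.records]
    for p1, p2 in combinations(biallelic, 2):
        gametes = {(s[p1 - 1], s[p2 - 1]) for s in seqs}
        viol.append(len(gametes) == 4)
        dists.append(abs(p2 - p1))
    return np.array(viol, dtype=float), np.array(dists, dtype=float)


def estimate_rho_theta(aln: Alignment, grid_points: int = 51,
                       rho_max: float = 100.0) -> RecombEstimates:
    """Watterson theta plus grid composite-likelihood rho.

    The composite likelihood multiplies Bernoulli terms for the
    four-gamete-violation indicator of every biallelic column pair; the
    per-pair violation probability depends on rho scaled by the pair's
    fractional distance, interpolated from a simulated calibration curve.
    """
    if len(aln) < 4:
        raise ValueError("estimate_rho_theta needs >= 4 sequences")
    positions = _polymorphic_columns(aln)
    theta = watterson_theta(len(aln), len(positions))
    if len(positions) == 0:
        return RecombEstimates(rho=0.0, theta=0.0,
                               ratio_note="no segregating sites")
    viol, dists = _four_gamete_matrix(aln, positions)
    if len(viol) == 0:
        return RecombEstimates(rho=0.0, theta=theta,
                               ratio_note="low recombination (rho < theta)"
                               if theta > 0 else "no informative pairs")
    c_grid, p_grid = _violation_curve(len(aln))
    rho_grid = np.concatenate([[0.0], np.geomspace(0.1, rho_max, grid_points - 1)])
    L = aln.n_sites
    best_rho, best_ll = 0.0, -np.inf
    for rho in rho_grid:
        c_pair = rho * dists / L
        p_v = np.interp(c_pair, c_grid, p_grid)
        ll = float(np.sum(viol * np.log(p_v) + (1 - viol) * np.log1p(-p_v)))
        if ll > best_ll + 1e-12:
            best_ll, best_rho = ll, float(rho)
    note = ("low recombination (rho < theta)" if best_rho < theta
            else "rho >= theta")
    return RecombEstimates(rho=best_rho, theta=theta, ratio_note=note)
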