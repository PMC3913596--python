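"""Turn raw clone reads into validated variants.

Acceptance rules, in order:

1. forward/reverse strand agreement (IUPAC-compatible positions agree);
2. support: a sequence is a candidate if it was seen in >=2 clones of one
   individual, or in >=2 individuals (within or across species);
3. near-redundancy: a single-clone sequence <3 bp from a multi-clone
   sequence of the same PCR product is discarded;
4. within-individual chimeras: a sequence exactly equal to a single
   crossover of two other sequences of the same individual is discarded.

Every input ends up either supporting a variant or in exactly one
RejectionRecord, and all outputs are invariant to input order.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .codons import IUPAC_NUC
from .seq_model import CloneRead, ConsensusSequence, SpeciesMeta, ValidatedVariant

REJECTION_RULES = (
    "strand_mismatch",
    "singleton_unsupported",
    "near_redundant_lt3bp",
    "within_individual_chimera",
)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn-",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RejectionRecord:
    seq: str
    rule: str
    evidence: str = ""

    def __post_init__(self):
        if self.rule not in REJECTION_RULES:
            raise ValueError(f"unknown rejection rule {self.rule!r}")


@dataclass
class Candidate:
    """A collapsed sequence with its support evidence."""

    seq: str
    species: SpeciesMeta
    n_clones: int                      # max clone count within one individual
    n_individuals: int                 # distinct individuals (any species)
    individuals: frozenset = frozenset()
    clones_per_pcr: dict = field(default_factory=dict)  # pcr_id -> clone count
    species_by_prefix: dict = field(default_factory=dict)  # prefix -> SpeciesMeta


def _resolve_column(a: str, b: str) -> str | None:
    """Most specific base compatible with both IUPAC codes, or None."""
    sa, sb = IUPAC_NUC.get(a.upper()), IUPAC_NUC.get(b.upper())
    if sa is None or sb is None:
        return None
    common = sa & sb
    if not common:
        return None
    for code, bases in IUPAC_NUC.items():
        if bases == common:
            return code
    return None


def build_consensus(forward: CloneRead, reverse: CloneRead
                    ) -> ConsensusSequence | RejectionRecord:
    """Merge a forward/reverse read pair of one clone insert.

    The reverse read is reverse-complemented first.  A consensus is
    returned only when every overlapping position is IUPAC-compatible;
    one incompatibility rejects the clone with ``strand_mismatch``.
    """
    if forward.direction != "forward" or reverse.direction != "reverse":
        raise ValueError("build_consensus expects one forward and one reverse read")
    rc = reverse_complement(reverse.seq)
    if len(rc) != len(forward.seq):
        raise ValueError(
            f"reads of clone {forward.read_id} do not fully overlap "
            f"({len(forward.seq)} vs {len(rc)} nt)"
        )
    out = []
    for pos, (a, b) in enumerate(zip(forward.seq, rc), start=1):
        if a == "-" and b == "-":
            out.append("-")
            continue
        resolved = _resolve_column(a, b)
        if resolved is None:
            return RejectionRecord(
                seq=forward.seq, rule="strand_mismatch",
                evidence=f"position {pos}: {a} vs {b} ({forward.read_id})",
            )
        out.append(resolved)
    return ConsensusSequence(
        read_id=forward.read_id, species=forward.species,
        individual_id=forward.individual_id, pcr_id=forward.pcr_id,
        seq="".join(out), exon_target=forward.exon_target, n_reads=2,
    )


def pair_and_build_consensus(reads: list[CloneRead]
                             ) -> tuple[list[ConsensusSequence], list[RejectionRecord]]:
    """Pair reads by clone id and strand-merge each pair.

    Clone identity is the read id with a trailing ``/F`` or ``/R``
    stripped (ids without the suffix are taken as already merged).
    """
    groups: dict[str, dict[str, CloneRead]] = defaultdict(dict)
    consensuses, rejections = [], []
    for r in reads:
        if r.read_id.endswith(("/F", "/R")):
            groups[r.read_id[:-2]][r.direction] = r
        else:
            consensuses.append(ConsensusSequence(
                read_id=r.read_id, species=r.species, individual_id=r.individual_id,
                pcr_id=r.pcr_id, seq=r.seq, exon_target=r.exon_target, n_reads=1,
            ))
    for clone_id in sorted(groups):
        pair = groups[clone_id]
        if set(pair) != {"forward", "reverse"}:
            rejections.append(RejectionRecord(
                seq=next(iter(pair.values())).seq, rule="strand_mismatch",
                evidence=f"clone {clone_id}: missing mate read",
            ))
            continue
        result = build_consensus(pair["forward"], pair["reverse"])
        if isinstance(result, RejectionRecord):
            rejections.append(result)
        else:
            consensuses.append(result)
    return consensuses, rejections


def collapse_and_screen(consensuses: list[ConsensusSequence]
                        ) -> tuple[list[Candidate], list[RejectionRecord]]:
    """Collapse identical sequences and apply the support rule.

    Accept iff seen in >=2 clones of one individual and/or in >=2
    individuals (within or across species); everything else is a
    ``singleton_unsupported`` rejection.
    """
    by_seq: dict[str, list[ConsensusSequence]] = defaultdict(list)
    for c in consensuses:
        by_seq[c.seq].append(c)
    candidates, rejections = [], []
    for seq in sorted(by_seq):
        group = sorted(by_seq[seq],
                       key=lambda c: (c.species.gene_prefix, c.individual_id, c.read_id))
        individuals = frozenset((c.species.gene_prefix, c.individual_id) for c in group)
        per_individual = defaultdict(int)
        per_pcr = defaultdict(int)
        for c in group:
            per_individual[(c.species.gene_prefix, c.individual_id)] += 1
            per_pcr[c.pcr_id] += 1
        max_clones = max(per_individual.values())
        if max_clones >= 2 or len(individuals) >= 2:
            # cross-species identical sequences become per-species
            # variants downstream; keep every observed SpeciesMeta.
            candidates.append(Candidate(
                seq=seq, species=group[0].species, n_clones=max_clones,
                n_individuals=len(individuals), individuals=individuals,
                clones_per_pcr=dict(per_pcr),
                species_by_prefix={c.species.gene_prefix: c.species for c in group},
            ))
        else:
            rejections.append(RejectionRecord(
                seq=seq, rule="singleton_unsupported",
                evidence=f"single clone {group[0].read_id}",
            ))
    return candidates, rejections


def hamming(a: str, b: str) -> int:
    """Hamming distance on equal-length strings; gaps count as differences."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def filter_near_redundant(candidates: list[Candidate], threshold_bp: int = 3
                          ) -> tuple[list[Candidate], list[RejectionRecord]]:
    """Discard single-clone sequences < ``threshold_bp`` from a redundant
    (multi-clone) sequence of the same PCR product."""
    by_pcr: dict[str, list[Candidate]] = defaultdict(list)
    for cand in candidates:
        for pcr_id, n in cand.clones_per_pcr.items():
            by_pcr[pcr_id].append(cand)
    doomed: dict[str, RejectionRecord] = {}
    for pcr_id, members in by_pcr.items():
        redundant = [c for c in members if c.clones_per_pcr.get(pcr_id, 0) >= 2]
        unique = [c for c in members if c.clones_per_pcr.get(pcr_id, 0) == 1]
        for u in unique:
            for r in redundant:
                if len(u.seq) != len(r.seq):
                    continue
                d = hamming(u.seq, r.seq)
                if 0 < d < threshold_bp:
                    doomed[u.seq] = RejectionRecord(
                        seq=u.seq, rule="near_redundant_lt3bp",
                        evidence=f"{d} bp from redundant sequence in {pcr_id}",
                    )
                    break
    kept = [c for c in candidates if c.seq not in doomed]
    return kept, sorted(doomed.values(), key=lambda r: r.seq)


def find_single_crossover(child: str, p1: str, p2: str) -> int | None:
    """Smallest k (1 <= k < L) with child == p1[:k] + p2[k:], else None."""
    L = len(child)
    if len(p1) != L or len(p2) != L:
        return None
    # longest common prefix with p1 / suffix with p2
    pre = 0
    while pre < L and child[pre] == p1[pre]:
        pre += 1
    suf = 0
    while suf < L and child[L - 1 - suf] == p2[L - 1 - suf]:
        suf += 1
    if pre + suf < L:
        return None
    k_lo, k_hi = max(1, L - suf), min(pre, L - 1)
    return k_lo if k_lo <= k_hi else None


def detect_within_individual_chimeras(variants: dict[str, str]
                                      ) -> dict[str, tuple[str, str, int]]:
    """Flag sequences composed of one exact crossover of two other
    sequences of the same individual.

    ``variants`` maps label -> sequence; returns flagged label ->
    (parent1, parent2, breakpoint).  Needs >=3 sequences to flag anything.
    """
    labels = sorted(variants)
    if len(labels) < 3:
        return {}
    flags = {}
    for child in labels:
        cseq = variants[child]
        found = None
        for a in labels:
            if a == child:
                continue
            for b in labels:
                if b == child or b == a:
                    continue
                k = find_single_crossover(cseq, variants[a], variants[b])
                if k is not None and cseq != variants[a] and cseq != variants[b]:
                    found = (a, b, k)
                    break
            if found:
                break
        if found:
            flags[child] = found
    return flags


def screen_chimeras(candidates: list[Candidate]
                    ) -> tuple[list[Candidate], list[RejectionRecord]]:
    """Run the exact-crossover screen per individual across candidates."""
    by_individual: dict[tuple, list[Candidate]] = defaultdict(list)
    for cand in candidates:
        for indiv in cand.individuals:
            by_individual[indiv].append(cand)
    doomed: dict[str, RejectionRecord] = {}
    for indiv, members in sorted(by_individual.items()):
        if len(members) < 3:
            continue
        seqs = {f"c{i}": m.seq for i, m in enumerate(sorted(members, key=lambda c: c.seq))}
        names = {f"c{i}": m for i, m in enumerate(sorted(members, key=lambda c: c.seq))}
        for label, (pa, pb, k) in detect_within_individual_chimeras(seqs).items():
            seq = seqs[label]
            if seq not in doomed:
                doomed[seq] = RejectionRecord(
                    seq=seq, rule="within_individual_chimera",
                    evidence=f"crossover at {k} between sequences of individual "
                             f"{indiv[0]}:{indiv[1]}",
                )
    kept = [c for c in candidates if c.seq not in doomed]
    return kept, sorted(doomed.values(), key=lambda r: r.seq)


def assign_names(candidates: list[Candidate], chain: str,
                 taxonomy: dict[str, SpeciesMeta] | None = None
                 ) -> list[ValidatedVariant]:
    """Name accepted variants ``<Prefix>-<DA|DB><nn>`` per species.

    Canonical order inside a species: descending clone support, then
    lexicographic sequence — deterministic under input permutation.  A
    sequence seen in several species yields one named variant per species.
    """
    if chain not in ("DA", "DB"):
        raise ValueError("chain must be 'DA' or 'DB'")
    per_species: dict[str, dict[str, Candidate]] = defaultdict(dict)
    for cand in candidates:
        for prefix in sorted({sp for sp, _ in cand.individuals}):
            if cand.seq in per_species[prefix]:
                raise ValueError(f"duplicate sequence within species {prefix}")
            per_species[prefix][cand.seq] = cand
    out = []
    for prefix in sorted(per_species):
        members = sorted(per_species[prefix].values(),
                         key=lambda c: (-c.n_clones, c.seq))
        if taxonomy and prefix in taxonomy:
            meta = taxonomy[prefix]
        else:
            meta = members[0].species_by_prefix.get(prefix, members[0].species)
        for i, cand in enumerate(members, start=1):
            out.append(ValidatedVariant(
                name=f"{prefix}-{chain}{i:02d}", seq=cand.seq,
                n_clones=cand.n_clones, n_individuals=cand.n_individuals,
                species=meta,
            ))
    return out


def validate_reads(reads: list[CloneRead], chain: str = "DB",
                   redundancy_bp: int = 3,
                   taxonomy: dict[str, SpeciesMeta] | None = None
                   ) -> tuple[list[ValidatedVariant], list[RejectionRecord]]:
    """Full validation pipeline: consensus -> support -> <3bp -> chimera -> names."""
    consensuses, rejections = pair_and_build_consensus(reads)
    candidates, rej2 = collapse_and_screen(consensuses)
    candidates, rej3 = filter_near_redundant(candidates, threshold_bp=redundancy_bp)
    candidates, rej4 = screen_chimeras(candidates)
    variants = assign_names(candidates, chain=chain, taxonomy=taxonomy)
    return variants, rejections + rej2 + rej3 + rej4
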