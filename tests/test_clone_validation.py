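import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crocmhc.clone_validation import (Candidate, RejectionRecord,
                                      build_consensus, collapse_and_screen,
                                      detect_within_individual_chimeras,
                                      filter_near_redundant,
                                      find_single_crossover, hamming,
                                      pair_and_build_consensus,
                                      reverse_complement, validate_reads,
                                      assign_names)
from crocmhc.seq_model import ConsensusSequence

from .conftest import make_read

SEQ = "ATGAAACCCGGGTTTAAACCCGGGTTTAAA"


def _pair(species, seq, read_id="c1", **kw):
    fwd = make_read(species, seq, read_id=read_id + "/F", direction="forward", **kw)
    rev = make_read(species, reverse_complement(seq), read_id=read_id + "/R",
                    direction="reverse", **kw)
    return fwd, rev


class TestBuildConsensus:
    def test_identical_strands_give_forward_sequence(self, species_a):
        fwd, rev = _pair(species_a, SEQ)
        result = build_consensus(fwd, rev)
        assert isinstance(result, ConsensusSequence)
        assert result.seq == SEQ

    def test_internal_disagreement_rejected(self, species_a):
        fwd, rev = _pair(species_a, SEQ)
        bad = rev.seq[:5] + ("C" if rev.seq[5] != "C" else "G") + rev.seq[6:]
        rev = make_read(species_a, bad, read_id="c1/R", direction="reverse")
        result = build_consensus(fwd, rev)
        assert isinstance(result, RejectionRecord)
        assert result.rule == "strand_mismatch"

    def test_iupac_compatible_positions_resolve(self, species_a):
        # forward has R (A/G) where reverse-complemented strand has A
        seq_f = "R" + SEQ[1:]
        seq_r_template = "A" + SEQ[1:]
        fwd = make_read(species_a, seq_f, read_id="c1/F")
        rev = make_read(species_a, reverse_complement(seq_r_template),
                        read_id="c1/R", direction="reverse")
        result = build_consensus(fwd, rev)
        assert isinstance(result, ConsensusSequence)
        assert result.seq == seq_r_template  # 'A' is the specific resolution

    def test_iupac_resolution_matches_set_intersection_oracle(self, species_a):
        # oracle: brute-force IUPAC sets
        from crocmhc.codons import IUPAC_NUC

        for a in "ACGTRYSWKMN":
            for b in "ACGT":
                fwd = make_read(species_a, a + SEQ[1:], read_id="c/F")
                rev = make_read(species_a, reverse_complement(b + SEQ[1:]),
                                read_id="c/R", direction="reverse")
                result = build_consensus(fwd, rev)
                expected = IUPAC_NUC[a] & IUPAC_NUC[b]
                if expected:
                    assert isinstance(result, ConsensusSequence)
                    assert IUPAC_NUC[result.seq[0]] == expected
                else:
                    assert isinstance(result, RejectionRecord)

    def test_non_overlapping_reads_error(self, species_a):
        fwd = make_read(species_a, SEQ, read_id="c1/F")
        rev = make_read(species_a, reverse_complement(SEQ[:10]),
                        read_id="c1/R", direction="reverse")
        with pytest.raises(ValueError, match="overlap"):
            build_consensus(fwd, rev)


def _cons(species, seq, individual="i1", pcr="p1", read_id="r"):
    return ConsensusSequence(read_id=read_id, species=species,
                             individual_id=individual, pcr_id=pcr, seq=seq,
                             exon_target="IIb_ex3")


class TestCollapseAndScreen:
    def test_three_clones_one_individual_accepted(self, species_a):
        group = [_cons(species_a, SEQ, read_id=f"r{i}") for i in range(3)]
        cands, rej = collapse_and_screen(group)
        assert len(cands) == 1 and not rej
        assert cands[0].n_clones == 3

    def test_two_individuals_across_species_accepted(self, species_a, species_b):
        group = [_cons(species_a, SEQ, individual="i1", read_id="r1"),
                 _cons(species_b, SEQ, individual="i9", read_id="r2")]
        cands, rej = collapse_and_screen(group)
        assert len(cands) == 1 and not rej
        assert cands[0].n_individuals == 2

    def test_lone_singleton_rejected(self, species_a):
        cands, rej = collapse_and_screen([_cons(species_a, SEQ)])
        assert not cands
        assert [r.rule for r in rej] == ["singleton_unsupported"]


class TestNearRedundant:
    def _candidate(self, species, seq, clones_in_pcr, pcr="p1"):
        return Candidate(seq=seq, species=species, n_clones=clones_in_pcr,
                         n_individuals=1,
                         individuals=frozenset({(species.gene_prefix, "i1")}),
                         clones_per_pcr={pcr: clones_in_pcr})

    def test_singleton_2bp_from_redundant_discarded(self, species_a):
        redundant = self._candidate(species_a, SEQ, 4)
        near = self._candidate(species_a, "TT" + SEQ[2:], 1)
        kept, rej = filter_near_redundant([redundant, near])
        assert kept == [redundant]
        assert rej[0].rule == "near_redundant_lt3bp"

    def test_singleton_exactly_3bp_retained(self, species_a):
        redundant = self._candidate(species_a, SEQ, 4)
        far = self._candidate(species_a, "CCC" + SEQ[3:], 1)  # hamming 3
        kept, rej = filter_near_redundant([redundant, far])
        assert len(kept) == 2 and not rej

    def test_two_singletons_without_redundant_partner_survive(self, species_a):
        s1 = self._candidate(species_a, SEQ, 1)
        s2 = self._candidate(species_a, "T" + SEQ[1:], 1)
        kept, rej = filter_near_redundant([s1, s2])
        assert len(kept) == 2 and not rej

    def test_matches_brute_force_rule_oracle(self, species_a, rng):
        # oracle: direct restatement over all (unique, redundant) pairs
        base = "".join(rng.choice(list("ACGT"), 60))
        cands = []
        for k in range(8):
            seq = list(base)
            for pos in rng.choice(60, size=rng.integers(0, 5), replace=False):
                seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
            cands.append(self._candidate(species_a, "".join(seq),
                                         int(rng.integers(1, 4))))
        kept, rej = filter_near_redundant(cands)
        rejected = {r.seq for r in rej}
        for c in cands:
            doomed = any(
                c.clones_per_pcr.get("p1", 0) == 1
                and r.clones_per_pcr.get("p1", 0) >= 2
                and c.seq != r.seq
                and hamming(c.seq, r.seq) < 3
                for r in cands)
            assert (c.seq in rejected) == doomed


class TestChimeraDetection:
    def test_constructed_chimera_flagged(self):
        v1 = "A" * 120 + "C" * 140
        v2 = "G" * 120 + "T" * 140
        v3 = v1[:120] + v2[120:]
        flags = detect_within_individual_chimeras({"v1": v1, "v2": v2, "v3": v3})
        assert set(flags) == {"v3"}
        parent1, parent2, k = flags["v3"]
        assert {parent1, parent2} == {"v1", "v2"}

    def test_two_variants_cannot_flag(self):
        assert detect_within_individual_chimeras({"a": "AAAA", "b": "TTTT"}) == {}

    def test_random_triples_match_exhaustive_breakpoint_oracle(self, rng):
        for _ in range(50):
            seqs = {f"v{i}": "".join(rng.choice(list("ACGT"), 30))
                    for i in range(3)}
            flags = detect_within_individual_chimeras(seqs)
            for child, others in (("v0", ("v1", "v2")), ("v1", ("v0", "v2")),
                                  ("v2", ("v0", "v1"))):
                expected = False
                c = seqs[child]
                for a in ("v0", "v1", "v2"):
                    for b in ("v0", "v1", "v2"):
                        if child in (a, b) or a == b:
                            continue
                        for k in range(1, 30):
                            if (c == seqs[a][:k] + seqs[b][k:]
                                    and c != seqs[a] and c != seqs[b]):
                                expected = True
                assert (child in flags) == expected

    def test_find_single_crossover_exhaustive(self, rng):
        p1 = "".join(rng.choice(list("ACGT"), 40))
        p2 = "".join(rng.choice(list("ACGT"), 40))
        for k in (1, 10, 39):
            child = p1[:k] + p2[k:]
            found = find_single_crossover(child, p1, p2)
            assert found is not None
            assert child == p1[:found] + p2[found:]


class TestAssignNames:
    def _cand(self, species, seq, n_clones):
        return Candidate(seq=seq, species=species, n_clones=n_clones,
                         n_individuals=1,
                         individuals=frozenset({(species.gene_prefix, "i1")}),
                         clones_per_pcr={"p1": n_clones},
                         species_by_prefix={species.gene_prefix: species})

    def test_sequential_names(self, species_a):
        cands = [self._cand(species_a, SEQ, 3),
                 self._cand(species_a, "T" + SEQ[1:], 2)]
        named = assign_names(cands, chain="DB")
        assert [v.name for v in named] == ["Crpo-DB01", "Crpo-DB02"]

    def test_empty_input(self):
        assert assign_names([], chain="DA") == []

    def test_permutation_invariance(self, species_a, species_b, rng):
        cands = [self._cand(species_a, SEQ, 3),
                 self._cand(species_a, "T" + SEQ[1:], 2),
                 self._cand(species_b, "G" + SEQ[1:], 5)]
        baseline = {(v.name, v.seq) for v in assign_names(cands, chain="DB")}
        for _ in range(5):
            shuffled = list(cands)
            rng.shuffle(shuffled)
            assert {(v.name, v.seq)
                    for v in assign_names(shuffled, chain="DB")} == baseline

    def test_duplicate_sequence_within_species_errors(self, species_a):
        cands = [self._cand(species_a, SEQ, 3), self._cand(species_a, SEQ, 1)]
        with pytest.raises(ValueError, match="duplicate"):
            assign_names(cands, chain="DB")


class TestPipelineProperties:
    def test_partition_every_read_accounted(self, species_a, species_b, rng):
        reads = []
        for i, sp in enumerate((species_a, species_b)):
            for indiv in ("i1", "i2"):
                for c in range(3):
                    seq = SEQ if c < 2 else "".join(rng.choice(list("ACGT"), 30))
                    reads.extend(_pair(sp, seq, read_id=f"{sp.gene_prefix}{indiv}c{c}",
                                       individual=indiv,
                                       pcr=f"{sp.gene_prefix}-{indiv}"))
        variants, rejections = validate_reads(reads)
        validated_seqs = {v.seq for v in variants}
        rejected_seqs = {r.seq for r in rejections}
        consensuses, _ = pair_and_build_consensus(reads)
        for cons in consensuses:
            assert (cons.seq in validated_seqs) or (cons.seq in rejected_seqs)

    def test_order_independence(self, species_a, species_b, rng):
        reads = []
        for sp in (species_a, species_b):
            for indiv in ("i1", "i2"):
                for c in range(4):
                    seq = SEQ if c % 2 == 0 else "G" * 5 + SEQ[5:]
                    reads.extend(_pair(sp, seq, read_id=f"{sp.gene_prefix}{indiv}c{c}",
                                       individual=indiv,
                                       pcr=f"{sp.gene_prefix}-{indiv}"))
        base_v, base_r = validate_reads(reads)
        for _ in range(3):
            shuffled = list(reads)
            rng.shuffle(shuffled)
            v, r = validate_reads(shuffled)
            assert {(x.name, x.seq) for x in v} == {(x.name, x.seq) for x in base_v}
            assert {(x.seq, x.rule) for x in r} == {(x.seq, x.rule) for x in base_r}


@settings(max_examples=50, deadline=None)
@given(st.text(alphabet="ACGTRYSWKMN-", min_size=1, max_size=50))
def test_reverse_complement_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


@settings(max_examples=50, deadline=None)
@given(st.text(alphabet="ACGT-", min_size=1, max_size=40),
       st.text(alphabet="ACGT-", min_size=1, max_size=40))
def test_hamming_symmetric(a, b):
    if len(a) != len(b):
        with pytest.raises(ValueError):
            hamming(a, b)
    else:
        assert hamming(a, b) == hamming(b, a)
        assert hamming(a, a) == 0
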