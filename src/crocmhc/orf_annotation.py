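"""Translate exon amplicons and classify functional vs non-functional.

A sequence is non-functional when it carries a premature stop codon, a
frameshifting (length % 3 != 0) indel relative to a functional reference
of the same exon target, or lacks a required conserved residue (the
disulfide-bridge cysteines and any configured termini-binding sites).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import Align

from .codons import translate_codon

_DATA_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class ConservedSiteSpec:
    """Required residues for one exon target; positions are 1-based aa sites."""

    exon_target: str
    cys_pair: tuple[int, int] | None = None
    termini_binding_sites: tuple[tuple[int, str], ...] = ()
    cd4_region: tuple[int, int] | None = None
    phase: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, exon_target: str) -> "ConservedSiteSpec":
        spec = yaml.safe_load(Path(path).read_text())[exon_target]
        cys = spec.get("cys_pair")
        termini = tuple((int(p), str(r)) for p, r in spec.get("termini_binding_sites", []))
        cd4 = spec.get("cd4_region")
        return cls(
            exon_target=exon_target,
            cys_pair=tuple(cys) if cys else None,
            termini_binding_sites=termini,
            cd4_region=tuple(cd4) if cd4 else None,
            phase=int(spec.get("phase", 0)),
        )


def default_site_spec(exon_target: str) -> ConservedSiteSpec:
    return ConservedSiteSpec.from_yaml(_DATA_DIR / "conserved_sites.yaml", exon_target)


@dataclass(frozen=True)
class FunctionalityCall:
    functionality: str  # functional | non_functional
    reasons: tuple[str, ...] = ()

    def __post_init__(self):
        if self.functionality == "functional" and self.reasons:
            raise ValueError("functional call cannot carry reasons")


def translate_exon(nt_seq: str, phase: int = 0) -> str:
    """Standard-code translation from ``phase`` (0-2); trailing partial
    codon dropped; stops '*', any-ambiguous codons 'X'."""
    if not nt_seq:
        raise ValueError("empty sequence")
    if phase not in (0, 1, 2):
        raise ValueError("phase must be 0, 1 or 2")
    seq = nt_seq.upper().replace("U", "T").replace("-", "")
    aa = []
    for start in range(phase, len(seq) - 2, 3):
        aa.append(translate_codon(seq[start : start + 3]))
    return "".join(aa)


def _pairwise_align(query: str, reference: str):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -1
    return aligner.align(reference, query)[0]


def detect_frameshift(nt_seq: str, reference: str, phase: int = 0
                      ) -> list[tuple[str, int]]:
    """Indel events vs a functional reference, in aa-site coordinates.

    Aligns ``nt_seq`` against ``reference`` and reports every gap whose
    length is not divisible by 3 as ``("frameshift_deletion"|"frameshift_insertion",
    aa_site)`` where the aa site is the reference codon containing the
    gap's first base.
    """
    if not reference:
        raise ValueError("a functional reference sequence of the same exon "
                         "target is required for frameshift detection")
    aln = _pairwise_align(nt_seq.replace("-", ""), reference.replace("-", ""))
    ref_aln, query_aln = str(aln[0]), str(aln[1])
    events = []
    ref_pos = 0  # 1-based position of last consumed reference base
    i = 0
    while i < len(ref_aln):
        if query_aln[i] == "-":  # deletion in query
            start_ref = ref_pos + 1
            length = 0
            while i < len(ref_aln) and query_aln[i] == "-":
                length += 1
                ref_pos += 1
                i += 1
            if length % 3:
                events.append(("frameshift_deletion", (start_ref - 1 - phase) // 3 + 1))
        elif ref_aln[i] == "-":  # insertion in query
            start_ref = max(ref_pos, 1)
            length = 0
            while i < len(ref_aln) and ref_aln[i] == "-":
                length += 1
                i += 1
            if length % 3:
                events.append(("frameshift_insertion", (start_ref - 1 - phase) // 3 + 1))
        else:
            ref_pos += 1
            i += 1
    return events


def classify_functionality(aa_seq: str,
                           indel_events: list[tuple[str, int]] | None = None,
                           sites: ConservedSiteSpec | None = None
                           ) -> FunctionalityCall:
    """Non-functional iff a stop, a frameshift event, or a missing
    required conserved residue; reasons enumerate every trigger."""
    reasons: list[str] = []
    for pos, aa in enumerate(aa_seq, start=1):
        if aa == "*":
            reasons.append(f"stop_codon@{pos}")
    for kind, site in indel_events or []:
        reasons.append(f"{kind}@{site}")
    if sites is not None:
        required = list(sites.termini_binding_sites)
        if sites.cys_pair:
            required += [(p, "C") for p in sites.cys_pair]
        for pos, residue in sorted(required):
            if pos < 1 or pos > len(aa_seq) or aa_seq[pos - 1] != residue:
                reasons.append(f"missing_conserved@{pos}")
    if reasons:
        return FunctionalityCall("non_functional", tuple(dict.fromkeys(reasons)))
    return FunctionalityCall("functional")


def annotate_variants(variants, exon_target: str,
                      sites: ConservedSiteSpec | None = None,
                      reference: str | None = None):
    """Classify a list of ValidatedVariants; returns updated copies.

    The reference for frameshift detection defaults to the longest
    variant that translates without stops.
    """
    from dataclasses import replace

    if sites is None:
        sites = default_site_spec(exon_target)
    phase = sites.phase
    if reference is None:
        clean = [v for v in variants if "*" not in translate_exon(v.seq, phase)]
        reference = max((v.seq for v in clean), key=len, default=None)
    out = []
    ref_clean = reference.replace("-", "") if reference else None
    for v in variants:
        aa = translate_exon(v.seq, phase)
        events = []
        seq_clean = v.seq.replace("-", "")
        # frameshifts of interest are length-changing deletions; aligning
        # equal-length divergent sequences would only produce spurious
        # compensating gaps
        if ref_clean and len(seq_clean) != len(ref_clean):
            events = [e for e in detect_frameshift(v.seq, reference, phase)
                      if e[0] == "frameshift_deletion"]
        call = classify_functionality(aa, events, sites)
        out.append(replace(v, functionality=call.functionality, reasons=call.reasons))
    return out
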