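# Study sequence inputs (user-supplied)

`scripts/acceptance.py` recomputes its paper-comparable targets from the
study's deposited sequences. They are **not** bundled here (and cannot be
fetched in an offline environment); fetch them from GenBank yourself and
lay them out as plain-text FASTA in this directory:

| file | contents |
|---|---|
| `class2_alpha_ex2.fasta` | class II α exon 2 study variants, record ids `<Prefix>-DAnn` |
| `class2_alpha_ex3.fasta` | class II α exon 3 study variants, ids `<Prefix>-DAnn` |
| `class2_beta_ex3.fasta`  | class II β exon 3 study variants, ids `<Prefix>-DBnn` |
| `alpha_selection.fasta`  | α exon 2+3 codon alignment used for selection tests |
| `beta_ex2_selection.fasta` | β exon 2 codon alignment used for selection tests |
| `pbr_beta_ex2.txt` | 1-based PBR codon columns of that alignment, whitespace-separated |

Relevant accessions: GU126804–GU126967; AF256650, AF256651, AF256652,
AF277661; FJ886734–FJ886741; AY491421–AY491430.

Record ids must carry the species gene prefix (four letters, e.g. `Crpo`)
so sequences can be grouped by species. Alignment files must be gapped to
equal length with the gap character `-`; unknown characters may be `N`.

When a file is missing, the corresponding target is simply omitted from
the acceptance report.
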