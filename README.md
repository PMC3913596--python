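# crocmhc

Analysis toolkit for clonal MHC amplicon data across a multi-species
panel: clone-variant validation, pseudogene annotation, trans-species
polymorphism (TSP) detection, site-wise dN/dS selection inference,
recombination screening, distance phylogenetics with clade diagnostics,
and a clone-sampling coverage model — plus a synthetic-data generator
with full ground truth, so every analysis is testable end-to-end without
external data.

## Modules

| module | what it does |
|---|---|
| `crocmhc.seq_model` | domain types; FASTA/TSV/Newick readers and writers |
| `crocmhc.clone_validation` | strand consensus, support screening, <3 bp redundancy filter, within-individual single-crossover chimera removal, Klein-style variant naming |
| `crocmhc.orf_annotation` | exon translation, frameshift detection, functional / non-functional classification against a conserved-site table |
| `crocmhc.tsp_detection` | TSP clusters from identical translated sequences in ≥2 species; genus tally matrix |
| `crocmhc.diversity` | pairwise differences; NG86 synonymous/nonsynonymous counting with Jukes–Cantor correction |
| `crocmhc.selection` | per-site ω posteriors from a PAC-style composite-likelihood MCMC (NY98 rates, independent ω per codon, grid Gibbs); codon-based Z-tests with site bootstrap |
| `crocmhc.recombination` | MaxChi, triplet-incongruence and exact-composition detectors with a ≥2-detector / score>60 consensus rule; Watterson θ and grid composite-likelihood ρ |
| `crocmhc.phylo` | JC69/K80/HKY85/TN93 (±Γ) model selection by BIC/AIC, model-corrected distances, deterministic NJ, column bootstrap, RELL-based expected likelihood weights, clade-diagnostic fixed differences |
| `crocmhc.coverage` | probability that *n* sequenced clones capture all *m* variants of an individual (inclusion–exclusion), expected detected fraction, planning helper |
| `crocmhc.simulate` | two-family species tree, NY98 codon evolution with elevated ω at PBR columns, trans-species allele retention, pseudogenising stops/deletions, PCR errors and chimeric clones; truth tables |
| `crocmhc.pipeline` | `run_all` orchestration with per-stage seeds and a hash manifest |

## CLI

```bash
crocmhc simulate --seed 42 --out simdir/
crocmhc validate --reads simdir/reads.fasta --meta simdir/meta.tsv \
    --taxonomy simdir/taxonomy.tsv --out valdir/
crocmhc annotate --variants valdir/variants.fasta --exon IIb_ex3
crocmhc tsp --variants IIb_ex3=valdir/variants.fasta --taxonomy simdir/taxonomy.tsv
crocmhc diversity --aln aln.fasta --codon
crocmhc selection --aln codon.fasta --runs 2 --seed 17
crocmhc recomb --aln aln.fasta --permutations 10000 --seed 7
crocmhc phylo --aln aln.fasta --model auto --bootstrap 10000 --seed 3
crocmhc coverage --m 4 --n 6
crocmhc run --config run.yaml --out outdir/
```

## Notes

- All coordinates (alignment columns, amino-acid sites) are 1-based.
- The ω sampler is a desk-scale reimplementation of the PAC idea:
  pairwise NY98 transition terms along random sequence orderings, with
  per-site ω Gibbs-sampled on a log-spaced grid. It targets qualitative
  agreement with full omegaMap-style samplers, not numeric identity.
- Conserved-site and PBR tables ship as editable YAML under
  `src/crocmhc/data/`.
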