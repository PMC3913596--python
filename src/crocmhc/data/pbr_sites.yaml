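# Peptide-binding-region (PBR) column maps, 1-based amino-acid positions
# in HLA class II domain numbering (Bondinas-style crystallographic
# pocket residues).  These are defaults for annotation; analyses accept
# an explicit site list, which takes precedence.  The neighbourhood rule
# (a site within `neighbourhood` columns of a PBR site counts as
# PBR-adjacent) is applied downstream.

beta_chain:
  sites: [9, 11, 13, 26, 28, 30, 32, 37, 38, 47, 56, 57, 60, 61, 65, 67,
          70, 71, 74, 78, 81, 82, 85, 86, 89, 90]
alpha_chain:
  sites: [9, 11, 22, 24, 31, 43, 52, 53, 54, 55, 58, 61, 62, 65, 66, 68,
          69, 72, 73, 76]
neighbourhood: 2
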