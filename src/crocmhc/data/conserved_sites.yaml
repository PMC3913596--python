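# Conserved-residue requirements per exon target (1-based aa sites).
#
# cys_pair: the disulfide-bridge cysteines of the membrane-proximal
#   domain; both positions must carry 'C' in a functional sequence.
# termini_binding_sites: [site, residue] pairs for antigen N/C-termini
#   binding positions (Kaufman-style scheme).  Shipped empty so that the
#   requirements applied are exactly what the user configures; audit and
#   extend per your alignment's numbering.
# cd4_region: informational interval, not used for classification.
# phase: reading phase of the amplicon (0-2).

IIa_ex2:
  cys_pair: null
  termini_binding_sites: []
  cd4_region: null
  phase: 0

IIa_ex3:
  cys_pair: null
  termini_binding_sites: []
  cd4_region: null
  phase: 0

IIb_ex3:
  cys_pair: [24, 80]
  termini_binding_sites: []
  cd4_region: [42, 66]
  phase: 0
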