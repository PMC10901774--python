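# Default stapled-peptide library design fixture.
#
# A synthetic 12-position macrocyclic scaffold: positions 4 and 11 are the
# fixed staple-attachment residues (serine stand-ins; the staple itself is
# metadata only), the remaining ten positions draw from the 16-letter trimer
# alphabet (the 20 canonical residues without Cys, Lys, Pro, Gly).  One
# trimer codon per residue; the spike-in insert translates to a Lys/Gly
# repeat and is therefore never a library member.
name: stapled-helix-12mer
alphabet: ADEFHILMNQRSTVWY
codon_map:
  A: GCT
  D: GAT
  E: GAA
  F: TTT
  H: CAT
  I: ATT
  L: CTG
  M: ATG
  N: AAT
  Q: CAG
  R: CGT
  S: AGC
  T: ACC
  V: GTT
  W: TGG
  Y: TAT
positions:
  - variable: all
  - variable: all
  - variable: all
  - fixed: S
  - variable: all
  - variable: all
  - variable: all
  - variable: all
  - variable: all
  - variable: all
  - fixed: S
  - variable: all
flank5: TCTCACTCTGCA
flank3: GGTTCGGGTACC
staple_positions: [4, 11]
spike_in_dna: AAAGGTAAAGGTAAAGGTAAAGGTAAAGGTAAAGGT
spike_in_label: SPIKE
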