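# Allele -> KIR-ligand group lookup (version lg-2024.1).
#
# HLA-C alleles split into C1/C2 by the position-80 dimorphism
# (C1 = Asn80, ligand of KIR2DL2/KIR2DL3; C2 = Lys80, ligand of KIR2DL1).
# HLA-B (and a few HLA-A) alleles with the Bw4 motif at positions 77-83 are
# ligands of KIR3DL1, subdivided by the residue at position 80 (80I / 80T).
# HLA-A*03/A*11 are ligands of KIR3DL2.
#
# Entries may be one-field ("B*57") or two-field ("B*27:05") prefixes; the
# most specific matching prefix wins.  The table is editable package data,
# not an exhaustive registry: it covers the common European alleles the
# synthetic cohorts draw from plus the alleles named in the literature.
version: lg-2024.1
c1:
  - C*01
  - C*03
  - C*07
  - C*08
  - C*12
  - C*14
  - C*16
c2:
  - C*02
  - C*04
  - C*05
  - C*06
  - C*15
  - C*17
  - C*18
bw4_80i:
  - A*23
  - A*24
  - A*25
  - A*32
  - B*25
  - B*27:02
  - B*38
  - B*49
  - B*51
  - B*52
  - B*53
  - B*57
  - B*58
  - B*59
bw4_80t:
  - B*13
  - B*27:05
  - B*27:04
  - B*37
  - B*44
  - B*47
a3a11:
  - A*03
  - A*11
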