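# Default iKIR-ligand interaction weights (version w-2024.1).
#
# The iKIR score of an individual is the sum, over their functional
# iKIR-ligand gene pairs, of the weight of that pair.  Weights grade the
# strength of the receptor-ligand interaction: KIR2DL1/C2 and
# KIR3DL1/Bw4-80I are the strongest inhibitory interactions, KIR2DL3/C1 and
# KIR3DL1/Bw4-80T intermediate, KIR2DL2/C1 weaker.  With this table the
# attainable score range is [0, 3.25], so the stratification thresholds
# used in the analyses (1.5, 1.75, 2.0, 2.5) all fall strictly inside it.
#
# KIR3DL2/A3-A11 is a weak, peptide-dependent interaction; it carries a
# weight here but is excluded from the score unless include_kir3dl2 is
# set true.
version: w-2024.1
threshold_default: 1.75
include_kir3dl2: false
weights:
  KIR2DL1/C2: 1.0
  KIR2DL2/C1: 0.5
  KIR2DL3/C1: 0.75
  KIR3DL1/Bw4-80I: 1.0
  KIR3DL1/Bw4-80T: 0.75
  KIR3DL2/A3A11: 0.25
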