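# Default transcription-factor-diagnostic Pfam domains.
# The screening rule "transcript carries a major TF motif" is a curation
# decision; this list seeds it with the DNA-binding domains observed among
# silkworm silk-gland regulators plus the standard insect TF families.
# Supply your own file (one accession per line) to replace it.

# Homeodomain family
PF00046   # Homeodomain
PF05920   # Homeobox_KN (TALE / homothorax-like)
PF16493   # Homeodomain-like

# Forkhead / winged helix
PF00250   # Forkhead (SGF1/fork head)

# Basic leucine zipper
PF00170   # bZIP_1
PF07716   # bZIP_2

# Basic helix-loop-helix
PF00010   # HLH (sage-like)

# LIM domain (Arrowhead / SGF2 complex)
PF00412   # LIM

# Heat-shock factor
PF00447   # HSF_DNA-bind

# NF-Y / histone-fold CCAAT-binding
PF00808   # CBFD_NFYB_HMF

# MBF2 coactivator
PF15868   # MBF2

# POU
PF00157   # Pou

# Nuclear receptor
PF00104   # Hormone_recep
PF00105   # zf-C4

# Myb / SANT
PF00249   # Myb_DNA-binding
PF15963   # Myb_DNA-bind_7

# C2H2-type zinc fingers
PF00096   # zf-C2H2
PF13894   # zf-C2H2_4
PF13912   # zf-C2H2_6
PF13913   # zf-C2HC_2

# GATA
PF00320   # GATA

# T-box
PF00907   # T-box

# MADS / SRF
PF00319   # SRF-TF

# Doublesex / DM
PF00751   # DM

# Bromodomain-adjacent chromatin regulators
PF00439   # Bromodomain

# FLYWCH / BTB-ZF
PF04500   # FLYWCH_zf
PF00651   # BTB/POZ
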