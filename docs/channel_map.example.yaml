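# Channel map: binds FCS channel names to pipeline roles.
#
# volume      - total-protein (cell-volume proxy) stain channels, e.g. the
#               ruthenium isotope channels of an ASCQ-type stain; one or more.
# cell_cycle  - exactly these four roles, each bound to one distinct channel.
# functional  - every other channel to carry through the pipeline.
# excluded    - channels dropped at read time (DNA intercalators, barcodes,
#               beads, event length, time, ...).
#
# Matrices are always assembled in the order: volume channels, then the four
# cell-cycle roles (IdU, cyclinB1, pHH3, pRB), then functional channels —
# regardless of the channel order inside the FCS file.

volume: [ASCQ_102Ru, ASCQ_104Ru]
cell_cycle:
  IdU: IdU_127I
  cyclinB1: CyclinB1_166Er
  pHH3: pHH3_175Lu
  pRB: pRB_150Nd
functional: [pS6_172Yb, pERK_167Er, pP38_156Gd]
excluded: [Time, Event_length, DNA1_191Ir, DNA2_193Ir]
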