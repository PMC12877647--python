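# hERG (KCNH2 isoform 1a, NM_000238.4 numbering, 1159 residues) region map.
#
# `unresolved` lists the protein intervals with no coordinates in the
# reference cryo-EM model: variants there are scored in A-C mode.
#
# Domain boundaries are editable placeholders in the conventional hERG
# architecture (N-tail / PAS / N-linker / VSD / pore / C-linker / CNBHD /
# C-tail); they drive annotation and calibration strata only, never the
# scores themselves.
unresolved:
  - [132, 398]
  - [433, 448]
  - [511, 519]
  - [578, 582]
  - [598, 602]
  - [864, 1159]
domains:
  - name: N-tail
    interval: [1, 25]
  - name: PAS
    interval: [26, 135]
  - name: N-linker
    interval: [136, 397]
  - name: VSD
    interval: [398, 545]
  - name: pore
    interval: [546, 670]
  - name: C-linker
    interval: [671, 740]
  - name: CNBHD
    interval: [741, 863]
  - name: C-tail
    interval: [864, 1159]
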