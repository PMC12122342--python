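# Marker panels for spot annotation on gastric-cancer spatial data.
# A spot is called positive for a cell type when EVERY group contributes at
# least one gene at raw count >= threshold (ANY within group, ALL across
# groups). Tc17 spots require a CD8 T-cell marker plus a type-17 marker;
# tumor spots require any gastric-cancer-specific epithelial marker.
tc17:
  groups:
    - [CD8A, CD8B]
    - [IL17A, RORC]
  threshold: 1
tumor:
  groups:
    - [KRT17, PRAME, GNGT1, GJB5, PI3]
  threshold: 1
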