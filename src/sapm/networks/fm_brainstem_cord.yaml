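# Default brainstem / cervical spinal cord pain-regulation network.
#
# 10 regions, 32 inter-region connections, 3 latent inputs (35 directed
# links in total).  Connections marked "named" are explicitly named in the
# source description of this circuit; connections marked "fixture" are
# additional anatomically plausible links (classical ascending nociceptive
# and descending modulatory pathways) added to complete the declared count
# of 32 inter-region connections.
regions:
  - {name: right dorsal horn of the sixth cervical spinal cord segment, abbrev: C6RD, n_subregions: 5}
  - {name: dorsal reticular nucleus of the medulla, abbrev: DRt, n_subregions: 5}
  - {name: hypothalamus, abbrev: Hypothalamus, n_subregions: 5}
  - {name: locus coeruleus, abbrev: LC, n_subregions: 5}
  - {name: nucleus gigantocellularis, abbrev: NGc, n_subregions: 5}
  - {name: nucleus raphe magnus, abbrev: NRM, n_subregions: 5}
  - {name: nucleus tractus solitarius, abbrev: NTS, n_subregions: 5}
  - {name: periaqueductal gray, abbrev: PAG, n_subregions: 5}
  - {name: parabrachial nuclei, abbrev: PBN, n_subregions: 5}
  - {name: medial thalamus, abbrev: Thalamus, n_subregions: 5}
connections:
  # named
  - {source: PBN, target: Thalamus}
  - {source: LC, target: Hypothalamus}
  - {source: PBN, target: Hypothalamus}
  - {source: Hypothalamus, target: LC}
  - {source: LC, target: Thalamus}
  - {source: LC, target: DRt}
  - {source: LC, target: PBN}
  - {source: C6RD, target: Thalamus}
  - {source: PAG, target: NTS}
  - {source: PAG, target: LC}
  - {source: PBN, target: LC}
  # fixture: ascending projections from the dorsal horn
  - {source: C6RD, target: NTS}
  - {source: C6RD, target: DRt}
  - {source: C6RD, target: PBN}
  - {source: C6RD, target: NGc}
  # fixture: medullary reticular / raphe loops with the cord
  - {source: DRt, target: C6RD}
  - {source: NRM, target: C6RD}
  - {source: NGc, target: C6RD}
  - {source: NGc, target: NRM}
  # fixture: periaqueductal gray outputs
  - {source: PAG, target: NRM}
  - {source: PAG, target: NGc}
  - {source: PAG, target: DRt}
  # fixture: hypothalamic outputs
  - {source: Hypothalamus, target: PAG}
  - {source: Hypothalamus, target: NTS}
  - {source: Hypothalamus, target: NRM}
  # fixture: solitary nucleus outputs
  - {source: NTS, target: PBN}
  - {source: NTS, target: LC}
  - {source: NTS, target: Hypothalamus}
  - {source: NTS, target: NRM}
  # fixture: parabrachial and coeruleus descending outputs, thalamic feedback
  - {source: PBN, target: PAG}
  - {source: LC, target: C6RD}
  - {source: Thalamus, target: Hypothalamus}
latents:
  - {name: int1, targets: [C6RD]}
  - {name: int2, targets: [LC]}
  - {name: int3, targets: [PBN]}
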