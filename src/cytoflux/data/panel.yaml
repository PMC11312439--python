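# 33-marker CyTOF antibody panel: 21 signaling + 12 identity markers.
# class: identity markers encode lineage / cell state; signaling markers are
# phospho-epitopes and activation read-outs.
markers:
  - {name: CD11b,        metal: In115, class: identity}
  - {name: CD45,         metal: Sm147, class: identity}
  - {name: GFAP,         metal: Nd142, class: identity}
  - {name: Olig2,        metal: Nd143, class: identity}
  - {name: Fibronectin,  metal: Nd144, class: identity}
  - {name: CD68,         metal: Nd145, class: identity}
  - {name: F480,         metal: Nd146, class: identity}
  - {name: Ly6C,         metal: Nd148, class: identity}
  - {name: Sox2,         metal: Nd150, class: identity}
  - {name: Galectin-1,   metal: Sm149, class: identity}
  - {name: Cx3CR1,       metal: Sm152, class: identity}
  - {name: CD86,         metal: Pr141, class: identity}
  - {name: CD40,         metal: Yb172, class: signaling}
  - {name: pERK,         metal: Er168, class: signaling}
  - {name: pp38,         metal: Gd156, class: signaling}
  - {name: pRSK,         metal: Gd155, class: signaling}
  - {name: pCREB,        metal: Tb159, class: signaling}
  - {name: pS6,          metal: Yb171, class: signaling}
  - {name: pSTAT1,       metal: Eu153, class: signaling}
  - {name: pSTAT3,       metal: Gd158, class: signaling}
  - {name: pSrc,         metal: Dy162, class: signaling}
  - {name: pNFkB,        metal: Dy164, class: signaling}
  - {name: pAkt,         metal: Er166, class: signaling}
  - {name: pcJun,        metal: Er167, class: signaling}
  - {name: pgH2AX,       metal: Dy161, class: signaling}
  - {name: b-catenin,    metal: Yb173, class: signaling}
  - {name: Ki67,         metal: Er170, class: signaling}
  - {name: pJNK,         metal: Gd160, class: signaling}
  - {name: pMEK,         metal: Dy163, class: signaling}
  - {name: pSTAT5,       metal: Yb174, class: signaling}
  - {name: pAMPK,        metal: Tm169, class: signaling}
  - {name: p4EBP1,       metal: Yb176, class: signaling}
  - {name: pIkBa,        metal: La139, class: signaling}
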