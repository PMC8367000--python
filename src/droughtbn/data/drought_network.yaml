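# Curated Arabidopsis drought-signaling Bayesian network.
#
# Roles: reporter = drought-responsive readout gene; regulator = everything
# upstream. Signs annotate the direction of regulation reported in the
# literature (+ activating, - inhibiting, ? unknown); they are documentation
# only and never enter any probability computation. The edges into and out of
# ATAF1 are of unknown direction.
#
# Curation choices where the pathway literature is not explicit:
#   - The MAP-kinase cascade is MAP3K15 -> MKK4 -> MPK6 -> WRKY59 -> DREB2A,
#     the Arabidopsis analogue of the cotton drought cascade that converges
#     on DREB2.
#   - All four ABRE-family bZIP factors (AREB1, AREB2, ABF1, ABF3) parent
#     both DREB2A and DREB1D as well as RD29A.
#   - WRKY18 and WRKY40 are roots: the hormones ABA and JA are not nodes
#     (no expression values exist for hormones), so ABA/JA-induced factors
#     start the graph.
name: arabidopsis-drought
nodes:
  # WRKY triad (ABA-induced)
  - {name: WRKY18, role: regulator}
  - {name: WRKY40, role: regulator}
  - {name: WRKY60, role: regulator}
  # JA/ABA crosstalk pair
  - {name: MYC2, role: regulator}
  - {name: MYB2, role: regulator}
  # NAC cluster
  - {name: ANAC019, role: regulator}
  - {name: ANAC055, role: regulator}
  - {name: ATAF1, role: regulator}
  - {name: ZFHD1, role: regulator}
  - {name: ANAC072, role: regulator}  # RD26
  # ABRE/AREB bZIP family (ABA-dependent)
  - {name: AREB1, role: regulator}   # ABF2
  - {name: AREB2, role: regulator}   # ABF4
  - {name: ABF1, role: regulator}
  - {name: ABF3, role: regulator}
  # DREB module and its regulators
  - {name: DREB1A, role: regulator}  # CBF3
  - {name: DREB1B, role: regulator}  # CBF1
  - {name: DREB1C, role: regulator}  # CBF2
  - {name: DREB1D, role: regulator}  # CBF4
  - {name: DREB2A, role: regulator}
  - {name: MYB15, role: regulator}
  - {name: ICE1, role: regulator}
  - {name: HOS1, role: regulator}
  - {name: SIZ1, role: regulator}
  - {name: DRIP1, role: regulator}
  # MAP-kinase cascade
  - {name: MAP3K15, role: regulator}
  - {name: MKK4, role: regulator}
  - {name: MPK6, role: regulator}
  - {name: WRKY59, role: regulator}
  # Drought-responsive reporter genes
  - {name: RD29A, role: reporter}
  - {name: RD22, role: reporter}
  - {name: RD20, role: reporter}
  - {name: ERD1, role: reporter}
edges:
  # WRKY triad
  - {parent: WRKY18, child: RD29A, sign: "+"}
  - {parent: WRKY60, child: RD29A, sign: "+"}
  - {parent: WRKY40, child: RD29A, sign: "-"}
  - {parent: WRKY40, child: WRKY60, sign: "-"}
  - {parent: WRKY60, child: MYB2, sign: "-"}
  # MYC2 / MYB2 onto the NAC cluster and RD22
  - {parent: MYC2, child: ANAC019, sign: "+"}
  - {parent: MYC2, child: ANAC055, sign: "+"}
  - {parent: MYC2, child: ATAF1, sign: "?"}
  - {parent: MYC2, child: RD22, sign: "+"}
  - {parent: MYB2, child: ANAC019, sign: "+"}
  - {parent: MYB2, child: ANAC055, sign: "+"}
  - {parent: MYB2, child: ATAF1, sign: "?"}
  - {parent: MYB2, child: RD22, sign: "+"}
  # NAC cluster, ZFHD1 and ANAC072 onto ERD1; ANAC072 onto RD20
  - {parent: ANAC019, child: ERD1, sign: "+"}
  - {parent: ANAC055, child: ERD1, sign: "+"}
  - {parent: ATAF1, child: ERD1, sign: "?"}
  - {parent: ZFHD1, child: ERD1, sign: "+"}
  - {parent: ANAC072, child: ERD1, sign: "+"}
  - {parent: ANAC072, child: RD20, sign: "+"}
  # ABRE family onto RD29A and the ABA-coupled DREBs
  - {parent: AREB1, child: RD29A, sign: "+"}
  - {parent: AREB2, child: RD29A, sign: "+"}
  - {parent: ABF1, child: RD29A, sign: "+"}
  - {parent: ABF3, child: RD29A, sign: "+"}
  - {parent: AREB1, child: DREB2A, sign: "+"}
  - {parent: AREB2, child: DREB2A, sign: "+"}
  - {parent: ABF1, child: DREB2A, sign: "+"}
  - {parent: ABF3, child: DREB2A, sign: "+"}
  - {parent: AREB1, child: DREB1D, sign: "+"}
  - {parent: AREB2, child: DREB1D, sign: "+"}
  - {parent: ABF1, child: DREB1D, sign: "+"}
  - {parent: ABF3, child: DREB1D, sign: "+"}
  # DREB module onto RD29A
  - {parent: DREB1A, child: RD29A, sign: "+"}
  - {parent: DREB1B, child: RD29A, sign: "+"}
  - {parent: DREB1C, child: RD29A, sign: "+"}
  - {parent: DREB1D, child: RD29A, sign: "+"}
  - {parent: DREB2A, child: RD29A, sign: "+"}
  # DREB1A-C regulators
  - {parent: MYB15, child: DREB1A, sign: "-"}
  - {parent: MYB15, child: DREB1B, sign: "-"}
  - {parent: MYB15, child: DREB1C, sign: "-"}
  - {parent: ICE1, child: DREB1A, sign: "+"}
  - {parent: ICE1, child: DREB1B, sign: "+"}
  - {parent: ICE1, child: DREB1C, sign: "+"}
  - {parent: ICE1, child: MYB15, sign: "-"}
  - {parent: HOS1, child: ICE1, sign: "-"}
  - {parent: SIZ1, child: ICE1, sign: "+"}
  # DREB2A repressor
  - {parent: DRIP1, child: DREB2A, sign: "-"}
  # MAP-kinase cascade converging on DREB2A
  - {parent: MAP3K15, child: MKK4, sign: "+"}
  - {parent: MKK4, child: MPK6, sign: "+"}
  - {parent: MPK6, child: WRKY59, sign: "+"}
  - {parent: WRKY59, child: DREB2A, sign: "+"}
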