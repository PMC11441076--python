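"""Published summary counts used as worked-example inputs.

Small printed tables from the longitudinal two-photon study of neuron
fate in tau-transgenic mice (rTg4510, ThyTau22) and from cleared human
inferior temporal gyrus tissue.  They are inputs for the worked examples
and report reproductions — never outputs of this package's simulations.
"""

#: rTg4510 mice, 4 weekly sessions (n = 6 animals): tracked neurons and
#: disappearances, split by ever-tangled status.
RTG4510 = {
    "total": 1721,
    "died": 178,
    "tangle_total": 235,
    "tangle_died": 6,
    "nontangle_total": 1486,
    "nontangle_died": 172,
}

#: Littermate control mice (n = 4): non-tangle-bearing neurons only.
RTG4510_CONTROL = {"total": 1589, "died": 8}

#: ThyTau22 mice (n = 3) and wild-type littermates (n = 4), 4 weeks.
THYTAU22 = {"total": 845, "died": 24}
THYTAU22_WT = {"total": 860, "died": 1}

#: Tangle bookkeeping in rTg4510: tangles present at week 1 plus tangles
#: watched appearing during the 4 weeks.
TANGLE_COUNTS = {"initial": 128, "new": 107}

#: Cleared human inferior temporal gyrus: segmented neurons and the
#: subset with >60% local 3-NN enlargement, AD vs control donors.
HUMAN_ITG = {
    "ad_neurons": 268849,
    "ad_enlarged": 5391,
    "control_neurons": 425540,
    "control_enlarged": 2072,
}

#: Microstructure summary values (micrometres / percent): mean neighbour-
#: volume increase of dying neurons over their final 2-week window, and
#: mean first-week 3-NN distances by group.
MICROSTRUCTURE = {
    "dying_volume_increase_pct": 29.5,
    "persisting_d3_um": 24.0,
    "dying_d3_um": 33.9,
    "control_d3_um": 22.4,
}
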