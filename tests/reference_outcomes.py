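"""Frozen reference outcome table for a two-district region.

Published projections for a regional mental-health system over a ten-year
forecast window: cumulative suicides, mental-health-related ED presentations
and service disengagements under business as usual and under the seventeen
non-dominated four-intervention scenarios, used here as a fixture for
arithmetic and set-logic checks (percent reductions, Pareto filtering,
regional aggregation).
"""

# scenario label -> (suicides, ED presentations, disengagements)
BASELINE_PHN = (1778.0, 155_901.0, 544_972.0)

NON_DOMINATED_PHN = {
    "a": (1532.0, 143_266.0, 501_191.0),
    "b": (1534.0, 138_444.0, 506_134.0),
    "c": (1543.0, 141_327.0, 505_835.0),
    "d": (1544.0, 143_114.0, 496_362.0),
    "e": (1566.0, 138_145.0, 501_555.0),
    "f": (1576.0, 141_079.0, 501_267.0),
    "g": (1578.0, 142_842.0, 491_787.0),
    "h": (1578.0, 138_001.0, 496_730.0),
    "i": (1588.0, 140_963.0, 496_443.0),
    "j": (1619.0, 137_991.0, 494_169.0),
    "k": (1629.0, 140_891.0, 493_829.0),
    "l": (1630.0, 142_641.0, 484_337.0),
    "m": (1632.0, 137_852.0, 489_305.0),
    "n": (1642.0, 140_782.0, 488_964.0),
    "o": (1667.0, 137_573.0, 484_531.0),
    "p": (1678.0, 140_555.0, 484_195.0),
    "q": (1689.0, 143_738.0, 483_846.0),
}

# per-district baseline splits (suicides, ED presentations, disengagements)
BASELINE_CC = (471.0, 42_423.0, 164_293.0)
BASELINE_HNE = (1307.0, 113_478.0, 380_678.0)

# printed 1-dp percent reductions spot-checked against the counts
PRINTED_REDUCTIONS = {
    ("a", "suicides"): 13.8,
    ("b", "ed_presentations"): 11.2,
    ("o", "ed_presentations"): 11.8,
    ("q", "disengagements"): 11.2,
}
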