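"""Class conventions shared by all modules.

The fixed component order (C, F, LRNC) also defines the tie-breaking
order used everywhere: ties resolve to the lowest class index.
Label-map codes: 0 = background, 1..3 = components, 4 = lumen (only in
composite region maps used for warping).
"""

CLASS_NAMES = ("C", "F", "LRNC")

BACKGROUND = 0
CLASS_CODES = {"C": 1, "F": 2, "LRNC": 3}
CODE_TO_CLASS = {v: k for k, v in CLASS_CODES.items()}
LUMEN_CODE = 4

#: MR channels in canonical order; CTA is kept separate because it is
#: never intensity-normalized (original Hounsfield-like values are used).
MR_CHANNELS = ("t1w2d", "pdw", "tof", "t1w3d_pre", "t1w3d_post")
CTA_CHANNEL = "cta"
ALL_CHANNELS = MR_CHANNELS + (CTA_CHANNEL,)
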