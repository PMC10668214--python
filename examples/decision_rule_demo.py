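"""The two-montage decision mechanism (TMDM) on hand-built probability frames.

Builds three 2 x 19 probability frames and applies the TMDM and the
single-montage mechanism (SMDM).  The TMDM requires activation on both
montages plus a shared scalp electrode between the active channels; the
SMDM only looks at the maximum referential probability.
"""

import numpy as np

from iedscan.decision import decide_instant
from iedscan.inference import ProbabilityFrame
from iedscan.io import SCALP_ELECTRODES
from iedscan.montage import BIPOLAR_PAIRS

REF_NAMES = list(SCALP_ELECTRODES)
BIP_NAMES = [f"{a}-{b}" for a, b in BIPOLAR_PAIRS]


def frame(ear: dict, bip: dict) -> ProbabilityFrame:
    probs = np.zeros((2, 19))
    for name, p in ear.items():
        probs[0, REF_NAMES.index(name)] = p
    for name, p in bip.items():
        probs[1, BIP_NAMES.index(name)] = p
    return ProbabilityFrame(
        0.0, probs, "earlobe",
        REF_NAMES, [frozenset({e}) for e in REF_NAMES],
        BIP_NAMES, [frozenset(p) for p in BIPOLAR_PAIRS],
    )


cases = {
    "left frontal spike, consistent montages": frame(
        ear={"F3": 0.9}, bip={"F3-C3": 0.9, "C3-P3": 0.85}
    ),
    "frontal referential, posterior bipolar (spatially inconsistent)": frame(
        ear={"F3": 0.9}, bip={"T6-O2": 0.9, "P4-O2": 0.85}
    ),
    "single bipolar channel only": frame(ear={"F3": 0.9}, bip={"F3-C3": 0.9}),
}

print(f"{'case':55s}  TMDM   SMDM")
for name, fr in cases.items():
    tmdm = decide_instant(fr, 0.5, "TMDM").positive
    smdm = decide_instant(fr, 0.5, "SMDM").positive
    print(f"{name:55s}  {str(tmdm):5s}  {str(smdm):5s}")

print(
    "\nTMDM fires only when >=1 referential and >=2 bipolar channels are active\n"
    "AND they share a scalp electrode; SMDM fires on any strong referential\n"
    "channel, which is why it admits more artifacts."
)
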