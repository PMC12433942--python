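"""Canonical muscle set and movement events.

Fourteen lower-limb muscles are recorded bilaterally (seven per leg):
vastus lateralis (VL), rectus femoris (RF), vastus medialis (VM),
biceps femoris (BF), semitendinosus (ST), tibialis anterior (TA) and
lateral gastrocnemius (GL).  Labels are ``<side>-<muscle>`` with the
kicking (right) leg listed first.
"""

from __future__ import annotations

CANONICAL_MUSCLES: tuple[str, ...] = (
    "R-VL", "R-RF", "R-VM", "R-BF", "R-ST", "R-TA", "R-GL",
    "L-VL", "L-RF", "L-VM", "L-BF", "L-ST", "L-TA", "L-GL",
)

N_MUSCLES = len(CANONICAL_MUSCLES)

#: movement events, in required temporal order
EVENT_ORDER: tuple[str, ...] = ("touchdown", "ball_contact", "swing_end")

#: antagonist pairs used for the co-activation index: thigh (RF vs BF)
#: and shank (GL vs TA), per leg.  Only the lateral gastrocnemius head
#: is instrumented, so the shank pair uses GL alone.
ANTAGONIST_PAIRS: tuple[tuple[str, str, str], ...] = (
    ("R-thigh", "R-RF", "R-BF"),
    ("R-shank", "R-GL", "R-TA"),
    ("L-thigh", "L-RF", "L-BF"),
    ("L-shank", "L-GL", "L-TA"),
)
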