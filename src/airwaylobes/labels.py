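"""Lobe label vocabulary shared by every stage of the pipeline."""

from __future__ import annotations

from enum import IntEnum


class LobeLabel(IntEnum):
    """Per-branch / per-voxel anatomical label.

    The five pulmonary lobes are the right upper (RUL), right middle (RML),
    right lower (RLL), left upper (LUL) and left lower (LLL) lobes; the
    trachea is kept as its own class.  Integer values double as the voxel
    codes written into label volumes (0 is background).
    """

    BACKGROUND = 0
    TRACHEA = 1
    RUL = 2
    RML = 3
    RLL = 4
    LUL = 5
    LLL = 6
    UNLABELED = 7


#: Labels a successfully classified tree may carry (no UNLABELED).
LOBE_LABELS = (
    LobeLabel.TRACHEA,
    LobeLabel.RUL,
    LobeLabel.RML,
    LobeLabel.RLL,
    LobeLabel.LUL,
    LobeLabel.LLL,
)
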