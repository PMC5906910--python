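"""R:FR signal processing: dose-response and threshold shade-avoidance rules.

A logistic dose-response curve maps the red:far-red ratio sensed at a leaf
tip onto a shade fraction S in [0, 1]; S interpolates every locally mediated
trait (internode elongation, leaf length/width ratio, leaf angle) between the
open-grown and the shaded phenotype.  Two responses are thresholded instead:
branch abortion (handled in the architecture module) and the systemic
whole-plant response that advances flowering and shortens potential leaf
length, which latches once triggered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import PlantParameters


def shade_fraction(rfr: float, params: PlantParameters) -> float:
    """Logistic shade dose S(rfr) = 1 / (1 + exp(steep * (rfr - mid))).

    S -> 1 in deep shade (low R:FR), S -> 0 in open light; S = 0.5 at the
    response midpoint.
    """
    if rfr <= 0:
        raise ValueError("rfr must be > 0")
    x = params.rfr_steep * (rfr - params.rfr_mid)
    if x > 500:
        return 0.0
    if x < -500:
        return 1.0
    return 1.0 / (1.0 + math.exp(x))


@dataclass
class LocalModifiers:
    """Phytomer-level trait values interpolated by the shade fraction."""

    internode_len_mult: float
    leaf_len_mult: float
    leaf_angle: float     # degrees from vertical
    lw_ratio: float


def local_modifiers(S: float, params: PlantParameters) -> LocalModifiers:
    """Interpolate the open-grown and shade phenotypes by S in [0, 1]."""
    if not 0 <= S <= 1:
        raise ValueError("S must be within [0, 1]")
    return LocalModifiers(
        internode_len_mult=1.0 + (params.int_elong_factor - 1.0) * S,
        leaf_len_mult=1.0 - (1.0 - params.leaf_red_factor) * S,
        leaf_angle=params.leaf_angle - (params.leaf_angle - params.leaf_angle_high) * S,
        lw_ratio=params.lw_ratio + (params.lw_ratio_high - params.lw_ratio) * S,
    )


def systemic_signal(main_stem_tip_rfrs, params: PlantParameters) -> bool:
    """Whole-plant signal: True when the mean main-stem tip R:FR falls below
    the flowering threshold, switching the phytomer target to the shade draw
    and reducing potential leaf length.  Callers must latch the switch."""
    rfrs = list(main_stem_tip_rfrs)
    if not rfrs:
        raise ValueError("need at least one live main-stem leaf")
    return (sum(rfrs) / len(rfrs)) < params.rfr_flower_threshold
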