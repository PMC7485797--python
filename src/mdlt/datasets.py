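"""Published pooled life-table inputs for the wheat stem sawfly in barley.

A multi-site field study of *Cephus cinctus* in eight barley cultivars
(two Montana locations, 2016-2018; ~64,000 dissected stems and 3,200 stubs)
published a pooled multiple decrement life table across five causes of death:
parasitism, plant defense, cannibalism, unknown factors and pathogens.  The
printed stage-specific probabilities and cause decrements below serve as the
package's worked example: the recursion, cause totals and combination
percentages can all be recomputed from them at desk scale.
"""

from __future__ import annotations

from .records import CAUSES, STAGES, MortalityCause, Stage

__all__ = [
    "POOLED_BARLEY_AQ",
    "POOLED_BARLEY_AL",
    "POOLED_BARLEY_AD",
    "POOLED_BARLEY_L",
    "POOLED_BARLEY_DECREMENTS",
    "POOLED_BARLEY_TOTALS",
]

#: Stage-specific probability of dying from all causes, aq_x, for the five
#: decremented stages (Egg, Larva I, Larva III, Larva IV, Larva V).
POOLED_BARLEY_AQ: tuple[float, ...] = (0.619, 0.478, 0.554, 0.169, 0.1368)

#: Printed proportion living at stage entry, al_x (Egg .. Adult).
POOLED_BARLEY_AL: tuple[float, ...] = (1.0, 0.381, 0.199, 0.089, 0.074, 0.064)

#: Printed proportion of the cohort dying in each decremented stage, ad_x.
POOLED_BARLEY_AD: tuple[float, ...] = (0.619, 0.182, 0.110, 0.015, 0.010)

#: Examined counts per stage row (independent cross-sectional samples; the
#: raw column is non-monotone and is never used for cohort survival).
POOLED_BARLEY_L: dict[Stage, int] = {
    Stage.EGG: 8968,
    Stage.LARVA_I: 18447,
    Stage.LARVA_III: 17254,
    Stage.LARVA_IV: 1546,
    Stage.LARVA_V: 1499,
    Stage.ADULT: 1291,
}

#: Printed unconditional stage-by-cause decrements ad_ix, cause order
#: parasitism, plant defense, cannibalism, unknown, pathogens.
POOLED_BARLEY_DECREMENTS: dict[Stage, tuple[float, ...]] = {
    Stage.EGG: (0.0, 0.0, 0.619, 0.0, 0.0),
    Stage.LARVA_I: (0.0, 0.102, 0.072, 0.008, 0.0),
    Stage.LARVA_III: (0.010, 0.063, 0.009, 0.027, 0.0),
    Stage.LARVA_IV: (0.002, 0.0, 0.0, 0.012, 0.0007),
    Stage.LARVA_V: (0.002, 0.0, 0.0, 0.006, 0.0013),
}

#: Printed crude cohort mortality totals aD_i per cause.
POOLED_BARLEY_TOTALS: dict[MortalityCause, float] = {
    MortalityCause.PARASITISM: 0.015,
    MortalityCause.PLANT_DEFENSE: 0.165,
    MortalityCause.CANNIBALISM: 0.701,
    MortalityCause.UNKNOWN: 0.054,
    MortalityCause.PATHOGENS: 0.002,
}
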