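"""Shared fixtures: the pooled published table and small record sets."""

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from mdlt.records import MortalityCause as M
from mdlt.records import Stage, StageCauseCounts


@pytest.fixture
def pooled_counts() -> StageCauseCounts:
    """Integer stage-by-cause counts reconstructed from the published pooled
    table's examined counts and printed decrements: feeding them through the
    builder reproduces every printed stage cell at display precision."""
    c = StageCauseCounts(stratum="POOLED")
    c.l = {
        Stage.EGG: 8968,
        Stage.LARVA_I: 18447,
        Stage.LARVA_III: 17254,
        Stage.LARVA_IV: 1546,
        Stage.LARVA_V: 1499,
        Stage.ADULT: 1291,
    }
    c.deaths[Stage.EGG][M.CANNIBALISM] = 5551
    c.deaths[Stage.LARVA_I].update(
        {M.PLANT_DEFENSE: 4939, M.CANNIBALISM: 3486, M.UNKNOWN: 393}
    )
    c.deaths[Stage.LARVA_III].update(
        {M.PARASITISM: 880, M.PLANT_DEFENSE: 5500, M.CANNIBALISM: 800, M.UNKNOWN: 2380}
    )
    c.deaths[Stage.LARVA_IV].update(
        {M.PARASITISM: 35, M.UNKNOWN: 214, M.PATHOGENS: 12}
    )
    c.deaths[Stage.LARVA_V].update(
        {M.PARASITISM: 45, M.UNKNOWN: 133, M.PATHOGENS: 27}
    )
    c.validate()
    return c
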