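"""Abridged multiple decrement life tables.

A multiple decrement life table (MDLT) partitions total mortality at each
developmental stage among mutually exclusive causes of death.  Stage-specific
probabilities of dying, aq_x = d_x / l_x, are estimated independently per
stage from the examined counts; the cohort schedule then follows the
recursion

    al_0 = 1,        ad_x = al_x * aq_x,        al_{x+1} = al_x - ad_x,

so that al_x is the proportion of the original cohort alive entering stage x
and ad_x the proportion dying in stage x.  Within a stage, ad_x is
apportioned among causes proportionally to the observed cause-specific death
counts; no within-stage competing-risk correction is applied, which is the
standard abridged-table arithmetic.  All arithmetic is carried in full
precision; rounding is a display/serialisation policy only, except when a
per-step rounding is explicitly requested to replicate a printed table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .records import CAUSES, STAGES, MortalityCause, Stage, StageCauseCounts

__all__ = [
    "StageRow",
    "MultipleDecrementTable",
    "build_mdlt",
    "survival_schedule",
    "cause_totals",
    "pct_in_presence",
    "display_round",
]


def display_round(value: float, ndigits: int = 3) -> float:
    """Half-up decimal rounding; values too small for the 3-decimal grid
    (below 0.002) keep one extra digit so that tiny decrements such as
    0.0007 survive display instead of collapsing to the grid."""
    value = float(value)
    if 0 < abs(value) < 0.002:
        ndigits = max(ndigits, 4)
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _round_step(value: float, ndigits: int | None) -> float:
    if ndigits is None:
        return value
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def survival_schedule(
    aq_x: Sequence[float], rounding: int | None = None
) -> tuple[list[float], list[float]]:
    """Run the al/ad recursion over stage-specific probabilities of dying.

    Returns ``(al, ad)`` where ``al`` has one more entry than ``aq_x`` (the
    proportion surviving past the last decremented stage) and ``ad[x] =
    al[x] * aq_x[x]``.  With ``rounding`` set, al and ad are rounded to that
    many decimals at each step, reproducing the arithmetic of a printed table
    whose entries were rounded stage by stage.
    """
    al = [1.0]
    ad = []
    for aq in aq_x:
        if not 0.0 <= aq <= 1.0:
            raise ValueError(f"stage probability of dying out of [0, 1]: {aq}")
        d = _round_step(al[-1] * aq, rounding)
        ad.append(d)
        al.append(_round_step(al[-1] - d, rounding))
    return al, ad


@dataclass(frozen=True)
class StageRow:
    """One life-table row.

    ``aq_x`` is conditional on entering the stage; ``al_x``/``ad_x``/
    ``ad_ix`` are unconditional proportions of the original cohort; ``cq_ix``
    are the conditional within-stage cause probabilities d_ix / l_x.  Both
    conditional and unconditional cause columns are stored because printed
    tables conventionally show the unconditional ones even when labelled as
    conditional.
    """

    stage: Stage
    l_x: int
    d_x: int
    aq_x: float
    al_x: float
    ad_x: float
    ad_ix: tuple[float, ...]
    cq_ix: tuple[float, ...]


@dataclass(frozen=True)
class MultipleDecrementTable:
    stratum: str
    rows: tuple[StageRow, ...]

    @property
    def final_survival(self) -> float:
        """Proportion of the original cohort alive at the adult stage."""
        return self.rows[-1].al_x

    @property
    def cause_totals_(self) -> np.ndarray:
        totals = np.zeros(len(CAUSES))
        for row in self.rows:
            totals += np.asarray(row.ad_ix)
        return totals

    @property
    def total_mortality(self) -> float:
        return float(self.cause_totals_.sum())

    def to_frame(self, rounding: int | None = None) -> pd.DataFrame:
        """Tabular layout matching the published convention: stage, l_x,
        aq_x, al_x, ad_x, then one unconditional decrement column per cause
        (labelled aq_1x..aq_5x), plus a Total row.  The adult row shows the
        final survival in the ad_x position, replicating the printed layout;
        internally that value is survival, not death."""
        rnd = (lambda v: display_round(v, rounding)) if rounding is not None else (lambda v: v)
        rows = []
        for row in self.rows[:-1]:
            r = {
                "stage": row.stage.name,
                "l_x": row.l_x,
                "aq_x": rnd(row.aq_x),
                "al_x": rnd(row.al_x),
                "ad_x": rnd(row.ad_x),
            }
            for cause, ad_i in zip(CAUSES, row.ad_ix):
                r[f"aq_{cause.value}x"] = rnd(ad_i)
            rows.append(r)
        adult = self.rows[-1]
        rows.append(
            {
                "stage": adult.stage.name,
                "l_x": adult.l_x,
                "aq_x": 0.0,
                "al_x": rnd(adult.al_x),
                "ad_x": rnd(adult.al_x),
            }
        )
        total = {"stage": "Total", "ad_x": rnd(self.total_mortality + self.final_survival)}
        for cause, t in zip(CAUSES, self.cause_totals_):
            total[f"aq_{cause.value}x"] = rnd(t)
        rows.append(total)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path, rounding: int | None = 3) -> None:
        self.to_frame(rounding).to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "stratum": self.stratum,
            "causes": [c.name for c in CAUSES],
            "rows": [
                {
                    "stage": r.stage.name,
                    "l_x": r.l_x,
                    "d_x": r.d_x,
                    "aq_x": r.aq_x,
                    "al_x": r.al_x,
                    "ad_x": r.ad_x,
                    "ad_ix": list(r.ad_ix),
                    "cq_ix": list(r.cq_ix),
                }
                for r in self.rows
            ],
            "cause_totals": self.cause_totals_.tolist(),
            "final_survival": self.final_survival,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MultipleDecrementTable":
        try:
            is_file = Path(str(source)).exists()
        except OSError:
            is_file = False
        text = Path(source).read_text() if is_file else str(source)
        payload = json.loads(text)
        rows = tuple(
            StageRow(
                stage=Stage[r["stage"]],
                l_x=r["l_x"],
                d_x=r["d_x"],
                aq_x=r["aq_x"],
                al_x=r["al_x"],
                ad_x=r["ad_x"],
                ad_ix=tuple(r["ad_ix"]),
                cq_ix=tuple(r["cq_ix"]),
            )
            for r in payload["rows"]
        )
        return cls(stratum=payload["stratum"], rows=rows)


def build_mdlt(
    counts: StageCauseCounts,
    *,
    skip_empty_stages: bool = False,
    rounding: int | None = None,
) -> MultipleDecrementTable:
    """Build the life table for one stratum from stage-by-cause counts.

    ``aq_x`` is computed per stage from the examined counts, the al/ad
    recursion is run from al=1, and each stage's ``ad_x`` is apportioned to
    causes proportionally to the observed cause counts.  A non-terminal stage
    with no examined occupants is an error unless ``skip_empty_stages``
    bridges it with aq_x = 0 (with a warning).  ``rounding`` applies the
    per-step rounding policy of :func:`survival_schedule`.
    """
    counts.validate()
    aq, fractions = [], []
    for stage in STAGES[:-1]:
        l_x, d_x = counts.l[stage], counts.d_x(stage)
        if l_x == 0:
            if not skip_empty_stages:
                raise ValueError(
                    f"{counts.stratum}: no examined occupants at stage "
                    f"{stage.name}; pass skip_empty_stages to bridge with aq=0"
                )
            warnings.warn(
                f"{counts.stratum}: stage {stage.name} has no examined occupants; "
                "bridged with aq_x = 0",
                stacklevel=2,
            )
            aq.append(0.0)
            fractions.append(np.zeros(len(CAUSES)))
            continue
        aq.append(d_x / l_x)
        f = np.array([counts.deaths[stage][c] for c in CAUSES], dtype=float)
        fractions.append(f / d_x if d_x else np.zeros(len(CAUSES)))
    al, ad = survival_schedule(aq, rounding)

    rows = []
    for i, stage in enumerate(STAGES[:-1]):
        l_x, d_x = counts.l[stage], counts.d_x(stage)
        ad_ix = tuple(float(ad[i] * f) for f in fractions[i])
        cq_ix = tuple(
            counts.deaths[stage][c] / l_x if l_x else 0.0 for c in CAUSES
        )
        rows.append(
            StageRow(
                stage=stage,
                l_x=l_x,
                d_x=d_x,
                aq_x=aq[i],
                al_x=al[i],
                ad_x=ad[i],
                ad_ix=ad_ix,
                cq_ix=cq_ix,
            )
        )
    rows.append(
        StageRow(
            stage=Stage.ADULT,
            l_x=counts.l[Stage.ADULT],
            d_x=0,
            aq_x=0.0,
            al_x=al[-1],
            ad_x=0.0,
            ad_ix=tuple(0.0 for _ in CAUSES),
            cq_ix=tuple(0.0 for _ in CAUSES),
        )
    )
    return MultipleDecrementTable(stratum=counts.stratum, rows=tuple(rows))


def cause_totals(table: MultipleDecrementTable) -> np.ndarray:
    """Crude cohort mortality aD_i per cause (summed unconditional stage
    decrements), in fixed cause order."""
    return table.cause_totals_


def pct_in_presence(table: MultipleDecrementTable) -> np.ndarray:
    """Percent of the original cohort dying of each cause with all causes
    operating (100 * aD_i)."""
    return 100.0 * cause_totals(table)


#: canonical cause order for consumers
CAUSE_NAMES = [c.name for c in CAUSES]
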