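"""Directional communication scores.

An interaction i between a central condition j and a partner k is scored as

    s_ijk = combine(ligand subunits) * combine(receptor subunits)

on scaled ([0, 10]) expression, where ``combine`` is the geometric mean of
the side's subunit values — so a multimeric side scores zero unless every
chain is expressed.  For outward communication the ligand side is read from
the central cell and the receptor side from the partner; inward swaps the
roles.  The global score S_jk is the (optionally weighted) sum of the
per-interaction scores; S can be normalized to a reference condition
(S / S_ref) and linearly rescaled onto [1, 10] for network display.

Interactions with a subunit gene absent from a platform's rows are excluded
from S (absence is not evidence of non-expression) unless
``missing_as_zero`` is requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .lr_database import InteractionDatabase, InteractionRecord
from .scaling import ScaledMatrix

Direction = Literal["out", "in"]


def combine_subunits(values: Sequence[float]) -> float:
    """Geometric mean of subunit values; zero if any subunit is zero."""
    if len(values) == 0:
        raise ValueError("combine_subunits requires at least one value")
    if any(v < 0 for v in values):
        raise ValueError("scaled values must be non-negative")
    if any(v == 0 for v in values):
        return 0.0
    if len(values) == 1:
        return float(values[0])
    if len(values) == 2:
        return math.sqrt(values[0] * values[1])
    return float(math.exp(sum(math.log(v) for v in values) / len(values)))


@dataclass(frozen=True)
class InteractionScore:
    interaction_id: str
    s: float
    ligand_value: float
    receptor_value: float


@dataclass
class ScoreResult:
    """Per-interaction breakdown and global score for one (j, k, direction)."""

    central_condition: str
    partner: str
    direction: Direction
    scores: dict[str, InteractionScore]
    excluded: list[str] = field(default_factory=list)
    weight: float = 1.0

    @property
    def S(self) -> float:
        return self.weight * sum(sc.s for sc in self.scores.values())

    def breakdown(self) -> pd.Series:
        return pd.Series(
            {iid: sc.s for iid, sc in self.scores.items()}, dtype=float
        ).sort_values(ascending=False)


@dataclass
class ScoreMatrix:
    """Global scores over central conditions (rows) x partners (columns)."""

    raw: pd.DataFrame
    normalized: pd.DataFrame | None = None
    rescaled: pd.DataFrame | None = None
    direction: Direction = "out"


def _side_values(
    genes: Sequence[str], column: pd.Series
) -> tuple[float | None, list[str]]:
    """Combined side value, or None plus the missing genes."""
    missing = [g for g in genes if g not in column.index]
    if missing:
        return None, missing
    return combine_subunits([float(column[g]) for g in genes]), []


def interaction_score(
    record: InteractionRecord,
    central: pd.Series,
    partner: pd.Series,
    direction: Direction = "out",
    missing_as_zero: bool = False,
) -> InteractionScore | None:
    """Score one interaction between a central and a partner profile.

    ``central`` and ``partner`` are scaled expression columns.  Returns
    ``None`` when a subunit gene is absent from its matrix (the interaction
    is not scoreable on this platform), unless ``missing_as_zero``.
    """
    if direction not in ("out", "in"):
        raise ValueError(f"direction must be 'out' or 'in', got {direction!r}")
    lig_col, rec_col = (central, partner) if direction == "out" else (partner, central)
    lig, lig_missing = _side_values(record.ligand_subunits, lig_col)
    rec, rec_missing = _side_values(record.receptor_subunits, rec_col)
    if lig_missing or rec_missing:
        if not missing_as_zero:
            return None
        lig = lig if lig is not None else 0.0
        rec = rec if rec is not None else 0.0
    return InteractionScore(
        interaction_id=record.interaction_id,
        s=lig * rec,
        ligand_value=lig,
        receptor_value=rec,
    )


def global_score(
    central: pd.Series,
    partner: pd.Series,
    db: InteractionDatabase,
    direction: Direction = "out",
    w: float = 1.0,
    missing_as_zero: bool = False,
    central_condition: str = "",
    partner_label: str = "",
) -> ScoreResult:
    """Sum per-interaction scores over the database into a global score."""
    if w <= 0:
        raise ValueError("weight w must be positive")
    scores: dict[str, InteractionScore] = {}
    excluded: list[str] = []
    for rec in db.records:
        sc = interaction_score(rec, central, partner, direction, missing_as_zero)
        if sc is None:
            excluded.append(rec.interaction_id)
        else:
            scores[rec.interaction_id] = sc
    if not scores:
        raise ValueError(
            "no scoreable interactions: every database record has a subunit "
            "gene missing from the inputs"
        )
    return ScoreResult(
        central_condition=central_condition or str(central.name),
        partner=partner_label or str(partner.name),
        direction=direction,
        scores=scores,
        excluded=excluded,
        weight=w,
    )


def score_matrix(
    central: ScaledMatrix,
    partners: ScaledMatrix,
    db: InteractionDatabase,
    direction: Direction = "out",
    w: float = 1.0,
    missing_as_zero: bool = False,
) -> ScoreMatrix:
    """Global scores for every central condition x partner pair."""
    raw = pd.DataFrame(
        index=pd.Index(central.sample_ids, name="condition"),
        columns=pd.Index(partners.sample_ids, name="partner"),
        dtype=float,
    )
    for j in central.sample_ids:
        for k in partners.sample_ids:
            raw.loc[j, k] = global_score(
                central.column(j),
                partners.column(k),
                db,
                direction,
                w=w,
                missing_as_zero=missing_as_zero,
            ).S
    return ScoreMatrix(raw=raw, direction=direction)


def score_breakdown_table(
    central: ScaledMatrix,
    partners: ScaledMatrix,
    db: InteractionDatabase,
    direction: Direction = "out",
    missing_as_zero: bool = False,
) -> pd.DataFrame:
    """Per-interaction scores, rows = interactions, columns = (j, k) pairs."""
    cols = {}
    for j in central.sample_ids:
        for k in partners.sample_ids:
            res = global_score(
                central.column(j), partners.column(k), db, direction,
                missing_as_zero=missing_as_zero,
            )
            cols[f"{j}->{k}" if direction == "out" else f"{k}->{j}"] = {
                iid: sc.s for iid, sc in res.scores.items()
            }
    return pd.DataFrame(cols).fillna(np.nan)


def family_contributions(
    result: ScoreResult,
    db: InteractionDatabase,
    by: Literal["family", "subfamily"] = "family",
) -> pd.Series:
    """Sum the per-interaction scores by family (or cytokine subfamily).

    Groups partition the breakdown, so the contributions sum to S / w.
    """
    lookup = {}
    for rec in db.records:
        if by == "family":
            lookup[rec.interaction_id] = rec.family
        else:
            lookup[rec.interaction_id] = rec.subfamily or "unclassified"
    sums: dict[str, float] = {}
    for iid, sc in result.scores.items():
        group = lookup.get(iid)
        if group is None:
            raise KeyError(f"interaction {iid!r} not found in the database")
        sums[group] = sums.get(group, 0.0) + sc.s
    return pd.Series(sums, dtype=float).sort_values(ascending=False)


def normalize_scores(
    sm: ScoreMatrix, reference_condition: str
) -> ScoreMatrix:
    """Divide every row by the reference condition's row (S / S_ref).

    The reference row becomes identically 1.  A zero reference score for
    any partner is an error naming that partner.
    """
    raw = sm.raw
    if reference_condition not in raw.index:
        raise KeyError(f"reference condition {reference_condition!r} not found")
    ref = raw.loc[reference_condition]
    zero = ref[ref == 0]
    if len(zero):
        raise ValueError(
            f"reference score is zero for partner(s) {list(zero.index)}; "
            "cannot normalize"
        )
    return ScoreMatrix(
        raw=raw, normalized=raw.div(ref, axis=1), rescaled=sm.rescaled,
        direction=sm.direction,
    )


def _minmax_rescale(frame: pd.DataFrame) -> pd.DataFrame:
    lo = float(np.nanmin(frame.to_numpy()))
    hi = float(np.nanmax(frame.to_numpy()))
    if hi == lo:
        # Degenerate: every score identical -> display everything at 10.
        return frame * 0 + 10.0
    return 1.0 + 9.0 * (frame - lo) / (hi - lo)


def rescale_scores(sm: ScoreMatrix, use_normalized: bool = False) -> ScoreMatrix:
    """Linearly map all scores in the matrix onto [1, 10].

    The minimum score maps to 1 and the maximum to 10; the map is computed
    over every entry of the matrix at once so columns stay comparable.
    """
    source = sm.normalized if use_normalized else sm.raw
    if source is None:
        raise ValueError("requested view is not present on this ScoreMatrix")
    if source.size == 0:
        raise ValueError("cannot rescale an empty score matrix")
    return ScoreMatrix(
        raw=sm.raw, normalized=sm.normalized,
        rescaled=_minmax_rescale(source), direction=sm.direction,
    )


def rescale_values(values: Iterable[float]) -> list[float]:
    """Min-max rescale a flat score collection onto [1, 10]."""
    frame = pd.DataFrame({"v": list(values)})
    if frame.empty:
        raise ValueError("need at least one score")
    return list(_minmax_rescale(frame)["v"])
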