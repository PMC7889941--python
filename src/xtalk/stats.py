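"""Statistical comparison of communication scores and robustness checks.

Two comparison modes mirror how replicate structure enters the score:

* partner comparison — the central cell's ligand side is averaged over its
  replicates while each partner replicate is scored separately, giving one
  score distribution per partner type;
* condition comparison — each central replicate is scored separately against
  the replicate-averaged partner, giving one distribution per condition.

Distributions are compared pairwise with a two-sided Wilcoxon rank-sum test
(exact null when both sides have <= 25 observations and no ties, normal
approximation with tie correction otherwise) and p-values are adjusted with
Benjamini-Hochberg over the full pairwise family of one call.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix
from .lr_database import InteractionDatabase
from .scaling import ScaledMatrix, scale_expression
from .scoring import Direction, global_score

logger = logging.getLogger(__name__)


@dataclass
class ScoreDistribution:
    """Replicate-wise communication scores for one partner or condition."""

    label: str
    scores: list[float]
    mode: Literal["partner_comparison", "condition_comparison"]

    @property
    def n(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class ComparisonResult:
    label_a: str
    label_b: str
    p_raw: float
    p_adjusted: float
    significant: bool
    test: str = "two-sided Wilcoxon rank-sum"


@dataclass
class ComparisonTable:
    """All pairwise comparisons from one call, with BH-adjusted p-values."""

    labels: list[str]
    raw: pd.DataFrame
    adjusted: pd.DataFrame
    alpha_display: float
    results: list[ComparisonResult] = field(default_factory=list)

    @property
    def significant(self) -> pd.DataFrame:
        return self.adjusted <= self.alpha_display


@dataclass
class SubsamplingReport:
    fractions: list[float]
    scores: dict[float, list[float]]
    sd: pd.Series
    seed: int
    n_rep: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fractions:
            for rep, s in enumerate(self.scores[f]):
                rows.append((f, rep, s))
        return pd.DataFrame(rows, columns=["fraction", "rep", "score"])


def _mean_profile(sm: ScaledMatrix, samples: Sequence[str] | None = None) -> pd.Series:
    cols = sm.values[list(samples)] if samples is not None else sm.values
    return cols.mean(axis=1)


def partner_comparison_scores(
    central_replicates: ScaledMatrix,
    partner_replicates: ScaledMatrix,
    db: InteractionDatabase,
    direction: Direction = "out",
) -> dict[str, ScoreDistribution]:
    """One score distribution per partner type.

    The central profile is the mean over its replicate columns; every
    partner replicate (grouped by the partner matrix's annotation) is
    scored separately against it.
    """
    central = _mean_profile(central_replicates)
    central.name = "central(mean)"
    if not partner_replicates.annotation:
        raise ValueError("partner matrix needs a replicate -> type annotation")
    groups: dict[str, list[str]] = {}
    for sample in partner_replicates.sample_ids:
        label = partner_replicates.annotation.get(sample)
        if label is None:
            logger.warning("partner replicate %r has no annotation; skipped", sample)
            continue
        groups.setdefault(label, []).append(sample)

    out = {}
    for label, samples in groups.items():
        if len(samples) < 2:
            logger.warning(
                "partner type %r has %d replicate(s); distribution returned "
                "but testing will be refused", label, len(samples),
            )
        scores = [
            global_score(
                central, partner_replicates.column(s), db, direction,
                partner_label=label,
            ).S
            for s in samples
        ]
        out[label] = ScoreDistribution(label, scores, "partner_comparison")
    return out


def condition_comparison_scores(
    central_replicates: ScaledMatrix,
    partner_mean: pd.Series,
    db: InteractionDatabase,
    direction: Direction = "out",
) -> dict[str, ScoreDistribution]:
    """One score distribution per central-cell condition.

    Mirror of :func:`partner_comparison_scores`: each central replicate is
    scored separately against the replicate-averaged partner profile.
    """
    if not central_replicates.annotation:
        raise ValueError("central matrix needs a replicate -> condition annotation")
    groups: dict[str, list[str]] = {}
    for sample in central_replicates.sample_ids:
        label = central_replicates.annotation.get(sample)
        if label is None:
            logger.warning("central replicate %r has no annotation; skipped", sample)
            continue
        groups.setdefault(label, []).append(sample)

    out = {}
    for label, samples in groups.items():
        scores = [
            global_score(
                central_replicates.column(s), partner_mean, db, direction,
                central_condition=label,
            ).S
            for s in samples
        ]
        out[label] = ScoreDistribution(label, scores, "condition_comparison")
    return out


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when both samples have <= 25 observations and
    there are no ties; otherwise the normal approximation with tie
    correction.  Two identical constant samples give p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        logger.warning("both groups constant and equal; p = 1 by convention")
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not has_ties) else "asymptotic"
    return float(
        mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH step-up adjusted p-values over one declared family of tests."""
    if len(p_values) == 0:
        return []
    return list(multipletests(list(p_values), method="fdr_bh")[1])


def compare_distributions(
    groups: Sequence[ScoreDistribution] | Mapping[str, ScoreDistribution],
    alpha_display: float = 0.1,
) -> ComparisonTable:
    """All pairwise Wilcoxon tests between score distributions, BH-adjusted."""
    if isinstance(groups, Mapping):
        groups = list(groups.values())
    if len(groups) < 2:
        raise ValueError("nothing to compare: need at least two distributions")
    for g in groups:
        if g.n < 2:
            raise ValueError(
                f"group {g.label!r} has {g.n} replicate(s); testing refused"
            )
    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        raise ValueError("distribution labels must be unique")

    pairs = [
        (i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))
    ]
    raw_p = [wilcoxon_rank_sum(groups[i].scores, groups[j].scores) for i, j in pairs]
    adj_p = benjamini_hochberg(raw_p)

    raw = pd.DataFrame(np.nan, index=labels, columns=labels)
    adj = pd.DataFrame(np.nan, index=labels, columns=labels)
    results = []
    for (i, j), p, q in zip(pairs, raw_p, adj_p):
        raw.iloc[i, j] = raw.iloc[j, i] = p
        adj.iloc[i, j] = adj.iloc[j, i] = q
        results.append(
            ComparisonResult(labels[i], labels[j], p, q, q <= alpha_display)
        )
    return ComparisonTable(
        labels=labels, raw=raw, adjusted=adj,
        alpha_display=alpha_display, results=results,
    )


def subsample_robustness(
    cluster_cells: ExpressionMatrix,
    partner_profile: pd.Series,
    db: InteractionDatabase,
    direction: Direction = "out",
    fractions: Sequence[float] = (0.1, 0.25, 0.5, 0.75, 0.9, 1.0),
    n_rep: int = 20,
    seed: int = 0,
    context: ExpressionMatrix | None = None,
    reuse_denominators: bool = False,
    top_fraction: float = 0.05,
) -> SubsamplingReport:
    """Score variability when only a fraction of a cluster's cells is used.

    For each fraction f and repetition, ``ceil(f * n_cells)`` cells are drawn
    without replacement (seeded), averaged into a pseudo-profile, max-scaled
    through the standard pipeline, and scored against the fixed (already
    scaled) ``partner_profile``; the per-fraction standard deviation of the
    ``n_rep`` scores is reported.

    ``context`` supplies additional unscaled columns (typically the other
    cluster means) that participate in the per-gene scaling so that a lone
    subsampled column does not trivially scale to 10.  With
    ``reuse_denominators`` the denominators are computed once from the full
    cluster mean plus context and reused for every subsample.
    """
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    n_cells = cluster_cells.values.shape[1]
    if n_cells < 1:
        raise ValueError("cluster has no cells")
    rng = np.random.default_rng(seed)

    context_frame = context.values if context is not None else None
    full_mean = cluster_cells.values.mean(axis=1)

    fixed_denoms = None
    if reuse_denominators:
        basis = pd.DataFrame({"__cluster__": full_mean})
        if context_frame is not None:
            basis = pd.concat([basis, context_frame], axis=1).fillna(0.0)
        fixed_denoms = scale_expression(
            ExpressionMatrix(values=basis), top_fraction
        ).denominators

    scores: dict[float, list[float]] = {}
    for f in fractions:
        size = math.ceil(f * n_cells)
        if size == 0:
            raise ValueError(f"fraction {f} selects zero cells")
        reps = []
        for _ in range(n_rep):
            chosen = rng.choice(n_cells, size=size, replace=False)
            mean = cluster_cells.values.iloc[:, chosen].mean(axis=1)
            if fixed_denoms is not None:
                with np.errstate(divide="ignore", invalid="ignore"):
                    scaled = 10.0 * mean / fixed_denoms.reindex(mean.index)
                scaled = scaled.where(fixed_denoms.reindex(mean.index) > 0, 0.0)
                column = scaled.clip(upper=10.0)
            else:
                frame = pd.DataFrame({"__sub__": mean})
                if context_frame is not None:
                    frame = pd.concat([frame, context_frame], axis=1).fillna(0.0)
                column = scale_expression(
                    ExpressionMatrix(values=frame), top_fraction
                ).column("__sub__")
            # The subsampled cluster is always the central cell; global_score
            # swaps ligand/receptor roles internally for direction "in".
            reps.append(global_score(column, partner_profile, db, direction).S)
        scores[f] = reps

    sd = pd.Series(
        {f: float(np.std(scores[f], ddof=1)) if n_rep > 1 else 0.0 for f in fractions},
        name="sd",
    )
    return SubsamplingReport(
        fractions=list(fractions), scores=scores, sd=sd, seed=seed, n_rep=n_rep
    )
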