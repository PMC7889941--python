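"""Per-gene max-scaling of expression values onto [0, 10].

For each gene the scaling denominator is the mean of its ``k`` largest
values across the dataset's samples, with ``k = max(1, ceil(top_fraction *
n_samples))`` (default top 5%).  Values are multiplied by ``10 / denom`` and
outliers above the denominator are capped at 10.  Genes that are zero
everywhere stay all-zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix


@dataclass
class ScaledMatrix:
    """Gene-by-sample values in [0, 10] plus the per-gene denominators."""

    values: pd.DataFrame
    denominators: pd.Series
    annotation: dict[str, str] = field(default_factory=dict)
    provenance: str = ""

    def column(self, sample: str) -> pd.Series:
        return self.values[sample]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_with_label(self, label: str) -> list[str]:
        return [s for s, lab in self.annotation.items() if lab == label]

    def subset(self, samples: Sequence[str]) -> "ScaledMatrix":
        return ScaledMatrix(
            values=self.values[list(samples)],
            denominators=self.denominators,
            annotation={s: v for s, v in self.annotation.items() if s in set(samples)},
            provenance=self.provenance,
        )


def top_fraction_mean(row: np.ndarray, top_fraction: float) -> float:
    """Mean of the ``k = max(1, ceil(top_fraction * n))`` largest values."""
    n = row.size
    k = max(1, math.ceil(top_fraction * n))
    if k >= n:
        return float(row.mean())
    part = np.partition(row, n - k)[n - k:]
    return float(part.mean())


def scale_expression(
    m: ExpressionMatrix,
    top_fraction: float = 0.05,
    samples: Sequence[str] | None = None,
    provenance: str = "",
) -> ScaledMatrix:
    """Max-scale each gene of *m* to [0, 10].

    Parameters
    ----------
    m
        Non-negative expression matrix.
    top_fraction
        Fraction of highest values whose mean defines the per-gene maximum;
        must lie in (0, 1].
    samples
        If given, denominators are computed from this sample subset only
        (sensitivity analysis); all columns are still scaled and returned.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    frame = m.values
    basis = frame[list(samples)] if samples is not None else frame
    if basis.shape[1] == 0:
        raise ValueError("no samples to compute scaling denominators from")

    denoms = pd.Series(
        np.apply_along_axis(top_fraction_mean, 1, basis.to_numpy(), top_fraction)
        if basis.size
        else np.zeros(frame.shape[0]),
        index=frame.index,
        name="denominator",
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = 10.0 * frame.to_numpy() / denoms.to_numpy()[:, None]
    scaled = np.where(denoms.to_numpy()[:, None] > 0, scaled, 0.0)
    scaled = np.minimum(scaled, 10.0)
    return ScaledMatrix(
        values=pd.DataFrame(scaled, index=frame.index, columns=frame.columns),
        denominators=denoms,
        annotation=dict(m.annotation),
        provenance=provenance,
    )
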