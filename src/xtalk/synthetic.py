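"""Seeded synthetic databases and expression datasets with known scores.

The generators plant ligand programs in a central dataset (two or more
conditions with replicates) and receptor programs in a partner dataset, and
ship a closed-form computation of the scores the pipeline should produce on
the noiseless data.  The closed form below is written as plain loops,
independent of the scaling and scoring modules, so it can serve as an
oracle for them.

The default noise model is multiplicative lognormal with unit mean; this is
a fixture choice, not a biological claim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .expression import ExpressionMatrix, write_expression_table, write_sparse_counts
from .lr_database import (
    CYTOKINE_SUBFAMILIES,
    FAMILIES,
    InteractionDatabase,
    InteractionRecord,
    write_database,
)


@dataclass
class SyntheticConfig:
    n_interactions: int = 10
    multi_ligand_fraction: float = 0.2
    multi_receptor_fraction: float = 0.3
    n_extra_genes: int = 5  # non-database genes padded into the matrices
    n_conditions: int = 2
    replicates_per_condition: int = 3
    n_partner_types: int = 3
    replicates_per_type: int = 3
    n_cells_per_cluster: int = 50
    ligand_level_range: tuple[float, float] = (1.0, 10.0)
    receptor_level_range: tuple[float, float] = (1.0, 10.0)
    noise_sigma: float = 0.0
    effect_size: float = 2.0  # condition-1 ligand multiplier vs condition 0
    top_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_interactions", "n_conditions", "replicates_per_condition",
            "n_partner_types", "replicates_per_type", "n_cells_per_cluster",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")


def generate_toy_database(cfg: SyntheticConfig) -> InteractionDatabase:
    """Deterministic toy database with disjoint genes per interaction.

    Interaction ``i`` owns its own ligand and receptor gene symbols, so
    per-interaction scores never share genes and closed forms stay simple.
    Families cycle through the closed vocabulary; cytokine records cycle
    through the subfamily vocabulary.
    """
    n_multi_l = round(cfg.multi_ligand_fraction * cfg.n_interactions)
    n_multi_r = round(cfg.multi_receptor_fraction * cfg.n_interactions)
    records = []
    for i in range(cfg.n_interactions):
        ligs = (f"LIG{i}A", f"LIG{i}B") if i < n_multi_l else (f"LIG{i}A",)
        recs = (f"REC{i}A", f"REC{i}B") if i < n_multi_r else (f"REC{i}A",)
        family = FAMILIES[i % len(FAMILIES)]
        subfamily = ""
        if family == "Cytokine":
            subfamily = CYTOKINE_SUBFAMILIES[i % len(CYTOKINE_SUBFAMILIES)]
        records.append(
            InteractionRecord(
                interaction_id="{} / {}".format("+".join(ligs), "+".join(recs)),
                ligand_subunits=ligs,
                receptor_subunits=recs,
                family=family,
                subfamily=subfamily,
                sources=(str(10_000_000 + i),),
            )
        )
    return InteractionDatabase(records=records)


def _closed_form_scaled(values: dict[str, list[float]], n_columns_per_value: int,
                        top_fraction: float) -> dict[str, list[float]]:
    """Scale planted per-group values exactly as the pipeline would.

    Each group value appears ``n_columns_per_value`` times in the dataset
    (identical replicates).  Plain-python re-statement of the top-fraction
    max-scaling rule; deliberately independent of :mod:`xtalk.scaling`.
    """
    out = {}
    for gene, groups in values.items():
        expanded = sorted(
            [v for v in groups for _ in range(n_columns_per_value)]
        )
        n = len(expanded)
        k = max(1, math.ceil(top_fraction * n))
        denom = sum(expanded[-k:]) / k
        if denom == 0:
            out[gene] = [0.0 for _ in groups]
        else:
            out[gene] = [min(10.0, 10.0 * v / denom) for v in groups]
    return out


def _geo_mean(vals: list[float]) -> float:
    if any(v == 0 for v in vals):
        return 0.0
    return math.exp(sum(math.log(v) for v in vals) / len(vals))


@dataclass
class BulkDataset:
    central: ExpressionMatrix
    partners: ExpressionMatrix
    expected_scores: pd.DataFrame  # conditions x partner types (noiseless)
    expected_breakdown: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=dict
    )


def generate_bulk_dataset(
    cfg: SyntheticConfig, db: InteractionDatabase
) -> BulkDataset:
    """Central + partner expression matrices with closed-form expected scores.

    Ligand genes are planted in the central matrix (condition 1 levels are
    ``effect_size`` times condition 0), receptor genes in the partner
    matrix.  With ``noise_sigma == 0`` replicates are identical and the
    pipeline's outward score matrix must equal ``expected_scores`` exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    lig_genes = sorted({g for r in db.records for g in r.ligand_subunits})
    rec_genes = sorted({g for r in db.records for g in r.receptor_subunits})

    lo, hi = cfg.ligand_level_range
    lig_levels = {}
    for g in lig_genes:
        base = float(rng.uniform(lo, hi))
        lig_levels[g] = [
            base * (cfg.effect_size if c >= 1 else 1.0)
            for c in range(cfg.n_conditions)
        ]
    rlo, rhi = cfg.receptor_level_range
    rec_levels = {
        g: [float(rng.uniform(rlo, rhi)) for _ in range(cfg.n_partner_types)]
        for g in rec_genes
    }

    conditions = [f"cond{c}" for c in range(cfg.n_conditions)]
    ptypes = [f"type{t}" for t in range(cfg.n_partner_types)]

    def noise(shape):
        if cfg.noise_sigma == 0:
            return np.ones(shape)
        # unit-mean lognormal so planted levels stay the expected values
        return rng.lognormal(
            mean=-cfg.noise_sigma**2 / 2, sigma=cfg.noise_sigma, size=shape
        )

    def build(levels, groups, reps, prefix, foreign_genes):
        cols, annotation = {}, {}
        for gi, group in enumerate(groups):
            for r in range(reps):
                name = f"{group}_{prefix}{r}"
                annotation[name] = group
                cols[name] = [levels[g][gi] for g in levels]
        frame = pd.DataFrame(cols, index=list(levels))
        frame = frame * noise(frame.shape)
        # genes from the other side plus padding, all zero: present on the
        # platform but silent in this dataset
        for g in foreign_genes:
            frame.loc[g] = 0.0
        for e in range(cfg.n_extra_genes):
            frame.loc[f"{prefix.upper()}PAD{e}"] = float(rng.uniform(lo, hi))
        return ExpressionMatrix(values=frame, annotation=annotation)

    central = build(
        lig_levels, conditions, cfg.replicates_per_condition, "rep",
        [g for g in rec_genes if g not in lig_genes],
    )
    partners = build(
        rec_levels, ptypes, cfg.replicates_per_type, "smp",
        [g for g in lig_genes if g not in rec_genes],
    )

    # --- closed-form expected scores on the noiseless planted values -----
    lig_scaled = _closed_form_scaled(
        lig_levels, cfg.replicates_per_condition, cfg.top_fraction
    )
    rec_scaled = _closed_form_scaled(
        rec_levels, cfg.replicates_per_type, cfg.top_fraction
    )
    expected = pd.DataFrame(
        0.0, index=pd.Index(conditions, name="condition"),
        columns=pd.Index(ptypes, name="partner"),
    )
    breakdown: dict[tuple[str, str], dict[str, float]] = {}
    for ci, cond in enumerate(conditions):
        for ti, ptype in enumerate(ptypes):
            per = {}
            for rec in db.records:
                l = _geo_mean([lig_scaled[g][ci] for g in rec.ligand_subunits])
                r = _geo_mean([rec_scaled[g][ti] for g in rec.receptor_subunits])
                per[rec.interaction_id] = l * r
            breakdown[(cond, ptype)] = per
            expected.loc[cond, ptype] = sum(per.values())
    return BulkDataset(
        central=central, partners=partners,
        expected_scores=expected, expected_breakdown=breakdown,
    )


@dataclass
class SingleCellDataset:
    cells: ExpressionMatrix
    assignment: dict[str, str]
    expected_means: pd.DataFrame  # genes x clusters (planted means)


def generate_sc_dataset(
    cfg: SyntheticConfig, db: InteractionDatabase
) -> SingleCellDataset:
    """Cluster-labelled single-cell matrix around planted cluster means.

    One cluster per partner type, ``n_cells_per_cluster`` cells each; cells
    equal the planted mean exactly when ``noise_sigma == 0`` and otherwise
    carry unit-mean lognormal noise, so :func:`xtalk.expression
    .cluster_average` recovers the means with error shrinking as 1/sqrt(n).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    genes = sorted(db.gene_universe)
    clusters = [f"cluster{t}" for t in range(cfg.n_partner_types)]
    lo, hi = cfg.receptor_level_range
    means = pd.DataFrame(
        rng.uniform(lo, hi, size=(len(genes), len(clusters))),
        index=genes, columns=clusters,
    )

    cols, assignment = {}, {}
    for cl in clusters:
        for i in range(cfg.n_cells_per_cluster):
            cid = f"{cl}_cell{i}"
            assignment[cid] = cl
            base = means[cl].to_numpy()
            if cfg.noise_sigma == 0:
                cols[cid] = base
            else:
                cols[cid] = base * rng.lognormal(
                    -cfg.noise_sigma**2 / 2, cfg.noise_sigma, size=base.shape
                )
    cells = ExpressionMatrix(values=pd.DataFrame(cols, index=genes))
    return SingleCellDataset(cells=cells, assignment=assignment, expected_means=means)


def required_replicates(
    effect_size: float, sigma: float, alpha: float = 0.1, power: float = 0.8
) -> int:
    """Replicates per group for a two-sided Wilcoxon test to reach *power*.

    Noether's approximation with equal group sizes: with
    ``p = P(X1 > X0) = Phi(ln(effect) / (sqrt(2) * sigma))`` for unit-mean
    lognormal noise around planted levels differing by ``effect_size``,

        n_per_group = (z_{1-alpha/2} + z_power)^2 / (6 * (p - 1/2)^2).
    """
    if effect_size == 1 or sigma == 0:
        return 2  # separation is deterministic; any testable n works
    p = norm.cdf(math.log(effect_size) / (math.sqrt(2) * sigma))
    z = norm.ppf(1 - alpha / 2) + norm.ppf(power)
    return max(2, math.ceil(z**2 / (6 * (p - 0.5) ** 2)))


def write_fixture_tree(cfg: SyntheticConfig, db: InteractionDatabase,
                       outdir: str | Path) -> dict[str, Path]:
    """Write a full synthetic fixture in the formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bulk = generate_bulk_dataset(cfg, db)
    sc = generate_sc_dataset(cfg, db)

    paths = {
        "database": outdir / "lr_pairs.tsv",
        "central": outdir / "central.tsv",
        "partners": outdir / "partners.tsv",
        "central_annotation": outdir / "central_annotation.tsv",
        "partner_annotation": outdir / "partner_annotation.tsv",
        "expected_scores": outdir / "expected_scores.tsv",
        "sc_matrix": outdir / "counts.mtx",
        "sc_genes": outdir / "genes.txt",
        "sc_cells": outdir / "cells.txt",
        "sc_assignment": outdir / "clusters.tsv",
    }
    write_database(db, paths["database"])
    write_expression_table(bulk.central, paths["central"])
    write_expression_table(bulk.partners, paths["partners"])
    for key, m in (("central_annotation", bulk.central),
                   ("partner_annotation", bulk.partners)):
        pd.Series(m.annotation).to_csv(paths[key], sep="\t", header=False)
    bulk.expected_scores.to_csv(paths["expected_scores"], sep="\t")
    write_sparse_counts(sc.cells, paths["sc_matrix"], paths["sc_genes"],
                        paths["sc_cells"])
    pd.Series(sc.assignment).to_csv(paths["sc_assignment"], sep="\t", header=False)
    return paths
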