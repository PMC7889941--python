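"""Curated multi-subunit ligand-receptor interaction database.

A record pairs an ordered tuple of ligand subunit gene symbols with an
ordered tuple of receptor subunit gene symbols, carries a family label from
a closed vocabulary (cytokine records additionally carry a structural
subfamily), and provenance PubMed identifiers.  The shipped database file
is a plain TSV whose column layout is described by a "dialect" mapping so
that externally curated files with different headers load unmodified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Closed family vocabulary.  Families outside the six named ones are
#: grouped under "other".
FAMILIES = (
    "Growth factor",
    "Cytokine",
    "Chemokine",
    "Checkpoint",
    "Notch signaling",
    "Antigen binding",
    "other",
)

#: Structural subfamilies recognised for cytokine records.
CYTOKINE_SUBFAMILIES = (
    "type 1",
    "type 2",
    "IL-1 family",
    "IL-17 family",
    "TNF family",
    "TGF family",
    "RTK",
    "unclassified",
)

_FAMILY_LOOKUP = {f.lower(): f for f in FAMILIES}
_SUBFAMILY_LOOKUP = {s.lower(): s for s in CYTOKINE_SUBFAMILIES}

#: Column roles -> column names for the shipped database file.
DEFAULT_DIALECT: Mapping[str, Sequence[str] | str] = {
    "ligand_subunits": ("Ligand 1", "Ligand 2"),
    "receptor_subunits": ("Receptor 1", "Receptor 2"),
    "family": "Family",
    "subfamily": "Subfamily",
    "sources": "PubMed ID",
}


class DatabaseSchemaError(ValueError):
    """Raised when mandatory columns are absent from a database file."""


@dataclass(frozen=True)
class InteractionRecord:
    """One ligand-receptor interaction with >=1 subunit per side."""

    interaction_id: str
    ligand_subunits: tuple[str, ...]
    receptor_subunits: tuple[str, ...]
    family: str = "other"
    subfamily: str = ""
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.ligand_subunits or not self.receptor_subunits:
            raise ValueError(
                f"{self.interaction_id!r}: both sides need at least one subunit"
            )
        for side, subunits in (
            ("ligand", self.ligand_subunits),
            ("receptor", self.receptor_subunits),
        ):
            if any(not s for s in subunits):
                raise ValueError(f"{self.interaction_id!r}: empty {side} symbol")
            if len(set(subunits)) != len(subunits):
                raise ValueError(
                    f"{self.interaction_id!r}: duplicate {side} subunit symbols"
                )
        # Out-of-vocabulary families are tolerated here so that
        # validate_database can report them; load_database normalizes.

    @property
    def pair(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        return (self.ligand_subunits, self.receptor_subunits)

    @property
    def genes(self) -> set[str]:
        return set(self.ligand_subunits) | set(self.receptor_subunits)

    def label(self) -> str:
        """Human-readable ``LIG1+LIG2 / REC1+REC2`` key."""
        return "{} / {}".format(
            "+".join(self.ligand_subunits), "+".join(self.receptor_subunits)
        )


@dataclass
class InteractionDatabase:
    """An ordered collection of unique interaction records."""

    records: list[InteractionRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def gene_universe(self) -> set[str]:
        universe: set[str] = set()
        for rec in self.records:
            universe |= rec.genes
        return universe

    def families(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.family] = counts.get(rec.family, 0) + 1
        return counts

    def subfamilies(self, family: str = "Cytokine") -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            if rec.family == family:
                key = rec.subfamily or "unclassified"
                counts[key] = counts.get(key, 0) + 1
        return counts


@dataclass(frozen=True)
class ValidationFinding:
    kind: str  # duplicate_pair | empty_side | bad_family | bad_subfamily | bad_source
    interaction_id: str
    message: str
    suggestion: str = ""


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.findings)

    @property
    def ok(self) -> bool:
        return not self.findings

    def by_kind(self, kind: str) -> list[ValidationFinding]:
        return [f for f in self.findings if f.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (f.kind, f.interaction_id, f.message, f.suggestion)
                for f in self.findings
            ],
            columns=["kind", "interaction_id", "message", "suggestion"],
        )


def _normalize_family(raw: str) -> str:
    raw = raw.strip()
    return _FAMILY_LOOKUP.get(raw.lower(), "other")


def _normalize_subfamily(raw: str) -> str:
    raw = raw.strip()
    if not raw:
        return ""
    return _SUBFAMILY_LOOKUP.get(raw.lower(), raw)


def _subunit_columns(dialect: Mapping, role: str) -> list[str]:
    cols = dialect[role]
    if isinstance(cols, str):
        return [cols]
    return list(cols)


def load_database(
    path: str | Path,
    dialect: Mapping[str, Sequence[str] | str] | None = None,
) -> InteractionDatabase:
    """Load a delimited database file into an :class:`InteractionDatabase`.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file with one interaction per row.
    dialect
        Mapping from column roles (``ligand_subunits``, ``receptor_subunits``,
        ``family``, ``subfamily``, ``sources``) to header names.  Defaults to
        the layout of the shipped database.

    Rows with an empty ligand or receptor side are skipped and logged; later
    duplicates of an already-seen (ligand set, receptor set) pair are skipped
    and logged so that global scores never double-count a channel.
    """
    path = Path(path)
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep, dtype=str).fillna("")

    lig_cols = _subunit_columns(dialect, "ligand_subunits")
    rec_cols = _subunit_columns(dialect, "receptor_subunits")
    missing = [c for c in lig_cols + rec_cols if c not in table.columns]
    if not lig_cols or not rec_cols:
        raise DatabaseSchemaError("dialect must name ligand and receptor columns")
    if missing:
        raise DatabaseSchemaError(
            f"{path}: missing mandatory columns {missing}; found "
            f"{list(table.columns)}"
        )

    fam_col = dialect.get("family")
    sub_col = dialect.get("subfamily")
    src_col = dialect.get("sources")

    records: list[InteractionRecord] = []
    seen: dict[tuple[frozenset[str], frozenset[str]], str] = {}
    skipped: list[str] = []
    for idx, row in table.iterrows():
        ligs = tuple(row[c].strip() for c in lig_cols if row[c].strip())
        recs = tuple(row[c].strip() for c in rec_cols if row[c].strip())
        rid = f"{path.name}:{idx + 2}"  # 1-based line number incl. header
        if not ligs or not recs:
            skipped.append(f"{rid}: empty ligand or receptor side")
            continue
        key = (frozenset(ligs), frozenset(recs))
        if key in seen:
            skipped.append(f"{rid}: duplicate of {seen[key]}")
            continue
        seen[key] = rid
        family = _normalize_family(row[fam_col]) if fam_col in table.columns else "other"
        subfamily = (
            _normalize_subfamily(row[sub_col]) if sub_col in table.columns else ""
        )
        sources = ()
        if src_col in table.columns and row[src_col].strip():
            sources = tuple(
                s.strip() for s in str(row[src_col]).replace(";", ",").split(",")
                if s.strip()
            )
        records.append(
            InteractionRecord(
                interaction_id="{} / {}".format("+".join(ligs), "+".join(recs)),
                ligand_subunits=ligs,
                receptor_subunits=recs,
                family=family,
                subfamily=subfamily,
                sources=sources,
            )
        )
    for msg in skipped:
        logger.warning("load_database: skipped row %s", msg)
    return InteractionDatabase(records=records)


def write_database(db: InteractionDatabase, path: str | Path) -> None:
    """Serialize *db* using the shipped file layout (round-trips with load)."""
    path = Path(path)
    rows = []
    for rec in db.records:
        lig = list(rec.ligand_subunits) + [""] * (2 - len(rec.ligand_subunits))
        rcp = list(rec.receptor_subunits) + [""] * (2 - len(rec.receptor_subunits))
        rows.append(lig[:2] + rcp[:2] + [rec.family, rec.subfamily, ",".join(rec.sources)])
    frame = pd.DataFrame(
        rows,
        columns=[
            "Ligand 1", "Ligand 2", "Receptor 1", "Receptor 2",
            "Family", "Subfamily", "PubMed ID",
        ],
    )
    frame.to_csv(path, sep="\t", index=False)


def default_database() -> InteractionDatabase:
    """Load the curated database shipped with the package."""
    with resources.as_file(
        resources.files("xtalk").joinpath("data/lr_pairs.tsv")
    ) as p:
        return load_database(p)


def filter_database(
    db: InteractionDatabase,
    families: Iterable[str] | None = None,
    subfamilies: Iterable[str] | None = None,
    genes: Iterable[str] | None = None,
) -> InteractionDatabase:
    """Return the sub-database matching every provided criterion.

    The gene filter keeps a record iff *all* its subunit symbols (both sides)
    are contained in ``genes``.  Passing no criteria returns an identical
    database.
    """
    if families is not None:
        families = {_FAMILY_LOOKUP.get(f.strip().lower()) for f in families}
        if None in families:
            raise ValueError(f"unknown family; valid names are {FAMILIES}")
    if subfamilies is not None:
        subfamilies = {_normalize_subfamily(s) for s in subfamilies}
    if genes is not None:
        genes = set(genes)

    kept = []
    for rec in db.records:
        if families is not None and rec.family not in families:
            continue
        if subfamilies is not None and rec.subfamily not in subfamilies:
            continue
        if genes is not None and not rec.genes <= genes:
            continue
        kept.append(rec)
    return InteractionDatabase(records=kept)


def validate_database(db: InteractionDatabase) -> ValidationReport:
    """Report structural problems without modifying the database.

    Checks duplicate (ligand set, receptor set) pairs, out-of-vocabulary
    family/subfamily labels, and malformed PubMed identifiers.
    """
    report = ValidationReport()
    seen: dict[tuple[frozenset[str], frozenset[str]], str] = {}
    for rec in db.records:
        key = (frozenset(rec.ligand_subunits), frozenset(rec.receptor_subunits))
        if key in seen:
            report.findings.append(
                ValidationFinding(
                    "duplicate_pair",
                    rec.interaction_id,
                    f"duplicates {seen[key]}",
                    "keep first occurrence",
                )
            )
        else:
            seen[key] = rec.interaction_id
        if rec.family not in FAMILIES:
            report.findings.append(
                ValidationFinding(
                    "bad_family",
                    rec.interaction_id,
                    f"family {rec.family!r} not in vocabulary",
                    "other",
                )
            )
        if (
            rec.family == "Cytokine"
            and rec.subfamily
            and rec.subfamily not in CYTOKINE_SUBFAMILIES
        ):
            report.findings.append(
                ValidationFinding(
                    "bad_subfamily",
                    rec.interaction_id,
                    f"subfamily {rec.subfamily!r} not in vocabulary",
                    "unclassified",
                )
            )
        for src in rec.sources:
            if src and not src.isdigit():
                report.findings.append(
                    ValidationFinding(
                        "bad_source",
                        rec.interaction_id,
                        f"PubMed ID {src!r} is not numeric",
                    )
                )
    return report
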