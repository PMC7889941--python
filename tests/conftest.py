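import pandas as pd
import pytest

from xtalk.expression import ExpressionMatrix
from xtalk.lr_database import InteractionDatabase, InteractionRecord
from xtalk.scaling import ScaledMatrix


def make_record(lig, rec, family="other", subfamily="", sources=("12345",)):
    ligs = tuple(lig.split("+"))
    recs = tuple(rec.split("+"))
    return InteractionRecord(
        interaction_id=f"{lig} / {rec}",
        ligand_subunits=ligs,
        receptor_subunits=recs,
        family=family,
        subfamily=subfamily,
        sources=sources,
    )


@pytest.fixture
def toy_db():
    """3 interactions, 8 distinct gene symbols total."""
    return InteractionDatabase(records=[
        make_record("IL12A+IL12B", "IL12RB1+IL12RB2", "Cytokine", "type 1"),
        make_record("CD86", "CD28", "Checkpoint"),
        make_record("CCL22", "CCR4", "Chemokine"),
    ])


@pytest.fixture
def toy_db_file(tmp_path, toy_db):
    from xtalk.lr_database import write_database

    path = tmp_path / "toy_db.tsv"
    write_database(toy_db, path)
    return path


def scaled_column(values: dict, name="col") -> pd.Series:
    return pd.Series(values, name=name, dtype=float)


def make_scaled(frame: pd.DataFrame, annotation=None) -> ScaledMatrix:
    """Wrap already-scaled values (tests plant values directly in [0, 10])."""
    return ScaledMatrix(
        values=frame.astype(float),
        denominators=pd.Series(1.0, index=frame.index),
        annotation=annotation or {},
    )


@pytest.fixture
def toy_expression():
    frame = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 3.0],
            "s2": [4.0, 5.0, 6.0],
        },
        index=["CD86", "CD28", "CCL22"],
    )
    return ExpressionMatrix(values=frame)
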