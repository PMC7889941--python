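import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_record, make_scaled, scaled_column
from xtalk.lr_database import InteractionDatabase, filter_database
from xtalk.scoring import (
    ScoreMatrix,
    combine_subunits,
    family_contributions,
    global_score,
    interaction_score,
    normalize_scores,
    rescale_scores,
    rescale_values,
    score_matrix,
)


class TestCombineSubunits:
    def test_single_value_identity(self):
        assert combine_subunits([6.0]) == 6.0

    def test_geometric_mean_of_two(self):
        assert combine_subunits([9.0, 4.0]) == pytest.approx(6.0)

    def test_zero_propagates(self):
        assert combine_subunits([5.0, 0.0]) == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            combine_subunits([])

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            combine_subunits([-1.0])

    def test_zero_propagation_every_position(self):
        for n in (1, 2, 3):
            for zero_at in range(n):
                vals = [4.0] * n
                vals[zero_at] = 0.0
                assert combine_subunits(vals) == 0.0

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.001, 10), min_size=1, max_size=4))
    def test_matches_numpy_geometric_mean(self, vals):
        expected = float(np.exp(np.mean(np.log(vals))))
        assert combine_subunits(vals) == pytest.approx(expected)


class TestInteractionScore:
    def test_simple_product_outward(self):
        rec = make_record("CD86", "CD28")
        s = interaction_score(
            rec, scaled_column({"CD86": 4.0}), scaled_column({"CD28": 3.0}), "out"
        )
        assert s.s == 12.0

    def test_zero_ligand_subunit_zeroes_score(self):
        rec = make_record("IL12A+IL12B", "IL12RB1+IL12RB2")
        s = interaction_score(
            rec,
            scaled_column({"IL12A": 4.0, "IL12B": 0.0}),
            scaled_column({"IL12RB1": 5.0, "IL12RB2": 5.0}),
        )
        assert s.s == 0.0

    def test_two_geometric_means(self):
        rec = make_record("IL12A+IL12B", "IL12RB1+IL12RB2")
        s = interaction_score(
            rec,
            scaled_column({"IL12A": 4.0, "IL12B": 9.0}),
            scaled_column({"IL12RB1": 9.0, "IL12RB2": 4.0}),
        )
        assert s.s == pytest.approx(36.0)
        assert s.ligand_value == pytest.approx(6.0)
        assert s.receptor_value == pytest.approx(6.0)

    def test_inward_swaps_roles(self):
        rec = make_record("CD86", "CD28")
        central = scaled_column({"CD86": 4.0, "CD28": 7.0})
        partner = scaled_column({"CD86": 2.0, "CD28": 3.0})
        out = interaction_score(rec, central, partner, "out")
        inward = interaction_score(rec, central, partner, "in")
        assert out.s == 4.0 * 3.0
        assert inward.s == 2.0 * 7.0

    def test_missing_gene_excluded(self):
        rec = make_record("CD86", "CD28")
        s = interaction_score(
            rec, scaled_column({"CD86": 4.0}), scaled_column({"OTHER": 1.0})
        )
        assert s is None

    def test_missing_gene_zero_imputation_flag(self):
        rec = make_record("CD86", "CD28")
        s = interaction_score(
            rec, scaled_column({"CD86": 4.0}), scaled_column({"OTHER": 1.0}),
            missing_as_zero=True,
        )
        assert s.s == 0.0

    def test_bad_direction(self):
        rec = make_record("CD86", "CD28")
        with pytest.raises(ValueError, match="direction"):
            interaction_score(rec, scaled_column({"CD86": 1}),
                              scaled_column({"CD28": 1}), "sideways")


@pytest.fixture
def toy_profiles(toy_db):
    central = scaled_column(
        {"IL12A": 0.0, "IL12B": 0.0, "CD86": 4.0, "CCL22": 4.0,
         "IL12RB1": 0.0, "IL12RB2": 0.0, "CD28": 0.0, "CCR4": 0.0},
        name="central",
    )
    partner = scaled_column(
        {"IL12A": 0.0, "IL12B": 0.0, "CD86": 0.0, "CCL22": 0.0,
         "IL12RB1": 1.0, "IL12RB2": 1.0, "CD28": 3.0, "CCR4": 5.0},
        name="partner",
    )
    return central, partner


class TestGlobalScore:
    def test_sum_of_breakdown(self, toy_db, toy_profiles):
        central, partner = toy_profiles
        res = global_score(central, partner, toy_db)
        # CD86/CD28 = 12, CCL22/CCR4 = 20, IL12 = 0
        assert res.S == pytest.approx(32.0)
        assert res.scores["CD86 / CD28"].s == 12.0

    def test_weight_scales_s_not_ratios(self, toy_db, toy_profiles):
        central, partner = toy_profiles
        res1 = global_score(central, partner, toy_db, w=1.0)
        res2 = global_score(central, partner, toy_db, w=2.0)
        assert res2.S == pytest.approx(2 * res1.S)
        pd.testing.assert_series_equal(res1.breakdown(), res2.breakdown())

    def test_no_scoreable_interactions_raises(self, toy_db):
        empty = scaled_column({"UNRELATED": 1.0})
        with pytest.raises(ValueError, match="no scoreable"):
            global_score(empty, empty, toy_db)

    def test_empty_family_filter_raises(self, toy_db, toy_profiles):
        central, partner = toy_profiles
        sub = filter_database(toy_db, families=["Growth factor"])
        with pytest.raises(ValueError):
            global_score(central, partner, sub)

    def test_excluded_interactions_reported(self, toy_db):
        central = scaled_column({"CD86": 4.0, "CCL22": 1.0})
        partner = scaled_column({"CD28": 3.0, "CCR4": 1.0})
        res = global_score(central, partner, toy_db)
        assert "IL12A+IL12B / IL12RB1+IL12RB2" in res.excluded

    def test_additivity_over_disjoint_databases(self, toy_db, toy_profiles):
        central, partner = toy_profiles
        d1 = InteractionDatabase(records=toy_db.records[:2])
        d2 = InteractionDatabase(records=toy_db.records[2:])
        s_union = global_score(central, partner, toy_db).S
        assert s_union == pytest.approx(
            global_score(central, partner, d1).S
            + global_score(central, partner, d2).S
        )

    def test_outward_monotone_in_ligand_value(self, toy_db, toy_profiles):
        central, partner = toy_profiles
        base = global_score(central, partner, toy_db).S
        bumped = central.copy()
        bumped["CD86"] = 9.0
        assert global_score(bumped, partner, toy_db).S >= base

    def test_direction_duality(self, toy_db):
        rng = np.random.default_rng(0)
        genes = sorted(toy_db.gene_universe)
        a = scaled_column(dict(zip(genes, rng.uniform(0, 10, len(genes)))), "A")
        b = scaled_column(dict(zip(genes, rng.uniform(0, 10, len(genes)))), "B")
        out_ab = global_score(a, b, toy_db, "out").S
        in_ba = global_score(b, a, toy_db, "in").S
        assert out_ab == pytest.approx(in_ba)


def _oracle_score(db, central, partner):
    """Independent per-interaction loop with its own geometric mean."""
    total = 0.0
    for rec in db.records:
        lig = [central[g] for g in rec.ligand_subunits]
        rcp = [partner[g] for g in rec.receptor_subunits]
        l = 0.0 if any(v == 0 for v in lig) else math.prod(lig) ** (1 / len(lig))
        r = 0.0 if any(v == 0 for v in rcp) else math.prod(rcp) ** (1 / len(rcp))
        total += l * r
    return total


class TestScoreMatrix:
    def _random_setup(self, rng, n_interactions=4):
        records = []
        for i in range(n_interactions):
            nl = rng.integers(1, 3)
            nr = rng.integers(1, 3)
            lig = "+".join(f"L{i}_{k}" for k in range(nl))
            rec = "+".join(f"R{i}_{k}" for k in range(nr))
            records.append(make_record(lig, rec))
        db = InteractionDatabase(records=records)
        genes = sorted(db.gene_universe)
        vals = rng.uniform(0, 10, size=len(genes))
        vals[rng.random(len(genes)) < 0.2] = 0.0
        central = scaled_column(dict(zip(genes, vals)), "c")
        partner = scaled_column(
            dict(zip(genes, rng.uniform(0, 10, len(genes)))), "p"
        )
        return db, central, partner

    def test_single_pair_reduces_to_global_score(self, toy_db, toy_profiles):
        central, partner = toy_profiles
        cs = make_scaled(central.to_frame())
        ps = make_scaled(partner.to_frame())
        sm = score_matrix(cs, ps, toy_db)
        assert sm.raw.loc["central", "partner"] == pytest.approx(
            global_score(central, partner, toy_db).S
        )

    def test_grid_matches_independent_calls(self, toy_db):
        rng = np.random.default_rng(5)
        genes = sorted(toy_db.gene_universe)
        cs = make_scaled(pd.DataFrame(
            rng.uniform(0, 10, (len(genes), 2)), index=genes, columns=["j0", "j1"]
        ))
        ps = make_scaled(pd.DataFrame(
            rng.uniform(0, 10, (len(genes), 3)), index=genes,
            columns=["k0", "k1", "k2"],
        ))
        sm = score_matrix(cs, ps, toy_db)
        for j in ["j0", "j1"]:
            for k in ["k0", "k1", "k2"]:
                assert sm.raw.loc[j, k] == pytest.approx(
                    global_score(cs.column(j), ps.column(k), toy_db).S
                )

    def test_partner_permutation_equivariance(self, toy_db):
        rng = np.random.default_rng(6)
        genes = sorted(toy_db.gene_universe)
        cs = make_scaled(pd.DataFrame(
            rng.uniform(0, 10, (len(genes), 1)), index=genes, columns=["j"]
        ))
        ps = make_scaled(pd.DataFrame(
            rng.uniform(0, 10, (len(genes), 3)), index=genes,
            columns=["k0", "k1", "k2"],
        ))
        sm = score_matrix(cs, ps, toy_db)
        perm = ps.subset(["k2", "k0", "k1"])
        sm_perm = score_matrix(cs, perm, toy_db)
        pd.testing.assert_frame_equal(
            sm_perm.raw, sm.raw[["k2", "k0", "k1"]]
        )

    def test_oracle_equivalence_thousand_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            db, central, partner = self._random_setup(rng)
            got = global_score(central, partner, db).S
            assert got == pytest.approx(_oracle_score(db, central, partner))


class TestFamilyContributions:
    def test_conservation(self, toy_db, toy_profiles):
        central, partner = toy_profiles
        res = global_score(central, partner, toy_db, w=3.0)
        contrib = family_contributions(res, toy_db)
        assert contrib.sum() == pytest.approx(res.S / res.weight)

    def test_hand_computed_groups(self, toy_db, toy_profiles):
        central, partner = toy_profiles
        res = global_score(central, partner, toy_db)
        contrib = family_contributions(res, toy_db)
        assert contrib["Checkpoint"] == pytest.approx(12.0)
        assert contrib["Chemokine"] == pytest.approx(20.0)

    def test_equals_filtered_global_score(self, toy_db, toy_profiles):
        central, partner = toy_profiles
        res = global_score(central, partner, toy_db)
        contrib = family_contributions(res, toy_db)
        chem = filter_database(toy_db, families=["Chemokine"])
        assert contrib["Chemokine"] == pytest.approx(
            global_score(central, partner, chem).S
        )

    def test_subfamily_grouping(self, toy_db, toy_profiles):
        central, partner = toy_profiles
        res = global_score(central, partner, toy_db)
        contrib = family_contributions(res, toy_db, by="subfamily")
        # non-cytokine records have empty subfamily -> "unclassified"
        assert set(contrib.index) <= {"type 1", "unclassified"}


class TestNormalize:
    def test_reference_row_all_ones(self):
        sm = ScoreMatrix(raw=pd.DataFrame(
            [[10.0, 20.0], [30.0, 10.0]], index=["ref", "x"], columns=["a", "b"]
        ))
        out = normalize_scores(sm, "ref")
        assert (out.normalized.loc["ref"] == 1.0).all()

    def test_hand_computed_values(self):
        sm = ScoreMatrix(raw=pd.DataFrame(
            [[10.0, 20.0], [30.0, 10.0]], index=["r0", "r1"], columns=["a", "b"]
        ))
        out = normalize_scores(sm, "r0")
        assert out.normalized.loc["r1", "a"] == pytest.approx(3.0)
        assert out.normalized.loc["r1", "b"] == pytest.approx(0.5)

    def test_scale_invariance(self):
        raw = pd.DataFrame([[10.0, 20.0], [30.0, 10.0]],
                           index=["r0", "r1"], columns=["a", "b"])
        n1 = normalize_scores(ScoreMatrix(raw=raw), "r0").normalized
        n2 = normalize_scores(ScoreMatrix(raw=raw * 7.5), "r0").normalized
        pd.testing.assert_frame_equal(n1, n2)

    def test_zero_reference_names_partner(self):
        sm = ScoreMatrix(raw=pd.DataFrame(
            [[1.0, 0.0], [2.0, 3.0]], index=["r0", "r1"], columns=["a", "b"]
        ))
        with pytest.raises(ValueError, match="'b'"):
            normalize_scores(sm, "r0")

    def test_missing_reference(self):
        sm = ScoreMatrix(raw=pd.DataFrame([[1.0]], index=["r0"], columns=["a"]))
        with pytest.raises(KeyError):
            normalize_scores(sm, "nope")


class TestRescale:
    def test_endpoints(self):
        assert rescale_values([3.0, 7.0]) == [1.0, 10.0]

    def test_linear_interpolation(self):
        assert rescale_values([0.0, 5.0, 10.0]) == [1.0, 5.5, 10.0]

    def test_constant_matrix_maps_to_ten(self):
        assert rescale_values([4.0, 4.0]) == [10.0, 10.0]

    def test_matrix_rescale_bounds_and_rank(self):
        rng = np.random.default_rng(11)
        raw = pd.DataFrame(rng.uniform(0, 500, size=(3, 4)))
        out = rescale_scores(ScoreMatrix(raw=raw)).rescaled
        flat_raw = raw.to_numpy().ravel()
        flat_out = out.to_numpy().ravel()
        assert flat_out.min() == pytest.approx(1.0)
        assert flat_out.max() == pytest.approx(10.0)
        assert (np.argsort(flat_raw) == np.argsort(flat_out)).all()

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0, 1e5, allow_nan=False), min_size=1, max_size=20))
    def test_rank_preservation_property(self, scores):
        out = rescale_values(scores)
        assert all(1.0 - 1e-9 <= v <= 10.0 + 1e-9 for v in out)
        for i in range(len(scores)):
            for j in range(len(scores)):
                if scores[i] < scores[j]:
                    assert out[i] <= out[j] + 1e-9

    def test_rescale_normalized_view(self):
        raw = pd.DataFrame([[10.0, 20.0], [30.0, 10.0]],
                           index=["r0", "r1"], columns=["a", "b"])
        sm = normalize_scores(ScoreMatrix(raw=raw), "r0")
        out = rescale_scores(sm, use_normalized=True)
        assert out.rescaled.to_numpy().min() == pytest.approx(1.0)
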