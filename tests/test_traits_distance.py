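"""Trait-table validation and Gower/Euclidean distance builders."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import funcdisp as fd
from funcdisp._errors import NumericalError, ValidationError
from funcdisp.traits import TraitDefinition, default_definitions


def _table(rows: dict, defs=None) -> fd.TraitTable:
    df = pd.DataFrame(rows).T
    df.columns = [d.name for d in (defs or default_definitions())]
    return fd.TraitTable(df, defs or default_definitions())


class TestTraitTableValidation:
    def test_missing_values_rejected(self):
        df = pd.DataFrame(
            {"h": [1.0, np.nan]}, index=["a", "b"]
        )
        with pytest.raises(ValidationError, match="missing"):
            fd.TraitTable(df, [TraitDefinition("h", "continuous", "cm")])

    def test_undeclared_categorical_level_rejected(self):
        df = pd.DataFrame({"lh": ["annual", "biennial"]}, index=["a", "b"])
        with pytest.raises(ValidationError, match="undeclared"):
            fd.TraitTable(
                df, [TraitDefinition("lh", "categorical", levels=("annual", "perennial"))]
            )

    def test_duplicate_species_rejected(self):
        df = pd.DataFrame({"h": [1.0, 2.0]}, index=["a", "a"])
        with pytest.raises(ValidationError, match="duplicate"):
            fd.TraitTable(df, [TraitDefinition("h", "continuous")])

    def test_non_finite_continuous_rejected(self):
        df = pd.DataFrame({"h": [1.0, np.inf]}, index=["a", "b"])
        with pytest.raises(ValidationError, match="non-finite"):
            fd.TraitTable(df, [TraitDefinition("h", "continuous")])

    def test_csv_yaml_round_trip(self, toy_traits, tmp_path):
        toy_traits.to_csv(tmp_path / "traits.csv")
        toy_traits.config_to_yaml(tmp_path / "traits.yaml")
        again = fd.TraitTable.from_csv(tmp_path / "traits.csv", tmp_path / "traits.yaml")
        pd.testing.assert_frame_equal(again.data, toy_traits.data)
        assert again.continuous_traits == toy_traits.continuous_traits


class TestGowerDistance:
    def test_identical_species_distance_zero(self, toy_traits):
        data = toy_traits.data.copy()
        data.loc["sp2"] = data.loc["sp1"]
        tt = fd.TraitTable(data, default_definitions())
        d = fd.gower_distance(tt)
        assert d.between("sp1", "sp2") == 0.0

    def test_single_categorical_mismatch_is_one(self):
        defs = [TraitDefinition("lh", "categorical", levels=("annual", "perennial"))]
        df = pd.DataFrame({"lh": ["annual", "perennial"]}, index=["a", "b"])
        d = fd.gower_distance(fd.TraitTable(df, defs), ["lh"])
        assert d.between("a", "b") == 1.0

    def test_mixed_two_trait_hand_example(self):
        # categorical mismatch (1) + continuous half-range difference (0.5)
        defs = [
            TraitDefinition("lh", "categorical", levels=("annual", "perennial")),
            TraitDefinition("h", "continuous", "cm"),
        ]
        df = pd.DataFrame(
            {"lh": ["annual", "perennial", "annual"], "h": [0.0, 5.0, 10.0]},
            index=["a", "b", "c"],
        )
        d = fd.gower_distance(fd.TraitTable(df, defs))
        assert d.between("a", "b") == pytest.approx((1.0 + 0.5) / 2.0)

    def test_matches_per_trait_loop(self, toy_traits):
        # independent per-pair, per-trait evaluation of the Gower formula
        d = fd.gower_distance(toy_traits)
        data, defs = toy_traits.data, toy_traits.definitions
        for a in toy_traits.species:
            for b in toy_traits.species:
                contribs = []
                for t, dfn in defs.items():
                    if dfn.kind == "continuous":
                        rng = data[t].max() - data[t].min()
                        contribs.append(abs(data.loc[a, t] - data.loc[b, t]) / rng)
                    else:
                        contribs.append(float(data.loc[a, t] != data.loc[b, t]))
                assert d.between(a, b) == pytest.approx(np.mean(contribs))

    def test_bounded_unit_interval(self, toy_traits):
        d = fd.gower_distance(toy_traits)
        assert (d.values >= 0).all() and (d.values <= 1).all()

    @given(scale=st.floats(0.1, 100), shift=st.floats(-50, 50))
    def test_affine_rescaling_invariance(self, scale, shift):
        defs = [TraitDefinition("h", "continuous", "cm"),
                TraitDefinition("w", "continuous", "g")]
        base = pd.DataFrame(
            {"h": [1.0, 3.0, 7.0, 10.0], "w": [2.0, 5.0, 1.0, 9.0]},
            index=["a", "b", "c", "d"],
        )
        rescaled = base.copy()
        rescaled["h"] = base["h"] * scale + shift
        d0 = fd.gower_distance(fd.TraitTable(base, defs))
        d1 = fd.gower_distance(fd.TraitTable(rescaled, defs))
        np.testing.assert_allclose(d0.values, d1.values, atol=1e-10)

    def test_row_permutation_consistency(self, toy_traits):
        order = ["sp4", "sp1", "sp6", "sp2", "sp3", "sp5"]
        permuted = fd.TraitTable(toy_traits.data.loc[order], default_definitions())
        d0 = fd.gower_distance(toy_traits).to_dataframe()
        d1 = fd.gower_distance(permuted).to_dataframe()
        pd.testing.assert_frame_equal(d1, d0.loc[order, order])

    def test_unknown_trait_raises(self, toy_traits):
        with pytest.raises(KeyError):
            fd.gower_distance(toy_traits, ["no_such_trait"])

    def test_fewer_than_two_species_raises(self):
        df = pd.DataFrame({"h": [1.0]}, index=["a"])
        tt = fd.TraitTable(df, [TraitDefinition("h", "continuous")])
        with pytest.raises(ValidationError):
            fd.gower_distance(tt)

    def test_constant_trait_contributes_zero(self, caplog):
        defs = [TraitDefinition("h", "continuous"), TraitDefinition("w", "continuous")]
        df = pd.DataFrame({"h": [5.0, 5.0], "w": [0.0, 2.0]}, index=["a", "b"])
        with caplog.at_level("WARNING"):
            d = fd.gower_distance(fd.TraitTable(df, defs))
        assert "constant" in caplog.text
        # constant trait counts in the unweighted mean with contribution 0
        assert d.between("a", "b") == pytest.approx(0.5)

    def test_all_constant_traits_raise(self):
        defs = [TraitDefinition("h", "continuous")]
        df = pd.DataFrame({"h": [5.0, 5.0]}, index=["a", "b"])
        with pytest.raises(NumericalError):
            fd.gower_distance(fd.TraitTable(df, defs))


class TestEuclideanDistance:
    def test_equal_values_zero(self):
        defs = [TraitDefinition("h", "continuous")]
        df = pd.DataFrame({"h": [3.0, 3.0, 9.0]}, index=["a", "b", "c"])
        d = fd.euclidean_distance(fd.TraitTable(df, defs), "h")
        assert d.between("a", "b") == 0.0

    def test_standardized_unit_spacing(self):
        # raw 0,1,2 standardize (ddof=1) to -1,0,+1 -> distances 1,1,2
        defs = [TraitDefinition("h", "continuous")]
        df = pd.DataFrame({"h": [0.0, 1.0, 2.0]}, index=["a", "b", "c"])
        d = fd.euclidean_distance(fd.TraitTable(df, defs), "h")
        assert d.between("a", "b") == pytest.approx(1.0)
        assert d.between("b", "c") == pytest.approx(1.0)
        assert d.between("a", "c") == pytest.approx(2.0)

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=8, unique=True))
    def test_matches_pairwise_loop(self, values):
        defs = [TraitDefinition("h", "continuous")]
        labels = [f"s{i}" for i in range(len(values))]
        df = pd.DataFrame({"h": values}, index=labels)
        d = fd.euclidean_distance(fd.TraitTable(df, defs), "h")
        x = np.asarray(values)
        z = (x - x.mean()) / x.std(ddof=1)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                assert d.between(a, b) == pytest.approx(abs(z[i] - z[j]), abs=1e-10)

    def test_categorical_trait_rejected(self, toy_traits):
        with pytest.raises(ValidationError, match="categorical"):
            fd.euclidean_distance(toy_traits, "life_history")

    def test_zero_variance_rejected(self):
        defs = [TraitDefinition("h", "continuous")]
        df = pd.DataFrame({"h": [1.0, 1.0]}, index=["a", "b"])
        with pytest.raises(NumericalError):
            fd.euclidean_distance(fd.TraitTable(df, defs), "h")


class TestDistanceMatrixValidation:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            fd.TraitDistanceMatrix(np.array([[0, 1], [2, 0]]), ["a", "b"])

    def test_negative_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            fd.TraitDistanceMatrix(np.array([[0, -1], [-1, 0]]), ["a", "b"])

    def test_csv_round_trip(self, toy_traits, tmp_path):
        d = fd.gower_distance(toy_traits)
        d.to_csv(tmp_path / "d.csv")
        again = fd.TraitDistanceMatrix.from_csv(tmp_path / "d.csv")
        np.testing.assert_allclose(again.values, d.values, atol=1e-12)
        assert again.labels == d.labels
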