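"""Abundance weighting, Zc partitions, correlations and ordination inputs."""

import numpy as np
import pandas as pd
import pytest

from iplome.database import LipidSpecies, build_species
from iplome.formula import parse_formula, zc
from iplome.stats import (
    AbundanceMatrix,
    PropertySpec,
    gower,
    hellinger,
    n_chains_of,
    partition_formula,
    relative_abundance,
    taxa_lipid_correlation,
    weighted_property,
    weighted_zc,
)


def frac(d):
    return AbundanceMatrix(pd.DataFrame(d))


class TestRelativeAbundance:
    def test_single_lipid(self):
        conc = pd.DataFrame({"S1": [3.0]}, index=["a"])
        x = relative_abundance(conc, {"a": 700.0})
        assert x.fractions.loc["a", "S1"] == 1.0

    def test_equal_molar(self):
        conc = pd.DataFrame({"S1": [1.0, 2.0]}, index=["a", "b"])
        x = relative_abundance(conc, {"a": 350.0, "b": 700.0})
        assert x.fractions["S1"].tolist() == [0.5, 0.5]

    def test_mass_vs_molar_differ(self):
        conc = pd.DataFrame({"S1": [1.0, 1.0]}, index=["a", "b"])
        molar = relative_abundance(conc, {"a": 350.0, "b": 700.0}, molar=True)
        massf = relative_abundance(conc, molar=False)
        assert massf.fractions.loc["a", "S1"] == 0.5
        assert molar.fractions.loc["a", "S1"] == pytest.approx(2 / 3)

    def test_all_zero_sample_rejected(self):
        conc = pd.DataFrame({"S1": [0.0]}, index=["a"])
        with pytest.raises(ValueError):
            relative_abundance(conc, {"a": 700.0})


class TestWeightedProperty:
    def test_single_dag_36_0(self):
        x = frac({"S1": pd.Series({"DAG 36:0": 1.0})})
        spec = PropertySpec("nC", {"DAG 36:0": 36.0}, {"DAG 36:0": 2.0})
        assert weighted_property(x, spec)["S1"] == 18.0

    def test_two_lipid_mixture(self):
        x = frac({"S1": pd.Series({"a": 0.5, "b": 0.5})})
        nc = PropertySpec("nC", {"a": 36.0, "b": 32.0}, {"a": 2.0, "b": 2.0})
        nuns = PropertySpec("nUns", {"a": 0.0, "b": 2.0}, {"a": 2.0, "b": 2.0})
        assert weighted_property(x, nc)["S1"] == pytest.approx(17.0, abs=1e-12)
        assert weighted_property(x, nuns)["S1"] == pytest.approx(0.5, abs=1e-12)

    def test_one_chain_limit(self):
        x = frac({"S1": pd.Series({"a": 1.0})})
        spec = PropertySpec("nC", {"a": 16.0}, {"a": 1.0})
        assert weighted_property(x, spec)["S1"] == 16.0

    def test_missing_property_for_abundant_lipid(self):
        x = frac({"S1": pd.Series({"a": 1.0})})
        with pytest.raises(ValueError):
            weighted_property(x, PropertySpec("nC", {}, {}))


class TestPartition:
    def test_parts_sum_to_whole_across_database(self, full_db):
        from iplome.stats import partition_name

        names = full_db.entries.drop_duplicates("name").sample(n=300, random_state=1)
        for _, row in names.iterrows():
            whole = parse_formula(row["formula"])
            p = partition_name(row["name"], whole, n_chains_of(row["name"]))
            assert p.headgroup + p.backbone + p.chains == whole

    def test_ceramide_backbone_anchor(self, components):
        comp = next(c for c in components if c.key == ("1G", "Cer"))
        sp = build_species(comp, (34, 0, 0))
        p = partition_formula(sp)
        assert zc(p.backbone) == pytest.approx(-0.75)

    def test_pc_dag_34_0_partition(self, components):
        comp = next(c for c in components if c.key == ("PC", "DAG"))
        p = partition_formula(build_species(comp, (34, 0, 0)))
        assert p.headgroup == parse_formula("C5H12NO3P")
        assert p.backbone == parse_formula("C3H8O3")
        assert p.chains == parse_formula("C34H64O2")


class TestWeightedZc:
    def one_lipid(self, components):
        comp = next(c for c in components if c.key == ("1G", "DEG"))
        sp = build_species(comp, (32, 1, 0))
        return sp, partition_formula(sp)

    def test_single_lipid_community_whole(self, components):
        sp, part = self.one_lipid(components)
        x = frac({"S1": pd.Series({sp.name: 1.0})})
        out = weighted_zc(x, {sp.name: part}, "whole")
        assert out["S1"] == pytest.approx(zc(sp.formula))

    def test_fifty_fifty_mixture(self):
        # two synthetic parts with part-zc -1 and -2 and equal carbon counts
        from iplome.stats import PartitionedFormula

        a = parse_formula("C10H10")   # zc -1
        b = parse_formula("C10H20")   # zc -2
        pa = PartitionedFormula(a, parse_formula(""), parse_formula(""), a)
        pb = PartitionedFormula(b, parse_formula(""), parse_formula(""), b)
        x = frac({"S1": pd.Series({"a": 0.5, "b": 0.5})})
        out = weighted_zc(x, {"a": pa, "b": pb}, "chains")
        assert out["S1"] == pytest.approx(-1.5)

    def test_pure_ceramide_backbone(self, components):
        comp = next(c for c in components if c.key == ("1G", "Cer"))
        sp = build_species(comp, (34, 0, 0))
        x = frac({"S1": pd.Series({sp.name: 1.0})})
        out = weighted_zc(x, {sp.name: partition_formula(sp)}, "backbone")
        assert out["S1"] == pytest.approx(-0.75)


class TestCorrelation:
    def test_identical_vectors(self):
        lip = pd.DataFrame({"S1": [0.1], "S2": [0.5], "S3": [0.9]}, index=["L"])
        taxa = lip.rename(index={"L": "T"})
        out = taxa_lipid_correlation(lip, taxa, alpha=0.05)
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_orthogonal_patterns(self):
        lip = pd.DataFrame([[1, -1, 1, -1]], index=["L"], columns=list("abcd"), dtype=float)
        taxa = pd.DataFrame([[1, 1, -1, -1]], index=["T"], columns=list("abcd"), dtype=float)
        out = taxa_lipid_correlation(lip, taxa, alpha=0.05)
        assert out.loc[0, "r"] == pytest.approx(0.0, abs=1e-12)

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(0)
        lip = pd.DataFrame(rng.normal(size=(2, 6)), index=["L1", "L2"])
        taxa = pd.DataFrame(rng.normal(size=(5, 6)), index=[f"T{i}" for i in range(5)])
        out = taxa_lipid_correlation(lip, taxa, alpha=0.05)
        m = out["tested"].sum()
        assert m == 10
        tested = out[out["tested"]]
        assert np.allclose(tested["p_adj"], np.minimum(1.0, tested["p"] * m))
        assert (tested["p_adj"] >= tested["p"]).all()

    def test_zero_variance_reported_untested(self):
        lip = pd.DataFrame({"S1": [1.0], "S2": [1.0], "S3": [1.0]}, index=["L"])
        taxa = pd.DataFrame({"S1": [0.1], "S2": [0.4], "S3": [0.6]}, index=["T"])
        out = taxa_lipid_correlation(lip, taxa, alpha=0.05)
        assert not out.loc[0, "tested"]
        assert np.isnan(out.loc[0, "r"])

    def test_significant_set_shrinks_with_alpha(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=8)
        lip = pd.DataFrame([base + rng.normal(scale=0.1, size=8) for _ in range(4)],
                           index=[f"L{i}" for i in range(4)])
        taxa = pd.DataFrame([base, rng.normal(size=8)], index=["T0", "T1"])
        loose = taxa_lipid_correlation(lip, taxa, alpha=0.05)
        strict = taxa_lipid_correlation(lip, taxa, alpha=0.0005)
        loose_set = set(map(tuple, loose[loose["significant"]][["lipid", "taxon"]].values))
        strict_set = set(map(tuple, strict[strict["significant"]][["lipid", "taxon"]].values))
        assert strict_set <= loose_set

    def test_too_few_samples(self):
        lip = pd.DataFrame({"S1": [1.0], "S2": [2.0]}, index=["L"])
        with pytest.raises(ValueError):
            taxa_lipid_correlation(lip, lip, 0.05)


class TestHellinger:
    def test_row_example(self):
        out = hellinger(np.array([[1.0, 1.0, 2.0]]))
        assert np.allclose(out, [[0.5, 0.5, np.sqrt(0.5)]])

    def test_one_hot_unchanged(self):
        row = np.array([[0.0, 1.0, 0.0]])
        assert np.allclose(hellinger(row), row)

    def test_unit_sum_of_squares(self):
        rng = np.random.default_rng(2)
        x = rng.random((5, 7))
        out = hellinger(x)
        assert np.allclose((out**2).sum(axis=1), 1.0)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            hellinger(np.array([[0.0, 0.0]]))


class TestGower:
    def test_identical_rows(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 5.0]])
        d = gower(x)
        assert d[0, 1] == 0.0

    def test_two_samples_are_unit_distance(self):
        d = gower(np.array([[0.0, 3.0], [2.0, 9.0]]))
        assert d[0, 1] == pytest.approx(1.0)

    def test_symmetry_bounds_diagonal(self):
        rng = np.random.default_rng(3)
        x = rng.random((6, 10))
        d = gower(x)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d <= 1.0 + 1e-12).all()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            gower(np.array([[1.0, 2.0]]))
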