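"""Database generation: chain-state enumeration, species assembly, IO.

The combinatorial counts are checked against an independent brute-force
enumerator written directly from the chain rules (triple loops over
per-chain length/double bonds/hydroxylations), kept free of any call
into the enumeration under test.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from iplome.database import (
    ChainConstraints,
    ComponentDef,
    LipidDatabase,
    build_species,
    enumerate_chain_states,
    expand_unique_components,
    generate_database,
    read_component_table,
    read_database,
    starter_component_path,
    write_database,
)
from iplome.formula import get_adduct, monoisotopic_mass, parse_formula


def brute_force_states(cc: ChainConstraints, n_chains: int) -> set:
    """Independent enumeration: explicit per-chain loops, then totals."""

    def chain_ok(length, db):
        if db == 0:
            return True
        return db <= cc.max_db and length >= 3 * (db - 1) + 2

    singles = [
        (length, db)
        for length in range(cc.c_min, cc.c_max + 1)
        for db in range(cc.max_db + 1)
        if chain_ok(length, db)
    ]
    totals = set()
    for combo in itertools.product(singles, repeat=n_chains):
        c = sum(x[0] for x in combo)
        d = sum(x[1] for x in combo)
        for oh in range(cc.max_oh + 1):
            totals.add((c, d, oh))
    return totals


class TestComponentTable:
    def test_starter_table_parses(self, components):
        assert len(components) >= 20
        keys = {c.key for c in components}
        assert ("1G", "DEG") in keys
        assert ("PC", "DAG") in keys
        assert ("DGTS", "DAG") in keys
        assert ("OL", "FA") in keys

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("headgroup\tbackbone\tadducts\n")
        with pytest.raises(ValueError):
            read_component_table(p)

    def test_duplicate_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text(
            "headgroup\tbackbone\tadducts\n1G\tDAG\tMH\n1G\tDAG\tMH\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_component_table(p)

    def test_unknown_backbone_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("headgroup\tbackbone\tadducts\n1G\tXAG\tMH\n")
        with pytest.raises(ValueError, match="backbone"):
            read_component_table(p)

    def test_excess_chain_count_rejected(self):
        with pytest.raises(ValueError, match="n_chains"):
            ComponentDef(
                headgroup="1G",
                backbone="DAG",
                base_formula=parse_formula("C9H14O10"),
                n_chains=5,
                linkages=("ester",) * 5,
                adducts=(get_adduct("MH"),),
            )


class TestChainStates:
    def test_hand_enumeration(self):
        cc = ChainConstraints(c_min=2, c_max=4, max_db=1, max_oh=0)
        states = enumerate_chain_states(cc, 1)
        assert states == [(2, 0, 0), (2, 1, 0), (3, 0, 0), (3, 1, 0), (4, 0, 0), (4, 1, 0)]

    def test_single_state(self):
        cc = ChainConstraints(c_min=2, c_max=2, max_db=0, max_oh=0)
        assert enumerate_chain_states(cc, 1) == [(2, 0, 0)]

    def test_defaults_match_brute_force_one_chain(self):
        cc = ChainConstraints()
        assert set(enumerate_chain_states(cc, 1)) == brute_force_states(cc, 1)

    def test_spacing_rule_caps_double_bonds(self):
        cc = ChainConstraints(c_min=2, c_max=30, max_db=6, max_oh=0)
        states = {(c, d) for c, d, _ in enumerate_chain_states(cc, 1)}
        assert (2, 1) in states       # one double bond fits a 2-carbon chain
        assert (4, 2) not in states   # two need >= 5 carbons (3*1+2)
        assert (5, 2) in states
        assert (16, 6) not in states  # six need >= 17 carbons
        assert (17, 6) in states

    @pytest.mark.parametrize("n_chains", [2, 3])
    def test_multichain_matches_brute_force(self, n_chains):
        cc = ChainConstraints(c_min=2, c_max=8, max_db=2, max_oh=1)
        assert set(enumerate_chain_states(cc, n_chains)) == brute_force_states(cc, n_chains)

    def test_two_chain_is_self_convolution(self):
        cc = ChainConstraints(c_min=2, c_max=10, max_db=3, max_oh=0)
        one = {(c, d) for c, d, _ in enumerate_chain_states(cc, 1)}
        two = {(c, d) for c, d, _ in enumerate_chain_states(cc, 2)}
        assert two == {(c1 + c2, d1 + d2) for (c1, d1) in one for (c2, d2) in one}

    def test_bad_chain_count(self):
        with pytest.raises(ValueError):
            enumerate_chain_states(ChainConstraints(), 5)


class TestBuildSpecies:
    def test_pc_dag_34_0(self, components):
        comp = next(c for c in components if c.key == ("PC", "DAG"))
        sp = build_species(comp, (34, 0, 0))
        assert sp.name == "PC-DAG 34:0"
        assert sp.formula == parse_formula("C42H84NO8P")
        assert sp.mass == pytest.approx(761.5935, abs=2e-4)

    def test_hydroxylation_suffix(self, components):
        comp = next(c for c in components if c.key == ("PG", "DAG"))
        assert build_species(comp, (34, 0, 1)).name == "PG-DAG 34:0 + 1O"

    def test_formula_tracks_state(self, components):
        comp = next(c for c in components if c.key == ("1G", "DEG"))
        base = build_species(comp, (32, 0, 0)).formula
        unsat = build_species(comp, (32, 1, 0)).formula
        assert base["H"] - unsat["H"] == 2
        oh = build_species(comp, (32, 0, 1)).formula
        assert oh["O"] - base["O"] == 1


class TestUniqueComponents:
    def test_archaeol(self, unique_defs):
        ar = [u for u in unique_defs if u.core == "AR"]
        species = expand_unique_components(ar, ["1G"])
        named = {s.name: s for s in species}
        assert "1G-AR" in named
        assert named["1G-AR"].formula == parse_formula("C49H98O8")

    def test_gdgt(self, unique_defs):
        g = [u for u in unique_defs if u.core == "GDGT"]
        species = expand_unique_components(g, ["2G"])
        named = {s.name: s for s in species}
        assert "2G-GDGT-0" in named
        assert named["2G-GDGT-0"].formula == parse_formula("C98H192O16")

    def test_isoprene_extension_arithmetic(self, unique_defs):
        ar = [u for u in unique_defs if u.core == "AR"]
        species = {s.name: s for s in expand_unique_components(ar, ["1G"])}
        base = species["1G-AR"]
        modified = species["1G-AR + 1u + 2Ip - 1Ip"]
        # net +C5H10 (one isoprene unit) and -H2 (one unsaturation)
        assert modified.formula["C"] - base.formula["C"] == 5
        assert modified.formula["H"] - base.formula["H"] == 8


def brute_force_db_count(comps, cc):
    """Independent ionized-entry count for iterative components."""
    total = 0
    for comp in comps:
        states = brute_force_states(cc, comp.n_chains)
        total += len(states) * len(comp.adducts)
    return total


class TestGenerateDatabase:
    def test_empty_inputs(self):
        db = generate_database([], [])
        assert len(db) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_match_brute_force(self, components, seed):
        rng = np.random.default_rng(seed)
        picks = rng.choice(len(components), size=rng.integers(1, 4), replace=False)
        comps = [components[i] for i in picks]
        cc = ChainConstraints(
            c_min=int(rng.integers(2, 4)),
            c_max=int(rng.integers(5, 9)),
            max_db=int(rng.integers(0, 3)),
            max_oh=int(rng.integers(0, 3)),
        )
        db = generate_database(comps, [], cc)
        assert len(db) == brute_force_db_count(comps, cc)

    def test_superset_under_larger_ranges(self, components):
        comps = components[:3]
        small = generate_database(comps, [], ChainConstraints(c_min=2, c_max=6, max_db=1, max_oh=1))
        large = generate_database(comps, [], ChainConstraints(c_min=2, c_max=8, max_db=2, max_oh=2))
        small_keys = set(zip(small.entries["name"], small.entries["adduct"]))
        large_keys = set(zip(large.entries["name"], large.entries["adduct"]))
        assert small_keys <= large_keys

    def test_no_duplicate_keys_and_mz_consistency(self, full_db):
        ent = full_db.entries
        assert not ent.duplicated(subset=["name", "adduct"]).any()
        sample = ent.sample(n=500, random_state=0)
        for _, row in sample.iterrows():
            mass = monoisotopic_mass(parse_formula(row["formula"]))
            assert mass == pytest.approx(row["neutral_mass"], abs=1e-6)
            from iplome.formula import adduct_mz

            assert adduct_mz(mass, row["adduct"]) == pytest.approx(row["mz"], abs=1e-6)

    def test_scan_range_filter(self, components):
        comps = components[:2]
        cc = ChainConstraints(c_min=2, c_max=20, max_db=1, max_oh=0)
        full = generate_database(comps, [], cc)
        windowed = generate_database(comps, [], cc, scan_range=(400.0, 2000.0))
        assert len(windowed) < len(full)
        assert windowed.entries["mz"].between(400, 2000).all()


class TestDatabaseIO:
    def test_roundtrip(self, components, tmp_path):
        db = generate_database(
            components[:3], [], ChainConstraints(c_min=2, c_max=10, max_db=2, max_oh=1)
        )
        path = tmp_path / "db.csv"
        write_database(db, path)
        back = read_database(path)
        assert back == db
        assert back.content_hash() == db.content_hash()

    def test_duplicate_rows_rejected(self, components, tmp_path):
        db = generate_database(
            components[:1], [], ChainConstraints(c_min=2, c_max=4, max_db=0, max_oh=0)
        )
        dup = pd.concat([db.entries, db.entries.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            LipidDatabase(dup)

    def test_empty_roundtrip(self, tmp_path):
        db = generate_database([], [])
        path = tmp_path / "empty.csv"
        write_database(db, path)
        assert len(read_database(path)) == 0


def test_naming_roundtrip_over_full_database(full_db):
    """Every generated name survives parse -> format unchanged."""
    from iplome.nomenclature import format_name, parse_name

    names = full_db.entries["name"].drop_duplicates()
    for name in names:
        p = parse_name(name)
        rebuilt = format_name(
            p.headgroup, p.backbone, p.c, p.db, p.oh,
            kind=p.kind, uns=p.uns, me=p.me, ext=p.ext, abr=p.abr,
        )
        assert rebuilt == name
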