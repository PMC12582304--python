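"""Backtracking, label reading, necklace canonicalization and census."""

from collections import Counter
from itertools import product

import numpy as np
import pandas as pd
import pytest
import sympy
from hypothesis import given, settings, strategies as st

from symcensus import (
    EXCLUDED,
    SUBUNIT_INDEX_TAG,
    ParticleTable,
    SubunitLabelVector,
    backtrack_parents,
    canonical_form,
    census,
    census_from_table,
    enumerate_configurations,
    necklace_count,
    read_labels,
    rotate_string,
    symmetry_expand,
)
from symcensus.configuration import BacktrackError, ClassMapError, parse_class_map

PENTAMER_CONFIGS = ["iiiii", "iiiio", "iiioo", "iiooo", "ioooo", "ooooo", "iioio", "ioioo"]


def _expanded_fixture(n_parents=2, n=5, rng_seed=0):
    rng = np.random.default_rng(rng_seed)
    df = pd.DataFrame(
        {
            "_rlnMicrographName": [f"m{i}.mrc" for i in range(n_parents)],
            "_rlnImageName": [f"{i}@s.mrcs" for i in range(n_parents)],
            "_rlnCoordinateX": rng.uniform(0, 4000, n_parents).round(2),
            "_rlnCoordinateY": rng.uniform(0, 4000, n_parents).round(2),
            "_rlnAngleRot": rng.uniform(-180, 180, n_parents),
            "_rlnAngleTilt": rng.uniform(0, 180, n_parents),
            "_rlnAnglePsi": rng.uniform(-180, 180, n_parents),
        }
    )
    return symmetry_expand(ParticleTable(df=df), n)


class TestBacktrack:
    def test_groups_of_five(self):
        expanded = _expanded_fixture(2)
        groups, incomplete = backtrack_parents(expanded, 5)
        assert len(groups) == 2 and not incomplete
        for g in groups:
            assert list(g.records[SUBUNIT_INDEX_TAG]) == [0, 1, 2, 3, 4]

    def test_incomplete_parent_reported(self):
        expanded = _expanded_fixture(2)
        expanded.df = expanded.df.drop(index=7).reset_index(drop=True)
        groups, incomplete = backtrack_parents(expanded, 5)
        assert len(groups) == 1 and len(incomplete) == 1
        with pytest.raises(BacktrackError):
            backtrack_parents(expanded, 5, strict=True)

    def test_same_coordinates_different_micrographs_are_distinct(self):
        expanded = _expanded_fixture(2)
        for tag in ("_rlnCoordinateX", "_rlnCoordinateY", "_rlnImageName"):
            expanded.df[tag] = [expanded.df[tag].iloc[0]] * len(expanded.df)
        groups, incomplete = backtrack_parents(expanded, 5)
        assert len(groups) == 2 and not incomplete

    def test_duplicate_subunit_index_is_error(self):
        expanded = _expanded_fixture(1)
        expanded.df.loc[1, SUBUNIT_INDEX_TAG] = 0
        with pytest.raises(BacktrackError, match="duplicate"):
            backtrack_parents(expanded, 5)

    def test_index_recovery_without_stored_column(self):
        expanded = _expanded_fixture(3, rng_seed=3)
        expanded.df = expanded.df.drop(columns=[SUBUNIT_INDEX_TAG])
        groups, _ = backtrack_parents(expanded, 5)
        assert len(groups) == 3
        for g in groups:
            # row order within group follows recovered index 0..4
            rot = g.records["_rlnAngleRot"].to_numpy()
            delta = np.mod(rot - rot[0] + 180.0, 360.0) - 180.0
            k = np.rint(np.mod(delta, 360.0) / 72.0).astype(int) % 5
            assert sorted(k) == [0, 1, 2, 3, 4]


class TestLabels:
    def test_read_in_subunit_order(self):
        expanded = _expanded_fixture(1)
        expanded.df["_rlnClassNumber"] = [1, 1, 1, 1, 2]
        (group,), _ = backtrack_parents(expanded, 5)
        vec = read_labels(group, {1: "i", 2: "o"})
        assert vec.as_string() == "iiiio"
        assert not vec.excluded

    def test_excluded_class_flags_pentamer(self):
        expanded = _expanded_fixture(1)
        expanded.df["_rlnClassNumber"] = [1, 3, 1, 1, 2]
        (group,), _ = backtrack_parents(expanded, 5)
        vec = read_labels(group, {1: "i", 2: "o", 3: EXCLUDED})
        assert vec.excluded
        with pytest.raises(ValueError):
            vec.as_string()

    def test_unknown_class_names_class(self):
        expanded = _expanded_fixture(1)
        expanded.df["_rlnClassNumber"] = [1, 7, 1, 1, 2]
        (group,), _ = backtrack_parents(expanded, 5)
        with pytest.raises(ClassMapError, match="7"):
            read_labels(group, {1: "i", 2: "o"})


class TestCanonicalForm:
    def test_rotated_string(self):
        c = canonical_form("oiiii")
        assert (c.canonical, c.shift, c.period) == ("iiiio", 1, 5)

    def test_uniform_string(self):
        c = canonical_form("iiiii")
        assert (c.canonical, c.shift, c.period) == ("iiiii", 0, 1)

    @pytest.mark.parametrize("name", PENTAMER_CONFIGS)
    def test_reported_names_are_fixed_points(self, name):
        """Each of the eight standard pentamer configuration names is its own
        lexicographic-minimal rotation."""
        c = canonical_form(name)
        assert c.canonical == name and c.shift == 0

    @given(
        s=st.text(alphabet="io", min_size=1, max_size=9),
        r=st.integers(0, 8),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_rotation_invariant_and_idempotent(self, s, r):
        c1 = canonical_form(s)
        c2 = canonical_form(rotate_string(s, r))
        assert c1.canonical == c2.canonical
        assert canonical_form(c1.canonical).canonical == c1.canonical
        assert canonical_form(c1.canonical).shift == 0
        # shift contract: rotating the input by shift yields the canonical
        assert rotate_string(s, c1.shift) == c1.canonical


class TestEnumeration:
    def test_pentamer_two_states_has_eight(self):
        assert enumerate_configurations(5, "io") == sorted(PENTAMER_CONFIGS)

    def test_small_cases(self):
        assert enumerate_configurations(1, "io") == ["i", "o"]
        # Burnside by hand for n=6, two symbols:
        # phi(1)*2^6 + phi(2)*2^3 + phi(3)*2^2 + phi(6)*2 = 64+8+8+4 = 84; 84/6 = 14
        assert len(enumerate_configurations(6, "io")) == 14

    @pytest.mark.parametrize("n", range(1, 9))
    @pytest.mark.parametrize("a", [2, 3])
    def test_count_matches_burnside_formula(self, n, a):
        expected = (
            sum(sympy.totient(d) * a ** (n // d) for d in sympy.divisors(n)) // n
        )
        assert necklace_count(n, a) == expected
        alphabet = "io" if a == 2 else "iox"
        assert len(enumerate_configurations(n, alphabet)) == expected


class TestCensus:
    def test_all_binary_strings_orbit_sizes(self):
        """Over all 32 strings of length 5: uniform orbits have size 1,
        aperiodic orbits size 5 (2 + 6*5 = 32)."""
        configs = [canonical_form("".join(t)) for t in product("io", repeat=5)]
        c = census(configs)
        assert c.counts["iiiii"] == 1 and c.counts["ooooo"] == 1
        aperiodic = {k: v for k, v in c.counts.items() if k not in ("iiiii", "ooooo")}
        assert len(aperiodic) == 6 and set(aperiodic.values()) == {5}
        assert c.included_total == 32

    def test_frequencies_and_subunit_fraction(self):
        configs = [canonical_form("iiiio") for _ in range(10)]
        c = census(configs)
        assert c.particle_frequencies == {"iiiio": 1.0}
        assert c.subunit_fraction == pytest.approx({"i": 0.8, "o": 0.2})

    def test_empty_census_is_zero_safe(self):
        c = census([])
        assert c.counts == {}
        assert c.particle_frequencies == {}
        assert c.subunit_fraction == {}
        assert c.included_total == 0

    def test_subunit_fraction_matches_raw_label_counting(self, clean_dataset):
        """Two counting paths agree: fractions from canonical strings weighted
        by counts equal the direct fraction over raw labels."""
        gc, truths, table = clean_dataset
        c = census_from_table(table, gc.class_map, gc.n)
        raw = Counter()
        for gt in truths:
            raw.update(gt.observed_labels())
        total = sum(raw.values())
        for lab, frac in c.subunit_fraction.items():
            assert frac == pytest.approx(raw[lab] / total)


def test_parse_class_map():
    assert parse_class_map("i=1,o=2") == {1: "i", 2: "o"}
    assert parse_class_map("i=1,o=2,excluded=3,4") == {
        1: "i",
        2: "o",
        3: "excluded",
        4: "excluded",
    }
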