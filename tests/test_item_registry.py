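"""Registry loading, composite coding and matrix assembly."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from pharmirt import assemble_matrix, build_inspections_composite, load_registry
from pharmirt.errors import CodingError, RegistryFormatError, RegistryValidationError
from pharmirt.item_registry import (
    INDEX_SIZES,
    ResponseMatrix,
    read_survey_csv,
    write_registry,
)


def brute_force_composite(freqs, variant):
    """Independent re-statement of the inspections coding rule."""
    if any(f is None or (isinstance(f, float) and math.isnan(f)) for f in freqs):
        return math.nan
    if variant == "regular":
        return 1.0 if (max(freqs) <= 3) or (min(freqs) <= 1) else 0.0
    return 1.0 if max(freqs) <= 1 else 0.0


class TestRegistry:
    def test_default_cardinalities(self, registry):
        assert {name: len(registry[name]) for name in INDEX_SIZES} == INDEX_SIZES

    def test_private_market_has_exactly_one_derived_item(self, registry):
        derived = [it for it in registry["private_market"].items if it.is_derived]
        assert len(derived) == 1
        assert derived[0].item_id == "Inspections"

    def test_aspects_cover_private_market(self, registry):
        aspects = {it.aspect for it in registry["private_market"].items}
        assert aspects == {"legal_framework", "supply_chain", "pharmacovigilance"}

    def test_anchor_items_belong_to_their_index(self, registry):
        for name in INDEX_SIZES:
            idx = registry[name]
            assert idx.anchor_item in idx.item_ids

    def test_omitted_item_is_named_in_error(self, registry, tmp_path):
        path = tmp_path / "registry.yaml"
        write_registry(registry, path)
        doc = yaml.safe_load(path.read_text())
        items = doc["indices"]["infrastructure"]["items"]
        doc["indices"]["infrastructure"]["items"] = [e for e in items if e["id"] != "5.05.03"]
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(RegistryValidationError, match="5.05.03"):
            load_registry(path)

    def test_malformed_config_names_block(self, registry, tmp_path):
        path = tmp_path / "bad.yaml"
        write_registry(registry, path)
        doc = yaml.safe_load(path.read_text())
        doc["indices"]["infrastructure"] = 42
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(RegistryFormatError, match="infrastructure"):
            load_registry(path)

    def test_round_trip(self, registry, tmp_path):
        path = tmp_path / "registry.yaml"
        write_registry(registry, path)
        reloaded = load_registry(path)
        for name in INDEX_SIZES:
            assert reloaded[name] == registry[name]


class TestCompositeRule:
    @pytest.mark.parametrize(
        "freqs, variant, expected",
        [
            ((3, 3, 3), "regular", 1.0),
            ((5, 5, 1), "regular", 1.0),
            ((5, 5, 1), "annual", 0.0),
            ((1, 1, 1), "annual", 1.0),
            ((4, 4, 4), "regular", 0.0),
        ],
    )
    def test_stated_examples(self, freqs, variant, expected):
        assert build_inspections_composite(freqs, variant) == expected

    @pytest.mark.parametrize("variant", ["regular", "annual"])
    def test_exhaustive_truth_table_matches_brute_force(self, variant):
        grid = [0.5, 1, 2, 3, 4]
        for freqs in itertools.product(grid, repeat=3):
            got = build_inspections_composite(freqs, variant)
            assert got == brute_force_composite(freqs, variant), (freqs, variant)

    @given(
        st.lists(
            st.one_of(st.none(), st.floats(0.25, 10.0)), min_size=3, max_size=3
        ),
        st.sampled_from(["regular", "annual"]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_brute_force_and_missing_propagation(self, freqs, variant):
        got = build_inspections_composite(freqs, variant)
        want = brute_force_composite(freqs, variant)
        assert (math.isnan(got) and math.isnan(want)) or got == want

    def test_annual_never_exceeds_regular(self):
        for freqs in itertools.product([0.5, 1, 2, 3, 5], repeat=3):
            assert build_inspections_composite(freqs, "annual") <= build_inspections_composite(
                freqs, "regular"
            )

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            build_inspections_composite((0.0, 2, 2), "regular")

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            build_inspections_composite((1, 1, 1), "biennial")


def _infra_frame(registry, values):
    ids = list(registry["infrastructure"].item_ids)
    return pd.DataFrame(values, index=["AAA", "AAB", "AAC"], columns=ids)


class TestAssembleMatrix:
    def test_zero_passthrough(self, registry):
        raw = _infra_frame(registry, np.zeros((3, 14)))
        m = assemble_matrix(raw, registry["infrastructure"])
        assert m.values.shape == (3, 14)
        # every row/column still validates because zeros are observed entries
        assert (m.values == 0).all()

    def test_idempotent_on_assembled_matrix(self, registry):
        rng = np.random.default_rng(0)
        raw = _infra_frame(registry, (rng.random((3, 14)) < 0.5).astype(float))
        once = assemble_matrix(raw, registry["infrastructure"])
        twice = assemble_matrix(once.to_frame(), registry["infrastructure"])
        np.testing.assert_array_equal(once.values, twice.values)
        assert once.item_ids == twice.item_ids

    def test_derived_column_matches_rowwise_composite(self, registry):
        idx = registry["private_market"]
        rng = np.random.default_rng(1)
        n = 6
        data = {
            it.item_id: (rng.random(n) < 0.5).astype(float)
            for it in idx.items
            if not it.is_derived
        }
        freq_cols = {
            "insp_years_manufacturers": [0.5, 2, 5, 1, 4, 3],
            "insp_years_retail": [1, 2, 5, 5, 4, 3],
            "insp_years_dispensing": [2, 3, 5, 5, 1, 3],
        }
        raw = pd.DataFrame({**data, **freq_cols}, index=[f"AA{c}" for c in "ABCDEF"])
        for variant in ("regular", "annual"):
            m = assemble_matrix(raw, idx, variant=variant)
            col = m.values[:, m.item_ids.index("Inspections")]
            expected = [
                brute_force_composite(
                    (row["insp_years_manufacturers"], row["insp_years_retail"],
                     row["insp_years_dispensing"]),
                    variant,
                )
                for _, row in raw.iterrows()
            ]
            np.testing.assert_array_equal(col, expected)

    def test_variants_differ_on_constructed_table(self, registry):
        idx = registry["private_market"]
        rng = np.random.default_rng(2)
        n = 4
        data = {
            it.item_id: (rng.random(n) < 0.5).astype(float)
            for it in idx.items
            if not it.is_derived
        }
        # all three segments inspected every 2-3 years: regular=1, annual=0
        freq_cols = {
            "insp_years_manufacturers": [2, 3, 2, 3],
            "insp_years_retail": [3, 2, 3, 2],
            "insp_years_dispensing": [2, 2, 3, 3],
        }
        raw = pd.DataFrame({**data, **freq_cols}, index=["AAA", "AAB", "AAC", "AAD"])
        reg = assemble_matrix(raw, idx, variant="regular")
        ann = assemble_matrix(raw, idx, variant="annual")
        k = reg.item_ids.index("Inspections")
        assert (reg.values[:, k] == 1).all()
        assert (ann.values[:, k] == 0).all()

    def test_nonbinary_cell_reports_coordinates(self, registry):
        vals = np.zeros((3, 14))
        vals[1, 3] = 2.0
        raw = _infra_frame(registry, vals)
        with pytest.raises(CodingError, match="AAB"):
            assemble_matrix(raw, registry["infrastructure"])

    def test_all_missing_column_rejected(self, registry):
        vals = np.ones((3, 14))
        vals[:, 0] = np.nan
        raw = _infra_frame(registry, vals)
        with pytest.raises(RegistryValidationError, match="3.01.04"):
            assemble_matrix(raw, registry["infrastructure"])

    def test_missing_item_column_rejected(self, registry):
        raw = _infra_frame(registry, np.zeros((3, 14))).drop(columns=["5.01.02"])
        with pytest.raises(RegistryValidationError, match="5.01.02"):
            assemble_matrix(raw, registry["infrastructure"])


class TestSurveyCsv:
    def test_missing_tokens_and_round_trip(self, tmp_path, registry):
        path = tmp_path / "survey.csv"
        ids = list(registry["infrastructure"].item_ids)
        header = "country," + ",".join(ids)
        row1 = "AAA," + ",".join(["1"] * 13 + [""])
        row2 = "AAB," + ",".join(["0"] * 12 + ["NA", "1"])
        path.write_text(f"{header}\n{row1}\n{row2}\n")
        df = read_survey_csv(path)
        assert np.isnan(df.iloc[0, 13]) and np.isnan(df.iloc[1, 12])
        m = assemble_matrix(df, registry["infrastructure"])
        out = tmp_path / "matrix.csv"
        m.to_csv(out)
        again = ResponseMatrix.from_csv(out)
        np.testing.assert_array_equal(m.values, again.values)

    def test_unreadable_cell_reports_coordinates(self, tmp_path):
        path = tmp_path / "survey.csv"
        path.write_text("country,Q1,Q2\nAAA,1,yes\nAAB,0,1\n")
        with pytest.raises(CodingError, match="Q2"):
            read_survey_csv(path)

    def test_wrong_key_column_rejected(self, tmp_path):
        path = tmp_path / "survey.csv"
        path.write_text("nation,Q1\nAAA,1\n")
        with pytest.raises(RegistryFormatError, match="country"):
            read_survey_csv(path)
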