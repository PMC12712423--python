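"""Trait-table I/O, standardization, pairing and complete-case filtering."""

import math

import numpy as np
import pytest

from traitshift import (
    TRAIT_NAMES,
    complete_cases,
    pair_stages,
    read_trait_table,
    transform_and_standardize,
    write_trait_table,
)
from traitshift.data import LOG_TRAITS, TRAIT_UNITS, StandardizedMatrix, TraitMeta

from conftest import make_record


def meta_subset(*names: str) -> list[TraitMeta]:
    return [TraitMeta(t, TRAIT_UNITS[t], t in LOG_TRAITS) for t in names]


def _write_csv(tmp_path, text, name="traits.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


HEADER = "species_id,site_id,stage,phenology,growth_form," + ",".join(TRAIT_NAMES)


class TestReadTraitTable:
    def test_reads_rows_with_missing_and_case_folded_labels(self, tmp_path):
        csv = "\n".join(
            [
                HEADER,
                "sp1,1,Seedling,Deciduous,Liana,10,0.4,NA,0.6,2.0,30,100,2.5",
                "sp2,2,adult,evergreen,free-standing,12,0.5,150,0.7,2.5,40,80,3.0",
                "sp3,3,ADULT,,,15,0.45,,0.65,2.2,35,90,2.8",
            ]
        )
        table = read_trait_table(_write_csv(tmp_path, csv))
        assert len(table) == 3
        assert table[0].stage == "seedling"
        assert table[0].phenology == "deciduous"
        assert table[0].growth_form == "liana"
        assert table[0].traits["SLA"] is None
        assert table[1].growth_form == "free_standing"
        assert table[2].phenology == "unknown"
        assert table[2].traits["SLA"] is None
        assert table[1].traits["SLA"] == 150.0

    def test_roundtrip_preserves_values_bitwise(self, tmp_path):
        rng = np.random.default_rng(5)
        rows = [
            make_record(
                f"sp{i}", site=1 + i % 4, stage="adult",
                SLA=float(np.exp(rng.normal(5, 0.4))),
                LDMC=float(rng.uniform(0.2, 0.6)),
                d_h=float(np.exp(rng.normal(3.5, 0.3))),
            )
            for i in range(10)
        ]
        path = tmp_path / "out.csv"
        write_trait_table(rows, path)
        back = read_trait_table(path)
        for orig, rec in zip(rows, back):
            for t in TRAIT_NAMES:
                a, b = orig.traits[t], rec.traits[t]
                assert (a is None) == (b is None)
                if a is not None:
                    assert a == b  # exact repr round-trip

    def test_unknown_stage_names_row(self, tmp_path):
        csv = "\n".join([HEADER, "sp1,1,sapling,,,10,0.4,100,0.6,2,30,100,2.5"])
        with pytest.raises(ValueError, match="stage.*row 1"):
            read_trait_table(_write_csv(tmp_path, csv))

    def test_duplicate_population_stage_rejected(self, tmp_path):
        row = "sp1,1,adult,,,10,0.4,100,0.6,2,30,100,2.5"
        with pytest.raises(ValueError, match="duplicate"):
            read_trait_table(_write_csv(tmp_path, "\n".join([HEADER, row, row])))

    def test_nonpositive_log_trait_names_trait_and_row(self, tmp_path):
        csv = "\n".join([HEADER, "sp1,1,adult,,,10,0.4,100,0.6,2,30,0,2.5"])
        with pytest.raises(ValueError, match="VD.*row 1"):
            read_trait_table(_write_csv(tmp_path, csv))


class TestStandardize:
    def test_log_trait_hand_computed(self):
        e = math.e
        table = [
            make_record("sp1", stage="adult", SLA=e, LDMC=0.3),
            make_record("sp2", stage="adult", SLA=e**2, LDMC=0.5),
        ]
        std = transform_and_standardize(table, meta=meta_subset("SLA", "LDMC"))
        # log values {1, 2}: mean 1.5, sample SD sqrt(1/2)
        np.testing.assert_allclose(
            std.column("SLA"), [-0.7071067811865475, 0.7071067811865475], atol=1e-12
        )

    def test_zero_sd_errors_with_trait_name(self):
        table = [make_record(f"sp{i}", stage="adult", LDMC=0.4, SLA=100 + i) for i in range(3)]
        with pytest.raises(ValueError, match="LDMC"):
            transform_and_standardize(table, meta=meta_subset("SLA", "LDMC"))

    def test_columns_are_zero_mean_unit_sd_within_scope(self, small_synth_config):
        from traitshift import generate_dataset

        table, _ = generate_dataset(small_synth_config)
        for scope in ("pooled_stages", "adults_only"):
            std = transform_and_standardize(table, scope=scope)
            for j in range(std.p):
                col = std.values[:, j]
                obs = col[~np.isnan(col)]
                assert abs(obs.mean()) < 1e-10
                assert abs(obs.std(ddof=1) - 1) < 1e-10

    def test_destandardize_roundtrip(self, small_synth_config):
        from traitshift import generate_dataset

        table, _ = generate_dataset(small_synth_config)
        std = transform_and_standardize(table)
        natural = std.destandardize()
        for i, rec_key in enumerate(std.row_index):
            rec = next(
                r for r in table
                if (r.species_id, r.site_id, r.stage) == rec_key
            )
            for j, t in enumerate(std.trait_names):
                v = rec.traits[t]
                if v is None:
                    assert np.isnan(natural[i, j])
                else:
                    assert abs(natural[i, j] - v) < 1e-10 * max(1.0, abs(v))

    def test_explicit_reference_scale(self):
        table = [
            make_record("sp1", stage="adult", LDMC=0.3),
            make_record("sp2", stage="adult", LDMC=0.5),
        ]
        std = transform_and_standardize(
            table, meta=meta_subset("LDMC"), center=np.array([0.4]), scale=np.array([0.1])
        )
        np.testing.assert_allclose(std.column("LDMC"), [-1.0, 1.0], atol=1e-12)


class TestPairStages:
    def test_pairs_only_populations_with_both_stages(self, paired_table):
        std = transform_and_standardize(paired_table, meta=meta_subset("SLA", "LDMC"))
        shift = pair_stages(std, "SLA")
        assert shift.n == 3
        assert [p[0] for p in shift.population_index] == ["sp1", "sp2", "sp3"]

    def test_equal_stage_values_give_zero_delta(self):
        table = [
            make_record("sp1", stage="adult", SLA=100.0),
            make_record("sp1", stage="seedling", SLA=100.0),
            make_record("sp2", stage="adult", SLA=150.0),
            make_record("sp2", stage="seedling", SLA=150.0),
        ]
        shift = pair_stages(
            transform_and_standardize(table, meta=meta_subset("SLA")), "SLA"
        )
        np.testing.assert_array_equal(shift.delta, [0.0, 0.0])

    def test_swapping_stage_labels_negates_deltas_exactly(self, paired_table):
        std = transform_and_standardize(paired_table, meta=meta_subset("SLA", "LDMC"))
        delta = pair_stages(std, "SLA").delta
        swapped = StandardizedMatrix(
            row_index=[
                (sp, site, "adult" if st == "seedling" else "seedling")
                for sp, site, st in std.row_index
            ],
            trait_names=std.trait_names,
            values=std.values,
            center=std.center,
            scale=std.scale,
            scope=std.scope,
            covariates=std.covariates,
        )
        np.testing.assert_array_equal(pair_stages(swapped, "SLA").delta, -delta)

    def test_deltas_match_generator_bookkeeping(self, small_synth_config):
        from traitshift import generate_dataset

        table, truth = generate_dataset(small_synth_config)
        std = transform_and_standardize(
            table, center=truth.reference_center, scale=truth.reference_scale
        )
        shift = pair_stages(std, "d_h")
        assert shift.n > 0
        for pop, delta in zip(shift.population_index, shift.delta):
            assert abs(delta - truth.paired_deltas["d_h"][pop]) < 1e-12

    def test_no_qualifying_population_errors(self):
        table = [
            make_record("sp1", stage="adult", SLA=100.0),
            make_record("sp2", stage="seedling", SLA=150.0),
        ]
        with pytest.raises(ValueError, match="both stages"):
            pair_stages(transform_and_standardize(table, meta=meta_subset("SLA")), "SLA")


class TestCompleteCases:
    def _table(self):
        rows = []
        for i in range(10):
            sla = None if i in (0, 1) else 100.0 + i
            rows.append(make_record(f"sp{i}", stage="adult", SLA=sla, LDMC=0.3 + 0.01 * i))
        return rows

    def test_incomplete_rows_dropped(self):
        std = transform_and_standardize(self._table(), meta=meta_subset("SLA", "LDMC"))
        cc = complete_cases(std, ["SLA", "LDMC"], stage_filter="adults_only")
        assert cc.n == 8
        assert cc.trait_names == ("SLA", "LDMC")

    def test_no_missingness_is_identity(self):
        rows = self._table()[2:]
        std = transform_and_standardize(rows, meta=meta_subset("SLA", "LDMC"))
        cc = complete_cases(std, ["SLA", "LDMC"])
        np.testing.assert_array_equal(cc.values[:, 0], std.column("SLA"))
        assert cc.row_index == std.row_index

    def test_column_restriction_excludes_unlisted_traits(self):
        std = transform_and_standardize(self._table(), meta=meta_subset("SLA", "LDMC"))
        traits = [t for t in ("SLA", "LDMC") if t != "LDMC"]
        cc = complete_cases(std, traits)
        assert "LDMC" not in cc.trait_names

    def test_empty_result_reports_missingness_tallies(self):
        rows = [
            make_record("sp0", stage="adult", SLA=100.0),
            make_record("sp1", stage="adult", SLA=130.0),
            make_record("sp2", stage="adult", LDMC=0.30),
            make_record("sp3", stage="adult", LDMC=0.45),
        ]
        std = transform_and_standardize(rows, meta=meta_subset("SLA", "LDMC"))
        with pytest.raises(ValueError, match="tallies"):
            complete_cases(std, ["SLA", "LDMC"])
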