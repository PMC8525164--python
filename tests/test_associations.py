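import numpy as np
import pandas as pd
import pytest

from hostphylo.associations import (
    AssociationTable,
    ConsistencyError,
    SchemaError,
    binarize_polyphagy,
    filter_for_dec,
    host_breadth,
    interaction_matrix,
    load_association_table,
    main_host_families,
    tip_range_states,
)
from hostphylo.synthetic import simulate_association_system


def _write(tmp_path, rows, header="fly_species\thost_species\thost_genus\thost_family"):
    p = tmp_path / "assoc.tsv"
    p.write_text(header + "\n" + "\n".join(rows) + "\n")
    return p


class TestLoad:
    def test_exact_duplicate_rows_merged(self, tmp_path):
        p = _write(
            tmp_path,
            [
                "f1\tCucumis sativus\tCucumis\tCucurbitaceae",
                "f1\tCucumis sativus\tCucumis\tCucurbitaceae",
                "f1\tCitrus limon\tCitrus\tRutaceae",
            ],
        )
        t = load_association_table(p)
        assert t.n_valid == 2

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("fly_species\thost_species\thost_genus\nf1\ta b\ta\n")
        with pytest.raises(SchemaError, match="host_family"):
            load_association_table(p)

    def test_empty_family_rejected_with_row_number(self, tmp_path):
        p = _write(
            tmp_path,
            ["f1\tCucumis sativus\tCucumis\tCucurbitaceae", "f1\tCitrus limon\tCitrus\t"],
        )
        with pytest.raises(ValueError, match=r"row\(s\) \[3\]"):
            load_association_table(p)

    def test_species_in_two_families_inconsistent(self, tmp_path):
        p = _write(
            tmp_path,
            [
                "f1\tCitrus limon\tCitrus\tRutaceae",
                "f2\tCitrus limon\tCitrus\tCucurbitaceae",
            ],
        )
        with pytest.raises(ConsistencyError, match="Citrus"):
            load_association_table(p)

    def test_whitespace_normalised_and_status_kept(self, tmp_path):
        p = tmp_path / "assoc.tsv"
        p.write_text(
            "fly_species\thost_species\thost_genus\thost_family\tstatus\n"
            " f1 \tCucumis  sativus\tCucumis\tCucurbitaceae\tvalid\n"
            "f1\tWeird plant\tWeird\tWeirdaceae\texcluded_doubtful\n"
        )
        t = load_association_table(p)
        assert t.n_valid == 1
        assert t.valid_records.iloc[0]["host_species"] == "Cucumis sativus"
        assert len(t.records) == 2

    def test_synthetic_export_roundtrip_counts(self, tmp_path):
        system = simulate_association_system(
            n_flies=15, n_genera=60, n_families=12, seed=4
        )
        p = tmp_path / "sim.tsv"
        system.table.write(p)
        t = load_association_table(p)
        assert t.n_valid == system.table.n_valid
        assert len(t.fly_species) == 15


class TestBreadth:
    def test_species_genus_family_counts(self):
        t = AssociationTable.from_records(
            [
                ("f1", "Cucumis sativus", "Cucumis", "Cucurbitaceae"),
                ("f1", "Cucumis melo", "Cucumis", "Cucurbitaceae"),
                ("f1", "Citrus limon", "Citrus", "Rutaceae"),
            ]
        )
        prof = host_breadth(t)
        assert prof.loc["f1"].tolist() == [3, 2, 2]

    def test_breadth_ordering_invariant(self):
        system = simulate_association_system(n_flies=10, n_genera=50, n_families=10, seed=1)
        prof = host_breadth(system.table)
        assert (prof["n_host_families"] <= prof["n_host_genera"]).all()
        assert (prof["n_host_genera"] <= prof["n_host_species"]).all()
        assert (prof["n_host_species"] >= 1).all()

    def test_adding_record_never_decreases_breadth(self):
        base = [
            ("f1", "Cucumis sativus", "Cucumis", "Cucurbitaceae"),
            ("f1", "Citrus limon", "Citrus", "Rutaceae"),
        ]
        prof0 = host_breadth(AssociationTable.from_records(base))
        prof1 = host_breadth(
            AssociationTable.from_records(base + [("f1", "Mangifera indica", "Mangifera", "Anacardiaceae")])
        )
        assert (prof1.loc["f1"] >= prof0.loc["f1"]).all()


class TestPolyphagyPartitions:
    def test_threshold_examples(self):
        prof = pd.DataFrame({"n_host_families": [1, 2, 3, 4, 5]}, index=list("abcde"))
        trait, count = binarize_polyphagy(prof, 2)
        assert trait.tolist() == [0, 0, 1, 1, 1]
        assert count == 3
        assert binarize_polyphagy(prof, 3)[1] == 2

    def test_counts_non_increasing_in_threshold(self):
        system = simulate_association_system(n_flies=20, n_genera=60, n_families=15, seed=2)
        prof = host_breadth(system.table)
        counts = [binarize_polyphagy(prof, k)[1] for k in range(1, 8)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_threshold(self):
        prof = pd.DataFrame({"n_host_families": [1]})
        with pytest.raises(ValueError):
            binarize_polyphagy(prof, 0)


class TestInteractionMatrix:
    def test_two_fly_example(self):
        t = AssociationTable.from_records(
            [
                ("f1", "Cucumis sativus", "Cucumis", "Cucurbitaceae"),
                ("f2", "Cucumis melo", "Cucumis", "Cucurbitaceae"),
                ("f2", "Citrus limon", "Citrus", "Rutaceae"),
            ]
        )
        m = interaction_matrix(t)
        assert m.loc["f1"].tolist() == [0, 1]  # columns sorted: Citrus, Cucumis
        assert m.loc["f2"].tolist() == [1, 1]
        assert int(m.values.sum()) == 3  # distinct (fly, genus) pairs

    def test_row_sums_equal_genus_breadth(self):
        system = simulate_association_system(n_flies=12, n_genera=40, n_families=8, seed=6)
        m = interaction_matrix(system.table)
        prof = host_breadth(system.table)
        assert (m.sum(axis=1) == prof["n_host_genera"]).all()

    def test_matrix_recovers_generator_truth(self):
        system = simulate_association_system(n_flies=12, n_genera=40, n_families=8, seed=8)
        m = interaction_matrix(system.table)
        truth = system.matrix.loc[m.index, m.columns]
        # genera without any association are absent from the table's matrix
        attacked = system.matrix.columns[system.matrix.sum(axis=0) > 0]
        assert set(m.columns) == set(attacked)
        assert (m == truth).all().all()


class TestDECFilters:
    def test_paper_like_retention_count(self):
        system = simulate_association_system(
            seed=3,
            breadth_profile={
                "n_monophages": 8,
                "n_extreme_polyphages": 11,
                "extreme_min_families": 20,
            },
        )
        # drop the 11 extreme polyphages plus one designated oligophage
        one_monophage = system.truth.params["monophages"][0]
        _, retained = filter_for_dec(system.table, max_families=20, exclude=[one_monophage])
        assert len(retained) == 25

    def test_identity_filter(self):
        t = AssociationTable.from_records(
            [("f1", "Cucumis sativus", "Cucumis", "Cucurbitaceae")]
        )
        filtered, retained = filter_for_dec(t, max_families=10**6, exclude=[])
        assert retained == ["f1"]
        assert filtered.n_valid == t.n_valid

    def test_all_flies_removed_warns_and_empties(self, caplog):
        t = AssociationTable.from_records(
            [("f1", "Cucumis sativus", "Cucumis", "Cucurbitaceae")]
        )
        with caplog.at_level("WARNING", logger="hostphylo.associations"):
            filtered, retained = filter_for_dec(t, max_families=1)
        assert retained == []
        assert "empty" in caplog.text

    def test_unknown_exclusion_is_warning_not_error(self, caplog):
        t = AssociationTable.from_records(
            [("f1", "Cucumis sativus", "Cucumis", "Cucurbitaceae")]
        )
        with caplog.at_level("WARNING", logger="hostphylo.associations"):
            _, retained = filter_for_dec(t, exclude=["not a fly"])
        assert retained == ["f1"]
        assert "absent" in caplog.text


class TestMainFamiliesAndTipStates:
    @staticmethod
    def _table():
        rows = []
        for i in range(4):
            rows.append(("f1", f"Cucumis sp{i}", "Cucumis", "Cucurbitaceae"))
        for i in range(3):
            rows.append(("f2", f"Citrus sp{i}", "Citrus", "Rutaceae"))
        rows.append(("f2", "Rosa canina", "Rosa", "Rosaceae"))
        return AssociationTable.from_records(rows)

    def test_top_k_by_host_species(self):
        assert main_host_families(self._table(), k=2) == ["Cucurbitaceae", "Rutaceae"]

    def test_rank_by_fly_species(self):
        fams = main_host_families(self._table(), k=3, rank_by="n_fly_species")
        assert set(fams) == {"Cucurbitaceae", "Rutaceae", "Rosaceae"}

    def test_tie_break_is_alphabetical(self):
        t = AssociationTable.from_records(
            [
                ("f1", "Cucumis sativus", "Cucumis", "Cucurbitaceae"),
                ("f1", "Citrus limon", "Citrus", "Rutaceae"),
            ]
        )
        assert main_host_families(t, k=1) == ["Cucurbitaceae"]

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            main_host_families(self._table(), k=10)

    def test_tip_states_subset_of_families(self):
        states = tip_range_states(self._table(), ["Cucurbitaceae", "Rutaceae"])
        assert states["f1"] == frozenset({"Cucurbitaceae"})
        assert states["f2"] == frozenset({"Rutaceae"})

    def test_empty_tip_state_is_hard_error(self):
        with pytest.raises(ValueError, match="null DEC range"):
            tip_range_states(self._table(), ["Anacardiaceae"])
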