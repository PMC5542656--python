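import numpy as np
import pandas as pd
import pytest

from caninegbv.cohort_io import (
    Cohort,
    CohortError,
    Contingency2x2,
    contingency_2x2,
    cross_tabulate,
    dichotomize,
    dosage_matrix,
    encode_dosage,
    read_cohort,
    write_cohort,
)


class TestReadWrite:
    def test_csv_round_trip(self, tmp_path, toy_cohort, toy_panel):
        path = tmp_path / "cohort.csv"
        write_cohort(toy_cohort, path, header_comment="round-trip fixture")
        back = read_cohort(path, toy_panel)
        pd.testing.assert_frame_equal(back.genotypes, toy_cohort.genotypes)
        pd.testing.assert_frame_equal(back.phenotypes, toy_cohort.phenotypes)

    def test_xlsx_ingest(self, tmp_path, toy_cohort, toy_panel):
        path = tmp_path / "cohort.xlsx"
        out = pd.concat([toy_cohort.phenotypes, toy_cohort.genotypes], axis=1)
        out.to_excel(path, index_label="animal_id")
        back = read_cohort(path, toy_panel)
        pd.testing.assert_frame_equal(back.genotypes, toy_cohort.genotypes)

    def test_column_map_renames_headings(self, tmp_path, toy_cohort, toy_panel):
        path = tmp_path / "cohort.csv"
        out = pd.concat([toy_cohort.phenotypes, toy_cohort.genotypes], axis=1)
        out.index.name = "DogID"
        out.rename(columns={"chd_class": "HD", "ced_class": "ED"}).to_csv(path)
        back = read_cohort(
            path, toy_panel,
            column_map={"DogID": "animal_id", "HD": "chd_class", "ED": "ced_class"},
        )
        assert back.n_animals == toy_cohort.n_animals

    def test_wrong_strand_allele_names_marker(self, tmp_path, toy_panel):
        # M2 is a T/C marker; an A/C call (e.g. lagging-strand alleles) must fail
        path = tmp_path / "bad.csv"
        path.write_text(
            "animal_id,chd_class,ced_class,M1,M2,M3\n"
            "d1,1,1,A/A,A/C,C/C\n"
        )
        with pytest.raises(CohortError, match="M2"):
            read_cohort(path, toy_panel)

    def test_empty_file_rejected(self, tmp_path, toy_panel):
        path = tmp_path / "empty.csv"
        path.write_text("animal_id,chd_class,ced_class,M1,M2,M3\n")
        with pytest.raises(CohortError, match="empty"):
            read_cohort(path, toy_panel)

    def test_duplicate_animal_rejected(self, tmp_path, toy_panel):
        path = tmp_path / "dup.csv"
        path.write_text(
            "animal_id,chd_class,ced_class,M1\nd1,1,1,A/A\nd1,2,1,A/G\n"
        )
        with pytest.raises(CohortError, match="duplicate animal_id"):
            read_cohort(path, toy_panel)

    def test_class_out_of_range_rejected(self, tmp_path, toy_panel):
        path = tmp_path / "cls.csv"
        path.write_text("animal_id,chd_class,ced_class,M1\nd1,6,1,A/A\n")
        with pytest.raises(CohortError, match="chd_class"):
            read_cohort(path, toy_panel)

    @pytest.mark.parametrize("token", ["", "NA", "./."])
    def test_missing_tokens_become_missing(self, tmp_path, toy_panel, token):
        path = tmp_path / "miss.csv"
        path.write_text(
            f'animal_id,chd_class,ced_class,M1\nd1,{token},1,"{token}"\n'
        )
        cohort = read_cohort(path, toy_panel)
        assert cohort.genotypes["M1"].isna().all()
        assert cohort.phenotypes["chd_class"].isna().all()


class TestDosage:
    @pytest.mark.parametrize(
        "call, expected", [("A/A", 0), ("A/G", 1), ("G/A", 1), ("G/G", 2), (None, None)]
    )
    def test_mutant_allele_count(self, toy_panel, call, expected):
        assert encode_dosage(call, toy_panel["M1"]) == expected

    def test_symmetric_in_allele_order(self, toy_panel):
        m = toy_panel["M1"]
        assert encode_dosage("A/G", m) == encode_dosage("G/A", m)

    def test_foreign_allele_rejected(self, toy_panel):
        with pytest.raises(CohortError, match="M1"):
            encode_dosage("A/T", toy_panel["M1"])

    def test_dosage_matrix(self, toy_cohort):
        d = dosage_matrix(toy_cohort)
        assert d.loc["d1"].tolist() == [0, 0, 0]
        assert d.loc["d3"].tolist() == [2, 2, 2]
        assert pd.isna(d.loc["d4", "M2"])


class TestDichotomize:
    @pytest.mark.parametrize(
        "cls, scheme, expected",
        [(1, "affected", 0), (2, "affected", 1), (5, "affected", 1),
         (4, "severe", 0), (5, "severe", 1), (1, "severe", 0)],
    )
    def test_schemes(self, cls, scheme, expected):
        assert dichotomize(cls, scheme) == expected

    def test_severe_implies_affected(self):
        for cls in range(1, 6):
            assert dichotomize(cls, "severe") <= dichotomize(cls, "affected")

    def test_missing_propagates_and_range_checked(self):
        assert dichotomize(None, "affected") is None
        with pytest.raises(CohortError):
            dichotomize(0, "affected")
        with pytest.raises(CohortError):
            dichotomize(3, "worst")

    def test_series_dichotomy(self):
        s = pd.Series([1, 2, 5, pd.NA], dtype="Int64")
        out = dichotomize(s, "affected")
        assert out.tolist()[:3] == [0, 1, 1] and pd.isna(out.iloc[3])


class TestCrossTabulate:
    def test_class_distribution_sums_to_included(self, toy_cohort):
        table, excluded = cross_tabulate(toy_cohort, "ced")
        assert table.loc["ced"].sum() + excluded == toy_cohort.n_animals
        assert excluded == 1  # d4 has no CED class

    def test_two_by_two_layout(self, toy_cohort):
        table, excluded = cross_tabulate(toy_cohort, "ced:affected", "chd:affected")
        t = contingency_2x2(table)
        # d1 neither, d2 chd-only, d3 both, d5 ced-only; d4 excluded
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)
        assert excluded == 1
        assert t.total + excluded == toy_cohort.n_animals

    def test_single_animal_cohort(self, toy_panel):
        geno = pd.DataFrame(
            {"M1": ["A/A"]}, index=pd.Index(["solo"], name="animal_id")
        )
        pheno = pd.DataFrame({"chd_class": [3], "ced_class": [1]}, index=geno.index)
        cohort = Cohort(geno, pheno, toy_panel)
        table, excluded = cross_tabulate(cohort, "chd")
        assert table.loc["chd"].sum() == 1 and excluded == 0
        assert table.loc["chd", 3] == 1

    def test_unknown_spec_rejected(self, toy_cohort):
        with pytest.raises(CohortError, match="unknown phenotype spec"):
            cross_tabulate(toy_cohort, "weight")


class TestContingency:
    def test_negative_or_empty_rejected(self):
        with pytest.raises(CohortError):
            Contingency2x2(-1, 2, 3, 4)
        with pytest.raises(CohortError):
            Contingency2x2(0, 0, 0, 0)
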