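import numpy as np
import pandas as pd
import pytest

import peddrugsafe as pds

from conftest import make_encounters


def cohort(drug_rows, dx_rows, alpha=0.05):
    enc = make_encounters(drug_rows, dx_rows)
    assoc = pds.enrich(pds.build_pairs(enc), alpha=alpha)
    return enc, assoc


@pytest.fixture
def paired_cohorts():
    """Cohort A and B sharing drug dA/diagnosis gx; B adds its own codes."""
    a = cohort(
        [("e1", "dA"), ("e2", "dA"), ("e3", "dB")],
        [("e1", "gx"), ("e2", "gx"), ("e3", "gy")],
    )
    b = cohort(
        [("f1", "dA"), ("f2", "dC"), ("f3", "dC")],
        [("f1", "gx"), ("f2", "gz"), ("f3", "gz")],
    )
    return a, b


class TestIncidence:
    def test_ubiquitous_diagnosis_is_1000_permille(self):
        enc = make_encounters([("e1", "d")], [("e1", "g"), ("e2", "g")])
        assert pds.incidence(enc)["g"] == pytest.approx(1000.0)

    def test_direct_ratio(self):
        dx = [(f"e{i}", "common") for i in range(2000)] + [("e0", "rare")]
        enc = make_encounters([("e0", "d")], dx)
        inc = pds.incidence(enc)
        assert inc["rare"] == pytest.approx(0.5)
        assert inc["common"] == pytest.approx(1000.0)

    def test_absent_diagnosis_defaults_to_zero_in_alignment(self, paired_cohorts):
        (enc_a, assoc_a), (enc_b, assoc_b) = paired_cohorts
        table = pds.align_by_diagnosis(assoc_a, assoc_b, enc_a, enc_b)
        only_a = table.set_index("diagnosis_code").loc["gy"]
        assert only_a["incidence_B"] == 0.0 and not only_a["present_in_B"]


class TestAlignment:
    def test_identical_cohorts_overlap_completely(self):
        enc, assoc = cohort(
            [("e1", "dA"), ("e2", "dA")], [("e1", "gx"), ("e2", "gx")]
        )
        table = pds.align_by_diagnosis(assoc, assoc, enc, enc)
        assert (table["n_assoc_overlap"] == table["n_assoc_drugs_A"]).all()
        assert (table["n_assoc_drugs_A"] == table["n_assoc_drugs_B"]).all()

    def test_union_completeness_and_overlap_bound(self, paired_cohorts):
        (enc_a, assoc_a), (enc_b, assoc_b) = paired_cohorts
        table = pds.align_by_diagnosis(assoc_a, assoc_b, enc_a, enc_b)
        assert sorted(table["diagnosis_code"]) == sorted(
            set(enc_a.diagnoses) | set(enc_b.diagnoses)
        )
        assert (
            table["n_assoc_overlap"]
            <= table[["n_assoc_drugs_A", "n_assoc_drugs_B"]].min(axis=1)
        ).all()

    def test_diagnosis_overlap_matches_hand_set_arithmetic(self):
        # significant sets by construction: strong co-occurrence of
        # (d1,g1), (d2,g1) in A; (d1,g1) in B -> overlap on g1 is {d1}
        a_drugs = [(f"e{i}", d) for i in range(30) for d in ("d1", "d2")]
        a_dx = [(f"e{i}", "g1") for i in range(30)] + [("x1", "g9")]
        b_drugs = [(f"f{i}", "d1") for i in range(30)] + [("y1", "d3")]
        b_dx = [(f"f{i}", "g1") for i in range(30)] + [("y1", "g8")]
        (enc_a, assoc_a) = cohort(a_drugs + [("x1", "d9")], a_dx)
        (enc_b, assoc_b) = cohort(b_drugs, b_dx)
        table = pds.align_by_diagnosis(assoc_a, assoc_b, enc_a, enc_b).set_index(
            "diagnosis_code"
        )
        sa = set(assoc_a.significant_pairs().query("diagnosis_code=='g1'")["drug_code"])
        sb = set(assoc_b.significant_pairs().query("diagnosis_code=='g1'")["drug_code"])
        assert table.loc["g1", "n_assoc_overlap"] == len(sa & sb)

    def test_align_by_drug_swap_symmetry(self, paired_cohorts):
        (enc_a, assoc_a), (enc_b, assoc_b) = paired_cohorts
        ab = pds.align_by_drug(assoc_a, assoc_b, enc_a, enc_b)
        ba = pds.align_by_drug(assoc_b, assoc_a, enc_b, enc_a)
        swapped = ba.rename(
            columns={
                "present_in_A": "present_in_B", "present_in_B": "present_in_A",
                "use_volume_A": "use_volume_B", "use_volume_B": "use_volume_A",
                "n_assoc_dx_A": "n_assoc_dx_B", "n_assoc_dx_B": "n_assoc_dx_A",
            }
        )[ab.columns]
        pd.testing.assert_frame_equal(ab, swapped)

    def test_drug_only_in_b_has_zero_a_fields(self, paired_cohorts):
        (enc_a, assoc_a), (enc_b, assoc_b) = paired_cohorts
        table = pds.align_by_drug(assoc_a, assoc_b, enc_a, enc_b).set_index("drug_code")
        row = table.loc["dC"]
        assert row["use_volume_A"] == 0 and row["n_assoc_dx_A"] == 0
        assert not row["present_in_A"]


class TestGroupAlignment:
    def _planted_table(self):
        rows = []
        for i in range(10):  # A-only block
            rows.append(("a%d" % i, True, False, 5.0, 0.0, 8, 0, 0))
        for i in range(10):  # B-only block
            rows.append(("b%d" % i, False, True, 0.0, 5.0, 0, 8, 0))
        return pd.DataFrame(
            rows,
            columns=[
                "diagnosis_code", "present_in_A", "present_in_B",
                "incidence_A", "incidence_B",
                "n_assoc_drugs_A", "n_assoc_drugs_B", "n_assoc_overlap",
            ],
        )

    def test_two_planted_blocks_separate_perfectly(self):
        from sklearn.metrics import adjusted_rand_score

        table = self._planted_table()
        groups = pds.group_alignment(table, n_groups=2)
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_score(truth, groups.to_numpy()) == 1.0

    def test_n_groups_equal_rows_gives_singletons(self):
        table = self._planted_table().iloc[:5]
        groups = pds.group_alignment(table, n_groups=5)
        assert groups.nunique() == 5

    def test_duplicated_rows_share_group(self):
        table = self._planted_table()
        groups = pds.group_alignment(table, n_groups=2)
        assert groups.iloc[0] == groups.iloc[1]

    def test_too_many_groups_rejected(self):
        with pytest.raises(ValueError):
            pds.group_alignment(self._planted_table(), n_groups=21)


class TestCategoryComposition:
    def test_single_category_is_100(self):
        groups = pd.Series([1, 1], index=[0, 1])
        codes = pd.Series(["J12", "J20"], index=[0, 1])
        comp = pds.category_composition(groups, codes, {"J12": "X", "J20": "X"})
        assert comp.loc[1, "X"] == pytest.approx(100.0)

    def test_even_split(self):
        groups = pd.Series([1] * 4)
        codes = pd.Series(["a", "b", "c", "d"])
        comp = pds.category_composition(
            groups, codes, {"a": "u", "b": "u", "c": "v", "d": "v"}
        )
        assert comp.loc[1, "u"] == pytest.approx(50.0)
        assert comp.loc[1, "v"] == pytest.approx(50.0)

    def test_hand_tally_with_unmapped(self):
        groups = pd.Series([1, 1, 1, 2, 2])
        codes = pd.Series(["a", "b", "q", "a", "z"])
        comp = pds.category_composition(groups, codes, {"a": "u", "b": "v"})
        assert comp.loc[1, "u"] == pytest.approx(100 / 3)
        assert comp.loc[1, "unmapped"] == pytest.approx(100 / 3)
        assert comp.loc[2, "u"] == pytest.approx(50.0)
        np.testing.assert_allclose(comp.sum(axis=1), 100.0, atol=1e-9)
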