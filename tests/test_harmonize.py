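import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate.harmonize import (
    align_record,
    harmonize_tables,
    is_palindromic,
    orient_to_frame,
)

from conftest import make_table


@pytest.mark.parametrize(
    "ea,oa,expected",
    [("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
     ("A", "G", False), ("C", "T", False), ("A", "C", False)],
)
def test_is_palindromic(ea, oa, expected):
    assert is_palindromic(ea, oa) is expected


def _row(**kw):
    base = {
        "variant_id": "rs1", "chrom": "1", "pos": 100,
        "effect_allele": "A", "other_allele": "G",
        "eaf": 0.3, "beta": 0.1, "se": 0.01, "pvalue": 1e-10, "n": 1e5,
    }
    base.update(kw)
    return pd.Series(base)


class TestAlignRecord:
    def test_swapped_alleles_flip_sign_and_frequency(self):
        exp = _row(beta=0.10)
        out = _row(effect_allele="G", other_allele="A", beta=-0.05, eaf=0.30)
        rec = align_record(exp, out)
        assert rec["action"] == "flipped"
        assert rec["Gamma"] == pytest.approx(0.05)
        assert rec["eaf_y"] == pytest.approx(0.70)

    def test_strand_complement_aligned(self):
        exp = _row()
        out = _row(effect_allele="T", other_allele="C", beta=0.07)
        rec = align_record(exp, out)
        assert rec["action"] == "kept"
        assert rec["Gamma"] == pytest.approx(0.07)

    def test_palindrome_same_side_kept(self):
        exp = _row(effect_allele="A", other_allele="T", eaf=0.10)
        out = _row(effect_allele="A", other_allele="T", eaf=0.12, beta=0.02)
        rec = align_record(exp, out, freq_window=(0.42, 0.58))
        assert rec["action"] == "kept"
        assert rec["Gamma"] == pytest.approx(0.02)

    def test_palindrome_opposite_side_inferred_flip(self):
        exp = _row(effect_allele="A", other_allele="T", eaf=0.10)
        out = _row(effect_allele="A", other_allele="T", eaf=0.88, beta=0.02)
        rec = align_record(exp, out)
        assert rec["action"] == "palindrome_inferred"
        assert rec["Gamma"] == pytest.approx(-0.02)
        assert rec["eaf_y"] == pytest.approx(0.12)

    def test_palindrome_inside_window_dropped(self):
        exp = _row(effect_allele="C", other_allele="G", eaf=0.30)
        out = _row(effect_allele="C", other_allele="G", eaf=0.48)
        rec = align_record(exp, out)
        assert rec["action"] == "dropped_ambiguous"

    def test_incompatible_pair_dropped(self):
        exp = _row()
        out = _row(effect_allele="A", other_allele="C")
        rec = align_record(exp, out)
        assert rec["action"] == "dropped_incompatible"

    def test_mismatched_variant_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            align_record(_row(), _row(variant_id="rs2"))

    def test_magnitudes_never_altered(self):
        exp = _row()
        out = _row(effect_allele="G", other_allele="A", beta=-0.05, se=0.033)
        rec = align_record(exp, out)
        assert abs(rec["Gamma"]) == pytest.approx(0.05)
        assert rec["se_y"] == pytest.approx(0.033)


class TestHarmonizeTables:
    def _mixed_fixture(self):
        exp_rows = [
            {"variant_id": "v1", "pos": 1},
            {"variant_id": "v2", "pos": 2, "beta": 0.10},
            {"variant_id": "v3", "pos": 3},
            {"variant_id": "v4", "pos": 4, "effect_allele": "A", "other_allele": "T", "eaf": 0.10},
            {"variant_id": "v5", "pos": 5, "effect_allele": "A", "other_allele": "T", "eaf": 0.10},
            {"variant_id": "v6", "pos": 6, "effect_allele": "C", "other_allele": "G", "eaf": 0.30},
            {"variant_id": "v7", "pos": 7},
        ]
        out_rows = [
            {"variant_id": "v1", "pos": 1},                                     # kept
            {"variant_id": "v2", "pos": 2, "effect_allele": "G",
             "other_allele": "A", "beta": -0.05, "eaf": 0.30},                  # flipped
            {"variant_id": "v3", "pos": 3, "effect_allele": "T",
             "other_allele": "C"},                                              # strand → kept
            {"variant_id": "v4", "pos": 4, "effect_allele": "A",
             "other_allele": "T", "eaf": 0.12},                                 # palindrome kept
            {"variant_id": "v5", "pos": 5, "effect_allele": "A",
             "other_allele": "T", "eaf": 0.88},                                 # inferred flip
            {"variant_id": "v6", "pos": 6, "effect_allele": "C",
             "other_allele": "G", "eaf": 0.48},                                 # ambiguous
            {"variant_id": "v7", "pos": 7, "effect_allele": "A",
             "other_allele": "C"},                                              # incompatible
        ]
        return make_table(exp_rows, "exp"), make_table(out_rows, "out")

    def test_mixed_fixture_audit(self):
        exp, out = self._mixed_fixture()
        h = harmonize_tables(exp, out)
        assert dict(h.audit) == {
            "kept": 3,
            "flipped": 1,
            "palindrome_inferred": 1,
            "dropped_ambiguous": 1,
            "dropped_incompatible": 1,
        }
        assert sum(h.audit.values()) == 7
        assert len(h) == 5

    def test_disjoint_tables_empty_result(self):
        exp = make_table([{"variant_id": "a"}])
        out = make_table([{"variant_id": "b"}])
        h = harmonize_tables(exp, out)
        assert len(h) == 0
        assert sum(h.audit.values()) == 0

    def test_self_harmonization_is_identity(self):
        exp, _ = self._mixed_fixture()
        h = harmonize_tables(exp, exp)
        kept = h.df
        np.testing.assert_allclose(kept["gamma"], kept["Gamma"])

    def test_output_in_genomic_order(self):
        exp, out = self._mixed_fixture()
        h = harmonize_tables(exp, out)
        pos = list(h.df["pos"])
        assert pos == sorted(pos)


ALLELES = st.sampled_from("ACGT")


@settings(derandomize=True, max_examples=200)
@given(
    ea=ALLELES, oa=ALLELES,
    eaf_x=st.floats(0.01, 0.99), eaf_y=st.floats(0.01, 0.99),
    beta=st.floats(-1, 1, allow_nan=False),
)
def test_double_flip_identity(ea, oa, eaf_x, eaf_y, beta):
    """Recoding the outcome study (swap alleles, negate beta, complement
    frequency) never changes the harmonized effect."""
    if ea == oa:
        return
    # stay clear of the palindrome frequency-window boundaries, where the
    # kept/dropped decision is legitimately knife-edge
    for f in (eaf_x, eaf_y, 1 - eaf_x, 1 - eaf_y):
        if abs(f - 0.42) < 1e-6 or abs(f - 0.58) < 1e-6:
            return
    exp = _row(effect_allele=ea, other_allele=oa, eaf=eaf_x)
    out1 = _row(effect_allele=ea, other_allele=oa, eaf=eaf_y, beta=beta)
    out2 = _row(effect_allele=oa, other_allele=ea, eaf=1 - eaf_y, beta=-beta)
    r1 = align_record(exp, out1)
    r2 = align_record(exp, out2)
    assert r1["action"].startswith("dropped") == r2["action"].startswith("dropped")
    if not r1["action"].startswith("dropped"):
        assert r1["Gamma"] == pytest.approx(r2["Gamma"], abs=1e-12)


@settings(derandomize=True, max_examples=100)
@given(ea=ALLELES, oa=ALLELES, eaf=st.floats(0.01, 0.99))
def test_orientation_sign_only_modifies_beta(ea, oa, eaf):
    """orient_to_frame returns sign ±1 for retained records, 0 for drops."""
    if ea == oa:
        return
    action, sign = orient_to_frame(ea, oa, ea, oa, eaf, eaf)
    if action.startswith("dropped"):
        assert sign == 0
    else:
        assert sign in (-1, 1)
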