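"""Table IO, allele harmonization, QC filtering and exclusion lists."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_instrument, make_outcome
from summr.errors import HarmonizationError, ValidationError
from summr.estimate import ivw_from_harmonized
from summr.instrument_io import (
    InstrumentVariant,
    OutcomeAssociation,
    VariantQCRecord,
    estimable,
    exclude_variants,
    harmonize,
    qc_filter,
    read_instrument_table,
    reoriented,
    write_instrument_table,
)

HEADER = "rsid\teffect_allele\tother_allele\tbeta_exposure\tse_exposure\tlocus_label\n"


def _write(tmp_path, body, header=HEADER):
    path = tmp_path / "instruments.tsv"
    path.write_text(header + body)
    return path


class TestReadInstrumentTable:
    def test_reads_full_fi_sized_table_preserving_order(self, tmp_path, rng):
        variants = [
            make_instrument(rsid=f"rs{i}", beta=float(rng.uniform(-0.1, 0.1)) or 0.01, locus=("FTO" if i == 3 else None))
            for i in range(18)
        ]
        path = tmp_path / "fi.tsv"
        write_instrument_table(path, variants, header_comments=["seed=1"])
        got = read_instrument_table(path)
        assert got == variants

    def test_header_only_gives_empty_list(self, tmp_path):
        assert read_instrument_table(_write(tmp_path, "")) == []

    def test_comment_lines_ignored(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("# seed=42\n" + HEADER + "rs1\tA\tG\t0.03\t0.01\t\n")
        assert len(read_instrument_table(path)) == 1

    @pytest.mark.parametrize(
        "body,match",
        [
            ("rs1\tA\tG\t0.03\t0\t\n", "row 1"),  # zero se violates invariant
            ("rs1\tA\tG\t0.03\t0.01\t\nrs2\tA\tG\tlots\t0.01\t\n", "row 2"),  # non-numeric beta
            ("rs1\tA\tG\t0.03\t0.01\t\nrs1\tA\tG\t0.04\t0.01\t\n", "duplicate rsid"),
        ],
    )
    def test_bad_rows_rejected_with_row_number(self, tmp_path, body, match):
        with pytest.raises(ValidationError, match=match):
            read_instrument_table(_write(tmp_path, body))

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("rsid\teffect_allele\tbeta_exposure\nrs1\tA\t0.03\n")
        with pytest.raises(ValidationError, match="missing column"):
            read_instrument_table(path)


class TestRecordInvariants:
    def test_identical_alleles_rejected(self):
        with pytest.raises(ValidationError):
            make_instrument(ea="A", oa="A")

    def test_invalid_allele_letter_rejected(self):
        with pytest.raises(ValidationError):
            make_instrument(ea="N")

    def test_qc_record_range_checked(self):
        with pytest.raises(ValidationError):
            VariantQCRecord("rs1", call_rate=1.2, maf=0.1, hwe_p_cases=0.5, hwe_p_controls=0.5, imputed=False)


def _expected_action(inst_ea, inst_oa, out_ea, out_oa, policy):
    """Independent restatement of the harmonization policy, built by enumeration."""
    if policy == "strict" and {inst_ea, inst_oa} in ({"A", "T"}, {"C", "G"}):
        return "dropped_palindromic"
    if (out_ea, out_oa) == (inst_ea, inst_oa):
        return "as_is"
    if (out_ea, out_oa) == (inst_oa, inst_ea):
        return "swapped"
    return "dropped_mismatch"


class TestHarmonize:
    def test_matching_alleles_pass_through(self):
        [h] = harmonize([make_instrument(beta=0.03)], [make_outcome(logor=0.10)], "UK")
        assert h.harmonization_action == "as_is"
        assert h.logor_outcome == pytest.approx(0.10)

    def test_swapped_alleles_flip_outcome_sign(self):
        [h] = harmonize([make_instrument(beta=0.03)], [make_outcome(ea="G", oa="A", logor=0.10)], "UK")
        assert h.harmonization_action == "swapped"
        assert h.logor_outcome == pytest.approx(-0.10)

    @pytest.mark.parametrize("inst_ea,inst_oa", [("A", "G"), ("A", "T"), ("C", "G")])
    @pytest.mark.parametrize("policy", ["trust", "strict"])
    def test_action_matches_enumerated_policy_table(self, inst_ea, inst_oa, policy):
        # every outcome allele pair against each instrument pair and policy
        for out_ea, out_oa in itertools.permutations("ACGT", 2):
            [h] = harmonize(
                [make_instrument(ea=inst_ea, oa=inst_oa)],
                [make_outcome(ea=out_ea, oa=out_oa)],
                "UK",
                palindromic_policy=policy,
            )
            assert h.harmonization_action == _expected_action(inst_ea, inst_oa, out_ea, out_oa, policy), (
                inst_ea, inst_oa, out_ea, out_oa, policy,
            )

    def test_negative_exposure_effect_reoriented(self):
        [h] = harmonize([make_instrument(beta=-0.03)], [make_outcome(logor=0.10)], "UK")
        assert h.beta_exposure == pytest.approx(0.03)
        assert h.logor_outcome == pytest.approx(-0.10)

    def test_sign_convention_invariance_of_estimate(self, rng):
        instruments = [
            make_instrument(rsid=f"rs{i}", beta=float(rng.normal(0, 0.05)) or 0.01) for i in range(8)
        ]
        outcomes = [make_outcome(rsid=f"rs{i}", logor=float(rng.normal(0, 0.1))) for i in range(8)]
        flipped = [reoriented(iv) for iv in instruments]
        est_a = ivw_from_harmonized(harmonize(instruments, outcomes, "UK"))
        est_b = ivw_from_harmonized(harmonize(flipped, outcomes, "UK"))
        assert est_a == pytest.approx(est_b)

    def test_idempotent_on_already_harmonized_tables(self, rng):
        instruments = [make_instrument(rsid=f"rs{i}", beta=float(rng.uniform(0.01, 0.1))) for i in range(6)]
        outcomes = [make_outcome(rsid=f"rs{i}", logor=float(rng.normal(0, 0.1))) for i in range(6)]
        once = harmonize(instruments, outcomes, "UK")
        # express the harmonized records back as tables in the aligned orientation
        inst2 = [
            InstrumentVariant(h.rsid, "A", "G", h.beta_exposure, h.se_exposure) for h in once
        ]
        out2 = [
            OutcomeAssociation(h.rsid, "A", "G", h.logor_outcome, h.se_outcome, "UK") for h in once
        ]
        assert harmonize(inst2, out2, "UK") == once

    def test_missing_instruments_warned_not_dropped_silently(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="summr.instrument_io"):
            got = harmonize(
                [make_instrument(rsid="rs1"), make_instrument(rsid="rs2")],
                [make_outcome(rsid="rs1")],
                "UK",
            )
        assert [h.rsid for h in got] == ["rs1"]
        assert "rs2" in caplog.text

    def test_zero_overlap_is_hard_error(self):
        with pytest.raises(HarmonizationError):
            harmonize([make_instrument(rsid="rs1")], [make_outcome(rsid="rs9")], "UK")

    def test_dropped_records_are_not_estimable(self):
        got = harmonize(
            [make_instrument(ea="A", oa="T")], [make_outcome(ea="A", oa="T")], "UK", palindromic_policy="strict"
        )
        assert estimable(got) == []


class TestQCFilter:
    @pytest.mark.parametrize(
        "kwargs,expect_pass,reason",
        [
            (dict(call_rate=0.96, maf=0.10), True, None),  # common variant branch
            (dict(call_rate=0.96, maf=0.01), False, "call_rate/maf"),  # between branches
            (dict(call_rate=0.99, maf=0.01), True, None),  # rare variant branch
            (dict(call_rate=0.95, maf=0.05), True, None),  # inclusive boundaries
            (dict(hwe_p_cases=1e-12), False, "hwe_cases"),  # strict: equality fails
            (dict(hwe_p_controls=1e-7), False, "hwe_controls"),
            (dict(imputed=True, imputation_r2=0.59), False, "imputation_r2"),
            (dict(imputed=True, imputation_r2=0.60), True, None),
            (dict(imputed=False, imputation_r2=0.0), True, None),  # r2 ignored when genotyped
        ],
    )
    def test_threshold_rules(self, kwargs, expect_pass, reason):
        base = dict(call_rate=0.99, maf=0.2, hwe_p_cases=0.5, hwe_p_controls=0.5, imputed=False, imputation_r2=1.0)
        base.update(kwargs)
        passed, failed = qc_filter([VariantQCRecord("rs1", **base)])
        if expect_pass:
            assert passed == ["rs1"] and failed == []
        else:
            assert passed == [] and failed == [("rs1", reason)]

    @given(
        st.lists(
            st.tuples(
                st.floats(0.9, 1.0), st.floats(0.0, 0.5), st.floats(0, 1), st.floats(0, 1), st.booleans(), st.floats(0, 1)
            ),
            max_size=30,
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_partitions_input(self, rows):
        records = [VariantQCRecord(f"rs{i}", *row) for i, row in enumerate(rows)]
        passed, failed = qc_filter(records)
        assert len(passed) + len(failed) == len(records)
        assert set(passed).isdisjoint({r for r, _ in failed})


class TestExcludeVariants:
    def test_locus_exclusion_mirrors_secretion_set(self, rng):
        # 19 variants, two tagged with the loci to drop -> 17 remain
        loci = [None] * 19
        loci[4], loci[11] = "DGKB", "TFB1M"
        variants = [make_instrument(rsid=f"rs{i}", locus=loci[i]) for i in range(19)]
        kept = exclude_variants(variants, {"DGKB", "TFB1M"})
        assert len(kept) == 17
        assert all(iv.locus_label not in ("DGKB", "TFB1M") for iv in kept)

    def test_rsid_exclusion_for_sensitivity_set(self):
        variants = [make_instrument(rsid=f"rs{i}") for i in range(18)]
        kept = exclude_variants(variants, {"rs7"})
        assert len(kept) == 17

    def test_empty_exclusion_is_identity(self):
        variants = [make_instrument(rsid=f"rs{i}") for i in range(5)]
        assert exclude_variants(variants, set()) == variants

    def test_unmatched_names_warn_not_error(self, caplog):
        import logging

        variants = [make_instrument(rsid="rs1")]
        with caplog.at_level(logging.WARNING, logger="summr.instrument_io"):
            kept = exclude_variants(variants, {"NOPE"})
        assert kept == variants
        assert "NOPE" in caplog.text
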