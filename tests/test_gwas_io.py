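"""I/O round-trips, row validation, and allele harmonization."""

import numpy as np
import pandas as pd
import pytest

from mrpipe.exceptions import HarmonizationError, SchemaError
from mrpipe.gwas_io import (
    harmonize, read_summary_stats, table_from_dataframe, write_summary_stats,
)
from mrpipe.synthgwas import SimulationConfig, simulate_pair

from conftest import make_table


class TestReadWrite:
    def test_well_formed_tsv(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "snp\teffect_allele\tother_allele\tbeta\tse\tpval\n"
            "rs1\tA\tG\t0.1\t0.01\t1e-8\n"
            "rs2\tC\tT\t-0.2\t0.02\t1e-7\n"
            "rs3\tT\tG\t0.3\t0.03\t1e-6\n"
        )
        table = read_summary_stats(path)
        assert table.n_variants == 3
        assert table.n_rejected == 0

    @pytest.mark.parametrize("field,value,reason_part", [
        ("se", "0", "non-positive se"),
        ("se", "-1", "non-positive se"),
        ("pval", "0", "pval outside"),
        ("pval", "1.5", "pval outside"),
        ("beta", "not_a_number", "unparseable beta"),
    ])
    def test_bad_rows_rejected_with_reason(self, tmp_path, field, value, reason_part):
        row = {"snp": "rs1", "effect_allele": "A", "other_allele": "G",
               "beta": "0.1", "se": "0.01", "pval": "1e-8"}
        row[field] = value
        path = tmp_path / "t.tsv"
        path.write_text("\t".join(row) + "\n" + "\t".join(row.values()) + "\n")
        table = read_summary_stats(path)
        assert table.n_variants == 0
        assert table.n_rejected == 1
        assert reason_part in table.rejections["reason"].iloc[0]

    def test_missing_mandatory_column_is_fatal(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("snp\tbeta\tse\tpval\nrs1\t0.1\t0.01\t0.5\n")
        with pytest.raises(SchemaError, match="mandatory"):
            read_summary_stats(path)

    def test_dialect_maps_custom_headers(self, tmp_path):
        canonical = tmp_path / "canonical.tsv"
        custom = tmp_path / "custom.tsv"
        canonical.write_text(
            "snp\teffect_allele\tother_allele\tbeta\tse\tpval\n"
            "rs1\tA\tG\t0.1\t0.01\t1e-8\n")
        custom.write_text(
            "SNP\tEA\tNEA\tb\tsebeta\tP\n"
            "rs1\tA\tG\t0.1\t0.01\t1e-8\n")
        a = read_summary_stats(canonical)
        b = read_summary_stats(custom, dialect={
            "snp": "SNP", "effect_allele": "EA", "other_allele": "NEA",
            "beta": "b", "se": "sebeta", "pval": "P"})
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_empty_table_writes_header_only(self, tmp_path):
        table = make_table([])
        path = tmp_path / "empty.tsv"
        write_summary_stats(table, path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 1
        assert lines[0].startswith("snp\t")

    def test_three_records_write_four_lines(self, tmp_path, basic_tables):
        exposure, _ = basic_tables
        path = tmp_path / "t.tsv"
        write_summary_stats(exposure, path)
        assert len(path.read_text().strip().split("\n")) == 4

    def test_random_table_roundtrip_identity(self, tmp_path, rng):
        n = 100
        df = pd.DataFrame({
            "snp": [f"rs{i}" for i in range(n)],
            "chr": rng.choice([str(c) for c in range(1, 23)], n),
            "pos": rng.integers(1, 2**28, n),
            "effect_allele": rng.choice(["A", "C", "G", "T"], n),
            "other_allele": "GTAC" * 25,  # may equal EA; those rows reject
            "eaf": rng.uniform(0.01, 0.99, n),
            "beta": rng.normal(0, 0.3, n),
            "se": rng.uniform(0.001, 0.1, n),
            "pval": rng.uniform(1e-12, 1, n),
            "n": rng.integers(1000, 500000, n),
        })
        df["other_allele"] = list("GTAC" * 25)
        table = table_from_dataframe(df, trait_id="random")
        path = tmp_path / "random.tsv"
        write_summary_stats(table, path)
        back = read_summary_stats(path, trait_id="random")
        pd.testing.assert_frame_equal(table.data, back.data)

    def test_gzip_transparent_roundtrip(self, tmp_path, basic_tables):
        exposure, _ = basic_tables
        path = tmp_path / "t.tsv.gz"
        write_summary_stats(exposure, path)
        back = read_summary_stats(path)
        pd.testing.assert_frame_equal(exposure.data, back.data)


class TestHarmonize:
    def test_matching_alleles_unchanged(self):
        exp = make_table([{"snp": "rs1", "effect_allele": "A", "other_allele": "G",
                           "beta": 0.10, "se": 0.01, "pval": 1e-8}])
        out = make_table([{"snp": "rs1", "effect_allele": "A", "other_allele": "G",
                           "beta": 0.05, "se": 0.01, "pval": 0.1}])
        h = harmonize(exp, out)
        assert h.n_snp == 1
        assert h.by[0] == pytest.approx(0.05)
        assert not h.data["flipped"].iloc[0]

    def test_swapped_alleles_flip_beta(self):
        exp = make_table([{"snp": "rs1", "effect_allele": "A", "other_allele": "G",
                           "beta": 0.10, "se": 0.01, "pval": 1e-8}])
        out = make_table([{"snp": "rs1", "effect_allele": "G", "other_allele": "A",
                           "beta": 0.05, "se": 0.01, "pval": 0.1, "eaf": 0.7}])
        h = harmonize(exp, out)
        assert h.by[0] == pytest.approx(-0.05)
        assert h.data["flipped"].iloc[0]

    def test_strand_flipped_alleles_recognized(self):
        exp = make_table([{"snp": "rs1", "effect_allele": "A", "other_allele": "G",
                           "beta": 0.10, "se": 0.01, "pval": 1e-8}])
        out = make_table([{"snp": "rs1", "effect_allele": "T", "other_allele": "C",
                           "beta": 0.05, "se": 0.01, "pval": 0.1}])
        h = harmonize(exp, out)
        assert h.n_snp == 1
        assert h.by[0] == pytest.approx(0.05)

    def test_irreconcilable_alleles_dropped_with_reason(self):
        exp = make_table([{"snp": "rs1", "effect_allele": "A", "other_allele": "G",
                           "beta": 0.10, "se": 0.01, "pval": 1e-8},
                          {"snp": "rs2", "effect_allele": "A", "other_allele": "G",
                           "beta": 0.10, "se": 0.01, "pval": 1e-8}])
        out = make_table([{"snp": "rs1", "effect_allele": "A", "other_allele": "C",
                           "beta": 0.05, "se": 0.01, "pval": 0.1},
                          {"snp": "rs2", "effect_allele": "A", "other_allele": "G",
                           "beta": 0.05, "se": 0.01, "pval": 0.1}])
        h = harmonize(exp, out)
        assert h.n_snp == 1
        assert list(h.dropped["snp"]) == ["rs1"]
        assert "mismatch" in h.dropped["reason"].iloc[0]

    @pytest.mark.parametrize("eaf_exp,eaf_out,expected", [
        (0.50, 0.50, "dropped"),   # dead-centre frequency: unresolvable
        (0.55, 0.55, "dropped"),   # inside the 0.08 ambiguity window
        (0.80, 0.80, "kept"),      # frequencies agree: orientation as-is
        (0.80, 0.20, "flipped"),   # frequencies disagree: strand flip implied
        (None, 0.80, "dropped"),   # missing exposure frequency
    ])
    def test_palindromic_infer_by_eaf(self, eaf_exp, eaf_out, expected):
        exp = make_table([{"snp": "rs1", "effect_allele": "A", "other_allele": "T",
                           "beta": 0.10, "se": 0.01, "pval": 1e-8,
                           "eaf": eaf_exp}])
        out = make_table([{"snp": "rs1", "effect_allele": "A", "other_allele": "T",
                           "beta": 0.05, "se": 0.01, "pval": 0.1,
                           "eaf": eaf_out}])
        h = harmonize(exp, out, palindrome_policy="infer_by_eaf")
        if expected == "dropped":
            assert h.n_snp == 0 and len(h.dropped) == 1
        elif expected == "kept":
            assert h.by[0] == pytest.approx(0.05)
        else:
            assert h.by[0] == pytest.approx(-0.05)

    def test_palindrome_policy_drop_and_keep(self):
        exp = make_table([{"snp": "rs1", "effect_allele": "C", "other_allele": "G",
                           "beta": 0.10, "se": 0.01, "pval": 1e-8, "eaf": 0.9}])
        out = make_table([{"snp": "rs1", "effect_allele": "C", "other_allele": "G",
                           "beta": 0.05, "se": 0.01, "pval": 0.1, "eaf": 0.9}])
        assert harmonize(exp, out, palindrome_policy="drop").n_snp == 0
        kept = harmonize(exp, out, palindrome_policy="keep")
        assert kept.n_snp == 1 and kept.by[0] == pytest.approx(0.05)

    def test_empty_intersection_fatal(self):
        exp = make_table([{"snp": "rs1", "effect_allele": "A", "other_allele": "G",
                           "beta": 0.10, "se": 0.01, "pval": 1e-8}])
        out = make_table([{"snp": "rs9", "effect_allele": "A", "other_allele": "G",
                           "beta": 0.05, "se": 0.01, "pval": 0.1}])
        with pytest.raises(HarmonizationError, match="no shared"):
            harmonize(exp, out)

    def test_retained_plus_dropped_equals_intersection(self):
        config = SimulationConfig(seed=7, palindromic_fraction=0.4)
        exposure, outcome, _ = simulate_pair(config)
        h = harmonize(exposure, outcome)
        assert h.n_snp + len(h.dropped) == config.n_snp

    def test_orientation_invariance(self, sim_pair):
        """Pre-flipping every outcome row (alleles + beta sign + eaf) is a no-op."""
        exposure, outcome, _ = sim_pair
        flipped = outcome.data.copy()
        flipped[["effect_allele", "other_allele"]] = \
            flipped[["other_allele", "effect_allele"]].to_numpy()
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1.0 - flipped["eaf"]
        out2 = table_from_dataframe(flipped, trait_id=outcome.trait_id)
        h1 = harmonize(exposure, outcome)
        h2 = harmonize(exposure, out2)
        np.testing.assert_allclose(h1.by, h2.by, atol=1e-14)
        np.testing.assert_allclose(h1.bx, h2.bx)

    def test_harmonization_is_involution(self, sim_pair):
        """Re-harmonizing the already-aligned outcome changes nothing."""
        exposure, outcome, _ = sim_pair
        h1 = harmonize(exposure, outcome)
        realigned = exposure.data.copy()
        realigned = realigned[realigned["snp"].isin(h1.data["snp"])]
        aligned_out = realigned.copy()
        merged = h1.data.set_index("snp")
        aligned_out["beta"] = [merged.loc[s, "beta_out"] for s in aligned_out["snp"]]
        aligned_out["se"] = [merged.loc[s, "se_out"] for s in aligned_out["snp"]]
        out2 = table_from_dataframe(aligned_out, trait_id=outcome.trait_id)
        exp2 = table_from_dataframe(realigned, trait_id=exposure.trait_id)
        h2 = harmonize(exp2, out2)
        np.testing.assert_allclose(h1.by, h2.by)
        assert not h2.data["flipped"].any()
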