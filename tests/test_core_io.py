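import numpy as np
import pytest

from dosagescope.core_io import (
    CnvRecord,
    GenomeBuild,
    GRCH37,
    MAMMAL_SPECIES,
    OrthologyStatus,
    read_bed,
    read_cnv_table,
    read_gene_table,
    read_orthology_table,
    write_bed,
)

from conftest import random_cnv_set


def write_cnv_tsv(path, rows):
    with open(path, "w") as fh:
        fh.write("id\tchrom\tstart\tend\ttype\tinterpretation\tstudy\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


class TestReadCnvTable:
    def test_one_based_inclusive_converted(self, tmp_path, toy_build):
        p = tmp_path / "cnvs.tsv"
        write_cnv_tsv(p, [("c1", "1", 1001, 2000, "gain", "benign", "s1")])
        (rec,) = read_cnv_table(p, "dbvar_tsv", toy_build)
        assert (rec.start, rec.end) == (1000, 2000)
        assert rec.length == 1000

    def test_bed_like_not_shifted(self, tmp_path, toy_build):
        p = tmp_path / "cnvs.tsv"
        write_cnv_tsv(p, [("c1", "1", 1000, 2000, "gain", "benign", "s1")])
        (rec,) = read_cnv_table(p, "bed_like", toy_build)
        assert (rec.start, rec.end) == (1000, 2000)

    def test_short_cnv_dropped(self, tmp_path, toy_build):
        # 49 bp is below the 50 bp minimum call length
        p = tmp_path / "cnvs.tsv"
        write_cnv_tsv(p, [("c1", "1", 100, 148, "loss", "benign", "s1")])
        assert read_cnv_table(p, "dbvar_tsv", toy_build) == []

    def test_long_cnv_dropped(self, tmp_path, toy_build):
        # 0.11 x chromosome length exceeds the tenth-of-chromosome cap
        L = toy_build.chrom_lengths["1"]
        p = tmp_path / "cnvs.tsv"
        write_cnv_tsv(p, [("c1", "1", 1, int(0.11 * L), "gain", "pathogenic", "s")])
        assert read_cnv_table(p, "dbvar_tsv", toy_build) == []
        write_cnv_tsv(p, [("c2", "1", 1, int(0.09 * L), "gain", "pathogenic", "s")])
        assert len(read_cnv_table(p, "dbvar_tsv", toy_build)) == 1

    def test_non_autosomal_dropped(self, tmp_path, toy_build):
        p = tmp_path / "cnvs.tsv"
        write_cnv_tsv(p, [("c1", "X", 100, 2000, "gain", "benign", "s")])
        assert read_cnv_table(p, "dbvar_tsv", toy_build) == []

    def test_unknown_chromosome_errors(self, tmp_path):
        build = GenomeBuild("partial", {"1": 1_000_000})
        p = tmp_path / "cnvs.tsv"
        write_cnv_tsv(p, [("c1", "2", 100, 2000, "gain", "benign", "s")])
        with pytest.raises(ValueError, match="not in build"):
            read_cnv_table(p, "dbvar_tsv", build)

    def test_unparsable_row_names_line(self, tmp_path, toy_build):
        p = tmp_path / "cnvs.tsv"
        write_cnv_tsv(p, [("c1", "1", 100, 2000, "gain", "benign", "s"),
                          ("c2", "1", "oops", 3000, "gain", "benign", "s")])
        with pytest.raises(ValueError, match=":3"):
            read_cnv_table(p, "dbvar_tsv", toy_build)

    def test_sorted_output(self, tmp_path, toy_build):
        p = tmp_path / "cnvs.tsv"
        write_cnv_tsv(p, [("a", "2", 5001, 6000, "gain", "benign", "s"),
                          ("b", "1", 9001, 9900, "loss", "benign", "s"),
                          ("c", "1", 101, 900, "gain", "benign", "s")])
        recs = read_cnv_table(p, "dbvar_tsv", toy_build)
        assert [r.id for r in recs] == ["c", "b", "a"]

    def test_filtering_is_idempotent(self, tmp_path, toy_build):
        rng = np.random.default_rng(11)
        cnvs = random_cnv_set(rng, 60, toy_build)
        p = tmp_path / "cnvs.tsv"
        write_cnv_tsv(
            p,
            [(c.id, c.chromosome, c.start, c.end, c.cnv_type.value,
              c.interpretation.value, "s") for c in cnvs],
        )
        once = read_cnv_table(p, "bed_like", toy_build)
        write_cnv_tsv(
            p,
            [(c.id, c.chromosome, c.start, c.end, c.cnv_type.value,
              c.interpretation.value, "s") for c in once],
        )
        twice = read_cnv_table(p, "bed_like", toy_build)
        assert [(c.id, c.start, c.end) for c in once] == [
            (c.id, c.start, c.end) for c in twice
        ]

    def test_surviving_records_satisfy_invariants(self, tmp_path):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(200):
            start = int(rng.integers(1, 40_000_000))
            length = int(rng.integers(10, 8_000_000))
            rows.append((f"c{i}", str(rng.integers(1, 23)), start, start + length,
                         "gain", "benign", "s"))
        p = tmp_path / "cnvs.tsv"
        write_cnv_tsv(p, rows)
        for rec in read_cnv_table(p, "dbvar_tsv", GRCH37):
            assert rec.length >= 50
            assert rec.length <= 0.1 * GRCH37.chrom_lengths[rec.chromosome]


class TestCnvRecordInvariants:
    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            CnvRecord("c", "1", 200, 100, "gain", "benign")

    def test_sub_minimum_length_rejected(self):
        with pytest.raises(ValueError, match="50"):
            CnvRecord("c", "1", 100, 130, "gain", "benign")

    def test_sex_chromosome_rejected(self):
        with pytest.raises(ValueError, match="autosomal"):
            CnvRecord("c", "X", 100, 900, "gain", "benign")


class TestReadGeneTable:
    def _write(self, path, header, rows):
        with open(path, "w") as fh:
            fh.write(header + "\n")
            for r in rows:
                fh.write("\t".join(str(x) for x in r) + "\n")

    def test_three_gene_toy_file(self, tmp_path):
        p = tmp_path / "genes.tsv"
        self._write(p, "gene_id\tchrom\tstart\tend\tstrand",
                    [("g3", "1", 5000, 6000, "+"),
                     ("g1", "1", 100, 900, "-"),
                     ("g2", "1", 2000, 2500, "+")])
        genes = read_gene_table(p)
        assert [g.gene_id for g in genes] == ["g1", "g2", "g3"]

    def test_missing_hi_score_column_marks_absent(self, tmp_path):
        p = tmp_path / "genes.tsv"
        self._write(p, "gene_id\tchrom\tstart\tend\tstrand",
                    [("g1", "1", 100, 900, "+")])
        (g,) = read_gene_table(p)
        assert g.hi_score is None and g.max_expression is None

    def test_duplicate_gene_id_errors(self, tmp_path):
        p = tmp_path / "genes.tsv"
        self._write(p, "gene_id\tchrom\tstart\tend\tstrand",
                    [("g1", "1", 100, 900, "+"), ("g1", "2", 100, 900, "+")])
        with pytest.raises(ValueError, match="g1"):
            read_gene_table(p)


class TestReadOrthologyTable:
    def _write(self, path, rows):
        with open(path, "w") as fh:
            fh.write("human_gene\tspecies\tstatus\n")
            for r in rows:
                fh.write("\t".join(r) + "\n")

    def test_full_one2one_profile(self, tmp_path):
        p = tmp_path / "orth.tsv"
        self._write(p, [("g1", sp, "one2one") for sp in MAMMAL_SPECIES])
        (prof,) = read_orthology_table(p)
        assert all(s is OrthologyStatus.ONE2ONE for s in prof.statuses.values())

    def test_missing_species_filled_as_none(self, tmp_path):
        p = tmp_path / "orth.tsv"
        self._write(p, [("g1", sp, "one2one") for sp in MAMMAL_SPECIES[:-1]])
        (prof,) = read_orthology_table(p)
        assert prof.statuses[MAMMAL_SPECIES[-1]] is OrthologyStatus.NONE
        assert len(prof.statuses) == 13

    def test_many2many_rejected(self, tmp_path):
        p = tmp_path / "orth.tsv"
        self._write(p, [("g1", MAMMAL_SPECIES[0], "many2many")])
        with pytest.raises(ValueError, match="many2many"):
            read_orthology_table(p)

    def test_unknown_species_rejected(self, tmp_path):
        p = tmp_path / "orth.tsv"
        self._write(p, [("g1", "tyrannosaurus_rex", "one2one")])
        with pytest.raises(ValueError, match="tyrannosaurus"):
            read_orthology_table(p)


class TestBedRoundTrip:
    def test_single_line(self, tmp_path):
        p = tmp_path / "out.bed"
        write_bed([("1", 0, 100, "r1", 2)], p)
        assert p.read_text() == "1\t0\t100\tr1\t2\n"

    def test_empty_list(self, tmp_path):
        p = tmp_path / "out.bed"
        write_bed([], p)
        assert p.read_text() == ""

    def test_unsorted_input_sorted_output(self, tmp_path):
        p = tmp_path / "out.bed"
        write_bed([("2", 5, 10, "b"), ("1", 50, 60, "a"), ("1", 5, 10, "c")], p)
        lines = p.read_text().splitlines()
        assert [l.split("\t")[3] for l in lines] == ["c", "a", "b"]

    def test_round_trip_preserves_coordinates(self, tmp_path, toy_build):
        rng = np.random.default_rng(3)
        cnvs = random_cnv_set(rng, 40, toy_build)
        rows = sorted(
            (c.chromosome, c.start, c.end, c.id, 1) for c in cnvs
        )
        p = tmp_path / "rt.bed"
        write_bed(rows, p)
        assert [(r[0], r[1], r[2]) for r in read_bed(p)] == [
            (r[0], r[1], r[2]) for r in rows
        ]
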