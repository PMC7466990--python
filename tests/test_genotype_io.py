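import numpy as np
import pytest

from goosepop.genotype_io import (
    MISSING,
    GenotypeMatrix,
    LocusRecord,
    PopulationMap,
    VcfParseError,
    allele_frequency,
    read_popmap,
    read_vcf,
    write_popmap,
    write_vcf,
)

HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=chr1>\n"
)


def _write(tmp_path, body, samples=("s1", "s2")):
    path = tmp_path / "t.vcf"
    cols = "\t".join(
        ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        + list(samples)
    )
    path.write_text(HEADER + cols + "\n" + body)
    return str(path)


class TestReadVcf:
    def test_toy_dosage_transcription(self, tmp_path):
        body = (
            "chr1\t10\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/0\n"
            "chr1\t20\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t0|1\n"
            "chr1\t30\t.\tG\tA\t.\tPASS\t.\tGT\t1/1\t1/1\n"
        )
        gm = read_vcf(_write(tmp_path, body))
        assert gm.individuals == ["s1", "s2"]
        assert [(l.chrom, l.pos, l.ref, l.alts) for l in gm.loci] == [
            ("chr1", 10, "A", ("G",)),
            ("chr1", 20, "C", ("T",)),
            ("chr1", 30, "G", ("A",)),
        ]
        # phase is ignored: 0/1 and 0|1 both give dosage 1
        assert gm.dosages.tolist() == [[0, 1, 2], [0, 1, 2]]

    def test_empty_vcf(self, tmp_path):
        gm = read_vcf(_write(tmp_path, ""))
        assert gm.n_loci == 0
        assert gm.n_individuals == 2

    def test_missing_and_half_calls(self, tmp_path):
        body = "chr1\t10\t.\tA\tG\t.\tPASS\t.\tGT\t./.\t./1\n"
        gm = read_vcf(_write(tmp_path, body))
        assert gm.dosages.tolist() == [[MISSING], [MISSING]]

    def test_multiallelic_retained(self, tmp_path):
        body = "chr1\t10\t.\tA\tG,T\t.\tPASS\t.\tGT\t1/2\t0/2\n"
        gm = read_vcf(_write(tmp_path, body))
        assert gm.loci[0].alts == ("G", "T")
        # any non-reference allele counts toward the alternate dosage
        assert gm.dosages.tolist() == [[2], [1]]

    def test_malformed_header_names_line(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("not a vcf\n")
        with pytest.raises(VcfParseError, match="line 1"):
            read_vcf(str(path))

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_vcf("/nonexistent/file.vcf")


class TestWriteVcf:
    def test_round_trip_identity(self, tmp_path, synth):
        gm, _, _ = synth
        path = tmp_path / "rt.vcf"
        write_vcf(gm, path)
        assert read_vcf(path) == gm

    def test_empty_matrix_header_only(self, tmp_path):
        gm = GenotypeMatrix(["a", "b"], [], np.empty((2, 0), dtype=np.int8))
        path = tmp_path / "e.vcf"
        write_vcf(gm, path)
        lines = path.read_text().splitlines()
        assert all(l.startswith("#") for l in lines)
        assert read_vcf(path) == gm

    def test_homozygote_encoding(self, tmp_path):
        gm = GenotypeMatrix(
            ["a", "b"],
            [LocusRecord("chr1", 5, "A", ("C",))],
            np.array([[0], [2]], dtype=np.int8),
        )
        path = tmp_path / "h.vcf"
        write_vcf(gm, path)
        record = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
        assert record.endswith("GT\t0/0\t1/1")


def _pm(pops):
    ind2pop = {i: p for p, inds in pops.items() for i in inds}
    return PopulationMap(ind2pop, {p: "wild" for p in pops})


class TestAlleleFrequency:
    def test_all_heterozygotes(self):
        gm = GenotypeMatrix(
            list("abcd"),
            [LocusRecord("c", 1, "A", ("C",))],
            np.ones((4, 1), dtype=np.int8),
        )
        freq, count = allele_frequency(gm, "p", _pm({"p": list("abcd")}))
        assert freq[0] == 0.5
        assert count[0] == 8

    def test_with_missing(self):
        gm = GenotypeMatrix(
            list("abc"),
            [LocusRecord("c", 1, "A", ("C",))],
            np.array([[0], [2], [MISSING]], dtype=np.int8),
        )
        freq, count = allele_frequency(gm, "p", _pm({"p": list("abc")}))
        assert freq[0] == 0.5
        assert count[0] == 4

    def test_no_calls_flagged(self):
        gm = GenotypeMatrix(
            list("ab"),
            [LocusRecord("c", 1, "A", ("C",))],
            np.full((2, 1), MISSING, dtype=np.int8),
        )
        freq, count = allele_frequency(gm, "p", _pm({"p": list("ab")}))
        assert np.isnan(freq[0])
        assert count[0] == 0

    def test_unknown_population(self, synth):
        gm, popmap, _ = synth
        with pytest.raises(KeyError):
            allele_frequency(gm, "atlantis", popmap)

    def test_invariant_to_individual_order(self, synth, rng):
        gm, popmap, _ = synth
        perm = rng.permutation(gm.n_individuals)
        shuffled = gm.subset_individuals(np.array(gm.individuals)[perm].tolist())
        f1, c1 = allele_frequency(gm, "wild_a", popmap)
        f2, c2 = allele_frequency(shuffled, "wild_a", popmap)
        np.testing.assert_array_equal(c1, c2)
        np.testing.assert_allclose(f1, f2, equal_nan=True)

    def test_merged_population_is_weighted_mean(self, synth):
        gm, popmap, _ = synth
        fa, ca = allele_frequency(gm, "wild_a", popmap)
        fb, cb = allele_frequency(gm, "wild_b", popmap)
        merged = PopulationMap(
            {
                i: ("merged" if popmap.individual_to_population[i] in ("wild_a", "wild_b") else "other")
                for i in gm.individuals
            },
            {"merged": "wild", "other": "domestic_european"},
        )
        fm, cm = allele_frequency(gm, "merged", merged)
        both = (ca > 0) & (cb > 0)
        expect = (fa * ca + fb * cb)[both] / (ca + cb)[both]
        np.testing.assert_allclose(fm[both], expect)


class TestPopmapIO:
    def test_round_trip(self, tmp_path, synth):
        _, popmap, _ = synth
        path = tmp_path / "pm.tsv"
        write_popmap(popmap, path)
        back = read_popmap(path)
        assert back.individual_to_population == popmap.individual_to_population
        assert back.population_to_group == popmap.population_to_group

    def test_conflicting_group_rejected(self, tmp_path):
        path = tmp_path / "pm.tsv"
        path.write_text(
            "individual\tpopulation\tgroup\n"
            "a\tp1\twild\n"
            "b\tp1\tdomestic_european\n"
        )
        with pytest.raises(ValueError, match="two groups"):
            read_popmap(path)

    def test_unknown_group_rejected(self, tmp_path):
        path = tmp_path / "pm.tsv"
        path.write_text("individual\tpopulation\tgroup\na\tp1\tferal\n")
        with pytest.raises(ValueError, match="unknown group"):
            read_popmap(path)


class TestGenotypeMatrixInvariants:
    def test_bad_dosage_rejected(self):
        with pytest.raises(ValueError, match="dosages"):
            GenotypeMatrix(
                ["a"], [LocusRecord("c", 1, "A", ("C",))], np.array([[3]], dtype=np.int8)
            )

    def test_duplicate_individuals_rejected(self):
        with pytest.raises(ValueError, match="duplicate individual"):
            GenotypeMatrix(
                ["a", "a"],
                [LocusRecord("c", 1, "A", ("C",))],
                np.zeros((2, 1), dtype=np.int8),
            )

    def test_duplicate_positions_rejected(self):
        loci = [LocusRecord("c", 1, "A", ("C",)), LocusRecord("c", 1, "G", ("T",))]
        with pytest.raises(ValueError, match="duplicate"):
            GenotypeMatrix(["a"], loci, np.zeros((1, 2), dtype=np.int8))
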