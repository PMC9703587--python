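"""Counting, TPM, biotype and Sequin normalisation.

The counting oracle recomputes, per pair and per mate, the base-level
overlap of aligned match positions with exon unions and the strand rule,
independently of the interval index used by count_reads.
"""

import numpy as np
import pandas as pd
import pysam
import pytest

from xenosplit import countquant, samcore
from xenosplit.countquant import (
    AMBIGUOUS,
    NO_FEATURE,
    NOT_ALIGNED,
    NOT_UNIQUE,
    AnnotationIndex,
    biotype_summary,
    count_reads,
    robust_genes,
    sequin_normalize,
    tpm,
)

from conftest import make_header, make_record, make_pair_records


def write_gtf(path, genes):
    """genes: (gene_id, contig, start0, end, strand, biotype, [extra exons])"""
    with open(path, "w") as fh:
        for gene_id, contig, start, end, strand, biotype, *extra in genes:
            attrs = f'gene_id "{gene_id}"; gene_biotype "{biotype}";'
            exons = [(start, end)] + (extra[0] if extra else [])
            for s, e in exons:
                fh.write(f"{contig}\tt\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}\n")
    return path


@pytest.fixture
def toy_ann(tmp_path):
    return AnnotationIndex.from_gtf(
        write_gtf(
            tmp_path / "toy.gtf",
            [
                ("G1", "chr1", 100, 700, "+", "protein_coding"),
                ("G2", "chr1", 650, 1200, "+", "lincRNA"),  # overlaps G1
                ("G3", "chr1", 2000, 2600, "-", "protein_coding"),
                ("G4", "chr2", 100, 400, "+", "miRNA", [(600, 900)]),  # two exons
            ],
        )
    )


def rev_pair(header, qname, refname, pos1, pos2, **kw):
    """Gene-on-plus-strand pair under the reverse protocol: mate1 reverse."""
    r1 = make_record(header, qname, 83, refname, pos1, kw.get("cigar1", "50M"),
                     kw.get("nh", 1), kw.get("nm1", 0))
    r2 = make_record(header, qname, 163, refname, pos2, kw.get("cigar2", "50M"),
                     kw.get("nh", 1), kw.get("nm2", 0))
    return [r1, r2]


class TestAnnotationIndex:
    def test_union_exon_length(self, toy_ann):
        assert toy_ann.genes["G1"].union_exon_length == 600
        assert toy_ann.genes["G4"].union_exon_length == 600

    def test_overlapping_exons_merged(self, tmp_path):
        ann = AnnotationIndex.from_gtf(
            write_gtf(tmp_path / "m.gtf", [("G", "chr1", 0, 100, "+", "x", [(50, 150)])])
        )
        assert ann.genes["G"].intervals == {"chr1": [(0, 150)]}
        assert ann.genes["G"].union_exon_length == 150

    def test_strand_specific_lookup(self, toy_ann):
        assert toy_ann.overlapping("chr1", "+", 150, 200) == {"G1"}
        assert toy_ann.overlapping("chr1", "-", 150, 200) == set()
        assert toy_ann.overlapping("chr1", "+", 660, 690) == {"G1", "G2"}


class TestCountReads:
    def test_pair_in_single_gene(self, header, toy_ann):
        counts, specials = count_reads(rev_pair(header, "q", "chr1", 151, 301), toy_ann)
        assert counts == {"G1": 1}
        assert specials[NO_FEATURE] == 0

    def test_two_gene_overlap_is_ambiguous(self, header, toy_ann):
        counts, specials = count_reads(rev_pair(header, "q", "chr1", 640, 660), toy_ann)
        assert counts == {}
        assert specials[AMBIGUOUS] == 1

    def test_sense_pair_under_reverse_is_no_feature(self, header, toy_ann):
        # mate1 forward over a + gene violates the reverse protocol
        recs = make_pair_records(header, "q", "chr1", 151, 301)
        counts, specials = count_reads(recs, toy_ann)
        assert counts == {}
        assert specials[NO_FEATURE] == 1

    def test_same_pair_counts_under_forward(self, header, toy_ann):
        recs = make_pair_records(header, "q", "chr1", 151, 301)
        counts, _ = count_reads(recs, toy_ann, strandedness="forward")
        assert counts == {"G1": 1}

    def test_minus_strand_gene(self, header, toy_ann):
        # for a - gene under reverse protocol mate1 must be forward
        recs = make_pair_records(header, "q", "chr1", 2101, 2201)
        counts, _ = count_reads(recs, toy_ann)
        assert counts == {"G3": 1}

    def test_multimapper_counted_separately(self, header, toy_ann):
        counts, specials = count_reads(
            rev_pair(header, "q", "chr1", 151, 301, nh=2), toy_ann
        )
        assert counts == {} and specials[NOT_UNIQUE] == 1

    def test_unknown_strandedness(self, header, toy_ann):
        with pytest.raises(ValueError):
            count_reads([], toy_ann, strandedness="sideways")

    def test_conservation(self, header, toy_ann):
        recs = []
        recs += rev_pair(header, "a", "chr1", 151, 301)
        recs += rev_pair(header, "b", "chr1", 640, 660)
        recs += make_pair_records(header, "c", "chr1", 5000, 5100)
        counts, specials = count_reads(recs, toy_ann)
        assert sum(counts.values()) + sum(specials.values()) == 3


def count_oracle(pairs, ann, strandedness="reverse"):
    """Base-level brute-force reimplementation of union-mode counting."""
    counts: dict = {}
    specials = {k: 0 for k in countquant.SPECIAL_COUNTERS}
    for pair in pairs:
        mapped = [m for m in (pair.mate1, pair.mate2) if m is not None and not m.is_unmapped]
        if not mapped:
            specials[NOT_ALIGNED] += 1
            continue
        if any(m.get_tag("NH") > 1 for m in mapped):
            specials[NOT_UNIQUE] += 1
            continue
        genes = set()
        for m in mapped:
            aligned_strand = "-" if m.is_reverse else "+"
            want_sense = (strandedness == "forward") != bool(m.is_read2)
            target = aligned_strand if want_sense else ("-" if aligned_strand == "+" else "+")
            positions = set()
            for s, e in samcore.reference_blocks(m, include_deletions=False):
                positions |= set(range(s, e))
            for g in ann.genes.values():
                if g.strand != target:
                    continue
                for s, e in g.intervals.get(m.reference_name, []):
                    if positions & set(range(s, e)):
                        genes.add(g.gene_id)
        if not genes:
            specials[NO_FEATURE] += 1
        elif len(genes) > 1:
            specials[AMBIGUOUS] += 1
        else:
            g = genes.pop()
            counts[g] = counts.get(g, 0) + 1
    return counts, specials


class TestCountOracle:
    def test_oracle_agreement_on_random_pairs(self, toy_ann):
        rng = np.random.default_rng(7)
        header = make_header({"chr1": 100000, "chr2": 100000})
        recs = []
        for i in range(300):
            contig = "chr1" if rng.random() < 0.7 else "chr2"
            pos1 = int(rng.integers(1, 3000))
            pos2 = pos1 + int(rng.integers(0, 300))
            nh = 2 if rng.random() < 0.1 else 1
            if rng.random() < 0.5:
                recs += rev_pair(header, f"q{i:04d}", contig, pos1, pos2, nh=nh)
            else:
                recs += make_pair_records(header, f"q{i:04d}", contig, pos1, pos2, nh=nh)
        pairs = list(samcore.iterate_pairs(recs))
        got_counts, got_specials = count_reads(
            (r for p in pairs for r in p.mates()), toy_ann
        )
        exp_counts, exp_specials = count_oracle(pairs, toy_ann)
        assert got_counts == exp_counts
        assert got_specials == exp_specials


class TestRobustGenes:
    def test_threshold_five(self):
        assert robust_genes({"A": 5, "B": 4}) == {"A"}

    def test_all_zero(self):
        assert robust_genes({"A": 0, "B": 0}) == set()

    def test_threshold_one(self):
        assert robust_genes({"A": 1, "B": 0, "C": 9}, threshold=1) == {"A", "C"}


class TestTpm:
    def test_single_gene_is_1e6(self, toy_ann):
        assert tpm({"G1": 42}, toy_ann)["G1"] == pytest.approx(1e6)

    def test_length_ratio(self, tmp_path):
        ann = AnnotationIndex.from_gtf(
            write_gtf(
                tmp_path / "l.gtf",
                [("A", "chr1", 0, 1000, "+", "x"), ("B", "chr1", 2000, 4000, "+", "x")],
            )
        )
        values = tpm({"A": 10, "B": 10}, ann)
        assert values["A"] / values["B"] == pytest.approx(2.0)

    def test_sums_to_1e6(self, toy_ann):
        values = tpm({"G1": 3, "G2": 9, "G3": 1}, toy_ann)
        assert values.sum() == pytest.approx(1e6)

    def test_zero_counts_all_zero(self, toy_ann):
        assert (tpm({"G1": 0, "G2": 0}, toy_ann) == 0).all()

    def test_zero_length_gene_is_error(self, toy_ann):
        toy_ann.genes["G0"] = countquant.GeneInfo("G0", "+", "x")
        with pytest.raises(ValueError):
            tpm({"G0": 1}, toy_ann)


class TestBiotypeSummary:
    def test_tally(self, tmp_path):
        ann = AnnotationIndex.from_gtf(
            write_gtf(
                tmp_path / "b.gtf",
                [
                    ("A", "chr1", 0, 10, "+", "protein_coding"),
                    ("B", "chr1", 20, 30, "+", "protein_coding"),
                    ("C", "chr1", 40, 50, "+", "protein_coding"),
                    ("D", "chr1", 60, 70, "+", "lincRNA"),
                ],
            )
        )
        s = biotype_summary({"A", "B", "C", "D"}, ann)
        assert s["protein_coding"] == pytest.approx(0.75)
        assert sum(s.values()) == pytest.approx(1.0)

    def test_empty(self, toy_ann):
        assert biotype_summary(set(), toy_ann) == {}

    def test_unknown_gene(self, toy_ann):
        assert biotype_summary({"NOT_A_GENE"}, toy_ann) == {"unknown": 1.0}


class TestSequinNormalize:
    def table(self):
        return pd.DataFrame(
            {"R1_1": [60, 120, 240], "R1_2": [40, 80, 160], "ENSG1": [10, 10, 10],
             "DEAD": [0, 0, 0]},
            index=["s1", "s2", "s3"],
        )

    def test_derived_factors(self):
        # sequin sums 100, 200, 400 -> median 200 -> factors 0.5, 1, 2
        normalized, factors = sequin_normalize(self.table(), ["R1_1", "R1_2"])
        assert list(factors) == [0.5, 1.0, 2.0]
        assert list(normalized["ENSG1"]) == [20.0, 10.0, 5.0]

    def test_unexpressed_genes_dropped(self):
        normalized, _ = sequin_normalize(self.table(), ["R1_1", "R1_2"])
        assert "DEAD" not in normalized.columns

    def test_equal_sums_identity(self):
        t = pd.DataFrame({"R1_1": [5, 5], "G": [7, 9]}, index=["a", "b"])
        normalized, factors = sequin_normalize(t, ["R1_1"])
        assert (factors == 1.0).all()
        assert normalized["G"].tolist() == [7.0, 9.0]

    def test_scale_invariance(self):
        # doubling every count of a non-median sample leaves its normalized
        # values unchanged (the cohort median sum is unaffected)
        t = self.table()
        doubled = t.copy()
        doubled.loc["s3"] *= 2
        a, _ = sequin_normalize(t, ["R1_1", "R1_2"])
        b, _ = sequin_normalize(doubled, ["R1_1", "R1_2"])
        pd.testing.assert_series_equal(a.loc["s3"], b.loc["s3"])

    def test_zero_sequin_sample_is_error(self):
        t = pd.DataFrame({"R1_1": [5, 0], "G": [7, 9]}, index=["a", "bad"])
        with pytest.raises(ValueError, match="bad"):
            sequin_normalize(t, ["R1_1"])
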