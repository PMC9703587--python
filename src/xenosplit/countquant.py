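"""Union-mode stranded gene counting and downstream count transforms.

Counting follows the union convention for paired-end data: the feature set of
a pair is the union, over both mates' aligned match blocks, of genes whose
union-exon intervals overlap on the matching strand.  A singleton set counts
that gene, a larger set is ambiguous, an empty one no_feature.  Under the
``reverse`` protocol mate1 must align antisense to the feature and mate2
sense (TruSeq-stranded orientation); ``forward`` is the mirror image.
"""

from __future__ import annotations

import math
import re
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import pysam

from . import samcore
from .maskkit import merge_intervals

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')

NO_FEATURE = "__no_feature"
AMBIGUOUS = "__ambiguous"
NOT_ALIGNED = "__not_aligned"
NOT_UNIQUE = "__alignment_not_unique"
SPECIAL_COUNTERS = (NO_FEATURE, AMBIGUOUS, NOT_ALIGNED, NOT_UNIQUE)

STRANDEDNESS = ("reverse", "forward")


@dataclass
class GeneInfo:
    gene_id: str
    strand: str
    biotype: str
    # contig -> merged, sorted exon-union intervals (0-based half-open)
    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def union_exon_length(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)


class AnnotationIndex:
    """Gene lookup by (contig, strand) interval overlap, built from a GTF."""

    def __init__(self, genes: dict[str, GeneInfo]):
        self.genes = genes
        # (contig, strand) -> parallel arrays sorted by start, with a running
        # max of ends so nested intervals are found by a bounded left walk
        self._index: dict[tuple[str, str], tuple[list, list, list, list]] = {}
        flat: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
        for gene in genes.values():
            for contig, ivs in gene.intervals.items():
                key = (contig, gene.strand)
                flat.setdefault(key, []).extend((s, e, gene.gene_id) for s, e in ivs)
        for key, ivs in flat.items():
            ivs.sort()
            starts = [s for s, _, _ in ivs]
            ends = [e for _, e, _ in ivs]
            gids = [g for _, _, g in ivs]
            maxend: list[int] = []
            running = 0
            for e in ends:
                running = max(running, e)
                maxend.append(running)
            self._index[key] = (starts, ends, gids, maxend)

    @classmethod
    def from_gtf(cls, path: Union[str, Path]) -> "AnnotationIndex":
        genes: dict[str, GeneInfo] = {}
        raw: dict[str, dict[str, list[tuple[int, int]]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise ValueError(f"{path}:{lineno}: not a GTF record")
                if fields[2] != "exon":
                    continue
                attrs = dict(_ATTR_RE.findall(fields[8]))
                gene_id = attrs.get("gene_id")
                if gene_id is None:
                    raise ValueError(f"{path}:{lineno}: exon without gene_id")
                contig, start, end, strand = fields[0], int(fields[3]), int(fields[4]), fields[6]
                info = genes.get(gene_id)
                if info is None:
                    info = GeneInfo(
                        gene_id=gene_id,
                        strand=strand,
                        biotype=attrs.get("gene_biotype", "unknown"),
                    )
                    genes[gene_id] = info
                elif info.strand != strand:
                    raise ValueError(f"{path}:{lineno}: {gene_id} exons on both strands")
                raw.setdefault(gene_id, {}).setdefault(contig, []).append((start - 1, end))
        for gene_id, per_contig in raw.items():
            genes[gene_id].intervals = {
                contig: merge_intervals(ivs) for contig, ivs in per_contig.items()
            }
        return cls(genes)

    def overlapping(self, contig: str, strand: str, start: int, end: int) -> set[str]:
        """gene_ids on (contig, strand) whose exon union overlaps [start, end)."""
        entry = self._index.get((contig, strand))
        if entry is None:
            return set()
        starts, ends, gids, maxend = entry
        hits: set[str] = set()
        j = bisect_left(starts, end) - 1
        while j >= 0 and maxend[j] > start:
            if ends[j] > start:
                hits.add(gids[j])
            j -= 1
        return hits

    def lengths(self) -> pd.Series:
        return pd.Series(
            {g: info.union_exon_length for g, info in self.genes.items()}, dtype=float
        ).sort_index()


def _mate_target_strand(rec: pysam.AlignedSegment, strandedness: str) -> str:
    """Feature strand a mate is allowed to count towards."""
    aligned = "-" if rec.is_reverse else "+"
    antisense = "-" if aligned == "+" else "+"
    sense_mate1 = strandedness == "forward"
    if rec.is_read2:
        sense_mate1 = not sense_mate1
    return aligned if sense_mate1 else antisense


def pair_feature_set(
    pair: samcore.ReadPair, ann: AnnotationIndex, strandedness: str
) -> set[str]:
    genes: set[str] = set()
    for rec in pair.mapped_mates():
        target = _mate_target_strand(rec, strandedness)
        for start, end in samcore.reference_blocks(rec, include_deletions=False):
            genes |= ann.overlapping(rec.reference_name, target, start, end)
    return genes


def count_reads(
    alignments: Union[str, Iterable[pysam.AlignedSegment]],
    ann: AnnotationIndex,
    strandedness: str = "reverse",
) -> tuple[dict[str, int], dict[str, int]]:
    """Count pairs per gene from a queryname-sorted stream.

    Returns (gene counts, special counters).  Gene counts plus the special
    counters always sum to the number of input pairs.
    """
    if strandedness not in STRANDEDNESS:
        raise ValueError(f"unknown strandedness {strandedness!r}; use one of {STRANDEDNESS}")
    close_in = False
    if isinstance(alignments, (str, Path)):
        afile = samcore.open_alignments(alignments)
        records: Iterable[pysam.AlignedSegment] = afile
        close_in = True
    else:
        afile = None
        records = alignments

    counts: dict[str, int] = {}
    specials = {k: 0 for k in SPECIAL_COUNTERS}
    try:
        for pair in samcore.iterate_pairs(records):
            mapped = pair.mapped_mates()
            if not mapped:
                specials[NOT_ALIGNED] += 1
                continue
            if not all(samcore.is_unique(m) for m in mapped):
                specials[NOT_UNIQUE] += 1
                continue
            genes = pair_feature_set(pair, ann, strandedness)
            if not genes:
                specials[NO_FEATURE] += 1
            elif len(genes) > 1:
                specials[AMBIGUOUS] += 1
            else:
                gene = genes.pop()
                counts[gene] = counts.get(gene, 0) + 1
    finally:
        if close_in and afile is not None:
            afile.close()
    return counts, specials


def write_counts(
    counts: Mapping[str, int], specials: Mapping[str, int], path: Union[str, Path]
) -> None:
    """Counts TSV with bit-stable lexicographic gene order; specials trail."""
    with open(path, "w") as fh:
        for gene in sorted(counts):
            fh.write(f"{gene}\t{counts[gene]}\n")
        for key in SPECIAL_COUNTERS:
            fh.write(f"{key}\t{specials.get(key, 0)}\n")


def robust_genes(counts: Mapping[str, int], threshold: int = 5) -> set[str]:
    """Genes considered robustly detected: count >= threshold (default 5)."""
    return {g for g, c in counts.items() if c >= threshold}


def tpm(counts: Mapping[str, int], ann: AnnotationIndex) -> pd.Series:
    """Transcripts per million over union-exon lengths.

    Zero-length genes are an error; an all-zero count vector maps to all
    zeros (no division).
    """
    genes = sorted(counts)
    rates = {}
    for g in genes:
        info = ann.genes.get(g)
        if info is None:
            raise KeyError(f"gene {g!r} not in annotation")
        length = info.union_exon_length
        if length <= 0:
            raise ValueError(f"gene {g!r} has zero union-exon length")
        rates[g] = counts[g] / length
    total = sum(rates.values())
    if total == 0:
        return pd.Series({g: 0.0 for g in genes})
    return pd.Series({g: 1e6 * r / total for g, r in rates.items()})


def log2_tpm(tpm_values: pd.Series) -> pd.Series:
    return tpm_values.map(lambda v: math.log2(v + 1.0))


def biotype_summary(gene_set: Iterable[str], ann: AnnotationIndex) -> dict[str, float]:
    """Fraction of genes per biotype; unannotated genes fall under 'unknown'."""
    tally: dict[str, int] = {}
    n = 0
    for gene in gene_set:
        info = ann.genes.get(gene)
        biotype = info.biotype if info is not None else "unknown"
        tally[biotype] = tally.get(biotype, 0) + 1
        n += 1
    return {b: c / n for b, c in sorted(tally.items())} if n else {}


def sequin_normalize(
    table: pd.DataFrame, sequin_ids: Iterable[str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Scale each sample by its Sequin count sum relative to the cohort median.

    ``table`` is samples x genes.  All-zero gene columns are dropped first.
    Factor per sample: sum of its Sequin counts divided by the median of
    those sums; each sample row is divided by its factor, making the result
    invariant under global rescaling of any one sample.
    """
    sequin_cols = [g for g in sequin_ids if g in table.columns]
    if not sequin_cols:
        raise ValueError("no sequin ids present in count table")
    sums = table[sequin_cols].sum(axis=1)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"zero sequin counts in sample(s): {', '.join(map(str, zero.index))}")
    expressed = table.loc[:, table.sum(axis=0) > 0]
    factors = sums / sums.median()
    return expressed.div(factors, axis=0), factors
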