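"""Empirical misalignment masks.

Pure-species control samples aligned to the *other* genome leave behind the
footprint of sequence too homologous to deconvolve.  ``build_mask`` takes
those misaligned reads and records the per-base union of their aligned blocks
(M/=/X/D; splice gaps N are skipped so introns are never masked);
``apply_mask`` then drops any read pair with >= 1 bp of block overlap.  By
construction, applying a mask built from a read set to that same read set
removes every read — the closure property the whole scheme rests on.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pysam

from . import samcore

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and merge; abutting intervals are coalesced."""
    out: list[Interval] = []
    for start, end in sorted(intervals):
        if start >= end:
            raise ValueError(f"empty or inverted interval ({start}, {end})")
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


@dataclass
class MaskSet:
    """Merged, disjoint masked intervals per contig (0-based half-open)."""

    intervals: dict[str, list[Interval]] = field(default_factory=dict)
    species: str = ""
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.intervals = {c: merge_intervals(ivs) for c, ivs in self.intervals.items() if ivs}
        self._starts = {c: [s for s, _ in ivs] for c, ivs in self.intervals.items()}

    @property
    def total_bp(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)

    def overlaps(self, contig: str, start: int, end: int) -> bool:
        """True iff [start, end) overlaps any masked interval by >= 1 bp."""
        ivs = self.intervals.get(contig)
        if not ivs:
            return False
        i = bisect_right(self._starts[contig], start)
        if i > 0 and ivs[i - 1][1] > start:
            return True
        return i < len(ivs) and ivs[i][0] < end

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for contig in sorted(self.intervals):
                for start, end in self.intervals[contig]:
                    fh.write(f"{contig}\t{start}\t{end}\n")

    @classmethod
    def from_bed(cls, path: str, species: str = "") -> "MaskSet":
        intervals: dict[str, list[Interval]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                intervals.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
        return cls(intervals=intervals, species=species)


def build_mask(
    control_alignments: Sequence[Union[str, Iterable[pysam.AlignedSegment]]],
    min_reads: int = 1,
    species: str = "",
) -> MaskSet:
    """Union the aligned-block footprints of misaligned control reads.

    ``min_reads`` keeps only bases covered by at least that many reads
    (pooled over all control samples); the default of 1 is what guarantees
    closure.  Secondary/supplementary records are ignored.
    """
    if not control_alignments:
        warnings.warn("no control samples given; mask is empty", stacklevel=2)
        return MaskSet(species=species)

    if min_reads <= 1:
        raw: dict[str, list[Interval]] = {}
        for blocks_of in _iter_block_lists(control_alignments):
            for contig, start, end in blocks_of:
                raw.setdefault(contig, []).append((start, end))
        return MaskSet(intervals=raw, species=species, n_samples=len(control_alignments))

    # coverage sweep per contig for thresholds > 1
    events: dict[str, dict[int, int]] = {}
    for blocks_of in _iter_block_lists(control_alignments):
        for contig, start, end in blocks_of:
            d = events.setdefault(contig, {})
            d[start] = d.get(start, 0) + 1
            d[end] = d.get(end, 0) - 1
    intervals: dict[str, list[Interval]] = {}
    for contig, d in events.items():
        depth = 0
        open_start: Optional[int] = None
        ivs: list[Interval] = []
        for pos in sorted(d):
            depth += d[pos]
            if depth >= min_reads and open_start is None:
                open_start = pos
            elif depth < min_reads and open_start is not None:
                ivs.append((open_start, pos))
                open_start = None
        if ivs:
            intervals[contig] = ivs
    return MaskSet(intervals=intervals, species=species, n_samples=len(control_alignments))


def _iter_block_lists(sources):
    for src in sources:
        close = False
        if isinstance(src, (str, Path)):
            src = samcore.open_alignments(src)
            close = True
        try:
            for rec in src:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                yield [
                    (rec.reference_name, s, e)
                    for s, e in samcore.reference_blocks(rec, include_deletions=True)
                ]
        finally:
            if close:
                src.close()


def pair_overlaps_mask(pair: samcore.ReadPair, mask: MaskSet) -> bool:
    for rec in pair.mapped_mates():
        for start, end in samcore.reference_blocks(rec, include_deletions=True):
            if mask.overlaps(rec.reference_name, start, end):
                return True
    return False


def apply_mask(
    alignments: Union[str, Iterable[pysam.AlignedSegment]],
    mask: MaskSet,
    out_path: Optional[str] = None,
) -> tuple[int, int]:
    """Drop read pairs with any masked-block overlap; return (kept, removed).

    Contigs absent from the mask simply have no intervals, so their reads
    pass through.  The operation is idempotent.
    """
    close_in = False
    header = None
    if isinstance(alignments, (str, Path)):
        afile = samcore.open_alignments(alignments)
        header = afile.header
        records: Iterable[pysam.AlignedSegment] = afile
        close_in = True
    else:
        afile = None
        records = alignments

    out = None
    if out_path is not None and header is not None:
        out = pysam.AlignmentFile(str(out_path), "wh", header=header)

    kept = removed = 0
    try:
        for pair in samcore.iterate_pairs(records):
            if pair_overlaps_mask(pair, mask):
                removed += 1
                continue
            kept += 1
            if out is not None:
                for m in pair.mates():
                    out.write(m)
    finally:
        if out is not None:
            out.close()
        if close_in and afile is not None:
            afile.close()
    return kept, removed


def mask_summary(mask: MaskSet, genome_sizes: dict[str, int]) -> dict[str, float]:
    """Total masked bp and fraction of the genome covered by the mask."""
    for contig in mask.intervals:
        if contig not in genome_sizes:
            raise KeyError(f"no genome size for masked contig {contig!r}")
    total = mask.total_bp
    genome = sum(genome_sizes.values())
    return {
        "masked_bp": float(total),
        "genome_bp": float(genome),
        "fraction": total / genome if genome else 0.0,
    }
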