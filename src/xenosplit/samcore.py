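"""Alignment record arithmetic and name-grouped pair iteration.

All downstream species assignment is driven by three primitives defined here:
per-record soft-clip length, per-pair edit-distance score (NM + soft clips,
summed over mapped mates) and NH-based uniqueness.  Pair iteration assumes
queryname-sorted input and groups primary alignments by name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Union

import pysam

_CIGAR_OP_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: CIGAR operations that consume reference bases.
REF_CONSUMING = frozenset("MDN=X")
#: CIGAR operations that consume query (read) bases.
QUERY_CONSUMING = frozenset("MIS=X")

OrphanPolicy = str  # "penalize" | "ignore"


class MalformedCigarError(ValueError):
    pass


class MissingTagError(KeyError):
    pass


class SortOrderError(ValueError):
    pass


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) tuples.

    Raises :class:`MalformedCigarError` if the string is not a valid
    concatenation of ``<int><op>`` tokens.
    """
    if not cigar or cigar == "*":
        return []
    pos = 0
    ops: list[tuple[int, str]] = []
    for m in _CIGAR_OP_RE.finditer(cigar):
        if m.start() != pos:
            raise MalformedCigarError(f"malformed CIGAR: {cigar!r}")
        ops.append((int(m.group(1)), m.group(2)))
        pos = m.end()
    if pos != len(cigar):
        raise MalformedCigarError(f"malformed CIGAR: {cigar!r}")
    return ops


def soft_clip_bases(cigar: Union[str, pysam.AlignedSegment]) -> int:
    """Total length of soft-clip (S) operations; hard clips do not count."""
    if isinstance(cigar, pysam.AlignedSegment):
        cigar = cigar.cigarstring or ""
    return sum(n for n, op in parse_cigar(cigar) if op == "S")


def query_length_from_cigar(cigar: Union[str, pysam.AlignedSegment]) -> int:
    """Read length implied by the CIGAR (sum of query-consuming ops, S included)."""
    if isinstance(cigar, pysam.AlignedSegment):
        cigar = cigar.cigarstring or ""
    return sum(n for n, op in parse_cigar(cigar) if op in QUERY_CONSUMING)


def get_tag(rec: pysam.AlignedSegment, tag: str) -> int:
    try:
        return int(rec.get_tag(tag))
    except KeyError as exc:
        raise MissingTagError(f"read {rec.query_name!r} lacks {tag} tag") from exc


def is_unique(rec: pysam.AlignedSegment) -> bool:
    """True iff the record carries NH:i:1.

    NH=0 violates the SAM contract for a mapped record and raises.
    """
    nh = get_tag(rec, "NH")
    if nh < 1:
        raise ValueError(f"read {rec.query_name!r} has invalid NH={nh}")
    return nh == 1


def record_score(rec: pysam.AlignedSegment) -> int:
    """Edit-distance score of one mapped record: NM + soft-clipped bases."""
    return get_tag(rec, "NM") + soft_clip_bases(rec)


def reference_blocks(
    rec: pysam.AlignedSegment, *, include_deletions: bool
) -> list[tuple[int, int]]:
    """Reference intervals (0-based half-open) covered by the alignment.

    Blocks extend through M/=/X (and D when ``include_deletions``); N splice
    gaps always split blocks and never contribute bases.
    """
    if rec.is_unmapped:
        return []
    blocks: list[tuple[int, int]] = []
    ref = rec.reference_start
    block_start: Optional[int] = None
    for n, op in parse_cigar(rec.cigarstring or ""):
        if op in ("M", "=", "X") or (op == "D" and include_deletions):
            if block_start is None:
                block_start = ref
            ref += n
        elif op in ("N", "D"):  # D lands here only when not included
            if block_start is not None:
                blocks.append((block_start, ref))
                block_start = None
            ref += n
        # I, S, H, P: no reference consumption
    if block_start is not None:
        blocks.append((block_start, ref))
    return blocks


@dataclass
class ReadPair:
    """Primary alignments of one template: mate1 and/or mate2 (either may be None)."""

    qname: str
    mate1: Optional[pysam.AlignedSegment] = None
    mate2: Optional[pysam.AlignedSegment] = None

    def mates(self) -> Iterator[pysam.AlignedSegment]:
        if self.mate1 is not None:
            yield self.mate1
        if self.mate2 is not None:
            yield self.mate2

    def mapped_mates(self) -> list[pysam.AlignedSegment]:
        return [m for m in self.mates() if not m.is_unmapped]

    @property
    def n_mates(self) -> int:
        return (self.mate1 is not None) + (self.mate2 is not None)


def pair_edit_distance(pair: ReadPair, orphan_policy: OrphanPolicy = "penalize") -> int:
    """Sum of (NM + soft-clip) over mapped mates of the pair.

    With ``orphan_policy="penalize"`` a pair with exactly one mapped mate is
    additionally charged the missing mate's read length, i.e. the unmapped
    mate is treated as fully soft-clipped.  With ``"ignore"`` only mapped
    mates contribute.
    """
    mapped = pair.mapped_mates()
    if not mapped:
        raise ValueError(f"pair {pair.qname!r} has no mapped mate")
    score = sum(record_score(rec) for rec in mapped)
    if orphan_policy == "penalize" and len(mapped) == 1:
        # Prefer the unmapped mate's own length if its record is present.
        other = [m for m in pair.mates() if m.is_unmapped]
        if other and other[0].query_length:
            score += other[0].query_length
        else:
            score += query_length_from_cigar(mapped[0])
    elif orphan_policy not in ("penalize", "ignore"):
        raise ValueError(f"unknown orphan policy {orphan_policy!r}")
    return score


def _is_primary(rec: pysam.AlignedSegment) -> bool:
    return not (rec.is_secondary or rec.is_supplementary)


def iterate_pairs(
    records: Iterable[pysam.AlignedSegment], *, check_sorted: bool = True
) -> Iterator[ReadPair]:
    """Group a queryname-sorted primary alignment stream into ReadPairs.

    Secondary and supplementary records are skipped.  A qname that reappears
    after a different qname was seen indicates unsorted input and raises
    :class:`SortOrderError`.
    """
    seen: set[str] = set()
    current: Optional[ReadPair] = None
    for rec in records:
        if not _is_primary(rec):
            continue
        qname = rec.query_name
        if current is not None and qname == current.qname:
            _slot(current, rec)
            continue
        if check_sorted and qname in seen:
            raise SortOrderError(f"input not queryname-sorted: {qname!r} reappeared")
        if current is not None:
            seen.add(current.qname)
            yield current
        current = ReadPair(qname=qname)
        _slot(current, rec)
    if current is not None:
        yield current


def _slot(pair: ReadPair, rec: pysam.AlignedSegment) -> None:
    if rec.is_read2:
        if pair.mate2 is not None:
            raise ValueError(f"duplicate primary mate2 for {pair.qname!r}")
        pair.mate2 = rec
    else:
        if pair.mate1 is not None:
            raise ValueError(f"duplicate primary mate1 for {pair.qname!r}")
        pair.mate1 = rec


def open_alignments(path: str) -> pysam.AlignmentFile:
    """Open SAM/BAM/CRAM for reading; format inferred from magic bytes."""
    return pysam.AlignmentFile(str(path), check_sq=False)
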