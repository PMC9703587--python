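"""Species assignment on a combined reference: classify by contig class.

A read pair survives only if every mapped mate is uniquely mapped (NH=1).
Surviving pairs are routed by the class of the contig they align to; pairs
whose mates land on contigs of different classes are possible chimeric
artifacts and go to a separate discordant bucket, excluded from both species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pysam

from . import samcore
from .samcore import ReadPair

DISCORDANT = "discordant"
NON_UNIQUE = "non_unique"
UNMAPPED = "unmapped"


@dataclass
class SpeciesSplit:
    """Per-class pair tallies for one combined-reference alignment stream."""

    class_counts: dict[str, int] = field(default_factory=dict)
    discordant: int = 0
    non_unique: int = 0
    unmapped: int = 0
    total_pairs: int = 0

    @property
    def unique_pairs(self) -> int:
        return sum(self.class_counts.values()) + self.discordant

    def as_rows(self) -> list[tuple[str, int]]:
        rows = sorted(self.class_counts.items())
        rows += [
            (DISCORDANT, self.discordant),
            (NON_UNIQUE, self.non_unique),
            (UNMAPPED, self.unmapped),
        ]
        return rows


def classify_by_contig(refname: str, contig_class: dict[str, str]) -> str:
    try:
        return contig_class[refname]
    except KeyError:
        raise KeyError(f"contig {refname!r} absent from contig class table") from None


def classify_pair(pair: ReadPair, contig_class: dict[str, str]) -> str:
    """Class label of a pair, or DISCORDANT when its mates' classes differ."""
    labels = {classify_by_contig(m.reference_name, contig_class) for m in pair.mapped_mates()}
    if len(labels) > 1:
        return DISCORDANT
    return labels.pop()


def split_combined(
    alignments: Union[str, Iterable[pysam.AlignedSegment]],
    contig_class: dict[str, str],
    out_dir: Optional[str] = None,
    summary_path: Optional[str] = None,
) -> SpeciesSplit:
    """Route a queryname-sorted combined-reference stream by contig class.

    When ``out_dir`` is given, one SAM per observed class (plus a discordant
    file) is written there.  Returns the per-class pair tallies; class counts
    plus the discordant count partition the unique mapped pairs exactly.
    """
    close_in = False
    if isinstance(alignments, (str, Path)):
        afile = samcore.open_alignments(alignments)
        header = afile.header
        records: Iterable[pysam.AlignedSegment] = afile
        close_in = True
    else:
        afile = None
        header = None
        records = alignments

    writers: dict[str, pysam.AlignmentFile] = {}

    def writer(label: str) -> Optional[pysam.AlignmentFile]:
        if out_dir is None or header is None:
            return None
        if label not in writers:
            writers[label] = pysam.AlignmentFile(
                str(Path(out_dir) / f"{label}.sam"), "wh", header=header
            )
        return writers[label]

    split = SpeciesSplit()
    try:
        for pair in samcore.iterate_pairs(records):
            split.total_pairs += 1
            mapped = pair.mapped_mates()
            if not mapped:
                split.unmapped += 1
                continue
            if not all(samcore.is_unique(m) for m in mapped):
                split.non_unique += 1
                continue
            label = classify_pair(pair, contig_class)
            if label == DISCORDANT:
                split.discordant += 1
            else:
                split.class_counts[label] = split.class_counts.get(label, 0) + 1
            w = writer(label)
            if w is not None:
                for m in pair.mates():
                    w.write(m)
    finally:
        for w in writers.values():
            w.close()
        if close_in and afile is not None:
            afile.close()

    if summary_path is not None:
        write_summary(split, summary_path)
    return split


def write_summary(split: SpeciesSplit, path: str) -> None:
    unique = split.unique_pairs
    with open(path, "w") as fh:
        fh.write("class\tpairs\tfraction_of_unique\n")
        for label, n in split.as_rows():
            frac = n / unique if unique and label not in (NON_UNIQUE, UNMAPPED) else 0.0
            fh.write(f"{label}\t{n}\t{frac:.6f}\n")
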