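"""Species assignment from two independent per-species alignment runs.

Each template is scored in both runs with the pair edit distance
(NM + soft-clip summed over mapped mates) and assigned to the species with
the strictly smaller score.  Equal scores are an explicit ambiguous outcome,
excluded from both species.  The two inputs are merged by queryname without
loading either file in memory, so both must be queryname-sorted with the
same (lexicographic) collation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Union

import pysam

from . import samcore
from .samcore import ReadPair, SortOrderError

HUMAN_ONLY = "human_only"
MOUSE_ONLY = "mouse_only"
HUMAN_BY_SCORE = "human_by_score"
MOUSE_BY_SCORE = "mouse_by_score"
AMBIGUOUS_TIE = "ambiguous_tie"
UNASSIGNED = "unassigned"
SPIKE = "spike"

HUMAN_DECISIONS = (HUMAN_ONLY, HUMAN_BY_SCORE)
MOUSE_DECISIONS = (MOUSE_ONLY, MOUSE_BY_SCORE)


@dataclass
class PairAssignment:
    qname: str
    score_human: Optional[int]
    score_mouse: Optional[int]
    decision: str


def assign_pair(
    human_pair: Optional[ReadPair],
    mouse_pair: Optional[ReadPair],
    orphan_policy: str = "penalize",
) -> PairAssignment:
    """Argmin of the two pair edit distances; one-sided pairs are *_only."""
    qname = (human_pair or mouse_pair).qname if (human_pair or mouse_pair) else ""
    sh = samcore.pair_edit_distance(human_pair, orphan_policy) if human_pair else None
    sm = samcore.pair_edit_distance(mouse_pair, orphan_policy) if mouse_pair else None
    if sh is None and sm is None:
        return PairAssignment(qname, None, None, UNASSIGNED)
    if sm is None:
        return PairAssignment(qname, sh, None, HUMAN_ONLY)
    if sh is None:
        return PairAssignment(qname, None, sm, MOUSE_ONLY)
    if sh < sm:
        return PairAssignment(qname, sh, sm, HUMAN_BY_SCORE)
    if sm < sh:
        return PairAssignment(qname, sh, sm, MOUSE_BY_SCORE)
    return PairAssignment(qname, sh, sm, AMBIGUOUS_TIE)


def _unique_pairs(path: str) -> Iterator[tuple[ReadPair, object]]:
    """Yield (pair, header); pairs with any multimapping mate are dropped."""
    afile = samcore.open_alignments(path)
    try:
        for pair in samcore.iterate_pairs(afile):
            mapped = pair.mapped_mates()
            if not mapped:
                continue
            if all(samcore.is_unique(m) for m in mapped):
                yield pair, afile.header
    finally:
        afile.close()


def deconvolve_parallel(
    human_path: str,
    mouse_path: str,
    out_dir: Optional[str] = None,
    spike_contigs: Optional[set[str]] = None,
    orphan_policy: str = "penalize",
    summary_path: Optional[str] = None,
    collect: bool = False,
) -> tuple[Counter, list[PairAssignment]]:
    """Merge two queryname-sorted per-species runs and assign each template.

    Templates aligned to spike contigs (present identically in both
    references) are routed to a ``spike`` bucket before species scoring.
    Returns the decision tally and, when ``collect``, every assignment.
    Conservation: every qname in the union of inputs receives exactly one
    decision.
    """
    spike_contigs = spike_contigs or set()
    summary: Counter = Counter()
    assignments: list[PairAssignment] = []

    writers: dict[str, pysam.AlignmentFile] = {}

    def writer(label: str, header) -> Optional[pysam.AlignmentFile]:
        if out_dir is None:
            return None
        if label not in writers:
            writers[label] = pysam.AlignmentFile(
                str(Path(out_dir) / f"{label}.sam"), "wh", header=header
            )
        return writers[label]

    def emit(label: str, pair: ReadPair, header) -> None:
        w = writer(label, header)
        if w is not None:
            for m in pair.mates():
                w.write(m)

    def handle(hp: Optional[ReadPair], mp: Optional[ReadPair], hh, mh) -> None:
        refnames = {
            m.reference_name for p in (hp, mp) if p for m in p.mapped_mates()
        }
        if refnames & spike_contigs:
            summary[SPIKE] += 1
            if hp is not None:
                emit(SPIKE, hp, hh)
            elif mp is not None:
                emit(SPIKE, mp, mh)
            if collect:
                assignments.append(PairAssignment((hp or mp).qname, None, None, SPIKE))
            return
        a = assign_pair(hp, mp, orphan_policy)
        summary[a.decision] += 1
        if a.decision in HUMAN_DECISIONS:
            emit("human", hp, hh)
        elif a.decision in MOUSE_DECISIONS:
            emit("mouse", mp, mh)
        elif a.decision == AMBIGUOUS_TIE:
            emit("ambiguous", hp, hh)
        if collect:
            assignments.append(a)

    hiter = _unique_pairs(human_path)
    miter = _unique_pairs(mouse_path)
    hcur = next(hiter, None)
    mcur = next(miter, None)
    last_h = last_m = None
    while hcur is not None or mcur is not None:
        if hcur is not None:
            if last_h is not None and hcur[0].qname <= last_h:
                raise SortOrderError(f"human input not sorted at {hcur[0].qname!r}")
        if mcur is not None:
            if last_m is not None and mcur[0].qname <= last_m:
                raise SortOrderError(f"mouse input not sorted at {mcur[0].qname!r}")
        if mcur is None or (hcur is not None and hcur[0].qname < mcur[0].qname):
            handle(hcur[0], None, hcur[1], None)
            last_h = hcur[0].qname
            hcur = next(hiter, None)
        elif hcur is None or mcur[0].qname < hcur[0].qname:
            handle(None, mcur[0], None, mcur[1])
            last_m = mcur[0].qname
            mcur = next(miter, None)
        else:
            handle(hcur[0], mcur[0], hcur[1], mcur[1])
            last_h = hcur[0].qname
            last_m = mcur[0].qname
            hcur = next(hiter, None)
            mcur = next(miter, None)

    for w in writers.values():
        w.close()

    if summary_path is not None:
        with open(summary_path, "w") as fh:
            fh.write("decision\tpairs\n")
            for decision in (
                HUMAN_ONLY,
                HUMAN_BY_SCORE,
                MOUSE_ONLY,
                MOUSE_BY_SCORE,
                AMBIGUOUS_TIE,
                SPIKE,
            ):
                fh.write(f"{decision}\t{summary.get(decision, 0)}\n")
    return summary, assignments
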