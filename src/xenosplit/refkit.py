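"""Combined and per-species reference construction.

Combined mode concatenates the two genomes into one FASTA with host contigs
renamed by a prefix (default ``m``, no separator: ``chr1`` -> ``mchr1``) so the
namespace stays unambiguous, adds spike and rDNA contigs once, and records a
contig -> class table that drives downstream classification.  Parallel mode
produces one reference per species, each carrying its own copy of the spike
contigs so spike reads map in either run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CLASS_HUMAN = "human"
CLASS_MOUSE = "mouse"
CLASS_SEQUIN = "spike_sequin"
CLASS_ERCC = "spike_ercc"
CLASS_RDNA_HUMAN = "rdna_human"
CLASS_RDNA_MOUSE = "rdna_mouse"

CONTIG_CLASSES = (
    CLASS_HUMAN,
    CLASS_MOUSE,
    CLASS_SEQUIN,
    CLASS_ERCC,
    CLASS_RDNA_HUMAN,
    CLASS_RDNA_MOUSE,
)

#: classes whose counts/concentrations are attributed to a species
SPECIES_OF_CLASS = {
    CLASS_HUMAN: CLASS_HUMAN,
    CLASS_MOUSE: CLASS_MOUSE,
    CLASS_RDNA_HUMAN: CLASS_HUMAN,
    CLASS_RDNA_MOUSE: CLASS_MOUSE,
}


class ContigCollisionError(ValueError):
    """Raised when prefixing does not yield a unique combined namespace."""


@dataclass
class GenomeBundle:
    """One species' contig set with the prefix applied in combined mode."""

    species_label: str
    contig_names: list[str]
    contig_lengths: dict[str, int]
    prefix: str = ""

    def __post_init__(self) -> None:
        if len(set(self.contig_names)) != len(self.contig_names):
            raise ValueError(f"duplicate contig names in {self.species_label} bundle")
        for name, length in self.contig_lengths.items():
            if length <= 0:
                raise ValueError(f"contig {name!r} has non-positive length {length}")

    @classmethod
    def from_fasta(cls, path: str, species_label: str, prefix: str = "") -> "GenomeBundle":
        names, lengths = [], {}
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            lengths[rec.id] = len(rec.seq)
        return cls(species_label, names, lengths, prefix)

    @property
    def prefixed_names(self) -> list[str]:
        return [self.prefix + n for n in self.contig_names]

    @property
    def total_length(self) -> int:
        return sum(self.contig_lengths.values())


def classify_spike(name: str) -> str:
    """ERCC ids start with 'ERCC'; everything else in the spike FASTA is a Sequin."""
    return CLASS_ERCC if name.upper().startswith("ERCC") else CLASS_SEQUIN


def classify_rdna(name: str) -> str:
    """Attribute an rDNA repeat unit to its species by accession or suffix.

    Known units: U13369 (human), BK000964 (mouse); names ending in
    ``_human``/``_mouse`` are also accepted (synthetic fixtures).
    """
    upper = name.upper()
    if "U13369" in upper or upper.endswith("_HUMAN"):
        return CLASS_RDNA_HUMAN
    if "BK000964" in upper or upper.endswith("_MOUSE"):
        return CLASS_RDNA_MOUSE
    raise ValueError(
        f"cannot attribute rDNA contig {name!r} to a species; "
        "rename it with a _human/_mouse suffix or use a known accession"
    )


def _iter_fasta(path: Optional[str]) -> Iterable[SeqRecord]:
    if path is None:
        return []
    return SeqIO.parse(str(path), "fasta")


def build_combined_fasta(
    human_fasta: str,
    mouse_fasta: str,
    spike_fasta: Optional[str] = None,
    rdna_fasta: Optional[str] = None,
    prefix: str = "m",
    out_fasta: Optional[str] = None,
    out_classes: Optional[str] = None,
) -> dict[str, str]:
    """Write the combined reference FASTA and return the contig -> class map.

    Human contigs are copied verbatim, mouse contigs renamed ``prefix+name``,
    spike and rDNA contigs appended once each.  Collisions after prefixing are
    a hard error listing the offending names.
    """
    records: list[SeqRecord] = []
    classes: dict[str, str] = {}

    def add(rec: SeqRecord, name: str, cls: str) -> None:
        if name in classes:
            raise ContigCollisionError(f"contig name collision: {name!r}")
        classes[name] = cls
        records.append(SeqRecord(rec.seq, id=name, description=""))

    for rec in _iter_fasta(human_fasta):
        add(rec, rec.id, CLASS_HUMAN)

    mouse_names = [r.id for r in _iter_fasta(mouse_fasta)]
    colliding = sorted(set(prefix + n for n in mouse_names) & set(classes))
    if colliding:
        raise ContigCollisionError(
            "contig names collide after prefixing: " + ", ".join(colliding)
        )
    for rec in _iter_fasta(mouse_fasta):
        add(rec, prefix + rec.id, CLASS_MOUSE)

    for rec in _iter_fasta(spike_fasta):
        add(rec, rec.id, classify_spike(rec.id))
    for rec in _iter_fasta(rdna_fasta):
        add(rec, rec.id, classify_rdna(rec.id))

    if not records:
        warnings.warn("combined reference is empty", stacklevel=2)

    if out_fasta is not None:
        SeqIO.write(records, str(out_fasta), "fasta")  # wraps at 60 columns
    if out_classes is not None:
        write_contig_classes(classes, out_classes)
    return classes


def write_contig_classes(classes: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tclass\n")
        for name, cls in classes.items():
            fh.write(f"{name}\t{cls}\n")


def read_contig_classes(path: str) -> dict[str, str]:
    classes: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("contig"):
            raise ValueError(f"{path}: expected 'contig\\tclass' header")
        for line in fh:
            if not line.strip():
                continue
            name, cls = line.rstrip("\n").split("\t")
            if cls not in CONTIG_CLASSES:
                raise ValueError(f"{path}: unknown contig class {cls!r}")
            classes[name] = cls
    return classes


def build_combined_gtf(
    human_gtf: str,
    mouse_gtf: str,
    spike_gtf: Optional[str] = None,
    prefix: str = "m",
    out_gtf: Optional[str] = None,
    known_contigs: Optional[dict[str, set[str]]] = None,
) -> list[str]:
    """Merge annotations onto the combined namespace; mouse seqnames get the prefix.

    Attributes are passed through untouched (Ensembl gene_id namespaces are
    already disjoint between species).  ``known_contigs`` maps
    human/mouse/spike to the contig sets of the corresponding FASTA; records
    on unknown contigs are an error naming the offending line.
    """
    out_lines: list[str] = []

    def check(seqname: str, which: str, lineno: int, source_path: str) -> None:
        if known_contigs is None:
            return
        allowed = known_contigs.get(which)
        if allowed is not None and seqname not in allowed:
            raise ValueError(
                f"{source_path}:{lineno}: record on unknown {which} contig {seqname!r}"
            )

    for which, path, pfx in (
        ("human", human_gtf, ""),
        ("mouse", mouse_gtf, prefix),
        ("spike", spike_gtf, ""),
    ):
        if path is None:
            continue
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                if line.startswith("#"):
                    out_lines.append(line.rstrip("\n"))
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise ValueError(f"{path}:{lineno}: not a GTF record")
                check(fields[0], which, lineno, str(path))
                fields[0] = pfx + fields[0]
                out_lines.append("\t".join(fields))

    if out_gtf is not None:
        with open(out_gtf, "w") as fh:
            for line in out_lines:
                fh.write(line + "\n")
    return out_lines


def build_parallel_fastas(
    human_fasta: str,
    mouse_fasta: str,
    spike_fasta: Optional[str],
    rdna_fasta: Optional[str],
    out_human: str,
    out_mouse: str,
) -> None:
    """Per-species references for parallel mapping.

    Each species keeps its own contig names (no prefix) plus one copy of the
    spike contigs and its own rDNA unit, so spike reads map in both runs.
    """
    spikes = [SeqRecord(r.seq, id=r.id, description="") for r in _iter_fasta(spike_fasta)]
    rdna = list(_iter_fasta(rdna_fasta))
    for species_fasta, out_path, rdna_cls in (
        (human_fasta, out_human, CLASS_RDNA_HUMAN),
        (mouse_fasta, out_mouse, CLASS_RDNA_MOUSE),
    ):
        records = [SeqRecord(r.seq, id=r.id, description="") for r in _iter_fasta(species_fasta)]
        records.extend(spikes)
        records.extend(
            SeqRecord(r.seq, id=r.id, description="")
            for r in rdna
            if classify_rdna(r.id) == rdna_cls
        )
        SeqIO.write(records, str(out_path), "fasta")
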