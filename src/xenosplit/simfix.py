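"""Synthetic two-species fixtures with truth labels.

Generates toy human/mouse genomes sharing homology blocks of configurable
identity, spike contigs, toy gene annotations, and paired-end alignments
written directly as aligner-style SAM (the simulator stands in for the
external spliced aligner, so NM/NH/soft-clip bookkeeping is exact by
construction).  Per-genome SAMs emulate parallel mapping; a combined SAM
emulates mapping to the prefixed combined reference, including NH=2
multimappers for reads that tie between the two genomes.  A count-level
fraction-series simulator models the platelet dilution design: host counts
scale with platelet level, tumour and spike counts stay constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import spikequant

BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CLASS_ORDER = ("human", "mouse", "homologous", "sequin", "ercc")
BIOTYPES = ("protein_coding", "lincRNA", "misc_RNA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimConfig:
    seed: int = 0
    n_contigs: int = 1
    contig_length: int = 20000
    homology_blocks: list[tuple[int, float]] = field(default_factory=lambda: [(2000, 0.9)])
    n_genes: int = 4
    gene_length: int = 600
    read_length: int = 50
    fragment_mean: float = 160.0
    fragment_sd: float = 20.0
    n_pairs: dict[str, int] = field(
        default_factory=lambda: {"human": 50, "mouse": 50, "homologous": 20, "sequin": 10, "ercc": 5}
    )
    error_rate: float = 0.0
    soft_clip_rate: float = 0.0
    max_soft_clip: int = 10
    n_sequin: int = 3
    n_ercc: int = 2
    spike_length: int = 1000
    gene_fraction: float = 0.0
    prefix: str = "m"

    def __post_init__(self) -> None:
        for length, identity in self.homology_blocks:
            if not 0.0 <= identity <= 1.0:
                raise ValueError(f"identity {identity} outside [0, 1]")
            if length <= 0:
                raise ValueError("homology block length must be positive")
        for cls, n in self.n_pairs.items():
            if cls not in CLASS_ORDER:
                raise ValueError(f"unknown pair class {cls!r}")
            if n < 0:
                raise ValueError("pair counts must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "homology_blocks" in data:
            data["homology_blocks"] = [tuple(b) for b in data["homology_blocks"]]
        return cls(**data)


@dataclass
class SimGene:
    gene_id: str
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str
    biotype: str


@dataclass
class SimGenomes:
    human: dict[str, str]
    mouse: dict[str, str]
    spikes: dict[str, str]
    blocks: list[tuple[str, int, int, float]]  # contig, start, end, identity (same coords both genomes)
    genes: dict[str, list[SimGene]]  # species -> genes
    paths: dict[str, Path] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mutate_to_identity(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Point-mutate each base with probability (1 - identity)."""
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < (1.0 - identity)
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _write_gtf(genes: Sequence[SimGene], path: Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            for feature in ("gene", "exon"):
                fh.write(
                    f"{g.contig}\tsimfix\t{feature}\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def make_toy_genomes(cfg: SimConfig, out_dir: Optional[str] = None) -> SimGenomes:
    """Build the two toy genomes, spike contigs, gene annotations and homology BED.

    Homology blocks are copied human -> mouse at identical coordinates in the
    first half of each contig and point-mutated down to the configured
    identity; genes live in the second half so gene-derived reads are always
    species-unique.
    """
    rng = np.random.default_rng(cfg.seed)
    human = {f"chr{i + 1}": _random_seq(rng, cfg.contig_length) for i in range(cfg.n_contigs)}
    mouse = {f"chr{i + 1}": _random_seq(rng, cfg.contig_length) for i in range(cfg.n_contigs)}

    blocks: list[tuple[str, int, int, float]] = []
    offsets = {name: 200 for name in human}
    for i, (length, identity) in enumerate(cfg.homology_blocks):
        contig = f"chr{(i % cfg.n_contigs) + 1}"
        start = offsets[contig]
        end = start + length
        if end > cfg.contig_length // 2:
            raise ValueError(
                f"homology block of {length} bp does not fit in the first half of {contig}"
            )
        src = human[contig][start:end]
        mutated = _mutate_to_identity(rng, src, identity)
        mouse[contig] = mouse[contig][:start] + mutated + mouse[contig][end:]
        blocks.append((contig, start, end, identity))
        offsets[contig] = end + 100

    genes: dict[str, list[SimGene]] = {"human": [], "mouse": []}
    for species, id_prefix in (("human", "ENSG"), ("mouse", "ENSMUSG")):
        pos = cfg.contig_length // 2 + 100
        contig_i = 0
        for gi in range(cfg.n_genes):
            contig = f"chr{contig_i + 1}"
            start, end = pos, pos + cfg.gene_length
            if end > cfg.contig_length - 100:
                contig_i = (contig_i + 1) % cfg.n_contigs
                pos = cfg.contig_length // 2 + 100
                contig = f"chr{contig_i + 1}"
                start, end = pos, pos + cfg.gene_length
                if end > cfg.contig_length - 100:
                    raise ValueError("too many genes for contig size")
            genes[species].append(
                SimGene(
                    gene_id=f"{id_prefix}{gi + 1:011d}",
                    contig=contig,
                    start=start,
                    end=end,
                    strand="+" if gi % 2 == 0 else "-",
                    biotype=BIOTYPES[gi % len(BIOTYPES)],
                )
            )
            pos = end + 100

    spikes: dict[str, str] = {}
    for i in range(cfg.n_sequin):
        spikes[f"R1_{i + 1}"] = _random_seq(rng, cfg.spike_length)
    for i in range(cfg.n_ercc):
        spikes[f"ERCC-{i + 1:05d}"] = _random_seq(rng, cfg.spike_length)

    sim = SimGenomes(human=human, mouse=mouse, spikes=spikes, blocks=blocks, genes=genes)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sim.paths = {
            "human_fasta": out / "human.fa",
            "mouse_fasta": out / "mouse.fa",
            "spike_fasta": out / "spikes.fa",
            "human_gtf": out / "human.gtf",
            "mouse_gtf": out / "mouse.gtf",
            "spike_gtf": out / "spikes.gtf",
            "homology_bed": out / "homology.bed",
        }
        _write_fasta(human, sim.paths["human_fasta"])
        _write_fasta(mouse, sim.paths["mouse_fasta"])
        _write_fasta(spikes, sim.paths["spike_fasta"])
        _write_gtf(genes["human"], sim.paths["human_gtf"])
        _write_gtf(genes["mouse"], sim.paths["mouse_gtf"])
        spike_genes = [
            SimGene(name, name, 0, len(seq), "+", "spikein") for name, seq in spikes.items()
        ]
        _write_gtf(spike_genes, sim.paths["spike_gtf"])
        with open(sim.paths["homology_bed"], "w") as fh:
            for contig, start, end, identity in blocks:
                fh.write(f"{contig}\t{start}\t{end}\tidentity={identity}\n")
    return sim


# ---------------------------------------------------------------------------
# alignment simulation


@dataclass
class _Mate:
    pos: int  # 0-based leftmost aligned base
    cigar: str
    seq: str  # stored in reference orientation, soft-clipped junk included
    reverse: bool
    aligned_start: int
    aligned_end: int


@dataclass
class _PairSpec:
    qname: str
    true_class: str
    contig: str
    frag_start: int
    frag_end: int
    from_block: bool
    mate1: _Mate
    mate2: _Mate


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _flag(mate1: bool, reverse: bool, mate_reverse: bool, secondary: bool = False) -> int:
    flag = 0x1 | 0x2 | (0x40 if mate1 else 0x80)
    if reverse:
        flag |= 0x10
    if mate_reverse:
        flag |= 0x20
    if secondary:
        flag |= 0x100
    return flag


def _sam_line(
    spec_mate: _Mate,
    other: _Mate,
    qname: str,
    contig: str,
    ref: dict[str, str],
    mate1: bool,
    nh: int,
    secondary: bool = False,
) -> str:
    a, b = spec_mate.aligned_start, spec_mate.aligned_end
    nm = _hamming(
        spec_mate.seq[_clip_lead(spec_mate.cigar) : _clip_lead(spec_mate.cigar) + (b - a)],
        ref[contig][a:b],
    )
    tlen = 0
    left = min(spec_mate.pos, other.pos)
    right = max(spec_mate.aligned_end, other.aligned_end)
    tlen = right - left
    if spec_mate.pos > other.pos or (spec_mate.pos == other.pos and not mate1):
        tlen = -tlen
    fields = [
        qname,
        str(_flag(mate1, spec_mate.reverse, other.reverse, secondary)),
        contig,
        str(spec_mate.pos + 1),
        "255",
        spec_mate.cigar,
        "=",
        str(other.pos + 1),
        str(tlen),
        spec_mate.seq,
        "*",
        f"NH:i:{nh}",
        f"NM:i:{nm}",
    ]
    return "\t".join(fields)


def _clip_lead(cigar: str) -> int:
    """Length of a leading soft clip, if any."""
    i = 0
    while i < len(cigar) and cigar[i].isdigit():
        i += 1
    return int(cigar[:i]) if i < len(cigar) and cigar[i] == "S" else 0


def _make_mate(
    rng: np.random.Generator,
    ref_seq: str,
    aligned_start: int,
    aligned_end: int,
    reverse: bool,
    clip_len: int,
    clip_at_start: bool,
    error_rate: float,
) -> _Mate:
    span = list(ref_seq[aligned_start:aligned_end])
    n_err = rng.binomial(len(span), error_rate) if error_rate > 0 else 0
    if n_err:
        for i in rng.choice(len(span), size=min(n_err, len(span)), replace=False):
            choices = [b for b in "ACGT" if b != span[i]]
            span[i] = choices[rng.integers(0, 3)]
    aligned = "".join(span)
    junk = _random_seq(rng, clip_len) if clip_len else ""
    n_match = aligned_end - aligned_start
    if clip_len == 0:
        cigar, seq = f"{n_match}M", aligned
    elif clip_at_start:
        cigar, seq = f"{clip_len}S{n_match}M", junk + aligned
    else:
        cigar, seq = f"{n_match}M{clip_len}S", aligned + junk
    return _Mate(
        pos=aligned_start,
        cigar=cigar,
        seq=seq,
        reverse=reverse,
        aligned_start=aligned_start,
        aligned_end=aligned_end,
    )


def _sample_fragment(
    rng: np.random.Generator, cfg: SimConfig, lo: int, hi: int
) -> tuple[int, int]:
    """Fragment [start, end) within [lo, hi)."""
    span = hi - lo
    frag = int(round(rng.normal(cfg.fragment_mean, cfg.fragment_sd)))
    frag = max(cfg.read_length, min(frag, span))
    start = lo + int(rng.integers(0, span - frag + 1))
    return start, start + frag


def _build_pair(
    rng: np.random.Generator,
    cfg: SimConfig,
    qname: str,
    true_class: str,
    contig: str,
    ref_seq: str,
    frag: tuple[int, int],
    from_block: bool,
    mate1_forward: bool = True,
) -> _PairSpec:
    start, end = frag
    rl = min(cfg.read_length, end - start)

    def clip() -> int:
        if cfg.soft_clip_rate > 0 and rng.random() < cfg.soft_clip_rate:
            return int(rng.integers(1, cfg.max_soft_clip + 1))
        return 0

    k_left = min(clip(), rl - 1)
    k_right = min(clip(), rl - 1)
    # FR pair: leftmost read forward, rightmost reverse; clipped junk sits on
    # the fragment's outer edges.  mate1_forward decides which mate is which.
    left = _make_mate(
        rng, ref_seq, start, start + rl - k_left, False,
        k_left, clip_at_start=True, error_rate=cfg.error_rate,
    )
    right = _make_mate(
        rng, ref_seq, end - rl + k_right, end, True,
        k_right, clip_at_start=False, error_rate=cfg.error_rate,
    )
    m1, m2 = (left, right) if mate1_forward else (right, left)
    return _PairSpec(qname, true_class, contig, start, end, from_block, m1, m2)


def _overlaps_block(blocks, contig: str, start: int, end: int) -> bool:
    return any(c == contig and start < be and bs < end for c, bs, be, _ in blocks)


def simulate_alignments(
    cfg: SimConfig, genomes: SimGenomes, out_dir: str, write_fastq: bool = False
) -> tuple[dict[str, Path], pd.DataFrame]:
    """Emit parallel-style and combined-style SAMs plus the truth table.

    ``human.sam``/``mouse.sam`` hold each template's alignment against one
    reference (homologous and spike templates appear in both, NH=1).
    ``combined.sam`` holds the best locus on the prefixed combined reference;
    score ties between the genomes become NH=2 multimappers with the second
    locus flagged secondary.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    specs: list[_PairSpec] = []
    idx = 0

    def next_qname() -> str:
        nonlocal idx
        idx += 1
        return f"P{idx:08d}"

    contigs = sorted(genomes.human)
    for true_class in CLASS_ORDER:
        n = cfg.n_pairs.get(true_class, 0)
        for j in range(n):
            qname = next_qname()
            if true_class in ("human", "mouse"):
                species = true_class
                ref = genomes.human if species == "human" else genomes.mouse
                gene_list = genomes.genes[species]
                if gene_list and rng.random() < cfg.gene_fraction:
                    gene = gene_list[int(rng.integers(0, len(gene_list)))]
                    frag = _sample_fragment(rng, cfg, gene.start, gene.end)
                    # reverse protocol: mate1 antisense to the gene
                    mate1_forward = gene.strand == "-"
                    specs.append(
                        _build_pair(rng, cfg, qname, true_class, gene.contig,
                                    ref[gene.contig], frag, False, mate1_forward)
                    )
                else:
                    for _ in range(1000):
                        contig = contigs[int(rng.integers(0, len(contigs)))]
                        frag = _sample_fragment(rng, cfg, 0, cfg.contig_length)
                        if not _overlaps_block(genomes.blocks, contig, *frag):
                            break
                    else:
                        raise RuntimeError("could not place fragment outside homology blocks")
                    specs.append(
                        _build_pair(rng, cfg, qname, true_class, contig, ref[contig], frag, False)
                    )
            elif true_class == "homologous":
                contig, bs, be, _ = genomes.blocks[j % len(genomes.blocks)]
                species = "human" if j % 2 == 0 else "mouse"
                ref = genomes.human if species == "human" else genomes.mouse
                frag = _sample_fragment(rng, cfg, bs, be)
                specs.append(
                    _build_pair(rng, cfg, qname, species, contig, ref[contig], frag, True)
                )
            else:  # sequin / ercc
                names = sorted(
                    n for n in genomes.spikes
                    if (n.startswith("ERCC")) == (true_class == "ercc")
                )
                contig = names[int(rng.integers(0, len(names)))]
                frag = _sample_fragment(rng, cfg, 0, len(genomes.spikes[contig]))
                specs.append(
                    _build_pair(rng, cfg, qname, true_class, contig,
                                genomes.spikes[contig], frag, False)
                )

    paths = {
        "human_sam": out / "human.sam",
        "mouse_sam": out / "mouse.sam",
        "combined_sam": out / "combined.sam",
        "truth": out / "truth.tsv",
    }
    _emit_sams(cfg, genomes, specs, paths)
    if write_fastq:
        paths["fastq1"] = out / "reads_1.fastq"
        paths["fastq2"] = out / "reads_2.fastq"
        _emit_fastq(specs, paths["fastq1"], paths["fastq2"])

    truth = pd.DataFrame(
        {
            "qname": [s.qname for s in specs],
            "true_class": [s.true_class for s in specs],
            "contig": [s.contig for s in specs],
            "frag_start": [s.frag_start for s in specs],
            "frag_end": [s.frag_end for s in specs],
            "from_homologous_block": [s.from_block for s in specs],
        }
    )
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths, truth


def _header(seqs: dict[str, str]) -> str:
    lines = ["@HD\tVN:1.6\tSO:queryname"]
    for name, seq in seqs.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{len(seq)}")
    return "\n".join(lines) + "\n"


def _pair_lines(spec: _PairSpec, contig: str, ref: dict[str, str], nh: int,
                secondary: bool = False) -> list[str]:
    return [
        _sam_line(spec.mate1, spec.mate2, spec.qname, contig, ref, True, nh, secondary),
        _sam_line(spec.mate2, spec.mate1, spec.qname, contig, ref, False, nh, secondary),
    ]


def _pair_nm_sum(spec: _PairSpec, contig: str, ref: dict[str, str]) -> int:
    total = 0
    for mate in (spec.mate1, spec.mate2):
        a, b = mate.aligned_start, mate.aligned_end
        lead = _clip_lead(mate.cigar)
        total += _hamming(mate.seq[lead : lead + (b - a)], ref[contig][a:b])
    return total


def _emit_sams(cfg, genomes: SimGenomes, specs: list[_PairSpec], paths) -> None:
    human_ref = {**genomes.human, **genomes.spikes}
    mouse_ref = {**genomes.mouse, **genomes.spikes}
    combined_ref = {
        **genomes.human,
        **{cfg.prefix + n: s for n, s in genomes.mouse.items()},
        **genomes.spikes,
    }
    with open(paths["human_sam"], "w") as fh_h, open(paths["mouse_sam"], "w") as fh_m, open(
        paths["combined_sam"], "w"
    ) as fh_c:
        fh_h.write(_header(human_ref))
        fh_m.write(_header(mouse_ref))
        fh_c.write(_header(combined_ref))
        for spec in specs:
            if spec.true_class in ("sequin", "ercc"):
                for line in _pair_lines(spec, spec.contig, human_ref, 1):
                    fh_h.write(line + "\n")
                for line in _pair_lines(spec, spec.contig, mouse_ref, 1):
                    fh_m.write(line + "\n")
                for line in _pair_lines(spec, spec.contig, combined_ref, 1):
                    fh_c.write(line + "\n")
                continue
            if not spec.from_block:
                if spec.true_class == "human":
                    for line in _pair_lines(spec, spec.contig, human_ref, 1):
                        fh_h.write(line + "\n")
                    for line in _pair_lines(spec, spec.contig, combined_ref, 1):
                        fh_c.write(line + "\n")
                else:
                    for line in _pair_lines(spec, spec.contig, mouse_ref, 1):
                        fh_m.write(line + "\n")
                    for line in _pair_lines(spec, cfg.prefix + spec.contig, combined_ref, 1):
                        fh_c.write(line + "\n")
                continue
            # homologous: present in both per-species runs, best locus in combined
            for line in _pair_lines(spec, spec.contig, human_ref, 1):
                fh_h.write(line + "\n")
            for line in _pair_lines(spec, spec.contig, mouse_ref, 1):
                fh_m.write(line + "\n")
            nm_h = _pair_nm_sum(spec, spec.contig, human_ref)
            nm_m = _pair_nm_sum(spec, spec.contig, mouse_ref)
            if nm_h < nm_m:
                for line in _pair_lines(spec, spec.contig, combined_ref, 1):
                    fh_c.write(line + "\n")
            elif nm_m < nm_h:
                for line in _pair_lines(spec, cfg.prefix + spec.contig, combined_ref, 1):
                    fh_c.write(line + "\n")
            else:
                for line in _pair_lines(spec, spec.contig, combined_ref, 2):
                    fh_c.write(line + "\n")
                for line in _pair_lines(
                    spec, cfg.prefix + spec.contig, combined_ref, 2, secondary=True
                ):
                    fh_c.write(line + "\n")


def _emit_fastq(specs: list[_PairSpec], path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for spec in specs:
            for mate, fh in ((spec.mate1, f1), (spec.mate2, f2)):
                seq = revcomp(mate.seq) if mate.reverse else mate.seq
                fh.write(f"@{spec.qname}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# fraction-series (count-level) simulation


def simulate_fraction_series(
    platelet_levels: Sequence[float],
    host_mean_per_unit: float,
    tumour_mean: float,
    sequin_mean: float,
    spike_mass_per_ml_pg: float = 21.94,
    labels: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Count-level model of the plasma fraction series.

    Host (mouse) counts are Poisson with mean proportional to the fraction's
    platelet level; tumour (human) and Sequin counts are Poisson with constant
    means.  Expected concentrations and delta-method standard errors follow
    analytically from the generating means and the spike mass model.
    """
    if list(platelet_levels) != sorted(platelet_levels, reverse=True):
        raise ValueError("platelet levels must be non-increasing (SSP >= DSP >= TSP)")
    if labels is None:
        default = ["SSP", "DSP", "TSP"]
        labels = [
            default[i] if i < len(default) else f"F{i + 1}" for i in range(len(platelet_levels))
        ]
    per_ml = spike_mass_per_ml_pg

    rng = np.random.default_rng(seed)
    rows = []
    for label, level in zip(labels, platelet_levels):
        mh = host_mean_per_unit * level
        host = int(rng.poisson(mh))
        tumour = int(rng.poisson(tumour_mean))
        sequin = int(rng.poisson(sequin_mean))
        est_host = spikequant.endogenous_concentration(host, sequin, per_ml) if sequin else np.nan
        est_tum = spikequant.endogenous_concentration(tumour, sequin, per_ml) if sequin else np.nan
        exp_host = (mh / sequin_mean) * per_ml
        exp_tum = (tumour_mean / sequin_mean) * per_ml
        se_host = (
            per_ml * (mh / sequin_mean) * np.sqrt(1.0 / mh + 1.0 / sequin_mean) if mh > 0 else 0.0
        )
        se_tum = (
            per_ml * (tumour_mean / sequin_mean) * np.sqrt(1.0 / tumour_mean + 1.0 / sequin_mean)
            if tumour_mean > 0
            else 0.0
        )
        frac = spikequant.tumour_fraction(est_tum, est_host)
        exp_frac = 100.0 * exp_tum / (exp_tum + exp_host) if (exp_tum + exp_host) > 0 else np.nan
        rows.append(
            {
                "fraction": label,
                "platelet_level": level,
                "host_counts": host,
                "tumour_counts": tumour,
                "sequin_counts": sequin,
                "est_conc_host": est_host,
                "est_conc_tumour": est_tum,
                "est_tumour_fraction_pct": frac,
                "expected_conc_host": exp_host,
                "expected_conc_tumour": exp_tum,
                "expected_tumour_fraction_pct": exp_frac,
                "se_conc_host": se_host,
                "se_conc_tumour": se_tum,
            }
        )
    return pd.DataFrame(rows)
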