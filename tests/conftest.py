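import pysam
import pytest

from xenosplit import simfix


def make_header(contigs=None):
    contigs = contigs or {"chr1": 100000, "chr2": 100000, "mchr1": 100000}
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "queryname"},
            "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
        }
    )


def make_record(
    header,
    qname="r1",
    flag=99,
    refname="chr1",
    pos=100,  # 1-based, as in SAM text
    cigar="50M",
    nh=1,
    nm=0,
    seq=None,
    extra_tags="",
):
    if seq is None:
        from xenosplit.samcore import query_length_from_cigar

        n = query_length_from_cigar(cigar) or 50
        seq = "A" * n
    fields = [
        qname, str(flag), refname, str(pos), "255", cigar, "=", str(pos), "0", seq, "*",
        f"NH:i:{nh}", f"NM:i:{nm}",
    ]
    if extra_tags:
        fields.append(extra_tags)
    return pysam.AlignedSegment.fromstring("\t".join(fields), header)


def make_pair_records(header, qname, refname="chr1", pos1=100, pos2=200,
                      cigar1="50M", cigar2="50M", nh=1, nm1=0, nm2=0):
    r1 = make_record(header, qname, 99, refname, pos1, cigar1, nh, nm1)
    r2 = make_record(header, qname, 147, refname, pos2, cigar2, nh, nm2)
    return [r1, r2]


@pytest.fixture
def header():
    return make_header()


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """One modest simulated dataset shared across read-only tests."""
    out = tmp_path_factory.mktemp("smallsim")
    cfg = simfix.SimConfig(
        seed=11,
        n_contigs=2,
        contig_length=30000,
        homology_blocks=[(2000, 0.9), (1500, 0.85)],
        n_genes=6,
        n_pairs={"human": 120, "mouse": 120, "homologous": 40, "sequin": 25, "ercc": 10},
        error_rate=0.01,
        soft_clip_rate=0.15,
        gene_fraction=0.5,
    )
    genomes = simfix.make_toy_genomes(cfg, out_dir=out)
    paths, truth = simfix.simulate_alignments(cfg, genomes, out)
    return cfg, genomes, paths, truth
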