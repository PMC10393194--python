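import numpy as np
import pysam
import pytest

from mrnp_atlas.synthetic_data import Transcript, Transcriptome


def _query_length(cigar: str) -> int:
    total = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MIS=X":
                total += int(num)
            num = ""
    return total


@pytest.fixture
def sam_writer(tmp_path):
    """Write hand-constructed SAM files: refs {name: length}, reads as dicts."""

    def write(refs: dict[str, int], reads: list[dict], name: str = "reads.sam") -> str:
        path = tmp_path / name
        header = {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": r, "LN": l} for r, l in refs.items()],
        }
        ref_index = {r: i for i, r in enumerate(refs)}
        with pysam.AlignmentFile(path, "wh", header=header) as fh:
            for i, r in enumerate(reads):
                a = pysam.AlignedSegment(fh.header)
                a.query_name = r.get("qname", f"r{i}")
                a.reference_id = ref_index[r["ref"]]
                a.reference_start = r["pos"]
                a.cigarstring = r["cigar"]
                a.flag = r.get("flag", 0)
                a.mapping_quality = 60
                n = _query_length(r["cigar"])
                a.query_sequence = "A" * n
                a.query_qualities = pysam.qualitystring_to_array("I" * n)
                fh.write(a)
        return str(path)

    return write


@pytest.fixture
def tiny_transcriptome() -> Transcriptome:
    """Three transcripts on one chromosome, the middle one intron-carrying."""
    t1 = Transcript("txA", "chr1", 100, mrna_length=300)
    t2 = Transcript(
        "txB", "chr1", 500, mrna_length=400, intron_length=200, exon1_length=150
    )
    t3 = Transcript("txC", "chr1", 1200, mrna_length=250, genome="mito")
    return Transcriptome(transcripts=[t1, t2, t3], chrom_seq={}, mature_seq={})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
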