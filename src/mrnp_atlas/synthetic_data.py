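"""Synthetic inputs for the mRNP analysis pipeline.

Everything the downstream stages consume — transcript annotation, aligned
reads, peptide-intensity tables, cross-link tables, per-residue confidence
scores, and RNA annealing substrates — can be generated here with the
statistical structure the analysis assumes:

* eluate read coverage is 5'-biased because a fraction of source molecules
  are nascent (3'-truncated at a uniform random point);
* eluate transcript abundance is shifted against mRNA half-life and in
  favour of transcript length, with mitochondrial transcripts depleted;
* junction-spanning reads are emitted unspliced (contiguous across the
  splice site) with a per-sample retention probability, otherwise split;
* peptide intensities are log-normal around protein copy number times a
  per-peptide detectability, so that iBAQ recovers planted stoichiometry;
* cross-link tables contain monolinks, intralinks (including planted
  homo-oligomer self-links) and interlinks with supporting peptide windows.

All generators are pure functions of their configuration and seed: the same
inputs produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import pysam

from .proteomics_quant import Protease, digest, observable_peptides

__all__ = [
    "GeneratorConfig",
    "ProteinSpec",
    "StoichiometrySpec",
    "XLProteinSpec",
    "CrosslinkTopologySpec",
    "Transcript",
    "Transcriptome",
    "generate_transcriptome",
    "simulate_counts",
    "simulate_reads",
    "simulate_junction_counts",
    "simulate_peptides",
    "simulate_crosslinks",
    "simulate_plddt",
    "make_annealing_pair",
    "default_mrnp_proteins",
    "default_crosslink_topology",
    "default_plddt_regions",
]

SPACER_NT = 100          # gap between tiled transcripts on the synthetic chromosomes
_QUAL = "I"              # constant placeholder base quality

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_ALPHABET = np.array(list("ACGT"))


def _rng(seed: int | np.random.Generator, *stream: int) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(np.random.SeedSequence([int(seed), *stream]))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the transcriptome and read simulators.

    ``truncation_fraction`` and ``retention_rate`` are per-sample: the eluate
    carries nascent (3'-truncated) molecules and a higher intron-retention
    probability, the lysate does not.
    """

    n_transcripts: int = 500
    length_range: tuple[int, int] = (400, 4000)
    length_shape: Literal["loguniform", "uniform"] = "loguniform"
    intron_fraction: float = 0.1
    mito_fraction: float = 0.05
    halflife_range: tuple[float, float] = (3.0, 100.0)  # minutes
    read_length: int = 75
    insert_size: float = 200.0
    insert_sd: float = 20.0
    truncation_fraction: dict[str, float] = field(
        default_factory=lambda: {"lysate": 0.0, "eluate": 0.5}
    )
    retention_rate: dict[str, float] = field(
        default_factory=lambda: {"lysate": 0.05, "eluate": 0.30}
    )
    enrichment_coefficients: tuple[float, float] = (-0.8, 0.5)  # (beta_halflife, beta_length)
    mito_depletion_factor: float = 0.01
    abundance_sd: float = 0.8   # log-scale spread of baseline transcript abundance
    n_read_pairs: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("intron_fraction", "mito_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("truncation_fraction", "retention_rate"):
            for sample, v in getattr(self, name).items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}[{sample!r}] must lie in [0, 1], got {v}")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError(f"degenerate length range {self.length_range}")
        if self.halflife_range[0] <= 0 or self.halflife_range[0] > self.halflife_range[1]:
            raise ValueError(f"invalid halflife_range {self.halflife_range}")
        if self.intron_fraction + self.mito_fraction > 1.0:
            raise ValueError("intron_fraction + mito_fraction exceeds 1")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class ProteinSpec:
    """One protein of the synthetic mRNP: sequence, class and per-condition copy number."""

    protein_id: str
    sequence: str
    weights: dict[str, float]          # condition label -> copy-number weight (>= 0)
    protein_class: str = "other"

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError(f"negative copy-number weight for {self.protein_id}")


@dataclass(frozen=True)
class StoichiometrySpec:
    proteins: tuple[ProteinSpec, ...]
    conditions: tuple[str, ...] = (
        "eluate",
        "flowthrough",
        "benzonase-eluate",
        "benzonase-flowthrough",
    )
    n_replicates: int = 3
    intensity_noise_sd: float = 0.1      # log-scale, natural log
    detectability_sd: float = 0.5        # per-peptide log-normal spread
    protease: Protease = Protease.LYSC
    peptide_length_range: tuple[int, int] = (7, 30)

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError("empty protein list")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class XLProteinSpec:
    protein_id: str
    length: int
    lysines: tuple[int, ...]            # 1-based positions

    def __post_init__(self) -> None:
        if any(not 1 <= k <= self.length for k in self.lysines):
            raise ValueError(f"lysine position outside protein bounds for {self.protein_id}")


@dataclass(frozen=True)
class CrosslinkTopologySpec:
    proteins: tuple[XLProteinSpec, ...]
    # (protein_a, residue_a, protein_b | None, residue_b | None); None partner = monolink
    planted_links: tuple[tuple[str, int, str | None, int | None], ...] = ()
    # intralinks constructed to satisfy the homo-oligomer rule: (protein, residue_a, residue_b)
    planted_self_links: tuple[tuple[str, int, int], ...] = ()
    peptide_window: int = 5              # half-width of the synthetic supporting-peptide interval


# ---------------------------------------------------------------------------
# transcript annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Transcript:
    """One synthetic transcript; coordinates are genomic 0-based half-open."""

    transcript_id: str
    chrom: str
    start: int
    mrna_length: int
    intron_length: int = 0
    exon1_length: int = 0          # mature-coordinate position of the splice junction
    genome: str = "nuclear"        # 'nuclear' | 'mito'
    half_life_min: float = 20.0

    @property
    def has_intron(self) -> bool:
        return self.intron_length > 0

    @property
    def span(self) -> int:
        """Genomic footprint of the pre-mRNA."""
        return self.mrna_length + self.intron_length

    @property
    def intron(self) -> tuple[int, int] | None:
        """Genomic intron interval (0-based half-open), or None."""
        if not self.has_intron:
            return None
        s = self.start + self.exon1_length
        return (s, s + self.intron_length)

    @property
    def exons(self) -> list[tuple[int, int]]:
        if not self.has_intron:
            return [(self.start, self.start + self.mrna_length)]
        iv = self.intron
        assert iv is not None
        return [(self.start, iv[0]), (iv[1], self.start + self.span)]

    def mature_to_genomic(self, pos: int) -> int:
        """Map a mature-mRNA coordinate to the genome."""
        if self.has_intron and pos >= self.exon1_length:
            return self.start + pos + self.intron_length
        return self.start + pos


@dataclass
class Transcriptome:
    transcripts: list[Transcript]
    chrom_seq: dict[str, str]
    mature_seq: dict[str, str]

    def __post_init__(self) -> None:
        self._by_id = {t.transcript_id: t for t in self.transcripts}

    def __getitem__(self, transcript_id: str) -> Transcript:
        return self._by_id[transcript_id]

    def __len__(self) -> int:
        return len(self.transcripts)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chrom_seq.items()}

    def table(self) -> pd.DataFrame:
        """Per-transcript covariates as a DataFrame indexed by transcript id."""
        rows = [
            {
                "transcript_id": t.transcript_id,
                "chrom": t.chrom,
                "length": t.mrna_length,
                "has_intron": t.has_intron,
                "genome": t.genome,
                "half_life_min": t.half_life_min,
            }
            for t in self.transcripts
        ]
        return pd.DataFrame(rows).set_index("transcript_id")

    # -- serialization ------------------------------------------------------

    def to_gff3(self, path: str) -> None:
        """Write the annotation as GFF3 (1-based closed intervals)."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom, length in sorted(self.chrom_lengths.items()):
                fh.write(f"##sequence-region {chrom} 1 {length}\n")
            for t in self.transcripts:
                attrs = (
                    f"ID={t.transcript_id};genome={t.genome};"
                    f"half_life_min={t.half_life_min:.4f}"
                )
                fh.write(
                    f"{t.chrom}\tmrnp_atlas\ttranscript\t{t.start + 1}\t"
                    f"{t.start + t.span}\t.\t+\t.\t{attrs}\n"
                )
                for i, (s, e) in enumerate(t.exons, start=1):
                    fh.write(
                        f"{t.chrom}\tmrnp_atlas\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                        f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n"
                    )

    @classmethod
    def from_gff3(cls, path: str) -> "Transcriptome":
        """Read an annotation written by :meth:`to_gff3` (sequences are not stored in GFF3)."""
        import gffutils.iterators

        feats: dict[str, dict] = {}
        order: list[str] = []
        chrom_lengths: dict[str, int] = {}
        for f in gffutils.iterators.DataIterator(path):
            if f.featuretype == "transcript":
                tid = f.attributes["ID"][0]
                feats[tid] = {
                    "chrom": f.seqid,
                    "start": f.start - 1,
                    "end": f.end,
                    "genome": f.attributes.get("genome", ["nuclear"])[0],
                    "half_life_min": float(f.attributes.get("half_life_min", ["20"])[0]),
                    "exons": [],
                }
                order.append(tid)
            elif f.featuretype == "exon":
                parent = f.attributes["Parent"][0]
                feats[parent]["exons"].append((f.start - 1, f.end))
            chrom_lengths[f.seqid] = max(chrom_lengths.get(f.seqid, 0), f.end)

        transcripts = []
        for tid in order:
            d = feats[tid]
            exons = sorted(d["exons"])
            mrna_length = sum(e - s for s, e in exons)
            if len(exons) == 1:
                intron_length = exon1_length = 0
            elif len(exons) == 2:
                intron_length = exons[1][0] - exons[0][1]
                exon1_length = exons[0][1] - exons[0][0]
            else:
                raise ValueError(f"transcript {tid} has {len(exons)} exons; expected 1 or 2")
            transcripts.append(
                Transcript(
                    transcript_id=tid,
                    chrom=d["chrom"],
                    start=d["start"],
                    mrna_length=mrna_length,
                    intron_length=intron_length,
                    exon1_length=exon1_length,
                    genome=d["genome"],
                    half_life_min=d["half_life_min"],
                )
            )
        return cls(transcripts=transcripts, chrom_seq={}, mature_seq={})

    def write_transcript_fasta(self, path: str) -> None:
        _write_fasta(path, self.mature_seq.items())

    def write_genome_fasta(self, path: str) -> None:
        _write_fasta(path, sorted(self.chrom_seq.items()))


def _write_fasta(path: str, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def generate_transcriptome(config: GeneratorConfig) -> Transcriptome:
    """Generate a synthetic annotation with sequences.

    Nuclear transcripts are tiled head-to-tail (with spacers) on chromosome
    ``chrN``, mitochondrial ones on ``chrM``.  A fraction ``intron_fraction``
    of nuclear transcripts carries exactly one intron (two exons); the rest
    are intronless.  Each transcript carries a genome-of-origin flag and an
    mRNA half-life drawn log-uniformly over ``halflife_range``.
    """
    rng = _rng(config.seed, 1)
    n = config.n_transcripts
    lo, hi = config.length_range
    if config.length_shape == "loguniform":
        lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)).astype(int)
    else:
        lengths = rng.integers(lo, hi + 1, size=n)
    lengths = np.clip(lengths, lo, hi)

    n_mito = int(round(config.mito_fraction * n))
    n_intron = int(round(config.intron_fraction * n))
    idx = rng.permutation(n)
    mito_idx = set(idx[:n_mito].tolist())
    intron_idx = set(idx[n_mito : n_mito + n_intron].tolist())  # disjoint from mito

    log_hl = rng.uniform(np.log(config.halflife_range[0]), np.log(config.halflife_range[1]), size=n)
    half_lives = np.exp(log_hl)

    transcripts: list[Transcript] = []
    mature_seq: dict[str, str] = {}
    chrom_parts: dict[str, list[str]] = {"chrN": [], "chrM": []}
    offsets = {"chrN": 0, "chrM": 0}

    for i in range(n):
        tid = f"tx{i + 1:04d}"
        length = int(lengths[i])
        genome = "mito" if i in mito_idx else "nuclear"
        chrom = "chrM" if genome == "mito" else "chrN"
        if i in intron_idx:
            exon1 = int(rng.integers(int(0.2 * length), int(0.8 * length) + 1))
            intron_len = int(rng.integers(80, 401))
        else:
            exon1 = 0
            intron_len = 0
        seq_mature = "".join(rng.choice(_DNA_ALPHABET, size=length))
        intron_seq = "".join(rng.choice(_DNA_ALPHABET, size=intron_len))
        pre = seq_mature[:exon1] + intron_seq + seq_mature[exon1:] if intron_len else seq_mature
        spacer = "".join(rng.choice(_DNA_ALPHABET, size=SPACER_NT))

        start = offsets[chrom] + SPACER_NT
        chrom_parts[chrom].extend([spacer, pre])
        offsets[chrom] = start + len(pre)

        transcripts.append(
            Transcript(
                transcript_id=tid,
                chrom=chrom,
                start=start,
                mrna_length=length,
                intron_length=intron_len,
                exon1_length=exon1,
                genome=genome,
                half_life_min=float(half_lives[i]),
            )
        )
        mature_seq[tid] = seq_mature

    chrom_seq = {c: "".join(parts) for c, parts in chrom_parts.items() if parts}
    return Transcriptome(transcripts=transcripts, chrom_seq=chrom_seq, mature_seq=mature_seq)


# ---------------------------------------------------------------------------
# abundance model and read simulation
# ---------------------------------------------------------------------------


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd


def expected_abundance(
    transcriptome: Transcriptome, config: GeneratorConfig, sample_label: str
) -> pd.Series:
    """Relative expected abundance per transcript (sums to 1).

    The lysate reflects the baseline (log-normal) abundance; the eluate adds
    ``beta_halflife * z(log half-life) + beta_length * z(log length)`` on the
    log scale and scales mitochondrial transcripts by ``mito_depletion_factor``.
    """
    if sample_label not in ("lysate", "eluate"):
        raise ValueError(f"unknown sample_label {sample_label!r}")
    tab = transcriptome.table()
    # baseline is a property of the transcript pool, shared by both samples
    base = _rng(config.seed, 2).normal(0.0, config.abundance_sd, size=len(tab))
    log_w = base.copy()
    if sample_label == "eluate":
        beta_hl, beta_len = config.enrichment_coefficients
        log_w += beta_hl * _standardize(np.log(tab["half_life_min"].to_numpy()))
        log_w += beta_len * _standardize(np.log(tab["length"].to_numpy()))
        log_w += np.where(
            tab["genome"].to_numpy() == "mito", np.log(config.mito_depletion_factor), 0.0
        )
    w = np.exp(log_w)
    return pd.Series(w / w.sum(), index=tab.index, name=sample_label)


def simulate_counts(
    transcriptome: Transcriptome,
    config: GeneratorConfig,
    sample_label: str,
    seed: int | np.random.Generator,
) -> pd.Series:
    """Poisson read-pair counts per transcript under the abundance model."""
    rng = _rng(seed, 3)
    w = expected_abundance(transcriptome, config, sample_label)
    lam = config.n_read_pairs * w.to_numpy()
    return pd.Series(rng.poisson(lam), index=w.index, name=sample_label)


def _fragments(
    rng: np.random.Generator, n: int, length: int, config: GeneratorConfig, trunc_frac: float
) -> tuple[np.ndarray, np.ndarray]:
    """Fragment intervals (start, end) in mature-molecule coordinates.

    A fraction ``trunc_frac`` of source molecules is 3'-truncated at a uniform
    random point (nascent-transcription proxy), which shifts fragment mass to
    the 5' end.  Inserts are normal(insert_size, insert_sd), clipped to the
    molecule and to the read length.
    """
    rl = config.read_length
    mol_len = np.full(n, length)
    truncated = rng.random(n) < trunc_frac
    if truncated.any():
        cut = np.ceil(rng.random(truncated.sum()) * length).astype(int)
        mol_len[truncated] = np.maximum(rl, cut)
    insert = np.rint(rng.normal(config.insert_size, config.insert_sd, size=n)).astype(int)
    insert = np.clip(insert, rl, mol_len)
    start = rng.integers(0, mol_len - insert + 1)
    return start, start + insert


def simulate_reads(
    transcriptome: Transcriptome,
    config: GeneratorConfig,
    sample_label: str,
    seed: int | np.random.Generator,
    path: str,
    mode: Literal["transcript", "genome"] = "transcript",
) -> None:
    """Simulate paired-end reads and write a SAM file.

    ``transcript`` mode aligns reads against per-transcript references in
    mature-mRNA coordinates (all CIGARs are a single M run) and feeds the
    coverage/metagene and enrichment paths.  ``genome`` mode aligns against
    the synthetic chromosomes: a mate spanning the splice junction of an
    intron-carrying transcript is emitted unspliced (contiguous across the
    junction, anchored at the 5' or 3' splice site with equal probability)
    with probability ``retention_rate[sample_label]``, otherwise split with an
    N gap spanning the annotated intron exactly.
    """
    if sample_label not in ("lysate", "eluate"):
        raise ValueError(f"unknown sample_label {sample_label!r}")
    rng = _rng(seed, 4)
    counts = simulate_counts(transcriptome, config, sample_label, rng)
    trunc = config.truncation_fraction.get(sample_label, 0.0)
    retention = config.retention_rate.get(sample_label, 0.0)
    rl = config.read_length

    if mode == "transcript":
        refs = [(t.transcript_id, t.mrna_length) for t in transcriptome.transcripts]
    elif mode == "genome":
        refs = sorted(transcriptome.chrom_lengths.items())
        if not refs:
            raise ValueError("transcriptome has no chromosome sequences (genome mode)")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in refs],
        "PG": [{"ID": "mrnp-atlas", "PN": "mrnp-atlas", "CL": f"simulate {sample_label} {mode}"}],
    }
    ref_index = {name: i for i, (name, _) in enumerate(refs)}

    # (ref_id, pos, cigar, seq, qname, flag, mate_pos) collected, then sorted per reference
    records: list[tuple[int, int, str, str, str, int, int]] = []

    for t in transcriptome.transcripts:
        n = int(counts[t.transcript_id])
        if n == 0:
            continue
        fs, fe = _fragments(rng, n, t.mrna_length, config, trunc)
        r1 = np.stack([fs, np.minimum(fs + rl, fe)], axis=1)
        r2 = np.stack([np.maximum(fe - rl, fs), fe], axis=1)
        for i in range(n):
            qname = f"{sample_label}.{t.transcript_id}.{i + 1}"
            mates = []
            for mate_idx, (ms, me) in enumerate((r1[i], r2[i])):
                ms, me = int(ms), int(me)
                if mode == "transcript":
                    ref = t.transcript_id
                    pos, cigar = ms, f"{me - ms}M"
                    seq = transcriptome.mature_seq[ref][ms:me] if transcriptome.mature_seq else None
                else:
                    ref = t.chrom
                    pos, cigar, seq = _genomic_alignment(t, ms, me, retention, rng, transcriptome)
                if seq is None:
                    seq = "N" * (me - ms)
                mates.append((ref_index[ref], pos, cigar, seq, mate_idx))
            flag1 = 0x1 | 0x2 | 0x20 | 0x40  # paired, proper, mate reverse, first
            flag2 = 0x1 | 0x2 | 0x10 | 0x80  # paired, proper, reverse, second
            for (ridx, pos, cigar, seq, mate_idx), flag, mate in (
                (mates[0], flag1, mates[1]),
                (mates[1], flag2, mates[0]),
            ):
                records.append((ridx, pos, cigar, seq, qname, flag, mate[1]))

    records.sort(key=lambda r: (r[0], r[1], r[4]))
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for ridx, pos, cigar, seq, qname, flag, mate_pos in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = ridx
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = cigar
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(_QUAL * len(seq))
            a.next_reference_id = ridx
            a.next_reference_start = mate_pos
            out.write(a)


def _genomic_alignment(
    t: Transcript,
    ms: int,
    me: int,
    retention: float,
    rng: np.random.Generator,
    transcriptome: Transcriptome,
) -> tuple[int, str, str | None]:
    """Map a mature-coordinate mate [ms, me) to a genomic alignment.

    Returns (0-based genomic start, CIGAR, sequence).  Junction-spanning
    mates are unspliced with probability ``retention``; an unspliced mate is
    anchored at the 5' or 3' splice site (equal odds) and runs contiguously
    into the intron, as a read from an intron-retaining pre-mRNA would.
    """
    chrom_seq = transcriptome.chrom_seq.get(t.chrom) if transcriptome.chrom_seq else None
    j = t.exon1_length
    length = me - ms

    def contiguous(gstart: int) -> tuple[int, str, str | None]:
        seq = chrom_seq[gstart : gstart + length] if chrom_seq else None
        return gstart, f"{length}M", seq

    if not t.has_intron or me <= j or ms >= j:
        return contiguous(t.mature_to_genomic(ms))
    if rng.random() < retention:
        if rng.random() < 0.5:
            return contiguous(t.start + ms)                      # 5'-anchored, runs into intron
        return contiguous(t.start + me + t.intron_length - length)  # 3'-anchored
    cigar = f"{j - ms}M{t.intron_length}N{me - j}M"
    if chrom_seq:
        g5 = t.start + ms
        g3 = t.start + j + t.intron_length
        seq = chrom_seq[g5 : g5 + (j - ms)] + chrom_seq[g3 : g3 + (me - j)]
    else:
        seq = None
    return t.start + ms, cigar, seq


def simulate_junction_counts(
    n_junctions: int,
    retention_rate: float,
    depth_mean: float,
    seed: int | np.random.Generator,
    sample: str = "sample",
) -> pd.DataFrame:
    """Read-count-level junction simulator (no alignments).

    Per junction, total junction-spanning depth is Poisson(``depth_mean``) and
    each spanning read is unspliced (nonsplit) with probability
    ``retention_rate`` — the same read-level model :func:`simulate_reads`
    applies, collapsed to counts.  Output matches the schema of
    :func:`mrnp_atlas.rnaseq_metrics.junction_stats`.
    """
    rng = _rng(seed, 5)
    depth = rng.poisson(depth_mean, size=n_junctions)
    nonsplit = rng.binomial(depth, retention_rate)
    split = depth - nonsplit
    frac = np.divide(nonsplit, split, out=np.full(n_junctions, np.nan), where=split > 0)
    return pd.DataFrame(
        {
            "junction_id": [f"j{i + 1}" for i in range(n_junctions)],
            "site": "5prime",
            "sample": sample,
            "split_count": split,
            "nonsplit_count": nonsplit,
            "covered": depth,
            "unspliced_fraction": frac,
        }
    )


# ---------------------------------------------------------------------------
# peptide intensities
# ---------------------------------------------------------------------------

_INTENSITY_SCALE = 1e6


def simulate_peptides(spec: StoichiometrySpec, seed: int | np.random.Generator) -> pd.DataFrame:
    """Simulate a peptide-intensity table (one row per protein, peptide, replicate, condition).

    Detected peptides are the theoretically observable ones from the in-silico
    digest (fully cleaved, length within ``peptide_length_range``).  Each
    peptide gets a fixed log-normal detectability; replicate intensities are
    log-normal around copy-number weight x detectability.  Proteins with
    weight 0 in a condition produce no rows there.
    """
    rng = _rng(seed, 6)
    rows = []
    for prot in spec.proteins:
        peptides = observable_peptides(prot.sequence, spec.protease, spec.peptide_length_range)
        if not peptides:
            continue
        detect = np.exp(rng.normal(0.0, spec.detectability_sd, size=len(peptides)))
        for condition in spec.conditions:
            weight = prot.weights.get(condition, 0.0)
            if weight == 0.0:
                continue
            for rep in range(1, spec.n_replicates + 1):
                noise = np.exp(rng.normal(0.0, spec.intensity_noise_sd, size=len(peptides)))
                intensities = _INTENSITY_SCALE * weight * detect * noise
                for pep, inten in zip(peptides, intensities):
                    rows.append(
                        {
                            "protein": prot.protein_id,
                            "peptide_seq": pep.sequence,
                            "replicate": rep,
                            "condition": condition,
                            "intensity": float(inten),
                        }
                    )
    return pd.DataFrame(
        rows, columns=["protein", "peptide_seq", "replicate", "condition", "intensity"]
    )


# ---------------------------------------------------------------------------
# cross-links
# ---------------------------------------------------------------------------


def simulate_crosslinks(
    spec: CrosslinkTopologySpec, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Build a cross-link table from planted links.

    Every planted link appears exactly once with supporting peptide intervals
    of half-width ``peptide_window`` clipped to protein bounds; monolinks have
    an empty partner side.  Planted residues must be lysines of the stated
    proteins.
    """
    proteins = {p.protein_id: p for p in spec.proteins}

    def anchor(pid: str, residue: int) -> tuple[int, int]:
        p = proteins[pid]
        if residue not in p.lysines:
            raise ValueError(f"planted residue {pid}:{residue} is not a lysine")
        return (max(1, residue - spec.peptide_window), min(p.length, residue + spec.peptide_window))

    rows = []
    for pa, ra, pb, rb in spec.planted_links:
        sa, ea = anchor(pa, ra)
        if pb is None:
            rows.append((pa, ra, sa, ea, "", "", "", ""))
        else:
            sb, eb = anchor(pb, rb)
            rows.append((pa, ra, sa, ea, pb, rb, sb, eb))
    for pid, ra, rb in spec.planted_self_links:
        sa, ea = anchor(pid, ra)
        sb, eb = anchor(pid, rb)
        rows.append((pid, ra, sa, ea, pid, rb, sb, eb))

    df = pd.DataFrame(
        rows,
        columns=[
            "protein_a",
            "residue_a",
            "pepA_start",
            "pepA_end",
            "protein_b",
            "residue_b",
            "pepB_start",
            "pepB_end",
        ],
    )
    rng = _rng(seed, 7)
    return df.iloc[rng.permutation(len(df))].reset_index(drop=True)


def simulate_plddt(
    proteins: Sequence[tuple[str, int, Sequence[tuple[int, int]]]],
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Per-residue confidence scores: (protein_id, length, structured regions 1-based closed).

    Residues inside structured regions score high (folded-like, >= 70),
    residues outside score low (disordered-like, < 70).
    """
    rng = _rng(seed, 8)
    rows = []
    for pid, length, regions in proteins:
        scores = np.clip(rng.normal(45.0, 8.0, size=length), 20.0, 69.5)
        for s, e in regions:
            scores[s - 1 : e] = np.clip(rng.normal(88.0, 4.0, size=e - s + 1), 70.5, 99.0)
        rows.extend(
            {"protein": pid, "residue": i + 1, "plddt": float(v)} for i, v in enumerate(scores)
        )
    return pd.DataFrame(rows, columns=["protein", "residue", "plddt"])


# ---------------------------------------------------------------------------
# annealing substrates
# ---------------------------------------------------------------------------


def reverse_complement_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def make_annealing_pair(
    substrate_len: int,
    core_len: int,
    flank_len: int,
    seed: int | np.random.Generator,
) -> tuple[str, str, tuple[int, int]]:
    """Construct a protection-assay substrate/probe pair.

    The probe is ``flank + reverse-complement(substrate core window) + flank``;
    every flank base that faces a substrate base at the annealed register is
    forced to mismatch it, so the perfectly complementary stretch is exactly
    ``core_len`` nucleotides.  Returns (substrate, probe, core interval on the
    substrate, 0-based half-open).
    """
    from .annealing_sim import anneal

    if core_len > substrate_len:
        raise ValueError(f"core_len {core_len} exceeds substrate_len {substrate_len}")
    if core_len < 1 or flank_len < 0:
        raise ValueError("core_len must be >= 1 and flank_len >= 0")
    rng = _rng(seed, 9)
    alphabet = np.array(list("ACGU"))
    complement = dict(zip("ACGU", "UGCA"))

    for _ in range(100):
        substrate = "".join(rng.choice(alphabet, size=substrate_len))
        core_start = int(rng.integers(0, substrate_len - core_len + 1))
        core_end = core_start + core_len
        probe_core = reverse_complement_rna(substrate[core_start:core_end])

        def flank_base(partner: int | None) -> str:
            if partner is None:
                return str(rng.choice(alphabet))
            banned = complement[substrate[partner]]
            return str(rng.choice([b for b in "ACGU" if b != banned]))

        # probe index p (within the annealed register) pairs substrate index
        # core_end - 1 - (p - flank_len); flanks extend that register outward
        probe5 = [
            flank_base(core_end - 1 + flank_len - i if core_end - 1 + flank_len - i < substrate_len else None)
            for i in range(flank_len)
        ]
        probe3 = [
            flank_base(core_end - 1 - i if core_end - 1 - i >= 0 else None)
            for i in range(flank_len + core_len, 2 * flank_len + core_len)
        ]
        probe = "".join(probe5) + probe_core + "".join(probe3)

        # reject the (vanishingly rare) draw with a spurious second match
        duplexes = anneal(substrate, probe, min_duplex=min(15, core_len))
        if len(duplexes) == 1 and duplexes[0].substrate_interval == (core_start, core_end):
            return substrate, probe, (core_start, core_end)
    raise RuntimeError("failed to construct an annealing pair without spurious matches")


# ---------------------------------------------------------------------------
# default synthetic mRNP protein set
# ---------------------------------------------------------------------------

# approximate amino-acid frequencies of the yeast proteome, K/R-rich enough
# for LysC/trypsin digestion to yield observable peptides
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_FREQ = np.array(
    [0.055, 0.013, 0.058, 0.065, 0.045, 0.050, 0.022, 0.066, 0.073, 0.095,
     0.021, 0.061, 0.044, 0.040, 0.044, 0.090, 0.059, 0.056, 0.010, 0.034]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length, p=_AA_FREQ))


def default_mrnp_proteins(seed: int = 0) -> tuple[ProteinSpec, ...]:
    """A 12-protein synthetic mRNP emulating the purified-particle landscape.

    Copy-number weights encode the qualitative composition of the particles:
    Yra1-like overstoichiometric in the intact eluate (10x the THO scaffold),
    reduced after nuclease (benzonase) treatment; Sub2-like substoichiometric;
    cap-binding and poly(A)-tail-binding proteins present; large amounts of
    Sub2/Yra1-like material in the flowthrough.
    """
    rng = _rng(seed, 10)
    # (id, class, length aa, weights: eluate, flowthrough, benzonase-eluate, benzonase-flowthrough)
    layout = [
        ("THO1L", "THO", 1450, (1.0, 0.2, 1.0, 0.2)),
        ("THO2L", "THO", 750, (1.0, 0.2, 1.0, 0.2)),
        ("THO3L", "THO", 390, (1.0, 0.2, 1.0, 0.2)),
        ("THO4L", "THO", 260, (1.0, 0.2, 1.0, 0.2)),
        ("SUB2L", "Sub2-like", 450, (0.5, 3.0, 0.5, 1.0)),
        ("YRA1L", "Yra1-like", 230, (10.0, 4.0, 1.5, 8.0)),
        ("YHS7L", "Yra1-like", 240, (3.0, 1.0, 0.5, 2.0)),
        ("CBP80L", "cap-binding", 860, (1.0, 0.5, 0.3, 1.2)),
        ("CBP20L", "cap-binding", 210, (1.0, 0.5, 0.3, 1.2)),
        ("NAB2L", "tail-binding", 520, (2.0, 1.0, 0.4, 2.5)),
        ("PAB1L", "tail-binding", 580, (2.5, 1.5, 0.4, 3.0)),
        ("YHSXL", "other", 320, (0.5, 0.3, 0.2, 0.5)),
    ]
    conditions = ("eluate", "flowthrough", "benzonase-eluate", "benzonase-flowthrough")
    return tuple(
        ProteinSpec(
            protein_id=pid,
            sequence=_random_protein(rng, length),
            weights=dict(zip(conditions, weights)),
            protein_class=cls,
        )
        for pid, cls, length, weights in layout
    )


def default_crosslink_topology(
    proteins: Sequence[ProteinSpec],
    seed: int = 0,
    n_intra: int = 12,
    n_inter: int = 9,
    n_mono: int = 20,
    peptide_window: int = 5,
) -> CrosslinkTopologySpec:
    """Plant a desk-scale cross-link topology on a protein set.

    Intralinks, interlinks and monolinks are planted on randomly chosen
    lysines; two homo-oligomer self-links are planted on the Yra1-like and
    tail-binding proteins (one identical-lysine pair, one
    overlapping-peptide pair), mirroring the particles' homo-oligomeric
    poly(A)-binding and Yra1-like species.
    """
    rng = _rng(seed, 11)
    xl_proteins = []
    lysines: dict[str, list[int]] = {}
    for p in proteins:
        ks = [i + 1 for i, aa in enumerate(p.sequence) if aa == "K"]
        if not ks:
            continue
        lysines[p.protein_id] = ks
        xl_proteins.append(
            XLProteinSpec(protein_id=p.protein_id, length=len(p.sequence), lysines=tuple(ks))
        )
    ids = list(lysines)

    def pick(pid: str) -> int:
        return int(rng.choice(lysines[pid]))

    links: list[tuple[str, int, str | None, int | None]] = []
    for _ in range(n_intra):
        pid = str(rng.choice(ids))
        ra, rb = pick(pid), pick(pid)
        # keep planted intralinks clear of the self-link rule
        tries = 0
        while (ra == rb or abs(ra - rb) <= 2 * peptide_window) and tries < 50:
            rb = pick(pid)
            tries += 1
        links.append((pid, ra, pid, rb))
    for _ in range(n_inter):
        pa, pb = rng.choice(ids, size=2, replace=False)
        links.append((str(pa), pick(str(pa)), str(pb), pick(str(pb))))
    for _ in range(n_mono):
        pid = str(rng.choice(ids))
        links.append((pid, pick(pid), None, None))

    self_links: list[tuple[str, int, int]] = []
    by_class = {p.protein_class: p.protein_id for p in proteins if p.protein_id in lysines}
    for cls in ("Yra1-like", "tail-binding"):
        pid = by_class.get(cls)
        if pid is None:
            continue
        ks = lysines[pid]
        r = ks[len(ks) // 2]
        if not self_links:
            self_links.append((pid, r, r))                     # identical lysines
        else:
            near = [k for k in ks if 0 < abs(k - r) <= 2 * peptide_window]
            self_links.append((pid, r, near[0] if near else r))  # overlapping peptides

    return CrosslinkTopologySpec(
        proteins=tuple(xl_proteins),
        planted_links=tuple(links),
        planted_self_links=tuple(self_links),
        peptide_window=peptide_window,
    )


def default_plddt_regions(
    proteins: Sequence[ProteinSpec],
) -> list[tuple[str, int, list[tuple[int, int]]]]:
    """One structured (RRM-like) region per protein, covering its middle 40%;
    the remainder emulates the disordered, low-confidence tails typical of
    mRNA-binding proteins."""
    regions = []
    for p in proteins:
        length = len(p.sequence)
        s, e = max(1, int(0.3 * length) + 1), max(1, int(0.7 * length))
        regions.append((p.protein_id, length, [(s, e)]))
    return regions
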