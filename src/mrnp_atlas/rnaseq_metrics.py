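"""RNA-content metrics for purified mRNP particles.

Coverage profiles and the 100-bin scaled metagene matrix, per-junction
unspliced fractions (nonsplit/split read ratio with a coverage filter and a
Wilcoxon rank-sum comparison between samples), and eluate/lysate enrichment
via median-of-ratios normalization with Spearman correlation against mRNA
half-life and transcript length.

Coordinates are 0-based half-open internally; GFF3 on disk is 1-based
closed; SAM follows its specification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .synthetic_data import Transcript, Transcriptome

__all__ = [
    "CoverageProfile",
    "MetageneMatrix",
    "coverage_profile",
    "coverage_profiles",
    "metagene_matrix",
    "classify_read_at_site",
    "junction_stats",
    "compare_unspliced",
    "count_reads",
    "enrichment_table",
    "correlate_enrichment",
]

DEFAULT_MIN_COV = 20
DEFAULT_MIN_ANCHOR = 3
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class CoverageProfile:
    """Per-nucleotide read depth along a transcript, 5' to 3'."""

    transcript_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    def __len__(self) -> int:
        return len(self.depth)


@dataclass
class MetageneMatrix:
    """Transcripts x positional bins, each row min-max scaled to [0, 1].

    ``column_summary`` is the per-bin average over transcripts, min-max
    rescaled to [0%, 100%].
    """

    transcript_ids: list[str]
    matrix: np.ndarray          # (n_transcripts, n_bins), values in [0, 1]
    column_summary: np.ndarray  # (n_bins,), values in [0, 100]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=pd.Index(self.transcript_ids, name="transcript_id"),
            columns=[f"bin{i + 1}" for i in range(self.n_bins)],
        )


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


def _aligned_blocks(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Reference intervals covered by M/=/X runs; N gaps, insertions and
    deletions contribute nothing to coverage (I/D are coverage-neutral
    length adjustments)."""
    blocks: list[tuple[int, int]] = []
    pos = read.reference_start
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8):        # M, =, X
            blocks.append((pos, pos + length))
            pos += length
        elif op in (2, 3):         # D, N consume reference without coverage
            pos += length
        # I, S, H, P consume no reference
    return blocks


def coverage_profiles(
    sam_path: str, lengths: dict[str, int] | None = None
) -> dict[str, CoverageProfile]:
    """One pass over a SAM file, returning a profile per reference.

    ``lengths`` defaults to the reference lengths in the SAM header.  Depth at
    a position is the number of aligned (M) segments covering it.
    """
    with pysam.AlignmentFile(sam_path) as sam:
        if lengths is None:
            lengths = dict(zip(sam.references, sam.lengths))
        diff = {ref: np.zeros(n + 1, dtype=np.int64) for ref, n in lengths.items()}
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped or read.reference_name not in diff:
                continue
            d = diff[read.reference_name]
            for s, e in _aligned_blocks(read):
                d[min(s, len(d) - 1)] += 1
                d[min(e, len(d) - 1)] -= 1
    return {
        ref: CoverageProfile(ref, np.cumsum(d[:-1])) for ref, d in diff.items()
    }


def coverage_profile(sam_path: str, transcript_id: str, length: int | None = None) -> CoverageProfile:
    """Coverage profile for one reference of a SAM file."""
    with pysam.AlignmentFile(sam_path) as sam:
        refs = dict(zip(sam.references, sam.lengths))
    if transcript_id not in refs:
        raise KeyError(f"transcript {transcript_id!r} absent from SAM header")
    length = length if length is not None else refs[transcript_id]
    return coverage_profiles(sam_path, {transcript_id: length})[transcript_id]


# ---------------------------------------------------------------------------
# metagene
# ---------------------------------------------------------------------------


def _bin_means(depth: np.ndarray, n_bins: int) -> np.ndarray:
    """Average depth within n_bins equal-width bins over the profile length."""
    L = len(depth)
    if L == 0:
        raise ValueError("empty profile")
    edges = (np.arange(n_bins + 1) * L) // n_bins
    if L >= n_bins:
        sums = np.add.reduceat(depth.astype(float), edges[:-1])
        widths = np.diff(edges)
        return sums / widths
    # short profile: resample positions onto the bin grid
    centers = (np.arange(n_bins) + 0.5) * L / n_bins
    return depth.astype(float)[np.floor(centers).astype(int)]


def _minmax(x: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Min-max scale to [0, scale]; a constant vector maps to all zeros."""
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x, dtype=float)
    return scale * (x - lo) / (hi - lo)


def metagene_matrix(
    profiles: list[CoverageProfile],
    n_bins: int = 100,
    subset: set[str] | None = None,
) -> MetageneMatrix:
    """Scaled metagene matrix over a set of coverage profiles.

    Each transcript's coverage is split into ``n_bins`` bins and averaged
    within each, the binned profile is scaled linearly between 0 and 1
    (constant profiles, including all-zero ones, scale to all zeros), and the
    per-bin average over transcripts is further scaled linearly between 0%
    and 100%.  ``subset`` restricts to the given transcript ids — the
    analysis convention is nuclear, intronless transcripts only.
    """
    if subset is not None:
        profiles = [p for p in profiles if p.transcript_id in subset]
    if not profiles:
        raise ValueError("empty profile set after subsetting")
    rows = np.stack([_minmax(_bin_means(p.depth, n_bins)) for p in profiles])
    summary = _minmax(rows.mean(axis=0), scale=100.0)
    return MetageneMatrix(
        transcript_ids=[p.transcript_id for p in profiles],
        matrix=rows,
        column_summary=summary,
    )


# ---------------------------------------------------------------------------
# splice junctions
# ---------------------------------------------------------------------------


def classify_read_at_site(
    blocks: list[tuple[int, int]],
    gaps: list[tuple[int, int]],
    site_pos: int,
    site: str,
    intron: tuple[int, int],
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> str | None:
    """Classify one read at one annotated splice site.

    Returns ``"split"`` if the read carries an N gap exactly matching the
    annotated intron, ``"nonsplit"`` if an aligned block crosses the junction
    point contiguously with at least ``min_anchor`` aligned nucleotides on
    each side, ``"discard"`` for reads whose gap overlaps the site but
    disagrees with the annotation, and None for reads that do not overlap
    the site.
    """
    for gs, ge in gaps:
        if (gs, ge) == intron:
            return "split"
        if gs < site_pos + min_anchor and ge > site_pos - min_anchor:
            return "discard"    # gapped at the locus but inconsistent with annotation
    for bs, be in blocks:
        if bs <= site_pos - min_anchor and be >= site_pos + min_anchor:
            return "nonsplit"
    return None


def _read_gaps(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    gaps = []
    pos = read.reference_start
    for op, length in read.cigartuples or []:
        if op in (0, 2, 7, 8):
            pos += length
        elif op == 3:
            gaps.append((pos, pos + length))
            pos += length
    return gaps


def junction_stats(
    sam_path: str,
    transcriptome: Transcriptome,
    min_cov: int = DEFAULT_MIN_COV,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    sample: str = "sample",
) -> pd.DataFrame:
    """Per-splice-site split/nonsplit counts with the coverage filter.

    Every annotated intron contributes two junction records (its 5' and 3'
    splice sites).  split = reads whose N gap matches the annotated intron
    exactly; nonsplit = reads covering the junction point contiguously with
    >= ``min_anchor`` nt on each side; reads gapped inconsistently with the
    annotation are discarded from both counts.  Junctions with
    split + nonsplit < ``min_cov`` are dropped.  The unspliced fraction
    (nonsplit / split) is defined only where split > 0.
    """
    sites: list[tuple[str, str, str, int, tuple[int, int]]] = []
    for t in transcriptome.transcripts:
        if t.intron_length < 0:
            raise ValueError(f"nonpositive intron length for {t.transcript_id}")
        iv = t.intron
        if iv is None:
            continue
        sites.append((t.transcript_id, t.chrom, "5prime", iv[0], iv))
        sites.append((t.transcript_id, t.chrom, "3prime", iv[1], iv))

    by_chrom: dict[str, list[int]] = {}
    for i, (_, chrom, _, pos, _) in enumerate(sites):
        by_chrom.setdefault(chrom, []).append(i)

    split = np.zeros(len(sites), dtype=np.int64)
    nonsplit = np.zeros(len(sites), dtype=np.int64)
    with pysam.AlignmentFile(sam_path) as sam:
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped or read.reference_name not in by_chrom:
                continue
            blocks = _aligned_blocks(read)
            gaps = _read_gaps(read)
            rs, re = read.reference_start, read.reference_end
            for i in by_chrom[read.reference_name]:
                _, _, site, pos, intron = sites[i]
                if re < pos - min_anchor or rs > pos + min_anchor:
                    continue
                verdict = classify_read_at_site(blocks, gaps, pos, site, intron, min_anchor)
                if verdict == "split":
                    split[i] += 1
                elif verdict == "nonsplit":
                    nonsplit[i] += 1

    covered = split + nonsplit
    frac = np.divide(
        nonsplit, split, out=np.full(len(sites), np.nan), where=split > 0
    )
    df = pd.DataFrame(
        {
            "junction_id": [s[0] for s in sites],
            "site": [s[2] for s in sites],
            "sample": sample,
            "split_count": split,
            "nonsplit_count": nonsplit,
            "covered": covered,
            "unspliced_fraction": frac,
        }
    )
    return df[df["covered"] >= min_cov].reset_index(drop=True)


def compare_unspliced(
    lysate: pd.DataFrame, eluate: pd.DataFrame
) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon rank-sum test on per-junction unspliced fractions.

    Junctions with no split reads (fraction undefined) are excluded.  Returns
    (statistic, p-value, degenerate); a comparison where every retained
    fraction is identical has an undefined p and is reported degenerate.
    Ties are handled by the normal approximation with tie correction for
    n > 20 (exact distribution otherwise, when tie-free).
    """
    x = lysate["unspliced_fraction"].dropna().to_numpy()
    y = eluate["unspliced_fraction"].dropna().to_numpy()
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 retained junctions per sample")
    if len(np.unique(np.concatenate([x, y]))) == 1:
        return float("nan"), float("nan"), True
    method = "exact" if (len(x) <= 20 and len(y) <= 20) else "asymptotic"
    if method == "exact" and len(np.unique(np.concatenate([x, y]))) < len(x) + len(y):
        method = "asymptotic"   # exact method is invalid under ties
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), False


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def count_reads(sam_path: str) -> pd.Series:
    """Read-pair counts per reference of a transcript-coordinate SAM.

    A pair counts once for the transcript either mate aligns to (mates of a
    pair share the reference in transcript-coordinate mode, so first-mate
    records are counted).
    """
    with pysam.AlignmentFile(sam_path) as sam:
        counts = dict.fromkeys(sam.references, 0)
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            if read.is_paired and read.is_read2:
                continue
            counts[read.reference_name] += 1
    return pd.Series(counts, name="count")


def enrichment_table(
    lysate_counts: pd.Series,
    eluate_counts: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Eluate-over-lysate enrichment with median-of-ratios normalization.

    Size factors are the median ratio of each sample to the geometric-mean
    pseudo-reference over transcripts with nonzero counts in both samples.
    log2fc = log2((eluate/sf_e + c) / (lysate/sf_l + c)) with pseudocount c,
    finite for every transcript.
    """
    idx = lysate_counts.index.intersection(eluate_counts.index)
    l = lysate_counts.loc[idx].to_numpy(dtype=float)
    e = eluate_counts.loc[idx].to_numpy(dtype=float)
    if l.sum() == 0 or e.sum() == 0:
        raise ValueError("a sample has all-zero counts")
    both = (l > 0) & (e > 0)
    if not both.any():
        raise ValueError("no transcript with nonzero counts in both samples")
    ref = np.sqrt(l[both] * e[both])
    sf_l = float(np.median(l[both] / ref))
    sf_e = float(np.median(e[both] / ref))
    log2fc = np.log2((e / sf_e + pseudocount) / (l / sf_l + pseudocount))
    return pd.DataFrame(
        {
            "transcript_id": idx,
            "lysate_count": l.astype(int),
            "eluate_count": e.astype(int),
            "size_factor_lysate": sf_l,
            "size_factor_eluate": sf_e,
            "log2fc": log2fc,
        }
    ).set_index("transcript_id")


def correlate_enrichment(
    records: pd.DataFrame, covariate: pd.Series
) -> tuple[float, float]:
    """Spearman rank correlation of log2fc against a per-transcript covariate.

    Ties get average ranks (scipy's convention).  Transcripts missing from
    either side are dropped; needs >= 3 shared transcripts and a
    non-constant covariate.
    """
    shared = records.index.intersection(covariate.dropna().index)
    if len(shared) < 3:
        raise ValueError("need >= 3 transcripts with a non-missing covariate")
    x = records.loc[shared, "log2fc"].to_numpy()
    y = covariate.loc[shared].to_numpy(dtype=float)
    if np.unique(y).size == 1:
        raise ValueError("constant covariate")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
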