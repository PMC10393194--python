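"""In-silico RNA-annealing / RNase T1 protection assay.

A substrate RNA and a probe carrying a perfectly complementary core are
annealed (exact antiparallel Watson-Crick matching; G.U wobble pairs are not
counted), single-stranded regions are digested, and the surviving fragment
lengths emulate the banding pattern of a denaturing gel.  Protein annealing
activity is modeled as a boolean switch: the assay readout is presence or
absence of the protected duplex band, not annealing kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

__all__ = [
    "RNAMolecule",
    "DuplexRegion",
    "ProtectedFragment",
    "anneal",
    "rnase_t1_digest",
    "assay",
]

_RNA_ALPHABET = set("ACGU")
_WC_PAIR = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
DEFAULT_MIN_DUPLEX = 15


@dataclass(frozen=True)
class RNAMolecule:
    """An RNA sequence, 5' to 3'."""

    molecule_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.molecule_id}")
        bad = set(self.sequence) - _RNA_ALPHABET
        if bad:
            raise ValueError(f"non-RNA characters {sorted(bad)} in {self.molecule_id}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DuplexRegion:
    """An antiparallel Watson-Crick duplex between substrate and probe.

    Intervals are 0-based half-open on each molecule; substrate position
    ``substrate_interval[0] + k`` pairs probe position
    ``probe_interval[1] - 1 - k``.
    """

    substrate_interval: tuple[int, int]
    probe_interval: tuple[int, int]

    def __post_init__(self) -> None:
        (ss, se), (ps, pe) = self.substrate_interval, self.probe_interval
        if se - ss != pe - ps:
            raise ValueError("duplex intervals differ in length")

    @property
    def length(self) -> int:
        return self.substrate_interval[1] - self.substrate_interval[0]


@dataclass(frozen=True)
class ProtectedFragment:
    """A fragment surviving RNase T1 digestion."""

    molecule_id: str
    interval: tuple[int, int]

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


def _seq(molecule: RNAMolecule | str) -> str:
    return molecule.sequence if isinstance(molecule, RNAMolecule) else molecule


def anneal(
    substrate: RNAMolecule | str,
    probe: RNAMolecule | str,
    min_duplex: int = DEFAULT_MIN_DUPLEX,
) -> list[DuplexRegion]:
    """All maximal exact antiparallel Watson-Crick duplexes of length >= ``min_duplex``.

    Overlapping candidates are resolved greedily by descending length, ties
    broken by leftmost substrate coordinate; the returned duplexes are
    mutually non-overlapping on both molecules.
    """
    if min_duplex < 1:
        raise ValueError("min_duplex must be >= 1")
    s = _seq(substrate)
    p = _seq(probe)
    n, m = len(s), len(p)

    # maximal runs along antiparallel diagonals: substrate i pairs probe j,
    # extension advances i and decreases j
    candidates: list[DuplexRegion] = []
    # each diagonal is indexed by d = i + j (constant along a run)
    for d in range(n + m - 1):
        i = max(0, d - m + 1)
        j = d - i
        run = 0
        run_start = i
        while i < n and j >= 0:
            if (s[i], p[j]) in _WC_PAIR:
                if run == 0:
                    run_start = i
                run += 1
            else:
                if run >= min_duplex:
                    candidates.append(_region(run_start, run, d))
                run = 0
            i += 1
            j -= 1
        if run >= min_duplex:
            candidates.append(_region(run_start, run, d))

    candidates.sort(key=lambda r: (-r.length, r.substrate_interval[0]))
    chosen: list[DuplexRegion] = []
    for cand in candidates:
        if all(
            not _overlap(cand.substrate_interval, c.substrate_interval)
            and not _overlap(cand.probe_interval, c.probe_interval)
            for c in chosen
        ):
            chosen.append(cand)
    chosen.sort(key=lambda r: r.substrate_interval[0])
    return chosen


def _region(sub_start: int, length: int, diagonal: int) -> DuplexRegion:
    sub_iv = (sub_start, sub_start + length)
    # substrate position k pairs probe position diagonal - k
    probe_hi = diagonal - sub_start          # pairs sub_start (highest probe index)
    probe_iv = (probe_hi - length + 1, probe_hi + 1)
    return DuplexRegion(substrate_interval=sub_iv, probe_interval=probe_iv)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _paired_mask(length: int, intervals: Iterable[tuple[int, int]]) -> list[bool]:
    mask = [False] * length
    for s, e in intervals:
        if not 0 <= s <= e <= length:
            raise ValueError(f"duplex interval ({s}, {e}) outside molecule of length {length}")
        for i in range(s, e):
            mask[i] = True
    return mask


def rnase_t1_digest(
    molecules: list[RNAMolecule],
    duplexes: list[DuplexRegion],
    mode: Literal["idealized", "g_specific"] = "idealized",
    substrate_id: str | None = None,
    probe_id: str | None = None,
) -> list[ProtectedFragment]:
    """Digest unpaired RNA, keeping duplex-protected fragments.

    ``idealized`` removes every unpaired nucleotide, returning exactly the
    duplexed intervals of each molecule (the assay's readout: unpaired
    regions are digested entirely).  ``g_specific`` models the enzyme's
    actual guanosine specificity: cleavage only 3' of unpaired G residues,
    so protected fragments may carry non-G single-stranded overhangs up to
    the nearest unpaired G; fragments containing no paired nucleotide are
    digestion products, not protection, and are dropped.
    """
    if not molecules:
        return []
    ids = [m.molecule_id for m in molecules]
    substrate_id = substrate_id or ids[0]
    probe_id = probe_id or (ids[1] if len(ids) > 1 else ids[0])
    for mid in (substrate_id, probe_id):
        if duplexes and mid not in ids:
            raise ValueError(f"duplex references unknown molecule {mid!r}")

    per_molecule: dict[str, list[tuple[int, int]]] = {m.molecule_id: [] for m in molecules}
    for d in duplexes:
        per_molecule.setdefault(substrate_id, []).append(d.substrate_interval)
        if probe_id in per_molecule:
            per_molecule[probe_id].append(d.probe_interval)

    fragments: list[ProtectedFragment] = []
    for mol in molecules:
        mask = _paired_mask(len(mol), per_molecule.get(mol.molecule_id, []))
        if mode == "idealized":
            fragments.extend(
                ProtectedFragment(mol.molecule_id, iv) for iv in _runs(mask)
            )
        elif mode == "g_specific":
            # cut 3' of every unpaired G, then keep fragments containing >= 1 paired nt
            cuts = [0] + [
                i + 1 for i, (aa, paired) in enumerate(zip(mol.sequence, mask))
                if aa == "G" and not paired
            ] + [len(mol)]
            for s, e in zip(cuts[:-1], cuts[1:]):
                if e > s and any(mask[s:e]):
                    fragments.append(ProtectedFragment(mol.molecule_id, (s, e)))
        else:
            raise ValueError(f"unknown digestion mode {mode!r}")
    return fragments


def _runs(mask: list[bool]) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def assay(
    substrate: RNAMolecule | None,
    probe: RNAMolecule | None,
    annealing_active: bool,
    min_duplex: int = DEFAULT_MIN_DUPLEX,
    mode: Literal["idealized", "g_specific"] = "idealized",
) -> dict[str, list[int]]:
    """Run the protection assay and report per-molecule lane contents.

    With annealing active (an annealing-competent protein present) the two
    RNAs are annealed and then digested; without it, or with one molecule
    absent, digestion removes everything and lanes are empty.  Fragment
    lengths per lane are sorted descending, emulating gel migration order.
    """
    molecules = [m for m in (substrate, probe) if m is not None]
    lanes: dict[str, list[int]] = {m.molecule_id: [] for m in molecules}
    duplexes: list[DuplexRegion] = []
    if annealing_active and substrate is not None and probe is not None:
        duplexes = anneal(substrate, probe, min_duplex)
    fragments = rnase_t1_digest(
        molecules,
        duplexes,
        mode=mode,
        substrate_id=substrate.molecule_id if substrate else None,
        probe_id=probe.molecule_id if probe else None,
    )
    for frag in fragments:
        lanes[frag.molecule_id].append(frag.length)
    return {mid: sorted(lengths, reverse=True) for mid, lengths in lanes.items()}
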