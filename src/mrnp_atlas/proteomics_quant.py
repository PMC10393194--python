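"""iBAQ protein quantitation: in-silico digestion, observable-peptide counting,
per-replicate iBAQ and condition-level stoichiometry ratios.

iBAQ (intensity-based absolute quantification) divides the summed peptide
intensity of a protein by the number of peptides the protease could
theoretically yield in the detectable length window, making abundances
comparable across proteins of different size and cleavability.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Protease",
    "Peptide",
    "ProteinEntry",
    "digest",
    "observable_peptides",
    "count_observable_peptides",
    "average_mass",
    "read_protein_fasta",
    "ibaq_table",
    "stoichiometry_report",
]

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")

# average (isotope-abundance-weighted) residue masses in Daltons, IUPAC standard
_AVG_RESIDUE_MASS = {
    "A": 71.0785, "C": 103.1435, "D": 115.0880, "E": 129.1146, "F": 147.1744,
    "G": 57.0519, "H": 137.1399, "I": 113.1582, "K": 128.1729, "L": 113.1582,
    "M": 131.1966, "N": 114.1032, "P": 97.1158, "Q": 128.1298, "R": 156.1863,
    "S": 87.0779, "T": 101.1045, "V": 99.1316, "W": 186.2105, "Y": 163.1738,
}
_WATER_AVG = 18.0147


class Protease(str, enum.Enum):
    """Supported proteases.

    LysC cleaves C-terminal to lysine; Trypsin/P cleaves C-terminal to lysine
    or arginine, including when the next residue is proline (unlike plain
    trypsin).
    """

    LYSC = "lysc"
    TRYPSIN_P = "trypsin/p"

    def cleaves_after(self, residue: str) -> bool:
        if self is Protease.LYSC:
            return residue == "K"
        return residue in "KR"


@dataclass(frozen=True)
class Peptide:
    """A proteolytic peptide with 1-based inclusive coordinates on its protein."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int = 0

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProteinEntry:
    """A protein with its class annotation, as plotted in the MW-vs-abundance landscape."""

    protein_id: str
    sequence: str
    protein_class: str = "other"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.protein_id}")
        bad = set(self.sequence) - _VALID_AA
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in {self.protein_id}")

    @property
    def theoretical_mw(self) -> float:
        return average_mass(self.sequence)


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - _VALID_AA
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)}")


def digest(
    sequence: str, protease: Protease | str, missed_cleavages: int = 0
) -> list[Peptide]:
    """In-silico proteolytic digest.

    Returns peptides for 0..``missed_cleavages`` missed cleavage sites, in
    order of start position then length, with 1-based inclusive coordinates.
    """
    protease = Protease(protease)
    _validate_sequence(sequence)
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")

    # fully cleaved boundaries: cut after every cleavage residue (not at the C terminus)
    cuts = [0]
    cuts.extend(
        i + 1
        for i, aa in enumerate(sequence)
        if protease.cleaves_after(aa) and i + 1 < len(sequence)
    )
    cuts.append(len(sequence))

    peptides = []
    n_frag = len(cuts) - 1
    for i in range(n_frag):
        for m in range(missed_cleavages + 1):
            if i + 1 + m > n_frag:
                break
            s, e = cuts[i], cuts[i + 1 + m]
            peptides.append(
                Peptide(sequence=sequence[s:e], start=s + 1, end=e, missed_cleavages=m)
            )
    return peptides


def observable_peptides(
    sequence: str,
    protease: Protease | str = Protease.LYSC,
    length_range: tuple[int, int] = (7, 30),
) -> list[Peptide]:
    """Fully cleaved peptides whose length falls within ``length_range`` (inclusive)."""
    lo, hi = length_range
    return [p for p in digest(sequence, protease, 0) if lo <= len(p) <= hi]


def count_observable_peptides(
    sequence: str,
    protease: Protease | str = Protease.LYSC,
    length_range: tuple[int, int] = (7, 30),
) -> int:
    """Theoretically observable peptide count — the iBAQ denominator.

    Floored at 1 so that short or cleavage-poor proteins keep a defined iBAQ.
    """
    return max(1, len(observable_peptides(sequence, protease, length_range)))


def average_mass(sequence: str) -> float:
    """Average-isotopic molecular weight in Daltons (residue sum + one water).

    ``X`` residues are tolerated and excluded from the sum.
    """
    _validate_sequence(sequence)
    return sum(_AVG_RESIDUE_MASS[aa] for aa in sequence if aa != "X") + _WATER_AVG


def read_protein_fasta(path: str, classes: dict[str, str] | None = None) -> list[ProteinEntry]:
    """Load proteins from FASTA.

    The class annotation is taken from a ``class=...`` token on the header
    line if present, else from the ``classes`` mapping, else ``other``.
    """
    from Bio import SeqIO

    entries = []
    for rec in SeqIO.parse(path, "fasta"):
        cls = None
        for token in rec.description.split():
            if token.startswith("class="):
                cls = token.split("=", 1)[1]
        if cls is None and classes is not None:
            cls = classes.get(rec.id)
        entries.append(ProteinEntry(rec.id, str(rec.seq), cls or "other"))
    return entries


def ibaq_table(
    peptides: pd.DataFrame,
    proteins: list[ProteinEntry],
    protease: Protease | str = Protease.LYSC,
    length_range: tuple[int, int] = (7, 30),
) -> pd.DataFrame:
    """Per-(protein, condition, replicate) iBAQ with condition means.

    ``peptides`` needs columns protein, peptide_seq, replicate, condition,
    intensity.  iBAQ = summed intensity / observable-peptide count.  A protein
    absent from a replicate (but present in the experiment) gets iBAQ 0 for
    that replicate, so condition means stay comparable across proteins.
    """
    required = {"protein", "peptide_seq", "replicate", "condition", "intensity"}
    missing = required - set(peptides.columns)
    if missing:
        raise ValueError(f"peptide table lacks columns {sorted(missing)}")
    by_id = {p.protein_id: p for p in proteins}
    unknown = set(peptides["protein"]) - set(by_id)
    if unknown:
        raise ValueError(f"peptide rows reference unknown proteins {sorted(unknown)}")

    denom = {
        pid: count_observable_peptides(p.sequence, protease, length_range)
        for pid, p in by_id.items()
    }

    summed = (
        peptides.groupby(["protein", "condition", "replicate"], as_index=False)["intensity"]
        .sum()
        .rename(columns={"intensity": "summed_intensity"})
    )
    # complete the (protein, condition) x replicate grid with zeros
    full = []
    for condition, sub in summed.groupby("condition"):
        reps = sorted(peptides.loc[peptides["condition"] == condition, "replicate"].unique())
        grid = pd.MultiIndex.from_product(
            [sorted(sub["protein"].unique()), [condition], reps],
            names=["protein", "condition", "replicate"],
        )
        full.append(
            sub.set_index(["protein", "condition", "replicate"])
            .reindex(grid, fill_value=0.0)
            .reset_index()
        )
    table = pd.concat(full, ignore_index=True)
    table["observable_peptides"] = table["protein"].map(denom)
    table["ibaq"] = table["summed_intensity"] / table["observable_peptides"]
    table["mean_ibaq"] = table.groupby(["protein", "condition"])["ibaq"].transform("mean")
    table["mw"] = table["protein"].map(lambda pid: by_id[pid].theoretical_mw)
    table["protein_class"] = table["protein"].map(lambda pid: by_id[pid].protein_class)
    return table


def condition_means(table: pd.DataFrame) -> pd.DataFrame:
    """One row per (protein, condition) with the replicate-mean iBAQ."""
    return (
        table.drop_duplicates(["protein", "condition"])[
            ["protein", "condition", "mean_ibaq", "observable_peptides", "mw", "protein_class"]
        ]
        .sort_values(["condition", "protein"])
        .reset_index(drop=True)
    )


def stoichiometry_report(
    table: pd.DataFrame,
    numerator_class: str,
    denominator_class: str,
) -> dict[str, float]:
    """Per-condition abundance ratio between two protein classes.

    ratio = mean over numerator-class proteins of their condition-mean iBAQ,
    divided by the same for the denominator class.  Raises if the denominator
    class is absent in a condition.
    """
    means = condition_means(table)
    report: dict[str, float] = {}
    for condition, sub in means.groupby("condition"):
        num = sub.loc[sub["protein_class"] == numerator_class, "mean_ibaq"]
        den = sub.loc[sub["protein_class"] == denominator_class, "mean_ibaq"]
        if den.empty or den.mean() == 0:
            raise ValueError(
                f"denominator class {denominator_class!r} absent in condition {condition!r}"
            )
        if num.empty:
            raise ValueError(
                f"numerator class {numerator_class!r} absent in condition {condition!r}"
            )
        report[condition] = float(num.mean() / den.mean())
    return report


def write_outputs(table: pd.DataFrame, report: dict[str, float], outdir: str) -> None:
    """Write the iBAQ TSV, stoichiometry JSON and MW-vs-abundance scatter CSV."""
    import os

    table.to_csv(os.path.join(outdir, "ibaq.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "stoichiometry.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    condition_means(table).rename(columns={"mean_ibaq": "abundance"}).to_csv(
        os.path.join(outdir, "mw_vs_ibaq.csv"), index=False
    )
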