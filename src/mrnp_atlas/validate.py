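"""Schema diagnostics for pipeline input files.

Lightweight, line-anchored format validation for GFF3, SAM, FASTA and the
pipeline's TSV schemas (peptide intensities, cross-links, pLDDT).  Each
problem is reported as a :class:`Diagnostic` naming the file, the line and
the violated rule; an empty list means the file passed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["Diagnostic", "validate_file", "validate_io"]

_CIGAR_RE = re.compile(r"^(\d+[MIDNSHP=X])+$|^\*$")
_GFF3_COLS = 9
_SAM_MIN_COLS = 11


@dataclass(frozen=True)
class Diagnostic:
    path: str
    line: int | None
    message: str

    def __str__(self) -> str:
        loc = f"{self.path}:{self.line}" if self.line is not None else self.path
        return f"{loc}: {self.message}"


def _validate_gff3(path: str) -> list[Diagnostic]:
    diags = []
    with open(path) as fh:
        for i, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF3_COLS:
                diags.append(Diagnostic(path, i, f"expected {_GFF3_COLS} columns, got {len(cols)}"))
                continue
            try:
                start, end = int(cols[3]), int(cols[4])
                if start < 1 or end < start:
                    diags.append(Diagnostic(path, i, f"invalid interval {start}..{end}"))
            except ValueError:
                diags.append(Diagnostic(path, i, "non-integer coordinates"))
    return diags


def _validate_sam(path: str) -> list[Diagnostic]:
    diags = []
    refs: set[str] = set()
    with open(path) as fh:
        for i, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    for field in line.split("\t")[1:]:
                        if field.startswith("SN:"):
                            refs.add(field[3:])
                continue
            cols = line.split("\t")
            if len(cols) < _SAM_MIN_COLS:
                diags.append(
                    Diagnostic(path, i, f"record {cols[0] if cols else '?'}: fewer than {_SAM_MIN_COLS} fields")
                )
                continue
            qname, _, rname, pos, _, cigar = cols[0], cols[1], cols[2], cols[3], cols[4], cols[5]
            if not _CIGAR_RE.match(cigar):
                diags.append(Diagnostic(path, i, f"record {qname}: malformed CIGAR {cigar!r}"))
            if rname != "*" and refs and rname not in refs:
                diags.append(Diagnostic(path, i, f"record {qname}: reference {rname!r} not in header"))
            try:
                if int(pos) < 0:
                    diags.append(Diagnostic(path, i, f"record {qname}: negative POS"))
            except ValueError:
                diags.append(Diagnostic(path, i, f"record {qname}: non-integer POS"))
    return diags


def _validate_fasta(path: str) -> list[Diagnostic]:
    diags = []
    seen_header = False
    with open(path) as fh:
        for i, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                seen_header = True
                if len(line) == 1:
                    diags.append(Diagnostic(path, i, "empty FASTA header"))
            elif not seen_header:
                diags.append(Diagnostic(path, i, "sequence before first header"))
                break
    if not seen_header:
        diags.append(Diagnostic(path, None, "no FASTA records"))
    return diags


def _validate_crosslinks(path: str) -> list[Diagnostic]:
    from .xlms_network import LINK_COLUMNS

    diags = []
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # unreadable / not a TSV
        return [Diagnostic(path, None, f"unparseable TSV: {exc}")]
    missing = set(LINK_COLUMNS) - set(df.columns)
    if missing:
        return [Diagnostic(path, None, f"missing columns {sorted(missing)}")]
    for idx, r in df.iterrows():
        line = int(idx) + 2  # header on line 1
        for side in ("A", "B"):
            prot = r[f"protein_{side.lower()}"]
            res = r[f"residue_{side.lower()}"]
            if pd.isna(prot) or prot == "":
                if not (pd.isna(res) or res == ""):
                    diags.append(Diagnostic(path, line, f"residue_{side.lower()} without protein"))
                continue
            try:
                res = int(res)
                s, e = int(r[f"pep{side}_start"]), int(r[f"pep{side}_end"])
            except (TypeError, ValueError):
                diags.append(Diagnostic(path, line, f"non-integer coordinates on side {side}"))
                continue
            if not s <= res <= e:
                diags.append(
                    Diagnostic(path, line, f"residue {res} outside peptide interval [{s}, {e}] on side {side}")
                )
    return diags


def _validate_tsv(path: str, required: set[str]) -> list[Diagnostic]:
    try:
        df = pd.read_csv(path, sep="\t", nrows=5, comment="#")
    except Exception as exc:
        return [Diagnostic(path, None, f"unparseable TSV: {exc}")]
    missing = required - set(df.columns)
    if missing:
        return [Diagnostic(path, None, f"missing columns {sorted(missing)}")]
    return []


def validate_file(path: str, kind: str | None = None) -> list[Diagnostic]:
    """Validate one file; ``kind`` is inferred from the suffix/name if omitted."""
    p = Path(path)
    if not p.is_file():
        return [Diagnostic(path, None, "unreadable file")]
    if kind is None:
        suffix = p.suffix.lower()
        if suffix in (".gff3", ".gff"):
            kind = "gff3"
        elif suffix == ".sam":
            kind = "sam"
        elif suffix in (".fasta", ".fa"):
            kind = "fasta"
        elif "crosslink" in p.name or p.name.startswith("xl"):
            kind = "crosslinks"
        elif "peptide" in p.name:
            kind = "peptides"
        elif "plddt" in p.name:
            kind = "plddt"
        else:
            kind = "tsv"
    dispatch = {
        "gff3": _validate_gff3,
        "sam": _validate_sam,
        "fasta": _validate_fasta,
        "crosslinks": _validate_crosslinks,
        "peptides": lambda q: _validate_tsv(
            q, {"protein", "peptide_seq", "replicate", "condition", "intensity"}
        ),
        "plddt": lambda q: _validate_tsv(q, {"protein", "residue", "plddt"}),
        "tsv": lambda q: _validate_tsv(q, set()),
    }
    if kind not in dispatch:
        raise ValueError(f"unknown file kind {kind!r}")
    return dispatch[kind](str(path))


def validate_io(paths: list[str]) -> list[Diagnostic]:
    """Validate a set of files, concatenating their diagnostics."""
    diags: list[Diagnostic] = []
    for path in paths:
        diags.extend(validate_file(path))
    return diags
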