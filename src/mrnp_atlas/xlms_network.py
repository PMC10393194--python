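"""Cross-linking mass-spectrometry link networks.

Classifies BS3 cross-link products into monolinks (one reacted end),
intralinks (both ends in the same protein) and interlinks (ends in two
different proteins), flags intralinks that evidence homo-oligomers
(identical lysines or overlapping supporting peptides imply two copies of
the same protein in proximity), overlays per-residue AlphaFold confidence
(pLDDT) as a disorder proxy, and computes the circular-map layout used to
draw the link network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LINK_COLUMNS",
    "read_links",
    "classify_links",
    "detect_self_links",
    "DisorderProfile",
    "disorder_overlay",
    "CircularLayout",
    "circular_layout",
    "plot_circular_map",
]

LINK_COLUMNS = [
    "protein_a",
    "residue_a",
    "pepA_start",
    "pepA_end",
    "protein_b",
    "residue_b",
    "pepB_start",
    "pepB_end",
]

DEFAULT_PLDDT_THRESHOLD = 70.0


def read_links(path: str) -> pd.DataFrame:
    """Read a cross-link TSV (monolinks have empty partner fields)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    missing = set(LINK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cross-link table lacks columns {sorted(missing)}")
    return df


def _is_empty(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or v == ""


def classify_links(links: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Partition links into mono/intra/inter and count categories.

    Interlinks are canonicalized to lexicographic protein order (and
    intralinks to ascending residue order) so that A-B and B-A duplicates
    collapse; duplicate links between the same residues are collapsed with a
    ``multiplicity`` count.  Returns (categorized table, category counts).
    """
    rows = []
    for _, r in links.iterrows():
        pa, ra = r["protein_a"], r["residue_a"]
        pb, rb = r["protein_b"], r["residue_b"]
        if _is_empty(pa):
            raise ValueError("link row without protein_a")
        if _is_empty(pb) != _is_empty(rb):
            raise ValueError(f"link row with residue but no protein (or vice versa): {r.to_dict()}")
        a = (str(pa), int(ra), int(r["pepA_start"]), int(r["pepA_end"]))
        if _is_empty(pb):
            rows.append(("mono", *a, None, None, None, None))
            continue
        b = (str(pb), int(rb), int(r["pepB_start"]), int(r["pepB_end"]))
        category = "intra" if a[0] == b[0] else "inter"
        if (b[0], b[1]) < (a[0], a[1]):
            a, b = b, a
        rows.append((category, *a, *b))

    out = pd.DataFrame(
        rows,
        columns=["category"] + LINK_COLUMNS[:4] + LINK_COLUMNS[4:],
    )
    out = (
        out.groupby(["category"] + LINK_COLUMNS, dropna=False, as_index=False)
        .size()
        .rename(columns={"size": "multiplicity"})
    )
    counts = {
        cat: int((out["category"] == cat).sum()) for cat in ("mono", "intra", "inter")
    }
    return out.reset_index(drop=True), counts


def detect_self_links(classified: pd.DataFrame) -> pd.DataFrame:
    """Flag intralinks that evidence homo-oligomers.

    ``self_link`` is True for an intralink whose two residues are identical
    or whose supporting peptide intervals overlap by at least one residue
    (closed intervals) — both imply the link bridged two copies of the same
    protein.  Non-intra rows get False.  The rule is symmetric in the two
    link ends.
    """
    out = classified.copy()

    def is_self(r) -> bool:
        if r["category"] != "intra":
            return False
        if int(r["residue_a"]) == int(r["residue_b"]):
            return True
        return (
            max(int(r["pepA_start"]), int(r["pepB_start"]))
            <= min(int(r["pepA_end"]), int(r["pepB_end"]))
        )

    out["self_link"] = [is_self(r) for _, r in out.iterrows()]
    return out


# ---------------------------------------------------------------------------
# disorder overlay
# ---------------------------------------------------------------------------


@dataclass
class DisorderProfile:
    """Per-residue pLDDT with per-protein min-max scaled shades in [0, 1]."""

    protein_id: str
    plddt: np.ndarray
    scaled_shade: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        if ((self.plddt < 0) | (self.plddt > 100)).any():
            raise ValueError("pLDDT values must lie in [0, 100]")
        lo, hi = self.plddt.min(), self.plddt.max()
        if hi == lo:
            self.scaled_shade = np.zeros_like(self.plddt)
        else:
            self.scaled_shade = (self.plddt - lo) / (hi - lo)

    def __len__(self) -> int:
        return len(self.plddt)


def disorder_overlay(
    protein_lengths: dict[str, int],
    plddt: pd.DataFrame,
    links: pd.DataFrame,
    threshold: float = DEFAULT_PLDDT_THRESHOLD,
) -> tuple[dict[str, DisorderProfile], pd.DataFrame, dict[str, dict[str, int]]]:
    """Scale pLDDT per protein and annotate link endpoints.

    ``plddt`` has columns protein, residue (1-based), plddt.  Each link
    endpoint is annotated ``structured`` if its residue's pLDDT >= threshold,
    else ``disordered``.  Returns (profiles, annotated links, per-category
    endpoint counts).
    """
    profiles: dict[str, DisorderProfile] = {}
    for pid, sub in plddt.groupby("protein"):
        sub = sub.sort_values("residue")
        length = protein_lengths.get(str(pid))
        if length is not None and len(sub) != length:
            raise ValueError(
                f"pLDDT profile length {len(sub)} != protein length {length} for {pid}"
            )
        profiles[str(pid)] = DisorderProfile(str(pid), sub["plddt"].to_numpy())

    def state(pid, residue) -> str | None:
        if _is_empty(pid):
            return None
        prof = profiles.get(str(pid))
        if prof is None or not 1 <= int(residue) <= len(prof):
            return None
        return "structured" if prof.plddt[int(residue) - 1] >= threshold else "disordered"

    out = links.copy()
    out["state_a"] = [state(r["protein_a"], r["residue_a"]) for _, r in out.iterrows()]
    out["state_b"] = [
        state(r["protein_b"], r["residue_b"]) if not _is_empty(r["protein_b"]) else None
        for _, r in out.iterrows()
    ]
    summary: dict[str, dict[str, int]] = {}
    for cat, sub in out.groupby("category"):
        states = pd.concat([sub["state_a"], sub["state_b"]]).dropna()
        summary[str(cat)] = {
            "structured": int((states == "structured").sum()),
            "disordered": int((states == "disordered").sum()),
        }
    return profiles, out, summary


# ---------------------------------------------------------------------------
# circular layout
# ---------------------------------------------------------------------------


@dataclass
class Sector:
    protein_id: str
    start_deg: float
    end_deg: float
    length: int

    def residue_angle(self, residue: int) -> float:
        """Angle of a residue, N to C terminus clockwise across the sector."""
        if not 1 <= residue <= self.length:
            raise ValueError(f"residue {residue} outside {self.protein_id} (1..{self.length})")
        if self.length == 1:
            return (self.start_deg + self.end_deg) / 2.0
        span = self.end_deg - self.start_deg
        return self.start_deg + (residue - 1) / (self.length - 1) * span


@dataclass
class CircularLayout:
    sectors: dict[str, Sector]
    chords: pd.DataFrame      # angle_a, angle_b, category, self_link

    def to_dict(self) -> dict:
        return {
            "sectors": {
                pid: {
                    "start_deg": s.start_deg,
                    "end_deg": s.end_deg,
                    "length": s.length,
                }
                for pid, s in self.sectors.items()
            },
            "chords": self.chords.to_dict(orient="records"),
        }


def circular_layout(
    protein_lengths: dict[str, int],
    links: pd.DataFrame,
    sector_order: list[str] | None = None,
    gap_deg: float = 2.0,
) -> CircularLayout:
    """Circular-map geometry: one sector per protein, chords for links.

    Sector width is proportional to protein length; residues map linearly
    onto the sector, N to C terminus clockwise.  Intralinks are drawn outside
    the circle and interlinks inside (the chord table carries the category).
    """
    if not protein_lengths:
        raise ValueError("no proteins")
    if any(length <= 0 for length in protein_lengths.values()):
        raise ValueError("zero-length protein")
    order = sector_order or sorted(protein_lengths)
    total = sum(protein_lengths[p] for p in order)
    available = 360.0 - gap_deg * len(order)
    if len(order) == 1 and gap_deg == 0.0:
        available = 360.0

    sectors: dict[str, Sector] = {}
    angle = 0.0
    for pid in order:
        span = available * protein_lengths[pid] / total
        sectors[pid] = Sector(pid, angle, angle + span, protein_lengths[pid])
        angle += span + gap_deg

    chords = []
    for _, r in links.iterrows():
        if r.get("category") == "mono" or _is_empty(r["protein_b"]):
            continue
        sa = sectors[str(r["protein_a"])]
        sb = sectors[str(r["protein_b"])]
        chords.append(
            {
                "protein_a": sa.protein_id,
                "residue_a": int(r["residue_a"]),
                "angle_a": sa.residue_angle(int(r["residue_a"])),
                "protein_b": sb.protein_id,
                "residue_b": int(r["residue_b"]),
                "angle_b": sb.residue_angle(int(r["residue_b"])),
                "category": r.get("category", "inter"),
                "self_link": bool(r.get("self_link", False)),
            }
        )
    chord_df = pd.DataFrame(
        chords,
        columns=[
            "protein_a", "residue_a", "angle_a",
            "protein_b", "residue_b", "angle_b",
            "category", "self_link",
        ],
    )
    return CircularLayout(sectors=sectors, chords=chord_df)


_CLASS_COLORS = {
    "THO": "#e6b800",
    "cap-binding": "#2e8b57",
    "tail-binding": "#1f6fb4",
    "Sub2-like": "#e377c2",
    "Yra1-like": "#d62728",
    "other": "#7f7f7f",
}


def plot_circular_map(
    layout: CircularLayout,
    profiles: dict[str, DisorderProfile] | None = None,
    protein_classes: dict[str, str] | None = None,
    path: str | None = None,
):
    """Render the circular cross-link map (sectors shaded by scaled pLDDT,
    intralink chords outside, interlink chords inside)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 7), subplot_kw={"projection": "polar"})
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)   # clockwise
    ax.set_axis_off()

    for pid, sector in layout.sectors.items():
        base = _CLASS_COLORS.get((protein_classes or {}).get(pid, "other"), "#7f7f7f")
        theta = np.radians(np.linspace(sector.start_deg, sector.end_deg, max(sector.length, 2)))
        if profiles and pid in profiles:
            shades = profiles[pid].scaled_shade
            if len(shades) != len(theta):
                shades = np.interp(
                    np.linspace(0, 1, len(theta)), np.linspace(0, 1, len(shades)), shades
                )
            for th, sh in zip(theta, shades):
                ax.plot([th, th], [0.95, 1.05], color=base, alpha=0.25 + 0.75 * sh, lw=0.8)
        else:
            ax.plot(theta, np.full_like(theta, 1.0), color=base, lw=6, solid_capstyle="butt")
        mid = np.radians((sector.start_deg + sector.end_deg) / 2)
        ax.text(mid, 1.15, pid, ha="center", va="center", fontsize=7)

    for _, c in layout.chords.iterrows():
        th_a, th_b = np.radians([c["angle_a"], c["angle_b"]])
        outside = c["category"] == "intra"
        r_peak = 1.12 if outside else 0.35
        color = "#d62728" if c["self_link"] else ("#555555" if not outside else "#b07aa1")
        th = np.linspace(th_a, th_b, 30)
        bulge = np.sin(np.linspace(0, np.pi, 30))
        r = 1.05 + (r_peak - 1.05) * bulge if outside else 0.95 - (0.95 - r_peak) * bulge
        ax.plot(th, r, color=color, lw=0.9, alpha=0.8)

    ax.set_ylim(0, 1.3)
    if path:
        fig.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(fig)
    return fig
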