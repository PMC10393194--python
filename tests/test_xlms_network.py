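"""Cross-link classification, homo-oligomer detection, disorder overlay, layout."""

import numpy as np
import pandas as pd
import pytest

from mrnp_atlas import synthetic_data as sd
from mrnp_atlas import xlms_network as xn


def _row(pa, ra, pb=None, rb=None, pep_a=None, pep_b=None):
    pep_a = pep_a or (ra - 5, ra + 5)
    return {
        "protein_a": pa,
        "residue_a": ra,
        "pepA_start": pep_a[0],
        "pepA_end": pep_a[1],
        "protein_b": pb,
        "residue_b": rb,
        "pepB_start": (pep_b or ((rb - 5, rb + 5) if rb else (None, None)))[0],
        "pepB_end": (pep_b or ((rb - 5, rb + 5) if rb else (None, None)))[1],
    }


def naive_classification(rows):
    """Independent enumeration: classify and dedup by canonical endpoint set."""
    counts = {"mono": set(), "intra": set(), "inter": set()}
    for r in rows:
        if r["protein_b"] is None or (isinstance(r["protein_b"], float) and np.isnan(r["protein_b"])):
            counts["mono"].add((r["protein_a"], r["residue_a"], r["pepA_start"], r["pepA_end"]))
        elif r["protein_a"] == r["protein_b"]:
            ends = tuple(sorted([
                (r["protein_a"], r["residue_a"], r["pepA_start"], r["pepA_end"]),
                (r["protein_b"], r["residue_b"], r["pepB_start"], r["pepB_end"]),
            ]))
            counts["intra"].add(ends)
        else:
            ends = tuple(sorted([
                (r["protein_a"], r["residue_a"], r["pepA_start"], r["pepA_end"]),
                (r["protein_b"], r["residue_b"], r["pepB_start"], r["pepB_end"]),
            ]))
            counts["inter"].add(ends)
    return {k: len(v) for k, v in counts.items()}


class TestClassifyLinks:
    def test_basic_categories(self):
        df = pd.DataFrame([
            _row("P1", 10, "P1", 50),
            _row("P1", 10, "P2", 5),
            _row("P1", 10),
        ])
        out, counts = xn.classify_links(df)
        assert counts == {"mono": 1, "intra": 1, "inter": 1}
        assert set(out["category"]) == {"mono", "intra", "inter"}

    def test_symmetric_interlinks_deduplicated(self):
        df = pd.DataFrame([_row("P1", 10, "P2", 5), _row("P2", 5, "P1", 10)])
        out, counts = xn.classify_links(df)
        assert counts["inter"] == 1
        assert out.loc[out["category"] == "inter", "multiplicity"].iloc[0] == 2
        assert out.iloc[0]["protein_a"] == "P1"  # canonical order

    def test_multiplicity_conserves_row_count(self, rng):
        rows = []
        for _ in range(20):
            kind = rng.integers(0, 3)
            if kind == 0:
                rows.append(_row(f"P{rng.integers(1, 4)}", int(rng.integers(1, 90))))
            elif kind == 1:
                p = f"P{rng.integers(1, 4)}"
                rows.append(_row(p, int(rng.integers(1, 90)), p, int(rng.integers(1, 90))))
            else:
                rows.append(_row("P1", int(rng.integers(1, 90)), "P2", int(rng.integers(1, 90))))
        out, counts = xn.classify_links(pd.DataFrame(rows))
        assert out["multiplicity"].sum() == 20
        assert sum(counts.values()) == len(out)

    def test_matches_naive_enumeration(self, rng):
        for trial in range(10):
            rows = []
            for _ in range(int(rng.integers(1, 20))):
                kind = rng.integers(0, 3)
                pa = f"P{rng.integers(1, 4)}"
                ra = int(rng.integers(6, 90))
                if kind == 0:
                    rows.append(_row(pa, ra))
                elif kind == 1:
                    rows.append(_row(pa, ra, pa, int(rng.integers(6, 90))))
                else:
                    pb = pa
                    while pb == pa:
                        pb = f"P{rng.integers(1, 4)}"
                    rows.append(_row(pa, ra, pb, int(rng.integers(6, 90))))
            _, counts = xn.classify_links(pd.DataFrame(rows))
            assert counts == naive_classification(rows)

    def test_residue_without_protein_rejected(self):
        df = pd.DataFrame([_row("P1", 10)])
        df.loc[0, "residue_b"] = 33
        with pytest.raises(ValueError):
            xn.classify_links(df)

    def test_round_trip_with_simulator(self):
        proteins = (
            sd.XLProteinSpec("P1", 100, (10, 30, 50, 70, 90)),
            sd.XLProteinSpec("P2", 80, (5, 40, 75)),
        )
        spec = sd.CrosslinkTopologySpec(
            proteins,
            planted_links=(
                ("P1", 10, "P1", 50),
                ("P1", 30, "P1", 70),
                ("P1", 10, "P1", 90),
                ("P2", 5, "P2", 40),
                ("P2", 5, "P2", 75),
                ("P1", 10, "P2", 5),
                ("P1", 30, "P2", 40),
                ("P1", 50, "P2", 75),
                ("P1", 70, None, None),
                ("P2", 40, None, None),
            ),
        )
        links = sd.simulate_crosslinks(spec, seed=3)
        _, counts = xn.classify_links(links)
        assert (counts["intra"], counts["inter"], counts["mono"]) == (5, 3, 2)


class TestSelfLinks:
    def test_identical_lysines_flagged(self):
        df = pd.DataFrame([_row("P1", 10, "P1", 10, pep_a=(5, 15), pep_b=(5, 15))])
        out = xn.detect_self_links(xn.classify_links(df)[0])
        assert out["self_link"].all()

    def test_overlapping_peptides_flagged(self):
        df = pd.DataFrame([_row("P1", 10, "P1", 12, pep_a=(5, 15), pep_b=(8, 20))])
        out = xn.detect_self_links(xn.classify_links(df)[0])
        assert out["self_link"].all()

    def test_disjoint_intralink_not_flagged(self):
        df = pd.DataFrame([_row("P1", 10, "P1", 50, pep_a=(5, 15), pep_b=(45, 55))])
        out = xn.detect_self_links(xn.classify_links(df)[0])
        assert not out["self_link"].any()

    def test_rule_symmetric_in_link_ends(self):
        a = pd.DataFrame([_row("P1", 10, "P1", 12, pep_a=(5, 15), pep_b=(8, 20))])
        b = pd.DataFrame([_row("P1", 12, "P1", 10, pep_a=(8, 20), pep_b=(5, 15))])
        out_a = xn.detect_self_links(xn.classify_links(a)[0])
        out_b = xn.detect_self_links(xn.classify_links(b)[0])
        assert out_a["self_link"].tolist() == out_b["self_link"].tolist()

    def test_planted_self_links_detected(self):
        proteins = (sd.XLProteinSpec("P1", 100, (10, 14, 50, 90)),)
        spec = sd.CrosslinkTopologySpec(
            proteins,
            planted_links=(("P1", 10, "P1", 50),),
            planted_self_links=(("P1", 10, 10), ("P1", 10, 14)),
            peptide_window=5,
        )
        out = xn.detect_self_links(xn.classify_links(sd.simulate_crosslinks(spec, 1))[0])
        assert int(out["self_link"].sum()) == 2
        unflagged = out[~out["self_link"]]
        assert len(unflagged) == 1 and unflagged.iloc[0]["residue_b"] == 50


class TestDisorderOverlay:
    def _plddt(self, values, pid="P1"):
        return pd.DataFrame(
            {"protein": pid, "residue": np.arange(1, len(values) + 1), "plddt": values}
        )

    def test_constant_profile_scales_to_zero(self):
        profiles, _, _ = xn.disorder_overlay(
            {"P1": 5}, self._plddt([80.0] * 5), pd.DataFrame(columns=xn.LINK_COLUMNS + ["category"])
        )
        assert np.array_equal(profiles["P1"].scaled_shade, np.zeros(5))

    def test_threshold_classification(self):
        links, _ = xn.classify_links(pd.DataFrame([_row("P1", 2, "P1", 8, pep_a=(1, 4), pep_b=(6, 10))]))
        values = [90.0, 90.0, 90.0, 50.0, 50.0, 40.0, 40.0, 40.0, 40.0, 95.0]
        _, annotated, _ = xn.disorder_overlay({"P1": 10}, self._plddt(values), links)
        assert annotated.iloc[0]["state_a"] == "structured"
        assert annotated.iloc[0]["state_b"] == "disordered"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            xn.disorder_overlay({"P1": 7}, self._plddt([80.0] * 5), pd.DataFrame(columns=xn.LINK_COLUMNS))

    def test_interlinks_in_structured_regions_all_structured(self):
        proteins = [("P1", 60, [(10, 30)]), ("P2", 60, [(20, 40)])]
        plddt = sd.simulate_plddt(proteins, seed=5)
        links, _ = xn.classify_links(
            pd.DataFrame([
                _row("P1", 15, "P2", 25),
                _row("P1", 20, "P2", 30),
                _row("P1", 25, "P2", 35),
            ])
        )
        _, annotated, summary = xn.disorder_overlay({"P1": 60, "P2": 60}, plddt, links)
        assert summary["inter"]["structured"] == 6
        assert summary["inter"]["disordered"] == 0


class TestCircularLayout:
    def test_single_protein_full_circle(self):
        layout = xn.circular_layout({"P1": 100}, pd.DataFrame(columns=xn.LINK_COLUMNS), gap_deg=0.0)
        s = layout.sectors["P1"]
        assert s.start_deg == 0.0 and s.end_deg == pytest.approx(360.0)
        assert s.residue_angle(1) == 0.0

    def test_equal_lengths_equal_spans(self):
        layout = xn.circular_layout({"A": 50, "B": 50}, pd.DataFrame(columns=xn.LINK_COLUMNS))
        spans = [s.end_deg - s.start_deg for s in layout.sectors.values()]
        assert spans[0] == pytest.approx(spans[1])

    def test_angle_inverse_round_trip(self):
        lengths = {"A": 120, "B": 340, "C": 77}
        links, _ = xn.classify_links(pd.DataFrame([_row("A", 37, "C", 61)]))
        layout = xn.circular_layout(lengths, links)
        chord = layout.chords.iloc[0]
        for pid, angle, residue in (
            ("A", chord["angle_a"], 37),
            ("C", chord["angle_b"], 61),
        ):
            s = layout.sectors[pid]
            back = 1 + (angle - s.start_deg) / (s.end_deg - s.start_deg) * (s.length - 1)
            assert abs(back - residue) <= 1.0

    def test_scale_invariance(self):
        lengths = {"A": 100, "B": 250}
        doubled = {k: 2 * v for k, v in lengths.items()}
        empty = pd.DataFrame(columns=xn.LINK_COLUMNS)
        l1 = xn.circular_layout(lengths, empty)
        l2 = xn.circular_layout(doubled, empty)
        for pid in lengths:
            assert l1.sectors[pid].start_deg == pytest.approx(l2.sectors[pid].start_deg)
            assert l1.sectors[pid].end_deg == pytest.approx(l2.sectors[pid].end_deg)

    def test_zero_length_protein_rejected(self):
        with pytest.raises(ValueError):
            xn.circular_layout({"A": 0}, pd.DataFrame(columns=xn.LINK_COLUMNS))

    def test_sectors_disjoint_and_ordered(self):
        layout = xn.circular_layout(
            {"A": 10, "B": 20, "C": 30}, pd.DataFrame(columns=xn.LINK_COLUMNS), gap_deg=2.0
        )
        sectors = list(layout.sectors.values())
        for prev, nxt in zip(sectors, sectors[1:]):
            assert nxt.start_deg > prev.end_deg
        assert sectors[-1].end_deg < 360.0

    def test_plot_writes_file(self, tmp_path):
        links, _ = xn.classify_links(pd.DataFrame([_row("A", 10, "B", 20), _row("A", 5, "A", 90)]))
        links = xn.detect_self_links(links)
        layout = xn.circular_layout({"A": 100, "B": 100}, links)
        out = tmp_path / "map.svg"
        xn.plot_circular_map(layout, path=str(out))
        assert out.stat().st_size > 0
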