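# mrnp-atlas

Analysis pipeline for the computational characterization of purified
nuclear messenger ribonucleoprotein (mRNP) particles, driven entirely by a
deterministic synthetic-data generator. It is aimed at computational
biologists who want a fully testable, download-free implementation of the
analyses used to describe such particles:

* **RNA content** — per-transcript coverage profiles; the 100-bin metagene
  matrix (per-transcript coverage scaled 0–1, per-bin average rescaled
  0–100%) that exposes the 5′ bias of nascent transcripts; per-junction
  unspliced fractions (nonsplit/split read ratio at annotated splice
  sites, junctions under 20 reads excluded) compared between samples with
  a Wilcoxon rank-sum test; eluate/lysate enrichment via median-of-ratios
  normalization, rank-correlated (Spearman) against mRNA half-life and
  transcript length.
* **Protein content** — iBAQ quantitation (summed peptide intensity over
  the count of theoretically observable peptides from an in-silico LysC or
  Trypsin/P digest), replicate means per condition, and class
  stoichiometry ratios such as Yra1-like : THO.
* **Protein proximity** — classification of BS³ cross-links into
  monolinks / intralinks / interlinks, detection of homo-oligomer
  evidence (intralinks with identical lysines or overlapping supporting
  peptides), a per-residue pLDDT disorder overlay, and the circular-map
  layout of the link network.
* **RNA annealing** — an in-silico RNase T1 protection assay: a probe with
  a perfectly complementary core is annealed to a substrate, unpaired RNA
  is digested, and surviving fragment lengths emulate the gel readout.

The statistic at the core of the enrichment stage is

```
log2FC(t) = log2( (e_t / sf_e + c) / (l_t / sf_l + c) ),    c = 0.5
sf_s      = median_t( n_st / sqrt(l_t * e_t) )   over transcripts with l_t, e_t > 0
```

and the eluate abundance model planted by the generator is
`log w = log w_base + β_hl·z(log t_1/2) + β_len·z(log L)` with β_hl < 0,
β_len > 0, mitochondrial transcripts depleted ×0.01.

## Worked example

```bash
mrnp-atlas all --seed 1 --outdir run1
```

runs simulate → rnaseq → proteomics → xlms → anneal (~20 s at the bundled
demo scale: 300 transcripts, 8×10⁴ read pairs per sample) and writes
`run1/report.json`:

```json
{
  "metagene_end_bin_contrast": {"lysate": -0.15, "eluate": 61.23},
  "junction_wilcoxon_p": 5.67e-11,
  "enrichment_correlations": {
    "half_life": {"rho": -0.745, "p": 1.9e-54},
    "length":    {"rho":  0.456, "p": 8.7e-17}
  },
  "stoichiometry_ratios": {
    "eluate": 6.18, "benzonase-eluate": 0.92,
    "flowthrough": 11.60, "benzonase-flowthrough": 24.09
  },
  "link_category_counts": {"mono": 20, "intra": 14, "inter": 9},
  "self_link_count": 2,
  "protected_fragment_lengths": {"substrate": [60], "probe": [60]}
}
```

Reading it: the eluate metagene falls 61 percentage points from the first
to the last positional bin (5′ bias from nascent transcripts) while the
lysate is flat; the eluate's unspliced fraction is significantly higher
than the lysate's (intron retention 0.30 vs 0.05 planted); enrichment is
negatively rank-correlated with half-life and positively with length, as
planted; the Yra1-like : THO iBAQ ratio is ~6 in the intact particle and
drops below 1 after benzonase treatment; the cross-link table classifies
into 20 monolinks, 14 intralinks (2 of them homo-oligomer self-links) and
9 interlinks; and the protection assay leaves a single 60-nt duplex band.

Each stage is also available standalone (`mrnp-atlas simulate | rnaseq |
proteomics | xlms | anneal | validate`) and operates on ordinary
GFF3/SAM/FASTA/TSV files; `validate` prints line-anchored schema
diagnostics. Exit codes: 0 success, 2 configuration error, 3 input-format
error, 4 stage failure.

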