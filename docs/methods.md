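# Methods

`mrnp-atlas` models the computational characterization of purified nuclear
messenger ribonucleoprotein (mRNP) particles: what RNA the particles carry,
what proteins coat that RNA and in what stoichiometry, how those proteins
sit relative to each other, and whether their disordered, positively
charged regions can promote RNA–RNA annealing. Because the corresponding
experimental datasets are large and instrument-bound, every analysis here
is driven by a synthetic-data generator that reproduces the *statistical
structure* of such experiments, so the full pipeline is testable on a
laptop in seconds to minutes.

## Synthetic transcriptome and read model

`GeneratorConfig` fixes the study conditions. Defaults: 500 transcripts,
lengths log-uniform on 400–4000 nt, 10% of transcripts carrying exactly one
intron (intron length uniform on 80–400 nt, a splice junction placed at
20–80% of the mature length), 5% mitochondrial, mRNA half-lives log-uniform
on 3–100 min, and a library depth of 10^6 read pairs per sample
(configurable; tests and the bundled demo run use smaller depths, stated
below). Transcripts are tiled head-to-tail with 100-nt spacers on two
synthetic chromosomes (`chrN`, `chrM`), which gives every transcript both a
genomic footprint (for splice-junction analysis) and a per-transcript
reference (for coverage and counting).

Per-transcript expected abundance is log-normal (baseline log-abundance
N(0, 0.8), a property of the transcript shared by both samples). The
**eluate** — the affinity-purified particle fraction — additionally applies

```
log w_eluate = log w_base + beta_hl * z(log half-life) + beta_len * z(log length)
               + log(mito_depletion) * 1[mitochondrial]
```

with defaults `beta_hl = -0.8` (short-lived transcripts enriched,
consistent with a nuclear rather than cytoplasmic pool),
`beta_len = +0.5` (longer transcripts carry more bait complexes), and
`mito_depletion = 0.01`. Observed counts are Poisson around the scaled
expectations; the **lysate** uses the baseline alone.

Fragments are insert-size N(200, 20) nt, clipped to the molecule, with
75-nt mates read off either end (paired-end geometry; no sequencing-error
model, constant placeholder qualities). Two features carry the biology:

* **5′ bias.** A per-sample fraction of source molecules (default: eluate
  0.5, lysate 0) is 3′-truncated at a uniform random point before
  fragmentation — a generative proxy for nascent, unfinished transcripts.
  Uniform fragmentation of truncated molecules shifts coverage mass toward
  the 5′ end.
* **Intron retention.** In genome-coordinate mode, each junction-spanning
  mate is emitted unspliced with a per-sample retention probability
  (default: eluate 0.30, lysate 0.05), otherwise split with an `N` gap that
  matches the annotated intron exactly. An unspliced read is anchored at
  the 5′ or 3′ splice site with equal probability and runs contiguously
  into the intron, as a read from an intron-retaining pre-mRNA would; this
  choice (the read model is otherwise silent on it) gives both site types
  nonsplit coverage.

All generators are pure functions of (config, seed): identical inputs give
byte-identical GFF3/SAM/FASTA/TSV outputs.

## RNA-content metrics

**Coverage and metagene.** Depth counts aligned (`M`) segments only;
`N` gaps contribute nothing and `I`/`D` are coverage-neutral length
adjustments. For the metagene, each (nuclear, intronless) transcript's
profile is averaged within 100 equal-width bins over its own length,
min–max scaled to [0, 1], and the per-bin mean over transcripts is min–max
rescaled to [0%, 100%]. A constant binned profile (including all-zero)
scales to all zeros: the 0/0 case is undefined and a flat profile carries
no positional signal. Profiles shorter than the bin count are resampled at
bin centers.

**Splice junctions.** Each annotated intron contributes two junction
records (5′ and 3′ splice sites). A read is *split* at a site iff it
carries an `N` gap equal to the annotated intron; *nonsplit* iff an aligned
block crosses the junction point with ≥ 3 nt (`min_anchor`) on each side;
reads gapped inconsistently with the annotation are discarded from both
counts, so every junction-overlapping read lands in exactly one of
split/nonsplit/discarded. Junctions with split + nonsplit < 20 reads
(`min_cov`) are excluded. The unspliced fraction is nonsplit/split, defined
only where split > 0; sample distributions are compared with a two-sided
Wilcoxon rank-sum test (exact when both n ≤ 20 and tie-free, otherwise the
tie-corrected normal approximation). An all-identical comparison is
reported as degenerate rather than assigned a p-value.

**Enrichment.** Size factors are median-of-ratios against the
geometric-mean pseudo-reference over transcripts nonzero in both samples;
log2FC = log2((eluate/sf_e + 0.5)/(lysate/sf_l + 0.5)), finite everywhere.
A read pair counts once per transcript if either mate aligns to it (in
transcript-coordinate mode both mates share the reference, so first mates
are counted). Downstream use is Spearman rank correlation against mRNA
half-life and transcript length (average ranks on ties), which depends on
ordering only — hence no dispersion shrinkage is needed or attempted.

## iBAQ quantitation

In-silico digestion: LysC cleaves C-terminal to K; Trypsin/P cleaves
C-terminal to K or R including before proline; peptides are enumerated for
0..m missed cleavages with 1-based inclusive coordinates. The iBAQ
denominator counts fully cleaved peptides of 7–30 residues (inclusive;
common practice for the detectable window, exposed as configuration) and
is floored at 1 so short or cleavage-poor proteins keep a defined value.
iBAQ = summed peptide intensity / observable-peptide count, per
(protein, condition, replicate); a protein absent from a replicate scores
0 for that replicate (absent, not unmeasured — appropriate for
affinity-capture samples), and condition means average over replicates.
Class stoichiometry is the ratio of class-mean condition-mean iBAQs
(e.g. Yra1-like over THO). Molecular weights use IUPAC average residue
masses plus one water; `X` residues are tolerated and excluded.

The peptide simulator emits exactly the observable peptides of each
protein, each with a fixed log-normal detectability (sigma 0.5) shared
across conditions and replicates, and per-replicate log-normal noise
(sigma 0.1 by default) around copy-number weight × detectability. iBAQ
then recovers planted ratios up to the detectability-mean fluctuation,
which is why the 10:1 recovery test accepts [5, 20].

## Cross-link networks

Rows are BS3 products: two residue anchors with supporting peptide
intervals. Classification: *mono* (one side empty), *intra* (same
protein), *inter* (different proteins); interlinks are canonicalized to
lexicographic protein order and intralinks to ascending residue order, so
A–B/B–A duplicates collapse; identical links collapse with a multiplicity
count. An intralink is flagged as homo-oligomer evidence (*self-link*) iff
its residues are identical or its peptide intervals share ≥ 1 residue
(closed intervals) — either way the link must have bridged two copies of
the same protein. The rule is symmetric in the link ends.

Per-residue pLDDT (AlphaFold confidence, consumed as an input table, never
computed here) is min–max scaled per protein for shading (constant
profiles scale to 0); link endpoints are *structured* at pLDDT ≥ 70, the
conventional confidence cut, exposed as configuration. The circular map
assigns each protein a sector proportional to its length (2° gaps),
residues mapping linearly N→C clockwise; intralink chords arc outside the
circle, interlinks inside.

## Annealing / RNase T1 protection assay

The assay is modeled at the level of its readout. `make_annealing_pair`
builds a random RNA substrate and a probe = flank + reverse-complement
(substrate core window) + flank; every flank base facing a substrate base
at the annealed register is forced to mismatch it, so the perfectly
complementary stretch is exactly the core length (a construction check
rejects the vanishingly rare draw with a spurious second match).
`anneal` finds all maximal exact antiparallel Watson–Crick duplexes of
≥ `min_duplex` nt (default 15, suppressing chance matches; G·U wobble not
counted — the assay is designed around perfect complementarity), selected
greedily by descending length with leftmost-substrate tie-break into a
non-overlapping set. Idealized digestion removes every unpaired
nucleotide, returning exactly the duplexed intervals (total protected
length = total duplexed length); `g_specific` mode instead cleaves only 3′
of unpaired G residues, so fragments may carry non-G overhangs, and keeps
only fragments containing paired nucleotides. Protein annealing activity
is a boolean switch — the experimental readout is presence/absence of the
protected band, not kinetics. With the printed design (315-nt substrate,
60-nt core, 10-nt flanks) the idealized assay yields a single 60-nt
protected fragment per molecule for any seed.

## Pipeline

`run_all` executes simulate → rnaseq → proteomics → xlms → anneal from one
YAML config (unknown keys rejected; the top-level seed propagates to every
stage; a resolved-config copy and `report.json` are written next to the
outputs; a failing stage aborts with its name and a nonzero exit). The
bundled default runs a demo-scale cohort (300 transcripts, 8×10^4 read
pairs per sample, a 12-protein synthetic mRNP with an overstoichiometric
Yra1-like species reduced under benzonase, 12+2 intralinks / 9 interlinks
/ 20 monolinks) in ~20 s. The report aggregates: per-sample metagene
end-bin contrast (bin 1 − bin 100 of the column summary), the junction
Wilcoxon p-value, both enrichment correlations, per-condition
stoichiometry ratios, link category counts, the self-link count, and
protected-fragment lengths.

## What the generator does and does not emulate

It reproduces: 5′-biased eluate coverage, per-sample intron retention,
mitochondrial depletion, half-life/length-structured enrichment,
log-normal peptide intensities with protein-level stoichiometry, and
planted link topologies. It does **not** emulate sequencing errors,
mapping ambiguity, rRNA contamination, isoform complexity, peptide
modification chemistry, cross-link false discovery, or real genome
sequence composition. Passing tests therefore demonstrate that the
*analysis* recovers planted structure under the stated noise models — not
that it is robust to every artifact of real libraries.

## Test and problem sizes

Property suites use: 200 transcripts × 4×10^4 read pairs for the 5′-bias
monotonicity check; 200 junctions at ~50× depth × 100 seeded runs for the
Wilcoxon power check (retention 0.05 vs 0.30, p < 0.01 required in ≥ 90
runs); 500 transcripts × 2×10^5 pairs × 40 runs for enrichment sign
recovery (≥ 95% must recover both signs) with 5 covariate permutations per
run as the null calibration; 1000 random ≤ 60-residue sequences for the
digestion oracle; ≤ 20-row tables against exhaustive enumeration for link
classification. These sizes are the package's chosen desk-scale study
conditions and are stated in the tests themselves.

## Known limitations

* Read counting assumes unique transcript assignment; multi-mapping is out
  of scope.
* The enrichment estimator is rank-faithful but unshrunken; per-transcript
  log2FC values at low counts are noisy by design.
* The annealing model has no thermodynamics: partial or mismatched
  duplexes either count (exact ≥ min_duplex match) or do not.
* Junction statistics assume the annotation is correct; novel junctions
  are discarded rather than discovered.
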