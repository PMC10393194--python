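"""End-to-end orchestration: simulate -> rnaseq -> proteomics -> xlms -> anneal.

A single :class:`RunConfig` (YAML on disk) drives a reproducible run: the
top-level seed is propagated to every stage, a resolved copy of the
configuration is written next to the outputs, and the consolidated report
aggregates one headline quantity per analysis: the metagene end-bin
contrast, the junction Wilcoxon p-value, the enrichment correlations, the
stoichiometry ratios, the cross-link category counts, the self-link count
and the protected-fragment lengths.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import annealing_sim, proteomics_quant, rnaseq_metrics, synthetic_data, xlms_network

__all__ = ["RunConfig", "StageError", "ConfigError", "run_all", "REPORT_KEYS"]

logger = logging.getLogger("mrnp_atlas")

REPORT_KEYS = [
    "metagene_end_bin_contrast",
    "junction_wilcoxon_p",
    "enrichment_correlations",
    "stoichiometry_ratios",
    "link_category_counts",
    "self_link_count",
    "protected_fragment_lengths",
]


class ConfigError(ValueError):
    """Invalid run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Resolved pipeline configuration.

    ``simulate`` mirrors :class:`~mrnp_atlas.synthetic_data.GeneratorConfig`
    fields; the other blocks carry per-stage parameters.  The bundled demo
    scale (300 transcripts, 8e4 read pairs per sample) keeps an end-to-end
    run in the tens of seconds; both are free parameters of the generator.
    """

    seed: int = 0
    outdir: str = "mrnp_atlas_run"
    log_level: str = "info"
    stages: dict = field(
        default_factory=lambda: {
            "simulate": True,
            "rnaseq": True,
            "proteomics": True,
            "xlms": True,
            "anneal": True,
        }
    )
    simulate: dict = field(
        default_factory=lambda: {"n_transcripts": 300, "n_read_pairs": 80_000}
    )
    rnaseq: dict = field(
        default_factory=lambda: {"min_cov": 20, "bins": 100, "pseudocount": 0.5, "min_anchor": 3}
    )
    proteomics: dict = field(
        default_factory=lambda: {
            "protease": "lysc",
            "length_range": [7, 30],
            "numerator_class": "Yra1-like",
            "denominator_class": "THO",
        }
    )
    xlms: dict = field(default_factory=lambda: {"plddt_threshold": 70.0, "gap_deg": 2.0})
    anneal: dict = field(
        default_factory=lambda: {
            "substrate_len": 315,
            "core_len": 60,
            "flank_len": 10,
            "min_duplex": 15,
            "mode": "idealized",
        }
    )

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls()
        for key, value in data.items():
            default = getattr(cfg, key)
            if isinstance(default, dict) and isinstance(value, dict):
                sub_unknown = set(value) - set(default)
                # simulate block may use any GeneratorConfig field
                if key == "simulate":
                    gen_fields = {f.name for f in dataclasses.fields(synthetic_data.GeneratorConfig)}
                    sub_unknown = set(value) - set(default) - gen_fields
                if sub_unknown:
                    raise ConfigError(f"unknown keys in {key!r} block: {sorted(sub_unknown)}")
                merged = dict(default)
                merged.update(value)
                setattr(cfg, key, merged)
            else:
                setattr(cfg, key, value)
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("configuration root must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _setup_logging(cfg: RunConfig, outdir: Path) -> None:
    level = getattr(logging, cfg.log_level.upper(), None)
    if level is None:
        raise ConfigError(f"unknown log level {cfg.log_level!r}")
    logger.setLevel(level)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(outdir / "run.log")):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


def _tsv_with_provenance(df: pd.DataFrame, path: Path, params: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mrnp-atlas {__version__}; {params}\n")
        df.to_csv(fh, sep="\t", index=index)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    """Generate every pipeline input and write it under ``outdir/simulate``."""
    d = outdir / "simulate"
    d.mkdir(parents=True, exist_ok=True)
    gen_kwargs = {
        k: v for k, v in cfg.simulate.items()
        if k in {f.name for f in dataclasses.fields(synthetic_data.GeneratorConfig)}
    }
    for key in ("length_range", "halflife_range", "enrichment_coefficients"):
        if key in gen_kwargs and isinstance(gen_kwargs[key], list):
            gen_kwargs[key] = tuple(gen_kwargs[key])
    gcfg = synthetic_data.GeneratorConfig(seed=cfg.seed, **gen_kwargs)
    tr = synthetic_data.generate_transcriptome(gcfg)
    tr.to_gff3(str(d / "annotation.gff3"))
    tr.write_transcript_fasta(str(d / "transcripts.fasta"))
    tr.write_genome_fasta(str(d / "genome.fasta"))

    sams = {}
    for sample in ("lysate", "eluate"):
        for mode in ("transcript", "genome"):
            path = d / f"{sample}_{mode}.sam"
            synthetic_data.simulate_reads(tr, gcfg, sample, cfg.seed, str(path), mode=mode)
            sams[(sample, mode)] = path
            logger.info("simulated %s reads (%s mode) -> %s", sample, mode, path.name)

    proteins = synthetic_data.default_mrnp_proteins(seed=cfg.seed)
    spec = synthetic_data.StoichiometrySpec(proteins=proteins)
    peptides = synthetic_data.simulate_peptides(spec, cfg.seed)
    _tsv_with_provenance(peptides, d / "peptides.tsv", f"seed={cfg.seed}")
    synthetic_data._write_fasta(
        str(d / "proteins.fasta"),
        ((f"{p.protein_id} class={p.protein_class}", p.sequence) for p in proteins),
    )

    topology = synthetic_data.default_crosslink_topology(proteins, seed=cfg.seed)
    links = synthetic_data.simulate_crosslinks(topology, cfg.seed)
    _tsv_with_provenance(links, d / "crosslinks.tsv", f"seed={cfg.seed}")
    plddt = synthetic_data.simulate_plddt(
        synthetic_data.default_plddt_regions(proteins), cfg.seed
    )
    _tsv_with_provenance(plddt, d / "plddt.tsv", f"seed={cfg.seed}")

    substrate, probe, core = synthetic_data.make_annealing_pair(
        cfg.anneal["substrate_len"], cfg.anneal["core_len"], cfg.anneal["flank_len"], cfg.seed
    )
    synthetic_data._write_fasta(
        str(d / "annealing.fasta"),
        [(f"substrate core={core[0]}-{core[1]}", substrate), ("probe", probe)],
    )
    return {
        "transcriptome": tr,
        "gcfg": gcfg,
        "sams": sams,
        "proteins": proteins,
        "peptides": peptides,
        "links": links,
        "plddt": plddt,
        "annealing": (substrate, probe, core),
        "dir": d,
    }


def stage_rnaseq(cfg: RunConfig, sim: dict, outdir: Path) -> dict:
    d = outdir / "rnaseq"
    d.mkdir(parents=True, exist_ok=True)
    tr: synthetic_data.Transcriptome = sim["transcriptome"]
    params = cfg.rnaseq
    tab = tr.table()
    if "half_lives" in sim:   # external covariate table overrides annotation attributes
        tab["half_life_min"] = sim["half_lives"].reindex(tab.index)
    nuclear_intronless = set(tab.index[(tab["genome"] == "nuclear") & ~tab["has_intron"]])

    contrast = {}
    matrices = {}
    for sample in ("lysate", "eluate"):
        profiles = list(rnaseq_metrics.coverage_profiles(str(sim["sams"][(sample, "transcript")])).values())
        mg = rnaseq_metrics.metagene_matrix(profiles, params["bins"], subset=nuclear_intronless)
        matrices[sample] = mg
        contrast[sample] = float(mg.column_summary[0] - mg.column_summary[-1])
        _tsv_with_provenance(
            mg.to_frame(), d / f"metagene_{sample}.csv", f"bins={params['bins']}", index=True
        )
        pd.DataFrame({"bin": np.arange(1, mg.n_bins + 1), "scaled_mean": mg.column_summary}).to_csv(
            d / f"metagene_summary_{sample}.csv", index=False
        )

    have_genome_sams = all((s, "genome") in sim["sams"] for s in ("lysate", "eluate"))
    if have_genome_sams:
        junction = {}
        for sample in ("lysate", "eluate"):
            stats_df = rnaseq_metrics.junction_stats(
                str(sim["sams"][(sample, "genome")]),
                tr,
                min_cov=params["min_cov"],
                min_anchor=params["min_anchor"],
                sample=sample,
            )
            junction[sample] = stats_df
            _tsv_with_provenance(stats_df, d / f"junctions_{sample}.tsv", f"min_cov={params['min_cov']}")
        stat, pval, degenerate = rnaseq_metrics.compare_unspliced(
            junction["lysate"], junction["eluate"]
        )
    else:   # junction path needs genome-coordinate alignments
        stat, pval, degenerate = None, None, None

    counts = {
        sample: rnaseq_metrics.count_reads(str(sim["sams"][(sample, "transcript")]))
        for sample in ("lysate", "eluate")
    }
    enrichment = rnaseq_metrics.enrichment_table(
        counts["lysate"], counts["eluate"], pseudocount=params["pseudocount"]
    )
    _tsv_with_provenance(enrichment, d / "enrichment.tsv", f"pseudocount={params['pseudocount']}", index=True)

    correlations = {}
    for covariate in ("half_life_min", "length"):
        rho, p = rnaseq_metrics.correlate_enrichment(enrichment, tab[covariate])
        correlations["half_life" if covariate == "half_life_min" else "length"] = {
            "rho": rho, "p": p
        }
    with open(d / "correlations.json", "w") as fh:
        json.dump(correlations, fh, indent=2)

    return {
        "metagene_end_bin_contrast": contrast,
        "junction_wilcoxon": {"statistic": stat, "p": pval, "degenerate": degenerate},
        "enrichment_correlations": correlations,
    }


def stage_proteomics(cfg: RunConfig, sim: dict, outdir: Path) -> dict:
    d = outdir / "proteomics"
    d.mkdir(parents=True, exist_ok=True)
    params = cfg.proteomics
    entries = [
        proteomics_quant.ProteinEntry(p.protein_id, p.sequence, p.protein_class)
        for p in sim["proteins"]
    ]
    table = proteomics_quant.ibaq_table(
        sim["peptides"],
        entries,
        protease=params["protease"],
        length_range=tuple(params["length_range"]),
    )
    ratios = proteomics_quant.stoichiometry_report(
        table, params["numerator_class"], params["denominator_class"]
    )
    proteomics_quant.write_outputs(table, ratios, str(d))
    return {"stoichiometry_ratios": ratios}


def stage_xlms(cfg: RunConfig, sim: dict, outdir: Path) -> dict:
    d = outdir / "xlms"
    d.mkdir(parents=True, exist_ok=True)
    params = cfg.xlms
    classified, counts = xlms_network.classify_links(sim["links"])
    classified = xlms_network.detect_self_links(classified)
    lengths = {p.protein_id: len(p.sequence) for p in sim["proteins"]}
    profiles, annotated, endpoint_summary = xlms_network.disorder_overlay(
        lengths, sim["plddt"], classified, threshold=params["plddt_threshold"]
    )
    layout = xlms_network.circular_layout(
        lengths, classified, sector_order=[p.protein_id for p in sim["proteins"]],
        gap_deg=params["gap_deg"],
    )
    _tsv_with_provenance(annotated, d / "links_classified.tsv", f"threshold={params['plddt_threshold']}")
    with open(d / "category_counts.json", "w") as fh:
        json.dump({"counts": counts, "endpoints": endpoint_summary}, fh, indent=2)
    with open(d / "layout.json", "w") as fh:
        json.dump(layout.to_dict(), fh, indent=2)
    xlms_network.plot_circular_map(
        layout, profiles,
        {p.protein_id: p.protein_class for p in sim["proteins"]},
        path=str(d / "circular_map.svg"),
    )
    return {
        "link_category_counts": counts,
        "self_link_count": int(classified["self_link"].sum()),
    }


def stage_anneal(cfg: RunConfig, sim: dict, outdir: Path) -> dict:
    d = outdir / "anneal"
    d.mkdir(parents=True, exist_ok=True)
    substrate_seq, probe_seq, core = sim["annealing"]
    substrate = annealing_sim.RNAMolecule("substrate", substrate_seq)
    probe = annealing_sim.RNAMolecule("probe", probe_seq)
    params = cfg.anneal
    lanes = {
        "substrate_alone": annealing_sim.assay(substrate, None, True, params["min_duplex"], params["mode"]),
        "probe_alone": annealing_sim.assay(None, probe, True, params["min_duplex"], params["mode"]),
        "no_annealing_protein": annealing_sim.assay(substrate, probe, False, params["min_duplex"], params["mode"]),
        "annealing_active": annealing_sim.assay(substrate, probe, True, params["min_duplex"], params["mode"]),
    }
    with open(d / "lanes.json", "w") as fh:
        json.dump(lanes, fh, indent=2)
    return {"protected_fragment_lengths": lanes["annealing_active"]}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_all(cfg: RunConfig) -> dict:
    """Run the enabled stages in dependency order and write the report bundle.

    Stages after ``simulate`` require it; disabling it disables them.  The
    resolved configuration is written next to the outputs, and the JSON
    report aggregates the stage summaries.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(cfg, outdir)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)

    report: dict = {}
    unknown_stages = set(cfg.stages) - {"simulate", "rnaseq", "proteomics", "xlms", "anneal"}
    if unknown_stages:
        raise ConfigError(f"unknown stages: {sorted(unknown_stages)}")
    if not cfg.stages.get("simulate", False):
        enabled = [s for s, on in cfg.stages.items() if on]
        if enabled:
            raise ConfigError("downstream stages require the simulate stage")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report

    try:
        logger.info("stage simulate (seed=%d)", cfg.seed)
        sim = stage_simulate(cfg, outdir)
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    stage_fns = {
        "rnaseq": stage_rnaseq,
        "proteomics": stage_proteomics,
        "xlms": stage_xlms,
        "anneal": stage_anneal,
    }
    for name, fn in stage_fns.items():
        if not cfg.stages.get(name, False):
            continue
        logger.info("stage %s", name)
        try:
            result = fn(cfg, sim, outdir)
        except Exception as exc:
            raise StageError(name, exc) from exc
        if name == "rnaseq":
            report["metagene_end_bin_contrast"] = result["metagene_end_bin_contrast"]
            report["junction_wilcoxon_p"] = result["junction_wilcoxon"]["p"]
            report["enrichment_correlations"] = result["enrichment_correlations"]
        else:
            report.update(result)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("report written to %s", outdir / "report.json")
    return report
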