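"""End-to-end pipeline runs: simulate -> quantify -> taxa -> compare -> screen.

`run_pipeline` executes a requested subset of stages against a manifest
of input files, writing versioned TSV outputs and a structured log (the
full configuration is echoed, and each stage reports its record
counts).  The manifest is validated before any stage runs, so a missing
input fails fast without partial outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import abundance, screen as screen_mod, stats, synthetic, taxa
from .config import PipelineConfig, validate_config

ALL_STAGES = ["simulate", "quantify", "taxa", "compare", "screen"]

# manifest keys each non-simulate stage requires (paths that must exist)
_STAGE_INPUTS = {
    "quantify": ["hits_dir", "families_tsv", "samples_tsv"],
    "taxa": ["taxa_table", "samples_tsv"],
    "compare": ["rpksm_tsv", "samples_tsv"],
    "screen": ["scan_table", "genomes_tsv", "plasmids_tsv"],
}


def _setup_log(outdir: Path) -> logging.Logger:
    logger = logging.getLogger("genecentric.pipeline")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(),
                    logging.FileHandler(outdir / "run.log", mode="w")):
        handler.setFormatter(fmt)
        logger.addHandler(handler)
    return logger


def validate_manifest(manifest: dict, stages: list[str]) -> None:
    """Fail fast if any stage input is missing before anything runs."""
    problems = []
    for stage in stages:
        for key in _STAGE_INPUTS.get(stage, []):
            if stage != "simulate" and "simulate" in stages:
                continue  # simulate produces downstream inputs itself
            if key not in manifest:
                problems.append(f"stage {stage}: manifest key {key!r} missing")
            elif not Path(manifest[key]).exists():
                problems.append(
                    f"stage {stage}: input {manifest[key]!r} does not exist")
    if problems:
        raise FileNotFoundError("; ".join(problems))


def run_pipeline(
    config: PipelineConfig,
    manifest: dict | None = None,
    outdir: str | Path = "runs",
    stages: list[str] | None = None,
    truth_config: synthetic.TruthConfig | None = None,
    screen_truth: synthetic.ScreenTruthConfig | None = None,
) -> Path:
    """Execute the requested stages in order; returns the run directory.

    ``truth_config`` and ``screen_truth`` override the simulate stage's
    default ground truth (the published three-cohort design with 20
    target families and 5 USCGs, and a two-clade screen).
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    stages = [s for s in ALL_STAGES if s in (stages or ALL_STAGES)]
    manifest = dict(manifest or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    validate_manifest(manifest, stages)

    log = _setup_log(outdir)
    log.info("configuration: %s", config.as_dict())
    log.info("stages: %s", stages)
    config.to_yaml(outdir / "config.yaml")

    if "simulate" in stages:
        tc = truth_config or synthetic.TruthConfig(seed=config.seed, n_uscg=5)
        samples = synthetic.simulate_cohort_design(tc)
        fasta, truths = synthetic.simulate_gene_families(tc)
        (outdir / "pangenome.faa").write_text(fasta)
        fam_meta = synthetic.family_metadata_frame(truths)
        fam_meta.to_csv(outdir / "families.tsv", sep="\t", index=False)
        synthetic.samples_to_frame(samples).to_csv(
            outdir / "samples.tsv", sep="\t", index=False)
        synthetic.simulate_alignment_hits(tc, samples, truths,
                                          outdir=outdir / "hits")
        taxa_table, _ = synthetic.simulate_taxa_table(samples, seed=config.seed)
        taxa_table.to_csv(outdir / "taxa_table.tsv", sep="\t")
        sc = screen_truth or synthetic.ScreenTruthConfig(
            clades=[synthetic.CladeSpec("Agathobacter", 150),
                    synthetic.CladeSpec("Blautia", 150)],
            prevalence={("Agathobacter", "buk"): 0.9,
                        ("Blautia", "buk"): 0.1,
                        ("Agathobacter", "yahK"): 0.5},
            plasmid_counts={"yahK": 8, "buk": 2},
            seed=config.seed)
        inputs = synthetic.simulate_screen_inputs(sc)
        inputs.genomes.to_csv(outdir / "genomes.tsv", sep="\t", index=False)
        inputs.plasmids.to_csv(outdir / "plasmids.tsv", sep="\t", index=False)
        (outdir / "scan.domtbl").write_text(inputs.scan_text)
        manifest.setdefault("hits_dir", outdir / "hits")
        manifest.setdefault("families_tsv", outdir / "families.tsv")
        manifest.setdefault("samples_tsv", outdir / "samples.tsv")
        manifest.setdefault("taxa_table", outdir / "taxa_table.tsv")
        manifest.setdefault("scan_table", outdir / "scan.domtbl")
        manifest.setdefault("genomes_tsv", outdir / "genomes.tsv")
        manifest.setdefault("plasmids_tsv", outdir / "plasmids.tsv")
        log.info("simulate: %d samples, %d families", len(samples), len(truths))

    if "quantify" in stages:
        samples = pd.read_csv(manifest["samples_tsv"], sep="\t")
        families = pd.read_csv(manifest["families_tsv"], sep="\t")
        hits_dir = Path(manifest["hits_dir"])
        hit_tables = {sid: hits_dir / f"{sid}.m8" for sid in samples["sample_id"]}
        missing = [s for s, p in hit_tables.items() if not p.exists()]
        if missing:
            raise FileNotFoundError(f"hit files missing for samples: {missing}")
        table = abundance.build_abundance_table(
            hit_tables, families, samples,
            e_max=config.e_max_reads, basis=config.rpksm_basis)
        table.write(outdir)
        manifest.setdefault("rpksm_tsv", outdir / "abundance_rpksm.tsv")
        log.info("quantify: %d families x %d samples "
                 "(e_max_reads=%g, basis=%s)", len(table.rpksm),
                 table.rpksm.shape[1], config.e_max_reads, config.rpksm_basis)

    if "taxa" in stages:
        samples = pd.read_csv(manifest["samples_tsv"], sep="\t")
        table = taxa.read_taxa_table(manifest["taxa_table"])
        cleaned = taxa.clean_clades(table, samples)
        per_cohort = {
            cohort: taxa.abundance_threshold_filter(
                sub, genus_min=config.genus_abundance_min,
                species_min=config.species_abundance_min)
            for cohort, sub in taxa.split_by_cohort(cleaned, samples).items()
        }
        for cohort, sub in per_cohort.items():
            sub.to_csv(outdir / f"taxa_{cohort}.tsv", sep="\t")
        if len(per_cohort) >= 2:
            shared, totals = taxa.shared_clades(per_cohort)
            report = totals.to_frame()
            report.insert(0, "n_shared", len(shared))
            report.to_csv(outdir / "taxa_shared.tsv", sep="\t")
            log.info("taxa: %d clades cleaned to %d; %d shared",
                     len(table), len(cleaned), len(shared))
        else:
            log.info("taxa: %d clades cleaned to %d (single cohort)",
                     len(table), len(cleaned))

    if "compare" in stages:
        samples = pd.read_csv(manifest["samples_tsv"], sep="\t")
        rpksm = pd.read_csv(manifest["rpksm_tsv"], sep="\t", index_col=0)
        results = stats.compare_groups(rpksm, samples)
        results.to_csv(outdir / "comparisons.tsv", sep="\t", index=False)
        calls = stats.cross_cohort_consistency(
            results, min_significant=config.min_significant_cohorts,
            alpha=config.alpha, exempt_cohorts=config.cohort_exemptions)
        calls.to_csv(outdir / "consistency.tsv", sep="\t", index=False)
        fam_path = manifest.get("families_tsv")
        if fam_path and Path(fam_path).exists():
            families = pd.read_csv(fam_path, sep="\t")
            uscg = list(families.loc[families["pathway_tag"] == "USCG",
                                     "family_id"].unique())
            if uscg:
                uscg_results, passed = stats.uscg_control(
                    rpksm, samples, uscg, alpha=config.alpha)
                uscg_results.to_csv(outdir / "uscg_control.tsv", sep="\t",
                                    index=False)
                log.info("compare: USCG control %s",
                         "PASS" if passed else "FAIL")
        log.info("compare: %d results, %d consistency calls (alpha=%g)",
                 len(results), len(calls), config.alpha)

    if "screen" in stages:
        genomes = pd.read_csv(manifest["genomes_tsv"], sep="\t")
        plasmids = pd.read_csv(manifest["plasmids_tsv"], sep="\t")
        result = screen_mod.run_screen(
            Path(manifest["scan_table"]), genomes, plasmids,
            cov_min=config.cov_min, e_max=config.e_max_scan,
            ie_max=config.ie_max_scan,
            completeness_min=config.completeness_min,
            min_genomes=config.clade_min_genomes)
        result.write(outdir)
        log.info("screen: %d genus and %d species prevalence records "
                 "(cov_min=%g, clade_min_genomes=%d)",
                 len(result.genus_prevalence), len(result.species_prevalence),
                 config.cov_min, config.clade_min_genomes)
    return outdir
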