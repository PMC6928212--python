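"""Pipeline orchestration: simulate → scan → bsa → retain from one config.

Every output file is stamped with the config digest; a ``provenance.json``
records the package version, the config, its digest and the seeds of all
stochastic stages.  Identical config and seed give byte-identical data
outputs (the provenance timestamp is the only run-dependent field).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import io as pio
from .bulkseg import BulkSegregantAnalyzer, cross_population_summary
from .config import RunConfig
from .genmap import uniform_map
from .popsim import (
    five_locus_protein_model,
    simulate_phenotypes,
    simulate_ril_population,
)
from .qtlscan import QTLScanner
from .retention import RetentionScanner, blocks_to_bed, blocks_to_frame
from .simstudy import simulate_pedigree_panel

__all__ = ["run_pipeline"]

log = logging.getLogger("protqtl")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the selected stages and write all outputs under ``outdir``.

    Returns a report bundle: a dict of output paths and headline numbers.
    """
    t0 = time.time()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if not logging.getLogger().handlers:
        logging.basicConfig(level=logging.INFO)
    digest = config.digest()
    header = f"protqtl v0.1.0 config_digest={digest}"
    seeds: dict[str, int] = {}
    report: dict = {"outdir": str(out), "config_digest": digest}
    rng = np.random.default_rng(config.seed)

    gmap = uniform_map(config.n_chrom, config.n_markers_per_chrom, config.chrom_length_cm)
    model = five_locus_protein_model(gmap, total_fraction=config.total_variance_fraction)

    ril = phenotypes = None
    if "simulate" in config.stages or "scan" in config.stages or "bsa" in config.stages:
        seeds["ril"] = int(rng.integers(2**31))
        seeds["phenotypes"] = int(rng.integers(2**31))
        ril = simulate_ril_population(
            gmap, config.ril_n_lines, config.derived_generation, seed=seeds["ril"]
        )
        phenotypes = simulate_phenotypes(ril, model, config.n_trials, seed=seeds["phenotypes"])
        if "simulate" in config.stages:
            pio.write_map(gmap, out / "map.csv", header=header)
            pio.write_ril_tsv(ril, out / "ril_genotypes.tsv", header=header)
            pio.write_phenotypes(phenotypes, out / "phenotypes.csv", header=header)
            report["map"] = str(out / "map.csv")
            log.info("simulate: %d lines x %d markers", ril.n_lines, gmap.n_markers)

    if "scan" in config.stages:
        seeds["permutations"] = int(rng.integers(2**31))
        scanner = QTLScanner(
            mode=config.scan_mode, step_cm=config.step_cm,
            n_permutations=config.n_permutations, alpha=config.alpha,
            window_cm=config.window_cm, random_state=seeds["permutations"],
        ).fit(ril, phenotypes)
        pio._write_table(scanner.result_.to_frame(), out / "scan_profile.tsv", "\t", header)
        pio._write_table(scanner.peaks_, out / "scan_peaks.tsv", "\t", header)
        report["n_peaks"] = len(scanner.peaks_)
        report["threshold"] = scanner.threshold_
        log.info("scan: threshold %.2f, %d peak(s)", scanner.threshold_, len(scanner.peaks_))

    if "bsa" in config.stages:
        calls = {}
        for k in range(config.bsa_n_populations):
            pop = f"POP{k + 1}"
            seeds[f"bsa_ril_{pop}"] = int(rng.integers(2**31))
            seeds[f"bsa_pheno_{pop}"] = int(rng.integers(2**31))
            pop_ril = simulate_ril_population(
                gmap, config.ril_n_lines, config.derived_generation,
                seed=seeds[f"bsa_ril_{pop}"],
            )
            pop_ph = simulate_phenotypes(pop_ril, model, config.n_trials,
                                         seed=seeds[f"bsa_pheno_{pop}"])
            analyzer = BulkSegregantAnalyzer(
                tail_fraction=config.tail_fraction, min_bulk=config.min_bulk,
                delta_threshold=config.delta_threshold, alpha=config.bsa_alpha,
                fixed_threshold=config.fixed_threshold, population=pop,
            ).fit(pop_ril, pop_ph)
            calls[pop] = analyzer.calls_
            pio._write_table(analyzer.calls_, out / f"bsa_calls_{pop}.tsv", "\t", header)
        loci = cross_population_summary(calls, gmap, config.merge_window_cm)
        pio._write_table(loci, out / "bsa_loci.tsv", "\t", header)
        report["n_bsa_loci"] = len(loci)
        log.info("bsa: %d merged locus/loci across %d populations", len(loci), len(calls))

    if "retain" in config.stages or "simulate" in config.stages:
        seeds["panel"] = int(rng.integers(2**31))
        panel, pedigree, truth = simulate_pedigree_panel(
            gmap, n_lines=config.panel_n_lines, snp_density=config.snp_density,
            n_blocks=config.n_retained_blocks, snps_per_block=config.snps_per_block,
            n_scattered=config.n_scattered_rare, rare_frequency=config.rare_frequency,
            retention_probability_outside=config.retention_probability_outside,
            n_derivatives=config.n_derivatives, seed=seeds["panel"],
        )
        if "simulate" in config.stages:
            pio.write_hapmap(panel, out / "panel.hmp.txt", header=header)

    if "retain" in config.stages:
        scanner = RetentionScanner(
            focal="donor", recurrent_parent=pedigree.recurrent_parent,
            derivatives=tuple(pedigree.derivatives),
            low_lines=tuple(pedigree.low_protein_contrast_lines),
            max_panel_frequency=config.max_panel_frequency,
            min_ratio=config.min_ratio, min_informative=config.min_informative,
            max_gap_bp=config.max_gap_bp, min_snps=config.min_snps,
        ).fit(panel)
        pio._write_table(scanner.records_, out / "retention_records.tsv", "\t", header)
        pio._write_table(blocks_to_frame(scanner.blocks_), out / "retention_blocks.tsv",
                         "\t", header)
        bed = blocks_to_bed(scanner.blocks_)
        with open(out / "retention_blocks.bed", "w") as fh:
            fh.write(f"# {header}\n")
            bed.to_csv(fh, sep="\t", index=False, header=False)
        report["n_blocks"] = len(scanner.blocks_)
        report["n_retained_snps"] = len(scanner.records_)
        log.info("retain: %d SNP(s) in %d block(s)", len(scanner.records_),
                 len(scanner.blocks_))

    provenance = {
        "package": "protqtl",
        "version": "0.1.0",
        "config_digest": digest,
        "config": json.loads(json.dumps(_config_dict(config))),
        "seeds": seeds,
        "runtime_s": round(time.time() - t0, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    report["provenance"] = str(out / "provenance.json")
    config.to_yaml(out / "config.yaml")
    return report


def _config_dict(config: RunConfig) -> dict:
    from dataclasses import asdict

    return asdict(config)
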