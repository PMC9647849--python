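"""End-to-end orchestration: simulate/load -> normalize -> QC -> SAM &
bootstrap-ROC differential expression -> consensus -> overrepresentation.

One seed drives every stochastic stage through per-stage substreams, so a
run with the same config and seed reproduces its summary byte for byte.
Every intermediate table is persisted in the run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import broc as broc_mod
from . import enrichment, normalize, qc, sam as sam_mod
from .broc import BrocConfig
from .io import (AbundanceMatrix, read_abundance_table, read_gmt,
                 write_abundance_table, write_results)
from .sam import SamConfig
from .simulate import SimulationConfig, config_to_dict, export_fixture, simulate_dataset

log = logging.getLogger("tmtde")

DEFAULT_CONTRASTS = (("PSP", "HC"), ("PSP", "PD"), ("PD", "HC"))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``simulation`` (generate data) or ``abundance_path`` +
    ``annotation_path`` (load data) must be given.  The top-level seed is
    split into per-stage substreams.
    """

    out_dir: str = "tmtde_run"
    simulation: SimulationConfig | None = None
    abundance_path: str | None = None
    annotation_path: str | None = None
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    sam: SamConfig = field(default_factory=SamConfig)
    broc: BrocConfig = field(default_factory=BrocConfig)
    q_threshold: float = 0.05
    gmt_path: str | None = None
    preserve_groups: bool = True
    ease: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulation is None and (self.abundance_path is None or self.annotation_path is None):
            raise ValueError("provide either a SimulationConfig or abundance+annotation paths")
        if self.simulation is not None:
            groups = set(self.simulation.groups)
            for a, b in self.contrasts:
                if a not in groups or b not in groups:
                    raise ValueError(f"contrast ({a}, {b}) references undeclared groups")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = config_to_dict(self.simulation)
        d["contrasts"] = [list(c) for c in self.contrasts]
        return d


def _stage_seeds(seed: int, contrasts) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    names = ["simulate"]
    for a, b in contrasts:
        names += [f"sam:{a}_vs_{b}", f"broc:{a}_vs_{b}"]
    vals = rng.integers(0, 2 ** 31 - 1, size=len(names))
    return {n: int(v) for n, v in zip(names, vals)}


def run_pipeline(config: RunConfig) -> str:
    """Execute all stages; returns the run directory.

    Writes abundance/annotation (and truth when simulated), each
    normalization stage, qc.tsv, per-contrast result TSVs, enrichment
    tables when a GMT is given, summary.json (machine-readable result
    counts; deterministic) and run.log (timings, warnings; not part of the
    deterministic surface).
    """
    os.makedirs(config.out_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(config.out_dir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    seeds = _stage_seeds(config.seed, config.contrasts)
    cfg_dict = config.to_dict()
    cfg_dict.pop("out_dir", None)  # where results land is not part of the run identity
    summary: dict = {"seed": config.seed,
                     "config_sha256": hashlib.sha256(
                         json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()}
    stage = "setup"
    t0 = time.time()
    try:
        stage = "input"
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=seeds["simulate"])
            matrix, truth = simulate_dataset(sim)
            export_fixture(matrix, truth, os.path.join(config.out_dir, "input"), overwrite=True)
        else:
            matrix = read_abundance_table(config.abundance_path, config.annotation_path)
        log.info("input: %d proteins x %d samples", matrix.n_proteins, matrix.n_samples)

        stage = "normalize"
        stages = normalize.normalize_pipeline(matrix, preserve_groups=config.preserve_groups)
        for name in ("median_ratio", "zscore", "batch_corrected"):
            write_abundance_table(stages[name], os.path.join(config.out_dir, f"{name}.tsv"))
        corrected: AbundanceMatrix = stages["batch_corrected"]
        summary["n_proteins_input"] = matrix.n_proteins
        summary["n_proteins_retained"] = corrected.n_proteins

        stage = "qc"
        med_complete = qc.filter_complete(stages["median_ratio"])
        report = qc.qc_report(stages["median_ratio"])
        report.to_frame().to_csv(os.path.join(config.out_dir, "qc.tsv"), sep="\t")
        pca_before = qc.pca_batch_check(qc.filter_complete(stages["zscore"]))
        pca_after = qc.pca_batch_check(corrected)
        summary["qc"] = {
            "frac_cv_below_30pct": round(report.frac_cv_below_30pct, 6),
            "frac_sn_above_1": round(report.frac_sn_above_1, 6),
            "batch_eta2_before": round(pca_before.batch_eta2, 6),
            "batch_eta2_after": round(pca_after.batch_eta2, 6),
        }

        summary["contrasts"] = {}
        universe_genes = sorted({g.upper() for g in corrected.genes.dropna()})
        gmt = read_gmt(config.gmt_path).with_universe(universe_genes) if config.gmt_path else None
        for a, b in config.contrasts:
            key = f"{a}_vs_{b}"
            stage = f"de-sam:{key}"
            sam_cfg = dataclasses.replace(config.sam, seed=seeds[f"sam:{key}"],
                                          q_threshold=config.q_threshold)
            sam_res = sam_mod.sam_qvalues(corrected, (a, b), sam_cfg)
            stage = f"de-broc:{key}"
            broc_cfg = dataclasses.replace(config.broc, seed=seeds[f"broc:{key}"],
                                           q_threshold=config.q_threshold)
            broc_res = broc_mod.broc_qvalues(corrected, (a, b), broc_cfg)
            stage = f"consensus:{key}"
            merged, venn = enrichment.consensus_select(sam_res, broc_res, config.q_threshold)
            merged.insert(0, "gene", corrected.genes)
            merged.insert(0, "accession", merged.index)
            write_results(merged, os.path.join(config.out_dir, f"results_{key}.tsv"))
            entry = {"n_sig_sam": int(merged["sig_sam"].sum()),
                     "n_sig_broc": int(merged["sig_broc"].sum()),
                     "n_sig_consensus": int(merged["sig_consensus"].sum()),
                     "venn": {"sam_only": venn.sam_only, "both": venn.both,
                              "broc_only": venn.broc_only}}
            if gmt is not None:
                stage = f"enrich:{key}"
                de_genes = set(corrected.genes.loc[merged.index[merged["sig_consensus"]]]
                               .dropna().str.upper())
                table = enrichment.enrich(de_genes, gmt, ease=config.ease)
                table.to_csv(os.path.join(config.out_dir, f"enrichment_{key}.tsv"),
                             sep="\t", index=False)
                entry["n_enriched_terms_p05"] = int((table["pvalue"] < 0.05).sum()) if not table.empty else 0
            summary["contrasts"][key] = entry

        stage = "summary"
        with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log.info("pipeline finished in %.1fs", time.time() - t0)
        return config.out_dir
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, exc) from exc
    finally:
        log.removeHandler(handler)
        handler.close()
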