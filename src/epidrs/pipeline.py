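"""End-to-end orchestration: io -> diffmod -> m6a -> polya -> integrate.

``run_pipeline`` executes every stage whose inputs are present, writes all
stage outputs under the configured output directory and assembles a
machine-readable run report (filter counts, thresholds, seed, version).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, diffmod, integrate, io_tables, metagene, polya, report

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Input paths, thresholds and output location for one pipeline run."""

    modcalls: str
    conditions: str
    outdir: str
    fasta: str | None = None
    annotations: str | None = None
    polya: str | None = None
    counts: str | None = None
    proteins: str | None = None
    id_map: str | None = None
    de_table: str | None = None
    prot_table: str | None = None

    min_cov: int = 50
    alpha: float = 0.05
    lfc_min: float = 0.5
    adjust: str = "none"
    min_cpm: float = 2.0
    min_samples: int = 2
    n_bins_full: int = 30
    bins_per_region: int = 20
    site_min_fraction: float = 0.1
    polya_accept_tags: tuple[str, ...] = ("PASS",)
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("min_cov", "alpha", "lfc_min", "min_cpm", "min_samples",
                     "n_bins_full", "bins_per_region"):
            if getattr(self, name) is not None and getattr(self, name) <= 0:
                raise io_tables.ValidationError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "polya_accept_tags" in raw:
            raw["polya_accept_tags"] = tuple(raw["polya_accept_tags"])
        return cls(**raw)


@dataclass
class RunResult:
    report: dict
    outputs: dict[str, Path] = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> RunResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rep: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "min_cov": config.min_cov,
            "alpha": config.alpha,
            "lfc_min": config.lfc_min,
            "adjust": config.adjust,
            "min_cpm": config.min_cpm,
            "min_samples": config.min_samples,
        },
        "stages": {},
    }
    outputs: dict[str, Path] = {}

    # ---- io ---------------------------------------------------------------
    load = _stage("io")(_load_inputs)
    inputs = load(config)
    table: io_tables.ModCallTable = inputs["modcalls"]
    if len(table) == 0:
        raise PipelineError("io", "modcall table is empty")
    rep["stages"]["io"] = {
        "modcall_rows": len(table),
        "samples": sorted(table.condition_map),
        "conditions": list(table.conditions),
    }

    # ---- diffmod ----------------------------------------------------------
    @_stage("diffmod")
    def run_diffmod():
        pooled = diffmod.pool_counts(table)
        results = diffmod.diffmod_scan(
            table, min_cov=config.min_cov, alpha=config.alpha,
            lfc_min=config.lfc_min, adjust=config.adjust,
        )
        n_removed = len(pooled) - len(results)
        report.check_filter_arithmetic(len(pooled), len(results), n_removed)
        tally = report.diffmod_tally(results)
        path = outdir / "diffmod.tsv"
        diffmod.write_diffmod(results, path)
        outputs["diffmod"] = path
        rep["stages"]["diffmod"] = {
            "positions_pooled": len(pooled),
            "positions_removed_low_coverage": n_removed,
            "tally": tally,
        }
        return pooled, results

    pooled, dm_results = run_diffmod()

    # ---- m6a --------------------------------------------------------------
    if inputs.get("sequences"):
        @_stage("m6a")
        def run_m6a():
            sites = []
            for tid, seq in inputs["sequences"].items():
                sites.extend(metagene.find_rrach_sites(seq, tid))
            annotations = inputs.get("annotations") or {}
            if annotations:
                sites = metagene.assign_regions(sites, annotations)
            freq = metagene.kmer_frequencies(sites)
            sites_path = outdir / "m6a_sites.tsv"
            metagene.sites_to_frame(sites).to_csv(sites_path, sep="\t",
                                                  index=False)
            freq_path = outdir / "m6a_kmer_frequencies.tsv"
            freq.rename("frequency").to_csv(freq_path, sep="\t",
                                            index_label="kmer")
            outputs["m6a_sites"] = sites_path
            outputs["m6a_kmers"] = freq_path
            stage: dict = {"n_sites": len(sites)}
            if annotations:
                by_cond = metagene.assign_site_conditions(
                    sites, pooled, min_fraction=config.site_min_fraction
                )
                full = metagene.metagene_full(by_cond, annotations,
                                              n_bins=config.n_bins_full)
                regions = metagene.metagene_regions(
                    by_cond, annotations, bins_per_region=config.bins_per_region
                )
                for name, profile in (("metagene_full", full),
                                      ("metagene_regions", regions)):
                    path = outdir / f"{name}.tsv"
                    profile.to_frame().to_csv(path, sep="\t", index=False)
                    outputs[name] = path
                stage["sites_per_condition"] = {
                    c: len(s) for c, s in by_cond.items()
                }
            results, n_p, n_both = metagene.m6a_diff(
                table, sites, min_cov=config.min_cov, alpha=config.alpha,
                lfc_min=config.lfc_min, adjust=config.adjust,
            )
            diff_path = outdir / "m6a_diff.tsv"
            diffmod.write_diffmod(results, diff_path)
            outputs["m6a_diff"] = diff_path
            stage["n_significant_p"] = n_p
            stage["n_significant_p_and_lfc"] = n_both
            rep["stages"]["m6a"] = stage
            return sites

        run_m6a()

    # ---- polya ------------------------------------------------------------
    polya_means_by_cond: dict[str, pd.Series] = {}
    if inputs.get("polya") is not None:
        @_stage("polya")
        def run_polya():
            records = inputs["polya"]
            kept = polya.filter_polya_pass(records,
                                           set(config.polya_accept_tags))
            report.check_filter_arithmetic(
                len(records), len(kept), len(records) - len(kept)
            )
            summaries, grand = polya.polya_summaries(kept, table.condition_map)
            hist = polya.polya_histogram(kept,
                                         condition_map=table.condition_map)
            for name, frame in (("polya_summaries", summaries),
                                ("polya_grand", grand),
                                ("polya_histogram", hist)):
                path = outdir / f"{name}.tsv"
                frame.to_csv(path, sep="\t", index=False)
                outputs[name] = path
            rep["stages"]["polya"] = {
                "records_in": len(records),
                "records_pass": len(kept),
                "removed_by_tag": kept.attrs.get("n_removed_by_tag", {}),
                "grand_means": {
                    row["condition"]: row["grand_mean"]
                    for _, row in grand.iterrows()
                },
            }
            for cond in sorted(set(table.condition_map.values())):
                sub = summaries[summaries["condition"] == cond]
                polya_means_by_cond[cond] = pd.Series(
                    sub["mean_length"].to_numpy(),
                    index=sub["transcript_id"], name=f"polya_mean_{cond}",
                )

        run_polya()

    # ---- integrate --------------------------------------------------------
    if inputs.get("counts") is not None:
        @_stage("integrate")
        def run_integrate():
            cpm_matrix = integrate.cpm(inputs["counts"])
            filtered = integrate.expression_filter(
                cpm_matrix, min_cpm=config.min_cpm,
                min_samples=config.min_samples,
            )
            n_removed = len(cpm_matrix.values) - len(filtered.values)
            report.check_filter_arithmetic(
                len(cpm_matrix.values), len(filtered.values), n_removed
            )
            log_ab = integrate.log_abundance_by_condition(
                filtered, table.condition_map
            )
            conds = sorted(set(table.condition_map.values()))
            mod_ratios = {
                c: diffmod.transcript_mod_ratio(pooled, c) for c in conds
            }
            rrach_keys = set()
            if inputs.get("sequences"):
                for tid, seq in inputs["sequences"].items():
                    for s in metagene.find_rrach_sites(seq, tid):
                        rrach_keys.add((s.transcript_id, s.position))
            if rrach_keys:
                sub = table.subset_positions(rrach_keys)
                m6a_pooled = diffmod.pool_counts(sub) if len(sub) else None
            else:
                m6a_pooled = None
            m6a_ratios = (
                {c: diffmod.transcript_mod_ratio(m6a_pooled, c) for c in conds}
                if m6a_pooled is not None and len(m6a_pooled)
                else mod_ratios
            )
            log_protein = None
            if inputs.get("proteins") is not None:
                prot = inputs["proteins"]
                logged = np.log2(prot.values + 1.0)
                log_protein = {}
                for cond in conds:
                    cols = [s for s in prot.samples
                            if table.condition_map.get(s) == cond]
                    if cols:
                        log_protein[cond] = logged[cols].mean(axis=1)
            corr = integrate.correlation_suite(
                mod_ratios, m6a_ratios, log_ab, polya_means_by_cond,
                log_protein=log_protein, id_map=inputs.get("id_map"),
            )
            corr_frame = integrate.correlations_to_frame(corr)
            path = outdir / "correlations.tsv"
            corr_frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
            outputs["correlations"] = path
            stage = {
                "transcripts_in": len(cpm_matrix.values),
                "transcripts_removed_low_expression": n_removed,
                "n_correlations": len(corr),
            }
            if config.de_table and config.prot_table:
                set_de = integrate.read_significance_table(config.de_table)
                set_prot = integrate.read_significance_table(config.prot_table)
                set_mod = set(
                    dm_results.loc[dm_results["status"] != "ns",
                                   "transcript_id"]
                )
                if inputs.get("id_map") is not None:
                    translate = dict(zip(inputs["id_map"]["protein_id"],
                                         inputs["id_map"]["transcript_id"]))
                    set_prot = {translate.get(p, p) for p in set_prot}
                overlap = integrate.multiomics_overlap(set_de, set_mod,
                                                       set_prot)
                opath = outdir / "overlap.tsv"
                report.overlap_to_frame(overlap).to_csv(opath, sep="\t",
                                                        index=False)
                outputs["overlap"] = opath
                stage["overlap_at_least_two"] = overlap.total_at_least_two
            rep["stages"]["integrate"] = stage

        run_integrate()

    report_path = outdir / "run_report.json"
    with open(report_path, "w") as fh:
        json.dump(rep, fh, indent=2, sort_keys=True)
    outputs["report"] = report_path
    return RunResult(report=rep, outputs=outputs)


def _load_inputs(config: RunConfig) -> dict:
    condition_map = io_tables.read_condition_map(config.conditions)
    annotations = (
        io_tables.read_annotations(config.annotations)
        if config.annotations else None
    )
    inputs = {
        "condition_map": condition_map,
        "annotations": annotations,
        "modcalls": io_tables.read_modcalls(
            config.modcalls, condition_map, annotations=annotations
        ),
        "sequences": io_tables.read_fasta(config.fasta) if config.fasta else None,
        "polya": io_tables.read_polya(config.polya) if config.polya else None,
        "counts": (io_tables.read_matrix(config.counts, "counts")
                   if config.counts else None),
        "proteins": (io_tables.read_matrix(config.proteins, "protein")
                     if config.proteins else None),
        "id_map": io_tables.read_id_map(config.id_map) if config.id_map else None,
    }
    return inputs
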