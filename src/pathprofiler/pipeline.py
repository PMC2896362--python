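"""End-to-end orchestration of the profiling chain.

Runs spot quantification -> background filtering and PMF identification
-> pathway enrichment -> focus-network construction, and, when
densitometry is supplied, the Bayesian MCMC ratio estimate.  A single
declarative config carries every file path, threshold and seed; defaults
are the study's stated settings (1.1-fold picking, 1.5-fold analysis,
50 ppm, one missed cleavage, 10% background rule, alpha 0.05, network
cap 35 with the score-6 convention, 0.4 target acceptance, PSRF 1.1).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bayes, enrichment, io as pio, network, pmf, quantify

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for one pipeline run."""

    spots: str = ""
    peak_lists: str = ""            # MGF file
    fasta: str = ""
    gmt: str = ""
    sif: str = ""
    densitometry: str = ""          # optional
    outdir: str = "pathprofiler_out"

    pick_fold: float = 1.1
    analysis_fold: float = 1.5
    tolerance_ppm: float = 50.0
    missed_cleavages: int = 1
    background_occurrence: float = 0.10
    bin_tolerance_ppm: float = 100.0
    min_batch: int = 10
    r_top: int = 5
    alpha: float = 0.05
    network_max: int = 35
    score_cutoff: float = 6.0
    target_acceptance: float = 0.4
    psrf_threshold: float = 1.1
    mcmc_iters: int = 15000
    mcmc_burn: int = 5000
    seeds: tuple[int, int, int] = (1, 2, 3)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seeds" in payload:
            payload["seeds"] = tuple(payload["seeds"])
        return cls(**payload)

    def search_config(self) -> pmf.SearchConfig:
        return pmf.SearchConfig(
            tolerance_ppm=self.tolerance_ppm,
            missed_cleavages=self.missed_cleavages,
            r_top=self.r_top, min_batch=self.min_batch,
            bin_tolerance_ppm=self.bin_tolerance_ppm)


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return run
    return wrap


@_stage("quantify")
def _quantify(config: PipelineConfig, outdir: Path) -> dict:
    spots = pio.read_spot_table(config.spots)
    records = quantify.normalize_volumes(spots)
    picked = quantify.fold_filter(records, config.pick_fold)
    records.to_csv(outdir / "spots_normalized.csv", index=False)
    picked.to_csv(outdir / "spots_picked.csv", index=False)
    log.info("quantify: %d spots in, %d picked at >=%.2f-fold",
             len(records), len(picked), config.pick_fold)
    return {"records": records, "picked": picked}


@_stage("pmf_identify")
def _identify(config: PipelineConfig, picked: pd.DataFrame,
              outdir: Path) -> pd.DataFrame:
    db = pio.read_fasta(config.fasta)
    batch = pio.read_mgf(config.peak_lists)
    wanted = set(picked["spot_id"])
    batch = [pl for pl in batch if pl.list_id in wanted]
    sc = config.search_config()
    filtered, removed = pmf.filter_background(
        batch, config.background_occurrence, config.bin_tolerance_ppm,
        config.min_batch)
    removed.to_csv(outdir / "background_peaks.csv", index=False)
    report = pmf.identify_batch(filtered, db, sc)
    report.to_csv(outdir / "identifications.csv", index=False)
    log.info("pmf: %d spectra searched, %d background bins removed, "
             "%d consensus identifications", len(batch), len(removed),
             int(report["consensus"].sum()))
    return report


@_stage("enrichment")
def _enrich(config: PipelineConfig, focus: set[str],
            outdir: Path) -> pd.DataFrame:
    kb = pio.read_gmt(config.gmt)
    result = enrichment.rank_pathways(focus, kb, alpha=config.alpha)
    result.to_csv(outdir / "pathway_enrichment.csv", index=False)
    log.info("enrichment: %d pathways tested, %d significant at "
             "alpha=%.2f", len(result),
             int(result["significant"].sum()) if len(result) else 0,
             config.alpha)
    return result


@_stage("network_inference")
def _networks(config: PipelineConfig, focus: set[str],
              outdir: Path) -> pd.DataFrame:
    graph = pio.read_sif(config.sif)
    nets = network.extract_networks(graph, focus, config.network_max)
    summary = network.network_summary(nets)
    summary.to_csv(outdir / "networks.csv", index=False)
    for i, net in enumerate(nets):
        network.node_attributes(net).to_csv(
            outdir / f"network_{i + 1}_nodes.csv", index=False)
    log.info("networks: %d emitted, best score %.2f", len(nets),
             summary["score"].max() if len(summary) else float("nan"))
    return summary


@_stage("bayes_ratio")
def _bayes(config: PipelineConfig, outdir: Path) -> dict:
    raw = pio.read_densitometry(config.densitometry)
    data = bayes.normalize_blots(raw)
    chains = bayes.run_mcmc(data, n_iter=config.mcmc_iters,
                            n_burn=config.mcmc_burn,
                            target_acceptance=config.target_acceptance,
                            seeds=config.seeds)
    summary = bayes.summarize_posterior(
        chains, psrf_threshold=config.psrf_threshold)
    payload = dataclasses.asdict(summary)
    payload["acceptance"] = chains.acceptance
    (outdir / "ratio_posterior.json").write_text(
        json.dumps(payload, indent=1))
    log.info("bayes: R mean %.4f (fold %.3f), PSRF %.3f, acceptance %.3f",
             summary.mean, summary.fold, summary.psrf, chains.acceptance)
    return payload


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and return the combined run report.

    The report carries the stage funnel (spots -> picked -> identified ->
    analysis set), the enrichment and network tables, and the posterior
    summary when densitometry was supplied.  Per-stage artifacts are
    written under ``config.outdir``; a stage failure raises
    :class:`StageError` and leaves earlier artifacts in place.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("thresholds: pick_fold=%.2f analysis_fold=%.2f ppm=%.0f "
             "missed=%d background=%.2f alpha=%.2f network_max=%d "
             "seeds=%s", config.pick_fold, config.analysis_fold,
             config.tolerance_ppm, config.missed_cleavages,
             config.background_occurrence, config.alpha,
             config.network_max, config.seeds)

    q = _quantify(config, outdir)
    ident = _identify(config, q["picked"], outdir)

    # analysis set: consensus-identified spots changed >= analysis_fold
    identified = ident[ident["consensus"]]
    picked = q["picked"].set_index("spot_id")
    analysis = quantify.fold_filter(
        picked.loc[picked.index.intersection(identified["list_id"])],
        config.analysis_fold)
    focus = set(
        identified.set_index("list_id").loc[analysis.index, "accession"])
    pd.Series(sorted(focus)).to_csv(outdir / "focus_proteins.csv",
                                    index=False, header=["accession"])

    enrich = _enrich(config, focus, outdir)
    nets = _networks(config, focus, outdir)

    report = {
        "n_spots": int(len(q["records"])),
        "n_picked": int(len(q["picked"])),
        "n_identified": int(identified["accession"].nunique()),
        "n_analysis": int(len(analysis)),
        "n_focus": len(focus),
        "focus": sorted(focus),
        "top_pathways": enrich.head(5).to_dict("records"),
        "networks": nets.to_dict("records"),
    }
    if config.densitometry:
        report["ratio_posterior"] = _bayes(config, outdir)
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report


def demo(outdir: str | Path, seed: int = 0, **generator_kwargs) -> dict:
    """Generate the synthetic dataset and run the full chain on it."""
    from .synthetic import generate_dataset
    outdir = Path(outdir)
    paths, truth = generate_dataset(outdir / "data", seed=seed,
                                    **generator_kwargs)
    config = PipelineConfig(
        spots=str(paths.spots), peak_lists=str(paths.mgf),
        fasta=str(paths.fasta), gmt=str(paths.gmt), sif=str(paths.sif),
        densitometry=str(paths.densitometry),
        outdir=str(outdir / "results"),
        seeds=(seed + 1, seed + 2, seed + 3))
    report = run_pipeline(config)
    report["truth"] = {
        "de_proteins": sorted(truth.de_proteins),
        "enriched_pathways": sorted(truth.enriched_pathways),
        "true_R": truth.true_R}
    return report
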