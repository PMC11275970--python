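"""End-to-end orchestration: simulate or load inputs, QC, MLE, model, annotate.

``run_pipeline`` is a pure function of (inputs, config, seeds): repeated
runs with the same configuration produce value-identical outputs. Each
stage logs probe/sample counts so the narrative counts of a run have a
machine-readable analogue (the filter report).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import annotate as ann
from . import io as hio
from .config import PipelineConfig
from .mle import oxbs_mle_matrix
from .model import fit_all, pvalue_histogram
from .qc import low_level_filter, run_qc
from .simulate import (
    simulate_betas,
    simulate_chrom_states,
    simulate_cohort,
    simulate_manifest,
    simulate_truth,
)
from .types import FilterReport, MLEEstimate, PairedBetaSet, SampleRecord

log = logging.getLogger(__name__)

RESULT_TSV_COLUMNS = [
    "probe_id", "chrom", "pos", "genes", "state", "b0", "b1", "b2", "b3",
    "b4", "b5", "se_interaction", "z", "p", "q", "direction", "converged",
]


@dataclass
class SimulatedInputs:
    paired: PairedBetaSet
    detp_bs: pd.DataFrame
    detp_oxbs: pd.DataFrame
    sheet: list[SampleRecord]
    manifest: pd.DataFrame
    states: pd.DataFrame
    truth_frame: pd.DataFrame


@dataclass
class PipelineResult:
    report: FilterReport
    mle: MLEEstimate
    probe_sets: dict[str, set[str]]  # mc / hmc / common
    results: pd.DataFrame  # per-probe interaction-model table
    annotated: pd.DataFrame
    unique_genes: list[str]
    state_freq: pd.DataFrame
    feature_freq: pd.DataFrame
    direction_counts: tuple[int, int]
    pval_label: str


def simulate_inputs(config: PipelineConfig) -> SimulatedInputs:
    """Generate a complete synthetic input bundle from the config's seed."""
    sim = config.simulate
    sheet = simulate_cohort(sim.n_control, sim.n_pd, seed=config.seed)
    truth = simulate_truth(
        sim.n_probes, sim.prop_idmc, sim.delta_magnitude,
        seed=config.seed + 1, config=sim,
    )
    paired, detp_bs, detp_oxbs = simulate_betas(truth, sheet, seed=config.seed + 2)
    manifest = simulate_manifest(truth, seed=config.seed + 3)
    states = simulate_chrom_states(manifest, seed=config.seed + 4)
    return SimulatedInputs(
        paired=paired, detp_bs=detp_bs, detp_oxbs=detp_oxbs, sheet=sheet,
        manifest=manifest, states=states, truth_frame=truth.to_frame(),
    )


def write_inputs(inputs: SimulatedInputs, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hio.write_matrix(inputs.paired.bs, outdir / "bs.tsv")
    hio.write_matrix(inputs.paired.oxbs, outdir / "oxbs.tsv")
    hio.write_matrix(inputs.detp_bs, outdir / "detp_bs.tsv")
    hio.write_matrix(inputs.detp_oxbs, outdir / "detp_oxbs.tsv")
    hio.write_sample_sheet(inputs.sheet, outdir / "samples.csv")
    hio.write_manifest(inputs.manifest, outdir / "manifest.csv")
    hio.write_chrom_states(inputs.states, outdir / "states.bed")
    inputs.truth_frame.to_csv(outdir / "truth.tsv", sep="\t")


def load_inputs(indir: str | Path) -> SimulatedInputs:
    indir = Path(indir)
    truth_path = indir / "truth.tsv"
    return SimulatedInputs(
        paired=PairedBetaSet(
            bs=hio.read_beta_matrix(indir / "bs.tsv"),
            oxbs=hio.read_beta_matrix(indir / "oxbs.tsv"),
        ),
        detp_bs=hio.read_detection_p(indir / "detp_bs.tsv"),
        detp_oxbs=hio.read_detection_p(indir / "detp_oxbs.tsv"),
        sheet=hio.read_sample_sheet(indir / "samples.csv"),
        manifest=hio.read_manifest(indir / "manifest.csv"),
        states=hio.read_chrom_states(indir / "states.bed"),
        truth_frame=(
            pd.read_csv(truth_path, sep="\t", index_col=0)
            if truth_path.exists() else pd.DataFrame()
        ),
    )


def run_pipeline(config: PipelineConfig, inputs: SimulatedInputs) -> PipelineResult:
    """QC -> constrained MLE -> low-level filter -> interaction model -> annotation."""
    config.validate()

    filtered, sheet, report = run_qc(
        inputs.paired, inputs.detp_bs, inputs.detp_oxbs,
        inputs.sheet, inputs.manifest, config.qc,
    )
    mle = oxbs_mle_matrix(filtered, boundary_as_missing=config.mle.boundary_as_missing)
    mc_set, hmc_set, common = low_level_filter(mle, config.qc.low_level_cutoff)
    log.info(
        "probe sets: beta_m %d, beta_h %d, common %d", len(mc_set), len(hmc_set), len(common)
    )
    # the interaction model runs on the common probe set (both marks analyzable)
    common_ordered = [p for p in mle.probe_ids if p in common]
    results = fit_all(mle, sheet, common_ordered, config.model)

    conv_p = results.loc[results["converged"], "p"].dropna().to_numpy()
    _, pval_label = pvalue_histogram(conv_p)
    log.info("p-value histogram shape: %s", pval_label)

    alpha = config.model.fdr_alpha
    annotated, unique_genes = ann.annotate_genes(results, inputs.manifest, alpha)
    states_assigned, state_freq = ann.annotate_chromatin(annotated, inputs.states)
    annotated = annotated.assign(state=states_assigned)
    feature_freq = ann.feature_distribution(results, inputs.manifest, alpha)
    direction_counts = ann.summarize_directions(results, alpha)

    return PipelineResult(
        report=report,
        mle=mle,
        probe_sets={"mc": mc_set, "hmc": hmc_set, "common": common},
        results=results,
        annotated=annotated,
        unique_genes=unique_genes,
        state_freq=state_freq,
        feature_freq=feature_freq,
        direction_counts=direction_counts,
        pval_label=pval_label,
    )


def results_table(result: PipelineResult, manifest: pd.DataFrame) -> pd.DataFrame:
    """The fixed-column-order per-probe results TSV payload."""
    res = result.results
    ann_idx = result.annotated.index
    table = pd.DataFrame(
        {
            "probe_id": res.index,
            "chrom": [manifest.loc[p, "chrom"] if p in manifest.index else "" for p in res.index],
            "pos": [int(manifest.loc[p, "pos"]) if p in manifest.index else -1 for p in res.index],
            "genes": [
                result.annotated.loc[p, "genes"] if p in ann_idx
                else ";".join(ann.split_genes(manifest.loc[p, "gene_symbols"]))
                if p in manifest.index else ""
                for p in res.index
            ],
            "state": [
                result.annotated.loc[p, "state"] if p in ann_idx else "" for p in res.index
            ],
            "b0": res["b0"].to_numpy(), "b1": res["b1"].to_numpy(),
            "b2": res["b2"].to_numpy(), "b3": res["b3"].to_numpy(),
            "b4": res["b4"].to_numpy(), "b5": res["b5"].to_numpy(),
            "se_interaction": res["se_b3"].to_numpy(),
            "z": res["z"].to_numpy(), "p": res["p"].to_numpy(),
            "q": res["q"].to_numpy(), "direction": res["direction"].to_numpy(),
            "converged": res["converged"].to_numpy(),
        }
    )
    return table[RESULT_TSV_COLUMNS]


def write_results(result: PipelineResult, manifest: pd.DataFrame, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.report.to_frame().to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    results_table(result, manifest).to_csv(outdir / "idmc_results.tsv", sep="\t", index=False)
    result.annotated.to_csv(outdir / "annotated_idmcs.tsv", sep="\t")
    with open(outdir / "unique_genes.txt", "w") as fh:
        for g in result.unique_genes:
            fh.write(g + "\n")
    result.state_freq.to_csv(outdir / "state_frequencies.tsv", sep="\t")
    result.feature_freq.to_csv(outdir / "feature_frequencies.tsv", sep="\t")
    n_pos, n_neg = result.direction_counts
    summary = pd.DataFrame(
        {
            "quantity": [
                "n_probes_beta_m", "n_probes_beta_h", "n_probes_common",
                "n_idmc", "n_positive_b3", "n_negative_b3", "pvalue_histogram",
            ],
            "value": [
                len(result.probe_sets["mc"]), len(result.probe_sets["hmc"]),
                len(result.probe_sets["common"]),
                len(result.annotated), n_pos, n_neg, result.pval_label,
            ],
        }
    )
    summary.to_csv(outdir / "run_summary.tsv", sep="\t", index=False)
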