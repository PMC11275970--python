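"""Staged probe/sample QC and the post-MLE low-level filter.

All threshold comparisons are strict (>): a probe failing in exactly 5% of
samples is kept, a sample with exactly 10% failed probes is kept, a glial
proportion of exactly 0.50 is kept, and a mean beta of exactly the
low-level cutoff is kept.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import QCConfig
from .types import (
    FilterReport,
    FilterStage,
    MLEEstimate,
    PairedBetaSet,
    SampleRecord,
    ValidationError,
)

log = logging.getLogger(__name__)


def flag_failed_probes(
    detp: pd.DataFrame, p_thresh: float = 0.01, sample_frac: float = 0.05
) -> set[str]:
    """Probes whose detection p exceeds ``p_thresh`` in strictly more than
    ``sample_frac`` of samples."""
    if detp.size == 0:
        raise ValidationError("flag_failed_probes: empty detection matrix")
    if not (0 < p_thresh < 1 and 0 < sample_frac < 1):
        raise ValidationError("thresholds must be in (0, 1)")
    vals = detp.to_numpy(dtype=float)
    failed = (vals > p_thresh).sum(axis=1)
    frac = failed / vals.shape[1]
    return set(detp.index[frac > sample_frac])


def flag_failed_samples(
    detp: pd.DataFrame, probe_frac: float = 0.10, p_thresh: float = 0.01
) -> set[str]:
    """Samples whose fraction of probes with detection p > ``p_thresh``
    strictly exceeds ``probe_frac``."""
    if detp.size == 0:
        raise ValidationError("flag_failed_samples: empty detection matrix")
    if not (0 < probe_frac < 1):
        raise ValidationError("probe_frac must be in (0, 1)")
    vals = detp.to_numpy(dtype=float)
    frac = (vals > p_thresh).sum(axis=0) / vals.shape[0]
    return set(detp.columns[frac > probe_frac])


def apply_probe_masks(
    probes: set[str] | list[str], manifest: pd.DataFrame, strict: bool = True
) -> set[str]:
    """Remove probes flagged ``masked`` in the manifest (cross-reactive / SNP
    probes); unknown probes are an error under strict mode, passed through
    otherwise."""
    probes = set(probes)
    known = probes & set(manifest.index)
    unknown = probes - known
    if unknown and strict:
        raise ValidationError(
            f"{len(unknown)} probe(s) absent from manifest, e.g. {sorted(unknown)[:5]}"
        )
    masked = set(manifest.index[manifest["masked"].to_numpy(dtype=bool)])
    return (known - masked) | unknown


def filter_high_glial_samples(
    sheet: list[SampleRecord], cutoff: float = 0.50
) -> set[str]:
    """Samples with glial proportion strictly above ``cutoff`` (to remove)."""
    if not (0 < cutoff < 1):
        raise ValidationError("glial cutoff must be in (0, 1)")
    return {r.sample_id for r in sheet if r.glial_proportion > cutoff}


def low_level_filter(
    mle: MLEEstimate, cutoff: float = 0.01
) -> tuple[set[str], set[str], set[str]]:
    """Split probes into analyzable sets by mean modification level.

    Returns ``(mc_set, hmc_set, common_set)``: probes whose across-sample
    mean beta_m (resp. beta_h) is at or above ``cutoff`` (missing values are
    excluded from the mean; probes with no data in a matrix are excluded
    from that set and logged). ``common_set`` is the intersection — the
    probe set the paired interaction model runs on.
    """
    if mle.beta_m.size == 0:
        raise ValidationError("low_level_filter: empty MLE matrices")

    def passing(df: pd.DataFrame) -> set[str]:
        means = df.mean(axis=1, skipna=True)
        all_missing = means.isna()
        if all_missing.any():
            log.info(
                "low_level_filter: %d probe(s) with no data excluded", int(all_missing.sum())
            )
        return set(df.index[(~all_missing) & (means >= cutoff)])

    mc_set = passing(mle.beta_m)
    hmc_set = passing(mle.beta_h)
    return mc_set, hmc_set, mc_set & hmc_set


def run_qc(
    paired: PairedBetaSet,
    detp_bs: pd.DataFrame,
    detp_oxbs: pd.DataFrame,
    sheet: list[SampleRecord],
    manifest: pd.DataFrame,
    config: QCConfig | None = None,
) -> tuple[PairedBetaSet, list[SampleRecord], FilterReport]:
    """Apply the staged QC in fixed order: failed samples, failed probes,
    probe masks, high-glial exclusion.

    Failure rules use the union of flags over both channels' detection
    matrices by default (``config.channels``): a probe or sample unusable in
    either channel cannot enter the paired MLE.
    """
    cfg = config or QCConfig()
    cfg.validate()
    report = FilterReport()
    probes = list(paired.probe_ids)
    samples = [r.sample_id for r in sheet]
    by_id = {r.sample_id: r for r in sheet}

    def detp_sources():
        if cfg.channels == "bs":
            return [detp_bs]
        if cfg.channels == "oxbs":
            return [detp_oxbs]
        return [detp_bs, detp_oxbs]

    # stage 1: failed samples
    bad_samples: set[str] = set()
    for d in detp_sources():
        bad_samples |= flag_failed_samples(
            d.loc[probes, samples], cfg.sample_fail_probe_frac, cfg.detp_threshold
        )
    kept_samples = [s for s in samples if s not in bad_samples]
    report.add(FilterStage(
        name="failed_samples",
        rule=f"> {cfg.sample_fail_probe_frac:.0%} probes with detection p > {cfg.detp_threshold}",
        probes_in=len(probes), probes_removed=0,
        samples_in=len(samples), samples_removed=len(bad_samples),
    ))
    if not kept_samples:
        raise ValidationError("run_qc: all samples removed at failed_samples stage")
    samples = kept_samples

    # stage 2: failed probes (recomputed on the retained samples)
    bad_probes: set[str] = set()
    for d in detp_sources():
        bad_probes |= flag_failed_probes(
            d.loc[probes, samples], cfg.detp_threshold, cfg.probe_fail_sample_frac
        )
    kept_probes = [p for p in probes if p not in bad_probes]
    report.add(FilterStage(
        name="failed_probes",
        rule=f"detection p > {cfg.detp_threshold} in > {cfg.probe_fail_sample_frac:.0%} of samples",
        probes_in=len(probes), probes_removed=len(bad_probes),
        samples_in=len(samples), samples_removed=0,
    ))
    probes = kept_probes

    # stage 3: masked probes
    unmasked = apply_probe_masks(probes, manifest)
    report.add(FilterStage(
        name="masked_probes",
        rule="cross-reactive / SNP-containing probes masked per manifest",
        probes_in=len(probes), probes_removed=len(probes) - len(unmasked),
        samples_in=len(samples), samples_removed=0,
    ))
    probes = [p for p in probes if p in unmasked]

    # stage 4: high-glial samples
    high_glial = filter_high_glial_samples(
        [by_id[s] for s in samples], cfg.glial_cutoff
    )
    kept_samples = [s for s in samples if s not in high_glial]
    report.add(FilterStage(
        name="high_glial_samples",
        rule=f"estimated glial proportion > {cfg.glial_cutoff}",
        probes_in=len(probes), probes_removed=0,
        samples_in=len(samples), samples_removed=len(high_glial),
    ))
    if not kept_samples:
        raise ValidationError("run_qc: all samples removed at high_glial stage")
    samples = kept_samples

    report.validate()
    for s in report.stages:
        log.info(
            "QC %s: probes %d -> %d, samples %d -> %d",
            s.name, s.probes_in, s.probes_out, s.samples_in, s.samples_out,
        )
    filtered = paired.subset(probes=probes, samples=samples)
    filtered_sheet = [by_id[s] for s in samples]
    return filtered, filtered_sheet, report
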