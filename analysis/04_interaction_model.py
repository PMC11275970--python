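"""Per-CpG disease x modification interaction model over the common set.

Each probe's paired (beta_m, beta_h) values are fit with the beta mixed
model (logit mean link, sample random intercept marginalized by
Gauss-Hermite quadrature; glial proportion and PMI as covariates); the
group x modification interaction is tested with a cluster-robust Wald
test and Benjamini-Hochberg FDR across probes. A p-value histogram
diagnostic summarizes calibration.
"""

from pathlib import Path

import pandas as pd

from hydroshift import io as hio
from hydroshift.config import load_config
from hydroshift.model import fit_all, pvalue_histogram
from hydroshift.types import MLEEstimate

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = load_config(ROOT / "inputs" / "config.yaml")
    beta_m = hio.read_beta_matrix(ROOT / "mle" / "beta_m.tsv")
    beta_h = hio.read_beta_matrix(ROOT / "mle" / "beta_h.tsv")
    flags = pd.read_csv(ROOT / "mle" / "flags.tsv", sep="\t", index_col=0)
    est = MLEEstimate(beta_m=beta_m, beta_h=beta_h, flags=flags)
    sheet = hio.read_sample_sheet(ROOT / "qc" / "samples_filtered.csv")
    from hydroshift.qc import low_level_filter

    _, _, common = low_level_filter(est, cfg.qc.low_level_cutoff)
    probes = [p for p in beta_m.index if p in common]
    results = fit_all(est, sheet, probes, cfg.model)

    outdir = ROOT / "model"
    outdir.mkdir(parents=True, exist_ok=True)
    results.to_csv(outdir / "idmc_results.tsv", sep="\t")
    conv = results[results["converged"]]
    counts, label = pvalue_histogram(conv["p"].to_numpy())
    pd.DataFrame({"bin": range(len(counts)), "count": counts}).to_csv(
        outdir / "pvalue_histogram.tsv", sep="\t", index=False
    )
    n_sig = int((conv["q"] < cfg.model.fdr_alpha).sum())
    print(f"fit {len(results)} probes ({len(conv)} converged)")
    print(f"p-value histogram: {label}")
    print(f"{n_sig} iDMCs at FDR < {cfg.model.fdr_alpha}")


if __name__ == "__main__":
    main()
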