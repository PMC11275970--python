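"""Annotate significant iDMCs: genes, array features, chromatin states,
and the direction-of-effect split.

A positive interaction coefficient marks a shift toward 5hmC (relative
5mC decrease) in the disease group; a negative one the reverse. Writes
the annotated table, the de-duplicated gene list for external enrichment
tools, and the state/feature frequency tables.
"""

from pathlib import Path

import pandas as pd

from hydroshift import annotate as ann
from hydroshift import io as hio
from hydroshift.config import load_config

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = load_config(ROOT / "inputs" / "config.yaml")
    alpha = cfg.model.fdr_alpha
    results = pd.read_csv(ROOT / "model" / "idmc_results.tsv", sep="\t",
                          index_col="probe_id")
    manifest = hio.read_manifest(ROOT / "inputs" / "manifest.csv")
    states = hio.read_chrom_states(ROOT / "inputs" / "states.bed")

    annotated, genes = ann.annotate_genes(results, manifest, alpha)
    assigned, state_freq = ann.annotate_chromatin(annotated, states)
    annotated = annotated.assign(state=assigned)
    n_idmc, n_genic, n_genes = ann.gene_counts(annotated)
    n_pos, n_neg = ann.summarize_directions(results, alpha)
    features = ann.feature_distribution(results, manifest, alpha)

    outdir = ROOT / "annotation"
    outdir.mkdir(parents=True, exist_ok=True)
    annotated.to_csv(outdir / "annotated_idmcs.tsv", sep="\t")
    (outdir / "unique_genes.txt").write_text("".join(g + "\n" for g in genes))
    state_freq.to_csv(outdir / "state_frequencies.tsv", sep="\t")
    features.to_csv(outdir / "feature_frequencies.tsv", sep="\t")

    print(f"{n_idmc} iDMCs at FDR < {alpha}: {n_genic} within genes, "
          f"{n_genes} unique gene symbols")
    print(f"direction split: {n_pos} toward hmC (b3 > 0), {n_neg} toward mC")
    if len(state_freq):
        top = state_freq["proportion"].idxmax()
        print(f"most common chromatin state among iDMCs: {top} "
              f"({state_freq.loc[top, 'proportion']:.0%})")


if __name__ == "__main__":
    main()
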