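"""Staged probe/sample QC on the simulated bundle.

Stages in fixed order: failed samples (> 10% failed probes in either
channel), failed probes (detection p > 0.01 in > 5% of samples, either
channel), manifest-masked probes, and high-glial samples (> 0.50). Writes
filtered matrices and the machine-readable filter report.
"""

from pathlib import Path

from hydroshift import io as hio
from hydroshift.config import load_config
from hydroshift.pipeline import load_inputs
from hydroshift.qc import run_qc

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = load_config(ROOT / "inputs" / "config.yaml")
    inputs = load_inputs(ROOT / "inputs")
    filtered, sheet, report = run_qc(
        inputs.paired, inputs.detp_bs, inputs.detp_oxbs,
        inputs.sheet, inputs.manifest, cfg.qc,
    )
    outdir = ROOT / "qc"
    outdir.mkdir(parents=True, exist_ok=True)
    hio.write_matrix(filtered.bs, outdir / "bs_filtered.tsv")
    hio.write_matrix(filtered.oxbs, outdir / "oxbs_filtered.tsv")
    hio.write_sample_sheet(sheet, outdir / "samples_filtered.csv")
    frame = report.to_frame()
    frame.to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    print(frame.to_string(index=False))
    print(f"retained {filtered.bs.shape[0]} probes, {filtered.bs.shape[1]} samples")


if __name__ == "__main__":
    main()
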