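"""Generate the study's synthetic input bundle.

Emulates a paired BS/oxBS EPIC-like experiment on sorted neuronal nuclei:
29 control + 27 disease male samples with the target cohort's age/PMI/glial
structure, 2,000 CpG probes (10% carrying a 0.10 mC<->hmC shift in the
disease group), beta-distributed measurement noise (oxBS harsher), probe
and sample failure structure, a probe manifest, and a chromatin-state BED.

Writes results/inputs/ plus the retained ground truth (truth.tsv).
"""

from pathlib import Path

from hydroshift.config import PipelineConfig, save_config
from hydroshift.pipeline import simulate_inputs, write_inputs

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "inputs"


def main() -> None:
    cfg = PipelineConfig(seed=20260901).validate()
    inputs = simulate_inputs(cfg)
    write_inputs(inputs, OUTDIR)
    save_config(cfg, OUTDIR / "config.yaml")
    n_eff = int(inputs.truth_frame["is_idmc"].sum())
    print(f"wrote {OUTDIR}")
    print(f"  {inputs.paired.bs.shape[0]} probes x {inputs.paired.bs.shape[1]} samples")
    print(f"  {n_eff} probes carry a true mC<->hmC shift")
    miss_ox = float(inputs.paired.oxbs.isna().to_numpy().mean())
    miss_bs = float(inputs.paired.bs.isna().to_numpy().mean())
    print(f"  missingness: BS {miss_bs:.3%}, oxBS {miss_ox:.3%} (oxBS harsher)")


if __name__ == "__main__":
    main()
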