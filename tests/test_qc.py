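"""QC filters: strict-inequality boundaries, brute-force recount oracles,
idempotence, and staged composition bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from hydroshift.config import QCConfig
from hydroshift.qc import (
    apply_probe_masks,
    filter_high_glial_samples,
    flag_failed_probes,
    flag_failed_samples,
    low_level_filter,
    run_qc,
)
from hydroshift.simulate import simulate_cohort
from hydroshift.types import PairedBetaSet, SampleRecord, ValidationError

from .conftest import toy_mle, toy_paired


def detp_frame(vals):
    vals = np.asarray(vals, dtype=float)
    return pd.DataFrame(
        vals,
        index=pd.Index([f"cg{i:05d}" for i in range(vals.shape[0])], name="probe_id"),
        columns=[f"S{j:03d}" for j in range(vals.shape[1])],
    )


def test_failed_probes_strict_boundary():
    # 20 samples: exactly 5% failures (1/20) kept, 10% (2/20) flagged
    vals = np.zeros((2, 20))
    vals[0, 0] = 0.5
    vals[1, :2] = 0.5
    detp = detp_frame(vals)
    assert flag_failed_probes(detp) == {"cg00001"}


def test_failed_probes_all_pass_and_oracle():
    assert flag_failed_probes(detp_frame(np.zeros((5, 10)))) == set()
    rng = np.random.default_rng(0)
    detp = detp_frame(rng.random((50, 10)) * 0.03)
    # brute-force double loop recount
    expected = set()
    for i in range(50):
        n_fail = sum(detp.iloc[i, j] > 0.01 for j in range(10))
        if n_fail / 10 > 0.05:
            expected.add(detp.index[i])
    assert flag_failed_probes(detp) == expected


def test_failed_samples_strict_boundary_and_oracle():
    # 10 probes: a sample failing exactly 10% kept, 20% flagged
    vals = np.zeros((10, 3))
    vals[0, 1] = 0.5
    vals[:2, 2] = 0.5
    detp = detp_frame(vals)
    assert flag_failed_samples(detp) == {"S002"}

    rng = np.random.default_rng(1)
    detp = detp_frame(rng.random((40, 8)) * 0.05)
    expected = set()
    for j in range(8):
        n_fail = sum(detp.iloc[i, j] > 0.01 for i in range(40))
        if n_fail / 40 > 0.10:
            expected.add(detp.columns[j])
    assert flag_failed_samples(detp) == expected


def test_empty_matrix_errors():
    empty = pd.DataFrame(index=pd.Index([], name="probe_id"))
    with pytest.raises(ValidationError):
        flag_failed_probes(empty)
    with pytest.raises(ValidationError):
        flag_failed_samples(empty)


def test_probe_masks_and_idempotence():
    manifest = pd.DataFrame(
        {
            "chrom": ["chr1"] * 5,
            "pos": range(1, 6),
            "gene_symbols": [""] * 5,
            "feature": ["Body"] * 5,
            "masked": [True, True, False, False, False],
        },
        index=pd.Index([f"cg{i}" for i in range(5)], name="probe_id"),
    )
    probes = {f"cg{i}" for i in range(5)}
    kept = apply_probe_masks(probes, manifest)
    assert kept == {"cg2", "cg3", "cg4"}
    assert apply_probe_masks(kept, manifest) == kept  # idempotent
    manifest["masked"] = False
    assert apply_probe_masks(probes, manifest) == probes  # identity case
    with pytest.raises(ValidationError, match="absent"):
        apply_probe_masks({"cg0", "cgX"}, manifest)
    assert apply_probe_masks({"cg0", "cgX"}, manifest, strict=False) == {"cg0", "cgX"}


def test_glial_filter_strict_boundary():
    def rec(sid, glial):
        return SampleRecord(sid, "control", "male", 75.0, 3.0, glial)

    sheet = [rec("A", 0.50), rec("B", 0.51), rec("C", 0.30)]
    assert filter_high_glial_samples(sheet) == {"B"}
    assert filter_high_glial_samples([rec("D", 0.3)] * 1) == set()


def test_glial_filter_removes_exactly_one_of_56():
    # mirror the cohort event: one sample above the 0.50 cutoff
    sheet = simulate_cohort(29, 27, seed=2)
    sheet = [
        SampleRecord(r.sample_id, r.group, r.sex, r.age_years, r.pmi_hours,
                     0.60 if i == 17 else min(r.glial_proportion, 0.49))
        for i, r in enumerate(sheet)
    ]
    removed = filter_high_glial_samples(sheet)
    assert removed == {sheet[17].sample_id}


def test_low_level_filter_constructed_fixture():
    # 10 probes: 4 pass both marks, 3 mC-only, 2 hmC-only, 1 neither
    m = np.zeros((10, 4))
    h = np.zeros((10, 4))
    m[:4] = 0.5
    h[:4] = 0.1
    m[4:7] = 0.3          # mC only (h stays 0)
    h[7:9] = 0.05         # hmC only (m stays 0)
    mle = toy_mle(m, h)
    mc, hmc, common = low_level_filter(mle)
    assert (len(mc), len(hmc), len(common)) == (7, 6, 4)
    # brute-force recount
    assert mc == set(mle.beta_m.index[mle.beta_m.mean(axis=1) >= 0.01])
    assert hmc == set(mle.beta_h.index[mle.beta_h.mean(axis=1) >= 0.01])
    assert common == mc & hmc


def test_low_level_filter_boundary_and_missing():
    # mean exactly at the cutoff is kept (strict-< removal)
    mle = toy_mle([[0.01, 0.01]], [[0.0, 0.0]])
    mc, hmc, common = low_level_filter(mle)
    assert mc == {"cg00000"} and hmc == set() and common == set()
    # all-missing probe excluded from every set
    mle2 = toy_mle([[np.nan, np.nan], [0.5, 0.5]], [[np.nan, np.nan], [0.5, 0.5]])
    mc, hmc, common = low_level_filter(mle2)
    assert mc == hmc == common == {"cg00001"}
    # cutoff 0: any probe with data in both marks
    mc, hmc, common = low_level_filter(toy_mle([[0.0]], [[0.0]]), cutoff=0.0)
    assert common == {"cg00000"}


def _clean_bundle(n_probes=8, n_samples=6):
    rng = np.random.default_rng(5)
    paired = toy_paired(
        bs=rng.random((n_probes, n_samples)) * 0.5 + 0.3,
        oxbs=rng.random((n_probes, n_samples)) * 0.3,
    )
    detp = pd.DataFrame(
        np.zeros((n_probes, n_samples)), index=paired.bs.index, columns=paired.bs.columns
    )
    sheet = [
        SampleRecord(s, "control" if j % 2 else "PD", "male", 75.0, 3.0, 0.3)
        for j, s in enumerate(paired.bs.columns)
    ]
    manifest = pd.DataFrame(
        {
            "chrom": ["chr1"] * n_probes,
            "pos": range(1, n_probes + 1),
            "gene_symbols": [""] * n_probes,
            "feature": ["Body"] * n_probes,
            "masked": [False] * n_probes,
        },
        index=paired.bs.index,
    )
    return paired, detp, sheet, manifest


def test_run_qc_clean_fixture_is_identity():
    paired, detp, sheet, manifest = _clean_bundle()
    filtered, out_sheet, report = run_qc(paired, detp, detp.copy(), sheet, manifest)
    assert filtered.bs.equals(paired.bs)
    assert [r.sample_id for r in out_sheet] == [r.sample_id for r in sheet]
    frame = report.to_frame()
    assert (frame["probes_removed"] == 0).all()
    assert (frame["samples_removed"] == 0).all()


def test_run_qc_each_stage_removes_known_count():
    paired, detp_bs, sheet, manifest = _clean_bundle(n_probes=10, n_samples=8)
    detp_ox = detp_bs.copy()
    # stage 1: sample S000 fails > 10% of probes in the oxBS channel
    detp_ox.iloc[:3, 0] = 0.5
    # stage 2: probe cg00001 fails in 1 of the 7 remaining samples (> 5%)
    detp_bs.iloc[1, 3] = 0.5
    # stage 3: two masked probes
    manifest.loc[["cg00004", "cg00005"], "masked"] = True
    # stage 4: one high-glial sample
    sheet[5] = SampleRecord(sheet[5].sample_id, "PD", "male", 75.0, 3.0, 0.8)

    filtered, out_sheet, report = run_qc(paired, detp_bs, detp_ox, sheet, manifest)
    by_stage = {s.name: s for s in report.stages}
    assert by_stage["failed_samples"].samples_removed == 1
    assert by_stage["failed_probes"].probes_removed == 1
    assert by_stage["masked_probes"].probes_removed == 2
    assert by_stage["high_glial_samples"].samples_removed == 1
    assert filtered.bs.shape == (7, 6)
    assert len(out_sheet) == 6
    # conservation invariant at every stage
    frame = report.to_frame()
    assert (frame["probes_out"] == frame["probes_in"] - frame["probes_removed"]).all()
    assert (frame["samples_out"] == frame["samples_in"] - frame["samples_removed"]).all()
    # stages compose
    assert (frame["probes_in"].iloc[1:].to_numpy() == frame["probes_out"].iloc[:-1].to_numpy()).all()


def test_run_qc_label_order_invariance():
    paired, detp_bs, sheet, manifest = _clean_bundle(n_probes=10, n_samples=8)
    detp_ox = detp_bs.copy()
    detp_ox.iloc[:3, 0] = 0.5
    detp_bs.iloc[1, 3] = 0.5
    f1, _, _ = run_qc(paired, detp_bs, detp_ox, sheet, manifest)

    perm = np.random.default_rng(0).permutation(10)
    paired2 = PairedBetaSet(
        bs=paired.bs.iloc[perm], oxbs=paired.oxbs.iloc[perm]
    )
    f2, _, _ = run_qc(paired2, detp_bs.iloc[perm], detp_ox.iloc[perm], sheet,
                      manifest.iloc[perm])
    assert set(f1.bs.index) == set(f2.bs.index)
    pd.testing.assert_frame_equal(f2.bs.loc[f1.bs.index], f1.bs)


def test_run_qc_all_samples_removed_errors():
    paired, detp, sheet, manifest = _clean_bundle()
    detp_bad = detp + 0.5
    with pytest.raises(ValidationError, match="failed_samples"):
        run_qc(paired, detp_bad, detp_bad, sheet, manifest, QCConfig())


def test_filter_idempotence():
    vals = np.zeros((30, 10))
    vals[:7, 0] = 0.02  # seven probes fail in one sample (10% > 5%)
    detp = detp_frame(vals)
    bad = flag_failed_probes(detp)
    assert len(bad) == 7
    survivors = detp.drop(index=list(bad))
    assert flag_failed_probes(survivors) == set()
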