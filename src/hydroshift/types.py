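"""Shared domain types for the paired BS/oxBS analysis.

Matrices are pandas DataFrames with probes as rows and samples as columns;
all joins are by label, never by position, so a BS matrix can never be
silently misaligned against its oxBS partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("control", "PD")
SEXES = ("male", "female")

#: per-cell MLE status codes
FLAG_INTERIOR = "interior"
FLAG_BOUNDARY_H0 = "boundary_h0"
FLAG_MISSING = "missing"


class HydroshiftError(Exception):
    """Base error for this package."""


class ParseError(HydroshiftError):
    """A file violated the expected format; the message names the offending cell."""


class ValidationError(HydroshiftError):
    """An in-memory object violated a domain invariant."""


@dataclass(frozen=True)
class SampleRecord:
    """Phenotype and covariates for one array sample.

    ``glial_proportion`` is the estimated fraction of non-neuronal nuclei in
    the sorted sample and ``pmi_hours`` the postmortem interval; both enter
    the interaction model as covariates.
    """

    sample_id: str
    group: str  # control | PD
    sex: str  # male | female
    age_years: float
    pmi_hours: float
    glial_proportion: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown group {self.group!r} "
                f"(expected one of {GROUPS})"
            )
        if self.sex not in SEXES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown sex {self.sex!r} "
                f"(expected one of {SEXES})"
            )
        if not np.isfinite(self.age_years) or self.age_years < 0:
            raise ValidationError(f"sample {self.sample_id!r}: age_years must be >= 0")
        if not np.isfinite(self.pmi_hours) or self.pmi_hours < 0:
            raise ValidationError(f"sample {self.sample_id!r}: pmi_hours must be >= 0")
        if not (0.0 <= self.glial_proportion <= 1.0):
            raise ValidationError(
                f"sample {self.sample_id!r}: glial_proportion "
                f"{self.glial_proportion} outside [0, 1]"
            )


def validate_sheet(records: list[SampleRecord]) -> list[SampleRecord]:
    """Check sample_id uniqueness across a sheet; return the sheet unchanged."""
    ids = [r.sample_id for r in records]
    dupes = {s for s in ids if ids.count(s) > 1}
    if dupes:
        raise ValidationError(f"duplicate sample_id(s) in sheet: {sorted(dupes)}")
    return records


def sheet_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    """Sample sheet as a DataFrame indexed by sample_id."""
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "group": [r.group for r in records],
            "sex": [r.sex for r in records],
            "age_years": [r.age_years for r in records],
            "pmi_hours": [r.pmi_hours for r in records],
            "glial_proportion": [r.glial_proportion for r in records],
        }
    )
    return df.set_index("sample_id", drop=False)


def check_beta_matrix(df: pd.DataFrame, name: str = "beta matrix") -> pd.DataFrame:
    """Validate a probes x samples matrix of beta values in [0, 1] (NaN = missing)."""
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{name}: duplicate probe ids {dup[:5]}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{name}: duplicate sample ids {dup[:5]}")
    vals = df.to_numpy(dtype=float)
    bad = (vals < 0.0) | (vals > 1.0)
    if np.any(bad & ~np.isnan(vals)):
        i, j = np.argwhere(bad & ~np.isnan(vals))[0]
        raise ValidationError(
            f"{name}: value {vals[i, j]!r} outside [0, 1] at "
            f"probe {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return df


def check_detection_p(df: pd.DataFrame, name: str = "detection-p matrix") -> pd.DataFrame:
    """Validate a detection p-value matrix (same layout contract as beta matrices)."""
    return check_beta_matrix(df, name=name)


def check_aligned(a: pd.DataFrame, b: pd.DataFrame, what: str) -> None:
    """Require identical probe and sample label sets and order."""
    if not a.index.equals(b.index):
        raise ValidationError(f"{what}: probe labels differ or are reordered")
    if not a.columns.equals(b.columns):
        raise ValidationError(f"{what}: sample labels differ or are reordered")


@dataclass
class PairedBetaSet:
    """Aligned BS and oxBS beta matrices, optionally with intensity weights.

    The BS channel reads 5mC + 5hmC jointly; the oxBS channel reads true 5mC
    only. Weights, when present, are effective read-equivalents per
    probe x sample and must be strictly positive.
    """

    bs: pd.DataFrame
    oxbs: pd.DataFrame
    weights_bs: pd.DataFrame | None = None
    weights_oxbs: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        check_beta_matrix(self.bs, "BS matrix")
        check_beta_matrix(self.oxbs, "oxBS matrix")
        check_aligned(self.bs, self.oxbs, "PairedBetaSet(bs, oxbs)")
        for w, nm in ((self.weights_bs, "weights_bs"), (self.weights_oxbs, "weights_oxbs")):
            if w is not None:
                check_aligned(self.bs, w, f"PairedBetaSet({nm})")
                vals = w.to_numpy(dtype=float)
                if np.any(~np.isnan(vals) & (vals <= 0.0)):
                    raise ValidationError(f"{nm}: weights must be strictly positive")

    @property
    def probe_ids(self) -> pd.Index:
        return self.bs.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.bs.columns

    def subset(self, probes=None, samples=None) -> "PairedBetaSet":
        """Label-based subset; order follows the given labels."""
        def cut(df):
            if df is None:
                return None
            out = df
            if probes is not None:
                out = out.loc[list(probes)]
            if samples is not None:
                out = out[list(samples)]
            return out

        return PairedBetaSet(
            bs=cut(self.bs),
            oxbs=cut(self.oxbs),
            weights_bs=cut(self.weights_bs),
            weights_oxbs=cut(self.weights_oxbs),
        )


@dataclass
class MLEEstimate:
    """Per-probe, per-sample constrained-MLE (beta_m, beta_h) with status flags.

    Every non-missing cell satisfies 0 <= beta_m, 0 <= beta_h,
    beta_m + beta_h <= 1 (within 1e-12). ``flags`` holds one of
    ``interior`` / ``boundary_h0`` / ``missing`` per cell.
    """

    beta_m: pd.DataFrame
    beta_h: pd.DataFrame
    flags: pd.DataFrame

    SIMPLEX_TOL = 1e-12

    def __post_init__(self) -> None:
        check_aligned(self.beta_m, self.beta_h, "MLEEstimate(beta_m, beta_h)")
        check_aligned(self.beta_m, self.flags, "MLEEstimate(beta_m, flags)")
        m = self.beta_m.to_numpy(dtype=float)
        h = self.beta_h.to_numpy(dtype=float)
        ok = np.isnan(m) | np.isnan(h) | (
            (m >= -self.SIMPLEX_TOL)
            & (h >= -self.SIMPLEX_TOL)
            & (m + h <= 1.0 + self.SIMPLEX_TOL)
        )
        if not np.all(ok):
            i, j = np.argwhere(~ok)[0]
            raise ValidationError(
                f"MLEEstimate violates simplex constraint at probe "
                f"{self.beta_m.index[i]!r}, sample {self.beta_m.columns[j]!r}: "
                f"m={m[i, j]}, h={h[i, j]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta_m.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta_m.columns


@dataclass
class FilterStage:
    """One QC stage's bookkeeping; kept + removed must equal input."""

    name: str
    rule: str
    probes_in: int
    probes_removed: int
    samples_in: int
    samples_removed: int

    @property
    def probes_out(self) -> int:
        return self.probes_in - self.probes_removed

    @property
    def samples_out(self) -> int:
        return self.samples_in - self.samples_removed


@dataclass
class FilterReport:
    """Ordered record of QC stages with conservation checks."""

    stages: list[FilterStage] = field(default_factory=list)

    def add(self, stage: FilterStage) -> None:
        if self.stages:
            prev = self.stages[-1]
            if stage.probes_in != prev.probes_out or stage.samples_in != prev.samples_out:
                raise ValidationError(
                    f"stage {stage.name!r} does not compose with {prev.name!r}: "
                    f"in=({stage.probes_in},{stage.samples_in}) "
                    f"vs previous out=({prev.probes_out},{prev.samples_out})"
                )
        self.stages.append(stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [s.name for s in self.stages],
                "rule": [s.rule for s in self.stages],
                "probes_in": [s.probes_in for s in self.stages],
                "probes_removed": [s.probes_removed for s in self.stages],
                "probes_out": [s.probes_out for s in self.stages],
                "samples_in": [s.samples_in for s in self.stages],
                "samples_removed": [s.samples_removed for s in self.stages],
                "samples_out": [s.samples_out for s in self.stages],
            }
        )

    def validate(self) -> None:
        for k, s in enumerate(self.stages):
            if s.probes_out != s.probes_in - s.probes_removed:
                raise ValidationError(f"stage {s.name!r}: probe arithmetic broken")
            if s.samples_out != s.samples_in - s.samples_removed:
                raise ValidationError(f"stage {s.name!r}: sample arithmetic broken")
            if k > 0:
                prev = self.stages[k - 1]
                if s.probes_in != prev.probes_out or s.samples_in != prev.samples_out:
                    raise ValidationError(
                        f"stage {s.name!r} input does not match previous output"
                    )


def check_manifest(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a probe manifest (indexed by probe_id).

    Required columns: chrom, pos (1-based position of the interrogated
    cytosine), gene_symbols (';'-separated, possibly empty), feature, masked.
    """
    required = {"chrom", "pos", "gene_symbols", "feature", "masked"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing column(s): {sorted(missing)}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"manifest: duplicate probe ids {dup[:5]}")
    if (df["pos"] < 1).any():
        bad = df.index[df["pos"] < 1][0]
        raise ValidationError(f"manifest: probe {bad!r} has pos < 1")
    return df


def check_chrom_states(df: pd.DataFrame) -> pd.DataFrame:
    """Validate chromatin-state intervals (BED4: chrom, start, end, state; 0-based half-open)."""
    required = ["chrom", "start", "end", "state"]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValidationError(f"chromatin states missing column(s): {sorted(missing)}")
    if (df["start"] < 0).any():
        raise ValidationError("chromatin states: negative start coordinate")
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise ValidationError(
            f"chromatin states: end <= start at {bad['chrom']}:{bad['start']}-{bad['end']}"
        )
    return df
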