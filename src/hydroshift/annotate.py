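"""Annotation of significant interaction probes (iDMCs).

Maps significant probes to manifest genes and features and to chromatin
states. Manifest positions are 1-based coordinates of the interrogated
cytosine; chromatin states are BED 0-based half-open intervals — the
conversion lives in exactly one place (:func:`probe_interval_query`).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import ValidationError, check_chrom_states

log = logging.getLogger(__name__)


def split_genes(field: str) -> list[str]:
    """Split a manifest gene field on ';', de-duplicated, order-preserving."""
    seen = []
    for g in str(field).split(";"):
        g = g.strip()
        if g and g not in seen:
            seen.append(g)
    return seen


def significant(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rows with q strictly below alpha (non-converged rows have no q)."""
    q = results["q"].to_numpy(dtype=float)
    return results[np.isfinite(q) & (q < alpha)]


def annotate_genes(
    results: pd.DataFrame, manifest: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, list[str]]:
    """Annotate significant probes with manifest genes/features.

    Returns the annotated table plus the globally de-duplicated gene list.
    A probe with an empty gene field is intergenic: it counts toward
    n_iDMCs but not n_genic_iDMCs; a multi-gene probe contributes each
    distinct symbol once, so the unique-gene count can exceed the genic
    probe count.
    """
    sig = significant(results, alpha)
    missing = [p for p in sig.index if p not in manifest.index]
    if missing:
        raise ValidationError(
            f"{len(missing)} significant probe(s) absent from manifest: {missing[:10]}"
        )
    genes_per_probe = [split_genes(manifest.loc[p, "gene_symbols"]) for p in sig.index]
    out = pd.DataFrame(
        {
            "chrom": [manifest.loc[p, "chrom"] for p in sig.index],
            "pos": [int(manifest.loc[p, "pos"]) for p in sig.index],
            "genes": [";".join(g) for g in genes_per_probe],
            "feature": [manifest.loc[p, "feature"] for p in sig.index],
            "b3": sig["b3"].to_numpy(),
            "q": sig["q"].to_numpy(),
            "direction": sig["direction"].to_numpy(),
        },
        index=sig.index,
    )
    unique_genes: list[str] = []
    for gl in genes_per_probe:
        for g in gl:
            if g not in unique_genes:
                unique_genes.append(g)
    n_genic = sum(1 for gl in genes_per_probe if gl)
    log.info(
        "annotate_genes: %d iDMCs, %d genic, %d unique genes",
        len(out), n_genic, len(unique_genes),
    )
    return out, unique_genes


def gene_counts(annotated: pd.DataFrame) -> tuple[int, int, int]:
    """(n_iDMCs, n_genic_iDMCs, n_unique_genes) from an annotated table."""
    gene_lists = [split_genes(g) for g in annotated["genes"]]
    uniq = {g for gl in gene_lists for g in gl}
    return len(annotated), sum(1 for gl in gene_lists if gl), len(uniq)


def probe_interval_query(
    chrom: str, pos_1based: int, trees: dict[str, IntervalTree]
) -> str | None:
    """State containing the probe's cytosine, or None.

    The 1-based manifest position p corresponds to 0-based coordinate p - 1;
    containment is evaluated against half-open [start, end) intervals. If
    several intervals cover the base, the tie-break is lexicographic by
    (start, end, state) — deterministic and logged by the caller.
    """
    tree = trees.get(chrom)
    if tree is None:
        return None
    hits = tree[pos_1based - 1]
    if not hits:
        return None
    best = sorted((iv.begin, iv.end, iv.data) for iv in hits)[0]
    return best[2]


def build_state_trees(states: pd.DataFrame) -> dict[str, IntervalTree]:
    check_chrom_states(states)
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in states.groupby("chrom"):
        trees[str(chrom)] = IntervalTree.from_tuples(
            (int(s), int(e), str(st))
            for s, e, st in zip(sub["start"], sub["end"], sub["state"])
        )
    return trees


def annotate_chromatin(
    annotated: pd.DataFrame, states: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign a chromatin state per probe and tabulate state frequencies.

    Probes falling in no interval get state ``None`` and are tallied under
    ``unassigned`` in the frequency table.
    """
    trees = build_state_trees(states)
    assigned = pd.Series(
        [
            probe_interval_query(str(c), int(p), trees)
            for c, p in zip(annotated["chrom"], annotated["pos"])
        ],
        index=annotated.index,
        name="chrom_state",
        dtype=object,
    )
    multi = 0
    for c, p in zip(annotated["chrom"], annotated["pos"]):
        t = trees.get(str(c))
        if t is not None and len(t[int(p) - 1]) > 1:
            multi += 1
    if multi:
        log.info("annotate_chromatin: %d probe(s) in overlapping intervals; "
                 "lexicographic tie-break applied", multi)
    labels = assigned.fillna("unassigned")
    freq = labels.value_counts()
    table = pd.DataFrame(
        {"count": freq, "proportion": freq / freq.sum() if len(freq) else freq}
    )
    table.index.name = "state"
    return assigned, table


def summarize_directions(results: pd.DataFrame, alpha: float = 0.05) -> tuple[int, int]:
    """(n_positive_b3, n_negative_b3) among significant probes.

    b3 == 0 counts toward the negative side, matching the direction
    convention (toward_mC).
    """
    sig = significant(results, alpha)
    b3 = sig["b3"].to_numpy(dtype=float)
    return int((b3 > 0).sum()), int((b3 <= 0).sum())


def feature_distribution(
    results: pd.DataFrame, manifest: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Counts and proportions per manifest feature class among significant probes."""
    sig = significant(results, alpha)
    if sig.empty:
        return pd.DataFrame(columns=["count", "proportion"])
    feats = pd.Series(
        [manifest.loc[p, "feature"] for p in sig.index], index=sig.index
    )
    counts = feats.value_counts()
    out = pd.DataFrame({"count": counts, "proportion": counts / counts.sum()})
    out.index.name = "feature"
    return out
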