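"""Multi-clone stability analysis after mutagenesis: counts-per-million
normalization, 2-fold-change categorization against a reference clone, and
the pooled-variance stability statistic.

Fold changes are computed on the linear scale with a pseudocount (a log2
option exists); the pooled variance is the degrees-of-freedom-weighted
combination of per-clone sample variances of those fold changes — a single
readout of how much a feature set moved after the mutagenic insult.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def normalize_cpm(raw_counts: pd.DataFrame, library_sizes: Mapping[str, float]) -> pd.DataFrame:
    """Counts-per-million: ``raw * 1e6 / library_size`` per clone column.

    Library sizes are total parsed reads per clone, not column sums, so
    features filtered out of the matrix do not distort the scaling.
    """
    sizes = pd.Series(library_sizes, dtype=float).reindex(raw_counts.columns)
    if sizes.isna().any():
        missing = list(sizes.index[sizes.isna()])
        raise ValueError(f"missing library sizes for clones: {missing}")
    if (sizes <= 0).any():
        bad = list(sizes.index[sizes <= 0])
        raise ValueError(f"library sizes must be > 0, offending clones: {bad}")
    return raw_counts * 1e6 / sizes


def min_count_filter(
    reference_counts: pd.Series, threshold: float = 100
) -> pd.Index:
    """Features whose raw count in the reference clone is strictly greater
    than ``threshold`` ("scored higher than N reads")."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    return reference_counts.index[reference_counts > threshold]


def fold_changes(
    normalized: pd.DataFrame,
    reference_clone: str,
    pseudocount: float = 1.0,
    log2: bool = False,
) -> pd.DataFrame:
    """Per-feature fold change of every non-reference clone versus the
    reference, on normalized counts: (x + pc) / (ref + pc)."""
    if reference_clone not in normalized.columns:
        raise ValueError(f"reference clone {reference_clone!r} not in matrix")
    ref = normalized[reference_clone] + pseudocount
    others = normalized.drop(columns=reference_clone)
    fc = others.add(pseudocount).div(ref, axis=0)
    return np.log2(fc) if log2 else fc


@dataclass
class StabilityReport:
    """Per-clone up/down/unchanged fractions at the fold-change criterion
    plus the pooled variance of fold changes across clones."""

    fractions: pd.DataFrame  # rows: clones; columns: up, down, unchanged
    pooled_variance: float
    fold_change_matrix: pd.DataFrame
    fold_threshold: float


def fold_change_categories(
    normalized: pd.DataFrame,
    reference_clone: str,
    fold_threshold: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Fraction of features up-/down-regulated/unchanged per clone.

    A feature is up if FC >= fold_threshold, down if FC <= 1/fold_threshold,
    else unchanged — an exact 2-fold change counts as changed.
    """
    if fold_threshold <= 1:
        raise ValueError(f"fold_threshold must be > 1, got {fold_threshold}")
    fc = fold_changes(normalized, reference_clone, pseudocount=pseudocount)
    up = (fc >= fold_threshold).mean()
    down = (fc <= 1.0 / fold_threshold).mean()
    out = pd.DataFrame({"up": up, "down": down})
    out["unchanged"] = 1.0 - out["up"] - out["down"]
    return out


def pooled_variance(fold_change_by_clone) -> float:
    """Pooled sample variance of fold changes across clones:
    sum((n_i - 1) * s_i^2) / sum(n_i - 1).

    Accepts a DataFrame (columns = clones) or a mapping clone -> values.
    Clones with fewer than 2 features are skipped with a warning; if every
    clone is skipped the statistic is undefined and an error is raised.
    Equals the ordinary sample variance when a single clone is supplied.
    """
    if isinstance(fold_change_by_clone, pd.DataFrame):
        groups = {c: fold_change_by_clone[c].to_numpy() for c in fold_change_by_clone.columns}
    else:
        groups = {k: np.asarray(v, dtype=float) for k, v in dict(fold_change_by_clone).items()}
    num = 0.0
    dof = 0
    for clone, values in groups.items():
        values = values[~np.isnan(values)]
        n = len(values)
        if n < 2:
            warnings.warn(f"clone {clone!r} has {n} usable features; skipped", stacklevel=2)
            continue
        num += (n - 1) * float(np.var(values, ddof=1))
        dof += n - 1
    if dof == 0:
        raise ValueError("no clone with >= 2 features; pooled variance undefined")
    return num / dof


def stability_report(
    raw_counts: pd.DataFrame,
    library_sizes: Mapping[str, float],
    reference_clone: str,
    fold_threshold: float = 2.0,
    pseudocount: float = 1.0,
    min_reference_count: float = 100,
) -> StabilityReport:
    """End-to-end stability readout: min-count filter on the reference,
    CPM normalization, fold-change categorization and pooled variance."""
    keep = min_count_filter(raw_counts[reference_clone], min_reference_count)
    filtered = raw_counts.loc[keep]
    if filtered.empty:
        raise ValueError("no feature passes the reference min-count filter")
    norm = normalize_cpm(filtered, library_sizes)
    fc = fold_changes(norm, reference_clone, pseudocount=pseudocount)
    fractions = fold_change_categories(
        norm, reference_clone, fold_threshold=fold_threshold, pseudocount=pseudocount
    )
    return StabilityReport(fractions, pooled_variance(fc), fc, fold_threshold)


def read_count_table(path) -> tuple:
    """Count-matrix TSV (first column feature_id, remaining columns clones)
    -> (DataFrame, clone names)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df, list(df.columns)


def read_library_sizes(path) -> dict:
    """Two-column TSV (clone, total parsed reads) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["clone", "size"], comment="#")
    return dict(zip(df["clone"], df["size"].astype(float)))
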