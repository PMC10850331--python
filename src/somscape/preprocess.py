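"""Raw counts -> centred log-fold-change (Delta-e) expression space.

The pipeline is: expression filter (CPM threshold derived from the median
library size, met in at least as many samples as the smallest replicate
class), TMM between-sample normalization factors, log2 CPM with an additive
prior, gene-wise centering so each gene's values become log2 fold changes
against its own mean over all samples, and optional replicate averaging to
(protocol, day) condition means.

The logCPM uses a fixed additive prior (``log2((y + p) / (N~ + 2p) * 1e6)``
with ``N~`` the TMM-effective library size); the expression filter is the
plain CPM-threshold rule stated above, without further edge-case
adjustments.  Both simplifications are deliberate so behaviour is exactly
the documented formulae.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from somscape.simulate import SEED_PROTOCOL


@dataclass
class NormalizationResult:
    """TMM factors and the effective library sizes they imply."""

    tmm_factors: pd.Series
    effective_library_sizes: pd.Series
    reference_sample: str


def group_sizes(metadata: pd.DataFrame) -> list[int]:
    """Replicate-class sizes: number of samples per (protocol, day) condition."""
    return metadata.groupby(["protocol", "day"]).size().tolist()


def filter_low_expression(
    counts: pd.DataFrame, group_sizes: list[int], min_count: int = 10
) -> pd.DataFrame:
    """Keep genes with at least ``min_count`` reads (as CPM) in enough samples.

    The CPM threshold is ``min_count / median(library size) * 1e6``; a gene
    is kept iff its CPM reaches the threshold in at least ``n`` samples,
    where ``n`` is the size of the smallest replicate class.
    """
    if min_count <= 0:
        raise ValueError("min_count must be positive")
    _check_counts(counts)
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    threshold = min_count / np.median(lib) * 1e6
    cpm = counts.to_numpy(dtype=float) / lib[None, :] * 1e6
    n_needed = min(group_sizes)
    keep = (cpm >= threshold).sum(axis=1) >= n_needed
    if not keep.any():
        raise ValueError("no genes pass the expression filter")
    return counts.loc[keep]


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.empty:
        raise ValueError("empty count matrix")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> NormalizationResult:
    """Trimmed-mean-of-M-values normalization factors.

    The reference is the sample whose upper-quartile CPM is closest to the
    mean upper quartile.  For every other sample, genes with a zero count in
    either sample are dropped, per-gene log2 expression ratios (M) and
    average log2 abundances (A) are computed, the fraction ``logratio_trim``
    is trimmed from each tail of M and ``sum_trim`` from each tail of A, and
    the factor is 2 to the precision-weighted mean of the surviving M values
    (delta-method inverse-variance weights).  Factors are rescaled to have
    geometric mean 1.  Ties at trim boundaries are broken by stable sort on
    gene identifier.
    """
    _check_counts(counts)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib == 0).any():
        bad = counts.columns[lib == 0].tolist()
        raise ValueError(f"samples with zero total count: {bad}")
    cpm = counts.to_numpy(dtype=float) / lib[None, :] * 1e6
    uq = np.quantile(cpm, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    y = counts.to_numpy(dtype=float)
    factors = np.array([
        _tmm_pair(y[:, k], lib[k], y[:, ref_idx], lib[ref_idx],
                  logratio_trim, sum_trim)
        for k in range(counts.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    tf = pd.Series(factors, index=counts.columns, name="tmm_factor")
    eff = pd.Series(lib * factors, index=counts.columns, name="effective_library_size")
    return NormalizationResult(tf, eff, str(counts.columns[ref_idx]))


def _tmm_pair(
    yk: np.ndarray, nk: float, yr: np.ndarray, nr: float,
    logratio_trim: float, sum_trim: float,
) -> float:
    ok = (yk > 0) & (yr > 0)
    yk, yr = yk[ok], yr[ok]
    if yk.size == 0:
        return 1.0
    m = np.log2((yk / nk) / (yr / nr))
    a = 0.5 * np.log2((yk / nk) * (yr / nr))
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    w = (nk - yk) / (nk * yk) + (nr - yr) / (nr * yr)
    keep = _double_trim(m, a, logratio_trim, sum_trim)
    if not keep.any():
        return 1.0
    return float(2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])))


def _double_trim(
    m: np.ndarray, a: np.ndarray, logratio_trim: float, sum_trim: float
) -> np.ndarray:
    """Mask of genes inside both tail trims; stable rank (original order breaks ties)."""
    n = m.size

    def inside(values: np.ndarray, frac: float) -> np.ndarray:
        lo = int(np.floor(n * frac))
        hi = n - lo
        order = np.argsort(values, kind="stable")
        rank = np.empty(n, dtype=int)
        rank[order] = np.arange(n)
        return (rank >= lo) & (rank < hi)

    return inside(m, logratio_trim) & inside(a, sum_trim)


def log_cpm(
    counts: pd.DataFrame, norm: NormalizationResult, prior_count: float = 3.0
) -> pd.DataFrame:
    """log2 counts per million with an additive prior and TMM-effective sizes."""
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    eff = norm.effective_library_sizes.reindex(counts.columns)
    if eff.isna().any():
        raise ValueError("normalization result does not cover all samples")
    y = counts.to_numpy(dtype=float)
    n = eff.to_numpy(dtype=float)[None, :]
    vals = np.log2((y + prior_count) / (n + 2.0 * prior_count) * 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def center_rows(log_expr: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's mean over all samples: Delta-e = e - <e>."""
    vals = log_expr.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("expression matrix contains non-finite values")
    return log_expr.sub(log_expr.mean(axis=1), axis=0)


def condition_label(protocol: str, day) -> str:
    return SEED_PROTOCOL if protocol == SEED_PROTOCOL else f"{protocol}_{day}"


def condition_of_samples(metadata: pd.DataFrame) -> pd.Series:
    """Sample id -> condition label (seed samples share one condition)."""
    lab = [condition_label(p, d) for p, d in zip(metadata["protocol"], metadata["day"])]
    return pd.Series(lab, index=metadata["sample_id"].to_numpy(), name="condition")


def average_replicates(expr: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Average replicate samples into (protocol, day) condition columns.

    Columns are ordered seed condition first, then by (protocol, day).
    """
    cond = condition_of_samples(metadata)
    missing = [s for s in expr.columns if s not in cond.index]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing}")
    meta = metadata.set_index("sample_id").loc[list(expr.columns)]
    order_key = sorted(
        {(condition_label(p, d), p != SEED_PROTOCOL, p, d)
         for p, d in zip(meta["protocol"], meta["day"])},
        key=lambda t: (t[1], t[2], t[3]),
    )
    ordered = [t[0] for t in order_key]
    grouped = expr.T.groupby(cond.loc[list(expr.columns)].to_numpy()).mean().T
    return grouped[ordered]


def preprocess_counts(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    min_count: int = 10,
    prior_count: float = 3.0,
) -> tuple[pd.DataFrame, NormalizationResult]:
    """Full preprocessing: filter, TMM, logCPM, gene centering.

    Returns the Delta-e (centred log2FC) matrix over individual samples and
    the normalization result.
    """
    filtered = filter_low_expression(counts, group_sizes(metadata), min_count)
    norm = tmm_factors(filtered)
    return center_rows(log_cpm(filtered, norm, prior_count)), norm
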