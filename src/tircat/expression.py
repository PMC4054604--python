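"""Expression quantification helpers and tissue-specificity statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Loci x conditions abundances plus condition metadata."""

    values: pd.DataFrame  # index = locus ids, columns = condition ids
    condition_type: str = "tissue_panel"  # or "erythroid_stage"
    library_sizes: dict | None = None

    def __post_init__(self):
        if (self.values.values < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.values.columns.duplicated().any():
            raise ValueError("condition ids must be unique")


def downsample_counts(counts, target_total, rng):
    """Hypergeometric down-sampling of per-locus counts without replacement."""
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if target_total > total:
        raise ValueError(f"target {target_total} exceeds total {total}")
    if target_total == total:
        return counts.copy()
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    return rng.multivariate_hypergeometric(counts, int(target_total))


def tmm_factors(count_matrix, stable_fraction=0.6, reference=None):
    """Simplified (unweighted) trimmed-mean-of-M-values scale factors.

    For each library the M-values (log2 ratio of within-library relative
    abundance vs the reference library) are computed on loci expressed in
    both; the central ``stable_fraction`` by M and by A is retained and the
    factor is 2**mean(retained M).  The reference is the library whose total
    is the median library size.
    """
    df = count_matrix if isinstance(count_matrix, pd.DataFrame) else pd.DataFrame(count_matrix)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 libraries")
    totals = df.sum(axis=0)
    if reference is None:
        reference = (totals - totals.median()).abs().idxmin()
    trim = (1.0 - stable_fraction) / 2.0
    ref = df[reference].to_numpy(dtype=float)
    ref_total = ref.sum()
    factors = {}
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        shared = (x > 0) & (ref > 0)
        if not shared.any():
            raise ValueError(f"library {col} shares no expressed loci with reference")
        p = x[shared] / x.sum()
        q = ref[shared] / ref_total
        m = np.log2(p / q)
        a = 0.5 * np.log2(p * q)
        keep = np.ones(len(m), dtype=bool)
        for v in (m, a):
            lo, hi = np.quantile(v, [trim, 1.0 - trim])
            keep &= (v >= lo) & (v <= hi)
        if not keep.any():
            keep[:] = True
        factors[col] = float(2.0 ** np.mean(m[keep]))
    return pd.Series(factors)


def fpkm(counts, length_bp, mapped_reads):
    """Fragments per kilobase of model per million mapped reads."""
    length_bp = np.asarray(length_bp, dtype=float)
    if np.any(length_bp <= 0):
        raise ValueError("length must be positive")
    if mapped_reads <= 0:
        raise ValueError("mapped_reads must be positive")
    counts = np.asarray(counts, dtype=float)
    return counts / (length_bp / 1e3) / (mapped_reads / 1e6)


def constitutive_exons(transcripts):
    """Bases present in every isoform's exon set, as (start, end) intervals.

    Falls back to the exon union (with a warning) when the intersection is
    empty.
    """
    if not transcripts:
        raise ValueError("need at least one transcript")

    def to_set(t):
        return set().union(*(range(s, e) for s, e in t.exons))

    common = to_set(transcripts[0])
    for t in transcripts[1:]:
        common &= to_set(t)
    if not common:
        warnings.warn("no constitutive bases; falling back to exon union")
        common = set()
        for t in transcripts:
            common |= to_set(t)
    return _bases_to_intervals(common)


def _bases_to_intervals(bases):
    out = []
    run_start = prev = None
    for b in sorted(bases):
        if run_start is None:
            run_start = prev = b
        elif b == prev + 1:
            prev = b
        else:
            out.append((run_start, prev + 1))
            run_start = prev = b
    if run_start is not None:
        out.append((run_start, prev + 1))
    return out


@dataclass
class TissueSpecificityResult:
    ts: np.ndarray  # fractional expression per condition; sums to 1
    max_ts: float
    argmax_condition: int
    fold_over_median: float  # alternate score: max / median (pseudocounted)


def tissue_specificity(expr, pseudocount=0.01):
    """Fractional-expression tissue specificity.

    Ts_i = x_i / sum(x); maxTs = max(Ts).  The alternate fold-over-median
    score is max(x) / median(x) with ``pseudocount`` guarding a zero median.
    Returns NaN fields for an all-zero vector.
    """
    x = np.asarray(expr, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a vector over >= 2 conditions")
    if (x < 0).any():
        raise ValueError("expression must be non-negative")
    total = x.sum()
    if total == 0:
        return TissueSpecificityResult(
            np.full(len(x), np.nan), float("nan"), -1, float("nan")
        )
    ts = x / total
    med = np.median(x)
    return TissueSpecificityResult(
        ts,
        float(ts.max()),
        int(ts.argmax()),
        float(x.max() / max(med, pseudocount)),
    )


def stage_detection(expr, detect_threshold=0.0):
    """Number of stages in which expression exceeds ``detect_threshold``."""
    x = np.asarray(expr, dtype=float)
    return int((x > detect_threshold).sum())
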