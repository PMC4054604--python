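"""Pairwise substitution distances and the constraint test against
G+C-matched neighboring ancestral repeats.

Distances come from closed-form estimators (JC69, K80, and a generalized
log-det form for the reversible model) on 4x4 site-pattern counts; gapped
and ambiguous columns are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .core import interval_distance

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# purine/pyrimidine partners for transition bookkeeping (A<->G, C<->T)
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class SaturationError(ValueError):
    """Observed divergence beyond the estimator's defined range."""


@dataclass
class AlignedPair:
    """Two gap-aligned sequences of equal length plus genomic metadata."""

    id: str
    seq_a: str
    seq_b: str
    kind: str = "locus"  # TIR | locus | exon | intron | AR
    anchor: object = None  # GenomicInterval on the reference genome
    gc: float = float("nan")

    def __post_init__(self):
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(f"pair {self.id}: unequal aligned lengths")
        allowed = set("ACGTN-")
        if set(self.seq_a) - allowed or set(self.seq_b) - allowed:
            raise ValueError(f"pair {self.id}: alphabet must be ACGTN-")
        if np.isnan(self.gc):
            try:
                self.gc = gc_content(self.seq_a.replace("-", ""))
            except ValueError:
                pass


def gc_content(sequence):
    """(G+C)/(A+C+G+T) over the ungapped sequence; Ns excluded."""
    seq = sequence.upper().replace("-", "")
    counts = {b: seq.count(b) for b in BASES}
    usable = sum(counts.values())
    if usable == 0:
        raise ValueError("no unambiguous bases")
    return (counts["G"] + counts["C"]) / usable


def count_site_patterns(pair):
    """4x4 joint base-count matrix; gap/N columns excluded.

    Returns (counts, n_used) with counts[i, j] = number of columns with base
    i in seq_a and base j in seq_b.
    """
    a = np.frombuffer(pair.seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(pair.seq_b.encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        lut[ord(base)] = idx
    ia, ib = lut[a], lut[b]
    mask = (ia >= 0) & (ib >= 0)
    n_used = int(mask.sum())
    if n_used == 0:
        raise ValueError(f"pair {pair.id}: no usable sites")
    counts = np.zeros((4, 4), dtype=np.int64)
    np.add.at(counts, (ia[mask], ib[mask]), 1)
    return counts, n_used


@dataclass
class DistanceEstimate:
    d: float
    model: str  # model actually used
    sites: int
    p_distance: float
    requested_model: str = ""
    fallback: bool = False


def _jc_distance(counts, n):
    p = (n - np.trace(counts)) / n
    if p >= 0.75:
        raise SaturationError(f"JC69 saturated (p = {p:.4f} >= 0.75)")
    return float(-0.75 * np.log1p(-4.0 * p / 3.0))


def _k80_distance(counts, n):
    ts = sum(
        counts[BASE_INDEX[x], BASE_INDEX[y]] for x, y in TRANSITIONS
    )
    p = ts / n
    q = (n - np.trace(counts) - ts) / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError("K80 saturated")
    return float(-0.5 * np.log(w1) - 0.25 * np.log(w2))


def _gtr_distance(counts, n):
    # generalized (log-det style) distance on the symmetrized joint matrix
    f = (counts + counts.T) / (2.0 * n)
    pi = f.sum(axis=1)
    if (pi <= 0).any():
        raise SaturationError("GTR undefined: missing base in composition")
    m = np.diag(1.0 / pi) @ f
    logm = linalg.logm(m)
    if np.iscomplexobj(logm):
        if np.abs(logm.imag).max() > 1e-8:
            raise SaturationError("GTR log has complex branch")
        logm = logm.real
    d = -float(np.trace(np.diag(pi) @ logm))
    if not np.isfinite(d) or d < 0:
        raise SaturationError("GTR distance not finite/non-negative")
    return d


_ESTIMATORS = {"JC69": _jc_distance, "K80": _k80_distance, "GTR": _gtr_distance}
_FALLBACK = {"GTR": "K80", "K80": "JC69"}


def estimate_distance(counts, model="GTR", allow_fallback=True):
    """Substitutions per site from a 4x4 pattern-count matrix.

    On numerical failure the estimator falls back GTR -> K80 -> JC69 (flagged
    in the result); JC69 saturation raises SaturationError.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n = int(counts.sum())
    if n == 0:
        raise ValueError("no usable sites")
    p_dist = float((n - np.trace(counts)) / n)
    requested = model
    current = model
    while True:
        try:
            d = _ESTIMATORS[current](counts, n)
            return DistanceEstimate(
                d, current, n, p_dist, requested, current != requested
            )
        except SaturationError:
            if not allow_fallback or current not in _FALLBACK:
                raise
            current = _FALLBACK[current]


def match_ancestral_repeats(element, ars, max_dist=500_000, gc_tol=0.05):
    """Pool site-pattern counts of nearby, G+C-matched ancestral repeats.

    ARs must lie within ``max_dist`` bp (edge-to-edge) of the element anchor
    without overlapping it, and within ``gc_tol`` of the element's G+C
    content; when none matches the tolerance, the single nearest-GC AR in
    range is used with a warning.  Raises when no AR is in range at all.
    """
    in_range = []
    for ar in ars:
        if ar.anchor is None or element.anchor is None:
            raise ValueError("anchors required for AR matching")
        if ar.anchor.chrom != element.anchor.chrom:
            continue
        d = interval_distance(element.anchor, ar.anchor)
        if d == 0:  # overlapping ARs are excluded
            continue
        if d < max_dist:
            in_range.append(ar)
    if not in_range:
        raise ValueError(f"element {element.id}: no ancestral repeat within range")
    matched = [ar for ar in in_range if abs(ar.gc - element.gc) <= gc_tol]
    if not matched:
        matched = [min(in_range, key=lambda ar: abs(ar.gc - element.gc))]
        warnings.warn(
            f"element {element.id}: no AR within GC tolerance; "
            f"using nearest-GC AR {matched[0].id}"
        )
    pooled = np.zeros((4, 4), dtype=np.int64)
    for ar in matched:
        counts, _ = count_site_patterns(ar)
        pooled += counts
    return pooled, [ar.id for ar in matched]


@dataclass
class ConstraintResult:
    element_id: str
    d_element: float
    d_ar: float
    relative_rate: float
    matched_ar_ids: list = field(default_factory=list)


def constraint_test(elements, ars, model="GTR", max_dist=500_000, gc_tol=0.05):
    """Per-element substitution rate vs pooled matched-AR rate.

    Returns (results, summary) where summary carries group medians and the
    two-tailed Mann-Whitney p comparing element and AR distance
    distributions.  Elements without any AR in range are skipped with a
    warning; an all-skipped input raises.
    """
    results = []
    for el in elements:
        try:
            ar_counts, ar_ids = match_ancestral_repeats(el, ars, max_dist, gc_tol)
        except ValueError as exc:
            warnings.warn(str(exc))
            continue
        el_counts, _ = count_site_patterns(el)
        d_el = estimate_distance(el_counts, model).d
        d_ar = estimate_distance(ar_counts, model).d
        rel = d_el / d_ar if d_ar > 0 else float("inf")
        results.append(ConstraintResult(el.id, d_el, d_ar, rel, ar_ids))
    if not results:
        raise ValueError("all elements skipped: no matchable ancestral repeats")
    if len(results) < 3:
        raise ValueError("need >= 3 scorable elements for the group comparison")
    d_elements = np.array([r.d_element for r in results])
    d_ars = np.array([r.d_ar for r in results])
    mw = stats.mannwhitneyu(d_elements, d_ars, alternative="two-sided")
    summary = {
        "n": len(results),
        "median_d_element": float(np.median(d_elements)),
        "median_d_ar": float(np.median(d_ars)),
        "median_relative_rate": float(np.median([r.relative_rate for r in results])),
        "p_value": float(mw.pvalue),
    }
    return results, summary


def read_pair_fasta(path, element_id=None, kind="locus", anchor=None):
    """Read a two-record aligned FASTA into an AlignedPair."""
    names, seqs = [], []
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                names.append(line[1:].split()[0])
                seqs.append([])
                current = seqs[-1]
            elif line and current is not None:
                current.append(line)
    if len(seqs) != 2:
        raise ValueError(f"{path}: expected exactly 2 records, got {len(seqs)}")
    return AlignedPair(
        element_id or names[0],
        "".join(seqs[0]),
        "".join(seqs[1]),
        kind=kind,
        anchor=anchor,
    )


def write_pair_fasta(pair, path, names=("ref", "alt")):
    with open(path, "w") as fh:
        fh.write(f">{names[0]} {pair.id}\n{pair.seq_a}\n")
        fh.write(f">{names[1]} {pair.id}\n{pair.seq_b}\n")
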