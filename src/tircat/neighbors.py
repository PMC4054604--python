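"""Gene territories, interval permutation enrichment, and the neighbor
expression fold-difference statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import GenomicInterval, interval_distance, merge_intervals, overlap_length


@dataclass(frozen=True)
class Territory:
    gene_id: str
    interval: GenomicInterval


def gene_territories(coding_genes, genome):
    """Partition each chromosome into per-gene territories.

    The boundary between consecutive genes is the midpoint of the intergenic
    gap (gene-body edges); chromosome ends belong to the terminal genes.
    Overlapping genes are merged into a single territory holder whose id
    joins the member ids with "|".
    """
    by_chrom = {}
    for g in coding_genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    territories = []
    for chrom, genes in sorted(by_chrom.items()):
        if chrom not in genome:
            continue
        genes = sorted(genes, key=lambda g: (g.start, g.end))
        # merge overlapping/abutting gene bodies into holders
        holders = []  # (start, end, [ids])
        for g in genes:
            if holders and g.start < holders[-1][1]:
                s, e, ids = holders[-1]
                holders[-1] = (s, max(e, g.end), ids + [g.name])
            else:
                holders.append((g.start, g.end, [g.name]))
        chrom_len = genome.length(chrom)
        bounds = [0]
        for (s1, e1, _), (s2, e2, _) in zip(holders, holders[1:]):
            bounds.append((e1 + s2) // 2)
        bounds.append(chrom_len)
        for (s, e, ids), lo, hi in zip(holders, bounds, bounds[1:]):
            territories.append(
                Territory("|".join(ids), GenomicInterval(chrom, lo, hi, ".", "|".join(ids)))
            )
    return territories


@dataclass
class EnrichmentResult:
    observed: int
    permuted_mean: float
    fold: float
    p_value: float
    n_permutations: int
    seed: int


def _count_hits(queries, targets, mode):
    """Number of query intervals hitting any target.

    mode "midpoint": the query midpoint must fall inside a target;
    mode "overlap": >= 1 bp overlap suffices.
    """
    by_chrom = {}
    for t in targets:
        by_chrom.setdefault(t.chrom, []).append(t)
    hits = 0
    for q in queries:
        cands = by_chrom.get(q.chrom, ())
        if mode == "midpoint":
            mid = q.midpoint
            if any(t.start <= mid < t.end for t in cands):
                hits += 1
        else:
            if any(overlap_length(q, t) >= 1 for t in cands):
                hits += 1
    return hits


def _random_placements(lengths, segments, rng):
    """Place intervals of given lengths uniformly at random within segments.

    Each interval picks a segment with probability proportional to the number
    of valid start positions, then a uniform start.  Placements are
    independent draws and may overlap each other.
    """
    chroms = [s.chrom for s in segments]
    starts = np.array([s.start for s in segments], dtype=np.int64)
    sizes = np.array([s.length for s in segments], dtype=np.int64)
    lengths = np.asarray(lengths, dtype=np.int64)
    placed = [None] * len(lengths)
    for length in np.unique(lengths):
        valid = np.maximum(0, sizes - length + 1)
        total = int(valid.sum())
        if total == 0:
            raise ValueError(f"no intergenic segment can hold a {length}-bp interval")
        where = np.flatnonzero(lengths == length)
        # uniform draw over the concatenation of all valid start positions
        u = rng.integers(0, total, size=len(where))
        cum = np.cumsum(valid)
        seg_idx = np.searchsorted(cum, u, side="right")
        offs = u - (cum[seg_idx] - valid[seg_idx])
        for i, si, off in zip(where, seg_idx, offs):
            start = int(starts[si] + off)
            placed[i] = GenomicInterval(chroms[si], start, start + int(length))
    return placed


def _enrichment(queries, targets, intergenic_space, n_perm, seed, mode):
    queries = list(queries)
    targets = list(targets)
    rng = np.random.default_rng(seed)
    observed = _count_hits(queries, targets, mode)
    lengths = [q.length for q in queries]
    perm_counts = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        placed = _random_placements(lengths, intergenic_space, rng)
        perm_counts[i] = _count_hits(placed, targets, mode)
    permuted_mean = float(perm_counts.mean())
    fold = observed / permuted_mean if permuted_mean > 0 else float("inf")
    p = (1 + int((perm_counts >= observed).sum())) / (n_perm + 1)
    return EnrichmentResult(observed, permuted_mean, fold, p, n_perm, seed)


def territory_enrichment(
    query_intervals, selected_territories, intergenic_space,
    n_perm=1000, seed=0, mode="midpoint",
):
    """Enrichment of queries inside selected gene territories.

    The null places same-length intervals uniformly at random within the
    intergenic space; the empirical p uses the add-one estimator
    (1 + #{perm >= obs}) / (n_perm + 1).
    """
    targets = [t.interval for t in selected_territories]
    return _enrichment(query_intervals, targets, intergenic_space, n_perm, seed, mode)


def overlap_enrichment(set_a, set_b, intergenic_space, n_perm=1000, seed=0):
    """Enrichment of overlap between two interval sets (same null machinery)."""
    return _enrichment(set_a, set_b, intergenic_space, n_perm, seed, "overlap")


def intergenic_segments(coding_genes, genome):
    """Complement of the merged coding-gene bodies over the genome."""
    merged = {c: [] for c in genome.chrom_names}
    for iv in merge_intervals(coding_genes):
        if iv.chrom in merged:
            merged[iv.chrom].append(iv)
    out = []
    for chrom in genome.chrom_names:
        pos = 0
        for iv in merged[chrom]:
            if iv.start > pos:
                out.append(GenomicInterval(chrom, pos, iv.start))
            pos = max(pos, iv.end)
        if pos < genome.length(chrom):
            out.append(GenomicInterval(chrom, pos, genome.length(chrom)))
    return out


def pair_loci(lncrnas, coding_genes, order="nearest"):
    """Pair each locus with its closest coding gene, or the gene beyond it.

    "nearest": minimal edge-to-edge distance (ties: leftmost start, then
    name).  "next_but_one": the nearest gene on the far side of the nearest
    gene, i.e. adjacent to it in the direction away from the locus; None
    when no such gene exists.

    Returns a list of (locus, gene-or-None, distance-or-None).
    """
    if order not in ("nearest", "next_but_one"):
        raise ValueError(f"unknown order {order!r}")
    by_chrom = {}
    for g in coding_genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda g: (g.start, g.name))
    pairs = []
    for lnc in lncrnas:
        genes = by_chrom.get(lnc.chrom, [])
        if not genes:
            pairs.append((lnc, None, None))
            continue
        keyed = sorted(
            (interval_distance(lnc, g), g.start, g.name, i)
            for i, g in enumerate(genes)
        )
        d, _, _, i = keyed[0]
        nearest = genes[i]
        if order == "nearest":
            pairs.append((lnc, nearest, d))
            continue
        # far side of the nearest gene relative to the locus
        if nearest.midpoint < lnc.midpoint:
            j = i - 1
        else:
            j = i + 1
        if 0 <= j < len(genes):
            g2 = genes[j]
            pairs.append((lnc, g2, interval_distance(lnc, g2)))
        else:
            pairs.append((lnc, None, None))
    return pairs


@dataclass
class DeltaResult:
    reference_id: str
    neighbor_id: str
    stage_min: int
    stage_max: int
    delta: float


def delta(reference_expr, neighbor_expr, epsilon=0.01,
          reference_id="", neighbor_id=""):
    """Fold difference of the neighbor between the reference's extreme stages.

    stage_max/stage_min are the argmax/argmin of the reference (earliest
    stage on ties).  Neighbor values below ``epsilon`` are floored to it
    before the ratio, so delta = (max(nb[max], eps) - max(nb[min], eps)) /
    max(nb[min], eps); a constant neighbor still gives exactly 0.  Returns
    NaN with a warning when the reference is constant across stages.
    """
    ref = np.asarray(reference_expr, dtype=float)
    nb = np.asarray(neighbor_expr, dtype=float)
    if ref.shape != nb.shape or ref.ndim != 1:
        raise ValueError("paired stage vectors required")
    stage_max = int(ref.argmax())
    stage_min = int(ref.argmin())
    if ref[stage_max] == ref[stage_min]:
        warnings.warn("reference constant across stages; delta undefined")
        return DeltaResult(reference_id, neighbor_id, stage_min, stage_max, float("nan"))
    lo = max(nb[stage_min], epsilon)
    hi = max(nb[stage_max], epsilon)
    value = (hi - lo) / lo
    return DeltaResult(reference_id, neighbor_id, stage_min, stage_max, float(value))


def compare_delta_distributions(deltas_a, deltas_b):
    """Medians and two-tailed Mann-Whitney p for two delta samples."""
    a = np.asarray([d for d in deltas_a if np.isfinite(d)], dtype=float)
    b = np.asarray([d for d in deltas_b if np.isfinite(d)], dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 finite values per group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(np.median(a)), float(np.median(b)), float(res.pvalue)


def foldchange_correlation(lnc_fc, gene_fc):
    """Pearson correlation between paired fold-change vectors."""
    x = np.asarray(lnc_fc, dtype=float)
    y = np.asarray(gene_fc, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("paired vectors of length >= 3 required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(x, y).statistic)
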