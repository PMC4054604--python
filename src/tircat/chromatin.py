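"""Chromatin-mark quantification around initiation regions and
enhancer-like vs promoter-like classification.

Scores are per-million-normalized coverage sums in a window centred on the
region midpoint; a region is enhancer_like when the H3K4me1 score exceeds
the H3K4me3 score and promoter_like in the opposite case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import read_bedgraph

ENHANCER_LIKE = "enhancer_like"
PROMOTER_LIKE = "promoter_like"
AMBIGUOUS = "ambiguous"


class ChromatinTrack:
    """Per-base coverage for one mark with an attached library size."""

    def __init__(self, mark, genome, coverage=None, library_size=None):
        self.mark = mark
        self.genome = genome
        self.coverage = coverage or {
            chrom: np.zeros(length, dtype=np.float64)
            for chrom, length in genome.chrom_lengths.items()
        }
        for vec in self.coverage.values():
            if (vec < 0).any():
                raise ValueError("coverage must be non-negative")
        if library_size is None:
            library_size = float(sum(v.sum() for v in self.coverage.values()))
        if library_size <= 0:
            raise ValueError("library_size must be positive")
        self.library_size = float(library_size)

    @classmethod
    def from_bedgraph(cls, mark, path, genome, library_size=None):
        cov = read_bedgraph(path)
        coverage = {
            chrom: np.zeros(length, dtype=np.float64)
            for chrom, length in genome.chrom_lengths.items()
        }
        for chrom, spans in cov.items():
            if chrom not in coverage:
                continue
            vec = coverage[chrom]
            for start, end, value in spans:
                vec[start : min(end, len(vec))] += value
        return cls(mark, genome, coverage, library_size)

    def window_sum(self, chrom, lo, hi):
        vec = self.coverage[chrom]
        return float(vec[max(lo, 0) : min(hi, len(vec))].sum())


def quantify_mark(track, regions, window=2000):
    """Per-region normalized score.

    score = coverage summed over [mid - window/2, mid + window/2) x 1e6 /
    library size, with the window clipped at chromosome edges.
    """
    half = window // 2
    scores = np.empty(len(regions))
    for i, r in enumerate(regions):
        mid = r.midpoint
        scores[i] = track.window_sum(r.chrom, mid - half, mid + half)
    return scores * 1e6 / track.library_size


@dataclass(frozen=True)
class TirClassification:
    region_id: str
    me1_score: float
    me3_score: float
    diff: float
    log2_ratio: float
    label: str


def classify_regions(region_ids, me1_scores, me3_scores, pseudocount=1.0):
    """Classify regions by the sign of the me1 - me3 normalized score."""
    me1 = np.asarray(me1_scores, dtype=float)
    me3 = np.asarray(me3_scores, dtype=float)
    if len(me1) != len(me3) or len(me1) != len(region_ids):
        raise ValueError("paired score vectors required")
    if (me1 < 0).any() or (me3 < 0).any():
        raise ValueError("scores must be non-negative")
    out = []
    for rid, a, b in zip(region_ids, me1, me3):
        diff = a - b
        label = ENHANCER_LIKE if diff > 0 else PROMOTER_LIKE if diff < 0 else AMBIGUOUS
        out.append(
            TirClassification(
                rid,
                float(a),
                float(b),
                float(diff),
                float(np.log2((a + pseudocount) / (b + pseudocount))),
                label,
            )
        )
    return out


def classification_table(classifications):
    return pd.DataFrame(
        [
            (c.region_id, c.me1_score, c.me3_score, c.diff, c.log2_ratio, c.label)
            for c in classifications
        ],
        columns=["id", "me1", "me3", "diff", "log2ratio", "label"],
    ).set_index("id")


@dataclass
class SignalMatrix:
    values: np.ndarray  # regions x bins, row order per ``row_ids``
    row_ids: list
    offsets: np.ndarray  # bin start offsets relative to region midpoint
    window: int
    bin: int

    def to_frame(self):
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.offsets)


def _region_profile(track, region, window, nbins, bin_size):
    """Mean normalized coverage per bin across the window (zeros off-genome)."""
    half = window // 2
    mid = region.midpoint
    vec = track.coverage[region.chrom]
    lo, hi = mid - half, mid + half
    padded = np.zeros(window)
    s, e = max(lo, 0), min(hi, len(vec))
    if e > s:
        padded[s - lo : e - lo] = vec[s:e]
    return padded.reshape(nbins, bin_size).mean(axis=1) * 1e6 / track.library_size


def signal_matrix(track, regions, window=4000, bin=50, sort_by=None):
    """Per-region binned signal across a midpoint-centred window ("hotpile").

    Rows are ordered by descending ``sort_by`` (default: input order kept
    when sort_by is None); values are mean per-million coverage per bin.
    """
    if window % bin != 0:
        raise ValueError("window must be divisible by bin")
    nbins = window // bin
    values = np.empty((len(regions), nbins))
    for i, r in enumerate(regions):
        values[i] = _region_profile(track, r, window, nbins, bin)
    ids = [r.name if r.name != "." else f"region{i}" for i, r in enumerate(regions)]
    if sort_by is not None:
        sort_by = np.asarray(sort_by, dtype=float)
        if len(sort_by) != len(regions):
            raise ValueError("sort_by must match regions")
        order = np.argsort(-sort_by, kind="stable")
        values = values[order]
        ids = [ids[i] for i in order]
    offsets = np.arange(nbins) * bin - window // 2
    return SignalMatrix(values, ids, offsets, window, bin)


def metaprofile(track, regions, window=4000, bin=50):
    """Column means of the signal matrix ("quantpile").

    Minus-strand rows are reversed first so that positive offsets always
    point in the direction of transcription.
    """
    if not regions:
        raise ValueError("empty region set")
    mat = signal_matrix(track, regions, window=window, bin=bin)
    values = mat.values.copy()
    for i, r in enumerate(regions):
        if r.strand == "-":
            values[i] = values[i][::-1]
    return values.mean(axis=0)


def stranded_tss_profile(tags, tss_list, flank=50):
    """Sense/antisense tag 5'-end counts per offset around each TSS ("SRP").

    ``tss_list`` holds stranded intervals whose 5' end is the anchor.
    Returns two vectors of length 2*flank + 1 covering offsets
    [-flank, +flank] in transcription direction, summed over all TSSs.
    """
    n = 2 * flank + 1
    sense = np.zeros(n, dtype=np.int64)
    antisense = np.zeros(n, dtype=np.int64)
    for region in tss_list:
        anchor = region.five_prime()
        for strand in ("+", "-"):
            pos, cnt = tags.positions(region.chrom, strand)
            if len(pos) == 0:
                continue
            offsets = pos - anchor
            if region.strand == "-":
                offsets = -offsets
            target = sense if strand == region.strand else antisense
            mask = (offsets >= -flank) & (offsets <= flank)
            np.add.at(target, offsets[mask] + flank, cnt[mask])
    return sense, antisense


def tag_density_track(tags, window=100, step=10):
    """Sliding-window tag density per strand, bedGraph-like.

    Windows start at multiples of ``step`` and span ``window`` bp; only
    windows containing at least one tag are emitted.
    """
    out = {}  # (chrom, strand) -> list of (start, end, count)
    for chrom, strand in tags.keys():
        pos, cnt = tags.positions(chrom, strand)
        if len(pos) == 0:
            continue
        first = max(0, (int(pos[0]) - window + step) // step)
        last = int(pos[-1]) // step
        rows = []
        for k in range(first, last + 1):
            w_start = k * step
            w_end = w_start + window
            mask = (pos >= w_start) & (pos < w_end)
            count = int(cnt[mask].sum())
            if count > 0:
                rows.append((w_start, w_end, count))
        out[(chrom, strand)] = rows
    return out
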