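"""Transcriptional-initiation-region (TIR) calling.

Single-base 5'-end tag positions are clustered per strand (single linkage,
gap <= 20 bp), clusters within 400 bp on the same strand are merged into
TIRs, and TIRs are filtered by read support (>= 5) and DNase-hypersensitive
site overlap before being associated with transcript models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import GenomicInterval, overlap_length

DEFAULT_MAX_GAP = 20
DEFAULT_MERGE_DIST = 400
DEFAULT_MIN_READS = 5
DEFAULT_TSS_WINDOW = 50


class TagSet:
    """Per-(chrom, strand) sorted single-base 5' positions with multiplicity."""

    def __init__(self):
        self._data = {}  # (chrom, strand) -> {pos: count}

    def add(self, chrom, strand, position, count=1):
        if strand not in ("+", "-"):
            raise ValueError(f"tags must be stranded, got {strand!r}")
        if count < 1:
            raise ValueError("multiplicity must be >= 1")
        key = (chrom, strand)
        self._data.setdefault(key, {})
        self._data[key][position] = self._data[key].get(position, 0) + count

    def keys(self):
        return sorted(self._data)

    def positions(self, chrom, strand):
        """(positions, counts) as sorted numpy arrays."""
        d = self._data.get((chrom, strand), {})
        pos = np.array(sorted(d), dtype=np.int64)
        cnt = np.array([d[p] for p in pos], dtype=np.int64)
        return pos, cnt

    def total_tags(self):
        return sum(c for d in self._data.values() for c in d.values())

    def __len__(self):
        return sum(len(d) for d in self._data.values())

    @classmethod
    def from_bed(cls, intervals):
        """Build from BED6 records: one single-base record per read 5' end.

        A record's score, when >= 1, is taken as tag multiplicity.
        """
        tags = cls()
        for iv in intervals:
            if iv.length != 1:
                raise ValueError(
                    f"tag record {iv.chrom}:{iv.start}-{iv.end} is not single-base"
                )
            count = int(iv.score) if iv.score >= 1 else 1
            tags.add(iv.chrom, iv.strand, iv.start, count)
        return tags

    def to_bed(self):
        out = []
        for chrom, strand in self.keys():
            pos, cnt = self.positions(chrom, strand)
            for p, c in zip(pos, cnt):
                out.append(GenomicInterval(chrom, int(p), int(p) + 1, strand, "tag", int(c)))
        out.sort(key=lambda iv: (iv.chrom, iv.start, iv.strand))
        return out


@dataclass
class TagCluster:
    chrom: str
    strand: str
    start: int  # min member position
    end: int  # max member position + 1
    n_reads: int
    member_positions: list

    @property
    def span(self):
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass
class TIR:
    id: str
    chrom: str
    strand: str
    start: int
    end: int
    n_reads: int
    member_clusters: list = field(default_factory=list)
    dhs_overlap: bool = False
    linked_transcript_ids: list = field(default_factory=list)

    @property
    def span(self):
        return GenomicInterval(
            self.chrom, self.start, self.end, self.strand, self.id, self.n_reads
        )


def cluster_tags(tags, max_gap=DEFAULT_MAX_GAP):
    """Single-linkage clustering of tag positions per (chrom, strand).

    Consecutive positions whose gap is <= ``max_gap`` join one cluster
    (gap = difference between adjacent single-base positions).
    """
    clusters = []
    for chrom, strand in tags.keys():
        pos, cnt = tags.positions(chrom, strand)
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for chunk_pos, chunk_cnt in zip(
            np.split(pos, breaks), np.split(cnt, breaks)
        ):
            clusters.append(
                TagCluster(
                    chrom,
                    strand,
                    int(chunk_pos[0]),
                    int(chunk_pos[-1]) + 1,
                    int(chunk_cnt.sum()),
                    [int(p) for p in chunk_pos],
                )
            )
    clusters.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return clusters


def merge_clusters(clusters, merge_dist=DEFAULT_MERGE_DIST):
    """Merge same-strand clusters whose edge-to-edge gap is <= ``merge_dist``.

    Merging is transitive; the TIR span is the hull of its member clusters.
    """
    by_key = {}
    for c in clusters:
        by_key.setdefault((c.chrom, c.strand), []).append(c)
    tirs = []
    for (chrom, strand), group in by_key.items():
        group.sort(key=lambda c: c.start)
        current = [group[0]]
        for c in group[1:]:
            gap = c.start - max(m.end for m in current)
            if gap <= merge_dist:
                current.append(c)
            else:
                tirs.append(_make_tir(chrom, strand, current))
                current = [c]
        tirs.append(_make_tir(chrom, strand, current))
    tirs.sort(key=lambda t: (t.chrom, t.start, t.strand))
    for i, t in enumerate(tirs):
        t.id = f"TIR{i + 1:05d}"
    return tirs


def _make_tir(chrom, strand, members):
    return TIR(
        id="",
        chrom=chrom,
        strand=strand,
        start=min(m.start for m in members),
        end=max(m.end for m in members),
        n_reads=sum(m.n_reads for m in members),
        member_clusters=list(members),
    )


def filter_tirs(tirs, dhs_peaks, min_reads=DEFAULT_MIN_READS, min_overlap=1):
    """Keep TIRs with read support >= ``min_reads`` that overlap a DHS peak.

    DHS peaks are strandless; overlap must be >= ``min_overlap`` bp with at
    least one peak.
    """
    dhs_by_chrom = {}
    for p in dhs_peaks:
        dhs_by_chrom.setdefault(p.chrom, []).append(p)
    kept = []
    for t in tirs:
        if t.n_reads < min_reads:
            continue
        span = t.span
        t.dhs_overlap = any(
            overlap_length(span, p) >= min_overlap
            for p in dhs_by_chrom.get(t.chrom, ())
        )
        if t.dhs_overlap:
            kept.append(t)
    return kept


def _exon_overlap(tir, transcript, min_overlap):
    span = tir.span
    return any(
        overlap_length(span, GenomicInterval(transcript.chrom, s, e)) >= min_overlap
        for s, e in transcript.exons
    )


def _covers_window(tir, position, window):
    # TIR span intersects [position - window, position + window]
    return tir.start <= position + window and tir.end > position - window


def associate_transcripts(
    tirs, transcripts, min_overlap=1, tss_window=DEFAULT_TSS_WINDOW
):
    """Link TIRs to transcripts and impute strand for mono-exonic ones.

    A stranded transcript links to a TIR when strands match, the TIR overlaps
    an exon by >= ``min_overlap`` bp, and the TIR intersects the window
    [TSS - tss_window, TSS + tss_window] around the transcript 5' end.

    A mono-exonic strand-"." transcript is linked only when exactly one of
    its two ends has candidate TIRs (a "+" TIR at the left end or a "-" TIR
    at the right end); its strand is then set so that end is 5'.

    Returns ``(links, linked_transcripts)`` where links is a sorted list of
    (tir_id, transcript_id) pairs and linked_transcripts carries imputed
    strands; transcripts with no link are dropped.
    """
    tirs_by_chrom = {}
    for t in tirs:
        tirs_by_chrom.setdefault(t.chrom, []).append(t)

    links = []
    linked = []
    for tr in transcripts:
        candidates = tirs_by_chrom.get(tr.chrom, ())
        if tr.strand in ("+", "-"):
            tss = tr.tss()
            hits = [
                t
                for t in candidates
                if t.strand == tr.strand
                and _exon_overlap(t, tr, min_overlap)
                and _covers_window(t, tss, tss_window)
            ]
            if hits:
                linked.append(tr)
                for t in hits:
                    links.append((t.id, tr.id))
                    t.linked_transcript_ids.append(tr.id)
        else:
            left_hits = [
                t
                for t in candidates
                if t.strand == "+"
                and _exon_overlap(t, tr, min_overlap)
                and _covers_window(t, tr.start, tss_window)
            ]
            right_hits = [
                t
                for t in candidates
                if t.strand == "-"
                and _exon_overlap(t, tr, min_overlap)
                and _covers_window(t, tr.end - 1, tss_window)
            ]
            if bool(left_hits) == bool(right_hits):
                continue  # no candidate end, or ambiguous both-end case
            hits = left_hits or right_hits
            tr.strand = "+" if left_hits else "-"
            linked.append(tr)
            for t in hits:
                links.append((t.id, tr.id))
                t.linked_transcript_ids.append(tr.id)
    links.sort()
    return links, linked


def tir_support_expression_correlation(n_reads, fpkm, pseudocount=0.01):
    """Pearson r between log10 TIR read support and log10(FPKM + pseudocount)."""
    n_reads = np.asarray(n_reads, dtype=float)
    fpkm = np.asarray(fpkm, dtype=float)
    if len(n_reads) != len(fpkm):
        raise ValueError("paired vectors required")
    if len(n_reads) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.log10(n_reads)
    y = np.log10(fpkm + pseudocount)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in log-transformed values")
    return float(stats.pearsonr(x, y).statistic)
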