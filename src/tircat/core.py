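"""Genome model, interval arithmetic and plain-text genomics I/O.

Coordinates are 0-based half-open throughout (BED native).  GTF input is
converted on read (start - 1) and converted back on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """Malformed record in an input file; message names the line number."""


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome names and lengths.

    Parameters
    ----------
    chrom_lengths : dict
        Ordered mapping of chromosome name to length in bp.
    """

    chrom_lengths: dict

    def __post_init__(self):
        if not self.chrom_lengths:
            raise ValueError("genome must have at least one chromosome")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chrom_names(self):
        return list(self.chrom_lengths)

    def __contains__(self, chrom):
        return chrom in self.chrom_lengths

    def length(self, chrom):
        return self.chrom_lengths[chrom]

    @classmethod
    def read_chrom_sizes(cls, path):
        lengths = {}
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise ParseError(f"{path}:{i}: expected 2 columns")
                lengths[fields[0]] = int(fields[1])
        return cls(lengths)

    def write_chrom_sizes(self, path):
        with open(path, "w") as fh:
            for name, length in self.chrom_lengths.items():
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval with optional strand, name and score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float = 0.0

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self):
        return self.end - self.start

    @property
    def length(self):
        return self.end - self.start

    @property
    def midpoint(self):
        return (self.start + self.end) // 2

    def five_prime(self):
        """0-based coordinate of the 5' end (requires a definite strand)."""
        if self.strand == "+":
            return self.start
        if self.strand == "-":
            return self.end - 1
        raise ValueError("5' end undefined for strand '.'")

    def three_prime(self):
        if self.strand == "+":
            return self.end - 1
        if self.strand == "-":
            return self.start
        raise ValueError("3' end undefined for strand '.'")

    def with_(self, **kwargs):
        return replace(self, **kwargs)


def overlap_length(a, b):
    """Overlap in bp between two intervals; 0 on different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def interval_distance(a, b):
    """Edge-to-edge distance in bp; 0 if overlapping or abutting."""
    if a.chrom != b.chrom:
        raise ValueError("distance undefined across chromosomes")
    if a.start < b.end and b.start < a.end:
        return 0
    return max(a.start, b.start) - min(a.end, b.end)


def nearest_feature(query, features, exclude_self=False):
    """Closest feature to ``query`` by edge-to-edge distance.

    Ties break to the leftmost start, then lexicographically smallest name.
    Returns ``(None, None)`` when no feature shares the query's chromosome.
    """
    best = None
    best_key = None
    for f in features:
        if f.chrom != query.chrom:
            continue
        if exclude_self and f is query:
            continue
        d = interval_distance(query, f)
        key = (d, f.start, f.name)
        if best_key is None or key < best_key:
            best, best_key = f, key
    if best is None:
        return None, None
    return best, best_key[0]


def merge_intervals(intervals):
    """Union of intervals per chromosome (strand ignored), sorted."""
    by_chrom = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


@dataclass
class TranscriptModel:
    """A transcript with ordered, disjoint exons.

    ``strand`` may be "." for mono-exonic transcripts prior to imputation.
    ``coding_potential`` is one of {"coding", "noncoding", "unknown"}.
    """

    id: str
    chrom: str
    strand: str
    exons: list  # list of (start, end), sorted, non-overlapping
    coding_potential: str = "unknown"
    pseudogene_overlap: bool = False
    gene_id: str = ""

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = -1
        for s, e in self.exons:
            if s < 0 or s >= e:
                raise ValueError(f"transcript {self.id}: bad exon ({s},{e})")
            if s < prev_end:
                raise ValueError(f"transcript {self.id}: overlapping exons")
            prev_end = e
        if self.strand == "." and len(self.exons) > 1:
            raise ValueError(f"multi-exonic transcript {self.id} must be stranded")

    @property
    def start(self):
        return self.exons[0][0]

    @property
    def end(self):
        return self.exons[-1][1]

    @property
    def span(self):
        return GenomicInterval(self.chrom, self.start, self.end, self.strand, self.id)

    @property
    def mature_length(self):
        return sum(e - s for s, e in self.exons)

    def tss(self):
        """0-based coordinate of the 5'-most transcribed base."""
        return self.span.five_prime()


# ---------------------------------------------------------------------------
# BED


def read_bed(path):
    """Read BED3/BED6 into GenomicInterval records."""
    intervals = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{i}: expected >=3 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else "."
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
                strand = fields[5] if len(fields) > 5 else "."
                intervals.append(GenomicInterval(chrom, start, end, strand, name, score))
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: {exc}") from exc
    return intervals


def write_bed(intervals, path, columns=6):
    with open(path, "w") as fh:
        for iv in intervals:
            if columns <= 3:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                score = int(iv.score) if float(iv.score).is_integer() else iv.score
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
                )


# ---------------------------------------------------------------------------
# BED12 / GTF transcripts


def read_bed12(path):
    transcripts = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{i}: expected 12 BED columns")
            try:
                chrom, start = f[0], int(f[1])
                name, strand = f[3], f[5]
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
                transcripts.append(TranscriptModel(name, chrom, strand, exons))
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: {exc}") from exc
    return transcripts


def _gtf_attributes(text):
    attrs = {}
    for part in text.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path):
    """Read exon features from a GTF file into TranscriptModel records.

    1-based inclusive GTF coordinates are converted to 0-based half-open.
    """
    exons = {}  # transcript_id -> (chrom, strand, gene_id, [(s,e)...])
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ParseError(f"{path}:{i}: expected 9 GTF columns")
            if f[2] != "exon":
                continue
            try:
                chrom, start, end, strand = f[0], int(f[3]) - 1, int(f[4]), f[6]
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: {exc}") from exc
            attrs = _gtf_attributes(f[8])
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ParseError(f"{path}:{i}: missing transcript_id")
            rec = exons.setdefault(tid, (chrom, strand, attrs.get("gene_id", ""), []))
            rec[3].append((start, end))
    out = []
    for tid, (chrom, strand, gene_id, ex) in exons.items():
        out.append(TranscriptModel(tid, chrom, strand, ex, gene_id=gene_id))
    out.sort(key=lambda t: (t.chrom, t.start, t.id))
    return out


def write_gtf(transcripts, path, source="tircat"):
    with open(path, "w") as fh:
        for t in transcripts:
            for s, e in t.exons:
                attrs = f'gene_id "{t.gene_id or t.id}"; transcript_id "{t.id}";'
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# bedGraph and matrices


def read_bedgraph(path):
    """Read a bedGraph into a dict chrom -> list of (start, end, value)."""
    cov = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 4:
                raise ParseError(f"{path}:{i}: expected 4 bedGraph columns")
            try:
                cov.setdefault(f[0], []).append((int(f[1]), int(f[2]), float(f[3])))
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: {exc}") from exc
    for chrom in cov:
        cov[chrom].sort()
    return cov


def write_bedgraph(cov, path):
    with open(path, "w") as fh:
        for chrom in sorted(cov):
            for start, end, value in cov[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_matrix(path):
    """TSV with header row = condition names, first column = locus id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df, path):
    df.to_csv(path, sep="\t")
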