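"""lncRNA cataloguing: intragenic/bidirectional/intergenic partition,
noncoding filters, elncRNA/plncRNA class assignment, orientation classes,
transposable-element density and CpG-island overlap.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromatin import AMBIGUOUS, ENHANCER_LIKE, PROMOTER_LIKE
from .core import (
    GenomicInterval,
    interval_distance,
    merge_intervals,
    nearest_feature,
    overlap_length,
)

INTRAGENIC = "intragenic"
BIDIRECTIONAL = "bidirectional"
INTERGENIC = "intergenic"

ELNCRNA = "elncRNA"
PLNCRNA = "plncRNA"

HEAD_TO_HEAD = "head_to_head"
TAIL_TO_TAIL = "tail_to_tail"
TAIL_TO_HEAD = "tail_to_head"
HEAD_TO_TAIL = "head_to_tail"

DEFAULT_BIDIRECTIONAL_WINDOW = 1000
DEFAULT_MIN_LEN = 200


@dataclass
class LncRnaRecord:
    transcript_id: str
    category: str
    passed_filter: bool = False
    lnc_class: str = "none"
    tir_id: str = ""
    nearest_gene_id: str = ""
    orientation: str = ""
    tss_distance: int = -1
    te_density_tir: float = float("nan")
    te_density_exons: float = float("nan")
    cpg_overlap: bool = False
    mature_length: int = 0
    n_exons: int = 0


def locate_transcript(
    transcript,
    coding_genes,
    coding_tirs,
    transcript_tir,
    bidirectional_window=DEFAULT_BIDIRECTIONAL_WINDOW,
):
    """Category of a TIR-linked transcript.

    intragenic: any-strand overlap >= 1 bp between the transcript span and a
    coding gene body.  bidirectional: its TIR lies on the opposite strand
    within ``bidirectional_window`` bp (edge-to-edge) of a coding-gene TIR,
    or overlaps one.  Otherwise intergenic.
    """
    span = transcript.span
    for gene in coding_genes:
        if overlap_length(span, gene) >= 1:
            return INTRAGENIC
    tir_span = transcript_tir.span
    for ct in coding_tirs:
        if ct.chrom != tir_span.chrom or ct.strand == tir_span.strand:
            continue
        if interval_distance(tir_span, ct.span) <= bidirectional_window:
            return BIDIRECTIONAL
    return INTERGENIC


def lncrna_filter(transcript, min_len=DEFAULT_MIN_LEN):
    """True iff mature length > min_len, flagged noncoding, no pseudogene hit."""
    if transcript.coding_potential == "unknown":
        warnings.warn(
            f"transcript {transcript.id} has unknown coding potential; excluded"
        )
        return False
    return (
        transcript.mature_length > min_len
        and transcript.coding_potential == "noncoding"
        and not transcript.pseudogene_overlap
    )


def assign_class(label):
    """Map a chromatin label to a lncRNA class."""
    if label == ENHANCER_LIKE:
        return ELNCRNA
    if label == PROMOTER_LIKE:
        return PLNCRNA
    if label == AMBIGUOUS:
        return "none"
    raise ValueError(f"unknown chromatin label {label!r}")


def orientation(lnc, gene):
    """Relative orientation class of a non-overlapping lncRNA/gene pair.

    The facing ends decide: 5'-vs-5' is head_to_head, 3'-vs-3' tail_to_tail,
    lncRNA-3' facing gene-5' tail_to_head and lncRNA-5' facing gene-3'
    head_to_tail.
    """
    if lnc.chrom == gene.chrom and overlap_length(lnc, gene) > 0:
        raise ValueError("orientation undefined for overlapping pair")
    lnc_left_of_gene = lnc.start < gene.start
    # the end of each element facing the other, as "head" (5') or "tail" (3')
    if lnc_left_of_gene:
        lnc_facing = "tail" if lnc.strand == "+" else "head"
        gene_facing = "head" if gene.strand == "+" else "tail"
    else:
        lnc_facing = "head" if lnc.strand == "+" else "tail"
        gene_facing = "tail" if gene.strand == "+" else "head"
    return {
        ("head", "head"): HEAD_TO_HEAD,
        ("tail", "tail"): TAIL_TO_TAIL,
        ("tail", "head"): TAIL_TO_HEAD,
        ("head", "tail"): HEAD_TO_TAIL,
    }[(lnc_facing, gene_facing)]


def te_density(intervals, te_annotation):
    """Fraction of interval bases covered by the union of TE annotations."""
    intervals = list(intervals)
    total = sum(iv.length for iv in intervals)
    if total == 0:
        return 0.0
    union = merge_intervals(te_annotation) if te_annotation else []
    covered = sum(
        overlap_length(iv, te) for iv in intervals for te in union
    )
    return covered / total


def cpg_overlap(tir_span, cpg_islands, min_overlap=2):
    """True iff the TIR overlaps a CpG island by >= ``min_overlap`` bp."""
    return any(overlap_length(tir_span, c) >= min_overlap for c in cpg_islands)


def build_catalog(
    transcripts,
    transcript_tirs,
    coding_genes,
    coding_tirs,
    tir_classifications,
    te_annotation=(),
    cpg_islands=(),
    bidirectional_window=DEFAULT_BIDIRECTIONAL_WINDOW,
    min_len=DEFAULT_MIN_LEN,
):
    """Apply the full decision tree to TIR-linked transcripts.

    ``transcript_tirs`` maps transcript id -> TIR; ``tir_classifications``
    maps TIR id -> TirClassification.  Returns one LncRnaRecord per
    transcript (category recorded for all; lnc_class only for intergenic
    lncRNAs with an unambiguous TIR classification).
    """
    class_by_tir = {c.region_id: c.label for c in tir_classifications.values()} \
        if isinstance(tir_classifications, dict) else {
            c.region_id: c.label for c in tir_classifications
        }
    records = []
    for tr in transcripts:
        tir = transcript_tirs[tr.id]
        category = locate_transcript(
            tr, coding_genes, coding_tirs, tir, bidirectional_window
        )
        rec = LncRnaRecord(
            transcript_id=tr.id,
            category=category,
            tir_id=tir.id,
            mature_length=tr.mature_length,
            n_exons=len(tr.exons),
        )
        if category == INTERGENIC and lncrna_filter(tr, min_len=min_len):
            rec.passed_filter = True
            if tir.id not in class_by_tir:
                raise ValueError(f"TIR {tir.id} has no chromatin classification")
            rec.lnc_class = assign_class(class_by_tir[tir.id])
            gene, dist = nearest_feature(tr.span, coding_genes)
            if gene is not None:
                rec.nearest_gene_id = gene.name
                if dist > 0:
                    rec.orientation = orientation(tr.span, gene)
                rec.tss_distance = abs(tr.tss() - gene.five_prime())
            rec.te_density_tir = te_density([tir.span], te_annotation)
            rec.te_density_exons = te_density(
                [GenomicInterval(tr.chrom, s, e) for s, e in tr.exons], te_annotation
            )
            rec.cpg_overlap = cpg_overlap(tir.span, cpg_islands)
        records.append(rec)
    return records


def catalog_table(records):
    columns = [f.name for f in dataclasses.fields(LncRnaRecord)]
    return pd.DataFrame(
        [vars(r) for r in records], columns=columns
    ).set_index("transcript_id")


def catalog_summary(records):
    """Per-class counts, mono-exonic fractions and medians."""
    rows = {}
    lnc = [r for r in records if r.lnc_class in (ELNCRNA, PLNCRNA)]
    for cls in (ELNCRNA, PLNCRNA):
        members = [r for r in lnc if r.lnc_class == cls]
        if not members:
            rows[cls] = dict.fromkeys(
                ["count", "fraction", "monoexonic_fraction", "median_length",
                 "median_tss_distance"],
                np.nan,
            )
            rows[cls]["count"] = 0
            continue
        rows[cls] = {
            "count": len(members),
            "fraction": len(members) / len(lnc),
            "monoexonic_fraction": np.mean([r.n_exons == 1 for r in members]),
            "median_length": float(np.median([r.mature_length for r in members])),
            "median_tss_distance": float(
                np.median([r.tss_distance for r in members if r.tss_distance >= 0])
            )
            if any(r.tss_distance >= 0 for r in members)
            else np.nan,
        }
    return pd.DataFrame(rows).T
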