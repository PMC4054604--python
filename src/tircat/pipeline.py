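"""End-to-end orchestration over a bundle directory.

Stages run in dependency order (TIR calling -> chromatin classification ->
catalogue -> expression -> neighbors -> evolution); every record dropped at
a filter is tallied by reason, and the machine-readable report echoes the
configuration and seed so reruns are byte-identical.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from . import catalog as cat
from . import chromatin, evolution, expression, neighbors, tir
from .core import (
    GenomeModel,
    overlap_length,
    read_bed,
    read_gtf,
    read_matrix,
    write_bed,
)

REPORT_SCHEMA_VERSION = 1

DEFAULT_PARAMS = {
    "max_gap": 20,
    "merge_dist": 400,
    "min_reads": 5,
    "min_overlap": 1,
    "tss_window": 50,
    "quant_window": 2000,
    "pseudocount": 1.0,
    "bidirectional_window": 1000,
    "min_len": 200,
    "detect_threshold": 0.0,
    "fold_thresholds": [2, 5, 10],
    "n_perm": 200,
    "max_dist_AR": 500_000,
    "gc_tol": 0.05,
    "model": "GTR",
    "seed": 0,
}


def _read_kinds(path):
    kinds = {}
    with open(path) as fh:
        for line in fh:
            pid, kind = line.split()
            kinds[pid] = kind
    return kinds


def _load_pairs(bundle_dir, anchors, kinds):
    pairs = []
    aln_dir = os.path.join(bundle_dir, "alignments")
    for anchor in anchors:
        path = os.path.join(aln_dir, f"{anchor.name}.fa")
        pair = evolution.read_pair_fasta(
            path, element_id=anchor.name,
            kind=kinds.get(anchor.name, "locus"), anchor=anchor,
        )
        pairs.append(pair)
    return pairs


def run_pipeline(bundle_dir, outdir, params=None):
    """Run every stage on a bundle directory; returns the report dict."""
    p = dict(DEFAULT_PARAMS)
    if params:
        p.update(params)
    os.makedirs(outdir, exist_ok=True)
    report = {"schema_version": REPORT_SCHEMA_VERSION, "params": p, "stages": {}}

    genome = GenomeModel.read_chrom_sizes(_need(bundle_dir, "chrom.sizes"))
    tags = tir.TagSet.from_bed(read_bed(_need(bundle_dir, "tags.bed")))
    dhs = read_bed(_need(bundle_dir, "dhs.bed"))
    transcripts = read_gtf(_need(bundle_dir, "transcripts.gtf"))
    coding_genes = read_bed(_need(bundle_dir, "coding_genes.bed"))
    flags = {}
    with open(_need(bundle_dir, "coding_flags.tsv")) as fh:
        for line in fh:
            tid, flag = line.split()
            flags[tid] = flag
    pseudogenes = read_bed(_need(bundle_dir, "pseudogene.bed"))
    for t in transcripts:
        t.coding_potential = flags.get(t.id, "unknown")
        t.pseudogene_overlap = any(
            overlap_length(t.span, pg) >= 1 for pg in pseudogenes
        )

    # --- TIR calling --------------------------------------------------------
    clusters = tir.cluster_tags(tags, max_gap=p["max_gap"])
    tirs = tir.merge_clusters(clusters, merge_dist=p["merge_dist"])
    filtered = tir.filter_tirs(tirs, dhs, min_reads=p["min_reads"],
                               min_overlap=p["min_overlap"])
    links, linked_transcripts = tir.associate_transcripts(
        filtered, transcripts, min_overlap=p["min_overlap"],
        tss_window=p["tss_window"],
    )
    report["stages"]["tir_calling"] = {
        "n_tags": tags.total_tags(),
        "n_clusters": len(clusters),
        "n_tirs": len(tirs),
        "n_filtered_tirs": len(filtered),
        "dropped": {
            "low_support_or_no_dhs": len(tirs) - len(filtered),
        },
        "n_links": len(links),
        "n_linked_transcripts": len(linked_transcripts),
        "n_unlinked_transcripts": len(transcripts) - len(linked_transcripts),
    }
    write_bed([t.span for t in filtered], os.path.join(outdir, "tirs.bed"))
    with open(os.path.join(outdir, "tir_links.tsv"), "w") as fh:
        for tid, trid in links:
            fh.write(f"{tid}\t{trid}\n")

    # --- chromatin classification ------------------------------------------
    me1 = chromatin.ChromatinTrack.from_bedgraph(
        "H3K4me1", _need(bundle_dir, "me1.bedgraph"), genome)
    me3 = chromatin.ChromatinTrack.from_bedgraph(
        "H3K4me3", _need(bundle_dir, "me3.bedgraph"), genome)
    regions = [t.span for t in filtered]
    me1_scores = chromatin.quantify_mark(me1, regions, window=p["quant_window"])
    me3_scores = chromatin.quantify_mark(me3, regions, window=p["quant_window"])
    classifications = chromatin.classify_regions(
        [t.id for t in filtered], me1_scores, me3_scores,
        pseudocount=p["pseudocount"],
    )
    class_table = chromatin.classification_table(classifications)
    class_table.to_csv(os.path.join(outdir, "tir_classes.tsv"), sep="\t")
    label_counts = class_table["label"].value_counts().to_dict()
    report["stages"]["chromatin"] = {
        "n_classified": len(classifications),
        "labels": {k: int(v) for k, v in sorted(label_counts.items())},
    }

    # --- lncRNA catalogue ---------------------------------------------------
    tir_by_id = {t.id: t for t in filtered}
    tr_by_id = {t.id: t for t in linked_transcripts}
    transcript_tirs = {}
    for tid, trid in links:
        tr = tr_by_id[trid]
        t = tir_by_id[tid]
        prev = transcript_tirs.get(trid)
        # keep the TIR whose span is closest to the transcript 5' end
        def _tss_gap(x):
            tss = tr.tss()
            return min(abs(x.start - tss), abs(x.end - 1 - tss))
        if prev is None or _tss_gap(t) < _tss_gap(prev):
            transcript_tirs[trid] = t
    coding_tirs = sorted(
        {transcript_tirs[t.id].id: transcript_tirs[t.id]
         for t in linked_transcripts
         if t.coding_potential == "coding" and t.id in transcript_tirs}.values(),
        key=lambda t: (t.chrom, t.start, t.strand),
    )
    te = read_bed(_need(bundle_dir, "te.bed"))
    cpg = read_bed(_need(bundle_dir, "cpg.bed"))
    records = cat.build_catalog(
        [t for t in linked_transcripts if t.id in transcript_tirs],
        transcript_tirs, coding_genes, coding_tirs,
        {c.region_id: c for c in classifications},
        te_annotation=te, cpg_islands=cpg,
        bidirectional_window=p["bidirectional_window"], min_len=p["min_len"],
    )
    cat_table = cat.catalog_table(records)
    cat_table.to_csv(os.path.join(outdir, "catalog.tsv"), sep="\t")
    lnc = [r for r in records if r.passed_filter]
    n_by_class = {
        "elncRNA": sum(r.lnc_class == "elncRNA" for r in lnc),
        "plncRNA": sum(r.lnc_class == "plncRNA" for r in lnc),
        "ambiguous": sum(r.lnc_class == "none" for r in lnc),
    }
    report["stages"]["catalog"] = {
        "n_transcripts": len(records),
        "categories": {
            c: sum(r.category == c for r in records)
            for c in (cat.INTRAGENIC, cat.BIDIRECTIONAL, cat.INTERGENIC)
        },
        "n_intergenic_lncrna": len(lnc),
        "classes": n_by_class,
    }

    # --- expression ---------------------------------------------------------
    tissue = read_matrix(_need(bundle_dir, "tissue_expression.tsv"))
    stage = read_matrix(_need(bundle_dir, "stage_expression.tsv"))
    lnc_gene_ids = sorted({r.transcript_id.rsplit(".", 1)[0] for r in lnc})
    max_ts = {}
    for lid in lnc_gene_ids:
        if lid in tissue.index:
            res = expression.tissue_specificity(tissue.loc[lid].to_numpy())
            max_ts[lid] = res.max_ts
    stage_counts = {
        lid: expression.stage_detection(stage.loc[lid].to_numpy(),
                                        p["detect_threshold"])
        for lid in lnc_gene_ids if lid in stage.index
    }
    cls_of = {r.transcript_id.rsplit(".", 1)[0]: r.lnc_class for r in lnc}
    report["stages"]["expression"] = {
        "median_max_ts": {
            c: _median([v for k, v in max_ts.items() if cls_of.get(k) == c])
            for c in ("elncRNA", "plncRNA")
        },
        "stage_detection_counts": {
            str(k): int(sum(1 for v in stage_counts.values() if v == k))
            for k in range(4)
        },
    }

    # --- neighbor association ----------------------------------------------
    territories = neighbors.gene_territories(coding_genes, genome)
    intergenic = neighbors.intergenic_segments(coding_genes, genome)
    gene_expr = {
        g.name: float(stage.loc[g.name].iloc[0]) if g.name in stage.index else 0.0
        for g in coding_genes
    }
    med_expr = float(np.median(list(gene_expr.values()))) if gene_expr else 0.0
    lnc_tir_spans = [
        tir_by_id[r.tir_id].span for r in lnc if r.tir_id in tir_by_id
    ]
    enrich = {}
    for fold_thr in p["fold_thresholds"]:
        selected = [
            t for t in territories
            if max(gene_expr.get(g, 0.0) for g in t.gene_id.split("|"))
            >= fold_thr * med_expr
        ]
        if not selected or not lnc_tir_spans:
            continue
        res = neighbors.territory_enrichment(
            lnc_tir_spans, selected, intergenic,
            n_perm=p["n_perm"], seed=p["seed"],
        )
        enrich[f"{fold_thr}x"] = {
            "observed": res.observed, "permuted_mean": res.permuted_mean,
            "fold": res.fold, "p_value": res.p_value,
        }
    deltas = {"elncRNA": [], "plncRNA": []}
    pairs = neighbors.pair_loci(
        [tr_by_id[r.transcript_id].span for r in lnc], coding_genes)
    span_class = {r.transcript_id: r.lnc_class for r in lnc}
    for lnc_span, gene, _dist in pairs:
        if gene is None:
            continue
        lid = lnc_span.name.rsplit(".", 1)[0]
        if lid not in stage.index or gene.name not in stage.index:
            continue
        ref = stage.loc[lid].to_numpy()
        nb = stage.loc[gene.name].to_numpy()
        if (expression.stage_detection(ref, p["detect_threshold"]) == 0
                or expression.stage_detection(nb, p["detect_threshold"]) == 0):
            continue
        d = neighbors.delta(ref, nb, reference_id=lid, neighbor_id=gene.name)
        c = span_class.get(lnc_span.name, "none")
        if c in deltas:
            deltas[c].append(d.delta)
    delta_summary = {
        c: {"n": len(v), "median": _median(v)} for c, v in deltas.items()
    }
    if len(deltas["elncRNA"]) >= 3 and len(deltas["plncRNA"]) >= 3:
        m_a, m_b, pval = neighbors.compare_delta_distributions(
            deltas["elncRNA"], deltas["plncRNA"])
        delta_summary["rank_test_p"] = pval
    report["stages"]["neighbors"] = {
        "n_territories": len(territories),
        "territory_enrichment": enrich,
        "delta": delta_summary,
    }

    # --- molecular evolution ------------------------------------------------
    anchors_path = os.path.join(bundle_dir, "element_anchors.bed")
    if os.path.exists(anchors_path):
        anchors = read_bed(anchors_path)
        kinds = _read_kinds(_need(bundle_dir, "element_kinds.tsv"))
        pairs_all = _load_pairs(bundle_dir, anchors, kinds)
        ars = [q for q in pairs_all if q.kind == "AR"]
        elements = [q for q in pairs_all if q.kind != "AR"]
        evo = {}
        for cls in ("elncRNA", "plncRNA"):
            tir_ids = {r.tir_id for r in lnc if r.lnc_class == cls}
            lnc_ids = {r.transcript_id.rsplit(".", 1)[0]
                       for r in lnc if r.lnc_class == cls}
            els = [e for e in elements
                   if e.id.rsplit("_", 1)[0] in lnc_ids]
            if len(els) < 3:
                continue
            results, summary = evolution.constraint_test(
                els, ars, model=p["model"],
                max_dist=p["max_dist_AR"], gc_tol=p["gc_tol"],
            )
            evo[cls] = summary
        report["stages"]["evolution"] = evo

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return report


def _need(bundle_dir, name):
    path = os.path.join(bundle_dir, name)
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing pipeline input: {path}")
    return path


def _median(values):
    values = [v for v in values if np.isfinite(v)]
    return float(np.median(values)) if values else None


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
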