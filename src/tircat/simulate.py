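"""Synthetic input generation with planted ground truth.

Lays out coding genes and lncRNAs on a small genome, then fabricates every
file the pipeline consumes: 5'-end tag positions, DHS peaks, H3K4me1/me3
coverage, transcript models, TE/CpG/pseudogene annotations, expression
matrices, and aligned sequence pairs evolved at planted rates next to
neutral ancestral repeats.  All randomness flows through one seeded
generator so a config + seed pair reproduces the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .core import (
    GenomeModel,
    GenomicInterval,
    TranscriptModel,
    write_bed,
    write_bedgraph,
    write_gtf,
    write_matrix,
)
from .evolution import AlignedPair, write_pair_fasta
from .tir import TagSet

BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 400_000
    genes_per_chrom: int = 8
    lnc_per_chrom: int = 6
    n_bidirectional: int = 2
    n_intragenic: int = 2
    frac_strandless_monoexonic: float = 0.5
    # nanoCAGE emulation
    cage_mean: float = 50.0
    cage_disp: float = 10.0
    jitter_sd: float = 2.0
    dhs_width: int = 200
    # chromatin marks (me1:me3 split per class)
    ratio_enh: tuple = (4.0, 1.0)
    ratio_prom: tuple = (1.0, 4.0)
    chip_depth: float = 100.0
    mark_halfwidth: int = 1000
    mark_bin: int = 50
    # expression
    n_tissues: int = 8
    dirichlet_enh: float = 0.2
    dirichlet_prom: float = 2.0
    n_stages: int = 3
    coupling_alpha_enh: float = 1.0
    coupling_alpha_prom: float = 0.0
    # annotations
    te_density_enh: float = 0.4
    te_density_prom: float = 0.1
    cpg_prob_enh: float = 0.1
    cpg_prob_prom: float = 0.8
    # molecular evolution
    neutral_d: float = 0.165
    rate_factor_enh: float = 1.0
    rate_factor_prom: float = 0.8
    element_length: int = 1000
    ar_length: int = 1000
    ars_per_element: int = 2

    def __post_init__(self):
        block = self.chrom_length // self.genes_per_chrom
        if block < 40_000:
            raise ValueError(
                "infeasible layout: need >= 40 kb per gene block "
                f"(got {block} bp); reduce genes_per_chrom or grow the genome"
            )
        if self.lnc_per_chrom > self.genes_per_chrom:
            raise ValueError("infeasible layout: more lncRNAs than gene blocks")


@dataclass
class TruthRecord:
    locus_id: str
    locus_type: str  # coding | lnc
    chrom: str
    strand: str
    tss: int
    span: tuple
    category: str = ""  # intergenic | bidirectional | intragenic (lnc only)
    lnc_class: str = ""  # elncRNA | plncRNA
    neighbor_gene: str = ""
    coupling_alpha: float = 0.0
    expression_mean: float = float("nan")
    substitution_rate: float = float("nan")


@dataclass
class Bundle:
    config: SimulationConfig
    genome: GenomeModel
    truth: dict  # locus_id -> TruthRecord
    tags: TagSet
    dhs: list
    transcripts: list
    coding_genes: list  # GenomicInterval, name = gene id
    coding_flags: dict  # transcript_id -> coding|noncoding
    me1_cov: dict  # chrom -> list of (start, end, value)
    me3_cov: dict
    te: list
    cpg: list
    pseudogenes: list
    tissue_expr: pd.DataFrame
    stage_expr: pd.DataFrame
    elements: list  # AlignedPair per lnc TIR
    ars: list


# ---------------------------------------------------------------------------
# elementary generators


def sample_cage_tags(tss, n_reads, jitter_sd, chrom_length, rng):
    """Tag positions: ``tss`` + discretized normal jitter, clipped to chrom."""
    if n_reads == 0:
        return np.empty(0, dtype=np.int64)
    jitter = np.rint(rng.normal(0.0, jitter_sd, size=n_reads)).astype(np.int64)
    return np.clip(tss + jitter, 0, chrom_length - 1)


def _nb_draw(rng, mean, disp):
    # negative binomial parameterized by mean and dispersion (size)
    p = disp / (disp + mean)
    return int(rng.negative_binomial(disp, p))


def random_sequence(length, gc, rng):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def _jc_rate_matrix():
    q = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(q, -1.0)
    return q


def evolve_pair(sequence, d, rng, model="JC69", Q=None, element_id="pair",
                kind="locus", anchor=None, indel_rate=0.0, indel_mean_len=3.0):
    """Evolve ``sequence`` along a branch of length ``d`` substitutions/site.

    ``model`` may be "JC69" or "GTR" (the latter requires a normalized rate
    matrix ``Q``).  With ``indel_rate`` > 0, gap runs of geometric length are
    opened in the derived sequence to exercise gap-aware site counting.
    """
    if d < 0:
        raise ValueError("branch length must be >= 0")
    if model == "JC69":
        Q = _jc_rate_matrix()
    elif Q is None:
        raise ValueError("GTR evolution requires an explicit rate matrix Q")
    P = linalg.expm(Q * d)
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    lut = {b: i for i, b in enumerate("ACGT")}
    idx = np.array([lut[b] for b in sequence.upper()])
    # per-site draw of the derived base from the row of P for the source base
    u = rng.random(len(idx))
    cdf = np.cumsum(P, axis=1)
    derived_idx = (u[:, None] > cdf[idx]).sum(axis=1)
    derived = list("ACGT"[i] for i in derived_idx)
    seq_a = list(sequence.upper())
    if indel_rate > 0:
        i = 0
        while i < len(derived):
            if rng.random() < indel_rate:
                run = 1 + int(rng.geometric(1.0 / indel_mean_len))
                for j in range(i, min(i + run, len(derived))):
                    derived[j] = "-"
                i += run
            else:
                i += 1
    return AlignedPair(element_id, "".join(seq_a), "".join(derived),
                       kind=kind, anchor=anchor)


def simulate_neighbor_pairs(n_pairs, alpha, rng, n_stages=3, base_log2=3.0,
                            sd_ref=1.5, sd_noise=0.5):
    """Stage-expression for reference loci and (optionally coupled) neighbors.

    Neighbor log2 expression = alpha * centred reference log2 + base + noise.
    Returns two (n_pairs x n_stages) FPKM arrays (reference, neighbor).
    """
    ref_log = base_log2 + rng.normal(0.0, sd_ref, size=(n_pairs, n_stages))
    centred = ref_log - ref_log.mean(axis=1, keepdims=True)
    nb_log = base_log2 + alpha * centred + rng.normal(
        0.0, sd_noise, size=(n_pairs, n_stages)
    )
    return 2.0 ** ref_log, 2.0 ** nb_log


# ---------------------------------------------------------------------------
# mark tracks


def _triangle_weights(halfwidth, bin_size):
    edges = np.arange(-halfwidth, halfwidth, bin_size)
    centers = edges + bin_size / 2.0
    w = np.maximum(0.0, 1.0 - np.abs(centers) / halfwidth)
    return edges, w / w.sum()


def simulate_mark_tracks(loci, genome, rng, ratio_enh=(4.0, 1.0),
                         ratio_prom=(1.0, 4.0), depth=100.0,
                         halfwidth=1000, bin_size=50):
    """Poisson mark coverage around each locus TSS with class-dependent split.

    ``loci`` is an iterable of (chrom, tss, is_enhancer).  Returns two
    bedGraph-style dicts (me1, me3) of per-bin counts.
    """
    edges, weights = _triangle_weights(halfwidth, bin_size)
    me1 = {}
    me3 = {}
    for chrom, tss, is_enh in loci:
        ratio = ratio_enh if is_enh else ratio_prom
        share1 = ratio[0] / (ratio[0] + ratio[1])
        lam1 = depth * share1 * weights
        lam3 = depth * (1.0 - share1) * weights
        c1 = rng.poisson(lam1)
        c3 = rng.poisson(lam3)
        chrom_len = genome.length(chrom)
        for off, v1, v3 in zip(edges, c1, c3):
            s = tss + int(off)
            e = s + bin_size
            if s < 0 or e > chrom_len:
                continue
            if v1 > 0:
                me1.setdefault(chrom, []).append((s, e, float(v1)))
            if v3 > 0:
                me3.setdefault(chrom, []).append((s, e, float(v3)))
    for cov in (me1, me3):
        for chrom in cov:
            cov[chrom].sort()
    return me1, me3


# ---------------------------------------------------------------------------
# full bundle


def simulate_bundle(config=None, outdir=None):
    """Generate all pipeline inputs with planted ground truth.

    Returns a Bundle; when ``outdir`` is given, also writes the file tree
    (BED/GTF/bedGraph/TSV/FASTA/JSON) under it.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    genome = GenomeModel(
        {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    )

    truth = {}
    transcripts = []
    coding_genes = []
    coding_flags = {}
    dhs = []
    mark_loci = []

    block = cfg.chrom_length // cfg.genes_per_chrom
    n_special = 0
    lnc_counter = 0
    gene_counter = 0
    lnc_records = []  # (TruthRecord, transcript)

    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        for bi in range(cfg.genes_per_chrom):
            b0 = bi * block
            strand = "+" if (ci + bi) % 2 == 0 else "-"
            gene_counter += 1
            gid = f"gene{gene_counter:04d}"
            exons = [(b0 + 10_000, b0 + 10_500), (b0 + 13_000, b0 + 14_000)]
            t = TranscriptModel(f"{gid}.t1", chrom, strand, exons,
                                coding_potential="coding", gene_id=gid)
            transcripts.append(t)
            coding_flags[t.id] = "coding"
            coding_genes.append(
                GenomicInterval(chrom, b0 + 10_000, b0 + 14_000, strand, gid)
            )
            tss = t.tss()
            truth[gid] = TruthRecord(gid, "coding", chrom, strand, tss,
                                     (b0 + 10_000, b0 + 14_000))
            dhs.append(GenomicInterval(chrom, tss - cfg.dhs_width // 2,
                                       tss + cfg.dhs_width // 2))
            mark_loci.append((chrom, tss, False))

            if bi >= cfg.lnc_per_chrom:
                continue
            lnc_counter += 1
            lid = f"lnc{lnc_counter:04d}"
            lnc_strand = "+" if lnc_counter % 2 == 1 else "-"
            is_enh = lnc_counter % 2 == 1  # deterministic 50/50 class mix
            category = "intergenic"
            if n_special < cfg.n_bidirectional:
                # opposite strand, TIR within ~100 bp of the coding TIR
                category = "bidirectional"
                lnc_strand = "-" if strand == "+" else "+"
                if strand == "+":
                    span = (tss - 900, tss - 100)
                    lnc_tss = span[1] - 1
                else:
                    span = (tss + 101, tss + 901)
                    lnc_tss = span[0]
                n_special += 1
            elif n_special < cfg.n_bidirectional + cfg.n_intragenic:
                category = "intragenic"
                span = (b0 + 11_000, b0 + 11_800)
                lnc_strand = "+"
                lnc_tss = span[0]
                n_special += 1
            else:
                span = (b0 + 25_000, b0 + 26_000)
                lnc_tss = span[0] if lnc_strand == "+" else span[1] - 1

            mono = lnc_counter % 4 in (1, 2)
            if mono:
                exns = [(span[0], span[1])]
            else:
                exns = [(span[0], span[0] + 300), (span[1] - 400, span[1])]
            strandless = mono and (lnc_counter % 2 == 1) and category == "intergenic"
            lt = TranscriptModel(
                f"{lid}.t1", chrom, "." if strandless else lnc_strand, exns,
                coding_potential="noncoding", gene_id=lid,
            )
            # keep the true strand for tag generation; the GTF may say "."
            transcripts.append(lt)
            coding_flags[lt.id] = "noncoding"
            rec = TruthRecord(lid, "lnc", chrom, lnc_strand, lnc_tss, span,
                              category=category,
                              lnc_class="elncRNA" if is_enh else "plncRNA",
                              neighbor_gene=gid)
            truth[lid] = rec
            lnc_records.append((rec, lt))
            dhs.append(GenomicInterval(chrom, lnc_tss - cfg.dhs_width // 2,
                                       lnc_tss + cfg.dhs_width // 2))
            mark_loci.append((chrom, lnc_tss, is_enh))

    # --- expression ---------------------------------------------------------
    lnc_ids = [rec.locus_id for rec, _ in lnc_records]
    tissue_rows = {}
    for rec, _ in lnc_records:
        conc = cfg.dirichlet_enh if rec.lnc_class == "elncRNA" else cfg.dirichlet_prom
        total = float(rng.lognormal(3.0, 1.0))
        profile = rng.dirichlet(np.full(cfg.n_tissues, conc)) * total
        tissue_rows[rec.locus_id] = profile
        rec.expression_mean = total
    tissue_expr = pd.DataFrame(
        tissue_rows, index=[f"tissue{i + 1}" for i in range(cfg.n_tissues)]
    ).T

    stage_rows = {}
    gene_ids = sorted(g for g in truth if truth[g].locus_type == "coding")
    gene_stage_log = {
        g: 3.0 + rng.normal(0.0, 1.5, size=cfg.n_stages) for g in gene_ids
    }
    for g in gene_ids:
        stage_rows[g] = 2.0 ** gene_stage_log[g]
    for rec, _ in lnc_records:
        alpha = (
            cfg.coupling_alpha_enh
            if rec.lnc_class == "elncRNA"
            else cfg.coupling_alpha_prom
        )
        rec.coupling_alpha = alpha
        g_log = gene_stage_log[rec.neighbor_gene]
        centred = g_log - g_log.mean()
        lnc_log = 2.0 + alpha * centred + rng.normal(0.0, 0.5, size=cfg.n_stages)
        stage_rows[rec.locus_id] = 2.0 ** lnc_log
    stage_expr = pd.DataFrame(
        stage_rows, index=[f"stage{i + 1}" for i in range(cfg.n_stages)]
    ).T

    # --- nanoCAGE tags (support scales with expression) ---------------------
    tags = TagSet()
    mean_expr = float(np.mean([truth[l].expression_mean for l in lnc_ids])) or 1.0
    for locus_id, rec in sorted(truth.items()):
        if rec.locus_type == "coding":
            mean = cfg.cage_mean
        else:
            mean = max(1.0, cfg.cage_mean * rec.expression_mean / mean_expr)
        n_reads = max(1, _nb_draw(rng, mean, cfg.cage_disp))
        positions = sample_cage_tags(rec.tss, n_reads, cfg.jitter_sd,
                                     genome.length(rec.chrom), rng)
        for p in positions:
            tags.add(rec.chrom, rec.strand, int(p))

    # --- chromatin marks ----------------------------------------------------
    me1_cov, me3_cov = simulate_mark_tracks(
        mark_loci, genome, rng, cfg.ratio_enh, cfg.ratio_prom,
        cfg.chip_depth, cfg.mark_halfwidth, cfg.mark_bin,
    )

    # --- TE / CpG / pseudogene annotations ----------------------------------
    te = []
    cpg = []
    for rec, _ in lnc_records:
        if rec.category != "intergenic":
            continue
        is_enh = rec.lnc_class == "elncRNA"
        dens = cfg.te_density_enh if is_enh else cfg.te_density_prom
        # plant a TIR-covering TE with class-dependent probability so that
        # the mean per-class TE density recovers the planted value
        if rng.random() < dens:
            te.append(GenomicInterval(rec.chrom, rec.tss - 500, rec.tss + 500,
                                      ".", "TE"))
        p_cpg = cfg.cpg_prob_enh if is_enh else cfg.cpg_prob_prom
        if rng.random() < p_cpg:
            cpg.append(GenomicInterval(rec.chrom, rec.tss - 100, rec.tss + 100,
                                       ".", "CpG"))
    pseudogenes = []

    # --- aligned pairs: lnc TIR elements + nearby neutral ARs ---------------
    elements = []
    ars = []
    for rec, _ in lnc_records:
        if rec.category != "intergenic":
            continue
        factor = (
            cfg.rate_factor_enh
            if rec.lnc_class == "elncRNA"
            else cfg.rate_factor_prom
        )
        d_el = cfg.neutral_d * factor
        rec.substitution_rate = d_el
        gc = 0.40 + 0.10 * rng.random()
        anchor = GenomicInterval(rec.chrom, rec.tss - cfg.element_length // 2,
                                 rec.tss + cfg.element_length // 2)
        seq = random_sequence(cfg.element_length, gc, rng)
        pair = evolve_pair(seq, d_el, rng, element_id=f"{rec.locus_id}_TIR",
                           kind="TIR", anchor=anchor)
        elements.append(pair)
        for k in range(cfg.ars_per_element):
            off = 5_000 + 6_000 * k
            ar_anchor = GenomicInterval(
                rec.chrom, anchor.start + off, anchor.start + off + cfg.ar_length
            )
            ar_gc = min(0.95, max(0.05, gc + rng.normal(0.0, 0.01)))
            ar_seq = random_sequence(cfg.ar_length, ar_gc, rng)
            ars.append(
                evolve_pair(ar_seq, cfg.neutral_d, rng,
                            element_id=f"{rec.locus_id}_AR{k + 1}",
                            kind="AR", anchor=ar_anchor)
            )

    bundle = Bundle(cfg, genome, truth, tags, dhs, transcripts, coding_genes,
                    coding_flags, me1_cov, me3_cov, te, cpg, pseudogenes,
                    tissue_expr, stage_expr, elements, ars)
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle, outdir):
    os.makedirs(outdir, exist_ok=True)
    bundle.genome.write_chrom_sizes(os.path.join(outdir, "chrom.sizes"))
    write_bed(bundle.tags.to_bed(), os.path.join(outdir, "tags.bed"))
    write_bed(bundle.dhs, os.path.join(outdir, "dhs.bed"), columns=3)
    write_gtf(bundle.transcripts, os.path.join(outdir, "transcripts.gtf"))
    with open(os.path.join(outdir, "coding_flags.tsv"), "w") as fh:
        for tid in sorted(bundle.coding_flags):
            fh.write(f"{tid}\t{bundle.coding_flags[tid]}\n")
    write_bedgraph(bundle.me1_cov, os.path.join(outdir, "me1.bedgraph"))
    write_bedgraph(bundle.me3_cov, os.path.join(outdir, "me3.bedgraph"))
    write_bed(bundle.te, os.path.join(outdir, "te.bed"))
    write_bed(bundle.cpg, os.path.join(outdir, "cpg.bed"))
    write_bed(bundle.pseudogenes, os.path.join(outdir, "pseudogene.bed"))
    write_bed(bundle.coding_genes, os.path.join(outdir, "coding_genes.bed"))
    write_matrix(bundle.tissue_expr, os.path.join(outdir, "tissue_expression.tsv"))
    write_matrix(bundle.stage_expr, os.path.join(outdir, "stage_expression.tsv"))
    aln_dir = os.path.join(outdir, "alignments")
    os.makedirs(aln_dir, exist_ok=True)
    anchors = []
    kinds = []
    for pair in bundle.elements + bundle.ars:
        write_pair_fasta(pair, os.path.join(aln_dir, f"{pair.id}.fa"))
        anchors.append(pair.anchor.with_(name=pair.id))
        kinds.append((pair.id, pair.kind))
    write_bed(anchors, os.path.join(outdir, "element_anchors.bed"))
    with open(os.path.join(outdir, "element_kinds.tsv"), "w") as fh:
        for pid, kind in kinds:
            fh.write(f"{pid}\t{kind}\n")
    truth_json = {
        lid: dataclasses.asdict(rec) for lid, rec in sorted(bundle.truth.items())
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(
            {"config": dataclasses.asdict(bundle.config), "loci": truth_json},
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")
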