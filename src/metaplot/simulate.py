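"""Deterministic synthetic genomes, annotation stores and BAM files.

The generator builds a small genome whose gene models provably exercise
every exon category and every region-location class, then samples reads as
background plus Gaussian enrichment peaks at TSSs, written as a sorted,
indexed BAM. Everything is a pure function of the seed, so fixtures are
reproducible byte for byte and no downloads are ever needed.

Read placement inverts fragment extension exactly: a fragment midpoint is
sampled first, then the read start is derived per strand so that the
fragment-extended footprint is centred on the midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy.stats import norm

from .annotation import (AnnotationStore, DEFAULT_CLASSIFIER_CONFIG,
                         build_gene, classify_region_location,
                         filter_and_assign_enhancers)
from .models import GenomicInterval, TranscriptModel


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic study.

    Defaults give 2 gene-bearing chromosomes of 1 Mb with 30 genes (plus one
    gene-free heterochromatin-annotated chromosome for gene-desert and
    pericentromeric probes) and a 5e4-read background ChIP sample with
    10-fold Gaussian peaks (sd 200 bp) at protein-coding TSSs — seconds to
    generate, yet dense enough for profile statistics.
    """

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 30
    n_reads: int = 50_000
    read_len: int = 50
    fraglen: int = 150
    peak_sd: float = 200.0
    fold_enrichment: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length", "n_genes", "n_reads",
                     "read_len", "fraglen"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


#: chromosome reserved for heterochromatin windows and desert probes
EMPTY_CHROM = "chrU"


def _showcase_transcripts(gene_id: str, chrom: str, offset: int,
                          strand: str) -> list[TranscriptModel]:
    """Two isoforms engineered to yield every internal exon category.

    Against isoform T2, T1's internal exons are, in order: canonical,
    altDonor, altAcceptor, altBoth and variant; terminal exons give
    promoter and polyA.
    """
    t1 = [(0, 100), (200, 300), (400, 500), (600, 700), (800, 900),
          (1000, 1100), (1200, 1300)]
    t2 = [(0, 100), (200, 300), (400, 520), (580, 700), (790, 910),
          (1200, 1300)]

    def mk(tid, pairs):
        exons = tuple(
            GenomicInterval(chrom, offset + s, offset + e, strand)
            for s, e in pairs
        )
        return TranscriptModel(tid, gene_id, exons, strand)

    return [mk(f"{gene_id}.t1", t1), mk(f"{gene_id}.t2", t2)]


def random_gene(rng: np.random.Generator, gene_id: str, chrom: str,
                offset: int, strand: str | None = None,
                biotype: str = "protein_coding",
                multi_isoform: bool = True):
    """A random gene model: an exon chain plus 0-2 perturbed isoforms.

    Perturbations drop internal exons and jitter internal splice boundaries,
    so multi-isoform genes carry a realistic mix of exon categories.
    """
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    n_exons = int(rng.integers(3, 7))
    pos = offset
    base: list[list[int]] = []
    for _ in range(n_exons):
        length = int(rng.integers(80, 300))
        base.append([pos, pos + length])
        pos += length + int(rng.integers(200, 1000))

    def jitter(pairs):
        out = []
        for i, (s, e) in enumerate(pairs):
            s2, e2 = s, e
            if 0 < i:
                s2 = s + int(rng.integers(-40, 41))
            if i < len(pairs) - 1:
                e2 = e + int(rng.integers(-40, 41))
            lo = out[-1][1] + 1 if out else 0
            s2 = max(s2, lo)
            e2 = max(e2, s2 + 10)
            out.append([s2, e2])
        return out

    isoform_pairs = [base]
    if multi_isoform:
        for _ in range(int(rng.integers(1, 3))):
            keep = [base[0]] + [
                ex for ex in base[1:-1] if rng.random() > 0.3
            ] + [base[-1]]
            isoform_pairs.append(jitter([list(p) for p in keep]))

    transcripts = []
    for k, pairs in enumerate(isoform_pairs):
        exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in pairs)
        transcripts.append(TranscriptModel(
            f"{gene_id}.t{k + 1}", gene_id, exons, strand, biotype))
    return build_gene(transcripts, gene_name=gene_id.replace("G", "Gene"))


def synth_annotation(spec: FixtureSpec, path: str | Path | None = None) -> AnnotationStore:
    """Build (and optionally save) an annotation store from a fixture spec.

    The store contains genes of all five biotypes, multi-isoform genes
    producing all seven exon categories, CGI / DHS / enhancer sets placed at
    controlled TSS distances so all eight location classes and the enhancer
    exclusion rule are exercised, plus centromere / telomere annotations on
    a gene-free chromosome.
    """
    rng = np.random.default_rng(spec.seed)
    chroms = {f"chr{i + 1}": spec.chrom_length for i in range(spec.n_chroms)}
    chroms[EMPTY_CHROM] = spec.chrom_length

    gene_chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    per_chrom = max(1, spec.n_genes // spec.n_chroms)
    margin = 20_000
    genes = {}
    gid_iter = iter(f"G{i:04d}" for i in range(1, spec.n_genes + 1))
    rare_biotypes = ["pseudogene", "lincRNA", "miRNA", "misc"]
    idx = 0
    for ci, chrom in enumerate(gene_chroms):
        n_here = per_chrom if ci < spec.n_chroms - 1 else spec.n_genes - per_chrom * (spec.n_chroms - 1)
        slot = (spec.chrom_length - 2 * margin) // max(n_here, 1)
        for k in range(n_here):
            gid = next(gid_iter)
            offset = margin + k * slot
            if idx == 0:
                g = build_gene(_showcase_transcripts(gid, chrom, offset, "+"),
                               gene_name="Showcase+")
            elif idx == 1:
                g = build_gene(_showcase_transcripts(gid, chrom, offset, "-"),
                               gene_name="Showcase-")
            elif idx == 2:
                # long single-isoform gene: a stable Genebody probe target
                exons = tuple(
                    GenomicInterval(chrom, offset + s, offset + e, "+")
                    for s, e in [(0, 400), (4000, 4400), (9600, 10000)]
                )
                g = build_gene(
                    [TranscriptModel(f"{gid}.t1", gid, exons, "+")],
                    gene_name="LongGene")
            elif 3 <= idx <= 6:
                g = random_gene(rng, gid, chrom, offset,
                                biotype=rare_biotypes[idx - 3],
                                multi_isoform=False)
            else:
                g = random_gene(rng, gid, chrom, offset)
            genes[gid] = g
            idx += 1

    het = pd.DataFrame(
        [
            (EMPTY_CHROM, spec.chrom_length // 2 - 5_000,
             spec.chrom_length // 2 + 5_000, "centromere"),
            (EMPTY_CHROM, 0, 10_000, "telomere"),
            (EMPTY_CHROM, spec.chrom_length - 10_000, spec.chrom_length,
             "telomere"),
        ],
        columns=["chrom", "start", "end", "kind"],
    )

    store = AnnotationStore(
        genome=f"synth{spec.seed}",
        chrom_sizes=chroms,
        genes=genes,
        heterochromatin=het,
        params={
            "source": "synthetic",
            "seed": spec.seed,
            "n_genes": spec.n_genes,
            "chrom_length": spec.chrom_length,
        },
    )

    # CGIs / DHSs at controlled distances from protein-coding TSSs
    coding = [g for g in store.iter_genes(biotype="protein_coding")]
    cgi_rows, dhs_rows = [], []
    probe_offsets = [0, 600, 2000, 30_000]
    for i, g in enumerate(coding):
        off = probe_offsets[i % len(probe_offsets)]
        centre = g.tss + off if g.strand == "+" else g.tss - off
        centre = min(max(centre, 200), spec.chrom_length - 200)
        cgi_rows.append((g.chrom, centre - 150, centre + 150, f"CGI_{i:03d}"))
        d_centre = int(rng.integers(200, spec.chrom_length - 200))
        dhs_rows.append((g.chrom, d_centre - 100, d_centre + 100, f"DHS_{i:03d}"))
    # a mid-gene CGI inside the long gene (Genebody class)
    long_gene = next(g for g in store.genes.values() if g.gene_name == "LongGene")
    mid = (long_gene.span.start + long_gene.span.end) // 2
    cgi_rows.append((long_gene.chrom, mid - 150, mid + 150, "CGI_genebody"))

    def classify_table(rows):
        out = []
        for chrom, start, end, name in rows:
            rc = classify_region_location(
                GenomicInterval(chrom, start, end), store)
            out.append((chrom, start, end, name, rc.label,
                        rc.nearest_gene or "", rc.distance_to_tss))
        return pd.DataFrame(out, columns=["chrom", "start", "end", "name",
                                          "region_class", "gene_id",
                                          "distance_to_tss"])

    store.cgis = classify_table(cgi_rows)
    store.dhss = classify_table(dhs_rows)

    # enhancers: half promoter-proximal (to be excluded), half distal
    raw_enhancers = []
    for i, g in enumerate(coding):
        near = g.tss + (4_000 if g.strand == "+" else -4_000)
        far = g.tss + (12_000 if g.strand == "+" else -12_000)
        for j, centre in enumerate((near, far)):
            centre = min(max(centre, 500), spec.chrom_length - 500)
            raw_enhancers.append(
                GenomicInterval(g.chrom, centre - 400, centre + 400))
    kept = filter_and_assign_enhancers(raw_enhancers, store)
    store.enhancers = pd.DataFrame(
        [(iv.chrom, iv.start, iv.end, f"ENH_{i:03d}", gid)
         for i, (iv, gid) in enumerate(kept)],
        columns=["chrom", "start", "end", "name", "gene_id"],
    )

    if path is not None:
        store.save(path)
    return store


def _peak_reads_per_tss(spec: FixtureSpec, genome_length: int) -> int:
    """Extra reads per TSS so that expected coverage at the peak centre is
    about ``fold_enrichment`` times the uniform background coverage."""
    if spec.fold_enrichment <= 1:
        return 0
    bg_cov = spec.n_reads * spec.fraglen / genome_length
    p_cover = 2 * norm.cdf((spec.fraglen / 2) / spec.peak_sd) - 1
    return int(round(bg_cov * (spec.fold_enrichment - 1) / p_cover))


def synth_reads(
    spec: FixtureSpec,
    store: AnnotationStore,
    out_bam: str | Path,
    control: bool = False,
) -> tuple[Path, int]:
    """Sample reads and write a sorted, indexed BAM.

    Background fragment midpoints are uniform over the genome; unless
    ``control`` is set, Gaussian peaks (sd ``peak_sd``) are added at every
    protein-coding TSS, sized so peak-centre coverage is about
    ``fold_enrichment`` times background. Returns the path and the number
    of reads written (all of which are mapped, primary and QC-pass, so the
    library size equals this count).
    """
    rng = np.random.default_rng(spec.seed * 2 + (1 if control else 0) + 1)
    chrom_names = sorted(store.chrom_sizes)
    sizes = store.chrom_sizes
    genome_length = sum(sizes.values())
    half = spec.fraglen // 2

    mids: dict[str, list[np.ndarray]] = {c: [] for c in chrom_names}
    n_per_chrom = rng.multinomial(
        spec.n_reads, [sizes[c] / genome_length for c in chrom_names])
    for c, n in zip(chrom_names, n_per_chrom):
        mids[c].append(rng.integers(half, sizes[c] - half, size=n))

    if not control:
        n_peak = _peak_reads_per_tss(spec, genome_length)
        for g in store.iter_genes(biotype="protein_coding"):
            offs = rng.normal(0.0, spec.peak_sd, size=n_peak)
            pos = np.clip(np.rint(g.tss + offs).astype(np.int64),
                          half, sizes[g.chrom] - half)
            mids[g.chrom].append(pos)

    out_bam = Path(out_bam)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": sizes[c]} for c in chrom_names],
    }
    n_written = 0
    with pysam.AlignmentFile(str(out_bam), "wb", header=header) as fh:
        for tid, c in enumerate(chrom_names):
            pos = np.concatenate(mids[c]) if mids[c] else np.zeros(0, dtype=np.int64)
            if pos.size == 0:
                continue
            rev = rng.random(pos.size) < 0.5
            # + read starts at mid - half; - read ends at mid - half + fraglen,
            # so fragment extension recovers [mid-half, mid-half+fraglen) exactly
            starts = np.where(
                rev,
                pos - half + spec.fraglen - spec.read_len,
                pos - half,
            )
            order = np.argsort(starts, kind="stable")
            for i in order:
                a = pysam.AlignedSegment()
                a.query_name = f"{c}_{n_written}"
                a.query_sequence = "A" * spec.read_len
                a.query_qualities = pysam.qualitystring_to_array("I" * spec.read_len)
                a.reference_id = tid
                a.reference_start = int(starts[i])
                a.mapping_quality = 60
                a.cigarstring = f"{spec.read_len}M"
                a.flag = 16 if rev[i] else 0
                fh.write(a)
                n_written += 1
    pysam.index(str(out_bam))
    return out_bam, n_written
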