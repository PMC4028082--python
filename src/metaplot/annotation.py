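"""Gene-model annotation: representative isoforms, exon categories,
region-location classes, enhancer filtering, and the on-disk annotation store.

The annotation store is a directory of flat TAB-separated tables plus a JSON
manifest, installable under a common root and loadable by genome name — the
local equivalent of a downloadable genome annotation package.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .models import GeneModel, GenomicInterval, TranscriptModel

STORE_FORMAT_VERSION = 1

#: the seven exon categories, from least to most "alternative"
EXON_CATEGORIES = (
    "promoter",
    "polyA",
    "canonical",
    "altDonor",
    "altAcceptor",
    "altBoth",
    "variant",
)

#: the eight location classes assigned to CGIs, DHSs and other intervals
REGION_CLASSES = (
    "ProximalPromoter",
    "Promoter1K",
    "Promoter3K",
    "Genebody",
    "Genedesert",
    "OtherIntergenic",
    "Pericentromere",
    "Subtelomere",
)


@dataclass(frozen=True, slots=True)
class ExonRecord:
    """One exon of one transcript with its assigned category."""

    exon: GenomicInterval
    transcript_id: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in EXON_CATEGORIES:
            raise ValueError(f"unknown exon category {self.category!r}")


@dataclass(frozen=True, slots=True)
class RegionClass:
    """Location class of an interval plus its nearest gene context."""

    label: str
    nearest_gene: str | None
    distance_to_tss: int | None

    def __post_init__(self) -> None:
        if self.label not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.label!r}")


@dataclass(frozen=True)
class RegionClassifierConfig:
    """Distance cutoffs for location classification (all in bp).

    ``proximal_bp`` bounds the ProximalPromoter ring around a TSS; the 1 kb and
    3 kb promoter rings are fixed by their class names; ``desert_bp`` is the
    minimum distance from any gene for a Genedesert call; ``heterochromatin_bp``
    is how far a pericentromeric / subtelomeric window extends beyond the
    annotated centromere / telomere boundary; ``enhancer_tss_exclusion_bp`` is
    the half-width of the TSS exclusion zone applied to enhancers.
    """

    proximal_bp: int = 250
    promoter1k_bp: int = 1_000
    promoter3k_bp: int = 3_000
    desert_bp: int = 1_000_000
    heterochromatin_bp: int = 100_000
    enhancer_tss_exclusion_bp: int = 5_000


DEFAULT_CLASSIFIER_CONFIG = RegionClassifierConfig()


def select_representative(gene_or_transcripts) -> str:
    """Pick a gene's representative isoform: the longest genomic span.

    Ties are broken by the lexicographically smallest transcript id.
    Accepts a :class:`GeneModel` or an iterable of transcripts and returns the
    chosen ``transcript_id``.
    """
    if isinstance(gene_or_transcripts, GeneModel):
        transcripts = gene_or_transcripts.transcripts
    else:
        transcripts = tuple(gene_or_transcripts)
    if not transcripts:
        raise ValueError("cannot select a representative from zero transcripts")
    return min(transcripts, key=lambda t: (-t.genomic_span, t.transcript_id)).transcript_id


def build_gene(transcripts, gene_name: str = "") -> GeneModel:
    """Assemble a :class:`GeneModel`, selecting the representative isoform."""
    transcripts = tuple(transcripts)
    rep = select_representative(transcripts)
    return GeneModel(
        gene_id=transcripts[0].gene_id,
        transcripts=transcripts,
        representative=rep,
        gene_name=gene_name or transcripts[0].gene_id,
    )


# ---------------------------------------------------------------------------
# Exon classification
# ---------------------------------------------------------------------------

def _terminal_flags(t: TranscriptModel, i: int) -> tuple[bool, bool]:
    """(is_5prime_terminal, is_3prime_terminal) for exon index i (genomic order)."""
    first = i == 0
    last = i == len(t.exons) - 1
    if t.strand == "+":
        return first, last
    return last, first


def _splice_boundaries(exon: GenomicInterval, strand: str) -> tuple[int, int]:
    """(acceptor, donor) genomic coordinates of an exon.

    The acceptor is the exon's 5' edge (where the upstream intron ends); the
    donor is its 3' edge (where the downstream intron begins).
    """
    if strand == "+":
        return exon.start, exon.end
    return exon.end, exon.start


def classify_exons(gene: GeneModel) -> list[ExonRecord]:
    """Assign each exon of each isoform one of the seven exon categories.

    Terminal exons are labelled by position alone: the 5'-most exon of every
    transcript is ``promoter``, the 3'-most is ``polyA`` (a single-exon
    transcript is ``promoter``). Internal exons start as ``canonical`` and are
    updated by pairwise comparison against every other isoform of the gene:

    * no overlapping exon in the other isoform -> ``variant``;
    * an overlapping exon whose donor (3' splice boundary) differs ->
      ``altDonor``; whose acceptor (5' boundary) differs -> ``altAcceptor``;
      both -> ``altBoth``.

    Updates are sticky in severity order canonical < altDonor/altAcceptor <
    altBoth < variant, and an exon that accumulates a donor mismatch from one
    comparison and an acceptor mismatch from another becomes ``altBoth``.
    Boundary comparisons ignore the outer boundary of a terminal exon in the
    partner isoform, since transcription start/end positions are not splice
    sites. Overlap means any shared bp.
    """
    strands = {t.strand for t in gene.transcripts}
    if len(strands) != 1:
        raise ValueError(f"gene {gene.gene_id} has transcripts on mixed strands")
    strand = strands.pop()

    records: list[ExonRecord] = []
    for t in gene.transcripts:
        n = len(t.exons)
        # mismatch flags per internal exon: donor, acceptor, variant
        flags = [[False, False, False] for _ in range(n)]
        for u in gene.transcripts:
            if u.transcript_id == t.transcript_id:
                continue
            for i, exon in enumerate(t.exons):
                is5, is3 = _terminal_flags(t, i)
                if is5 or is3:
                    continue
                overlapping = [
                    (j, x) for j, x in enumerate(u.exons) if exon.overlaps(x)
                ]
                if not overlapping:
                    flags[i][2] = True
                    continue
                acc, don = _splice_boundaries(exon, strand)
                best: tuple[bool, bool] | None = None
                for j, x in overlapping:
                    x5, x3 = _terminal_flags(u, j)
                    xacc, xdon = _splice_boundaries(x, strand)
                    # outer boundaries of partner terminal exons are not
                    # splice sites: mask those comparisons
                    acc_diff = (acc != xacc) and not x5
                    don_diff = (don != xdon) and not x3
                    cand = (don_diff, acc_diff)
                    if best is None or sum(cand) < sum(best):
                        best = cand
                    if best == (False, False):
                        break
                assert best is not None
                flags[i][0] |= best[0]
                flags[i][1] |= best[1]

        for i, exon in enumerate(t.exons):
            is5, is3 = _terminal_flags(t, i)
            if is5:  # single-exon transcripts fall here: promoter wins
                cat = "promoter"
            elif is3:
                cat = "polyA"
            else:
                don_alt, acc_alt, var = flags[i]
                if var:
                    cat = "variant"
                elif don_alt and acc_alt:
                    cat = "altBoth"
                elif don_alt:
                    cat = "altDonor"
                elif acc_alt:
                    cat = "altAcceptor"
                else:
                    cat = "canonical"
            records.append(ExonRecord(exon=exon, transcript_id=t.transcript_id, category=cat))
    return records


# ---------------------------------------------------------------------------
# Annotation store
# ---------------------------------------------------------------------------

class AnnotationStore:
    """In-memory annotation for one genome, serialisable to a TSV directory.

    Holds chromosome sizes, gene models (with representative isoforms), the
    exon table with categories, CGI / DHS / enhancer interval sets, and
    heterochromatin annotations (centromeres, telomeres).
    """

    def __init__(
        self,
        genome: str,
        chrom_sizes: dict[str, int],
        genes: dict[str, GeneModel],
        exon_table: pd.DataFrame | None = None,
        cgis: pd.DataFrame | None = None,
        dhss: pd.DataFrame | None = None,
        enhancers: pd.DataFrame | None = None,
        heterochromatin: pd.DataFrame | None = None,
        params: dict | None = None,
    ) -> None:
        self.genome = genome
        self.chrom_sizes = dict(chrom_sizes)
        self.genes = dict(genes)
        interval_cols = ["chrom", "start", "end", "name"]
        self.cgis = cgis if cgis is not None else pd.DataFrame(
            columns=interval_cols + ["region_class"])
        self.dhss = dhss if dhss is not None else pd.DataFrame(
            columns=interval_cols + ["region_class"])
        self.enhancers = enhancers if enhancers is not None else pd.DataFrame(
            columns=interval_cols + ["gene_id"])
        self.heterochromatin = heterochromatin if heterochromatin is not None else (
            pd.DataFrame(columns=["chrom", "start", "end", "kind"]))
        self.params = dict(params or {})
        if exon_table is None:
            exon_table = self._build_exon_table()
        self.exons = exon_table
        self._tss_cache: dict[str, tuple[np.ndarray, list[str], list[str]]] = {}

    def _build_exon_table(self) -> pd.DataFrame:
        rows = []
        for gid in sorted(self.genes):
            for rec in classify_exons(self.genes[gid]):
                rows.append(
                    (gid, rec.transcript_id, rec.exon.chrom, rec.exon.start,
                     rec.exon.end, rec.exon.strand, rec.category)
                )
        return pd.DataFrame(
            rows,
            columns=["gene_id", "transcript_id", "chrom", "start", "end",
                     "strand", "category"],
        )

    # -- gene queries -------------------------------------------------------

    def iter_genes(self, biotype: str | None = None):
        for gid in sorted(self.genes):
            g = self.genes[gid]
            if biotype is None or g.biotype == biotype:
                yield g

    def tss_index(self, chrom: str):
        """Sorted TSS positions on one chromosome with gene ids and strands."""
        if chrom not in self._tss_cache:
            entries = sorted(
                (g.tss, g.gene_id, g.strand)
                for g in self.genes.values()
                if g.chrom == chrom
            )
            pos = np.array([e[0] for e in entries], dtype=np.int64)
            self._tss_cache[chrom] = (pos, [e[1] for e in entries], [e[2] for e in entries])
        return self._tss_cache[chrom]

    def nearest_tss(self, chrom: str, point: int):
        """(gene_id, signed distance) of the nearest TSS on ``chrom``.

        The distance sign follows transcription: positive downstream of the
        TSS, negative upstream. Returns ``(None, None)`` if the chromosome
        carries no genes.
        """
        pos, gids, strands = self.tss_index(chrom)
        if len(pos) == 0:
            return None, None
        i = int(np.searchsorted(pos, point))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(pos):
                d = abs(point - int(pos[j]))
                if best is None or d < best[0]:
                    best = (d, j)
        _, j = best
        signed = point - int(pos[j]) if strands[j] == "+" else int(pos[j]) - point
        return gids[j], signed

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": STORE_FORMAT_VERSION,
            "genome": self.genome,
            "source": self.params.get("source", "synthetic"),
            "params": self.params,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        pd.DataFrame(
            sorted(self.chrom_sizes.items()), columns=["chrom", "size"]
        ).to_csv(path / "chroms.tsv", sep="\t", index=False)

        gene_rows, tx_rows = [], []
        for gid in sorted(self.genes):
            g = self.genes[gid]
            gene_rows.append(
                (gid, g.gene_name, g.chrom, g.strand, g.biotype,
                 g.representative, g.span.start, g.span.end)
            )
            for t in g.transcripts:
                tx_rows.append(
                    (t.transcript_id, gid, t.chrom, t.strand, t.biotype,
                     ",".join(str(e.start) for e in t.exons),
                     ",".join(str(e.end) for e in t.exons))
                )
        pd.DataFrame(
            gene_rows,
            columns=["gene_id", "name", "chrom", "strand", "biotype",
                     "representative", "span_start", "span_end"],
        ).to_csv(path / "genes.tsv", sep="\t", index=False)
        pd.DataFrame(
            tx_rows,
            columns=["transcript_id", "gene_id", "chrom", "strand", "biotype",
                     "exon_starts", "exon_ends"],
        ).to_csv(path / "transcripts.tsv", sep="\t", index=False)
        self.exons.to_csv(path / "exons.tsv", sep="\t", index=False)
        self.cgis.to_csv(path / "cgi.tsv", sep="\t", index=False)
        self.dhss.to_csv(path / "dhs.tsv", sep="\t", index=False)
        self.enhancers.to_csv(path / "enhancers.tsv", sep="\t", index=False)
        self.heterochromatin.to_csv(path / "heterochromatin.tsv", sep="\t", index=False)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "AnnotationStore":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        if manifest["format_version"] != STORE_FORMAT_VERSION:
            raise ValueError(
                f"annotation store format {manifest['format_version']} not "
                f"supported (expected {STORE_FORMAT_VERSION})"
            )
        chroms = pd.read_csv(path / "chroms.tsv", sep="\t")
        chrom_sizes = dict(zip(chroms["chrom"], chroms["size"].astype(int)))
        tx_df = pd.read_csv(path / "transcripts.tsv", sep="\t")
        gene_df = pd.read_csv(path / "genes.tsv", sep="\t")

        tx_by_gene: dict[str, list[TranscriptModel]] = {}
        for row in tx_df.itertuples(index=False):
            starts = [int(s) for s in str(row.exon_starts).split(",")]
            ends = [int(s) for s in str(row.exon_ends).split(",")]
            exons = tuple(
                GenomicInterval(row.chrom, s, e, row.strand)
                for s, e in zip(starts, ends)
            )
            tx_by_gene.setdefault(row.gene_id, []).append(
                TranscriptModel(row.transcript_id, row.gene_id, exons,
                                row.strand, row.biotype)
            )
        genes = {}
        for row in gene_df.itertuples(index=False):
            genes[row.gene_id] = GeneModel(
                gene_id=row.gene_id,
                transcripts=tuple(tx_by_gene[row.gene_id]),
                representative=row.representative,
                gene_name=str(row.name),
            )
        return cls(
            genome=manifest["genome"],
            chrom_sizes=chrom_sizes,
            genes=genes,
            exon_table=pd.read_csv(path / "exons.tsv", sep="\t"),
            cgis=pd.read_csv(path / "cgi.tsv", sep="\t"),
            dhss=pd.read_csv(path / "dhs.tsv", sep="\t"),
            enhancers=pd.read_csv(path / "enhancers.tsv", sep="\t"),
            heterochromatin=pd.read_csv(path / "heterochromatin.tsv", sep="\t"),
            params=manifest.get("params", {}),
        )


def list_stores(root: str | Path) -> list[str]:
    """Names of annotation stores installed under ``root``."""
    root = Path(root)
    if not root.is_dir():
        return []
    return sorted(
        p.name for p in root.iterdir() if (p / "manifest.json").is_file()
    )


def load_store(name: str, root: str | Path) -> AnnotationStore:
    """Load an installed annotation store by genome name."""
    path = Path(root) / name
    if not (path / "manifest.json").is_file():
        installed = ", ".join(list_stores(root)) or "(none)"
        raise FileNotFoundError(
            f"no annotation store named {name!r} under {root}; installed: {installed}"
        )
    return AnnotationStore.load(path)


# ---------------------------------------------------------------------------
# Region-location classification
# ---------------------------------------------------------------------------

def classify_region_location(
    iv: GenomicInterval,
    store: AnnotationStore,
    heterochromatin: pd.DataFrame | None = None,
    config: RegionClassifierConfig = DEFAULT_CLASSIFIER_CONFIG,
) -> RegionClass:
    """Classify an interval's midpoint into one of the eight location classes.

    Tested in precedence order: ProximalPromoter (within ``proximal_bp`` of a
    TSS), Promoter1K, Promoter3K, Genebody (inside a gene span), then
    Pericentromere / Subtelomere (within the expanded heterochromatin windows),
    Genedesert (farther than ``desert_bp`` from any gene on the chromosome),
    else OtherIntergenic.
    """
    if iv.chrom not in store.chrom_sizes:
        raise KeyError(f"chromosome {iv.chrom!r} absent from annotation store")
    het = heterochromatin if heterochromatin is not None else store.heterochromatin
    m = iv.midpoint
    gene_id, signed = store.nearest_tss(iv.chrom, m)
    dist = abs(signed) if signed is not None else None

    if dist is not None:
        if dist <= config.proximal_bp:
            return RegionClass("ProximalPromoter", gene_id, signed)
        if dist <= config.promoter1k_bp:
            return RegionClass("Promoter1K", gene_id, signed)
        if dist <= config.promoter3k_bp:
            return RegionClass("Promoter3K", gene_id, signed)
        for g in store.genes.values():
            if g.chrom == iv.chrom and g.span.start <= m < g.span.end:
                return RegionClass("Genebody", gene_id, signed)

    w = config.heterochromatin_bp
    for kind, label in (("centromere", "Pericentromere"), ("telomere", "Subtelomere")):
        sub = het[(het["kind"] == kind) & (het["chrom"] == iv.chrom)]
        for row in sub.itertuples(index=False):
            if row.start - w <= m < row.end + w:
                return RegionClass(label, gene_id, signed)

    gene_dist = None
    for g in store.genes.values():
        if g.chrom != iv.chrom:
            continue
        d = 0 if g.span.start <= m < g.span.end else min(
            abs(m - g.span.start), abs(m - (g.span.end - 1)))
        gene_dist = d if gene_dist is None else min(gene_dist, d)
    if gene_dist is None or gene_dist > config.desert_bp:
        return RegionClass("Genedesert", gene_id, signed)
    return RegionClass("OtherIntergenic", gene_id, signed)


# ---------------------------------------------------------------------------
# Enhancer filtering and nearest-gene assignment
# ---------------------------------------------------------------------------

def filter_and_assign_enhancers(
    enhancers: list[GenomicInterval],
    store: AnnotationStore,
    config: RegionClassifierConfig = DEFAULT_CLASSIFIER_CONFIG,
) -> list[tuple[GenomicInterval, str]]:
    """Drop promoter-proximal enhancers and assign survivors to genes.

    An enhancer whose midpoint lies within ``enhancer_tss_exclusion_bp``
    (default +/- 5 kb) of any TSS is removed to avoid mistaking promoters for
    enhancers; each survivor is paired with the gene whose TSS is nearest to
    its midpoint. Enhancers on chromosomes without genes cannot be assigned
    and are dropped with a warning.
    """
    out: list[tuple[GenomicInterval, str]] = []
    for enh in enhancers:
        gene_id, signed = store.nearest_tss(enh.chrom, enh.midpoint)
        if gene_id is None:
            warnings.warn(
                f"enhancer {enh} on a chromosome without genes: dropped",
                stacklevel=2,
            )
            continue
        if abs(signed) <= config.enhancer_tss_exclusion_bp:
            continue
        out.append((enh, gene_id))
    return out
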