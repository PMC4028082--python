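"""Build oriented query region sets from annotation stores, BED files and
gene lists.

Two anchor styles exist. *Point* regions are fixed-width windows centred on a
single anchor base (TSS, TES); every window in a set has the same length
``2 * flank_bp``. *Interval* regions keep each element's own variable-length
body (gene body, exon, CGI, enhancer, DHS, BED record) and attach fixed
``flank_bp`` margins on both sides; bodies are later equalised in length by
:func:`metaplot.transform.normalize_length`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .annotation import AnnotationStore, EXON_CATEGORIES, REGION_CLASSES
from .models import GenomicInterval

POINT_KINDS = ("tss", "tes")
INTERVAL_KINDS = ("genebody", "exon", "cgi", "enhancer", "dhs", "bed")
REGION_KINDS = POINT_KINDS + INTERVAL_KINDS


@dataclass(frozen=True, slots=True)
class RegionRequest:
    """What the user asked to plot: a region kind plus options."""

    kind: str
    flank_bp: int = 2000
    subtype: str | None = None
    gene_list: str | None = None
    bed_path: str | None = None
    biotype: str | None = "protein_coding"

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}; valid: {REGION_KINDS}")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        if (self.kind == "bed") != (self.bed_path is not None):
            raise ValueError("bed_path is required iff kind == 'bed'")


@dataclass(frozen=True, slots=True)
class Region:
    """One oriented query region.

    ``interval`` is the body (for point regions, the full window); ``flank``
    is the margin attached on each side of an interval body (0 for point
    regions, whose flank is already inside the window).
    """

    interval: GenomicInterval
    anchor_kind: str  # "point" | "interval"
    display_id: str
    flank: int = 0
    gene_id: str | None = None
    gene_name: str | None = None

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def extent(self) -> GenomicInterval:
        """Full genomic footprint including flanks."""
        if self.anchor_kind == "point" or self.flank == 0:
            return self.interval
        return GenomicInterval(
            self.interval.chrom,
            self.interval.start - self.flank,
            self.interval.end + self.flank,
            self.interval.strand,
        )


@dataclass(slots=True)
class RegionSet:
    """A named, ordered collection of regions sharing one anchor style."""

    regions: list[Region]
    axis_labels: tuple[str, str, str]
    kind: str

    def __post_init__(self) -> None:
        ids = [r.display_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("display_ids in a RegionSet must be unique")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)


def _within_bounds(extent: GenomicInterval, chrom_sizes: dict[str, int]) -> bool:
    size = chrom_sizes.get(extent.chrom)
    return size is not None and extent.start >= 0 and extent.end <= size


def build_point_windows(request: RegionRequest, store: AnnotationStore) -> RegionSet:
    """One fixed-width window per representative transcript, centred on the
    TSS or TES; windows falling off a chromosome end are dropped with a
    warning so all rows keep identical width."""
    if request.kind not in POINT_KINDS:
        raise ValueError(f"kind {request.kind!r} is not a point kind")
    if request.flank_bp == 0:
        raise ValueError("flank_bp must be positive for point windows")
    regions: list[Region] = []
    dropped = 0
    for gene in store.iter_genes(biotype=request.biotype):
        anchor = gene.tss if request.kind == "tss" else gene.tes
        start, end = anchor - request.flank_bp, anchor + request.flank_bp
        if start < 0 or end > store.chrom_sizes.get(gene.chrom, 0):
            dropped += 1
            continue
        regions.append(
            Region(
                interval=GenomicInterval(gene.chrom, start, end, gene.strand),
                anchor_kind="point",
                display_id=gene.gene_id,
                gene_id=gene.gene_id,
                gene_name=gene.gene_name,
            )
        )
    if dropped:
        warnings.warn(
            f"dropped {dropped} window(s) extending past a chromosome boundary",
            stacklevel=2,
        )
    anchor_name = request.kind.upper()
    labels = (f"-{request.flank_bp}", anchor_name, f"+{request.flank_bp}")
    return _apply_gene_list(RegionSet(regions, labels, request.kind), request)


def build_interval_regions(request: RegionRequest, store: AnnotationStore) -> RegionSet:
    """Variable-length bodies with fixed flanks for gene bodies, exons, CGIs,
    enhancers, DHSs, or a custom BED file."""
    kind = request.kind
    if kind not in INTERVAL_KINDS:
        raise ValueError(f"kind {kind!r} is not an interval kind")
    flank = request.flank_bp
    regions: list[Region] = []

    if kind == "bed":
        rset = read_bed(request.bed_path)
        regions = [
            Region(r.interval, "interval", r.display_id, flank)
            for r in rset.regions
        ]
        labels = ("L", "Region", "R")
    elif kind == "genebody":
        for gene in store.iter_genes(biotype=request.biotype):
            regions.append(
                Region(gene.span, "interval", gene.gene_id, flank,
                       gene.gene_id, gene.gene_name)
            )
        labels = ("L", "Genebody", "R")
    elif kind == "exon":
        subtype = request.subtype or "canonical"
        if subtype not in EXON_CATEGORIES:
            raise ValueError(
                f"unknown exon subtype {subtype!r}; valid: {EXON_CATEGORIES}")
        sub = store.exons[store.exons["category"] == subtype]
        for i, row in enumerate(sub.itertuples(index=False)):
            g = store.genes.get(row.gene_id)
            regions.append(
                Region(
                    GenomicInterval(row.chrom, row.start, row.end, row.strand),
                    "interval",
                    f"{row.transcript_id}:{row.start}-{row.end}",
                    flank,
                    row.gene_id,
                    g.gene_name if g else None,
                )
            )
        labels = ("A", f"Exon({subtype})", "D")
    elif kind in ("cgi", "dhs"):
        table = store.cgis if kind == "cgi" else store.dhss
        subtype = request.subtype or ("ProximalPromoter" if kind == "cgi" else None)
        if subtype is not None:
            if subtype not in REGION_CLASSES:
                raise ValueError(
                    f"unknown {kind} subtype {subtype!r}; valid: {REGION_CLASSES}")
            table = table[table["region_class"] == subtype]
        for row in table.itertuples(index=False):
            gid = getattr(row, "gene_id", None)
            g = store.genes.get(gid) if gid else None
            strand = g.strand if g else "."
            regions.append(
                Region(
                    GenomicInterval(row.chrom, int(row.start), int(row.end), strand),
                    "interval", str(row.name), flank, gid,
                    g.gene_name if g else None,
                )
            )
        labels = ("L", kind.upper(), "R")
    elif kind == "enhancer":
        for row in store.enhancers.itertuples(index=False):
            g = store.genes.get(row.gene_id)
            regions.append(
                Region(
                    GenomicInterval(row.chrom, int(row.start), int(row.end), "."),
                    "interval", str(row.name), flank, row.gene_id,
                    g.gene_name if g else None,
                )
            )
        labels = ("L", "E", "R")

    kept, dropped = [], 0
    for r in regions:
        if _within_bounds(r.extent, store.chrom_sizes):
            kept.append(r)
        else:
            dropped += 1
    if dropped:
        warnings.warn(
            f"dropped {dropped} region(s) extending past a chromosome boundary",
            stacklevel=2,
        )
    return _apply_gene_list(RegionSet(kept, labels, kind), request)


def build_regions(request: RegionRequest, store: AnnotationStore) -> RegionSet:
    """Dispatch to point or interval construction by kind."""
    if request.kind in POINT_KINDS:
        return build_point_windows(request, store)
    return build_interval_regions(request, store)


def _apply_gene_list(rset: RegionSet, request: RegionRequest) -> RegionSet:
    if request.gene_list is None:
        return rset
    return subset_by_gene_list(rset, read_gene_list(request.gene_list))


def read_gene_list(path: str | Path) -> list[str]:
    """One identifier per line; ``#`` comments and blank lines ignored."""
    entries = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            entries.append(line)
    return entries


def subset_by_gene_list(rset: RegionSet, gene_list: list[str]) -> RegionSet:
    """Keep regions whose gene name, gene id, or display id matches the list.

    Entries are whitespace-trimmed but matched case-sensitively. The output
    preserves gene-list order (so downstream ranking method "none" honours a
    user-supplied ordering); regions matching the same entry keep their input
    order. A list matching nothing yields an empty set with a warning.
    """
    wanted = [e.strip() for e in gene_list if e.strip()]
    kept: list[Region] = []
    seen: set[str] = set()
    for entry in wanted:
        for r in rset.regions:
            if r.display_id in seen:
                continue
            if entry in (r.gene_id, r.gene_name, r.display_id):
                kept.append(r)
                seen.add(r.display_id)
    if wanted and not kept:
        warnings.warn("gene list matched no regions; result is empty", stacklevel=2)
    return RegionSet(kept, rset.axis_labels, rset.kind)


def read_bed(path: str | Path) -> RegionSet:
    """Parse a BED3-BED6 file into an (unflanked) interval RegionSet.

    Columns beyond 6 are ignored; the name column (when present) becomes the
    display id, otherwise ``chrom:start-end``; the strand column is honoured.
    Malformed lines raise with their line number.
    """
    path = Path(path)
    regions: list[Region] = []
    seen_ids: dict[str, int] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start < 0 or start >= end:
            raise ValueError(
                f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}")
        name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else (
            f"{chrom}:{start}-{end}")
        strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
        # BED names need not be unique; suffix duplicates to keep ids unique
        if name in seen_ids:
            seen_ids[name] += 1
            name = f"{name}.{seen_ids[name]}"
        else:
            seen_ids[name] = 0
        regions.append(
            Region(GenomicInterval(chrom, start, end, strand), "interval", name)
        )
    return RegionSet(regions, ("L", "Region", "R"), "bed")
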