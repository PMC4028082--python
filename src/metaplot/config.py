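"""The TAB-delimited multi-plot configuration file.

Each row describes one panel: column 1 the BAM file (or a ``signal:control``
pair for log2-ratio mode), column 2 the region — a gene-list file, a BED
file, or ``-1`` for all regions of the chosen kind — and column 3 the panel
title. Optional columns 4 and 5 carry the fragment length and a custom
average-profile colour. Lines starting with ``#`` are comments.

Parsing also derives the figure layout: the ordered unique region and BAM
lists span a grid in which each configured row populates one cell
(row = region, column = BAM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .coverage import DEFAULT_FRAGLEN

ALL_REGIONS = "-1"


@dataclass(frozen=True, slots=True)
class ConfigRow:
    """One parsed configuration line."""

    bam: str
    region: str
    title: str
    fraglen: int = DEFAULT_FRAGLEN
    color: str | None = None
    control: str | None = None  # set for "signal:control" pairs

    @property
    def bam_key(self) -> str:
        """The column-1 token as written (pair syntax preserved)."""
        return f"{self.bam}:{self.control}" if self.control else self.bam

    @property
    def is_pair(self) -> bool:
        return self.control is not None


@dataclass
class PlotSpec:
    """Parsed configuration plus the unique-region x unique-BAM grid."""

    rows: list[ConfigRow]
    unique_bams: list[str] = field(init=False)
    unique_regions: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.unique_bams = _unique([r.bam_key for r in self.rows])
        self.unique_regions = _unique([r.region for r in self.rows])


def _unique(items: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in items:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out


def _parse_bam_token(token: str, lineno: int) -> tuple[str, str | None]:
    if ":" not in token:
        return token, None
    parts = token.split(":")
    if len(parts) != 2 or not all(parts):
        raise ValueError(
            f"line {lineno}: BAM pair must be 'signal:control', got {token!r}")
    return parts[0], parts[1]


def parse_config(path: str | Path) -> PlotSpec:
    """Parse a configuration file into a :class:`PlotSpec`.

    Missing optional columns take defaults (fragment length 150 bp,
    automatic colour cycle). Rows with fewer than 3 columns or a non-numeric
    fragment length raise with the offending line number.
    """
    rows: list[ConfigRow] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"line {lineno}: configuration rows need at least 3 "
                f"TAB-separated columns, got {len(fields)}")
        bam, control = _parse_bam_token(fields[0].strip(), lineno)
        fraglen = DEFAULT_FRAGLEN
        if len(fields) >= 4 and fields[3].strip():
            try:
                fraglen = int(fields[3].strip())
            except ValueError as exc:
                raise ValueError(
                    f"line {lineno}: fragment length must be an integer, "
                    f"got {fields[3]!r}") from exc
        color = fields[4].strip() if len(fields) >= 5 and fields[4].strip() else None
        rows.append(ConfigRow(
            bam=bam, region=fields[1].strip(), title=fields[2].strip(),
            fraglen=fraglen, color=color, control=control,
        ))
    return PlotSpec(rows=rows)


def serialize_config(rows: list[ConfigRow] | PlotSpec) -> str:
    """Inverse of :func:`parse_config`: parse(serialize(rows)) == rows."""
    if isinstance(rows, PlotSpec):
        rows = rows.rows
    lines = []
    for r in rows:
        lines.append("\t".join([
            r.bam_key, r.region, r.title, str(r.fraglen), r.color or ""
        ]).rstrip("\t"))
    return "\n".join(lines) + "\n"


def layout_grid(spec: PlotSpec) -> list[list[ConfigRow | None]]:
    """Region x BAM panel assignment; cells with no configured row are None.

    Grid order follows first appearance in the configuration, so shuffling
    rows that pair the same regions and BAMs yields the same set of
    populated cells.
    """
    grid: list[list[ConfigRow | None]] = [
        [None] * len(spec.unique_bams) for _ in spec.unique_regions
    ]
    for row in spec.rows:
        r = spec.unique_regions.index(row.region)
        b = spec.unique_bams.index(row.bam_key)
        if grid[r][b] is None:
            grid[r][b] = row
    return grid
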