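"""Gene-panel region model.

A reportable-gene panel is configured as a list of genes, each with the
exon coordinates of its selected (longest) RefSeq transcript on hg19.  The
analysis region of a gene is the interval from the first exon start to the
last exon end, extended symmetrically by a flank (default 1,000 bases) to
capture the 5' and 3' UTR margins.  Two panel genes carry comparison
exclusion masks: MSH3 exon 1 and the PMS2 exons with high homology to the
PMS2CL pseudogene (exon 9 and exons 11-15); variants inside those masks are
removed from orthogonal comparisons.

All coordinates are internally 0-based, half-open (BED convention).  VCF
positions are converted on ingest.  Flanking is symmetric regardless of
strand: "upstream and downstream" is interpreted as both transcript ends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Interval",
    "PanelGene",
    "PanelRegion",
    "PanelConfig",
    "ConfigurationError",
    "build_region",
    "apply_exclusions",
    "write_bed",
    "read_bed",
    "load_panel_config",
    "save_panel_config",
]

DEFAULT_FLANK = 1000
DEFAULT_VAF_THRESHOLD = 0.10

#: Comparison exclusion masks, as 1-based inclusive exon-number ranges in
#: transcript order.  PMS2 exon 9 and exons 11-15 are confounded by the
#: PMS2CL pseudogene; MSH3 exon 1 is a known assay limitation.
DEFAULT_EXCLUDED_EXONS: dict[str, list[tuple[int, int]]] = {
    "PMS2": [(9, 9), (11, 15)],
    "MSH3": [(1, 1)],
}


class ConfigurationError(ValueError):
    """Raised when a panel configuration is internally inconsistent."""


@dataclass(frozen=True, order=True)
class Interval:
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def intersection_length(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def normalize_chrom(chrom: str, use_prefix: bool) -> str:
    """Normalize a contig name to the configured 'chr'-prefix convention."""
    bare = chrom[3:] if chrom.startswith("chr") else chrom
    return f"chr{bare}" if use_prefix else bare


@dataclass
class PanelGene:
    """A reportable gene: selected transcript exons on one contig.

    Exons are ordered by genomic start and must not overlap.  Exon
    *numbering* (as used in CNV matching and exclusion masks) follows
    transcription direction: exon 1 is the leftmost exon for '+' strand
    genes and the rightmost for '-' strand genes.
    """

    symbol: str
    chrom: str
    transcript_id: str
    exons: list[tuple[int, int]]
    strand: str = "+"
    condition: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ConfigurationError(f"{self.symbol}: strand must be + or -")
        exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ConfigurationError(f"{self.symbol}: overlapping exons")
        for s, e in exons:
            if s < 0 or e <= s:
                raise ConfigurationError(f"{self.symbol}: bad exon [{s},{e})")
        self.exons = exons

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_interval(self, number: int) -> Interval:
        """Exon by transcript number (1-based, transcription direction)."""
        if not 1 <= number <= len(self.exons):
            raise ConfigurationError(
                f"{self.symbol}: exon {number} out of range 1..{len(self.exons)}"
            )
        idx = number - 1 if self.strand == "+" else len(self.exons) - number
        s, e = self.exons[idx]
        return Interval(self.chrom, s, e)

    def exon_number(self, idx_by_start: int) -> int:
        """Transcript exon number of the idx-th exon in genomic order."""
        if self.strand == "+":
            return idx_by_start + 1
        return len(self.exons) - idx_by_start


@dataclass
class PanelRegion:
    """Analysis region of one panel gene: flanked exon span plus masks."""

    symbol: str
    interval: Interval
    flank: int
    exclusions: list[Interval] = field(default_factory=list)


@dataclass
class PanelConfig:
    """The full panel: genes, flank, VAF threshold, exclusion masks."""

    genes: list[PanelGene]
    flank_bases: int = DEFAULT_FLANK
    vaf_threshold: float = DEFAULT_VAF_THRESHOLD
    genome_build: str = "hg19"
    excluded_regions: dict[str, list[tuple[int, int]]] = field(
        default_factory=lambda: dict(DEFAULT_EXCLUDED_EXONS)
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.vaf_threshold < 1.0:
            raise ConfigurationError("vaf_threshold must lie in (0,1)")
        if self.flank_bases < 0:
            raise ConfigurationError("flank_bases must be >= 0")
        seen: set[str] = set()
        for g in self.genes:
            if g.symbol in seen:
                raise ConfigurationError(f"duplicate gene symbol {g.symbol}")
            seen.add(g.symbol)
        for sym in list(self.excluded_regions):
            if sym not in seen:
                # default masks are harmless on panels lacking the gene
                if self.excluded_regions[sym] == DEFAULT_EXCLUDED_EXONS.get(sym):
                    del self.excluded_regions[sym]
                else:
                    raise ConfigurationError(
                        f"excluded_regions names {sym!r}, not a panel gene"
                    )

    def gene(self, symbol: str) -> PanelGene:
        for g in self.genes:
            if g.symbol == symbol:
                return g
        raise KeyError(symbol)

    def regions(self) -> list[PanelRegion]:
        """Build flanked regions for every gene with exclusions applied."""
        out = []
        for g in self.genes:
            r = build_region(g, self.flank_bases)
            out.append(apply_exclusions(r, self))
        return out


def build_region(gene: PanelGene, flank: int = DEFAULT_FLANK) -> PanelRegion:
    """Flanked analysis region: [first exon start - flank, last exon end + flank).

    The start is clamped at 0.  Flanking is strand-independent.
    """
    if not gene.exons:
        raise ConfigurationError(f"{gene.symbol}: gene has no exons")
    if flank < 0:
        raise ConfigurationError("flank must be >= 0")
    start = max(0, gene.exons[0][0] - flank)
    end = gene.exons[-1][1] + flank
    return PanelRegion(gene.symbol, Interval(gene.chrom, start, end), flank)


def apply_exclusions(region: PanelRegion, config: PanelConfig) -> PanelRegion:
    """Populate the region's comparison exclusion masks from the config.

    Exclusions are configured as transcript exon-number ranges and resolved
    to genomic intervals via the gene's exon list.  Genes without a mask
    entry are returned unchanged.
    """
    spans = config.excluded_regions.get(region.symbol)
    if not spans:
        return region
    gene = config.gene(region.symbol)
    masks: list[Interval] = []
    for lo, hi in spans:
        for number in range(lo, hi + 1):
            iv = gene.exon_interval(number)
            if not iv.overlaps(region.interval):
                raise ConfigurationError(
                    f"{region.symbol}: exclusion exon {number} outside gene region"
                )
            masks.append(iv)
    masks.sort()
    return PanelRegion(region.symbol, region.interval, region.flank, masks)


def _chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    bare = chrom[3:] if chrom.startswith("chr") else chrom
    if bare.isdigit():
        return (0, int(bare))
    order = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if bare in order:
        return (0, order[bare])
    if bare == "":
        raise ConfigurationError(f"unsortable contig name {chrom!r}")
    return (1, bare)


def write_bed(
    regions: Sequence[PanelRegion],
    path: str | Path,
    exclusions_path: str | Path | None = None,
) -> None:
    """Write regions as 4-column BED, sorted by contig then start.

    Exclusion masks, if any region has them, go to a companion BED whose
    name column is ``SYMBOL_excl``.
    """
    if not regions:
        raise ValueError("no regions to write")
    rows = sorted(
        regions, key=lambda r: (_chrom_sort_key(r.interval.chrom), r.interval.start)
    )
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t{r.symbol}\n"
            )
    if exclusions_path is not None:
        excl = [
            (iv, r.symbol)
            for r in regions
            for iv in r.exclusions
        ]
        excl.sort(key=lambda t: (_chrom_sort_key(t[0].chrom), t[0].start))
        with open(exclusions_path, "w") as fh:
            for iv, sym in excl:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{sym}_excl\n")


def read_bed(path: str | Path) -> list[PanelRegion]:
    """Read a 4-column BED written by :func:`write_bed` (flank unknown → 0)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name = line.split("\t")[:4]
            out.append(PanelRegion(name, Interval(chrom, int(start), int(end)), 0))
    return out


def save_panel_config(config: PanelConfig, path: str | Path) -> None:
    """Serialize a panel config to the JSON schema of :func:`load_panel_config`."""
    payload = {
        "flank_bases": config.flank_bases,
        "vaf_threshold": config.vaf_threshold,
        "genome_build": config.genome_build,
        "excluded_regions": {
            k: [list(v) for v in vv] for k, vv in config.excluded_regions.items()
        },
        "genes": [
            {
                "symbol": g.symbol,
                "chrom": g.chrom,
                "transcript_id": g.transcript_id,
                "strand": g.strand,
                "condition": g.condition,
                "exons": [list(e) for e in g.exons],
            }
            for g in config.genes
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_panel_config(path: str | Path) -> PanelConfig:
    """Load and validate a JSON panel configuration.

    Schema::

        {"flank_bases": 1000, "vaf_threshold": 0.10, "genome_build": "hg19",
         "excluded_regions": {"PMS2": [[9, 9], [11, 15]], "MSH3": [[1, 1]]},
         "genes": [{"symbol": ..., "chrom": ..., "transcript_id": ...,
                    "strand": "+", "condition": ...,
                    "exons": [[start, end], ...]}, ...]}
    """
    with open(path) as fh:
        raw = json.load(fh)
    try:
        genes = [
            PanelGene(
                symbol=g["symbol"],
                chrom=g["chrom"],
                transcript_id=g.get("transcript_id", ""),
                exons=[tuple(e) for e in g["exons"]],
                strand=g.get("strand", "+"),
                condition=g.get("condition", ""),
            )
            for g in raw["genes"]
        ]
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed panel config {path}: {exc}") from exc
    return PanelConfig(
        genes=genes,
        flank_bases=raw.get("flank_bases", DEFAULT_FLANK),
        vaf_threshold=raw.get("vaf_threshold", DEFAULT_VAF_THRESHOLD),
        genome_build=raw.get("genome_build", "hg19"),
        excluded_regions={
            k: [tuple(v) for v in vv]
            for k, vv in raw.get(
                "excluded_regions", DEFAULT_EXCLUDED_EXONS
            ).items()
        },
    )
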