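"""Genome coordinate system, annotation containers and feature classification.

All coordinates are 0-based, half-open (BED native).  The classification
rules follow the three-way genomic partition used throughout the pipeline:

* **promoter** — 2 kb centered on a TSS; sub-classified by CpG-island
  context (CGI > shore > shelf > non-CGI),
* **intragenic** — gene body outside promoters; sub-classified
  CGI > repeat > exon (first exon excluded) > intron > 3'UTR,
* **intergenic** — everything else; sub-classified CGI > repeat.

CGI *shores* are the 0–2 kb flanks of a CpG island on both sides, and
*shelves* the 2–4 kb flanks, each set made disjoint from the islands and
from the shores.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from intervaltree import IntervalTree

PROMOTER_HALF_WIDTH = 1000  # bp; promoter = 2 kb centered on the TSS
SHORE_WIDTH = 2000  # bp flank defining a CGI shore
SHELF_WIDTH = 2000  # bp flank beyond the shore defining a CGI shelf

REPEAT_CLASSES = ("LINE", "SINE", "LTR", "satellite", "other")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on `chrom`."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class FeatureLabel:
    """Primary genomic class and sub-feature of a region."""

    primary: str  # promoter | intragenic | intergenic
    sub: str  # CGI, shore, shelf, nonCGI, exon, intron, utr3, repeat:<class>, none

    _VALID = {
        "promoter": {"CGI", "shore", "shelf", "nonCGI"},
        "intragenic": {"CGI", "exon", "intron", "utr3", "none"},
        "intergenic": {"CGI", "none"},
    }

    def __post_init__(self) -> None:
        ok = self.sub in self._VALID.get(self.primary, set()) or (
            self.primary in ("intragenic", "intergenic")
            and self.sub.startswith("repeat:")
        )
        if not ok:
            raise ValueError(f"sub {self.sub!r} invalid for primary {self.primary!r}")


# ---------------------------------------------------------------------------
# interval algebra on plain (start, end) pairs within one chromosome
# ---------------------------------------------------------------------------


def merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching half-open spans into a sorted disjoint list."""
    spans = sorted(spans)
    out: list[list[int]] = []
    for s, e in spans:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def subtract_spans(
    spans: Sequence[tuple[int, int]], cut: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set-subtract merged `cut` spans from merged `spans` (both half-open)."""
    cut = merge_spans(cut)
    out: list[tuple[int, int]] = []
    for s, e in merge_spans(spans):
        cur = s
        for cs, ce in cut:
            if ce <= cur:
                continue
            if cs >= e:
                break
            if cs > cur:
                out.append((cur, cs))
            cur = max(cur, ce)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def total_span_length(spans: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_spans(spans))


# ---------------------------------------------------------------------------
# annotation container
# ---------------------------------------------------------------------------


@dataclass
class GenomeAnnotation:
    """Strand-aware genome annotation used by every caller and tally.

    ``tss`` maps each gene to a width-1 interval at its transcription start;
    ``genes`` holds the gene-body span (TSS to transcript end).  Interval
    lists are per-feature; lookup trees are built lazily and cached.
    """

    chrom_sizes: dict[str, int]
    tss: list[tuple[GenomicInterval, str]]  # (width-1 interval, gene_id)
    genes: list[tuple[GenomicInterval, str]]
    cgis: list[GenomicInterval]
    exons: list[tuple[GenomicInterval, str]]
    first_exons: list[tuple[GenomicInterval, str]]
    introns: list[tuple[GenomicInterval, str]]
    utr3: list[tuple[GenomicInterval, str]]
    repeats: list[tuple[GenomicInterval, str]]  # (interval, repeat class)
    _trees: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        for iv in self._all_intervals():
            size = self.chrom_sizes.get(iv.chrom)
            if size is None:
                raise ValueError(f"interval on unknown chromosome {iv.chrom}")
            if iv.end > size:
                raise ValueError(f"interval {iv} beyond chromosome end {size}")
        first_by_gene = {}
        for iv, g in self.first_exons:
            first_by_gene.setdefault(g, []).append(iv)
        exon_by_gene: dict[str, list[GenomicInterval]] = {}
        for iv, g in self.exons:
            exon_by_gene.setdefault(g, []).append(iv)
        for g, firsts in first_by_gene.items():
            for iv in firsts:
                if iv not in exon_by_gene.get(g, []):
                    raise ValueError(f"first exon of {g} not among its exons")

    def _all_intervals(self) -> Iterable[GenomicInterval]:
        for iv, _ in self.tss:
            yield iv
        for iv, _ in self.genes:
            yield iv
        yield from self.cgis
        for lst in (self.exons, self.first_exons, self.introns, self.utr3, self.repeats):
            for iv, _ in lst:
                yield iv

    # -- derived tracks -----------------------------------------------------

    def promoters(self, half_width: int = PROMOTER_HALF_WIDTH) -> dict[str, GenomicInterval]:
        """Per-gene promoter: `2*half_width` bp centered on the TSS, clipped."""
        return {
            gene: promoter_of(iv, self.chrom_sizes, half_width)
            for iv, gene in self.tss
        }

    def shores_shelves(self) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
        return shores_and_shelves(self.cgis, self.chrom_sizes)

    # -- lookup trees -------------------------------------------------------

    def _tree(self, name: str) -> dict[str, IntervalTree]:
        if name in self._trees:
            return self._trees[name]
        items: list[tuple[GenomicInterval, object]]
        if name == "promoter":
            items = [(iv, g) for g, iv in self.promoters().items()]
        elif name == "gene":
            items = list(self.genes)
        elif name == "cgi":
            items = [(iv, None) for iv in self.cgis]
        elif name == "shore":
            items = [(iv, None) for iv in self.shores_shelves()[0]]
        elif name == "shelf":
            items = [(iv, None) for iv in self.shores_shelves()[1]]
        elif name == "exon_not_first":
            firsts = {(iv.chrom, iv.start, iv.end, g) for iv, g in self.first_exons}
            items = [
                (iv, g)
                for iv, g in self.exons
                if (iv.chrom, iv.start, iv.end, g) not in firsts
            ]
        elif name == "intron":
            items = list(self.introns)
        elif name == "utr3":
            items = list(self.utr3)
        elif name == "repeat":
            items = list(self.repeats)
        else:  # pragma: no cover - internal misuse
            raise KeyError(name)
        trees: dict[str, IntervalTree] = {}
        for iv, payload in items:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, payload)
        self._trees[name] = trees
        return trees

    def overlapping(self, name: str, region: GenomicInterval) -> list:
        tree = self._tree(name).get(region.chrom)
        if tree is None:
            return []
        return sorted(tree.overlap(region.start, region.end))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def promoter_of(
    tss: GenomicInterval,
    chrom_sizes: Mapping[str, int],
    half_width: int = PROMOTER_HALF_WIDTH,
) -> GenomicInterval:
    """Promoter interval: `half_width` bp each side of the TSS, clipped.

    Centering is strand-independent.  The TSS position is taken as the
    start of the width-1 interval.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    size = chrom_sizes.get(tss.chrom)
    if size is None:
        raise ValueError(f"unknown chromosome {tss.chrom}")
    pos = tss.start
    if not (0 <= pos < size):
        raise ValueError(f"TSS position {pos} outside chromosome {tss.chrom}")
    return GenomicInterval(
        tss.chrom, max(0, pos - half_width), min(size, pos + half_width), tss.strand
    )


def shores_and_shelves(
    cgis: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """CGI shores (0–2 kb flanks) and shelves (2–4 kb flanks) on both sides.

    Overlapping CGIs are merged first; shores exclude any CGI base and
    shelves exclude both CGIs and shores, so the three track sets are
    mutually disjoint.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in cgis:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    shores: list[GenomicInterval] = []
    shelves: list[GenomicInterval] = []
    for chrom, spans in sorted(by_chrom.items()):
        merged = merge_spans(spans)
        limit = chrom_sizes.get(chrom) if chrom_sizes else None
        shore_raw, shelf_raw = [], []
        for s, e in merged:
            shore_raw += [(s - SHORE_WIDTH, s), (e, e + SHORE_WIDTH)]
            shelf_raw += [
                (s - SHORE_WIDTH - SHELF_WIDTH, s - SHORE_WIDTH),
                (e + SHORE_WIDTH, e + SHORE_WIDTH + SHELF_WIDTH),
            ]

        def _clip(spans_raw: list[tuple[int, int]]) -> list[tuple[int, int]]:
            out = []
            for s, e in spans_raw:
                s = max(0, s)
                if limit is not None:
                    e = min(e, limit)
                if s < e:
                    out.append((s, e))
            return out

        shore_spans = subtract_spans(_clip(shore_raw), merged)
        shelf_spans = subtract_spans(_clip(shelf_raw), merged + shore_spans)
        shores += [GenomicInterval(chrom, s, e) for s, e in shore_spans]
        shelves += [GenomicInterval(chrom, s, e) for s, e in shelf_spans]
    return shores, shelves


def classify_region(region: GenomicInterval, annotation: GenomeAnnotation) -> FeatureLabel:
    """Classify a region by ≥1 bp overlap with fixed precedence.

    Primary precedence: promoter > intragenic > intergenic.  Sub-feature
    precedence within promoters: CGI > shore > shelf > nonCGI; within
    gene bodies: CGI > repeat > exon (first excluded) > intron > 3'UTR;
    within intergenic space: CGI > repeat.
    """
    if region.chrom not in annotation.chrom_sizes:
        raise ValueError(f"unknown chromosome {region.chrom}")

    def hits(name: str) -> list:
        return annotation.overlapping(name, region)

    if hits("promoter"):
        for name, sub in (("cgi", "CGI"), ("shore", "shore"), ("shelf", "shelf")):
            if hits(name):
                return FeatureLabel("promoter", sub)
        return FeatureLabel("promoter", "nonCGI")
    if hits("gene"):
        if hits("cgi"):
            return FeatureLabel("intragenic", "CGI")
        rep = hits("repeat")
        if rep:
            return FeatureLabel("intragenic", f"repeat:{rep[0].data}")
        if hits("exon_not_first"):
            return FeatureLabel("intragenic", "exon")
        if hits("intron"):
            return FeatureLabel("intragenic", "intron")
        if hits("utr3"):
            return FeatureLabel("intragenic", "utr3")
        return FeatureLabel("intragenic", "none")
    if hits("cgi"):
        return FeatureLabel("intergenic", "CGI")
    rep = hits("repeat")
    if rep:
        return FeatureLabel("intergenic", f"repeat:{rep[0].data}")
    return FeatureLabel("intergenic", "none")


# ---------------------------------------------------------------------------
# BED / chrom.sizes I/O
# ---------------------------------------------------------------------------

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3–BED6 file into a DataFrame with canonical column names."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df.columns = _BED_COLS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df:
            df[col] = default
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in _BED_COLS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, sep="\t", header=False, index=False)


def intervals_to_bed(
    items: Iterable[tuple[GenomicInterval, str]], path: str | Path
) -> None:
    rows = [
        (iv.chrom, iv.start, iv.end, name, 0, iv.strand) for iv, name in items
    ]
    pd.DataFrame(rows, columns=_BED_COLS).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={0: str})
    return dict(zip(df.chrom, df["size"].astype(int)))


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def _bed_to_pairs(df: pd.DataFrame) -> list[tuple[GenomicInterval, str]]:
    return [
        (GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand), str(r.name))
        for r in df.itertuples(index=False)
    ]


def load_annotation(config_path: str | Path) -> GenomeAnnotation:
    """Load an annotation bundle from a YAML config of BED paths.

    Expected keys: chrom_sizes, tss, genes, cgis, exons, first_exons,
    introns, utr3, repeats.  Relative paths resolve against the config file.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = config_path.parent

    def p(key: str) -> Path:
        return base / cfg[key]

    return GenomeAnnotation(
        chrom_sizes=read_chrom_sizes(p("chrom_sizes")),
        tss=_bed_to_pairs(read_bed(p("tss"))),
        genes=_bed_to_pairs(read_bed(p("genes"))),
        cgis=[iv for iv, _ in _bed_to_pairs(read_bed(p("cgis")))],
        exons=_bed_to_pairs(read_bed(p("exons"))),
        first_exons=_bed_to_pairs(read_bed(p("first_exons"))),
        introns=_bed_to_pairs(read_bed(p("introns"))),
        utr3=_bed_to_pairs(read_bed(p("utr3"))),
        repeats=_bed_to_pairs(read_bed(p("repeats"))),
    )


def save_annotation(annotation: GenomeAnnotation, outdir: str | Path) -> Path:
    """Write the annotation bundle as BED files plus a YAML config; return config path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_chrom_sizes(annotation.chrom_sizes, outdir / "chrom.sizes")
    intervals_to_bed(annotation.tss, outdir / "tss.bed")
    intervals_to_bed(annotation.genes, outdir / "genes.bed")
    intervals_to_bed([(iv, ".") for iv in annotation.cgis], outdir / "cgis.bed")
    intervals_to_bed(annotation.exons, outdir / "exons.bed")
    intervals_to_bed(annotation.first_exons, outdir / "first_exons.bed")
    intervals_to_bed(annotation.introns, outdir / "introns.bed")
    intervals_to_bed(annotation.utr3, outdir / "utr3.bed")
    intervals_to_bed(annotation.repeats, outdir / "repeats.bed")
    cfg = {
        "chrom_sizes": "chrom.sizes",
        "tss": "tss.bed",
        "genes": "genes.bed",
        "cgis": "cgis.bed",
        "exons": "exons.bed",
        "first_exons": "first_exons.bed",
        "introns": "introns.bed",
        "utr3": "utr3.bed",
        "repeats": "repeats.bed",
    }
    cfg_path = outdir / "annotation.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return cfg_path
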