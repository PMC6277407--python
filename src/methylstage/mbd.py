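"""MBD-seq arm: bin counting, MES transform, CNV correction and DMR calling.

Enrichment reads are counted into fixed 200-bp bins and transformed into a
methylation enrichment score, the log2 ratio of a bin's per-bp read density
to the genome-wide average density::

    MES(bin) = log2( (n / bin_size) / (total_n / L) )

so MES = 0 marks a bin at exactly genome-average density and an MES
difference of 1 between samples is a 2-fold enrichment change.  Tumor
tracks are CNV-corrected (counts scaled by 2/CN) before the transform so
aneuploidy does not masquerade as methylation change.  Differential regions
come from a sliding 1-kb tile (five bins, 200-bp step): a paired t-test on
the per-bin MES differences plus a 2-fold change threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .genome import GenomeAnnotation, GenomicInterval, merge_spans
from .records import DMPRecord, DMRecord, EARLY_ONSET, GT_SPECIFIC, HYPER, HYPO

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 200  # bp
DEFAULT_EXTENSION = 200  # bp fragment footprint from the read start
TILE_BINS = 5  # 1-kb tile = five 200-bp bins
DEPTH_HISTOGRAM_EDGES = ((1, 5), (6, 25), (26, 100), (101, None))


@dataclass
class BinTrack:
    """Per-sample read counts on a fixed bin grid, with CNV-corrected counts
    and MES values filled in by the pipeline stages.

    ``corrected`` starts equal to ``raw``; NaN marks a bin excluded from
    testing (copy-number 0).  ``mes`` is NaN for uncovered bins.
    """

    sample_id: str
    bin_size: int
    chrom_sizes: dict[str, int]
    raw: dict[str, np.ndarray]
    corrected: dict[str, np.ndarray] = field(default_factory=dict)
    mes: dict[str, np.ndarray] = field(default_factory=dict)
    n_clipped: int = 0

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            n_bins = -(-size // self.bin_size)
            if chrom not in self.raw:
                self.raw[chrom] = np.zeros(n_bins, dtype=np.int64)
            if len(self.raw[chrom]) != n_bins:
                raise ValueError(f"bin grid mismatch on {chrom}")
            if (self.raw[chrom] < 0).any():
                raise ValueError("negative bin counts")
            if chrom not in self.corrected:
                self.corrected[chrom] = self.raw[chrom].astype(float)

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    @property
    def total_n(self) -> int:
        return int(sum(a.sum() for a in self.raw.values()))

    @property
    def corrected_total(self) -> float:
        return float(sum(np.nansum(a) for a in self.corrected.values()))

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    def copy(self) -> "BinTrack":
        return BinTrack(
            self.sample_id,
            self.bin_size,
            dict(self.chrom_sizes),
            {c: a.copy() for c, a in self.raw.items()},
            {c: a.copy() for c, a in self.corrected.items()},
            {c: a.copy() for c, a in self.mes.items()},
            self.n_clipped,
        )

    def bin_interval(self, chrom: str, index: int) -> GenomicInterval:
        start = index * self.bin_size
        return GenomicInterval(
            chrom, start, min(start + self.bin_size, self.chrom_sizes[chrom])
        )


def count_bins(
    read_starts: Iterable[tuple[str, int, str]],
    chrom_sizes: Mapping[str, int],
    extension: int = DEFAULT_EXTENSION,
    bin_size: int = DEFAULT_BIN_SIZE,
    sample_id: str = "sample",
) -> BinTrack:
    """Count extended read footprints into fixed bins.

    Each read is extended to `extension` bp: plus-strand reads extend
    rightward from their start, minus-strand reads leftward from their
    3'-most aligned position.  A read increments every bin its footprint
    overlaps by at least 1 bp.  Footprints reaching past a chromosome end
    are clipped (counted in ``n_clipped``).
    """
    if extension <= 0:
        raise ValueError("extension must be positive")
    track = BinTrack(sample_id, bin_size, dict(chrom_sizes), {})
    n_clipped = 0
    for chrom, pos, strand in read_starts:
        size = chrom_sizes.get(chrom)
        if size is None:
            raise ValueError(f"read on unknown chromosome {chrom}")
        if not (0 <= pos < size):
            raise ValueError(f"read position {pos} outside {chrom}")
        if strand == "-":
            fs, fe = pos + 1 - extension, pos + 1
        else:
            fs, fe = pos, pos + extension
        if fs < 0 or fe > size:
            n_clipped += 1
            fs, fe = max(0, fs), min(size, fe)
        first, last = fs // bin_size, (fe - 1) // bin_size
        track.raw[chrom][first : last + 1] += 1
    track.corrected = {c: a.astype(float) for c, a in track.raw.items()}
    track.n_clipped = n_clipped
    if n_clipped:
        logger.warning("%d read footprints clipped at chromosome ends", n_clipped)
    return track


def mes_transform(track: BinTrack, pseudocount: float | None = None) -> BinTrack:
    """Fill the methylation enrichment score for every covered bin.

    Operates on CNV-corrected counts (equal to raw counts if no correction
    was applied).  Bins with zero count get an NaN "uncovered" sentinel and
    are excluded from downstream tests; with `pseudocount` set, every bin
    instead receives ``count + pseudocount`` and none is uncovered.
    """
    out = track.copy()
    length = out.genome_length
    if length <= 0:
        raise ValueError("genome length must be positive")
    if pseudocount is not None:
        n_bins = sum(len(a) for a in out.corrected.values())
        total = out.corrected_total + pseudocount * n_bins
    else:
        total = out.corrected_total
    if not total > 0:
        raise ValueError("track has no reads; MES undefined")
    mean_density = total / length
    for chrom, counts in out.corrected.items():
        c = counts + pseudocount if pseudocount is not None else counts
        with np.errstate(divide="ignore", invalid="ignore"):
            mes = np.log2((c / out.bin_size) / mean_density)
        mes[~(c > 0)] = np.nan
        out.mes[chrom] = mes
    return out


def cnv_correct(
    track: BinTrack, cnv_segments: Sequence[tuple[GenomicInterval, int]]
) -> BinTrack:
    """Rescale counts to a diploid reference: corrected = raw × 2 / CN.

    A bin belongs to a segment when its midpoint lies inside it.  Bins in
    CN=0 segments are marked uncovered (NaN); bins outside any segment are
    assumed diploid and left unchanged.  Overlapping segments are an error.
    """
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for iv, cn in cnv_segments:
        if cn < 0 or int(cn) != cn:
            raise ValueError(f"copy number must be a nonnegative integer, got {cn}")
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, int(cn)))
    for chrom, segs in by_chrom.items():
        segs.sort()
        for (s1, e1, _), (s2, _, _) in zip(segs, segs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping CNV segments on {chrom}")
    out = track.copy()
    for chrom, counts in out.raw.items():
        corrected = counts.astype(float)
        mids = np.arange(len(counts)) * out.bin_size + out.bin_size / 2
        for s, e, cn in by_chrom.get(chrom, []):
            mask = (mids >= s) & (mids < e)
            if cn == 0:
                corrected[mask] = np.nan
            else:
                corrected[mask] = counts[mask] * 2.0 / cn
        out.corrected[chrom] = corrected
    out.mes = {}
    return out


# ---------------------------------------------------------------------------
# coverage / depth summary
# ---------------------------------------------------------------------------


def _class_bin_masks(
    track: BinTrack, annotation: GenomeAnnotation
) -> dict[str, dict[str, np.ndarray]]:
    """Boolean per-bin membership masks for the four summary region classes."""
    promoters = [iv for iv in annotation.promoters().values()]
    genes = [iv for iv, _ in annotation.genes]
    masks: dict[str, dict[str, np.ndarray]] = {}
    for chrom, size in track.chrom_sizes.items():
        n_bins = len(track.raw[chrom])
        prom = np.zeros(n_bins, dtype=bool)
        cgi = np.zeros(n_bins, dtype=bool)
        genic = np.zeros(n_bins, dtype=bool)

        def mark(mask: np.ndarray, spans: Iterable[tuple[int, int]]) -> None:
            for s, e in spans:
                mask[s // track.bin_size : -(-e // track.bin_size)] = True

        mark(prom, ((iv.start, iv.end) for iv in promoters if iv.chrom == chrom))
        mark(cgi, ((iv.start, iv.end) for iv in annotation.cgis if iv.chrom == chrom))
        mark(genic, ((iv.start, iv.end) for iv in genes if iv.chrom == chrom))
        masks[chrom] = {
            "whole_genome": np.ones(n_bins, dtype=bool),
            "promoters": prom,
            "CGIs": cgi,
            "intergenic": ~(prom | genic),
        }
    return masks


def coverage_depth_summary(
    track: BinTrack, annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Covered-bin fraction and read-depth histogram per region class.

    A bin is covered when it holds at least one read.  Depth histogram
    bins: 1–5, 6–25, 26–100, >100 reads.
    """
    masks = _class_bin_masks(track, annotation)
    rows = []
    for cls in ("whole_genome", "promoters", "CGIs", "intergenic"):
        counts = np.concatenate(
            [track.raw[chrom][masks[chrom][cls]] for chrom in track.chroms]
        )
        n_bins = len(counts)
        covered = int((counts > 0).sum())
        row = {
            "region_class": cls,
            "n_bins": n_bins,
            "covered_bins": covered,
            "covered_fraction": covered / n_bins if n_bins else float("nan"),
        }
        for lo, hi in DEPTH_HISTOGRAM_EDGES:
            label = f"depth_{lo}_{hi}" if hi is not None else f"depth_gt_{lo - 1}"
            sel = counts >= lo if hi is None else (counts >= lo) & (counts <= hi)
            row[label] = int(sel.sum())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sliding-tile differential test
# ---------------------------------------------------------------------------


def tile_test(
    track_a: BinTrack,
    track_b: BinTrack,
    tile_size: int = TILE_BINS * DEFAULT_BIN_SIZE,
    step: int = DEFAULT_BIN_SIZE,
    alpha: float = 0.01,
    min_fold: float = 2.0,
    min_covered_bins: int = 3,
) -> pd.DataFrame:
    """Paired t-test of per-bin MES differences in sliding 1-kb tiles.

    For each tile the differences d_i = MES_B − MES_A over bins covered in
    both samples are tested (df = k−1, k ≥ `min_covered_bins`); the fold
    change is 2^mean(d).  Direction is hyper when fold ≥ `min_fold` and
    p < `alpha`, hypo when fold ≤ 1/`min_fold` and p < `alpha`.  Tiles with
    zero variance and nonzero mean difference are significant in the limit
    (p = 0); zero mean with zero variance is not (p = 1).  Tiles with fewer
    than `min_covered_bins` shared covered bins are skipped.
    """
    if track_a.bin_size != track_b.bin_size:
        raise ValueError("tracks must share a bin grid")
    bin_size = track_a.bin_size
    if tile_size % bin_size or step % bin_size:
        raise ValueError("tile_size and step must be multiples of bin_size")
    k_bins = tile_size // bin_size
    step_bins = step // bin_size
    if not track_a.mes or not track_b.mes:
        raise ValueError("run mes_transform on both tracks first")

    frames = []
    n_skipped = 0
    for chrom in track_a.chroms:
        d = track_b.mes[chrom] - track_a.mes[chrom]
        if len(d) < k_bins:
            continue
        w = sliding_window_view(d, k_bins)[::step_bins]
        valid = ~np.isnan(w)
        k = valid.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            total = np.nansum(np.where(valid, w, 0.0), axis=1)
            mean = total / k
            ss = np.nansum(np.where(valid, w * w, 0.0), axis=1)
            var = np.maximum(ss - k * mean * mean, 0.0) / np.maximum(k - 1, 1)
            sd = np.sqrt(var)
            tstat = mean / (sd / np.sqrt(k))
        p = np.full(len(w), np.nan)
        ok = k >= min_covered_bins
        n_skipped += int((~ok).sum())
        regular = ok & (sd > 0)
        p[regular] = 2.0 * stats.t.sf(np.abs(tstat[regular]), df=k[regular] - 1)
        degenerate = ok & (sd == 0)
        p[degenerate] = np.where(mean[degenerate] != 0.0, 0.0, 1.0)
        fold = np.power(2.0, mean)
        direction = np.full(len(w), "none", dtype=object)
        direction[(p < alpha) & (fold >= min_fold)] = HYPER
        direction[(p < alpha) & (fold <= 1.0 / min_fold)] = HYPO
        starts = np.arange(len(w)) * step
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + tile_size,
                    "k": k,
                    "mean_mes_diff": mean,
                    "fold_change": fold,
                    "p_value": p,
                    "direction": direction,
                }
            )[ok]
        )
    if n_skipped:
        logger.info("%d tiles skipped (<%d covered bins)", n_skipped, min_covered_bins)
    if not frames:
        return pd.DataFrame(
            columns=[
                "chrom", "start", "end", "k",
                "mean_mes_diff", "fold_change", "p_value", "direction",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def assemble_dmrs(
    tiles: pd.DataFrame, platform: str = "MBD", comparison: str = "GT"
) -> list[DMRecord]:
    """Merge overlapping/adjacent significant tiles of one direction into DMRs.

    The merged record spans the union of its tiles and carries the best
    (smallest) tile p-value and that tile's fold change.  Opposite
    directions are never merged, even when adjacent.
    """
    records: list[DMRecord] = []
    sig = tiles[tiles["direction"].isin((HYPER, HYPO))]
    for (chrom, direction), grp in sig.groupby(["chrom", "direction"], sort=True):
        grp = grp.sort_values("start")
        cur_start = cur_end = None
        best_p, best_fold = np.inf, np.nan

        def flush() -> None:
            if cur_start is not None:
                records.append(
                    DMRecord(
                        region=GenomicInterval(chrom, int(cur_start), int(cur_end)),
                        platform=platform,
                        direction=direction,
                        comparison=comparison,
                        fold_change=float(best_fold),
                        p_value=float(best_p),
                    )
                )

        for row in grp.itertuples(index=False):
            if cur_start is None or row.start > cur_end:
                flush()
                cur_start, cur_end = row.start, row.end
                best_p, best_fold = row.p_value, row.fold_change
            else:
                cur_end = max(cur_end, row.end)
                if row.p_value < best_p:
                    best_p, best_fold = row.p_value, row.fold_change
        flush()
    records.sort(key=lambda r: (r.region.chrom, r.region.start, r.direction))
    return records


def classify_timing(
    gt_dmrs: Sequence[DMRecord], im_dmrs: Sequence[DMRecord]
) -> list[DMRecord]:
    """Label GT-vs-GM DMRs early-onset when a same-direction IM-vs-GM DMR
    overlaps them by ≥1 bp, otherwise GT-specific."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for rec in im_dmrs:
        key = (rec.region.chrom, rec.direction)
        trees.setdefault(key, IntervalTree()).addi(rec.region.start, rec.region.end)
    for rec in gt_dmrs:
        tree = trees.get((rec.region.chrom, rec.direction))
        hit = bool(tree and tree.overlap(rec.region.start, rec.region.end))
        rec.timing = EARLY_ONSET if hit else GT_SPECIFIC
    return list(gt_dmrs)


def mbd_dmps(
    dmrs: Sequence[DMRecord], annotation: GenomeAnnotation
) -> list[DMPRecord]:
    """Promoters overlapped (≥1 bp) by at least one DMR become DMPs.

    When DMRs of both directions overlap one promoter, the record with
    the largest overlap wins; ties break toward the smaller p-value.
    """
    trees: dict[str, IntervalTree] = {}
    for rec in dmrs:
        trees.setdefault(rec.region.chrom, IntervalTree()).addi(
            rec.region.start, rec.region.end, rec
        )
    dmps: list[DMPRecord] = []
    for gene, prom in sorted(annotation.promoters().items()):
        tree = trees.get(prom.chrom)
        if not tree:
            continue
        hits = [iv.data for iv in tree.overlap(prom.start, prom.end)]
        if not hits:
            continue
        best = max(
            hits,
            key=lambda r: (prom.overlap_len(r.region), -(r.p_value or 0.0)),
        )
        dmps.append(
            DMPRecord(
                gene_id=gene,
                promoter=prom,
                platforms={"MBD"},
                direction=best.direction,
                timing=best.timing,
                stats={
                    "MBD": {
                        "fold_change": best.fold_change,
                        "p_value": best.p_value,
                        "n_dmrs": len(hits),
                    }
                },
            )
        )
    return dmps


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def track_to_frame(track: BinTrack) -> pd.DataFrame:
    rows = []
    for chrom in track.chroms:
        starts = np.arange(len(track.raw[chrom])) * track.bin_size
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "bin_start": starts, "count": track.raw[chrom]}
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_bin_counts(track: BinTrack, path: str | Path) -> None:
    track_to_frame(track).to_csv(path, sep="\t", index=False)


def read_bin_counts(
    path: str | Path,
    chrom_sizes: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    sample_id: str | None = None,
) -> BinTrack:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    track = BinTrack(sample_id or Path(path).stem, bin_size, dict(chrom_sizes), {})
    for chrom, grp in df.groupby("chrom"):
        idx = (grp["bin_start"] // bin_size).to_numpy()
        track.raw[chrom][idx] = grp["count"].to_numpy()
    track.corrected = {c: a.astype(float) for c, a in track.raw.items()}
    return track


def write_mes_bedgraph(track: BinTrack, path: str | Path) -> None:
    """Write covered-bin MES values as a browser-loadable bedGraph."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.sample_id} MES"\n')
        for chrom in track.chroms:
            mes = track.mes.get(chrom)
            if mes is None:
                continue
            for i in np.flatnonzero(~np.isnan(mes)):
                iv = track.bin_interval(chrom, int(i))
                fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{mes[i]:.4f}\n")


def read_cnv_bed(path: str | Path) -> list[tuple[GenomicInterval, int]]:
    """CNV BED: chrom, start, end, name, copy-number in the score column."""
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    return [
        (GenomicInterval(str(r[0]), int(r[1]), int(r[2])), int(r[4]))
        for r in df.itertuples(index=False)
    ]


def write_cnv_bed(
    segments: Sequence[tuple[GenomicInterval, int]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for iv, cn in segments:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tCNV\t{cn}\t.\n")
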