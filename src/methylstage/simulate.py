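"""Synthetic three-stage (GM/IM/GT) methylome generator with known truth.

Emulates the structure of a staged gastric-carcinogenesis methylome at
desk scale: CpG-island promoters start unmethylated and gain methylation
in the tumor (and already in intestinal metaplasia for early-onset
events), non-CGI promoters and intergenic repeats start heavily methylated
and planted hypomethylation drops them, MBD enrichment counts follow local
methylation times CpG density with copy-number distortion of the tumor
sample, and RRBS read depth concentrates at CpG-dense regions.  A survival
cohort ties an exponential hazard to a linear combination of six
gene-expression values.

Every generator draws from a named substream of one seed, so changing one
component's parameters never perturbs another component's draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import (
    GenomeAnnotation,
    GenomicInterval,
    save_annotation,
)
from .mbd import BinTrack, write_bin_counts, write_cnv_bed
from .records import EARLY_ONSET, GT_SPECIFIC, HYPER, HYPO
from .rrbs import COUNT_COLUMNS, write_cpg_counts

SAMPLES = ("gm", "im", "gt")

# six-gene survival panel: GI hormone receptors silenced in gastric tumors
SURVIVAL_GENES = ("NPY1R", "PPYR1", "PTGDR", "PTGER2", "PTGER3", "SSTR2")

_STREAMS = {
    "annotation": 0,
    "cpg": 1,
    "truth": 2,
    "methylome": 3,
    "cnv": 4,
    "mbd": 5,
    "rrbs": 6,
    "survival": 7,
}

# per-bin CpG counts (Poisson means) by genomic context
CPG_DENSITY = {"cgi": 18.0, "promoter": 7.0, "background": 2.0}

# baseline GM methylation levels by context
BASELINE = {
    "promoter_cgi": 0.05,
    "cgi": 0.10,
    "promoter_noncgi": 0.70,
    "repeat": 0.85,
    "genic": 0.70,
    "intergenic": 0.85,
}

NOISE_AMPLITUDE = 0.05  # peak-to-peak per-region noise; |Δ| between any two
# samples of a null region stays < 0.05 by construction


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, reproducible from `seed`."""

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 5_000_000
    bin_size: int = 200
    n_genes: int = 300
    n_cgis: int = 260
    frac_promoter_cgi: float = 0.8
    n_hyper_dmps: int = 60
    n_hypo_dmps: int = 25
    n_hypo_repeat_blocks: int = 20
    frac_early_onset: float = 0.17
    mbd_mean_depth: float = 10.0
    rrbs_site_depth: float = 30.0
    rrbs_covered_frac_cgi: float = 0.25
    rrbs_covered_frac_bg: float = 0.039
    cnv_segments: list | None = None  # None -> 8 gains + 6 losses generated
    n_cnv_gains: int = 8
    n_cnv_losses: int = 6
    cnv_segment_len: int = 100_000
    beta_noise: float = 20.0
    conversion_error_rate: float = 0.0
    survival_n: int = 300
    survival_coefs: tuple = (0.8, -0.5, 0.6, 0.0, -0.3, 0.4)
    survival_base_hazard: float = 0.02  # events per month at score 0
    survival_censor_max: float = 120.0  # months

    def __post_init__(self) -> None:
        for name in (
            "frac_promoter_cgi",
            "frac_early_onset",
            "rrbs_covered_frac_cgi",
            "rrbs_covered_frac_bg",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_hyper_dmps + self.n_hypo_dmps > self.n_genes:
            raise ValueError("more planted DMPs than genes")
        if self.cnv_segments is not None:
            for _, cn in self.cnv_segments:
                if cn not in (0, 1, 2, 3, 4):
                    raise ValueError(f"copy number {cn} outside {{0..4}}")
        if self.beta_noise <= 0:
            raise ValueError("beta_noise must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream: independent per generator component."""
        ss = np.random.SeedSequence(
            entropy=self.seed, spawn_key=(_STREAMS[stream],)
        )
        return np.random.default_rng(ss)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_len for i in range(self.n_chroms)}


@dataclass
class GroundTruth:
    """Planted per-gene classes and true promoter levels per sample."""

    genes: pd.DataFrame  # gene_id, cls, timing, level_gm, level_im, level_gt
    repeat_blocks: pd.DataFrame  # chrom, start, end, timing

    def planted(self) -> pd.DataFrame:
        return self.genes[self.genes["cls"] != "null"]


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_REPEAT_MENU = (
    ("LINE", 1000, 5000, 0.30),
    ("SINE", 150, 400, 0.30),
    ("LTR", 500, 2000, 0.20),
    ("satellite", 1000, 3000, 0.10),
    ("other", 300, 1000, 0.10),
)


def simulate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Place non-overlapping genes, CGIs and repeats on the synthetic genome.

    Genes occupy evenly spaced slots; exactly
    ``round(frac_promoter_cgi * n_cgis)`` CGIs are centered on TSSs and the
    rest go to intergenic space.  Raises when the genome cannot hold the
    requested features.
    """
    rng = config.rng("annotation")
    sizes = config.chrom_sizes
    chroms = list(sizes)
    genes_per_chrom = [
        config.n_genes // config.n_chroms
        + (1 if i < config.n_genes % config.n_chroms else 0)
        for i in range(config.n_chroms)
    ]
    tss, genes, exons, first_exons, introns, utr3 = [], [], [], [], [], []
    gene_idx = 0
    for chrom, n_on_chrom in zip(chroms, genes_per_chrom):
        if n_on_chrom == 0:
            continue
        slot = sizes[chrom] // n_on_chrom
        if slot < 22_000:
            raise ValueError(
                f"genome too small: {n_on_chrom} genes on {chrom} leave "
                f"{slot} bp per gene slot (need >= 22000)"
            )
        for j in range(n_on_chrom):
            gene_id = f"gene{gene_idx:04d}"
            gene_idx += 1
            gene_len = int(rng.integers(3_000, 12_000))
            lo = j * slot + 4_000
            hi = (j + 1) * slot - 4_000 - gene_len
            gstart = int(rng.integers(lo, hi))
            gend = gstart + gene_len
            strand = "+" if rng.random() < 0.5 else "-"
            tss_pos = gstart if strand == "+" else gend - 1
            tss.append((GenomicInterval(chrom, tss_pos, tss_pos + 1, strand), gene_id))
            genes.append((GenomicInterval(chrom, gstart, gend, strand), gene_id))
            # exon/intron structure: alternating blocks from the gene start
            n_exons = int(rng.integers(3, 7))
            exon_lens = rng.integers(100, 400, size=n_exons)
            gaps = gene_len - int(exon_lens.sum())
            intron_lens = rng.multinomial(
                max(gaps, n_exons - 1), np.ones(n_exons - 1) / (n_exons - 1)
            )
            pos = gstart
            gene_exons = []
            for k in range(n_exons):
                e = GenomicInterval(chrom, pos, min(pos + int(exon_lens[k]), gend), strand)
                gene_exons.append(e)
                exons.append((e, gene_id))
                pos = e.end
                if k < n_exons - 1 and intron_lens[k] > 0:
                    iv = GenomicInterval(
                        chrom, pos, min(pos + int(intron_lens[k]), gend), strand
                    )
                    if iv.end > iv.start:
                        introns.append((iv, gene_id))
                    pos = iv.end
            first = gene_exons[0] if strand == "+" else gene_exons[-1]
            first_exons.append((first, gene_id))
            last = gene_exons[-1] if strand == "+" else gene_exons[0]
            u_len = min(200, last.width)
            if strand == "+":
                utr3.append((GenomicInterval(chrom, last.end - u_len, last.end, strand), gene_id))
            else:
                utr3.append((GenomicInterval(chrom, last.start, last.start + u_len, strand), gene_id))

    # CGIs: promoter-centered first, then intergenic
    n_prom_cgi = round(config.frac_promoter_cgi * config.n_cgis)
    if n_prom_cgi > config.n_genes:
        raise ValueError("more promoter CGIs requested than genes")
    cgi_gene_rows = rng.choice(config.n_genes, size=n_prom_cgi, replace=False)
    cgis = []
    cgi_genes: set[str] = set()
    for row in sorted(cgi_gene_rows):
        iv, gene_id = tss[row]
        half = int(rng.integers(300, 700))
        cgis.append(
            GenomicInterval(
                iv.chrom,
                max(0, iv.start - half),
                min(sizes[iv.chrom], iv.start + half),
            )
        )
        cgi_genes.add(gene_id)

    blocked = [
        (iv.chrom, max(0, iv.start - 1200), min(sizes[iv.chrom], iv.start + 1200))
        for iv, _ in tss
    ] + [(iv.chrom, iv.start, iv.end) for iv, _ in genes]
    n_bg_cgi = config.n_cgis - n_prom_cgi
    placed = 0
    attempts = 0
    while placed < n_bg_cgi:
        attempts += 1
        if attempts > 50 * max(n_bg_cgi, 1):
            raise ValueError("genome too small to place intergenic CGIs")
        chrom = chroms[int(rng.integers(config.n_chroms))]
        length = int(rng.integers(600, 1400))
        start = int(rng.integers(0, sizes[chrom] - length))
        cand = (chrom, start, start + length)
        clash = any(
            c == cand[0] and cand[1] < e and s < cand[2] for c, s, e in blocked
        ) or any(
            iv.chrom == chrom and cand[1] < iv.end and iv.start < cand[2]
            for iv in cgis
        )
        if not clash:
            cgis.append(GenomicInterval(chrom, cand[1], cand[2]))
            placed += 1

    # repeats: fill intergenic gaps to ~30%, plus occasional intronic SINEs
    repeats = []
    classes, lo_len, hi_len, probs = zip(*_REPEAT_MENU)
    probs = np.asarray(probs)
    for chrom in chroms:
        occupied = sorted(
            [(s, e) for c, s, e in blocked if c == chrom]
            + [(iv.start, iv.end) for iv in cgis if iv.chrom == chrom]
        )
        cursor = 0
        bounds = occupied + [(sizes[chrom], sizes[chrom])]
        for s, e in bounds:
            gap_start, gap_end = cursor, min(s, sizes[chrom])
            cursor = max(cursor, e)
            pos = gap_start
            while pos + 400 < gap_end:
                ci = int(rng.choice(len(classes), p=probs))
                length = int(rng.integers(lo_len[ci], hi_len[ci]))
                length = min(length, gap_end - pos)
                if rng.random() < 0.35 and length >= 150:
                    repeats.append(
                        (GenomicInterval(chrom, pos, pos + length), classes[ci])
                    )
                pos += length + int(rng.integers(200, 2000))
    for iv, gene_id in introns:
        if iv.width > 800 and rng.random() < 0.25:
            start = iv.start + int(rng.integers(0, iv.width - 300))
            repeats.append((GenomicInterval(iv.chrom, start, start + 300), "SINE"))

    ann = GenomeAnnotation(
        chrom_sizes=sizes,
        tss=tss,
        genes=genes,
        cgis=sorted(cgis),
        exons=exons,
        first_exons=first_exons,
        introns=introns,
        utr3=utr3,
        repeats=sorted(repeats, key=lambda t: (t[0].chrom, t[0].start)),
    )
    ann.cgi_promoter_genes = cgi_genes  # type: ignore[attr-defined]
    return ann


def cgi_promoter_genes(annotation: GenomeAnnotation) -> set[str]:
    """Genes whose promoter overlaps a CGI (≥1 bp)."""
    cached = getattr(annotation, "cgi_promoter_genes", None)
    if cached is not None:
        return cached
    out = set()
    for gene, prom in annotation.promoters().items():
        if annotation.overlapping("cgi", prom):
            out.add(gene)
    return out


# ---------------------------------------------------------------------------
# CpG sites
# ---------------------------------------------------------------------------


def simulate_cpg_sites(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Instantiate CpG positions: dense in CGIs, moderate in promoters,
    sparse elsewhere.  Returns (positions per chrom, CpG count per bin)."""
    rng = config.rng("cpg")
    bin_size = config.bin_size
    positions: dict[str, np.ndarray] = {}
    per_bin: dict[str, np.ndarray] = {}
    promoters = list(annotation.promoters().values())
    for chrom, size in annotation.chrom_sizes.items():
        n_bins = -(-size // bin_size)
        density = np.full(n_bins, CPG_DENSITY["background"])

        def paint(spans, value):
            for iv in spans:
                if iv.chrom != chrom:
                    continue
                density[iv.start // bin_size : -(-iv.end // bin_size)] = value

        paint(promoters, CPG_DENSITY["promoter"])
        paint(annotation.cgis, CPG_DENSITY["cgi"])
        counts = rng.poisson(density)
        counts = np.minimum(counts, bin_size // 2)
        pos_list = []
        for b in np.flatnonzero(counts):
            offs = rng.choice(bin_size, size=counts[b], replace=False)
            pos_list.append(b * bin_size + np.sort(offs))
        pos = np.concatenate(pos_list) if pos_list else np.empty(0, dtype=int)
        positions[chrom] = pos[pos < size]
        # recount after the chromosome-end trim
        per_bin[chrom] = np.bincount(positions[chrom] // bin_size, minlength=n_bins)
    return positions, per_bin


# ---------------------------------------------------------------------------
# truth plan + methylation surfaces
# ---------------------------------------------------------------------------


def plan_truth(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> pd.DataFrame:
    """Assign planted hyper/hypo classes and timing to genes.

    Hypermethylation targets CGI promoters (low baseline, room to rise);
    hypomethylation targets non-CGI promoters (high baseline, room to
    fall).  Exactly ``round(frac_early_onset * n_planted)`` planted genes
    are early-onset; the rest are GT-specific.
    """
    rng = config.rng("truth")
    cgi_genes = sorted(cgi_promoter_genes(annotation))
    noncgi_genes = sorted(set(g for _, g in annotation.tss) - set(cgi_genes))
    if config.n_hyper_dmps > len(cgi_genes):
        raise ValueError("not enough CGI-promoter genes for planted hyper DMPs")
    if config.n_hypo_dmps > len(noncgi_genes):
        raise ValueError("not enough non-CGI-promoter genes for planted hypo DMPs")
    hyper = list(rng.choice(cgi_genes, size=config.n_hyper_dmps, replace=False))
    hypo = list(rng.choice(noncgi_genes, size=config.n_hypo_dmps, replace=False))
    planted = hyper + hypo
    n_early = round(config.frac_early_onset * len(planted))
    early = set(rng.choice(planted, size=n_early, replace=False)) if planted else set()
    rows = []
    for _, gene in annotation.tss:
        if gene in hyper:
            cls = HYPER
        elif gene in hypo:
            cls = HYPO
        else:
            cls = "null"
        timing = (
            (EARLY_ONSET if gene in early else GT_SPECIFIC)
            if cls != "null"
            else "n/a"
        )
        rows.append({"gene_id": gene, "cls": cls, "timing": timing})
    return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)


def simulate_methylomes(
    annotation: GenomeAnnotation,
    truth_plan: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[dict[str, dict[str, np.ndarray]], GroundTruth]:
    """Per-sample true methylation level per bin, plus the ground truth.

    Baselines: CGI promoters 0.05, non-CGI promoters 0.70, CGIs 0.10,
    repeats/intergenic 0.85, gene bodies 0.70.  Planted hyper promoters
    rise to 0.6–0.9 in GT (and IM when early-onset); planted hypo
    promoters fall to 0.15–0.25; selected intergenic repeat blocks drop to
    0.30.  Per-region noise keeps any null region's between-sample
    difference below 0.05.
    """
    rng = config.rng("methylome")
    bin_size = config.bin_size
    promoters = annotation.promoters()
    cgi_genes = cgi_promoter_genes(annotation)

    base: dict[str, np.ndarray] = {}
    for chrom, size in annotation.chrom_sizes.items():
        n_bins = -(-size // bin_size)
        lv = np.full(n_bins, BASELINE["intergenic"])

        def paint(spans, value):
            for iv in spans:
                if iv.chrom != chrom:
                    continue
                lv[iv.start // bin_size : -(-iv.end // bin_size)] = value

        paint([iv for iv, _ in annotation.genes], BASELINE["genic"])
        paint(
            [iv for iv, _ in annotation.repeats if not annotation.overlapping("gene", iv)],
            BASELINE["repeat"],
        )
        paint([iv for iv in annotation.cgis], BASELINE["cgi"])
        paint(
            [promoters[g] for g in promoters if g not in cgi_genes],
            BASELINE["promoter_noncgi"],
        )
        paint(
            [promoters[g] for g in promoters if g in cgi_genes],
            BASELINE["promoter_cgi"],
        )
        base[chrom] = lv

    # planted per-sample shifts on a copy of base per sample
    shifted = {s: {c: a.copy() for c, a in base.items()} for s in SAMPLES}
    gene_rows = []
    by_gene = truth_plan.set_index("gene_id")
    for gene, prom in promoters.items():
        cls = by_gene.loc[gene, "cls"]
        timing = by_gene.loc[gene, "timing"]
        sl = slice(prom.start // bin_size, -(-prom.end // bin_size))
        gm_level = float(base[prom.chrom][sl].mean())
        if cls == HYPER:
            target = float(rng.uniform(0.6, 0.9))
        elif cls == HYPO:
            target = float(rng.uniform(0.15, 0.25))
        else:
            target = gm_level
        affected = (
            ("im", "gt") if timing == EARLY_ONSET else ("gt",) if cls != "null" else ()
        )
        for s in affected:
            shifted[s][prom.chrom][sl] = target
        gene_rows.append(
            {
                "gene_id": gene,
                "cls": cls,
                "timing": timing,
                "level_gm": gm_level,
                "level_im": target if "im" in affected else gm_level,
                "level_gt": target if "gt" in affected else gm_level,
            }
        )

    # hypomethylated intergenic repeat blocks (DMRs, not DMPs)
    intergenic_reps = [
        iv
        for iv, _ in annotation.repeats
        if iv.width >= 1000
        and not annotation.overlapping("gene", iv)
        and not annotation.overlapping("promoter", iv)
    ]
    n_blocks = min(config.n_hypo_repeat_blocks, len(intergenic_reps))
    block_rows = []
    if n_blocks:
        chosen = rng.choice(len(intergenic_reps), size=n_blocks, replace=False)
        n_early = round(config.frac_early_onset * n_blocks)
        early_idx = set(rng.choice(n_blocks, size=n_early, replace=False))
        for rank, idx in enumerate(sorted(chosen)):
            iv = intergenic_reps[idx]
            timing = EARLY_ONSET if rank in early_idx else GT_SPECIFIC
            sl = slice(iv.start // bin_size, -(-iv.end // bin_size))
            for s in ("im", "gt") if timing == EARLY_ONSET else ("gt",):
                shifted[s][iv.chrom][sl] = 0.30
            block_rows.append(
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "timing": timing}
            )

    # per-region per-sample noise: segment = run of constant level in ANY sample
    surfaces: dict[str, dict[str, np.ndarray]] = {s: {} for s in SAMPLES}
    for chrom in annotation.chrom_sizes:
        stacked = np.stack([shifted[s][chrom] for s in SAMPLES])
        change = np.any(np.diff(stacked, axis=1) != 0, axis=0)
        seg_id = np.concatenate([[0], np.cumsum(change)])
        n_segs = int(seg_id[-1]) + 1
        for s in SAMPLES:
            eps = (rng.beta(config.beta_noise, config.beta_noise, size=n_segs) - 0.5) * NOISE_AMPLITUDE
            surfaces[s][chrom] = np.clip(shifted[s][chrom] + eps[seg_id], 0.01, 0.99)

    truth = GroundTruth(
        genes=pd.DataFrame(gene_rows).sort_values("gene_id").reset_index(drop=True),
        repeat_blocks=pd.DataFrame(
            block_rows, columns=["chrom", "start", "end", "timing"]
        ),
    )
    return surfaces, truth


# ---------------------------------------------------------------------------
# CNV, MBD counts, RRBS counts, survival
# ---------------------------------------------------------------------------


def simulate_cnv_segments(
    config: SimulationConfig,
) -> list[tuple[GenomicInterval, int]]:
    """Tumor copy-number profile: gains (CN 3–4) and losses (CN 1)."""
    if config.cnv_segments is not None:
        return list(config.cnv_segments)
    rng = config.rng("cnv")
    sizes = config.chrom_sizes
    chroms = list(sizes)
    seg_len = config.cnv_segment_len
    segments: list[tuple[GenomicInterval, int]] = []
    kinds = [int(rng.integers(3, 5)) for _ in range(config.n_cnv_gains)] + [
        1
    ] * config.n_cnv_losses
    attempts = 0
    for cn in kinds:
        while True:
            attempts += 1
            if attempts > 1000:
                raise ValueError("cannot place non-overlapping CNV segments")
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, sizes[chrom] - seg_len))
            iv = GenomicInterval(chrom, start, start + seg_len)
            if not any(iv.overlaps(other) for other, _ in segments):
                segments.append((iv, cn))
                break
    segments.sort(key=lambda t: (t[0].chrom, t[0].start))
    return segments


def simulate_mbd_counts(
    surfaces: dict[str, dict[str, np.ndarray]],
    cpg_per_bin: dict[str, np.ndarray],
    cnv_segments: Sequence[tuple[GenomicInterval, int]],
    config: SimulationConfig,
) -> dict[str, BinTrack]:
    """Per-sample Poisson bin counts: λ ∝ depth × methylation × CpG weight.

    The tumor sample's rates are additionally scaled by CN/2 inside CNV
    segments (GM and IM are diploid everywhere).  λ is normalized so the
    genome-average expected count equals ``mbd_mean_depth``.
    """
    rng = config.rng("mbd")
    tracks: dict[str, BinTrack] = {}
    # shared normalization from the GM intensity so samples stay comparable
    gm_intensity = {
        chrom: (0.05 + surfaces["gm"][chrom]) * (cpg_per_bin[chrom] + 0.5)
        for chrom in cpg_per_bin
    }
    mean_intensity = float(
        np.mean(np.concatenate([a for a in gm_intensity.values()]))
    )
    scale = config.mbd_mean_depth / mean_intensity
    for sample in SAMPLES:
        raw: dict[str, np.ndarray] = {}
        expected = 0.0
        for chrom, weights in cpg_per_bin.items():
            lam = scale * (0.05 + surfaces[sample][chrom]) * (weights + 0.5)
            if sample == "gt":
                mids = (
                    np.arange(len(lam)) * config.bin_size + config.bin_size / 2
                )
                for iv, cn in cnv_segments:
                    if iv.chrom != chrom:
                        continue
                    mask = (mids >= iv.start) & (mids < iv.end)
                    lam[mask] *= cn / 2.0
            raw[chrom] = rng.poisson(lam)
            expected += float(lam.sum())
        tracks[sample] = BinTrack(
            sample, config.bin_size, dict(config.chrom_sizes), raw
        )
        tracks[sample].expected_total = expected  # type: ignore[attr-defined]
    return tracks


def simulate_rrbs_counts(
    surfaces: dict[str, dict[str, np.ndarray]],
    annotation: GenomeAnnotation,
    cpg_positions: dict[str, np.ndarray],
    config: SimulationConfig,
) -> pd.DataFrame:
    """Per-site C/T counts at the covered subset of CpG sites.

    A site inside a CGI or promoter is covered with probability
    ``rrbs_covered_frac_cgi``, elsewhere ``rrbs_covered_frac_bg``; the
    coverage draw is shared across samples (fragment selection is a
    property of the genome, not the library).  Depth per sample is
    1 + Poisson(mean − 1); methylated counts are Binomial(depth, level),
    with an optional flat conversion-error rate folded into the level.
    """
    rng = config.rng("rrbs")
    bin_size = config.bin_size
    err = config.conversion_error_rate
    enriched: dict[str, np.ndarray] = {}
    promoters = list(annotation.promoters().values())
    for chrom, size in annotation.chrom_sizes.items():
        mask = np.zeros(size, dtype=bool)
        for iv in annotation.cgis:
            if iv.chrom == chrom:
                mask[iv.start : iv.end] = True
        for iv in promoters:
            if iv.chrom == chrom:
                mask[iv.start : iv.end] = True
        enriched[chrom] = mask
    frames = []
    for chrom, pos in cpg_positions.items():
        if len(pos) == 0:
            continue
        p_cov = np.where(
            enriched[chrom][pos],
            config.rrbs_covered_frac_cgi,
            config.rrbs_covered_frac_bg,
        )
        covered = rng.random(len(pos)) < p_cov
        pos_c = pos[covered]
        if len(pos_c) == 0:
            continue
        bins = pos_c // bin_size
        cols = {"chrom": chrom, "pos": pos_c}
        for s in SAMPLES:
            depth = 1 + rng.poisson(
                max(config.rrbs_site_depth - 1.0, 0.0), size=len(pos_c)
            )
            level = surfaces[s][chrom][bins]
            level = level * (1 - err) + (1 - level) * err
            meth = rng.binomial(depth, level)
            cols[f"{s}_meth"] = meth
            cols[f"{s}_unmeth"] = depth - meth
        frames.append(pd.DataFrame(cols))
    if not frames:
        return pd.DataFrame(columns=COUNT_COLUMNS)
    return pd.concat(frames, ignore_index=True)[COUNT_COLUMNS]


def simulate_survival(config: SimulationConfig) -> pd.DataFrame:
    """Survival cohort: standard-normal expressions, exponential event
    times with hazard ∝ exp(Σ coef·expr), uniform censoring."""
    rng = config.rng("survival")
    coefs = np.asarray(config.survival_coefs, dtype=float)
    genes = (
        SURVIVAL_GENES
        if len(coefs) == len(SURVIVAL_GENES)
        else tuple(f"gene{i + 1}" for i in range(len(coefs)))
    )
    x = rng.standard_normal((config.survival_n, len(coefs)))
    rate = config.survival_base_hazard * np.exp(x @ coefs)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(1.0, config.survival_censor_max, size=config.survival_n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    df = pd.DataFrame(x, columns=list(genes))
    df.insert(0, "patient_id", [f"P{i + 1:04d}" for i in range(config.survival_n)])
    df.insert(1, "time", np.round(time, 4))
    df.insert(2, "event", event)
    df.attrs["true_coefs"] = dict(zip(genes, coefs))
    return df


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: GenomeAnnotation
    cpg_positions: dict[str, np.ndarray]
    cpg_per_bin: dict[str, np.ndarray]
    surfaces: dict[str, dict[str, np.ndarray]]
    truth: GroundTruth
    cnv_segments: list[tuple[GenomicInterval, int]]
    mbd_tracks: dict[str, BinTrack]
    rrbs_counts: pd.DataFrame
    survival: pd.DataFrame


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run every generator with its named substream and bundle the results."""
    annotation = simulate_annotation(config)
    cpg_positions, cpg_per_bin = simulate_cpg_sites(annotation, config)
    truth_plan = plan_truth(annotation, config)
    surfaces, truth = simulate_methylomes(annotation, truth_plan, config)
    cnv = simulate_cnv_segments(config)
    mbd_tracks = simulate_mbd_counts(surfaces, cpg_per_bin, cnv, config)
    rrbs_counts = simulate_rrbs_counts(surfaces, annotation, cpg_positions, config)
    survival = simulate_survival(config)
    return SimulatedDataset(
        config=config,
        annotation=annotation,
        cpg_positions=cpg_positions,
        cpg_per_bin=cpg_per_bin,
        surfaces=surfaces,
        truth=truth,
        cnv_segments=cnv,
        mbd_tracks=mbd_tracks,
        rrbs_counts=rrbs_counts,
        survival=survival,
    )


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Default conditions with no planted signal, CNV-flat tumor genome."""
    params = dict(
        seed=seed,
        n_hyper_dmps=0,
        n_hypo_dmps=0,
        n_hypo_repeat_blocks=0,
        cnv_segments=[],
    )
    params.update(overrides)
    return SimulationConfig(**params)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Write every output in the formats the pipeline reads back."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_annotation(ds.annotation, outdir / "annotation")
    for sample, track in ds.mbd_tracks.items():
        write_bin_counts(track, outdir / f"mbd_{sample}_bins.tsv")
    write_cpg_counts(ds.rrbs_counts, outdir / "rrbs_counts.tsv")
    write_cnv_bed(ds.cnv_segments, outdir / "cnv.bed")
    ds.survival.to_csv(outdir / "survival.tsv", sep="\t", index=False)
    ds.truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    ds.truth.repeat_blocks.to_csv(
        outdir / "truth_repeat_blocks.tsv", sep="\t", index=False
    )
    with open(outdir / "config.yaml", "w") as fh:
        cfg = dataclasses.asdict(ds.config)
        cfg["survival_coefs"] = list(cfg["survival_coefs"])
        yaml.safe_dump(cfg, fh, sort_keys=True)
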