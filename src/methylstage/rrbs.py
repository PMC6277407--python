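"""RRBS arm: per-CpG methylation levels and exact-test DMR/DMP calling.

Each CpG site carries methylated ('C') and unmethylated ('T') read counts
per stage (GM, IM, GT).  Differential sites are found with the
Freeman–Halton exact test on the 2×3 contingency table (rows meth/unmeth,
columns GM/IM/GT), Bonferroni-corrected over all tested sites; among the
significant sites, per-comparison calls require a methylation-level change
above 20 percentage points.  Promoters holding at least three called sites
become differentially methylated promoters.
"""

from __future__ import annotations

import logging
import math
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.special import gammaln, logsumexp
from scipy.stats import random_table

from .genome import GenomeAnnotation, GenomicInterval
from .records import DMPRecord, DMRecord, EARLY_ONSET, GT_SPECIFIC, HYPER, HYPO

logger = logging.getLogger(__name__)

SAMPLES = ("gm", "im", "gt")
COUNT_COLUMNS = [
    "chrom", "pos",
    "gm_meth", "gm_unmeth", "im_meth", "im_unmeth", "gt_meth", "gt_unmeth",
]

# Tables whose margin-constrained enumeration exceeds this many candidate
# tables fall back to seeded Monte-Carlo sampling.
ENUMERATION_CAP = 4_000_000
_REL_TOL = 1e-12  # relative probability tolerance for the ordering rule


def conversion_efficiency(
    converted: int, total: int, floor: float = 0.98
) -> float:
    """Bisulfite conversion efficiency from non-CpG cytosine counts.

    Returns converted/total and emits a warning when the efficiency falls
    below `floor` (default 0.98, the conventional QC threshold).
    """
    if total <= 0:
        raise ValueError("total non-CpG cytosines must be positive")
    eff = converted / total
    if eff < floor:
        warnings.warn(
            f"bisulfite conversion efficiency {eff:.3f} below floor {floor:.2f}",
            UserWarning,
            stacklevel=2,
        )
    return eff


def fisher_exact_2x3(
    table: np.ndarray | Sequence[Sequence[int]],
    mc_max_tables: int = ENUMERATION_CAP,
    mc_replicates: int = 200_000,
    seed: int = 0,
) -> float:
    """Two-sided Freeman–Halton exact test for a 2×3 table.

    Enumerates every 2×3 table with the observed margins; the p-value is
    the total multivariate-hypergeometric probability of tables no more
    probable than the observed one (within relative tolerance 1e-12).
    Degenerate margins need no special casing: a zero column reduces the
    enumeration to the classical 2×2 test and a zero row leaves a single
    admissible table (p = 1).  Tables whose enumeration would exceed
    `mc_max_tables` candidates are handled by seeded Monte-Carlo sampling
    of margin-preserving tables.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 3):
        raise ValueError(f"expected a 2x3 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("table entries must be nonnegative")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = int(t.sum())
    if n == 0:
        raise ValueError("empty table")

    r1 = int(row[0])
    a_lo, a_hi = max(0, int(col[0]) - int(row[1])), min(r1, int(col[0]))
    b_lo, b_hi = max(0, int(col[1]) - int(row[1])), min(r1, int(col[1]))
    n_candidates = (a_hi - a_lo + 1) * (b_hi - b_lo + 1)

    log_const = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(n + 1)
    logp_obs = log_const - gammaln(t + 1).sum()

    if n_candidates > mc_max_tables:
        rng = np.random.default_rng(seed)
        samples = random_table(row, col).rvs(mc_replicates, random_state=rng)
        logp = log_const - gammaln(samples + 1).sum(axis=(1, 2))
        hits = int((logp <= logp_obs + _REL_TOL).sum())
        logger.info(
            "Freeman-Halton Monte-Carlo fallback: %d replicates", mc_replicates
        )
        return hits / mc_replicates

    a = np.arange(a_lo, a_hi + 1)
    b = np.arange(b_lo, b_hi + 1)
    aa, bb = np.meshgrid(a, b, indexing="ij")
    x13 = r1 - aa - bb
    x21 = col[0] - aa
    x22 = col[1] - bb
    x23 = col[2] - x13
    valid = (x13 >= 0) & (x21 >= 0) & (x22 >= 0) & (x23 >= 0)
    cells = np.stack([aa, bb, x13, x21, x22, x23])
    logp = log_const - gammaln(np.where(valid, cells, 0) + 1).sum(axis=0)
    logp = logp[valid]
    keep = logp <= logp_obs + _REL_TOL
    # normalize by the full distribution to absorb floating-point drift
    p = float(np.exp(logsumexp(logp[keep]) - logsumexp(logp)))
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# site-level testing
# ---------------------------------------------------------------------------


def methylation_levels(table: pd.DataFrame) -> pd.DataFrame:
    """Add per-sample depth and methylation-level columns to a count table."""
    out = table.copy()
    for s in SAMPLES:
        depth = out[f"{s}_meth"] + out[f"{s}_unmeth"]
        out[f"{s}_depth"] = depth
        with np.errstate(invalid="ignore"):
            out[f"{s}_level"] = np.where(
                depth > 0, out[f"{s}_meth"] / depth, np.nan
            )
    return out


def test_all_sites(
    table: pd.DataFrame, min_depth: int = 10, alpha: float = 0.05
) -> pd.DataFrame:
    """Freeman–Halton test with Bonferroni correction at every deep site.

    Sites with depth ≥ `min_depth` in all three stages are tested; m is
    the number of tested sites and p_bonferroni = min(1, p·m).  A site is
    significant when p_bonferroni < `alpha`.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    df = methylation_levels(table)
    tested = df[(df[[f"{s}_depth" for s in SAMPLES]] >= min_depth).all(axis=1)].copy()
    m = len(tested)
    if m == 0:
        warnings.warn("no CpG sites pass the depth threshold", UserWarning)
        return tested.assign(
            p_value=pd.Series(dtype=float),
            p_bonferroni=pd.Series(dtype=float),
            significant=pd.Series(dtype=bool),
            diff_im=pd.Series(dtype=float),
            diff_gt=pd.Series(dtype=float),
        )
    meth = tested[[f"{s}_meth" for s in SAMPLES]].to_numpy()
    unmeth = tested[[f"{s}_unmeth" for s in SAMPLES]].to_numpy()
    pvals = np.array(
        [fisher_exact_2x3(np.vstack([m_, u_])) for m_, u_ in zip(meth, unmeth)]
    )
    tested["p_value"] = pvals
    tested["p_bonferroni"] = np.minimum(1.0, pvals * m)
    tested["significant"] = tested["p_bonferroni"] < alpha
    tested["diff_im"] = tested["im_level"] - tested["gm_level"]
    tested["diff_gt"] = tested["gt_level"] - tested["gm_level"]
    tested.attrs["n_tested"] = m
    return tested


def rrbs_site_dmrs(
    tests: pd.DataFrame, min_diff: float = 0.20
) -> list[DMRecord]:
    """Per-comparison calls at significant sites with >`min_diff` level change.

    Each call is a width-1 DMRecord.  A GT-vs-GM call is early-onset when
    the same site also carries a same-direction IM-vs-GM call, otherwise
    GT-specific; IM-vs-GM calls carry no timing.
    """
    if not (0 < min_diff < 1):
        raise ValueError("min_diff must lie in (0, 1)")
    records: list[DMRecord] = []
    sig = tests[tests["significant"]]
    for row in sig.itertuples(index=False):
        site = GenomicInterval(row.chrom, int(row.pos), int(row.pos) + 1)
        im_call = abs(row.diff_im) > min_diff
        gt_call = abs(row.diff_gt) > min_diff
        im_dir = HYPER if row.diff_im > 0 else HYPO
        gt_dir = HYPER if row.diff_gt > 0 else HYPO
        if im_call:
            records.append(
                DMRecord(
                    region=site,
                    platform="RRBS",
                    direction=im_dir,
                    comparison="IM",
                    diff=float(row.diff_im),
                    p_value=float(row.p_value),
                    p_adjusted=float(row.p_bonferroni),
                )
            )
        if gt_call:
            timing = (
                EARLY_ONSET if (im_call and im_dir == gt_dir) else GT_SPECIFIC
            )
            records.append(
                DMRecord(
                    region=site,
                    platform="RRBS",
                    direction=gt_dir,
                    comparison="GT",
                    timing=timing,
                    diff=float(row.diff_gt),
                    p_value=float(row.p_value),
                    p_adjusted=float(row.p_bonferroni),
                )
            )
    return records


def rrbs_dmps(
    site_dmrs: Sequence[DMRecord],
    annotation: GenomeAnnotation,
    min_sites: int = 3,
) -> list[DMPRecord]:
    """Promoters holding ≥ `min_sites` called CpG sites become DMPs.

    Direction follows the majority of member sites (GT-vs-GM calls where
    present, else IM-vs-GM); a tie goes to the direction with the larger
    mean |level difference|.  The DMP is early-onset when at least
    `min_sites` member sites are early-onset, else GT-specific.
    """
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    # one call per unique site: prefer the GT comparison for direction/timing
    per_site: dict[tuple[str, int], DMRecord] = {}
    for rec in site_dmrs:
        key = (rec.region.chrom, rec.region.start)
        cur = per_site.get(key)
        if cur is None or (cur.comparison == "IM" and rec.comparison == "GT"):
            per_site[key] = rec
    tree: dict[str, IntervalTree] = {}
    for (chrom, pos), rec in per_site.items():
        tree.setdefault(chrom, IntervalTree()).addi(pos, pos + 1, rec)
    dmps: list[DMPRecord] = []
    for gene, prom in sorted(annotation.promoters().items()):
        t = tree.get(prom.chrom)
        if not t:
            continue
        members = [iv.data for iv in t.overlap(prom.start, prom.end)]
        if len(members) < min_sites:
            continue
        by_dir = {HYPER: [], HYPO: []}
        for rec in members:
            by_dir[rec.direction].append(rec)
        n_hyper, n_hypo = len(by_dir[HYPER]), len(by_dir[HYPO])
        if n_hyper != n_hypo:
            direction = HYPER if n_hyper > n_hypo else HYPO
        else:
            mean_abs = {
                d: float(np.mean([abs(r.diff) for r in recs]))
                for d, recs in by_dir.items()
            }
            direction = max(mean_abs, key=mean_abs.get)
        n_early = sum(1 for r in members if r.timing == EARLY_ONSET)
        timing = EARLY_ONSET if n_early >= min_sites else GT_SPECIFIC
        best = min(by_dir[direction], key=lambda r: r.p_value)
        dmps.append(
            DMPRecord(
                gene_id=gene,
                promoter=prom,
                platforms={"RRBS"},
                direction=direction,
                timing=timing,
                stats={
                    "RRBS": {
                        "n_sites": len(members),
                        "n_hyper": n_hyper,
                        "n_hypo": n_hypo,
                        "best_p": best.p_value,
                        "mean_diff": float(
                            np.mean([r.diff for r in by_dir[direction]])
                        ),
                    }
                },
            )
        )
    return dmps


def rrbs_coverage_summary(
    table: pd.DataFrame,
    annotation: GenomeAnnotation,
    all_sites: pd.DataFrame,
) -> pd.DataFrame:
    """Fraction of CpG sites with depth ≥ 1, per region class.

    `all_sites` is the site universe (columns chrom, pos); `table` holds
    the observed counts.  Classes: whole genome, promoters, CGIs,
    intergenic (outside promoters and gene bodies).
    """
    covered_keys = set()
    df = methylation_levels(table)
    any_depth = df[[f"{s}_depth" for s in SAMPLES]].sum(axis=1) > 0
    for row in df[any_depth].itertuples(index=False):
        covered_keys.add((row.chrom, int(row.pos)))

    def span_trees(spans: list[GenomicInterval]) -> dict[str, IntervalTree]:
        out: dict[str, IntervalTree] = {}
        for iv in spans:
            out.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        return out

    proms = span_trees(list(annotation.promoters().values()))
    cgis = span_trees(annotation.cgis)
    genes = span_trees([iv for iv, _ in annotation.genes])

    def member(trees: dict[str, IntervalTree], chrom: str, pos: int) -> bool:
        t = trees.get(chrom)
        return bool(t and t.overlap(pos, pos + 1))

    tallies = {
        c: [0, 0] for c in ("whole_genome", "promoters", "CGIs", "intergenic")
    }
    for row in all_sites.itertuples(index=False):
        chrom, pos = row.chrom, int(row.pos)
        covered = (chrom, pos) in covered_keys
        classes = ["whole_genome"]
        in_prom = member(proms, chrom, pos)
        if in_prom:
            classes.append("promoters")
        if member(cgis, chrom, pos):
            classes.append("CGIs")
        if not in_prom and not member(genes, chrom, pos):
            classes.append("intergenic")
        for c in classes:
            tallies[c][0] += 1
            tallies[c][1] += int(covered)
    rows = [
        {
            "region_class": c,
            "n_sites": n,
            "covered_sites": k,
            "covered_fraction": k / n if n else float("nan"),
        }
        for c, (n, k) in tallies.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_cpg_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CpG count table missing columns: {missing}")
    return df


def write_cpg_counts(table: pd.DataFrame, path: str | Path) -> None:
    table[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bismark_coverage(
    paths: Mapping[str, str | Path]
) -> pd.DataFrame:
    """Merge per-sample bismark-style coverage files into one count table.

    `paths` maps sample keys (gm, im, gt) to files with columns chrom,
    start(1-based), end, percent, meth_count, unmeth_count.  Positions are
    converted to 0-based; sites absent from a sample get zero counts.
    """
    merged: pd.DataFrame | None = None
    for sample in SAMPLES:
        df = pd.read_csv(
            paths[sample],
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "percent", "meth", "unmeth"],
            dtype={0: str},
        )
        part = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "pos": df["start"].astype(int) - 1,
                f"{sample}_meth": df["meth"].astype(int),
                f"{sample}_unmeth": df["unmeth"].astype(int),
            }
        )
        merged = part if merged is None else merged.merge(
            part, on=["chrom", "pos"], how="outer"
        )
    merged = merged.fillna(0)
    for s in SAMPLES:
        merged[f"{s}_meth"] = merged[f"{s}_meth"].astype(int)
        merged[f"{s}_unmeth"] = merged[f"{s}_unmeth"].astype(int)
    return merged.sort_values(["chrom", "pos"]).reset_index(drop=True)


def write_site_calls_bed(records: Sequence[DMRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"{rec.region.chrom}\t{rec.region.start}\t{rec.region.end}\t"
                f"{rec.direction}|{rec.comparison}|{rec.timing or '.'}\t"
                f"{rec.diff:.3f}\t.\n"
            )
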