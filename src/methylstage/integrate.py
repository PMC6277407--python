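"""Cross-platform DMP integration, tallies, feature distribution, enrichment.

The MBD-seq and RRBS arms each emit per-promoter differential calls; here
they are merged by gene into one DMP set (platform provenance kept, with
direction conflicts resolved toward MBD-seq and flagged, timing resolved
toward early-onset), tallied by direction × timing, distributed across
genomic feature classes, and tested for gene-set enrichment with a
one-sided hypergeometric test and Benjamini–Hochberg correction.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genome import GenomeAnnotation
from .records import DMPRecord, DMRecord, EARLY_ONSET, GT_SPECIFIC, HYPER, HYPO


def union_dmps(
    mbd: Sequence[DMPRecord], rrbs: Sequence[DMPRecord]
) -> tuple[list[DMPRecord], dict[str, int]]:
    """Union the two platform DMP sets by gene/promoter identity.

    Returns the merged records plus the overlap tally
    {n_mbd, n_rrbs, n_both, n_union}.  Direction conflicts resolve to the
    MBD-seq call and are flagged; timing resolves to early-onset when
    either platform says early-onset.
    """
    for name, lst in (("MBD", mbd), ("RRBS", rrbs)):
        keys = [r.gene_id for r in lst]
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate promoter keys in the {name} DMP list")
    merged: dict[str, DMPRecord] = {}
    for rec in mbd:
        merged[rec.gene_id] = DMPRecord(
            gene_id=rec.gene_id,
            promoter=rec.promoter,
            platforms=set(rec.platforms),
            direction=rec.direction,
            timing=rec.timing,
            stats=dict(rec.stats),
        )
    n_both = 0
    for rec in rrbs:
        if rec.gene_id in merged:
            n_both += 1
            tgt = merged[rec.gene_id]
            tgt.platforms |= rec.platforms
            tgt.stats.update(rec.stats)
            if rec.direction != tgt.direction:
                tgt.direction_conflict = True  # MBD-first resolution
            if EARLY_ONSET in (rec.timing, tgt.timing):
                tgt.timing = EARLY_ONSET
        else:
            merged[rec.gene_id] = DMPRecord(
                gene_id=rec.gene_id,
                promoter=rec.promoter,
                platforms=set(rec.platforms),
                direction=rec.direction,
                timing=rec.timing,
                stats=dict(rec.stats),
            )
    out = sorted(merged.values(), key=lambda r: r.gene_id)
    tally = {
        "n_mbd": len(mbd),
        "n_rrbs": len(rrbs),
        "n_both": n_both,
        "n_union": len(out),
    }
    return out, tally


def tally_dmps(dmps: Sequence[DMPRecord]) -> pd.DataFrame:
    """Direction × timing count table with marginals (row/col 'total')."""
    idx = [HYPER, HYPO, "total"]
    cols = [EARLY_ONSET, GT_SPECIFIC, "total"]
    table = pd.DataFrame(0, index=idx, columns=cols)
    for rec in dmps:
        timing = rec.timing or GT_SPECIFIC
        table.loc[rec.direction, timing] += 1
    table.loc["total"] = table.loc[[HYPER, HYPO]].sum()
    table["total"] = table[[EARLY_ONSET, GT_SPECIFIC]].sum(axis=1)
    return table


def feature_distribution(
    dmrs: Sequence[DMRecord], annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Hyper/hypo DMR counts and hyper fraction per genomic feature class."""
    from .genome import classify_region

    counts: dict[tuple[str, str], dict[str, int]] = {}
    for rec in dmrs:
        label = rec.feature or classify_region(rec.region, annotation)
        key = (label.primary, label.sub)
        counts.setdefault(key, {HYPER: 0, HYPO: 0})[rec.direction] += 1
    rows = []
    for (primary, sub), c in sorted(counts.items()):
        total = c[HYPER] + c[HYPO]
        rows.append(
            {
                "primary": primary,
                "sub": sub,
                "hyper": c[HYPER],
                "hypo": c[HYPO],
                "total": total,
                "hyper_fraction": c[HYPER] / total if total else float("nan"),
            }
        )
    return pd.DataFrame(
        rows, columns=["primary", "sub", "hyper", "hypo", "total", "hyper_fraction"]
    )


def enrich(
    gene_list: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    background: Sequence[str],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of `gene_list` in each set.

    With N background genes, K in the set, n in the query list and k in
    both, p = P[X ≥ k] for X hypergeometric(N, K, n).  Benjamini–Hochberg
    correction is applied across all tested sets; rows sorted by adjusted
    then raw p.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background gene universe")
    query = set(gene_list) & bg
    if set(gene_list) - bg:
        raise ValueError("gene_list contains genes outside the background")
    n_bg, n_query = len(bg), len(query)
    rows = []
    for name, members in gene_sets.items():
        in_set = set(members) & bg
        k = len(in_set & query)
        big_k = len(in_set)
        p = float(hypergeom.sf(k - 1, n_bg, big_k, n_query))
        rows.append(
            {"set_name": name, "k": k, "K": big_k, "n": n_query, "N": n_bg, "p": min(p, 1.0)}
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
        df = df.sort_values(["p_adj", "p", "set_name"]).reset_index(drop=True)
    else:
        df["p_adj"] = pd.Series(dtype=float)
    return df


def fraction_of_pathway(matched: int, pathway_size: int) -> int:
    """Percent of a pathway's members matched, rounded to the nearest integer."""
    if pathway_size <= 0:
        raise ValueError("pathway_size must be positive")
    if matched > pathway_size:
        raise ValueError("matched exceeds pathway_size")
    return round(100.0 * matched / pathway_size)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene-set file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def dmps_to_frame(dmps: Sequence[DMPRecord]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": r.gene_id,
            "chrom": r.promoter.chrom,
            "start": r.promoter.start,
            "end": r.promoter.end,
            "platforms": ",".join(sorted(r.platforms)),
            "direction": r.direction,
            "timing": r.timing or ".",
            "direction_conflict": int(r.direction_conflict),
        }
        for r in dmps
    ]
    return pd.DataFrame(rows)


def write_dmps(dmps: Sequence[DMPRecord], path: str | Path) -> None:
    dmps_to_frame(dmps).to_csv(path, sep="\t", index=False)
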