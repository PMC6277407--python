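"""End-to-end orchestration of both platform arms and the integrated DMP set.

Ties the stages together in the canonical order: CNV-correct the tumor
MBD track, MES-transform, sliding-tile tests for IM-vs-GM and GT-vs-GM,
DMR assembly and timing classification, promoter DMP extraction; RRBS
site testing with Bonferroni correction, >20%-difference calls and ≥3-site
promoter DMPs; then the cross-platform union.  Also provides the
ground-truth recovery metrics used to validate the pipeline on synthetic
data.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import integrate, mbd, rrbs
from .genome import GenomeAnnotation, GenomicInterval
from .records import DMPRecord, DMRecord, EARLY_ONSET, HYPER, HYPO
from .simulate import SimulatedDataset


@dataclass
class MBDResult:
    im_tiles: pd.DataFrame
    gt_tiles: pd.DataFrame
    im_dmrs: list[DMRecord]
    gt_dmrs: list[DMRecord]
    dmps: list[DMPRecord]


@dataclass
class RRBSResult:
    site_tests: pd.DataFrame
    site_dmrs: list[DMRecord]
    dmps: list[DMPRecord]


def run_mbd_arm(
    tracks: dict[str, mbd.BinTrack],
    cnv_segments,
    annotation: GenomeAnnotation,
    alpha: float = 0.01,
    min_fold: float = 2.0,
    correct_cnv: bool = True,
) -> MBDResult:
    """MBD-seq arm: CNV-correct the tumor track, MES, tile tests, DMRs, DMPs."""
    gm = tracks["gm"]
    im = tracks["im"]
    gt = tracks["gt"]
    if correct_cnv and cnv_segments:
        gt = mbd.cnv_correct(gt, cnv_segments)
    gm_mes = mbd.mes_transform(gm)
    im_mes = mbd.mes_transform(im)
    gt_mes = mbd.mes_transform(gt)
    im_tiles = mbd.tile_test(gm_mes, im_mes, alpha=alpha, min_fold=min_fold)
    gt_tiles = mbd.tile_test(gm_mes, gt_mes, alpha=alpha, min_fold=min_fold)
    im_dmrs = mbd.assemble_dmrs(im_tiles, comparison="IM")
    gt_dmrs = mbd.assemble_dmrs(gt_tiles, comparison="GT")
    mbd.classify_timing(gt_dmrs, im_dmrs)
    dmps = mbd.mbd_dmps(gt_dmrs, annotation)
    return MBDResult(im_tiles, gt_tiles, im_dmrs, gt_dmrs, dmps)


def run_rrbs_arm(
    counts: pd.DataFrame,
    annotation: GenomeAnnotation,
    min_depth: int = 10,
    alpha: float = 0.05,
    min_diff: float = 0.20,
    min_sites: int = 3,
) -> RRBSResult:
    """RRBS arm: exact tests, Bonferroni, difference filter, promoter DMPs."""
    tests = rrbs.test_all_sites(counts, min_depth=min_depth, alpha=alpha)
    site_dmrs = rrbs.rrbs_site_dmrs(tests, min_diff=min_diff)
    dmps = rrbs.rrbs_dmps(site_dmrs, annotation, min_sites=min_sites)
    return RRBSResult(tests, site_dmrs, dmps)


def run_full(
    ds: SimulatedDataset,
    alpha_mbd: float = 0.01,
    alpha_rrbs: float = 0.05,
    correct_cnv: bool = True,
) -> dict:
    """Both arms on a simulated dataset plus the integrated DMP union."""
    mbd_res = run_mbd_arm(
        ds.mbd_tracks,
        ds.cnv_segments,
        ds.annotation,
        alpha=alpha_mbd,
        correct_cnv=correct_cnv,
    )
    rrbs_res = run_rrbs_arm(ds.rrbs_counts, ds.annotation, alpha=alpha_rrbs)
    union, overlap = integrate.union_dmps(mbd_res.dmps, rrbs_res.dmps)
    return {
        "mbd": mbd_res,
        "rrbs": rrbs_res,
        "union": union,
        "overlap": overlap,
        "tally": integrate.tally_dmps(union),
    }


def recovery_metrics(ds: SimulatedDataset, union: list[DMPRecord]) -> dict:
    """Planted-truth recovery: sensitivity, FDR and early-onset fraction.

    A planted gene counts as recovered when the union DMP set calls it
    with the planted direction; a called DMP at a null gene is a false
    discovery.  The early-onset fraction is computed over called DMPs at
    planted genes, using the integrated timing label.
    """
    truth = ds.truth.genes.set_index("gene_id")
    planted = truth[truth["cls"] != "null"]
    called = {r.gene_id: r for r in union}
    recovered = [
        g
        for g, row in planted.iterrows()
        if g in called and called[g].direction == row["cls"]
    ]
    false_calls = [g for g in called if truth.loc[g, "cls"] == "null"]
    n_called = len(called)
    planted_called = [r for r in union if truth.loc[r.gene_id, "cls"] != "null"]
    n_early = sum(1 for r in planted_called if r.timing == EARLY_ONSET)
    return {
        "n_planted": int(len(planted)),
        "n_called": n_called,
        "n_recovered": len(recovered),
        "recovery_rate": len(recovered) / len(planted) if len(planted) else float("nan"),
        "n_false": len(false_calls),
        "fdr": len(false_calls) / n_called if n_called else 0.0,
        "early_onset_fraction": (
            n_early / len(planted_called) if planted_called else float("nan")
        ),
        "n_planted_early": int((planted["timing"] == EARLY_ONSET).sum()),
    }
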