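"""Differential-methylation call records shared by both platform arms."""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import FeatureLabel, GenomicInterval

HYPER = "hyper"
HYPO = "hypo"
EARLY_ONSET = "early-onset"
GT_SPECIFIC = "GT-specific"


@dataclass
class DMRecord:
    """A differentially methylated region (MBD-seq tile union or RRBS site).

    ``timing`` is defined only for tumor-vs-mucosa (GT vs GM) calls;
    ``comparison`` records which pair of stages was tested.
    """

    region: GenomicInterval
    platform: str  # "MBD" | "RRBS"
    direction: str  # hyper | hypo
    comparison: str = "GT"  # "GT" (GT vs GM) or "IM" (IM vs GM)
    timing: str | None = None  # early-onset | GT-specific | None
    fold_change: float | None = None  # MBD: linear fold; RRBS: None
    diff: float | None = None  # RRBS: methylation-level difference
    p_value: float | None = None
    p_adjusted: float | None = None
    feature: FeatureLabel | None = None

    def __post_init__(self) -> None:
        if self.direction not in (HYPER, HYPO):
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.timing is not None and self.comparison != "GT":
            raise ValueError("timing is defined only for GT-vs-GM calls")


@dataclass
class DMPRecord:
    """A differentially methylated promoter, keyed by gene."""

    gene_id: str
    promoter: GenomicInterval
    platforms: set[str]
    direction: str
    timing: str | None = None
    stats: dict = field(default_factory=dict)  # per-platform statistics
    direction_conflict: bool = False

    def __post_init__(self) -> None:
        if not self.platforms:
            raise ValueError("platforms must be nonempty")
        if self.direction not in (HYPER, HYPO):
            raise ValueError(f"invalid direction {self.direction!r}")
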