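import numpy as np
import pytest

from methylstage.genome import GenomeAnnotation, GenomicInterval
from methylstage.pipeline import run_full
from methylstage.simulate import SimulationConfig, null_config, simulate_dataset


@pytest.fixture(scope="session")
def tiny_annotation() -> GenomeAnnotation:
    """Hand-built 100-kb single-chromosome annotation for unit tests.

    One plus-strand gene at [50,000, 60,000) with a CGI promoter, one
    intergenic CGI, a LINE in intergenic space and a SINE inside the
    intron.
    """
    chrom = "chr1"
    sizes = {chrom: 100_000}
    gene = GenomicInterval(chrom, 50_000, 60_000, "+")
    tss = GenomicInterval(chrom, 50_000, 50_001, "+")
    exon1 = GenomicInterval(chrom, 50_000, 50_300, "+")
    exon2 = GenomicInterval(chrom, 52_000, 52_400, "+")
    exon3 = GenomicInterval(chrom, 59_500, 60_000, "+")
    intron1 = GenomicInterval(chrom, 50_300, 52_000, "+")
    intron2 = GenomicInterval(chrom, 52_400, 59_500, "+")
    return GenomeAnnotation(
        chrom_sizes=sizes,
        tss=[(tss, "geneA")],
        genes=[(gene, "geneA")],
        cgis=[
            GenomicInterval(chrom, 49_600, 50_400),  # promoter CGI
            GenomicInterval(chrom, 10_000, 11_000),  # intergenic CGI
        ],
        exons=[(exon1, "geneA"), (exon2, "geneA"), (exon3, "geneA")],
        first_exons=[(exon1, "geneA")],
        introns=[(intron1, "geneA"), (intron2, "geneA")],
        utr3=[(GenomicInterval(chrom, 59_800, 60_000, "+"), "geneA")],
        repeats=[
            (GenomicInterval(chrom, 20_000, 23_000), "LINE"),
            (GenomicInterval(chrom, 55_000, 55_300), "SINE"),
        ],
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Default-condition simulation with planted hyper/hypo DMPs."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_results(default_dataset):
    """Full dual-platform pipeline run on the default simulation."""
    return run_full(default_dataset)


@pytest.fixture(scope="session")
def null_dataset():
    """No planted signal, CNV-flat tumor genome."""
    return simulate_dataset(null_config(seed=2))


@pytest.fixture(scope="session")
def null_results(null_dataset):
    return run_full(null_dataset)
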