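from __future__ import annotations

import textwrap
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from rgenome.regions import RegionSet
from rgenome.simulate import CohortConfig, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=1000000>
    ##contig=<ID=chr2,length=500000>
    ##FILTER=<ID=q10,Description="Low quality">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
    """
)


def make_vcf(
    tmp_path: Path, name: str, rows: list[tuple], header: str = VCF_HEADER
) -> Path:
    """Write a small single-sample VCF; rows are (chrom, pos, ref, alt,
    filter, gt) tuples."""
    path = tmp_path / name
    lines = [header.rstrip("\n")]
    for chrom, pos, ref, alt, flt, gt in rows:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t50\t{flt}\t.\tGT\t{gt}")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def small_cohort():
    """Six-sample, three-pipeline cohort on two small contigs with one
    planted discordant region per contig."""
    genome = {"chrA": 60_000, "chrB": 40_000}
    planted = RegionSet(
        "planted", genome, [("chrA", 20_000, 30_000), ("chrB", 5_000, 12_000)]
    )
    config = CohortConfig(
        n_samples=6,
        n_pipelines=3,
        genome=genome,
        snv_rate=3e-3,
        indel_rate=3e-4,
        planted_discordant_regions=planted,
        p_disc_in=0.85,
        p_disc_out=0.04,
        seed=20_260_930,
    )
    return simulate_cohort(config)
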