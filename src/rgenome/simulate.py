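"""Synthetic multi-sample, multi-pipeline cohorts with planted structure.

The generator emulates the situation the concordance pipeline is built for:
``N`` diploid samples, each analysed by ``M`` variant-calling pipelines that
mostly agree but disagree systematically inside designated genomic regions.
Variant sites (SNVs and short INDELs) are placed along each contig; every
sample carries every site with a random het/hom-alt genotype that all
pipelines report identically -- unless discordance is injected.

Discordance is injected per (sample, site) with probability ``p_disc_in``
inside the planted discordant regions and ``p_disc_out`` elsewhere, by one
of three mechanisms: a pipeline drops the call, a pipeline flips the
genotype het <-> hom-alt (the minimal change that breaks genotype
matching), or -- for INDELs, when ``indel_shift_max`` allows it -- a
pipeline shifts the call so far that the extended-interval matching cannot
absorb it.  Independently, INDEL calls receive small benign representation
jitter (shift <= indel_shift_max <= matching slack) that joining must
absorb.  The generator emits the ground truth (per-decision labels and the
planted regions) so recovery can be measured, and is byte-deterministic
under a fixed seed.

Default densities: ~3 cohort-wide polymorphic positions per kb of which
~1/11 are INDELs, in line with the per-kb polymorphic-site density seen in
deep human WGS cohorts of this size.  No reference FASTA is involved:
alleles are drawn once per site and are self-consistent across the cohort,
which is all genotype-sequence matching requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

from .calls import (
    Decision,
    Genotype,
    JoinParams,
    JoinedDecision,
    VariantCall,
    as_genotype,
    classify_variant,
    join_sample,
)
from .regions import RegionSet, write_chrom_sizes

log = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class CohortConfig:
    n_samples: int = 20
    n_pipelines: int = 3
    genome: dict[str, int] = field(default_factory=lambda: {"chr1": 1_000_000})
    snv_rate: float = 3e-3
    indel_rate: float = 2.5e-4
    planted_discordant_regions: RegionSet | None = None
    p_disc_in: float = 0.8
    p_disc_out: float = 0.05
    indel_shift_max: int = 3
    dropout_prob: float = 0.3
    #: the INDEL matching slack the cohort is meant to be joined with; used
    #: to decide which injected shifts count as breaking in the truth table
    indel_match_slack: int = 5
    het_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_pipelines < 2:
            raise ValueError("need N >= 1 samples and M >= 2 pipelines")
        for name in ("snv_rate", "indel_rate", "p_disc_in", "p_disc_out",
                     "dropout_prob", "het_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.indel_shift_max < 0 or self.indel_match_slack < 0:
            raise ValueError("shift/slack must be non-negative")
        if self.planted_discordant_regions is not None:
            if self.planted_discordant_regions.genome != dict(self.genome):
                raise ValueError("planted regions are not on the cohort genome")


@dataclass
class SimulatedCohort:
    config: CohortConfig
    sample_ids: list[str]
    pipeline_ids: list[str]
    #: calls[sample_id][pipeline_id] -> sorted list of VariantCall
    calls: dict[str, dict[str, list[VariantCall]]]
    #: per (sample, site) ground truth: sample_id, contig, pos, vclass, decision
    truth: pd.DataFrame
    truth_regions: RegionSet | None

    def join_all(self, params: JoinParams | None = None) -> dict[str, list[JoinedDecision]]:
        """Join every sample's pipelines with the concordance joiner."""
        return {
            s: join_sample(self.calls[s], params, sample_id=s)
            for s in self.sample_ids
        }

    def write(self, outdir: str | Path) -> None:
        """Emit per-(sample, pipeline) VCFs, chrom.sizes, truth TSV and BED."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s in self.sample_ids:
            for p in self.pipeline_ids:
                _write_vcf(self.calls[s][p], s, self.config.genome,
                           outdir / f"{s}.{p}.vcf")
        write_chrom_sizes(self.config.genome, outdir / "genome.chrom.sizes")
        self.truth.to_csv(outdir / "truth_decisions.tsv", sep="\t", index=False)
        if self.truth_regions is not None:
            self.truth_regions.to_bed(outdir / "planted_discordant.bed")


def _flip(gt: Genotype, ref: str, alt: str) -> Genotype:
    """het <-> hom-alt, the minimal genotype perturbation."""
    if gt == as_genotype(alt, alt):
        return as_genotype(ref, alt)
    return as_genotype(alt, alt)


def _site_alleles(rng: np.random.Generator, is_indel: bool) -> tuple[str, str]:
    anchor = _BASES[rng.integers(4)]
    if not is_indel:
        alt = _BASES[rng.integers(4)]
        while alt == anchor:
            alt = _BASES[rng.integers(4)]
        return anchor, alt
    tail = "".join(_BASES[i] for i in rng.integers(0, 4, int(rng.integers(1, 4))))
    if rng.random() < 0.5:
        return anchor + tail, anchor  # deletion
    return anchor, anchor + tail  # insertion


def simulate_cohort(config: CohortConfig | None = None) -> SimulatedCohort:
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    pipeline_ids = [f"P{j + 1}" for j in range(config.n_pipelines)]
    planted = config.planted_discordant_regions
    slack = config.indel_match_slack

    # -- site layout -------------------------------------------------------
    # Sites are spaced far enough apart that extended INDEL intervals of
    # neighbouring sites can never merge, keeping the planted truth per-site.
    sep = 2 * (slack + config.indel_shift_max + 4) + 1
    sites: dict[str, list[tuple[int, bool, str, str]]] = {}
    for contig in sorted(config.genome):
        length = config.genome[contig]
        margin = 10 + config.indel_shift_max + slack
        lo, hi = margin, length - margin
        if hi <= lo:
            sites[contig] = []
            continue
        n_snv = rng.binomial(length, config.snv_rate)
        n_ind = rng.binomial(length, config.indel_rate)
        n_tot = min(n_snv + n_ind, hi - lo)
        pool = rng.choice(np.arange(lo, hi), size=n_tot, replace=False)
        classes = np.zeros(n_tot, dtype=bool)
        classes[min(n_snv, n_tot):] = True  # True = INDEL
        order = np.argsort(pool, kind="stable")
        contig_sites = []
        last = -(10 ** 12)
        for idx in order:
            pos = int(pool[idx])
            if pos - last < sep:
                continue
            last = pos
            ref, alt = _site_alleles(rng, bool(classes[idx]))
            contig_sites.append((pos, bool(classes[idx]), ref, alt))
        sites[contig] = contig_sites

    # -- per-sample calls --------------------------------------------------
    calls: dict[str, dict[str, list[VariantCall]]] = {
        s: {p: [] for p in pipeline_ids} for s in sample_ids
    }
    truth_rows = []
    m = len(pipeline_ids)
    for contig in sorted(config.genome):
        for pos, is_indel, ref, alt in sites[contig]:
            in_planted = planted.contains(contig, pos - 1) if planted else False
            p_disc = config.p_disc_in if in_planted else config.p_disc_out
            break_min = 2 * slack + max(len(ref), 1)  # smallest breaking shift
            for s in sample_ids:
                het = rng.random() < config.het_fraction
                gt = as_genotype(ref, alt) if het else as_genotype(alt, alt)
                rep_pos = {p: pos for p in pipeline_ids}
                rep_gt = {p: gt for p in pipeline_ids}
                dropped: set[str] = set()
                broke = False
                # benign representation jitter on one pipeline's INDEL
                if is_indel and config.indel_shift_max > 0 and rng.random() < 0.5:
                    pid = pipeline_ids[rng.integers(m)]
                    delta = int(rng.integers(1, config.indel_shift_max + 1))
                    if rng.random() < 0.5:
                        delta = -delta
                    rep_pos[pid] = pos + delta
                    if abs(delta) > 2 * slack + max(len(ref), 1) - 1:
                        broke = True
                if rng.random() < p_disc:
                    pid = pipeline_ids[rng.integers(m)]
                    u = rng.random()
                    can_shift = is_indel and config.indel_shift_max >= break_min
                    if u < config.dropout_prob:
                        dropped.add(pid)
                    elif can_shift and u < config.dropout_prob + 0.3:
                        delta = int(rng.integers(break_min,
                                                 config.indel_shift_max + 1))
                        rep_pos[pid] = pos + delta
                        broke = True
                    else:
                        rep_gt[pid] = _flip(gt, ref, alt)
                discordant = bool(dropped) or broke or any(
                    rep_gt[p] != gt for p in pipeline_ids
                )
                truth_rows.append((
                    s, contig, pos,
                    "INDEL" if is_indel else "SNV",
                    Decision.DISCORDANT.value if discordant
                    else Decision.CONCORDANT.value,
                ))
                for pid in pipeline_ids:
                    if pid in dropped:
                        continue
                    g = rep_gt[pid]
                    calls[s][pid].append(VariantCall(
                        contig=contig,
                        pos=rep_pos[pid],
                        ref=ref,
                        alts=(alt,),
                        genotype=g,
                        vclass=classify_variant(ref, g),
                        qual=50.0,
                        filter="PASS",
                    ))
    for s in sample_ids:
        for pid in pipeline_ids:
            calls[s][pid].sort(key=lambda c: (c.contig, c.pos))
    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "contig", "pos", "vclass", "decision"]
    )
    return SimulatedCohort(
        config=config,
        sample_ids=sample_ids,
        pipeline_ids=pipeline_ids,
        calls=calls,
        truth=truth,
        truth_regions=planted,
    )


def _write_vcf(
    calls: list[VariantCall],
    sample_id: str,
    genome: Mapping[str, int],
    path: Path,
) -> None:
    header = pysam.VariantHeader()
    for contig in sorted(genome):
        header.contigs.add(contig, length=genome[contig])
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in calls:
            rec = out.new_record(
                contig=c.contig, start=c.pos - 1, alleles=(c.ref,) + c.alts,
            )
            rec.qual = c.qual
            rec.filter.add("PASS")
            alleles = (c.ref,) + c.alts
            idx = tuple(sorted(alleles.index(a) for a in c.genotype))
            rec.samples[sample_id]["GT"] = idx
            out.write(rec)
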