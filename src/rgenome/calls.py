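"""Joining per-pipeline variant call sets of one sample into decisions.

Running several variant-calling pipelines (mapper + caller combinations) on
the same sequencing data rarely yields identical call sets.  This module
merges the per-pipeline VCFs of a single diploid sample into one ordered
stream of per-site decisions: a site is CONCORDANT when every pipeline called
a variant there with a matching genotype, and DISCORDANT when any pipeline
missed the site or called a different genotype.

SNVs must agree on their exact (contig, position).  INDELs are frequently
placed at slightly different coordinates by different variant aligners, so
they are matched fuzzily: each INDEL occupies its reference footprint
``[pos, pos + max(len(ref), 1) - 1]`` (insertions occupy a single base),
the footprint is extended by ``l`` bases up- and downstream, and calls whose
extended intervals overlap between call sets are treated as one site --
provided their called genotypes (compared as unordered allele-sequence
pairs) also agree.  ``l = 5`` by default.

Only diploid, non-filtered (FILTER is PASS or '.') records participate;
haploid or missing genotypes are skipped with a warning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam

from . import __version__

log = logging.getLogger(__name__)

#: Unordered diploid genotype as a sorted pair of allele sequences.
Genotype = tuple[str, str]

_SEQ_RE = re.compile(r"^[ACGTNacgtn]+$")


class VariantClass(str, Enum):
    SNV = "SNV"
    INDEL = "INDEL"


class Decision(str, Enum):
    CONCORDANT = "CONCORDANT"
    DISCORDANT = "DISCORDANT"


def as_genotype(a: str, b: str) -> Genotype:
    """Normalize two allele sequences into an unordered (sorted) pair."""
    return tuple(sorted((a, b)))  # type: ignore[return-value]


def classify_variant(ref: str, genotype: Genotype) -> VariantClass:
    """SNV iff the ref and every called allele are single bases."""
    if len(ref) == 1 and all(len(a) == 1 for a in genotype):
        return VariantClass.SNV
    return VariantClass.INDEL


@dataclass(frozen=True)
class VariantCall:
    """One parsed, non-filtered VCF record for a (sample, pipeline)."""

    contig: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    genotype: Genotype
    vclass: VariantClass
    qual: float | None = None
    filter: str = "PASS"


@dataclass(frozen=True)
class JoinParams:
    """``l``: bases of INDEL footprint extension on each side."""

    l: int = 5

    def __post_init__(self) -> None:
        if self.l < 0:
            raise ValueError("INDEL extension l must be >= 0")


@dataclass
class JoinedDecision:
    """Per (sample, matched site) concordance verdict across M pipelines."""

    sample_id: str
    contig: str
    pos: int  # 1-based anchor (leftmost member of a matched INDEL group)
    decision: Decision
    per_pipeline: dict[str, Genotype | None]  # None = pipeline had no call
    vclass: VariantClass
    ref: str = "N"
    alts: tuple[str, ...] = ()


def load_callset(
    vcf_path: str | Path, pipeline_id: str = ""
) -> Iterator[VariantCall]:
    """Stream non-filtered diploid calls of a single-sample VCF in order.

    Multi-allelic records yield one :class:`VariantCall` carrying all ALTs.
    Unsorted input raises; records without a usable diploid GT are skipped
    with a warning.
    """
    vf = pysam.VariantFile(str(vcf_path))
    done_contigs: set[str] = set()
    last: tuple[str, int] | None = None
    for rec in vf:
        contig, pos = rec.contig, rec.pos
        if last is not None:
            lc, lp = last
            if contig != lc:
                if contig in done_contigs:
                    raise ValueError(
                        f"unsorted VCF {vcf_path}: contig {contig} reappears "
                        f"at record {contig}:{pos}"
                    )
                done_contigs.add(lc)
            elif pos < lp:
                raise ValueError(
                    f"unsorted VCF {vcf_path}: record {contig}:{pos} "
                    f"follows {lc}:{lp}"
                )
        last = (contig, pos)

        filters = list(rec.filter.keys())
        if filters and filters != ["PASS"]:
            continue
        if len(rec.samples) == 0:
            log.warning(
                "%s %s:%d: no sample/GT field; record skipped",
                pipeline_id or vcf_path, contig, pos,
            )
            continue
        gt = rec.samples[0].get("GT")
        if gt is None or any(i is None for i in gt):
            log.warning(
                "%s %s:%d: missing GT; record treated as no-call and skipped",
                pipeline_id or vcf_path, contig, pos,
            )
            continue
        if len(gt) != 2:
            log.warning(
                "%s %s:%d: non-diploid GT %s; record skipped (diploid "
                "genomes only)", pipeline_id or vcf_path, contig, pos, gt,
            )
            continue
        if all(i == 0 for i in gt):
            # homozygous-reference record: not a variant call
            continue
        alleles = rec.alleles
        try:
            seqs = tuple(alleles[i] for i in gt)
        except (IndexError, TypeError):
            log.warning(
                "%s %s:%d: GT indexes missing allele; skipped",
                pipeline_id or vcf_path, contig, pos,
            )
            continue
        if any(not _SEQ_RE.match(s) for s in seqs):
            log.warning(
                "%s %s:%d: symbolic/non-sequence allele in GT; skipped",
                pipeline_id or vcf_path, contig, pos,
            )
            continue
        genotype = as_genotype(*seqs)
        yield VariantCall(
            contig=contig,
            pos=pos,
            ref=rec.ref,
            alts=tuple(rec.alts or ()),
            genotype=genotype,
            vclass=classify_variant(rec.ref, genotype),
            qual=rec.qual,
            filter="PASS" if filters else ".",
        )


def indel_interval(call: VariantCall, params: JoinParams) -> tuple[int, int]:
    """Closed 1-based interval of an INDEL's l-extended reference footprint."""
    if call.vclass is not VariantClass.INDEL:
        raise ValueError(f"indel_interval called on SNV at {call.contig}:{call.pos}")
    start = call.pos - params.l
    end = call.pos + max(len(call.ref), 1) - 1 + params.l
    return start, end


def genotypes_match(a: Genotype, b: Genotype) -> bool:
    """Equality of unordered diploid allele-sequence pairs (phase ignored)."""
    if a is None or b is None:
        raise ValueError("genotypes_match requires two called genotypes")
    return tuple(sorted(a)) == tuple(sorted(b))


def join_sample(
    callsets: Mapping[str, Iterable[VariantCall]],
    params: JoinParams | None = None,
    sample_id: str = "sample",
) -> list[JoinedDecision]:
    """Merge M >= 2 pipeline call streams of one sample into decisions.

    Every position carrying at least one call in any pipeline yields exactly
    one decision; INDEL calls whose extended intervals mutually overlap
    across call sets collapse into a single site anchored at the leftmost
    member's position.  An SNV and an INDEL at the same position remain
    distinct sites.  The result is invariant under permutation of the
    pipeline mapping.
    """
    params = params or JoinParams()
    if len(callsets) < 2:
        raise ValueError("join_sample requires at least two pipeline call sets")
    pipelines = sorted(callsets)
    all_pipelines = set(pipelines)
    per_pipeline_calls = {pid: list(callsets[pid]) for pid in pipelines}
    contigs = sorted(
        {c.contig for calls in per_pipeline_calls.values() for c in calls}
    )

    out: list[JoinedDecision] = []
    for contig in contigs:
        present = {
            pid for pid in pipelines
            if any(c.contig == contig for c in per_pipeline_calls[pid])
        }
        if present != all_pipelines:
            log.debug(
                "contig %s absent from pipelines %s; their calls treated as "
                "absent", contig, sorted(all_pipelines - present),
            )
        snv_sites: dict[int, dict[str, list[VariantCall]]] = {}
        indels: list[tuple[int, int, str, VariantCall]] = []
        for pid in pipelines:
            for call in per_pipeline_calls[pid]:
                if call.contig != contig:
                    continue
                if call.vclass is VariantClass.SNV:
                    snv_sites.setdefault(call.pos, {}).setdefault(pid, []).append(call)
                else:
                    s, e = indel_interval(call, params)
                    indels.append((s, e, pid, call))

        # (pos, class-rank, decision); SNV sorts before an INDEL anchored there
        keyed: list[tuple[int, int, JoinedDecision]] = []

        for pos, per in snv_sites.items():
            gts = [c.genotype for pid in pipelines if pid in per for c in per[pid]]
            concordant = set(per) == all_pipelines and len(set(gts)) == 1
            rep = per[min(per)][0]
            keyed.append((
                pos, 0,
                JoinedDecision(
                    sample_id=sample_id,
                    contig=contig,
                    pos=pos,
                    decision=Decision.CONCORDANT if concordant else Decision.DISCORDANT,
                    per_pipeline={
                        pid: (per[pid][0].genotype if pid in per else None)
                        for pid in pipelines
                    },
                    vclass=VariantClass.SNV,
                    ref=rep.ref,
                    alts=rep.alts,
                ),
            ))

        # Greedy left-to-right grouping of mutually overlapping extended
        # intervals; a sweep over sorted starts yields the connected
        # components of the interval-overlap graph deterministically.
        indels.sort(key=lambda t: (t[0], t[1], t[2], t[3].pos, t[3].ref, t[3].alts))
        groups: list[list] = []  # [max_end, members]
        for item in indels:
            if groups and item[0] <= groups[-1][0]:
                groups[-1][0] = max(groups[-1][0], item[1])
                groups[-1][1].append(item)
            else:
                groups.append([item[1], [item]])
        for _, members in groups:
            per_g: dict[str, list[VariantCall]] = {}
            for _, _, pid, call in members:
                per_g.setdefault(pid, []).append(call)
            gts = [call.genotype for _, _, _, call in members]
            concordant = set(per_g) == all_pipelines and len(set(gts)) == 1
            anchor_call = min(members, key=lambda t: (t[3].pos, t[2]))[3]
            keyed.append((
                anchor_call.pos, 1,
                JoinedDecision(
                    sample_id=sample_id,
                    contig=contig,
                    pos=anchor_call.pos,
                    decision=Decision.CONCORDANT if concordant else Decision.DISCORDANT,
                    per_pipeline={
                        pid: (per_g[pid][0].genotype if pid in per_g else None)
                        for pid in pipelines
                    },
                    vclass=VariantClass.INDEL,
                    ref=anchor_call.ref,
                    alts=anchor_call.alts,
                ),
            ))

        keyed.sort(key=lambda t: (t[0], t[1]))
        out.extend(d for _, _, d in keyed)
    return out


# -- joined VCF round-trip -------------------------------------------------

_DISC_FILTER = "RG_DISC"


def write_joined_vcf(
    decisions: Iterable[JoinedDecision],
    path: str | Path,
    params: JoinParams | None = None,
    pipeline_ids: list[str] | None = None,
) -> None:
    """Write decisions as a sites-only VCF: PASS = concordant, RG_DISC = not.

    Per-pipeline genotypes travel in INFO/PP and the variant class in
    INFO/VC so the stream round-trips through :func:`load_joined_vcf`.
    """
    decisions = list(decisions)
    if len({d.sample_id for d in decisions}) > 1:
        raise ValueError("a joined VCF holds decisions of a single sample")
    header = pysam.VariantHeader()
    header.filters.add(_DISC_FILTER, None, None,
                       "Call discordant across variant-calling pipelines")
    header.info.add("PP", ".", "String",
                    "Per-pipeline genotype as pipeline:allele/allele ('.' = absent)")
    header.info.add("VC", "1", "String", "Variant class (SNV or INDEL)")
    pids = pipeline_ids or sorted({p for d in decisions for p in d.per_pipeline})
    if decisions:
        header.add_line(f"##rg_sample={decisions[0].sample_id}")
    header.add_line(
        f"##rg_join=version={__version__};pipelines={','.join(pids)}"
        f";l={(params or JoinParams()).l}"
    )
    for contig in sorted({d.contig for d in decisions}):
        header.contigs.add(contig)

    last: tuple[str, int] | None = None
    done: set[str] = set()
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for d in decisions:
            if last is not None:
                lc, lp = last
                if d.contig != lc:
                    if d.contig in done:
                        raise ValueError("decision stream not sorted by contig")
                    done.add(lc)
                elif d.pos < lp:
                    raise ValueError(
                        f"decision stream not sorted: {d.contig}:{d.pos} "
                        f"after {lc}:{lp}"
                    )
            last = (d.contig, d.pos)
            rec = out.new_record(
                contig=d.contig,
                start=d.pos - 1,
                alleles=(d.ref,) + (tuple(d.alts) or ("<ALT>",)),
            )
            rec.filter.add("PASS" if d.decision is Decision.CONCORDANT
                           else _DISC_FILTER)
            rec.info["PP"] = tuple(
                f"{pid}:{'/'.join(g) if g else '.'}"
                for pid, g in sorted(d.per_pipeline.items())
            )
            rec.info["VC"] = d.vclass.value
            out.write(rec)


def load_joined_vcf(path: str | Path) -> list[JoinedDecision]:
    """Read a joined VCF written by :func:`write_joined_vcf`."""
    vf = pysam.VariantFile(str(path))
    sample_id = "sample"
    for hr in vf.header.records:
        if hr.key == "rg_sample" and hr.value:
            sample_id = hr.value
    out = []
    for rec in vf:
        filters = list(rec.filter.keys())
        decision = (Decision.DISCORDANT if _DISC_FILTER in filters
                    else Decision.CONCORDANT)
        per_pipeline: dict[str, Genotype | None] = {}
        for entry in rec.info.get("PP", ()):
            pid, gt = entry.split(":", 1)
            per_pipeline[pid] = None if gt == "." else as_genotype(*gt.split("/"))
        vc = rec.info.get("VC")
        genotypes = [g for g in per_pipeline.values() if g is not None]
        if vc is not None:
            vclass = VariantClass(vc)
        elif genotypes:
            vclass = classify_variant(rec.ref, genotypes[0])
        else:
            vclass = VariantClass.SNV
        out.append(JoinedDecision(
            sample_id=sample_id,
            contig=rec.contig,
            pos=rec.pos,
            decision=decision,
            per_pipeline=per_pipeline,
            vclass=vclass,
            ref=rec.ref,
            alts=tuple(a for a in (rec.alts or ()) if a != "<ALT>"),
        ))
    return out
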