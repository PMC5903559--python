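# Methods

## Problem and model

Different variant-calling (VC) pipelines applied to the same sequencing
data disagree on a non-negligible fraction of SNV and INDEL calls, and
false positives/negatives are strongly enriched among these discordant
calls.  The package implements a method that turns this disagreement into a
genome annotation: given call sets from `M` pipelines over `N` samples, it
estimates for every base how reliably that locus can be genotyped by a
single pipeline, and partitions the genome into *concordant* (reliable) and
*discordant* (unreliable) regions.  The premise, which the holdout
experiment tests, is that discordance is predominantly a property of
genomic context rather than of the individual sequencing run, so a
partition trained on one cohort transfers to new data produced with
comparable technology.

The pipeline has two stages.

### Stage 1 — joining call sets per sample

For each sample, the `M` pipeline VCFs are merged by iterating over all
positions carrying at least one non-filtered call (FILTER `PASS` or `.`).
A site is **concordant** when every pipeline called it and all called
genotypes (VCF `GT`, compared as unordered pairs of allele *sequences*, so
phasing and ALT ordering are irrelevant) agree; it is **discordant** when
any pipeline lacks a call or any genotype differs.

SNVs match only at identical coordinates.  INDELs are matched fuzzily
because variant aligners place the same event at different coordinates:
each INDEL occupies its reference footprint `[pos, pos + max(|ref|,1) - 1]`
(an insertion occupies one base), extended by `l` bases on both sides
(default `l = 5`), and calls whose extended intervals overlap are one site.
Overlap is transitive: mutually overlapping extended intervals collapse
into one group (connected components of the interval-overlap graph,
computed by a left-to-right sweep), the group is anchored at its leftmost
member's position, and concordance additionally requires every pair of
member genotypes to agree.  Note the geometry: two same-length INDELs
shifted by `δ` match iff `δ ≤ 2l + |ref| - 1`; every shift `≤ l` is always
absorbed.  An SNV never satisfies an INDEL match; co-located SNV and INDEL
sites yield separate decisions.

Haploid or missing genotypes are skipped with a warning — the model is
diploid-only.  Decisions round-trip through a sites-only VCF (`PASS` /
`RG_DISC` in FILTER, per-pipeline genotypes in `INFO/PP`).

### Stage 2 — scoring, interpolation, partitioning

Decisions are aggregated across samples.  At each polymorphic position `p`
with `n_c` concordant and `n_d` discordant per-sample decisions, the
concordance score is

    s_p = (n_c·w_c + n_d·w_d) / (n_c·w_c + |n_d·w_d|)  ∈ [-1, 1]

with weights `w_c = 1 > 0` and `w_d = -3 < 0` by default.  `s = 1` iff no
sample was discordant, `s = -1` iff none was concordant, and the asymmetric
default weights put the zero crossing at `n_c = 3·n_d`: a position needs
three concordant samples to outweigh one discordant one.  This deliberately
trades sensitivity for a low false-discovery rate of the concordant
partition, the quantity a variant-filtering user cares most about.  The
score is invariant under joint rescaling of the weights and strictly
monotone in each count.

Between data points the signal is interpolated: each point radiates its
score over a window of `2x + 1` bases (default `x = 1000`), decaying
linearly to the neutral value 0 at distance `x`.  Consecutive points closer
than `x` are joined by a direct linear segment.  For gaps in `(x, 2x)` the
two decay ramps overlap; the implementation superposes them (their sum),
which is the unique choice that keeps the signal continuous, bounded by 1
in magnitude (the ramp sum at its peak is `≤ max(|s|)·(2 - gap/x)`), and
exact at both data points.  For gaps `≥ 2x` the signal decays to 0 on each
side and stays neutral in between.  Contig edges clip the decay; contigs
without data are entirely neutral.  The signal is stored as per-contig
piecewise-linear breakpoints (all at integer coordinates), never as
per-base arrays; evaluation is exact linear interpolation.

Thresholding yields the partition: concordant = bases with signal `> t_c`,
discordant = signal `≤ t_d` (`t_d ≤ t_c`, defaults 0/0).  With `t_c = t_d`
the two sets tile the genome, which is the binary-classifier mode used in
all evaluations here.  Putting the boundary/neutral state on the discordant
side is the conservative choice: no evidence is treated as unreliable.
Crossing coordinates are derived analytically per linear segment, with the
boundary base membership decided by direct evaluation so the result is
identical to per-base thresholding.

### High-density (HD) discordance windows

A second, coarser annotation flags windows where discordance keeps
flickering on and off.  Score points are labelled discordant (`s < 0`),
concordant (`s > 0`) or neutral (`s = 0`, transparent: it neither breaks
nor extends a run).  A *stretch* is a maximal run of discordant positions
separated by at least one concordant position.  Around every variant
position a window `[p - flank, p + flank]` (default flank 1000) is scanned;
windows containing at least `min_count` (default 10) stretches — a stretch
counts as soon as one of its positions lies inside — are emitted and
merged.  HD regions are typically subtracted from the concordant partition
together with external low-complexity region sets.

### Region algebra and evaluation

Region sets are sorted, merged, half-open 0-based intervals validated
against a contig-length map, with subtraction, intersection, union,
padding (used e.g. to widen low-complexity regions by 100 bp), complement
and coverage fractions — enough to build every derived partition
(partition minus LCR, minus HD, combined with an external set) and the
coverage summaries.

A partition is evaluated as a binary classifier of call concordance:
a joined decision is predicted positive iff its anchor position lies in the
concordant set, actual positive iff it is concordant.  Besides accuracy,
sensitivity and specificity, the informative quantities are
`FDR = FP/(FP+TP)` (discordant calls inside declared-concordant territory)
and `NPV = TN/(TN+FN)`.  Metrics with zero denominators are reported as
missing, never as 0.  `holdout_experiment`/`learning_curve` implement the
training protocol — random cohort subsets build the partition, held-out
samples are ground truth, replicated under a seeded generator — and
`fp_flagging_precision` the haploid-truth protocol, where every
heterozygous call in an effectively haploid genome is by construction a
false positive and the discordant set is scored on how precisely it flags
them.

## Synthetic cohorts

All testing runs on generated cohorts (`rgenome.simulate`); no external
data is required.  The generator plants the structure the method is meant
to detect: variant sites (SNV:INDEL ≈ 12:1) are placed along each contig,
every sample carries every site with a het/hom-alt genotype reported
identically by all pipelines, and per (sample, site) discordance is
injected with probability `p_disc_in` inside designated regions and
`p_disc_out` elsewhere (defaults 0.8 / 0.05).  The injection mechanism is a
pipeline dropout with probability `dropout_prob` (default 0.3), otherwise a
het↔hom-alt genotype flip — the minimal perturbation that breaks genotype
matching — or, for INDELs when `indel_shift_max` permits, a representation
shift too large for the matching slack.  Independently, INDELs receive
benign position jitter (≤ 3 bp by default) that joining must absorb.

Default site density is 3×10⁻³ SNV + 2.5×10⁻⁴ INDEL per base, in line
with the per-base polymorphic-position density of deep human WGS cohorts
at this sample count (heterozygosity ~10⁻³ per sample, union across ~20
samples).  The defaults give a mean inter-site gap of ~300 bp, well inside
the `x = 1000` interpolation radius, as in real cohort data.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: an allele-frequency spectrum (all samples carry
all sites), sequencing-error and coverage models, clustered/overlapping
variants (sites are spaced so neighbouring INDEL groups cannot merge,
keeping the planted truth per-site), multi-allelic sites, and any
correlation between discordance and sequence context beyond the planted
regions themselves.  The recovery experiments test the machinery, not the
biological claim.

## Numerical and design choices

- Scores and the signal are computed in double precision; score TSVs carry
  6 decimals, breakpoint TSVs 9 significant digits (lossless for the
  fractions that arise).  The per-base interpolation oracle agrees with the
  breakpoint representation to < 1e-9 (observed ~4e-16).
- Contigs are processed and emitted in lexicographic order everywhere, so
  outputs are byte-identical regardless of input VCF header order.
- Equal-score ties at a partition threshold are resolved by the strict
  `> t_c` / `≤ t_d` rule; exact-zero plateaus (no-data regions) are
  represented exactly and classified discordant at the default thresholds.
- Degenerate inputs: empty VCFs and empty contigs are valid (neutral);
  `n_c = n_d = 0`, inverted thresholds, unsorted streams, out-of-bounds
  intervals and degenerate holdout splits raise immediately.
- Problem sizes in the test-suite and acceptance script (100-kb oracle
  contigs, a 1-Mb 20-sample recovery cohort, 10,000/1,000-draw formula
  checks) were chosen as the smallest scales at which every behaviour of
  interest — saturating learning curves, ramp superposition, window
  merging — is exercised; all complete in seconds.

## Known limitations

- Diploid genomes only; haploid records are dropped, not modelled.
- No variant normalization/left-alignment beyond the interval-overlap
  tolerance; pipelines that represent the same INDEL further apart than
  `2l + |ref| - 1` bases are counted discordant.
- One decision per sample per site: pipeline-pair structure (which caller
  disagreed) is recorded in `INFO/PP` but not used by the score.
- The exact threshold pair used to publish reference partitions of this
  kind is not fixed by the method; `t_c = t_d = 0` is the package default
  and everything downstream is threshold-parameterised.
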