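# Methods

## Model and estimator

An MA line passes through repeated single-cell bottlenecks, so within-line
selection is negligible and new single-nucleotide mutations accumulate at
the spontaneous rate. For a haploid nuclear genome the estimator is the
count ratio

μ̂ = m / (n·g)

with m the number of accepted unique mutations, n the number of scorable
sites (unchanged + mutated, pooled over lines — each line-site is an
independent opportunity to observe a mutation), and g the number of cell
generations. m is treated as Poisson; the interval on μ is the exact
Garwood interval on m scaled by 1/(n·g):

- lower(k) = ½·χ²(α/2; 2k), 0 for k = 0
- upper(k) = ½·χ²(1−α/2; 2k+2)

These intervals are conservative (coverage ≥ nominal for every true
expectation; verified by simulation in the test suite). For one count at
95% the bounds are 0.02532 and 5.5716. Published analyses sometimes print
a slightly different lower bound for k=1 (0.0255 rather than the Garwood
0.0253); this package uses the Garwood convention throughout and makes no
attempt to reproduce alternative conventions. For the same reason the
mitochondrial interval here is the Garwood interval on the pooled retained
count applied multiplicatively to the mean rate; its upper bound for 19
counts is 29.671/19 ≈ 1.56× the point rate, which is wider than some
printed mitochondrial upper bounds derived by unstated methods.

## Site classification

The guiding principle is symmetry: any criterion applied to candidate
mutations must also gate the unchanged sites in the denominator, otherwise
m and n are counted under different definitions and μ̂ is biased.

Consensus is a plain majority rule: the strictly most frequent base,
provided it reaches 50% of counted reads; a two-way 50/50 tie (or any tie
for the maximum) is a no-call and the site is treated as uncovered. Base
qualities are parsed but ignored — filtering operates on coverage and
agreement only, because Bayesian consensus callers tuned for diploids
produced false positives on this kind of haploid data.

Per focal line and site, in order:

1. site excluded outright if not uniquely mappable, reference N, or any
   line has zero coverage;
2. focal filters: depth ≥ `min_cov_focal` (default 5), depth ≤
   `max_cov_factor` (default 3.0) × that line's own mean coverage over
   covered unique sites, a majority call, agreement ≥ `min_agree_focal`
   (default 0.90);
3. focal call ≠ reference: rejected as a shared candidate if the same
   alternate is the weak majority (depth ≥ `min_cov_confirm` = 1,
   agreement ≥ `min_agree_confirm` = 0.5) in any other line; otherwise a
   mutation;
4. focal call = reference: unchanged only if every other line's weak
   majority is the reference; otherwise confirmation failed.

Design points that were genuinely open:

- Acceptance of a mutation requires only the *absence* of its alternate
  elsewhere, not positive re-confirmation of the reference (the literal
  reading of the rule); a `strict_confirmation` flag enables the stricter
  reading. A third base as another line's weak majority does not veto a
  candidate.
- The 3× high-coverage cap uses each line's own mean (lines are sequenced
  to different depths); whether the original analysis pooled the mean is
  not recorded. A capped line is excluded only as focal; it may still
  confirm, since the confirmation rule carries no upper-coverage clause.
- `min_cov_focal` defaults to the published 5 as an explicit parameter; it
  is *not* re-derived as half the observed mean, favouring reproducible
  thresholds over data-coupled ones.

The implementation is vectorised over whole contigs; a scalar
rule-by-rule form (`classify_site`) is kept as the readable reference and
the two are tested against an independently written rule enumerator.

## Mappability

All length-L windows of the reference (L = 31, both strands) are aligned
back to the reference allowing ≤ `max_mismatch` (default 1) mismatches,
multi-mapping allowed. Self-coverage at a position is the number of
(read, placement) pairs spanning it; uniquely mappable ⇔ self-coverage =
2L = 62. The mismatch model is whole-read Hamming distance; seed-based
mapping policies restrict where the mismatch may fall, so whole-read
Hamming is the permissive, well-defined variant — the ==2L rule itself is
unchanged. The search uses pigeonhole seeding (a Hamming-1 match contains
an exact match of one read half; half-mer hashing proposes candidates,
full comparison verifies), making ~100 kb–1 Mb contigs practical on one
CPU while remaining exact; a brute-force all-pairs oracle checks it on
multi-kb genomes in the tests. L is validated odd so no window equals its
own reverse complement under exact matching. Nuclear contigs are linear
(ends can never be unique); the mitochondrial contig is circular and
windows wrap.

## Mitochondrial rate

Cells carry ~200 mitochondrial genomes, so new mutations surface as
heteroplasmies. Assuming mutation–drift balance, a mutation's fixation
probability equals its current frequency, so each retained mutation
contributes f(m): per line μ̂ = Σf(m)/(n·g) over sites that are uniquely
mappable and covered by ≥ `min_cov` reads (by default a tenth of the
line's mean mitochondrial coverage, resolved once per line); the overall
rate is the unweighted line mean. A candidate must exceed the frequency
cutoff in exactly one line; the same position+alternate above the cutoff
in two or more lines is excluded everywhere. The cutoff boundary is
inclusive (frequency ≥ cutoff is retained).

Cutoff selection:

- **grid minimum** — run the full pipeline at each cutoff (default grid
  0.01–0.10 in hundredths) and take the argmin, ties to the smallest.
  Below the right cutoff the estimate is inflated by sequencing errors;
  above it, excluded multi-line candidates can re-enter as "unique" when
  the partner line drops below the cutoff, lifting the tail — hence an
  interior minimum.
- **binomial bound** — smallest f with P[Binomial(c, e) > c·f] <
  α_per_site, with c a typical coverage (400), e the error rate *after*
  the caller's inflation (the CLI doubles the empirical 0.002 via
  `--error-inflation 2.0`, allowing for systematically error-prone
  sites), and α_per_site defaulting to 1/(total mitochondrial sites
  across lines) ≈ 6.7×10⁻⁶ for ~150,000 — i.e. under one expected false
  call genome-wide. The "more than" is strict (survival function at
  ⌊c·f⌋); at these parameters the non-strict variant selects the same
  cutoff, which a test verifies.

The per-read error rate itself is estimated empirically as the mean
fraction of reads disagreeing with the site majority, per line, then
averaged across lines; optionally restricted to sites passing the focal
filters.

## Synthetic data

The generator emulates exactly what the downstream rules consume —
per-site base counts — and nothing below that level: reads are never
materialised, since no rule looks at a read beyond its base at one site.
It reproduces:

- i.i.d. AT-rich genomes (defaults 0.78 nuclear, 0.7257 mitochondrial)
  with optional exact repeat blocks to exercise the mask;
- per-line mutation counts ~ Poisson(rate·length·g), positions uniform
  without replacement (within and across lines, so planted mutations are
  unambiguously unique), alternates uniform over the three other bases;
- shared ancestor-vs-reference differences planted identically in all
  lines, which the classifier must reject as shared candidates;
- heteroplasmic sites where each read's template is the alternate with
  probability equal to the true frequency (drift-free: the frequency is a
  fixed parameter, which is what makes the frequency-sum estimator's
  unbiasedness testable);
- depth ~ Poisson(mean), read errors uniform over the other three bases
  at rate e (default 0.002).

Not emulated: read-length structure, quality decay, strand bias, indels,
alignment ambiguity (repeats are handled by the mask, as in the real
pipeline, rather than by re-simulating mis-mapping). Passing recovery
tests therefore demonstrates the correctness of the counting rules and
estimators under the stated noise model, not robustness to artefacts the
model omits.

Everything derives from one config seed via spawned child streams, and
the pipeline derives per-stage seeds from its single seed by indexed
spawning, so runs are byte-reproducible and stages independently
re-runnable.

## Numerical and scale choices

- Rates are reported at full precision in JSON; human-readable summaries
  round to 2 significant figures.
- Total generations from plaque counts: mean of log₂(cells) × transfers,
  rounded half away from zero (14.22 × 70 = 995.4 → 995).
- Degenerate inputs: zero-depth sites are no-calls; lines with no
  eligible mitochondrial sites are dropped from the line mean with a
  warning; an empty eligible set for coverage or error estimation is an
  error, not a silent zero.
- Test and demo problem sizes are chosen so the full suite runs in well
  under a minute of compute per property: 2–5 kb genomes where a
  brute-force oracle must also run, 35–50 kb for false-positive and
  error-rate properties (≥10⁵ eligible line-sites), 100 replicates at
  5 kb for interval coverage, 50 replicates at 2 kb/3000× for the
  mitochondrial estimator. These sizes are statements about statistical
  sufficiency (3-standard-error bands), not about the method, which is
  linear in genome length.

## Known limitations

- The self-mapping mismatch model is whole-read Hamming; masks produced
  by seed-restricted mappers will differ slightly near near-repeats.
- The mitochondrial interval treats the retained-call count as Poisson
  and ignores uncertainty in the frequencies themselves; at thousands-fold
  coverage the frequency noise is negligible relative to count noise.
- No indel or microsatellite calling; single-nucleotide substitutions
  only.
- The classic pileup reader targets the documented 10-column `pileup -c`
  layout; sub-variant dialects of that era are not auto-detected by
  design.
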