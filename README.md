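# malines

Mutation-accumulation (MA) line analysis: from per-site read pileups to
nuclear and mitochondrial single-nucleotide mutation-rate estimates with
exact Poisson confidence intervals.

## The problem

In an MA experiment a lineage is propagated through repeated single-cell
bottlenecks, so selection is minimised and spontaneous mutations accumulate
essentially by drift. Sequencing a few MA lines after *g* generations and
counting new mutations gives a direct estimate of the spontaneous
per-site, per-generation mutation rate

μ = m / (n·g),

where *m* is the number of mutations unique to one line and *n* is the
number of sites scored under **the same criteria** as the mutations.
Getting *n* right is the hard part: every filter applied to candidate
mutations must be applied symmetrically to the unchanged sites that form
the denominator. This package implements that bookkeeping for haploid
genomes sequenced with short reads, as used for the social amoeba
*Dictyostelium discoideum* (three MA lines, 70 bottlenecks, g ≈ 1000):

* **Pileup decoding** — classic samtools 10-column `pileup -c` read
  strings, or a simplified 7-column count TSV, into per-site base counts.
* **Mappability masking** — every possible 31-bp window of the reference
  (both strands) is aligned back to the reference at ≤1 mismatch with
  multi-mapping allowed; a position is uniquely mappable iff exactly
  2L = 62 fake reads cover it. Repeats and near-repeats are excluded this
  way rather than by ad hoc filters.
* **Site classification** — majority consensus (≥50%, ties = uncovered);
  a site counts only if uniquely mappable and covered in every line; the
  focal line needs ≥5 reads, ≤3× its own mean coverage, and ≥90%
  agreement. A candidate mutation is rejected if its alternate base is the
  majority in any other line (even one read); an unchanged site requires
  the reference confirmed in every other line under those same weak
  criteria.
* **Mitochondrial heteroplasmy** — at high-copy mitochondrial sites new
  mutations appear at intermediate frequencies; under mutation–drift
  balance each contributes its frequency, μ = Σf(m)/(n·g). The
  error-vs-mutation frequency cutoff is chosen by a rate-minimum grid scan
  or a binomial error bound.
* **Exact Poisson intervals** — Garwood chi-square intervals on the
  mutation count, scaled by 1/(n·g); essential when m is 0, 1 or a few.
* **Synthetic data** — a generator for AT-rich genomes, planted per-line
  mutations, shared ancestor-vs-reference differences, heteroplasmies and
  Poisson-coverage pileups with a known truth set, so the whole pipeline
  is testable without the original reads.

## Worked example

The demonstration pipeline simulates a 40-kb nuclear contig (78% AT, one
120-bp duplication, shared ancestral differences, per-read error 0.002,
9–11× coverage) and a 4-kb circular mitochondrial contig (~4000×, six
planted heteroplasmies per line), then runs every stage:

```
$ malines run-all --seed 1 --out demo/
nuclear: m=8 n=114265 rate=7e-08 [3.02e-08, 1.38e-07]
mitochondrial: k=18 rate=1.93e-07 [1.15e-07, 3.06e-07]
```

Here 8 planted nuclear mutations were recovered (m) over 114,265 scorable
line-sites (n, pooled over the three lines) giving a rate of 7.0×10⁻⁸ per
site per generation with its exact 95% Poisson interval; the 15
shared-candidate exclusions in `demo/rates.json` are the planted
ancestor-vs-reference differences (5 per line), rejected because the same
alternate base appears in more than one line. All 18 planted
heteroplasmies were retained at the 3% cutoff (k), and the
frequency-weighted mitochondrial rate again carries a count-based Poisson
interval. `demo/` also contains the mask BED (99.2% of the nuclear contig
uniquely mappable — the rest is the planted duplication and the contig
ends), a minimal VCF of mutation calls, per-site classifications, the
truth set, and a MANIFEST with content hashes; rerunning with the same
seed reproduces every file byte for byte.

Library use mirrors the CLI:

```python
from malines import poisson_ci, rate_ci

rate_ci(1, 34_653_718, 1000).rate   # 2.9e-11 per site per generation
poisson_ci(1).upper                 # 5.572 expected events
```

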