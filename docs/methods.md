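# Methods

## Problem setting

Plant miRNAs ingested with food can survive digestion and reach host tissues;
whether they can repress host mRNAs depends, at minimum, on sequence
complementarity. This package implements the in-silico arm of that question
as a deterministic pipeline: which host transcripts carry sites exactly
antisense to the extended seed of an abundant plant miRNA, how stable is the
resulting RNA:RNA duplex, which genes and processes do the surviving
interactions point to, and do endogenous host miRNAs or other plant species
share the same sequence determinants.

## Selection criteria and their exact semantics

miRNA quality filtering keeps a record iff

* read count **> 1400** — strict: a count of exactly 1400 fails;
* length **19–25 nt inclusive** — 19 and 25 pass;
* orientation 5′→3′ — carried as a per-record flag, default compliant,
  because orientation cannot be derived from a mature-sequence table alone.

Records without a read count fail the abundance criterion unless the caller
waives it (`require_read_counts=False`); read counts are input data, never
computed, since public mature-sequence catalogues do not carry them (they are
a sidecar column of the miRNA TSV dialect).

An interaction is accepted iff the seed (nt 2–7) is fully Watson–Crick
paired, no seed pair is G·U, and the duplex MFE is **strictly below** the
threshold (default −25 kcal/mol). The mimicry stage re-uses the two seed
constraints with the threshold disabled.

## Site model

A candidate site is an exact occurrence of the reverse complement of miRNA
nt 2–13. A 12-nt query at 100% identity and >99% coverage in a short-word
alignment search admits only the full exact match, so the scan is implemented
directly (deterministic, no E-values, no heuristics). Only antisense matches
count: a transcript containing a miRNA's own sense sequence cannot hybridize
with it. Overlapping occurrences are all reported; output ordering is fixed
as (transcript, position, miRNA). The exactness of nt 2–13 already guarantees
that the seed hexamer opposite nt 2–7 is a perfect complement with no G·U, so
the seed constraints of the duplex stage can only bind through bulge/loop
geometry, not through the anchor itself.

Coordinates are 0-based, half-open, transcript-local, 5′→3′ throughout;
region classification (5′UTR / CDS / 3′UTR, ncRNA for noncoding biotypes)
uses the site start position, so a site straddling a boundary takes its
start's region — a deterministic rule matching the single stored anchor
coordinate.

## Duplex energy model

The duplex stage scores the miRNA:target hybrid as a single antiparallel
chain of base pairs (strictly increasing along the miRNA, strictly decreasing
along the target — no pseudoknots, no intramolecular pairs):

```
E = helix_init + Σ stack(pᵢ, pᵢ₊₁)          adjacent pairs
              + Σ bulge(s) or internal(s)    non-adjacent pairs
```

with admissible pairs {AU, UA, CG, GC, GU, UG}, affine penalties
`bulge(s) = 3.5 + 0.4·s`, `internal(s) = 4.0 + 0.3·s` (s = enclosed unpaired
nucleotides, capped at 15 per loop), `helix_init = +4.09` kcal/mol, and
unpaired terminal nucleotides free. Watson–Crick/Watson–Crick stack energies
are the standard published 37 °C nearest-neighbor values; wobble-containing
stacks, whose published values vary by context, use flat documented defaults
(−1.2 kcal/mol with one wobble pair, −0.4 with two). All parameters load from
a TSV, so any alternative table can be substituted. Dangling-end and
terminal-AU terms are deliberately excluded; they shift absolute energies
without changing the architecture, and the acceptance threshold is
configurable. Consequently absolute MFEs printed by other tools with other
parameter vintages are treated as *inputs* to downstream filters wherever
they appear, never as regeneration targets.

`hybridize` minimizes E by dynamic programming over chain-final pairs;
transitions look back at most max-loop+1 positions on each strand, giving
O(m·w·L²) time (milliseconds at miRNA/window scale). Seed constraints are
enforced inside the DP: a transition may not skip a required seed position,
a chain may not start after or end before the required block, and inadmissible
seed pairs are excluded from the pair grid. `brute_force_mfe` enumerates
*every* admissible chain on instances up to 10×12 nt and is the independent
oracle; both routes accumulate energy in chain order so co-optimal structures
tie bit-for-bit, and ties are broken by the lexicographically smallest pair
list, which makes results exactly reproducible. "No admissible structure" is
a distinct outcome (`None`), never an energy of zero, so thresholds cannot
pass vacuously.

The target window handed to the DP is
`[site_start − (L−13) − flank, site_end + 1 + flank)` clipped to the
transcript (L = miRNA length, flank default 10): room for the 3′ arm
(nt 14..L) 5′-ward of the anchor, nt 1 one base 3′-ward, and bulge slack.

## Gene-level collapse and reporting

Non-coding interactions are dropped for gene-level analyses; each remaining
gene symbol keeps one representative — the minimum-MFE interaction, ties by
(transcript, position) — because a lower MFE marks the more plausible site.
Interactions are counted per (miRNA, transcript, site), so a transcript hit
twice contributes two interactions but one gene. MFE histograms use 5 kcal/mol
bins from −25 downward, left-closed toward the more negative side (−30.0
falls in [−30,−35)); values above −25, which arise only when the threshold is
disabled, collect in a single overflow bin.

## Enrichment

Over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k) for overlap k between an n-gene query and a K-gene set in an N-gene
background (scipy's survival function, computed stably in log space), with
Benjamini–Hochberg step-up FDR within each collection and ranking by
(FDR, p, term). The default background is the coding-gene universe of the
supplied transcriptome; query genes outside it are dropped and counted.
Combined-score rankings of enrichment web services depend on their
precomputed background statistics and are intentionally not reproduced — the
adjusted p-value reported here is the comparable, reproducible quantity.

## Homology

Seed mimicry pairs every plant miRNA with every host miRNA whose nt 2–7 are
identical. Mimics are re-folded only at the (transcript, site) anchors their
plant partner actually hit, in a window anchored on the shared-seed
complement and sized to the *host* miRNA's length, with seed constraints on
and no MFE cutoff — the question is what the endogenous mimic could achieve,
however weak. Conservation is exact full-length mature-sequence identity
against a multi-species catalogue; T/U and case are normalized before
comparison, species come from the id prefix (miRBase convention) and the
query's own species is excluded. One-nucleotide variants never count.

## Synthetic data generator

The generator emulates the five external inputs at desk scale with one seeded
`numpy` Generator (identical config + seed ⇒ byte-identical bundles). Default
study conditions: 200 genes (20% noncoding, 30% with a second isoform),
transcripts ≈ 900 ± 150 nt of i.i.d. sequence at GC 0.5 with 15/55/30%
UTR5/CDS/UTR3 splits; 12 plant miRNAs of 19–25 nt with log-normal read counts
(median ≈ 5000), two forced below the 1400-read threshold and one beyond the
length window so the QC stage always has work; 19 true sites planted by
substitution (4/6/6/3 in 5′UTR/CDS/3′UTR/ncRNA) with 3′-arm extension
probability 0.9 per nucleotide; 4 decoys per class; 10 host miRNAs with 40%
seed sharing; 4 other species with 40% exact-duplicate probability per kept
miRNA; 10 gene sets of 15–40 genes with one term holding 80% of the targeted
genes. The 200-gene universe matches the scale at which the documented
enrichment fixture (200-gene background, 40-gene query, 30-gene planted set)
is decisive.

Sites are planted by substitution, not insertion, so annotation spans stay
valid; a planted site substitutes the exact 12-mer plus a geometric-tailed
run of 3′-arm complements that deepens the achievable MFE (a bare 12-mer
duplex folds to roughly −17 to −20 kcal/mol under the default table and does
*not* pass −25 — the threshold is only cleared by extended complementarity,
which is the biologically intended behaviour). Decoys violate exactly one
criterion: `SEED_GU` substitutes one base in the seed-opposing hexamer
(forming a wobble where the miRNA base is G or U, else a mismatch),
`SEED_ONLY` keeps only the seed hexamer complement, `SHUFFLED` permutes the
12-mer; decoy placement is rejection-sampled so no probe occurrence is
created by accident. Spontaneous background matches are expected at rate
n·(L−11)/4¹² per miRNA–transcript pair (≈ 0.13 per default bundle) and are
printed in the run log; recovery checks treat them as documented extras, and
they essentially never pass the MFE criterion for the same reason bare
12-mers do not.

What the generator does **not** emulate: codon structure, splice-isoform
sharing of planted sites, realistic expression levels, sequencing error.
Passing tests therefore demonstrate correctness of the machinery on known
ground truth, not performance on real transcriptomes.

## Calibration test design

Hypergeometric p-values are discrete, so P(p < α) under the null is at most α
with a deficit equal to the local step of the overlap distribution's tail.
The null-calibration check uses a 20 000-gene background, 2000-gene queries
and ten sets of 9000–10800 genes: overlap standard deviation ≈ 21, tail step
≈ 0.005, exact attainable rates 0.0464–0.0471 — inside the 99% binomial CI of
0.05 at 10⁴ replicates ([0.0444, 0.0556]). Null overlaps are drawn directly
from the exact overlap distribution of a uniformly drawn query; the
planted-term recovery check runs the full enrichment path on generator
output.

## Determinism and numerical choices

Every stochastic operation takes an explicit seeded generator; no global RNG
state. Pipeline outputs are plain TSV/text with fixed column orders, fixed
sort keys, fixed float formats, and a run log of counts (never timestamps),
so two runs over identical inputs are byte-identical — asserted in the test
suite. Energy comparisons use exact float equality, which is safe because
both the DP and the oracle accumulate identical operations in identical
order.

## Known limitations

* The duplex model omits accessibility, intramolecular structure,
  dangles/terminal-AU and suboptimal structures; absolute MFEs are therefore
  comparable within this model only.
* Genome-wide counts against a real transcriptome/miRBase release require
  those external inputs; the package supports such runs but ships no
  database-scale expectations.
* Orientation filtering is honored via a flag, not computed.
* Whether "perfect seed matching" should extend beyond nt 7 is ambiguous in
  common usage; this implementation enforces exactly nt 2–7 (nt 2–13
  exactness is already guaranteed by the site scan).
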