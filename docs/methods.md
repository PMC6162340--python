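# Methods

## The question the package models

During germinal-center (GC) affinity maturation, B cells in the dark zone
(DZ) mutate their immunoglobulin heavy-chain variable-region (V) genes by
somatic hypermutation (SHM) at roughly 10⁻³ substitutions per nucleotide per
division. Because the genetic code contains three stop codons, a predictable
fraction of these mutations destroys the receptor outright. `shmstop`
implements the arithmetic that turns a V-gene sequence and established SHM
rates into an expected frequency of stop-codon-bearing cells in a DZ
snapshot, a stochastic simulator that cross-checks that arithmetic, an
alignment-based stop-calling pipeline for per-cell (Sanger) and bulk (NGS)
amplicon reads, and the gate-weighted normalization needed when rare sorted
subpopulations were deliberately oversampled.

## The analytic chain

For a template of length L nucleotides (reading frame fixed at offset 0)
mutating at rate μ per nucleotide per division:

* **Per-mutation stop probability q.** Every codon has 9 single-nucleotide
  variants; counting how many are TAA/TAG/TGA gives the codon's risk k (k/9
  as a probability — 1/9 for singly at-risk codons, 2/9 for doubly at-risk
  ones; the code computes k by enumeration and does not hard-wire those two
  classes). Computation is per nucleotide position: position i contributes
  c_i = (stop-producing substitutions among its 3 alternatives)/3, and

      q = Σᵢ wᵢ·cᵢ / Σᵢ wᵢ

  where wᵢ is the SHM enrichment weight of the region containing i. The
  position-wise form generalizes per-codon bookkeeping exactly (they agree
  whenever a codon lies in one region) and handles codons that straddle a
  region boundary.

* **Region weights.** CDRs are mutated ×5 and AID hotspot-motif regions ×2
  relative to plain framework. The hotspot motifs default to RGYW and WRCY
  on the coding strand — the classic AID consensus — and are configurable;
  a motif inside a CDR composes multiplicatively (×10) by default,
  configurable to ×5. Both choices matter little: removing the enrichment
  entirely moves q by under 10% relative on realistic templates, consistent
  with the published observation that the enrichment has a negligible
  effect on this calculation.

* **Per-division probabilities.** p_m = L·μ (linear; valid while L·μ < 1),
  p_point = q·p_m. The deletion rate comes from published in-vivo
  correlations of point-mutation load and deletion frequency: a cohort with
  mean load x is assigned n = x/p_m divisions (rounded to the nearest
  integer by default; the unrounded variant differs in the 5th decimal),
  its per-division retention is (1−f)^(1/n), and the retentions are
  averaged arithmetically. The bundled default observations are
  (20, 40%), (15, 15%), (5, 5%), giving retention 0.994 and p_del = 0.006.
  Indels of length not divisible by 3 shift the frame and are treated as
  stop-causing: p_fs = p_del · 2/3. Combined, p_stop = p_point + p_fs.

* **Snapshot division distribution.** A cohort observed mid-expansion
  contains 2ᵏ descendants for every founder that completed k of at most D
  divisions, so P(k) = 2ᵏ/(2^(D+1)−1). D=2 gives 14%/29%/57%. The expected
  stop-bearing fraction is E = Σₖ P(k)·(1−(1−p_stop)ᵏ) — 4.1% at
  p_stop = 0.029 and D=2, and 6.4% at D=3. Arbitrary user distributions are
  accepted wherever a snapshot is.

* **Rounding modes.** "printed" rounds p_point, retention and p_fs to three
  decimals before the next step, which is how hand-reported chains are
  usually computed and is what reproduces the sequence
  39.3% → 2.5% → 0.994 → 0.6% → 0.4% → 2.9% → 4.1% exactly; "full" never
  rounds (the two differ by < 0.1 percentage point at the end). Reports
  carry both.

## The simulator

`simulate_cohort` draws each cell's division count, then applies per
division: substitutions at positions sampled proportionally to region
weight (new base uniform over the three alternatives), and with probability
p_del one deletion at a uniform position with length uniform over {1,2,3}
(exactly one third in-frame; configurable). Two substitution-count modes
exist because "a 39.3% chance of acquiring a mutation per division" can be
read two ways: `bernoulli` (at most one mutation, probability L·μ — linear,
matching the analytic chain, and the default for oracle comparisons) and
`poisson` (count ~ Poisson(length·μ)). Deletions whose drawn start would
run past the 3′ end slide left so the full length fits; truncating instead
would silently convert in-frame deletions into frameshifts. Back-mutation
is allowed (no infinite-sites assumption). Every event is logged with
enough coordinates that replaying the log on the template reproduces each
cell byte for byte, and a fixed seed reproduces the whole cohort.

Truth flags come from classifying the final sequence against the template:
a net length change not divisible by 3 is a frameshift (stop-causing); an
in-frame sequence is translated in the template frame and scanned for a
stop strictly before its final codon.

## Stop calling

Reads are globally aligned to the template (match 5, mismatch −4, affine
gap 10 open / 0.5 extend under the EMBOSS convention where a length-ℓ gap
costs open + ℓ·extend; reverse-complement reads are auto-reoriented;
identity below 50% flags the read unalignable — reported as missing, never
as stop-positive). The net indel length decides frame status; frameshifted
reads get one `frameshift` call at the first frame-breaking gap's template
codon, and only their in-frame prefix is scanned for substitution stops.
In-frame reads are translated template-anchored and any stop strictly
before the read's final complete codon becomes a `substitution_stop` call
at its template codon (1-based in all reports). Frameshifts count as
premature stops by default (a flag restricts counting to substitution
stops for sensitivity analysis).

For bulk NGS samples of n sorted cells, identical reads are collapsed and a
unique sequence is kept only when its read share strictly exceeds (100/n)%
— one cell's worth of reads. The inequality is strict, so a sequence at
exactly (100/n)% fails; anything at two or more cells' worth passes by
construction. The sample stop frequency is 100 × (passing reads with ≥1
call) / (all passing reads). Sanger samples are one sequence per cell and
skip the filter.

## Gate-weighted normalization

Rare gates (e.g. BCR-low DZ cells) are oversampled during index sorting, so
pooling sequenced cells overweights them. The correction weights each leaf
gate's observed frequency by its pre-enrichment cytometry fraction,
recursively up the gating tree:

    f(parent) = Σ_children f(child) · fraction_of_parent(child)

Fractions always come from the cytometry proportions, never from sequenced
counts — the two are kept as separate columns to make the correction
explicit. Children's fractions must sum to 1 under each parent unless a
covered fraction is declared. Leaves with zero sequenced cells either raise
(default) or have their weight renormalized over sequenced siblings; no
imputation is attempted. Per-leaf Wilson 95% intervals (statsmodels) are
propagated to parents with the same weights — a deliberate, conservative
extension beyond a point estimate.

## The synthetic-data generator

The generator emulates an index-sorted GC experiment: a random in-frame
393-nt template (no internal stops, three CDR blocks covering ~20% of the
gene at CDR1/2/3-like positions; the codon composition can be tuned so the
template's q matches a specified value, e.g. the ~6.4% typical of a
heavy-chain V region — resolution 1/(9·codons)); a gating tree with
pre-enrichment fractions; per-leaf cell cohorts; index tables whose
channels are simple gate-conditional Gaussians (sufficient for join and
rollup testing — no cytometer physics is modelled); per-gate Sanger FASTA;
and bulk NGS FASTQ with negative-binomial reads per cell (mean 50,
dispersion 5 — a realistic abundance spread around the threshold), optional
per-base substitution errors, and sub-threshold contaminant sequences
injected at 0.3 cells' worth of reads each.

Two modes: `prescribed` draws each cell's stop status Bernoulli(gate truth)
and constructs a matching sequence (background stop-free substitutions at
Binomial(divisions, L·μ), then a stop-creating substitution at a uniformly
chosen eligible site or a 1–2-nt deletion for the frameshift share, 0.138 ≈
0.4/2.9), so gate truths are exact by construction; `mechanistic` runs the
SHM simulator per gate and lets frequencies emerge. Presets carry the
frequencies measured in the index-sorted mouse experiments as generator
parameters: `wildtype` (DZ 4.6% = 0.84×2.2% + 0.16×17.2%, LZ 1.3%, 10×
enrichment of BCR-low gates, 500 cells per zone), `wildtype-dz-split` (the
DZ BCR-high/low contrast alone) and `bcl2` (DZ 11.6%, BCR-low 25.0%, LZ
0.8%). The BCR-low DZ fraction of 0.16 is chosen so that the BCR-low share
of all DZ stops (0.16×17.2/4.6 ≈ 60%) matches the reported two-thirds;
DZ/LZ/remainder fractions (0.55/0.35/0.10) reflect the typical DZ-major GC
composition. Everything emitted is deterministic per seed.

What passing tests on these data do **not** show: the generator has no
PCR amplification bias, no chimeric reads, no base-quality structure, no
insertions, no clonal genealogy, and prescribed-mode sequences carry
exactly one stop lesion; recovery results on it demonstrate the pipeline's
arithmetic and the enrichment correction, not robustness to every real
amplicon artifact.

## Problem sizes and numerical choices

Simulator–analytic agreement is checked on 2×10⁴ cells (Monte-Carlo SE
~0.14 percentage points at 4%; the 3-SE band is the test criterion);
end-to-end recovery pools ten seeds × 1060 sequenced cells of the wildtype
scenario; the calling round trip uses a 3000-cell mechanistic cohort. Ties
in alignment are broken deterministically by taking the aligner's first
reported alignment; equal-length reads with ≤20% mismatches short-circuit
the dynamic program (a pure-substitution read cannot gain from gaps under
the scoring used). Division-count rounding, the strict abundance
inequality, and the "printed" rounding ladder are all exposed as options
rather than buried.

## Known limitations

The linear analytic model ignores multiple mutations per division (at
L·μ ≈ 0.4 the Poisson correction is a few percent relative), selection
between divisions, insertions as a separate class, and repair of existing
stops by back-mutation; the simulator shares the first two by design in
`bernoulli` mode. The per-division interpretation breaks at L·μ ≥ 1 and is
rejected. Gate frequencies assume the cytometry fractions are measured
without error; replicate-to-replicate variation across animals is supported
only by running replicate trees.
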