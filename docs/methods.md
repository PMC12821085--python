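# Methods

This note records the models implemented in `capcogs`, the parameter choices
that matter, and what the synthetic benchmarks do and do not demonstrate.

## Coordinates and the fragment backbone

All positions are 0-based, half-open. Restriction fragment maps must tile
each chromosome contiguously; gaps or overlaps are rejected rather than
repaired, because every downstream feature (promoter windows, PIRs,
enhancers) is indexed by fragment ID and silent repair would shift those
IDs. Fragment IDs are assigned in genome order (chromosome name, then
start). Distance between a bait and another region is midpoint-to-midpoint,
the axis on which the contact-decay function is tabulated. Interval overlap
everywhere means ≥ 1 bp of intersection under half-open arithmetic.

The MHC (GRCh38 chr6, printed 1-based span 28,510,120–33,480,577) is stored
as the 0-based half-open interval [28,510,119, 33,480,577) and removed from
GWAS signals before gene scoring; a variant at 0-based position 28,510,118
is the last one retained on the left.

## ABCC

Contact imputation works in CHiCAGO-normalised count space. For a fragment
pair involving a baited promoter,

    C = max(N_obs, N_exp),   N_exp = Bmean / (s_i · s_j),

where `Bmean` is the Brownian collision level estimated by CHiCAGO and
`s_i`, `s_j` the bait- and other-end scaling factors. The printed form of
this expression is ambiguous between `Bmean/(s_i·s_j)` and `(Bmean/s_i)·s_j`;
we implement the former — the Brownian level transported into
normalised-count space by dividing by both factors, consistent with working
in that space throughout — and expose `divide_both=False` to flip the
reading. `N_obs` is 0 for pairs absent from the interaction table, so
contacts never fall below the Brownian floor.

Promoters that were not baited (or lack a bait scaling factor, i.e. failed
QC) instead use the distance function `f(d)`, represented as piecewise
linear interpolation in log-log space over supplied knots, with terminal
slopes extrapolated; `f` must be non-increasing. Because `f` is steep below
~1.5 kb and would otherwise dwarf all long-range contacts, elements whose
nearest fragment is the bait itself or an adjacent fragment are capped at
`f(median fragment length)`.

Activity is the geometric mean of ATAC and H3K27ac read counts with a
default pseudocount of 0 (a zero in either assay zeroes the element;
configurable). The candidate element universe is the union of ATAC and
H3K27ac peaks with overlapping peaks merged (counts summed per assay);
elements containing the gene's own baited promoter fragment are excluded
from that gene's candidates, mirroring the original ABC's promoter
exclusion. Window membership is element midpoint within 2.5 Mb of the TSS
(the "5 Mb window"). For elements spanning several fragments the contact is
the maximum over constituent fragments.

The score cutoff for calling pairs defaults to 0.023. `select_cutoff`
reproduces the selection procedure: for each grid cutoff, the per-gene
statistic is the summed numerator (`A·C`) of elements scoring at or above
it, and the returned cutoff maximises the Pearson correlation of that
statistic with expression (ties resolve to the smallest cutoff; the full
correlation curve is returned).

## Fine-mapping preparation

Variants are partitioned into non-overlapping LD blocks (half-open
containment). Missing z-scores are imputed by the conditional-mean Gaussian
rule `z_m = R_mo (R_oo + λI)⁻¹ z_o` with ridge λ = 0.1 by default, and a
per-variant imputation quality `r² = diag(R_mo (R_oo + λI)⁻¹ R_om)` is
reported. p-values for imputed variants are plain two-sided normal tails of
z — adequate for order-of-magnitude triage, which routes blocks with
minimum p < 1e-6 to multivariate fine-mapping. Multivariate fine-mapping
itself (SuSiE) is consumed, not implemented: its per-signal credible sets
and PIPs are ingested from a TSV in which PIPs are authoritative.

Remaining blocks get a single-causal-variant posterior via Wakefield
approximate Bayes factors,

    ABF = sqrt(V/(V+W)) · exp(z² W / (2(V+W))),   V = se²,

normalised within the block (computed in log space, so large z cannot
overflow). The prior effect variance W defaults to 0.04 (prior sd 0.2 on
the log-odds scale), the conventional value for case-control traits; both W
and λ are recorded in run manifests.

## COGS / multiCOGS

A gene's features are the union over its annotated promoters of four
categories: coding SNP positions (supplied as a table, not computed by a
VEP call), the TSS fragment ± 5 fragments (contributed by baited and
unbaited promoters alike), other ends of consensus contacts at CHiCAGO
score ≥ 5 anchored at the gene's baited promoter fragments, and ABCC
elements at score ≥ 0.04 (the feature threshold is deliberately distinct
from the 0.023 calling cutoff; both are configurable).

A signal's score for a gene is the sum of PIPs over the *unique* variants
covered by any feature — a variant inside both a PIR and the proximal
window counts once. Union semantics is the only reading that keeps the
score a probability; summing per feature class could exceed 1. Per-signal
scores are clipped to [0, 1] before combination. The combined score is
`1 − Π(1 − s)` over all (block, credible set) signals; standard COGS is the
same machinery restricted to one single-causal signal per block. Per-category
decomposition reruns the scoring with features restricted to one category at
a time — category scores are not bounded by the combined score in general,
though with disjoint variants the combined score dominates each category.

Prioritisation uses strict `multicogs > 0.5` (an inclusive option exists);
ranking is by score descending with lexicographic gene-ID tie-break for
determinism.

## cPIR transplantation enrichment

Adjacent (consecutive-fragment) or overlapping PIRs of a gene merge into
collapsed PIRs; trans-chromosomal PIRs are dropped first. Each cPIR stores
signed bp offsets from the gene's baited-fragment start, so the whole set
can be re-anchored exactly. The null transplants every gene's full cPIR set
to a uniformly drawn target gene's anchor (drawn independently per gene and
permutation, target may equal source), preserving each cPIR's length and
every bait-relative offset bit-for-bit — unlike per-PIR shuffles, this also
preserves the spatial relationships between a gene's PIRs. Transplants that
would exceed the target chromosome are re-drawn rather than clipped (count
reported), keeping sizes exact at the cost of a slight bias toward interior
anchors.

The overlap proportion is per-cPIR (share of cPIRs touching ≥ 1 feature
bp), not bp-weighted. Fold enrichment is observed proportion over null
mean; the 95% CI applies the delta method on the log fold, combining the
binomial variance of the observed proportion with the Monte-Carlo standard
error of the null mean:

    CI = exp( log fold ± 1.96 · sqrt( Var(p_obs)/p_obs² + Var(p̄_null)/p̄_null² ) ).

This is one concrete interpretation of "error propagation"; it degenerates
when the observed proportion is 0 (CI reported as NaN).

## Alternative-promoter sharing

Genes qualify with > 1 baited promoter, each having ≥ 1 contact at score
≥ 5 with ≥ 5 reads. Per significant PIR: `fully_shared` if it contacts all
qualifying promoters at score ≥ 5; `partially_shared` for a strict subset
of > 1 (possible only with > 2 promoters); otherwise the PIR is a distinct
candidate, demoted to the generic label `shared` when it — or either
immediately flanking fragment — contacts another promoter at the lenient
score ≥ 3. The rescue outcome needs its own label because rescued PIRs are
neither fully shared (no score-5 contact with all promoters) nor distinct.

## Synthetic data

The generator emulates every input at desk scale: 3 chromosomes × 2,000
fragments (lognormal lengths, median ≈ 1.5 kb), 200 genes with 1–3
alternative TSSs (~90% baited, base fragments ≥ 10 fragments apart),
power-law contact decay `f(d) = 20 · (d / median_len)⁻¹` with Bmean = 5 and
lognormal(σ = 0.2) scaling factors, negative-binomial raw counts
(dispersion 10) scored by a Poisson upper tail, 20 AR(1) LD blocks
(ρ = 0.9) × 100 variants, and expression equal to the summed ABC numerators
of elements above score 0.02 (plus optional Gaussian noise). Planted
enhancers receive a 15-fold contact boost (raw counts raised to the Poisson
1e-6 tail where sampling falls short, so planted contacts are significant
by construction), peaks of count ~20 in both assays against an
exponential(15) background in which 60% of locations are active in both
assays, and a causal variant at the enhancer midpoint whose one-variant
credible set carries PIP 0.95. Planted enhancers are kept out of every
promoter-proximal window so their causal variants are attributable to the
planted contact. All randomness flows from one integer seed.

What passing recovery tests shows: the pipeline's bookkeeping (fragment
assignment, thresholds, union semantics, score combination) is correct end
to end, and planted signal dominates background under the stated effect
sizes. What it does not show: performance on real data — the generator has
no haplotype-level LD structure, no depth or GC biases, no correlated
peak/contact confounding, and its 3 Mb chromosomes make the 5 Mb ABC
window genome-wide, so enhancer sharing between genes is more extreme than
in real genomes. A consequence worth knowing: very active elements can
legitimately exceed the 0.04 feature threshold for several genes, so a few
non-planted genes can be prioritised at default scale; this is multi-gene
enhancer assignment, not a bookkeeping error.

## Numerical choices and simulation sizes

- Per-gene ABC scores sum to 1 within 1e-9 whenever the denominator is
  positive; zero-denominator genes are flagged, not scored.
- The z-imputation masking benchmark uses ρ = 0.9, λ = 0.1, 50 fragments
  masked of 50 × 50 replicates. The single-causal argmax-recovery
  simulation uses ρ = 0.8 at non-centrality 7 over 200 replicates: at
  ρ = 0.9 the immediate neighbour's expected z is 6.3 against the causal's
  7.0 (difference sd ≈ 0.45), so no method can identify the causal variant
  much more than ~86% of the time — ρ = 0.8 is the moderate-LD regime in
  which argmax identification is a meaningful test.
- Transplantation benchmarks use 100 permutations, 40 genes, 600-fragment
  chromosomes; the full pipeline smoke test runs the default fixture in
  well under a minute on one CPU.
- Credible-set pips are written with full precision (`repr`) and parsed
  with round-trip float precision, so write/read is exact.
- Ties in cutoff selection resolve to the smallest cutoff; ties in gene
  ranking to lexicographic gene ID.

## Known limitations

- No bigWig/cooler/HiC parsing, no liftover, no haplotype-panel LD
  estimation, no SuSiE implementation, no VEP: these arrive as files.
- The consensus merge keeps, per (bait, other-end fragment) pair, the
  element-wise maximum of count/score across resolutions; alternative
  policies (e.g. fragment-resolution precedence) are not implemented.
- The delta-method CI is asymptotic and degenerates at observed proportion
  0 or very small null means.
- `capcogs abcc` scores one promoter per gene (preferring a baited one);
  scoring every alternative promoter separately is available through the
  library API.
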