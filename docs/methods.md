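# Methods

This note documents the statistical models implemented in `swampx`, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot show about real genomes.

## Data model and ploidy semantics

The pipeline starts from a genotyped, biallelic SNV panel: a sites ×
samples dosage matrix with 1-based VCF coordinates, a sample sheet
(sample → population, sex), and a chromosome-class map (autosome / X /
mito).  Copy numbers are implied, never stored per call: 2 on autosomes,
2/1 for females/males on X, 1 on the mitochondrial genome.  Sex must be
known for any sample contributing X or mito sites.  Male heterozygous X
calls — which upstream callers do emit — default to missing with a logged
count; a strict mode raises instead.  Region masks are BED-style 0-based
half-open intervals; the single 1-based↔0-based conversion happens inside
the mask membership test, so coordinates are never shifted twice.  The
default X mask excludes both pseudoautosomal regions and a 10-Mb window
proximal to the PAR1 boundary (shipped as the named presets `pars` and
`par1_proximal_10mb` on the baboon-assembly coordinates, config rather than
code, because such constants are assembly-specific).

Population allele counts pool individuals by copy number: a male
contributes one X copy, a female two.  The alternative — using females only
on the X — discards information and is not implemented; singleton
populations are first-class (one sampled diploid stands in for its
population's allele frequency).  The default missing-data policy for
f-statistics is complete-case filtering across all samples; allele counting
also operates on missing-tolerant matrices (per-site totals then vary).
f-statistics refuse mitochondrial sites: mito is carried through the data
model for phylogenetic use and for the simulator's truth record only.

## f-statistics

Per-site estimators with sample frequencies `p̂ = derived/total` and the
unbiased heterozygosity `ĥ = p̂(1−p̂)·n/(n−1)`:

    f2(A,B)       = (p̂A − p̂B)² − ĥA/nA − ĥB/nB
    f3(A,B;C)     = (p̂C − p̂A)(p̂C − p̂B) − ĥC/nC        (C the outgroup)
    f4(A,B;C,D)   = (p̂A − p̂B)(p̂C − p̂D)

The ĥ/n terms remove finite-sample bias so that the estimators target
population moments; f4 is already unbiased.  Bias correction defaults on
for f2/f3; sites where a correction term is undefined (a single called copy
in a corrected population) are skipped and counted, never silently
interpolated.  An infinite per-site value aborts with the offending site
named.

Pooled estimates are global means of per-site values.  Standard errors use
the weighted delete-one block jackknife over per-chromosome, half-open
windows `[kB, (k+1)B)` of B = 5 Mb by default, block weight = SNV count,
empty blocks dropped.  With `h_j = n/m_j`:

    τ_j = h_j θ̂ − (h_j − 1) θ̂_{−j}
    θ̂_J = g θ̂ − Σ_j (1 − m_j/n) θ̂_{−j}
    σ²  = (1/g) Σ_j (τ_j − θ̂_J)² / (h_j − 1)

which reduces to the textbook delete-one jackknife for equal blocks; the
test suite checks agreement with explicit leave-one-block-out recomputation
to 1e-12.  Constant input yields SE exactly 0 and a flagged infinite Z that
is never consumed downstream.

The f4 enumeration tests every unordered population triple {B, C, D}
against a fixed outgroup; per triple the three pairings are evaluated and
the best-fitting topology (smallest |Z|, ties broken lexicographically) is
reported as the tree hypothesis, with Bonferroni control across the
enumeration (the only correction offered; FDR variants are out of scope).

**Autosome-vs-X contrast.**  Welch's t (Satterthwaite df, two-sided p)
between the per-block f4 values of the two chromosome classes.  The blocks
enter as raw within-block means, not jackknife pseudovalues — simpler, and
variance-honest since the per-block means are independent across blocks;
with many blocks the two choices agree closely.  The reported direction
(`x_more_negative` / `x_less_negative` / `none` on an exact tie) is the
sign of the X-minus-autosome block-mean difference.

## Admixture graphs

A rooted DAG with drift lengths (f2 units: variance of allele-frequency
change along an edge) and two-parent admixture nodes mixing with weight α
toward the first parent; admixture edges themselves carry no drift (drift
is absorbed by the adjacent tree edges, the usual convention).  Writing a
leaf's frequency deviation from the root as an α-weighted sum of
independent per-edge increments gives the leaf covariance
`V_ij = Σ_e γ_e(i)γ_e(j)·len(e)`, from which every f-statistic follows
(`f2 = V_ii+V_jj−2V_ij`, etc.).  f2 is exactly additive along drift paths
(martingale increments), and pulse admixture mixes frequencies linearly, so
the graph model is exact for the simulator's dynamics up to the
heterozygosity decay along branches.

**Fitting** minimizes the 1/SE²-weighted squared residuals of an observed
basis — all pairwise f2 plus, when an outgroup is named, all outgroup f3 —
over bounded parameters (lengths ≥ 0, α ∈ [0,1]) with seeded multi-start
`least_squares` (20 starts by default; deterministic given the seed).  The
f3 rows are algebraically redundant given the f2 rows but enter the
weighting; the basis deliberately avoids inverting a full jackknife
covariance, which is unstable at small block counts.  Because f-statistics
see only the covariance *metric* among leaves, the root's position along
its two child edges is not identifiable; one root-child edge is pinned at
zero during fitting (the profile-probing diagnostics otherwise leak this
flat direction into other parameters).  After fitting, parameters whose
profile score is flat within tolerance are flagged `unconstrained` — note
that mixing weights attached between stems leading to single leaves can be
weakly identified even when no parameter is exactly flat, a known caveat of
this model class; with four populations and one admixture node the model is
a one-parameter family and α is not identifiable at all, which is why the
scenario presets sample the donor's sister population (five leaves).

**Greedy search** starts from a tree (by default NJ on the pairwise-f2
matrix, which is additive on trees), enumerates admixture insertions from
the midpoint of any tree edge into any other tree edge that keeps the DAG
acyclic, fits each candidate with a reduced restart budget, and keeps the
insertion that most reduces the largest |Z| among all predicted-vs-observed
f4 configurations; it stops at `z_stop` (default 3), at `max_edges`, or
when no candidate improves.

**X refit** freezes the topology and refits mixing weights on the
X-chromosome basis.  Three modes: `alpha_only` (drift frozen at autosomal
values), the default `alpha_and_scale` (one global drift rescale shared by
all edges — the X's effective size is about 3/4 of the autosomal one at an
even sex ratio, so X drift lengths are approximately a common multiple of
the autosomal ones; a single extra parameter keeps the refit identifiable
even on small graphs), and `alpha_and_drift` (every length free; refuses to
run when the X basis has fewer statistics than parameters rather than
returning ridge-contaminated numbers).  For continuous migration the
single-admixture-event graph is a compression of many small pulses, which
biases the fitted donor fraction somewhat below the cumulative truth; the
autosome-vs-X *comparison* is unaffected since both classes are compressed
the same way.

## Distances and trees

Pairwise distance is 1−IBS over autosomal diploid sites: the mean of
`|dosage_i − dosage_j|/2` across called sites (pairwise-complete; a pair
with no shared sites is an error).  X sites are excluded by default —
mixed ploidy makes per-site sharing inhomogeneous — and can be included
ploidy-normalized.  Neighbor joining is the Saitou–Nei algorithm with the
standard Q criterion, lexicographic tie-breaking for determinism, negative
branch lengths clamped to zero, and a final three-point join; additive
matrices are recovered exactly (checked against scikit-bio's independent
implementation).  Outgroup rooting bisects the outgroup's terminal branch.

## The simulator

Frequencies, not individuals: each population holds one allele-frequency
array per chromosome class, binomially resampled every generation with
copies 2N (autosome), ⌊3N/2⌋ (X), ⌊N/2⌋ (mito) — N must be even in presets
to avoid rounding bias.  Sex-specific migration and pulses update
`p ← (1−w)p + w·p_donor` with class-specific w from copy counting at a 1:1
sex ratio: `w_A=(m_f+m_m)/2`, `w_X=(2m_f+m_m)/3`, `w_mito=m_f`.  Sampling
draws genotypes binomially at the final frequencies with the correct
per-sample ploidy.  Runs are bit-reproducible given a seed (fixed
population and class iteration order).

The truth record tracks, per population and class, the expected ancestry
fraction from each source population (reset to self at creation, mixed at
the class rate each generation) — the deterministic expectation of the
admixture process, satisfying `d_t = 1−(1−w)^t` for a constant rate; drift
acts on frequencies only.  Ancestral frequencies default to Beta(0.8, 0.8)
truncated to [0.05, 0.95], a polymorphism-rich panel resembling a
complete-case SNV set (uniform available).

**What the simulator does not model:** linkage (loci are independent, so
jackknife SEs are exact-to-conservative and the block machinery is
exercised without LD), mutation during the simulation (standing variation
only), selection, a Y chromosome, and sequence-level reads.  Passing tests
therefore demonstrate correctness of the estimators and the inference
logic under the model's assumptions, not robustness to LD, ascertainment,
or calling artifacts in real data.

## Scenario presets and problem sizes

The default panel is 10⁴ autosomal loci on 20 chromosomes at 25-kb spacing
(60 jackknife blocks at 5 Mb) plus 2×10³ X loci (10 blocks) and one mito
locus, with diploid N = 500 and 2 females + 2 males sampled per population
— a desk-scale panel carrying roughly 1/7000 of the information of a
67-million-SNV genome study, which drives every other scale choice below.

The nuclear-swamping preset places the outgroup split at generation 0, the
(B,C)-ancestor/D-lineage split at 30, the donor split (Dp from D) at 60,
the B/C split at 210, and male-only migration Dp→C (m_f = 0, m_m = 0.02)
over generations 230–380, sampling at 400.  The B/C ancestor passes
through a founder bottleneck (N/5): at desk scale the contrast's power
comes entirely from the shared drifted ancestry that migration erodes, and
a strongly drifted founder lineage is the realistic way to supply it.  The
defaults give C a cumulative autosomal donor fraction of 0.78 ("almost
replaced"), an X fraction of 0.63, and an untouched maternal lineage.  The
donor's sister population is sampled by default so that graph fits on the
scenario are well-determined; the f4 contrast itself uses only (A,B;C,D).
Companion presets: a clean four-population tree (null calibration), the
same tree with sex-balanced B→C or B→D flow (sign rules), and a
five-population single-pulse scenario (α recovery), each with analogous
timelines at N = 100.

## Numerical conventions

Jackknife requires ≥ 2 non-empty blocks; zero-SE results carry a flagged
sentinel Z.  Welch's t requires n ≥ 2 per side and raises on zero variance
with unequal means.  Optimizer: `scipy.optimize.least_squares` (trf,
tolerances 1e-12), α clipped at [0,1] bounds (no logit transform — bound
recovery is exact), drift capped at 2 (the f2 range).  Fitting weights
floor the SE at 1e-9.  Degenerate f-statistic configurations (repeated
populations) are rejected at construction.

## Known limitations

Mixing weights are only interval-identified on stem-heavy topologies (see
above); the X refit's `alpha_and_scale` mode assumes a shared drift rescale
across edges, an approximation when donor fractions differ strongly by
class; greedy search is a local heuristic and inherits the usual caveats
(no exhaustive topology search, no admixture dating, no qpAdm-style
proportion estimation); and the Welch contrast's X side rests on few blocks
at desk scale, so its df is small and single replicates can miss — the
detection-rate guarantees are statements over seeds, not per run.
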