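# Methods

## The assay being modelled

A drop-off ddPCR assay interrogates a mutation hotspot (here IDH2 R140 or
R172) with two probes in one amplicon: a FAM-labelled reference probe on an
invariant sequence, and a HEX-labelled probe covering the wild-type hotspot
sequence. The reaction is partitioned into ~20,000 nanolitre droplets and
amplified to end point. Droplets with any template fire FAM; droplets whose
template is wild-type also fire HEX; droplets containing only mutant
template lose the HEX signal ("drop-off"), because any substitution under
the probe abolishes binding. The observable per well is therefore three
droplet clouds in the (channel 1, channel 2) amplitude plane: double
negative, double positive (wild-type) and FAM-only (mutant).

## Simulator

**Partitioning.** A known number of wild-type and mutant template copies is
distributed over the droplets by assigning each copy to a uniformly random
droplet (a multinomial model). This conserves copies exactly — column sums
of the occupancy table equal the requested copy numbers — and converges to
the independent-Poisson occupancy model that instrument software assumes;
the empty-droplet fraction at 4848 copies over 20,000 droplets is
e^(−0.2424) ≈ 0.785 up to binomial noise.

**Copies from mass.** Copy number = round(ng × 1000 / 3.3), one target
allele per haploid genome at the standard 3.3 pg/haploid-genome constant.
The default 16 ng input is therefore 4848 copies. Both constants are
configurable.

**Amplitude rendering.** Each droplet draws channel amplitudes from the
Gaussian cluster of its occupancy class. Droplets containing both mutant
and wild-type template render double-positive — physically correct for a
drop-off probe, and the reason the quantifier must subtract rates rather
than count droplets. Defaults (arbitrary but in the range of real
instrument exports, and configurable): negative (1000, 1000), double
positive (8000, 9000), FAM-only (8000, 1200), SD 300 a.u. per channel.
Cluster SDs of zero are permitted so that rendering can be made exactly
deterministic in tests. "Rain" is modelled as a chosen fraction of positive
droplets displaced halfway toward the negative centroid — the simplest
mechanism that stresses thresholding.

**Dilution series and seeding.** Each (level, replicate) well draws its RNG
from `SeedSequence(master_seed, spawn_key=(level, replicate))`, so results
are reproducible and adding levels or replicates never changes previously
generated wells. Mutant copies per level are `round(fraction × total)`,
e.g. 5 mutant + 4843 wild-type copies at 0.1% of 16 ng.

**What the simulator does not emulate.** PCR kinetics and probe chemistry,
droplet volume variability and coalescence, between-well pipetting noise,
cross-talk between channels, and multi-modal rain. Passing tests therefore
demonstrate the correctness of the statistical pipeline under idealised
cluster geometry, not robustness to every instrument artefact; the rain
model provides a first-order stress of the thresholding step only.

## Droplet classification

The quadrant structure of the three clouds makes the two channels
separable, so each channel is thresholded independently by a 1-D two-means
split: deterministic initialisation at the 5th and 95th percentiles, ≤ 100
iterations, tolerance 1e-6, cut at the midpoint of the final cluster means.
A channel whose cluster means are separated by less than 3 pooled
within-cluster SDs is declared single-cluster and its cut is placed above
the channel maximum (no positives) — this is what makes a pure-mutant well,
whose HEX channel shows only the negative and near-negative FAM-only
clusters, read as HEX-negative throughout. Determinism means no seed is
needed and droplet order is irrelevant. Rain droplets are assigned by the
hard threshold; no droplet exclusion band is applied.

HEX-only droplets are anomalous (the reference probe shares the amplicon
and must fire whenever any template is present); they are counted,
never merged, and surfaced by QC. Well QC fails below 10,000 accepted
droplets or above 0.5% HEX-only droplets; both limits are parameters.

## Poisson quantification

With occupancy approximately Poisson, the mean copies per droplet for a
target is estimated from its negative-droplet fraction:

    λ̂ = −ln(n_negative / n_total),  Var(λ̂) ≈ (e^λ − 1) / n_total,

the variance by the delta method on the binomial negative count; 95%
intervals are λ̂ ± 1.96·SE, floored at zero. A well with zero negative
droplets is saturated — λ is unbounded — and raises an error rather than
returning infinity, forcing dilution as in real practice. Concentration is
λ per droplet volume (default 0.85 nL ⇒ copies/µL = λ/0.00085).

The drop-off construction yields two rates per well: λ_total from the
FAM-negative count (the empty droplets) and λ_wt from the HEX-negative
count (empties + FAM-only). The mutant rate is their difference, floored at
zero, and the mutant allele fraction is MAF = 100·λ_mut/λ_total (zero when
λ_total is zero). This subtraction corrects for mutant copies hidden in
double-positive droplets that also carry wild-type template; at low
occupancy it converges to the naive droplet ratio
n_fam/(n_fam + n_double_positive) (difference < 0.1 pp at λ ≤ 0.01). The
MAF interval propagates the two λ variances by the delta method treating
the counts as independent binomials — an approximation, since both counts
share the empty droplets; the shared term cancels to first order in the
ratio, and simulation shows the mean estimate unbiased within Monte-Carlo
error across MAF 0.1–44%.

**Detection and sensitivity.** A well is called mutation-positive when its
FAM-only droplet count strictly exceeds max(LoB, minimum − 1), with the
minimum defaulting to one droplet. The limit of blank is the nearest-rank
95th percentile of FAM-only counts across mutation-free wells. The limit of
detection of a dilution series is the smallest tested mutant fraction
detected in ≥ 95% of replicate wells such that every larger tested fraction
also qualifies; blanks are never candidates, and a series with no
qualifying level reports the LoD as not reached. At 16 ng input a 0.1%
mutant fraction is ~5 mutant copies per well, of which a fraction e^(−λ_wt)
≈ 0.78 land in droplets free of wild-type template, so the probability of
at least one FAM-only droplet is ≈ 1 − e^(−3.9) ≈ 0.98 and the simulated
detection rate at 0.1% clears the 95% requirement — the dilution study in
`scripts/acceptance.py` (200 replicate wells per level, LoB from 50 blanks)
computes exactly this.

## ARMS ΔΔCt calling

The reference method's rules are implemented verbatim: ΔCt_sample =
Ct(mutant assay) − Ct(wild-type copy-number assay), ΔCt_healthy the same on
a healthy donor, ΔΔCt their difference; mutated when ΔΔCt > 4, wild-type
when ΔΔCt < 3, borderline in between. "Between 3 and 4" is implemented as
the closed interval [3, 4]: the printed strict inequalities leave the
endpoints to borderline. A mutant-assay Ct above 37, or no amplification
within the 40-cycle run (undetermined, encoded as NaN), forces wild-type
regardless of ΔΔCt. As printed, the orientation implies mutated samples
have a *larger* ΔΔCt than the healthy baseline — the opposite of the usual
ARMS contrast; it is implemented as stated, with an `invert_ddct` switch
(default off) for kits defining the contrast the other way. Batch calling
requires exactly one flagged healthy-donor row per assay and rejects
duplicate sample ids.

## Agreement statistics

The 2×2 table between two methods is stored as a = both positive, b =
B-only, c = A-only, d = both negative. Observed agreement is (a + d)/n;
Cohen's kappa is (p_o − p_e)/(1 − p_e) with p_e = [(a+c)(a+b) +
(b+d)(c+d)]/n², undefined (raised) when p_e = 1. Borderline calls map to
positive by default when building tables from categorical calls —
comparisons of published screens report only positive/negative totals — and
the mapping is configurable. Printed percentages round half-up to one
decimal (13/60 → 21.7%).

The MRD trajectory rule is deliberately explicit because no formal standard
exists: a series is concordant with the clinical course iff every
complete-remission timepoint has burden below 0.1% MAF (or ≤ 10% of the
diagnosis burden), and every progression timepoint is preceded by or
coincides with a ≥ 2-fold rise over the preceding timepoint. All three
parameters are arguments and the defaults are illustrative only; the rule
depends only on timepoint order, so it is invariant to time shifts.

## Problem sizes and numerical choices

Simulation-backed tests use 200–500 replicate wells per condition and
20,000 droplets per well (2,000 for pure-partition checks), sizes at which
3-standard-error bands separate correct estimators from plausible bugs
while the whole suite runs in well under a minute of compute. Estimator
checks compare mean estimates to ground truth within 3 SE; exact arithmetic
(rule tables, contingency statistics) is asserted to printed precision. All
randomness flows through numpy `SeedSequence` substreams from a single
master seed.

## Known limitations

- Classification is per-well and hard-threshold; no multi-well shared
  thresholds, soft assignment, or plate normalisation.
- The MAF interval is a delta-method approximation; no exact or bootstrap
  option.
- Quantification assumes one target allele per haploid genome; no
  copy-number-variation adjustment and no pooled-well ("merged") analysis.
- The ARMS module calls from Ct values only; amplification-curve processing
  and efficiency correction are out of scope.
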