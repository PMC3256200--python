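# Methods

This note documents the statistical model behind chromocorr, the choices
made where the design was genuinely open, and what the test suite does and
does not establish.

## The model: features as a 1-D point process on a masked support

A chromosome is a line segment [0, L) with a *mask*: intervals of ambiguous
or missing sequence that could not have been assayed. Features (here CpG
islands) are intervals on the assayed part; their 5′ start positions are
the points of a one-dimensional point process. The two-point correlation
function ξ(r) is defined by the excess probability, over a homogeneous
Poisson process of the same intensity, of finding two points at separation
r. ξ ≡ 0 for complete spatial randomness; ξ > 0 means clustering.

### Landy–Szalay estimation

The practical difficulty is the support: chromosome ends and interior gaps
make naive pair-histogram estimators biased, because points near an edge
have fewer possible neighbors. The Landy–Szalay (LS) estimator handles this
by comparing the data against a *random catalog* that lives on exactly the
same masked support:

- DD(r): data–data pairs per bin, normalized by N(N−1)/2;
- DR(r): data–random pairs, normalized by N·M;
- RR(r): random–random pairs, normalized by M(M−1)/2;
- ξ(r) = (DD − 2·DR + RR)/RR, with bins where RR = 0 flagged invalid.

The random catalog mimics the data in every respect except spatial
structure: M = 10·N intervals (so the randoms' shot noise is negligible
relative to the data's), lengths drawn with replacement from the observed
feature lengths, non-overlapping, and avoiding the mask. Start positions
are sampled uniformly over the positions at which the interval fits inside
a free segment — the exact conditional distribution of uniform-proposal
rejection sampling, but deterministic when only one placement is possible —
with rejection only against previously placed randoms (attempt budget
1000·M; exhausting it raises rather than returning a biased catalog).

Separations are |start_a − start_b| between 5′ starts; `ref_point` offers
centers or 3′ ends for sensitivity analyses (the choice only matters at
separations comparable to the feature length). Pairs are tallied in K = 15
logarithmically spaced half-open bins spanning 1 kb (below which detector
artifacts and the reference-point convention dominate) to 249 Mb (the
longest human chromosome); bin "centers" are geometric means of the edges,
the natural representative point of a log-spaced bin. Counting uses a sort
plus binary-search cumulative count per bin edge, O((N+K) log N); the
O(N²) double loop exists only as a test oracle.

### Errors

Two per-bin error estimates are computed:

- **Bootstrap SE** (default for fitting): 250 resamples of the N features
  with replacement; DD and DR are recounted per resample against the fixed
  random catalog (RR is computed once — resampling targets the data's
  sampling variance, not the survey geometry; a fresh catalog per resample
  is deliberately not the default). The reported 1+ξ is the bootstrap mean;
  the SE is the bootstrap standard deviation (ddof = 1). Resample
  duplicates produce zero-separation pairs, which fall below the 1 kb bin
  floor and are discarded.
- **Poisson σ** = (1+ξ)/√DD_raw, the error-propagation limit valid when
  M ≫ N and clustering is weak. Under strong clustering it underestimates
  the true variance; the package computes both so that their ratio itself
  is diagnostic (the suite checks they agree within a factor of 2 on
  Poisson data).

### Power-law metric

Chromosome-scale clustering is summarized by 1+ξ(r) = A·r^β over the
separations with signal. The fit range starts at the smallest valid bin and
stops before the first bin whose 1+ξ is within n_sigma (default 1, the
weakest reading) bootstrap errors of 1; at least 3 bins are required, and a
first bin already consistent with random is reported as "no clustering
signal" rather than fitted. The fit minimizes

    χ² = Σ_i [(log10(1+ξ_i) − log10 A − β log10 r_i) / σ_log,i]²,

with σ_log,i = σ_i/((1+ξ_i) ln 10) — the errors transformed to the log
scale — solved in closed form as weighted linear least squares; parameter
errors come from the covariance matrix inverse(XᵀWX). The fitted quantity
is 1+ξ (the plotted and modeled quantity); a flag fits ξ instead. Reported
goodness of fit: the error-weighted reduced χ²_ν = χ²/(n−2), its upper-tail
p, and the "traditional" Pearson statistic Σ(O−E)²/E on the 1+ξ scale.

The confidence band is parametric Monte Carlo: each of 10 000 realizations
perturbs the per-bin values with independent Gaussians at the stated σ
(Poisson σ by default, bootstrap SE behind a flag — both are legitimate
readings and both are provided), refits, and the pointwise 99% band is read
off at sorted-realization ranks ⌈0.005·n⌉ and ⌊0.995·n⌋ (50 and 9 950 for
n = 10 000). Non-positive draws are redrawn so the log transform exists;
with zero stated errors the band degenerates onto the fit line. The fitted
(A, β) of every realization is retained so parameter-level intervals can be
read from the same draws.

## CpG-island detection

Detection follows the sliding-window construction: 200 bp windows pass when
GC ≥ 0.55 and Obs/Exp CpG ≥ 0.65 (both inclusive — thresholds are minima);
passing windows whose starts lie within 200 bp of each other are chained
into one candidate region (provably the same region the classic
jump-200-bp-then-roll-back-1-bp scan produces); the candidate is trimmed
1 bp off *both* ends per step until the whole region passes all criteria,
and rejected if it drops below 500 bp first; accepted islands separated by
less than 100 bp are merged when the merged span itself passes. The
symmetric chain construction and symmetric trimming make detection exactly
reverse-complement invariant — GC content and CpG counts are themselves
strand-symmetric — which the suite asserts. The merge distance and the
both-ends trimming order are not canonical constants; both are parameters
(`CgiParams`) with the defaults documented here rather than asserted as
universal.

Windows never overlap non-ACGT bases: the sequence is split at masked runs
and each assayed segment is scanned independently, so no island crosses a
gap. All IUPAC ambiguity codes are masked, not just N (the conservative
reading of "ambiguous or missing"); lowercase soft-masking is treated as
assayed sequence since repeat masking is not an assay gap.

## Density statistics

Features are counted per non-overlapping 1 Mb window by 5′ start; the
trailing partial window is kept and counted as a full window (a flag drops
it). Summaries: mean; SD with the n−1 denominator; skewness as the biased
sample moment ratio g1 = m3/m2^(3/2) (the most common default; comparisons
against published 1-d.p. tables therefore carry a small tolerance).
Constant counts yield NaN skewness rather than a crash. The per-Mb-assayed
density is N/(total − missing) with lengths in Mb. Spearman correlations
use average ranks for ties and a t-approximation p-value (scipy).

The packaged GRCh37 table (22 autosomes + X, Y; total and missing Mb,
island count, assayed density, and per-window mean/SD/skewness) is used by
the suite for internal-consistency checks: the assayed-density column is
reproduced from the count and length columns at 1 d.p. for all 24 rows, and
length-vs-density rank correlations computed from the table are −0.50
(mean), −0.62 (SD) and 0.35 (skewness) within ±0.02.

## Synthetic data: what it emulates, what it does not

- `simulate_poisson_features`: n non-overlapping intervals uniform on the
  unmasked support — the null world in which the LS estimator must return
  ξ = 0 in every bin, mask or no mask. It emulates survey geometry, not
  any biology.
- `simulate_thomas`: Poisson(λp·L) parents, Poisson(μ) offspring each,
  Gaussian(0, σ²) displacements, offspring returned as 1 bp points (so the
  5′-start distance convention is exact). Its pair-correlation excess has
  the closed form ξ(r) = exp(−r²/4σ²)/(2σ√π·λp) — the density of the
  difference of two offspring displacements, N(0, 2σ²), divided by the
  parent intensity — re-derived and verified against a brute-force pair
  separation histogram in the suite. Oracle comparisons for *binned*
  estimates use `xi_thomas_bin_average` (the integral of ξ over the bin
  divided by its width), since a binned estimator measures the bin average
  and for log bins with edge ratio 2.29 the bin average differs from the
  center value by several percent around the Gaussian shoulder.
  The validation default (λp = 4×10⁻⁶/bp, μ = 5, σ = 10 kb on 100 Mb,
  E[N] = 2000) keeps ~400 independent clusters in a realization: enough
  that the closed form is a meaningful target; with only tens of clusters
  the realized amplitude fluctuates at the ten-percent level and no
  per-realization comparison is calibrated.
- `synth_genome`: iid background at 40% GC with the CG dinucleotide
  transition probability scaled by 0.2 (emulating vertebrate CpG
  depletion, so detection is non-trivial), islands iid at 70% GC (hence
  Obs/Exp ≈ 1), N-runs at specified gaps, ground truth returned. It does
  *not* emulate isochore structure, repeats, or realistic island length
  distributions — a green recovery test establishes that the detector
  finds strongly differentiated islands, not that it matches any
  particular published island list.

All generators are bit-reproducible under a fixed `numpy.random.Generator`;
pipeline entry points take a single integer seed and split it into
independent substreams (random catalog, bootstrap, Monte Carlo) via
`numpy.random.SeedSequence.spawn`.

## Numerical choices and degenerate inputs

- Threshold comparisons in the detector use division (fractions), not
  cross-multiplication, so vectorized window tests agree bit-for-bit with
  scalar whole-region tests at boundary values like GC = 110/200 = 0.55.
- Monte-Carlo band rank indices are computed with an epsilon guard because
  0.005 is not exactly representable in binary floating point.
- RR = 0 bins are flagged invalid, never divided through; DD_raw = 0 makes
  the Poisson σ infinite, excluding the bin from any fit.
- Degenerate fits raise informative errors: fewer than 3 bins (dof < 1),
  non-positive values under the log transform, indistinct separations.
- Coordinates are 0-based half-open everywhere internally and in BED; Mb
  conversions happen only at display time.

## Known limitations

- The bootstrap SE treats features as exchangeable; under very strong
  clustering it underestimates cluster-to-cluster variance (the full
  non-Poisson LS variance is out of scope).
- The LS estimator normalizes by the realized sample density, so strongly
  clustered small samples show the classic integral-constraint dip — a
  slight ξ < 0 plateau at intermediate separations — visible in Thomas
  validations as a systematic few-percent effect at high precision.
- The power law is a summary, not a generative claim: for a Thomas world
  the true log–log relation is curved, and χ²_ν honestly reports the
  misfit while β still ranks clustering strength.
- Genome-wide results on a real reference assembly are exercised only by
  the optional download script; the suite's guarantees are for synthetic
  worlds with known structure.
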