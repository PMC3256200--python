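# chromocorr

Spatial statistics of genomic features along chromosomes: how are CpG
islands (or any other interval-valued feature) organized on a chromosome,
beyond their mere count and density?

The package is aimed at genome biologists and statistical genomicists who
want a quantitative, uncertainty-aware answer. It treats feature positions
as a one-dimensional point process on a chromosome with gaps (ambiguous or
missing sequence) and measures their clustering with the two-point
correlation function (TPCF), the standard second-order statistic for point
patterns on irregular supports.

## What it computes

**CpG-island detection.** The classic sliding-window criteria: a CpG island
is a region of length ≥ 500 bp with G+C fraction ≥ 0.55 and observed /
expected CpG ratio

    Obs/Exp = (#CG × length) / (#C × #G) ≥ 0.65,

built from chains of passing 200 bp windows, trimmed until the whole region
passes, with nearby islands merged. Islands never cross unassayed (non-ACGT)
sequence.

**Density statistics.** Feature counts per non-overlapping 1 Mb window,
summarized by mean, standard deviation (n−1) and sample skewness
g1 = m3/m2^(3/2); per-Mb-assayed density N/(total − missing); Spearman rank
correlations between chromosome-level summaries. A reference per-chromosome
summary table for Takai–Jones islands on the GRCh37 human assembly ships
with the package.

**Two-point correlation.** The Landy–Szalay estimator

    ξ(r) = (DD − 2·DR + RR) / RR

per logarithmic separation bin (default 15 bins, 1 kb – 249 Mb), where DD,
DR, RR are normalized data–data, data–random and random–random pair counts
and the random catalog (M = 10 N points, lengths resampled from the data,
non-overlapping, mask-avoiding) carries the survey geometry so chromosome
ends and gaps do not bias the estimate. Errors come from 250 bootstrap
resamples of the features, cross-checked against the Poisson approximation
σ(r) = (1+ξ)/√DD_raw.

**Power-law clustering metric.** Over the separations that show signal
(from the smallest bin up to the first bin consistent with random), the
model 1+ξ(r) = A·r^β is fitted by weighted least squares in log–log space,
with a traditional and an error-weighted χ² goodness of fit and a 99%
Monte-Carlo confidence band (10 000 refitted Gaussian realizations; band
edges at sorted realizations 50 and 9 950).

**Synthetic data.** Everything is testable without external downloads:
homogeneous Poisson feature placement on masked supports (the null model),
a 1-D Thomas cluster process with the closed-form
ξ(r) = exp(−r²/4σ²)/(2σ√π·λp) as an analytic oracle, and a genome
synthesizer that plants CpG-rich islands and N-gaps on a CpG-depleted
background.

## Worked example

```python
import numpy as np
from chromocorr import (MaskSet, ThomasParams, simulate_thomas, compute_tpcf,
                        select_fit_bins, fit_powerlaw)

L = 100_000_000
params = ThomasParams(parent_rate=4e-6, mean_offspring=5,
                      sigma_disp=10_000, domain_length=L)
features = simulate_thomas(params, np.random.default_rng(1))
est = compute_tpcf(features, MaskSet("chr", (), L), seed=2)
fb = select_fit_bins(est)
fit = fit_powerlaw(est, fb)
print(f"beta = {fit.index:.4g} +- {fit.index_err:.2g}")
```

The same pipeline is packaged as `scripts/acceptance.py`; running

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

prints

```
[detect] planted 20 islands, detected 20, recovered 20 within +-200 bp; mask 2000 bp
[stats] density per 10 kb window: mean 0.95, sd 0.22, skewness -4.25
[tpcf] N = 2086, fitted bins [0, 1, 2, 3, 4, 5]
[fit] 1+xi = A r^beta with A = 983.2 +- 1.7e+02, beta = -0.5823 +- 0.018
[fit] chi2_nu = 37.7, traditional chi2 p = 0.57, 99% band on beta: (-0.6177, -0.5465)
```

Reading the output: all 20 planted islands are recovered with their
boundaries within ±200 bp; the Thomas process (2 086 clustered points on a
100 Mb domain) yields a strongly negative clustering index β ≈ −0.58 — the
excess probability of finding two features together decays with separation —
and the large error-weighted χ²_ν honestly reports that a pure power law
only approximates the Gaussian-shaped cluster correlation. The script
re-runs the whole pipeline from scratch under the given seed and writes its
JSON summary to `--out`.

## Command line

```
chromocorr mask <fasta> -o mask.bed
chromocorr detect <fasta> [--window 200 --min-gc 0.55 --min-oe 0.65
                           --min-len 500 --merge-gap 100] -o cgi.bed
chromocorr stats cgi.bed --mask mask.bed --chrom-length L -o stats.tsv
chromocorr tpcf cgi.bed --mask mask.bed --chrom-length L --seed S -o tpcf.tsv
chromocorr fit tpcf.tsv --seed S -o fit.tsv
chromocorr simulate {poisson|thomas|genome} --seed S -o out
```

## Genome-wide runs

Full-scale per-chromosome analysis of the human reference requires
downloading GRCh37 (~900 MB) and hours of CPU; it is provided by the
documented, optional `scripts/genome_wide.py` and is deliberately outside
the test suite. The suite instead validates every stage against synthetic
data with known structure and against brute-force oracles.

See `docs/methods.md` for the statistical model, its assumptions, parameter
choices and known limitations.
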