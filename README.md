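# paleodog

Analysis toolkit for ancient-canid paleogenomics: damage-aware genotype
calling, f-statistic admixture inference, coalescent divergence dating from
derived-allele sharing, read-depth copy-number estimation, and
divergence-based tree and haplotype analyses — with a synthetic-data module
that generates every input the chain needs.

## The scientific problem

Ancient dog genomes (typically ~9× coverage, 60–70 bp fragments) carry
post-mortem cytosine deamination: C→T mismatches concentrated at 5′ read ends
and G→A at 3′ ends. Left unmodelled, this damage creates false heterozygous
calls, inflates private variation, and biases divergence-time estimates.
This package implements the analysis chain used to place Neolithic-age dog
genomes against modern village dogs and wolves:

1. **Damage modelling** (`damagefit`). Misincorporation proportions are
   tabulated by read position and fitted with a Weibull-type decay
   `d(x) = a·exp(−(x^c)·b)`, where `x` is the 1-based position from the read
   end (`c = 1` recovers exponential decay).

2. **Damage-aware calling** (`damcall`). Per-read likelihoods compose damage
   before sequencing error, `P(o|g) = Σ_b P_err(o|b; ε)·P_dam(b|g; x, strand)`,
   over the 10 diploid genotypes. Fixed calling rules: reads with mapping or
   base quality < 15 are dropped, base qualities are capped at 40, sites
   under 7× effective coverage are reported missing, and a best heterozygote
   with Phred genotype quality < 30 is demoted to the best homozygote.

3. **f-statistics** (`fstats`). Patterson estimators (f2, f3, f4, D),
   f4-ratio admixture proportions, weighted block-jackknife standard errors,
   and expected-f evaluation/fitting on user-specified admixture graphs with
   |Z| ≥ 3 outlier reporting.

4. **Divergence dating** (`dating`). The ratio of derived alleles shared
   exclusively by the ancient sample and European dogs to those shared
   exclusively by European and Indian dogs, `R = n_anc,eur / n_eur,ind`, has
   a closed-form coalescent expectation under the model
   (((Ancient, Europe), India), Asia) with an Asian admixture pulse (α) into
   the ancient lineage, conditioned on mutation-scaled sizes θ₁, θ₂ and
   split times P₀ ≤ τ₁ ≤ P₂ ≤ P₃. The expectation is strictly decreasing in
   the ancient–European divergence τ₁, so the observed ratio inverts to a
   divergence time by bisection. The sample's age then bounds the mutation
   rate (μ ≤ g·τ₁/age) and calibrates times into years (years = g·τ/μ).
   Pseudo-haploidization (one random chromosome per population) and
   restriction to sites variable among modern samples make the estimate
   robust to residual damage in the ancient genome.

5. **Copy number** (`cnvdepth`). Per-position read depth is loess-corrected
   for GC inside copy-number-neutral control regions, averaged in 3 kb
   windows, and converted to copy number against the diploid control
   baseline — the approach used to type the pancreatic amylase (*AMY2B*)
   expansion.

6. **Trees and loci** (`loci_trees`). Pairwise sequence-divergence matrices,
   Saitou–Nei neighbour joining with 5 cM-window bootstrap support, and
   dog/wolf/heterozygous-like classification of candidate-locus haplotypes by
   centroid distance after a minor-allele-frequency filter.

All demographic quantities are mutation-scaled (τ in expected mutations per
site, θ = 4Nμ, pairwise coalescence rate 2/θ); calendar years enter only
through the calibration step.

## Worked example: dating an ancient–European divergence

```python
from paleodog.dating import (CoalParams, simulate_dating_panel, haploidize,
                             count_sharing_patterns, sharing_ratio, solve_tau1,
                             mu_upper, calibrate_time, DATING_POPS)

params = CoalParams(theta1=1e-4, theta2=1e-4, p0=1e-5, p2=2e-5, p3=3e-5,
                    alpha=0.2, tau1=1.5e-5)
panel = simulate_dating_panel(params, 200_000, seed=42)
hap = haploidize(panel, list(DATING_POPS), seed=42)
counts = count_sharing_patterns(hap)
r = sharing_ratio(counts)
est = solve_tau1(r, params)
print(counts.total_anc_eur, counts.total_eur_ind, r.r, est.tau1)
```

prints (seed 42):

```
exclusive sharing: ANC+EUR=7996  EUR+IND=7030
ratio R = 1.1374  (95% CI 1.0955-1.1793, 400 blocks)
tau1 = 1.533e-05  (CI 1.467e-05-1.601e-05)  true 1.5e-05
mu upper bound (age 7000 y, g=3): 6.57e-09 per generation
calibrated divergence at mu=4e-9: 11500 years
```

The ancient sample shares ~14% more derived alleles with European than
Indian dogs share with each other; inverting the coalescent expectation
recovers the true simulated divergence (1.5×10⁻⁵ mutations/site) inside the
jackknife interval, and a 7,000-year sample age caps the per-generation
mutation rate at 6.6×10⁻⁹. With the ancient-calibrated rate μ = 4×10⁻⁹ the
divergence converts to ~11,500 years.

A command-line interface mirrors the library
(`paleodog simulate|damage|call|fstats|date|cnv|loci|study`); e.g.

```
paleodog date calibrate --tau 0.5247e-4 --mu 4e-9 --generation-years 3
years=39352.5
```

converts a mutation-scaled dog–wolf divergence into calendar years, and
`paleodog study --seed 1 --out report.json` runs the full synthetic
end-to-end study.

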