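# recland

Inference and cross-population comparison of recombination landscapes in
structured plant genomes, built around the analysis design used for bread
wheat (*Triticum aestivum*): a Bayesian meiotic map from a biparental RIL
population, LD-based recombination profiles for several diverging
populations, colocalization testing of highly recombining intervals, and
statistics linking profile similarity to genetic differentiation.

It is aimed at quantitative/population geneticists who have (i) RIL
genotype matrices, (ii) per-interval posterior samples of LD-based
recombination parameters from an external sampler, and (iii) population
genotype panels, and who want tested, seedable implementations of the
estimators connecting them — plus generators that produce every input
synthetically with known ground truth.

## The models

**Meiotic map (RILs).** Crossovers are parental allele switches along each
line. A switch flanked by missing calls is assigned to a candidate marker
interval with probability proportional to interval length, replicated
1,000 times. Counts y_i are Poisson(C_i · L_i · M); a per-region
empirical-Bayes Gamma(α_r, β_r) prior (fitted by ML to the frequentist
rates y_i/(M·L_i)) gives the conjugate posterior

    C_i | y_i ~ Gamma(y_i + α_r,  M·L_i + β_r),

whose mean is converted to cM/Mb through the selfed-RIL
Haldane–Waddington inversion r = R/(2(1−R)) and the Morgan map
(cM = 100 r).

**LD profiles and HRIs.** Per interval i, an intensity λ_i relates the
LD-based rate to its window background: ρ_i = λ_i · ρ_w(i). Intervals
with median posterior λ ≥ 4 are highly recombining intervals (HRIs),
merged when adjacent and size-filtered. Profiles from different
populations are harmonized on the union of interval breakpoints.

**Colocalization.** HRIs of different populations that mutually overlap
form cliques; each clique's smallest common span is a hot window with a
sharing level 1–4. Chance sharing is assessed by re-assigning HRIs to
random intervals within their genomic region (1AR1 … in region
nomenclature) and recomputing sharing, with an exceedance p-value.

**Divergence.** Per region, log10 λ medians of the four populations are
fitted as MVN(μ·1, Σ) with Σ unstructured or equicorrelated, compared by
BIC; map divergence is a Gini coefficient of one population's genetic
distances along another's map; differentiation is multi-allelic
Weir–Cockerham F_ST; and OLS of pairwise correlation on pairwise F_ST
estimates how fast profile similarity decays with divergence.

## Worked example

Simulate a RIL population on a 2 × 100 Mb five-region genome, build the
Bayesian map, and check it against the generating truth:

```python
import numpy as np
from recland import synthetic_data as sd, ril_meiotic_map as rm

scheme   = sd.default_region_scheme()            # R1 R2a C R2b R3 per chromosome
true_map = sd.simulate_true_map(scheme, seed=11)
geno, truth = sd.simulate_ril_population(true_map, scheme,
                                         n_markers_per_chrom=2500,
                                         n_ril=400, seed=1)
map_df = rm.build_meiotic_map(geno, scheme, n_rep=1000, seed=2)

w_est  = rm.aggregate_map_windows(map_df, 4_000_000)
w_true = rm.aggregate_map_windows(
    truth.rename(columns={"true_cM_per_Mb": "cM_per_Mb"}), 4_000_000)
for reg in ("R1", "R3"):
    lab = [scheme.assign(c, int(s)) == reg
           for c, s in zip(w_est["chrom"], w_est["start"])]
    sel = np.array(lab) & w_est["value"].notna() & w_true["value"].notna()
    r = np.corrcoef(w_est["value"][sel], w_true["value"][sel])[0, 1]
    print(reg, "pearson", round(r, 3))
```

prints

```
R1 pearson 0.99
R3 pearson 0.973
```

i.e. with 400 lines the 4-Mb posterior-mean map tracks the true
telomeric-region rates at r ≈ 0.97–0.99; pericentromeres, with ten-fold
fewer crossovers, track more weakly, and the centromere is shrunk to the
pooled low-recombination prior. The same synthetic bundle feeds the other
stages (`sd.simulate_lambda_profiles` → `ld_profiles.call_hris` →
`colocalization.permutation_null`; `sd.simulate_coupled_experiment` →
`divergence.fst_correlation_regression`).

A CLI mirrors the main steps for shell use:

```sh
recland simulate ril --seed 1 --out sim/
recland ril-map --genotypes sim/ril_genotypes.tsv --regions sim/regions.bed \
                --n-rep 1000 --seed 2 --out map.tsv
```

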