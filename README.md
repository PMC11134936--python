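# nestniche

Tools for quantifying **diet convergence between social-insect hosts and the
symbiotic animals living in their nests**, built around two data types:

1. **Stable-isotope profiles** (δ¹³C, δ¹⁵N in ‰) of ants and ant-associated
   silverfish sampled per colony ("nest"). δ¹⁵N tracks trophic position,
   δ¹³C the basal resource, so a population occupies a region of the C–N
   biplot — its *isotopic niche*.
2. **16S rRNA zOTU amplicon tables** of the same insects, sequenced with a
   known plasmid spike-in (~1000 copies per reaction) and extraction/PCR
   blanks, allowing absolute quantification and blank-based decontamination.

The package is aimed at trophic ecologists and microbiome researchers who
need nest-level convergence statistics that generic community-ecology
toolboxes do not provide in one place.

## What it computes

**Isotope arm** (`nestniche.isotopes`)

- Nest-specific centroids and *unweighted* species summaries (each nest
  contributes equally, SEs over nest means).
- The within/between-nest distance-ratio statistic: for nest *j* with focal
  (silverfish) centroid **f**ⱼ and host centroid **h**ⱼ,

  ratio(j) = mean₍ₖ≠ⱼ₎ ‖**f**ⱼ − **h**ₖ‖ / ‖**f**ⱼ − **h**ⱼ‖,

  summarised as mean ± SE over nests; ratios ≫ 1 mean the focal group sits
  on its own colony's isotopic position.
- 95% maximum-likelihood bivariate-normal ellipses (centre = mean,
  shape = (n−1) covariance, Mahalanobis radius √χ²₀.₉₅(2)) with pairwise
  overlap computed by polygon intersection, reported as a percentage under
  the `union`, `min` or `first` convention.

**Variance partitioning** (`nestniche.permanova`)

A from-scratch sequential (Type I) PERMANOVA on any distance matrix
(Euclidean, Bray–Curtis, Jaccard): Gower-centred matrix
G = J(−½D∘D)J, per-term SS via nested projectors, pseudo-F, and permutation
p-values (exhaustive over all n! relabellings for small n, seeded sampling
with the +1 convention otherwise), plus Benjamini–Hochberg-corrected
pairwise tests.

**Microbiome arm** (`nestniche.amplicon`)

Spike-in absolute quantification (copies of 16S rRNA per ng template DNA),
the tenfold blank-based decontamination rule, symbiotic designation
(max experimental relative abundance > 0.001), intracellular-endosymbiont
(Anaplasmataceae) read subtraction, mean-20/low-variance curation,
order-level composition with top-9 folding and nest-lifestyle averaging,
and binary *Weissella* strain profiles for Jaccard-based partitioning.

**Synthetic data** (`nestniche.simulate`) generates isotope panels and
amplicon tables with exactly this structure (nest baselines, taxon offsets,
spike-ins, blank contaminants, nest-shared strain pools), so the whole
pipeline is testable end to end without any download.

## Worked example

```python
import pandas as pd
import nestniche as nn

# a convergent scenario: silverfish share each colony's isotopic baseline
panel = nn.gen_isotope_panel(nn.IsotopeSimConfig(seed=1))

ratio = nn.within_between_ratio(
    panel, {"taxon_group": "silverfish"}, {"taxon_group": "ant"}
)
print(f"distance ratio (between/within): "
      f"{ratio.mean_ratio:.2f} +/- {ratio.se_ratio:.2f} SE over "
      f"{len(ratio.per_nest)} nests")

dm = nn.cn_distance_matrix(panel)
design = pd.DataFrame(
    {"taxon": panel["taxon_group"].to_numpy(),
     "nest": panel["nest_id"].to_numpy()},
    index=panel["sample_id"].to_numpy(),
)
res = nn.permanova_sequential(
    dm, design, ["taxon", "nest", "taxon:nest"], n_permutations=999, seed=1
)
print(res.table.round(3))
```

prints

```
distance ratio (between/within): 9.38 +/- 2.66 SE over 12 nests
             df       SS     R2  pseudo_F  p_perm
term
taxon         1    0.584  0.002     1.579   0.192
nest         11  248.412  0.864    61.066   0.001
taxon:nest   11    2.855  0.010     0.702   0.769
Residual     96   35.502  0.124       NaN     NaN
Total       119  287.353  1.000       NaN     NaN
```

Silverfish sit ~9× closer to their own colony's workers than to workers of
other colonies, and the shared nest explains 86% of the variation in the
C–N biplot while taxon identity explains essentially none — the signature
of diet convergence. The same analyses run from the shell:

```bash
nestniche simulate-isotopes --seed 1 --out panel.csv
nestniche isotope-niche --panel panel.csv --out-dir iso_out --seed 1
nestniche simulate-amplicon --seed 1 --out-dir sim
nestniche microbiome --counts sim/counts.tsv --taxonomy sim/taxonomy.tsv \
    --meta sim/meta.csv --out-dir mb_out --seed 1
```

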