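# coralnet

Tools for quantifying the spatial structure and temporal stability of
host-associated microbiomes — built around the kind of survey in which
tagged coral colonies from several species (nested within genera) are
resampled across reef sites and time points and profiled by 16S OTU tables.
The package answers three questions about such data:

1. **Is the microbiome structured by host, space or time?** Median-of-ratios
   library-size normalization, core-microbiome detection (OTUs present in
   more than a prevalence threshold of a host group's samples), sequential
   (Type-I) PERMANOVA of Bray-Curtis dissimilarity over a nested crossed
   design, pairwise post-hoc tests with sequential-Bonferroni (Holm)
   correction, and SIMPER decomposition of between-group dissimilarity with
   class-level aggregation.
2. **Does community dissimilarity decay with distance?** Per-genus site-pair
   mean Bray-Curtis against great-circle distance, tested by a sequential
   ANCOVA on the log-log scale whose p-values come from Monte-Carlo shuffles
   of the (distance, genus) design.
3. **How strong is phylosymbiosis?** A sample-sample Pearson correlation
   network with homophily/heterophily scores, leading-eigenvector community
   detection, a stratified-shuffle modularity null, chi-square module-factor
   association, majority-vote classification rates, and eigenvector
   centrality as an (inverse) index of host influence.

A fully parameterized synthetic-data generator emulates the survey design
(genus/site/time effects of controllable magnitude, spatially correlated
site effects, planted high-occupancy core OTUs, overdispersed counts), so
every stage is testable without external downloads.

## Core statistics

- **Bray-Curtis dissimilarity** `d(a,b) = Σ_i |x_ai − x_bi| / Σ_i (x_ai + x_bi)`
  on normalized abundances `x = counts / s_j`, with size factors
  `s_j = median_i counts_ji / g_i` (`g_i` the OTU's geometric mean).
- **PERMANOVA** in the McArdle–Anderson form: with `G` the Gower-centered
  matrix of `−½ d²`, each term's sequential sum of squares is
  `SS_k = tr((H_k − H_{k−1}) G)`, `df_k` the realized projector-rank
  increment (so nesting like Species(Genus) and missing design cells come
  out right), `pseudo-F_k = (SS_k/df_k)/(SS_res/df_res)`, `R²_k = SS_k/tr(G)`,
  and `p = (1 + #{F* ≥ F}) / (1 + n_perm)` under free permutation of the
  distance matrix's sample labels.
- **SIMPER** per-OTU contribution
  `δ_i = mean_{(a,b)} |x_ai − x_bi| / Σ_k (x_ak + x_bk)` over cross-group
  sample pairs; the `δ_i` sum exactly to the mean between-group Bray-Curtis.
- **Modularity** `Q = (1/2m) Σ_ij (w_ij − k_i k_j/2m) δ(c_i, c_j)` maximized
  by recursive spectral bisection on the leading eigenvector of the
  (generalized) modularity matrix; **eigenvector centrality** is the leading
  eigenvector of the weight matrix, max-normalized.

## Worked example

```python
import coralnet as cn

cfg = cn.SimulationConfig(seed=42, colonies_per_cell=2, n_otus=120)
counts, metadata, taxonomy, truth = cn.simulate(cfg)
norm = cn.normalize_median_of_ratios(counts, "pseudo-geomean")
dm = cn.bray_curtis(norm)

res = cn.Permanova(dm, metadata, ["Genus", "Site", "Time", "Species(Genus)"]).fit(
    permutations=999, seed=1
)
print(res.summary())
```

```
PERMANOVA (sequential SS, 999 permutations)
Total SS: 46.6970
term                           df  pseudo-F       R2        p    p_adj
----------------------------------------------------------------------
Genus                           2    21.046   0.2244   0.0010
Site                            3     2.008   0.0321   0.0010
Time                            2     1.549   0.0165   0.0100
Species(Genus)                  3     1.123   0.0180   0.2060
Residual                      133   0.7090
```

Host genus explains the largest share of community variation (R² = 0.22 at
p = 0.001, the smallest value attainable with 999 permutations), site and
time much less — the planted ordering of the generator, recovered by the
fitted model. The network view agrees:

```python
r = cn.sample_correlation(norm)
for f in ("genus", "site", "time"):
    h = cn.homophily(r, metadata.factor(f), f)
    print(f"{f:<6} homophily {h.homophily:.4f}   heterophily {h.heterophily:.4f}")

net = cn.CorrelationNetwork.from_table(norm)
part = cn.leading_eigenvector_communities(net)
p_null, q, _ = cn.modularity_null(net, metadata.factor("genus"),
                                  permutations=999, seed=2)
acc = cn.classification_accuracy(part, metadata.factor("genus"),
                                 metadata.levels["genus"])
print(f"{part.n_modules} modules, Q = {q:.3f} (null p = {p_null:.3f}), "
      f"genus classification accuracy = {acc:.2f}")
```

```
genus  homophily 0.2793   heterophily 0.0039
site   homophily 0.1014   heterophily 0.0922
time   homophily 0.0958   heterophily 0.0937
3 modules, Q = 0.516 (null p = 0.000), genus classification accuracy = 0.99
```

Samples from the same genus correlate far more strongly with one another
(0.28) than with other genera (0.004); the detected network modules are
almost pure in genus, and the observed modularity exceeds every one of 999
host-stratified shuffles.

A CLI mirrors the library (`coralnet simulate / normalize / core /
permanova / simper / distance-decay / network / run`); `coralnet run
--config run.yaml` executes the whole pipeline and writes per-stage CSV/JSON
results plus a manifest with seeds and timings.

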