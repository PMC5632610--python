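# oscillate

Comparative-phylogenetic tests of the **oscillation hypothesis** — the
proposal that diversification in plant-feeding insects is driven by repeated
expansions (polyphagy) and contractions (re-specialisation) of host range.
The package is aimed at comparative biologists working with genus-level
phylogenies and compiled host-plant records (the motivating system is the
tussock moths, Erebidae: Lymantriinae, with nymphalid butterflies as the
contrast group), and implements the full analysis chain:

- **Phylogenetic signal of binary host-use traits.** A two-state equal-rates
  Markov (Mk/ER) model with transition probabilities
  `P_switch(t) = (1 − e^(−2qt))/2` is fitted by maximum likelihood
  (Felsenstein pruning, flat root prior); signal is measured inversely by
  the rate q̂, and calibrated by shuffling tip states on the tree:
  `p = #{q̂_perm ≤ q̂_obs}/n_perm` (low rate ⇒ strong signal).
- **Parsimony tracing.** Minimum-change reconstruction of binary polyphagy
  codings ("3+ orders", "7+ orders") with full MPR state sets, and
  squared-change parsimony for host diversity as a continuous character.
- **Sister-clade contrasts.** Pairs of putative sister clades differing by
  at least k host orders (default 3) are built by a deterministic greedy
  post-order sweep; the direction counts feed an exact two-tailed sign test
  and a one-sample t on `log10(R1/R2)` (R = summed species richness,
  side 1 = higher host diversity).
- **Phylogenetic regressions.** PGLS of log10 richness on log10 host
  diversity with Pagel's λ profiled by ML, and the MacroCAIC design:
  Felsenstein contrasts of the trait regressed through the origin against
  richness contrasts `ln(N1/N2)`.
- **Synthetic data.** Pure-birth trees, Mk traits, and full host-record
  universes whose generating values mirror the empirical regime (log-log
  slope 0.77, residual λ 0.70, 46-order host pool, host diversity and
  maximum single-species polyphagy correlated at r² ≈ 0.9), so every stage
  is testable end to end without external data.

## Worked example

The packaged ten-contrast sister-clade table ships with the package; the
first analysis driver recomputes every statistic from it:

```sh
$ python analysis/01_reproduce_contrast_table.py
9 of 10 contrasts have more species on the higher-host-diversity side (two-tailed sign test p = 0.0215).
Mean log10 relative richness = 0.60 (SD 0.48, SE 0.15); t_9 = 3.92, p = 0.0035.
The higher-diversity side holds the most polyphagous species in 10/10 contrasts (sign test p = 0.00195).
```

Nine of ten sister-clade pairs have more species on the side using more
host orders (exact binomial p = 0.0215), the average log richness ratio is
significantly above zero (t₉ = 3.92), and in all ten pairs the
higher-diversity side also contains the single most polyphagous species
(p = 0.00195) — the pattern the oscillation hypothesis predicts.

The same machinery is available programmatically:

```python
import oscillate as osc

tree = osc.parse_newick(open("tree.nwk").read())
records = osc.read_host_records("records.tsv")      # species-level host table
traits = osc.derive_genus_traits(records, richness) # per-genus HD, polyphagy
res = osc.permutation_signal_test(tree, osc.code_binary_trait(traits, 7),
                                  n_perm=1000, seed=42)
cs = osc.build_contrasts(tree, traits, min_hd_diff=3)
fit = osc.pgls_fit(tree, x_log_hd, y_log_richness, lambda_mode="ML")
```

and from the shell via the `oscillate` CLI
(`oscillate {tree,traits,signal,trace,contrasts,pgls,caic,simulate,reproduce,pipeline}`).

The remaining drivers (`analysis/02…05`) run the calibration and recovery
studies: permutation-test type-I error and power, the parsimony traces on a
synthetic universe, PGLS slope/λ recovery, and the richness-contrast
regression's null calibration and power. Each writes its tables under
`results/`.

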