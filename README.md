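# tfannot

Target-gene-based functional annotation of transcription factors (TFs).

Most human TFs have poorly characterized biological functions, yet
genome-wide binding data (ChIP-seq) tells us *which genes* each TF
regulates. `tfannot` turns that observation into function annotations: the
**target functions** of a TF are the functional terms statistically
over-represented among its target genes (TGs). The package implements the
full analysis chain as a tested library with a CLI, exercised end-to-end on
synthetic data with planted structure so every stage has ground truth:

1. **Target calling** (`tfannot.target_calling`) — TIP-style scoring of
   TSS-anchored binding-signal matrices. The TF's characteristic profile is
   the normalized mean binned signal, `w_i = s̄_i / Σ s̄_i`; each gene gets
   the weighted score `g_j = Σ_i w_i s_ji`; scores are standardized to
   z-scores, converted to upper-tail normal p-values and filtered by
   Benjamini–Hochberg (BH) FDR (default 0.01).
2. **Compendium** (`tfannot.compendium`) — the directed TF→TG network
   merged from multiple evidence sources, GMT-serializable, with degree
   statistics and master-regulator detection (no incoming edges from other
   TFs; self-loops don't disqualify).
3. **Enrichment** (`tfannot.enrichment`) — per TF×term 2×2 tests
   conditioned on an explicit gene universe (coding genes for machine
   annotations such as GWAS; the "literature rich" universe — coding genes
   with ≥ 1 curated annotation — for curated sources). Fisher's exact test
   (one- and two-tailed), the G-test `G = 2 Σ O ln(O/E)`, the phi
   coefficient `φ = (n₁₁n₀₀ − n₁₀n₀₁)/√((n₁₀+n₁₁)(n₀₀+n₁₀)(n₀₁+n₁₁)(n₀₀+n₀₁))`,
   odds ratios with Haldane–Anscombe-corrected log₂(OR), and per-source BH
   q-values.
4. **Null model** (`tfannot.null_model`) — fake TFs with matched in-universe
   TG counts resampled uniformly from the universe; pairwise comparison of
   real vs fake p-values estimates the number of true associations
   (n_upper − n_lower) and gives an empirical FDR (n_fake/n_real at a
   cutoff).
5. **Similarity** (`tfannot.similarity`) — TF–TF TG-sharing and
   target-function-sharing networks, function–function regulator sharing,
   and the discordance analysis (do TF pairs that share target functions
   *without* sharing TGs still share known functions?).
6. **Diversity** (`tfannot.diversity`) — uniqueness-weighted effective
   numbers: `u_t = 1/Σ_{t'} φ²_{tt'}`, `π = Σ_t u_t`, so k perfectly
   redundant regulators count as one; plus the regression of function
   diversity on regulator diversity controlling for TG count, and a
   PageRank control.
7. **Simulation** (`tfannot.simulate`) — gene spaces, six-source annotation
   collections, planted TF–term links, Bernoulli TG sampling, and Gaussian
   TSS-peak binding signals, all reproducible from one seed.

## Worked example

```python
from tfannot.simulate import (default_config, generate_gene_space,
                              sample_planted_links, generate_compendium)
from tfannot.enrichment import (build_universe, annotate_tfs,
                                DEFAULT_UNIVERSE_POLICY)

cfg = default_config(seed=1)             # 3,000 genes, 30 TFs, 30 planted links
genes, collections = generate_gene_space(cfg)
links = sample_planted_links(cfg, collections)
comp, truth = generate_compendium(cfg, genes, collections, links)

universes = {
    "coding": build_universe(genes, "coding"),
    "literature_rich": build_universe(
        genes, "literature_rich",
        curated_sources=[c.name for c in collections
                         if c.source_type == "curated"]),
}
records = annotate_tfs(comp, collections, universes,
                       DEFAULT_UNIVERSE_POLICY, fdr=0.05)
hits = records[records.significant & (records.direction == "positive")]
print(f"{len(records)} TF-term tests, {len(hits)} significant at FDR 0.05")
print(hits[["tf_id", "term_id", "n11", "odds_ratio", "p_greater", "q_value"]]
      .nsmallest(3, "q_value").to_string(index=False))
```

prints

```
2490 TF-term tests, 30 significant at FDR 0.05
  tf_id       term_id  n11  odds_ratio    p_greater      q_value
G000013     omim:T001   28   82.567442 1.466230e-30 5.278429e-28
G000022    go_bp:T002   25   97.196970 1.584979e-29 9.509874e-27
G000017 pharmgkb:T011   25   88.186813 3.118831e-29 1.122779e-26
```

All 2,490 TF×term pairs were tested; exactly the 30 planted TF–term links
come out significant (precision and recall 1.0 under this seed). Each row
shows the 2×2 overlap count `n11` (TGs of the TF that are members of the
term within the universe), the odds ratio, the one-tailed Fisher p-value
and the per-source BH q-value.

The same workflow is available from the shell:

```sh
tfannot run-all --seed 1 --out out/        # all seven stages + manifest
tfannot call-targets --signals sig.tsv --fdr 0.01 --out prefix
tfannot annotate --compendium comp.gmt --collections dir/ \
        --gene-table genes.tsv --fdr 0.05 --out assoc.tsv
```

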