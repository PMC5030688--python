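# Methods

## Model and procedure

The method rests on one assumption: across a panel of samples from the same
environment, all genomic material of one organism — its catalog genes and its
16S rRNA gene(s) — shares a single latent abundance trajectory, while
material from different organisms does not (unless the organisms are
ecologically coupled). Matching an OTU to an MGS therefore reduces to finding
the candidate whose abundance profile correlates best with the query's.

The pipeline runs in a fixed order:

1. **Downsampling.** Each sample's shotgun gene counts are reduced to a fixed
   target of mappable reads by a multivariate hypergeometric draw (sampling
   reads without replacement from the finite pool the counts imply). Column
   totals equal the target exactly; the draw is seeded. Sampling without
   replacement, not with, because the operation models picking reads from the
   sample's actual read set. One realization per run; no averaging.
2. **RPKM+TC.** abundance(g, s) = (count/length) / Σ(count/length) per
   sample. The constant "per kilobase, per million" factors of textbook RPKM
   cancel under the total-count renormalization, so they are omitted (a
   property test asserts the equivalence).
3. **Tracer selection.** Within each MGS, genes are ranked by connectivity in
   a co-abundance network: an edge joins two member genes when their Spearman
   correlation (average ranks; computed on the relative-abundance matrix) is
   ≥ 0.7. The mean profile of the top 50 genes is the MGS abundance vector.
   Rank correlation is invariant to the later log transform, so computing the
   network pre-log is consequence-free. Ties in connectivity break
   lexicographically by gene id, making selection deterministic. Genes with a
   constant profile have no defined correlations; they get degree 0, are
   flagged, and are never selected as tracers.
4. **Prevalence filter.** Rows with positive values in ≤ 10 samples are
   removed (strictly-greater-than-10 retained). For OTUs positivity is a
   count property; for MGS rows it is mean tracer abundance > 0.
5. **Log-ratio transform.** Each table is converted per sample to ratios, a
   pseudocount of 1e−17 is added on the ratio scale, and values are
   log10-transformed. Base 10 is chosen so a zero count maps exactly to −17;
   Pearson correlation is invariant to the base (asserted to 1e−12). The
   pseudocount is added after ratio conversion so its meaning does not depend
   on sequencing depth.
6. **Best hits.** Pearson correlation of every query row against every
   candidate row; candidates rank by decreasing r with ties broken by
   ascending id; best and second-best are reported, and a link passes when
   best r ≥ 0.65 (inclusive). Undefined correlations (constant profiles) are
   excluded from ranking rather than treated as zero, so a constant row can
   never be a best hit. Both directions are supported: per-OTU best MGS and
   per-MGS best OTU.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `target_depth` | 15,000,000 | mappable reads kept per sample; data-scale, configurable (synthetic runs use 1.5e5) |
| `k_tracers` | 50 | tracer genes averaged per MGS |
| `rho_threshold` | 0.7 | Spearman edge threshold of the gene network (inclusive) |
| `min_prevalence` | 10 | rows must be positive in strictly more samples than this |
| `pseudocount` | 1e−17 | added to per-sample ratios before log10 |
| `cutoff` | 0.65 | Pearson threshold for a passing link (inclusive) |

Validation-side defaults: RDP genus labels need classification confidence
≥ 0.80; an entity with conflicting multi-source genus labels counts as
unannotated; a gene cluster is assigned to an MGS holding ≥ 70% of its genes
(ties at the maximum are ambiguous → unassigned). Genus agreement is
case-insensitive string equality after whitespace stripping; no taxonomy-tree
reconciliation is attempted. Cutoff choice from a calibration curve is
reported, not automated; the provided helper (smallest cutoff reaching an
accuracy floor) is this package's own convenience rule.

## Synthetic communities

`generate_community` draws, per organism, a latent abundance vector
exp(σ·z) with z standard normal per sample (σ = `log_abundance_sigma`,
natural-log units, default 1.5 — organism abundances spread over roughly
±2 decades, a gut-like heavy tail). Confounded pairs and near-relative pairs
share a bivariate-normal z at correlation `rho_conf` / `rho_rel`. Counts are
Poisson with per-sample rates normalized so the expected column total equals
the configured depth: gene rates ∝ organism share × gene length (with
accessory genes gated by an independent per-sample Bernoulli presence
indicator, default fraction 0.10 at prevalence 0.60), OTU rates ∝ organism
share × 16S copy number (copies drawn 1–7, the common bacterial rRNA operon
range). Membership maps every gene — accessory included, deliberately: tracer
selection is supposed to demote them — to the organism's MGS. The answer key
(`truth_links`) pairs every OTU with its organism's MGS.

What the generator does **not** emulate: sequence content (no reads, no
alignment errors, no chimeras), overdispersion beyond Poisson (an
overdispersed count model is a known gap; real metagenomes are noisier),
compositional coupling beyond the shared denominator, strain-level variation,
and PCR primer bias beyond per-OTU copy number. Passing tests therefore show
the statistical machinery is correct under the model's assumptions, not that
real-data linkage rates will match.

## Numerical choices and degenerate inputs

- Correlations of constant vectors are undefined (`None`/NaN), never 0, and
  are excluded from both network edges and hit ranking.
- All-zero sample columns: RPKM+TC returns them as zeros and reports them;
  the log-ratio transform refuses them (the caller must drop the sample).
- Downsampling of samples below the target is a policy switch
  (`error`/`keep`/`drop`), since shallow samples are a data decision, not a
  method one.
- Every stochastic step takes an explicit seed; identical configuration and
  seed reproduce byte-identical outputs end to end.
- Tie-breaks (tracer selection, best hits) are lexicographic by id.

## Known limitations

The log-ratio transform's zero sentinel is a two-edged sword. When profiles
are mostly zero, the sentinel effectively binarizes them and correlation
measures co-occurrence — the regime sparse real OTU tables live in. But when
an OTU is detected in almost every sample, a *rare* zero becomes a single
extreme leverage point (−17 against a signal band a few log-units wide) that
can drag an otherwise near-perfect Pearson correlation below the cutoff. On
synthetic communities at moderate depths this caps recall around 0.75–0.80
even when the MGS profile is replaced by the noise-free true abundance, while
precision stays at 1.0: the attenuation costs sensitivity, never accuracy.
Users wanting higher sensitivity should inspect the full calibration curve
rather than relying on the single default cutoff.

Problem sizes in the test suite and acceptance script (tens of organisms,
60–120 samples, depths 10⁴–10⁵, 10 replicate seeds) are chosen to make the
statistical checks well-powered while keeping a full run interactive on one
CPU.
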