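# umifit

Clone-resolved fitness inference for pooled CRISPR screens that co-deliver a
degenerate UMI barcode with each sgRNA.

## The problem

In transplantable tumour models (e.g. patient-derived xenografts), only a
minority of transplanted cells found clones, and the clones that do engraft
have wildly uneven sizes — spanning 3–4 orders of magnitude.  Conventional
pooled-screen analysis, which compares bulk sgRNA read counts, conflates a
guide that founded many small clones with a guide that founded one enormous
clone.  Tagging each transduced founder cell with a random UMI (a 27-nt
degenerate barcode, `NNATCNNGATSSAAANNGGTNNAACNN`, >4×10⁶ variants) makes
individual clones countable: each (sgRNA, UMI) pair is a clone and its read
count is the clone size.

`umifit` implements the full quantitative chain for such screens:

1. **Extraction** — paired amplicon FASTQ → clone table: mean-phred ≥ 30
   filter, anchored sgRNA matching (20-nt window 24–43 nt downstream of the
   vector anchor, ≤1 mismatch), anchored UMI matching against the degenerate
   template, downsampling to 2×10⁶ reads, and directional merging of
   sequencing-error UMIs (collapse pairs at Hamming distance 1 when the
   larger count nₐ satisfies nₐ > 2n_b − 1).
2. **Diversity** — clones per million reads, Shannon diversity index
   (−Σ pᵢ ln pᵢ) and the Lorenz-curve area, each on a seeded exact
   per-million subsample.
3. **Fitness** — a hierarchical Bayesian model of clone counts and clone
   sizes.  Clone counts are Poisson, K_t ~ Poisson(c·π_t·ε_t) with plug-in
   library proportions π_t = I_t/ΣI from the plasmid counts; clone sizes
   follow a zero-truncated count family (default: a two-component
   negative-binomial mixture) scaled per guide by φ_t.  The fitness of guide
   t at each posterior draw is f_t = ε_t·W_t, the engraftment factor times
   the winsorized mean of the fitted size distribution (top 2% revalued to
   the 98th centile), i.e. the relative expected cellular output per
   transduced cell with outlying clones tempered.  Replicate transplants can
   be fitted jointly with shared guide-level parameters.
4. **Checking and comparison** — posterior-predictive goodness-of-fit
   (fraction of guides whose observed mean clone size falls in the 90%
   interval; ≈90% indicates a good fit), stepping-stone marginal likelihoods,
   a frequentist delta-method comparator, normalization (70th centile of
   targeting-guide medians set to 1), Benjamini–Hochberg neutrality calls,
   four-criterion outlier detection between screens, and Hasse-diagram
   resolution of the fitness partial order (pairs with non-overlapping 95%
   intervals).
5. **Simulation** — a synthetic-screen generator (skewed library,
   engraftment bottleneck, heavy-tailed sizes, UMI errors, optional FASTQ)
   with ground-truth fitness, used throughout the test suite.

## Worked example

```python
import umifit as u

# a 192-guide signaling-style library: 56 genes x 3 guides + 24 controls
lib = u.make_fixture("signaling")

# simulate one transplant where the first four genes double both clone
# number and clone size (true fitness ~4x neutral)
eps = {g.guide_id: 2.0 for g in lib.guides if g.gene in ("gene001", "gene002")}
cfg = u.SimulationConfig(library=lib, seed=1, clones_per_guide=200,
                         eps_star=eps, phi_star=eps)
sim = u.simulate_screen(cfg)

post = u.fit_fitness_model(sim.dataset,
                           u.ModelSpec(chains=2, warmup=600, draws=400, seed=2))
print(round(u.gof_coverage(sim.dataset, post), 1))   # 98.4
norm = u.normalize_fitness(post, lib)
calls = u.call_nonneutral(norm)
hits = calls[calls.nonneutral]
print(len(hits))                                     # 6
print(sorted({g.rsplit("_", 1)[0] for g in hits.guide_id}))
# ['gene001', 'gene002']
print(hits["median"].round(2).tolist())
# [2.76, 3.03, 2.55, 2.09, 2.9, 2.58]
```

The neutrality caller recovers exactly the six guides of the two perturbed
genes at FDR < 0.05 and nothing else.  Their normalized posterior medians
(2.1–3.0) sit below the generative 4x because the hierarchical prior,
having seen 186 neutral guides, shrinks sparse strong effects toward
neutrality — the calls, not the point estimates, are the robust readout at
this clone depth.  The GOF value (98.4%) says the mixture likelihood
reproduces every guide's observed mean clone size within its 90% predictive
interval.

The same pipeline is scriptable from the shell:

```bash
umifit simulate --library signaling --seed 1 --fastq --out-prefix run
umifit extract  --fastq1 run.R1.fastq --fastq2 run.R2.fastq \
                --library run.library.tsv --seed 2 --out run.clones.merged.tsv
umifit fit      --clones run.clones.merged.tsv --initial run.initial.tsv \
                --library run.library.tsv --model mix_nb --seed 3 --out run.fit.tsv
umifit poset    --summary run.fit.tsv --out run.poset.dot
```

Every command writes a `.manifest.json` (seeds, input checksums, stage
counters) sufficient to re-run it bit-identically.

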