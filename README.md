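# pathprofiler

Inferring the predominant signalling and metabolic pathways of a cell from a
*limited* proteomic sample — a single 2-DE gel replicate per condition — by
propagating the overall pattern of differential protein expression through
prior pathway knowledge, rather than testing each protein individually.

`pathprofiler` implements that inference chain as a reusable, tested Python
pipeline:

1. **quantify** — spot volumes are normalized to each gel's total spot volume,
   fold changes are computed symmetrically (`max/min` with a direction flag),
   and inclusive "at least *X*-fold" filters pick spots (1.1-fold) and select
   the analysis set (1.5-fold).
2. **pmf** — peptide-mass-fingerprint identification: batch removal of
   background peaks seen in >10% of spectra, in-silico tryptic digestion
   (Keil rule, one missed cleavage, fixed Cys carbamidomethylation, variable
   Met oxidation), 50 ppm monoisotopic [M+H]+ matching, three independent
   scoring schemes (shared peaks, sequence coverage, rarity-weighted peaks),
   a "ranked high in ≥2 of 3" consensus rule, and an M<sub>r</sub>/p*I*
   gel-coordinate plausibility check.
3. **enrichment** — per-pathway 2×2 contingency tables (*k* focus proteins
   among *n* pathway members, *K* focus in a universe of *N*), right-tailed
   Fisher's exact test p = Σ<sub>x≥k</sub> C(K,x)·C(N−K,n−x)/C(N,n),
   Benjamini–Hochberg correction, and the coverage ratio *k/n*.
4. **network** — greedy growth of connected focus-protein subnetworks on a
   curated interaction graph, scored as −log₁₀ of the hypergeometric
   probability of the observed focus concentration; score ≥ 6 (p < 10⁻⁶)
   flags a significant network, and degree-≤1 "hanging" nodes are reported.
5. **bayes** — the differential-expression coefficient *R* of the blot model
   log₁₀(X_A) = R + log₁₀(X_B) is estimated by random-walk Metropolis on
   (R, log σ) with flat priors, burn-in proposal adaptation to a 0.4
   acceptance fraction, the Gelman–Rubin PSRF across three chains, and a
   posterior summary (mean, credible interval, P(R ≤ 0), fold = 10^R).
6. **synthetic** — a first-class generator that emulates every input with
   planted ground truth (fold changes, spectrum identities, an enriched
   pathway, a dense focus community, a known *R*), so the whole chain is
   testable without any external data.

## Worked example

```bash
pathprofiler demo --outdir demo_out --seed 0
```

generates a synthetic study (100 proteins, 200 matched spots of which 20
carry a 2-fold change at 10% volume CV, spectra at 60% peptide detection and
15 ppm jitter, a 15-pathway knowledgebase with one planted enriched pathway,
six densitometry replicates at R = 0.146) and runs the full chain. The run
report (abridged) from that exact command:

```
"n_spots": 200,        # matched spots quantified
"n_picked": 77,        # spots changed >= 1.1-fold
"n_identified": 66,    # consensus PMF identifications among picked spots
"n_analysis": 20,      # identified spots changed >= 1.5-fold
"n_focus": 20,         # focus proteins uploaded to enrichment/networks
"top_pathways": [{"pathway_id": "PW001", "p_bh": 0.000122, ...}]
"ratio_posterior": {"mean": 0.109, "fold": 1.287, "psrf": 1.0006,
                    "acceptance": 0.439, ...}
```

Reading it: the 1.5-fold analysis set recovers exactly the 20 planted
differential proteins; the planted pathway PW001 ranks first with a
BH-corrected p ≈ 1.2×10⁻⁴; and the posterior mean of *R* (0.109, i.e. a
1.29-fold change) sits within 0.05 of the generating value 0.146 with
converged chains (PSRF ≈ 1.00) and the Metropolis acceptance tuned to ~0.4.

The same stages are available as library calls (`pathprofiler.run_pipeline`
with a `PipelineConfig`, or the per-module functions) and as subcommands
(`pathprofiler run -c config.yaml`, `pathprofiler filter-background`,
`pathprofiler search`, `pathprofiler bayes-ratio`).

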