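# Methods

This note documents the models, defaults and numerical choices behind each
stage, what the synthetic generator does and does not emulate, and the known
limitations.

## Quantification

Normalized spot volume is `raw / Σ raw` within each gel, so the per-gel
normalized volumes sum to 1 and the result is invariant to rescaling either
gel's overall staining intensity. Fold change is symmetric,
`max(norm_A, norm_B) / min(norm_A, norm_B) ≥ 1`, with a separate direction
flag (`up_in_A` / `up_in_B` / `unchanged`); this avoids sub-unity ratios and
makes thresholds one-sided. Both filters are **inclusive** ("at least
X-fold" means ≥ X): picking at 1.1-fold, analysis at 1.5-fold. Spots present
in only one gel are excluded with a warning rather than imputed. Expression
matrices are handled in log10 throughout: centering subtracts each probe's
row mean (idempotent by construction), and the fold-difference between two
lines is the difference of their log10 abundances.

## PMF identification

- **Digestion.** Trypsin under the Keil rule (cleave after K/R unless the
  next residue is P), products enumerated for 0..`missed_cleavages` internal
  missed sites (default 1), duplicates retained.
- **Masses.** Monoisotopic residue masses (5-decimal IUPAC table embedded as
  constants), water 18.010565, proton 1.007276; [M+H]+ singly charged.
  Fixed Cys modification defaults to carbamidomethyl (+57.02146), the
  product of the iodoacetamide alkylation used in standard 2-DE sample
  preparation; carboxymethyl (+58.00548) is selectable in `SearchConfig`
  for iodoacetic-acid workflows. Variable Met oxidation (+15.9949) expands
  each peptide to one mass per oxidation count.
- **Matching.** A peak matches a theoretical mass when
  |obs − theo|/theo·10⁶ ≤ 50 ppm (inclusive); each observed peak matches at
  most one theoretical mass, nearest ppm first, ties to the lower m/z.
- **Background filter.** All peaks of a batch are clustered on m/z by
  single-linkage with a 100 ppm gap threshold (twice the typical jitter, as
  no instrument-specific binning rule exists); any cluster observed in
  strictly more than 10% of the lists is deleted from every list. Batches
  smaller than 10 lists are refused: with few lists every peak trivially
  exceeds any occurrence fraction and the filter would destroy data.
- **Scoring.** Three independent schemes replace the commercial engines,
  whose algorithms are proprietary: (1) shared-peak count, (2) percent
  sequence coverage, (3) Σ over matched peptides of −log₁₀ (fraction of all
  database peptide masses in that peptide's 100 Da mass bin), which rewards
  matches in sparsely populated mass regions. Ranks are dense per scorer
  (equal scores share a rank); `consensus` requires rank ≤ R_top in at
  least two schemes, with R_top = 5 as the operational meaning of "ranked
  high" (exposed in config, since no published definition exists). The best
  consensus candidate per spectrum minimizes the rank sum, ties by
  accession.
- **Mr/pI check.** Theoretical Mr is the monoisotopic chain mass; pI is the
  unique root of the strictly decreasing Henderson–Hasselbalch net-charge
  function (termini plus D, E, C, Y, H, K, R; Bjellqvist pKa table),
  located by bisection on pH 0–14 to 1e-6. The plausibility bands — 20%
  relative on Mr, 1.0 unit on pI — are deliberately loose, matching the
  qualitative use of gel coordinates as supporting evidence only.

## Enrichment

The universe N defaults to the union of all pathway members (every protein
with at least one annotation); an explicit background list can be supplied
instead, since knowledgebases differ in whether they count all catalogued
molecules or only annotated ones. Focus proteins outside the universe are
dropped (with a warning) and reduce K. The right-tail p-value is evaluated
with scipy's log-space hypergeometric survival function and clamped to
(0, 1]; the test suite verifies it against exact rational enumeration on
every admissible table with N ≤ 30. BH adjustment is the standard step-up
with capping, returned in input order. The significance flag is strict
(p_bh < α, default α = 0.05), so a pathway at p = 1 is never flagged even
at α = 1. The reported ratio is k/n (pathway coverage), not k/K.

## Network inference

The published description of commercial network generation specifies only
the objective — connect as many focus proteins as possible, adding non-focus
connectors only as connectivity requires — and the score semantics. The
growth algorithm here is therefore a *defined* greedy surrogate with
deterministic tie-breaks: seed at the focus node with most focus neighbors
(ties by accession), then repeatedly add the frontier node that newly
connects the most focus nodes (itself if focus, plus adjacent unreached
focus), then by degree into the current set, then by accession; when no
frontier node touches new focus but unreached focus remains in the
component, the walk steers along shortest paths toward the nearest one.
Growth stops at `max_size` (default 35, a typical curated-network size) or
when every reachable focus node is included. On connected graphs with a
non-binding cap this provably attains the maximum focus count of any
same-size connected subgraph (the suite checks this exhaustively on graphs
of ≤ 12 nodes); on disconnected graphs the seed choice is a heuristic and
can in principle prefer a locally dense component.

The score is −log₁₀ of the right-tail hypergeometric probability of drawing
at least the observed number of focus nodes in a uniform node sample of the
network's size from the whole graph — an explicit model choice, reusing the
enrichment test. Score ≥ 6 (p < 10⁻⁶) is the significance convention.
Successive networks are emitted by retiring each network's focus nodes and
regrowing until the focus set is exhausted; BH adjustment is applied across
the emitted networks' p-values. Hanging nodes are those with degree ≤ 1
inside the network — swept in through a single interaction without forming
a loop.

## Bayesian ratio estimation

Replicate band densities are normalized to the loading control lane-wise;
the model for the log ratios y_i = log₁₀(x_A,i) − log₁₀(x_B,i) is
y_i ~ Normal(R, σ²). The published description names the mean model but not
the likelihood or prior; the defaults here are the minimal consistent
choice: Gaussian likelihood on the log scale, flat priors on R and log σ
(σ is sampled, not fixed, with a floor of 1e-6 to keep degenerate
zero-variance data finite). The sampler is random-walk Metropolis on
(R, log σ) with a zero-mean Gaussian proposal; during burn-in the proposal
scale is multiplied or divided by 1.1 after each 100-iteration block
according to whether the block's acceptance exceeded or fell short of the
0.4 target, and it is frozen afterwards so the retained chain is Markovian.
Three chains start overdispersed at the sample mean and mean ± 2 sample
standard deviations. Convergence is the Gelman–Rubin PSRF
(√(((n−1)/n·W + B/n)/W); identical chains give √((n−1)/n), zero
within-chain variance with separated chains reports +∞); summaries refuse
to pool unless PSRF < 1.1. The posterior summary pools the post-burn-in
tails of all chains: mean, median, equal-tail credible interval, the tail
probability P(R ≤ 0) as the significance measure for an up-in-A claim
(bounded by 1/pooled-n when no sample crosses zero), and the fold estimate
10^R. Default run length is 15000 iterations with 5000 burn-in per chain,
which converges in well under a second on this two-parameter posterior;
the coverage check in the suite uses 2000/800 per chain across 100 seeded
repeats, which is sufficient for a stable equal-tail interval on a
unimodal two-parameter posterior.

## Synthetic data: what it emulates, and what it does not

Each generator draws from an independent stream derived from one global
seed (`default_rng([stream_index, seed])` with fixed stream indices), so
datasets are reproducible byte-for-byte and modules can be regenerated
independently.

- **Protein database:** random sequences over the 20 standard residues with
  human-like composition (K+R ≈ 11%, so tryptic peptides have realistic
  lengths), rejection-sampled until each protein yields at least one
  in-window peptide. Real databases have homology, families and shared
  peptides, which random sequences lack almost entirely — identification
  here is therefore somewhat easier than against a real proteome.
- **Spot tables:** differential spots get a raw A/B ratio of fold ×
  log-normal noise (σ_ln = √ln(1+cv²)); directions alternate so both
  conditions carry up-regulated proteins, and whole spots are rescaled to
  equalize gel totals — preserving every ratio — so total-volume
  normalization recovers the planted fold exactly at cv = 0. With a strictly
  one-directional truth the gel totals cannot balance and the recovered
  folds absorb a common normalization factor, as they would on a real gel.
  Default conditions: 200 spots, 10% differential at 2-fold, 10% CV.
- **Peak lists:** Bernoulli(0.6) detection of the unmodified in-window
  digest masses, 15 ppm Gaussian relative jitter, a shared pool of 20
  uniform contaminant masses each present in a list with probability 0.15
  (so the >10% batch rule has a true target). No isotope envelopes,
  adducts, or intensity physics — intensities are uninformative log-normal.
- **Densitometry:** lane-wise log-normal loading and baseline levels with
  the per-replicate normalized log-ratio exactly Normal(true_R, σ²) by
  construction (default R = 0.146 ≈ log₁₀ 1.4, σ = 0.05, 6 replicates).
- **Knowledgebase:** pathways sampled without replacement; one planted
  pathway takes ≥ 80% of its members from the differential proteins, which
  are also wired into a dense interaction community, so enrichment and
  network growth have a recoverable signal. Real knowledgebases have
  scale-free degree structure and overlapping, nested pathways, none of
  which is modelled.

Passing tests on these data show the chain's *inference machinery* is
correct — planted signal in, planted signal out, at the stated noise — not
that any particular biological result would replicate; gel warping, spot
co-migration, PTM-driven spot trains and database incompleteness are all
outside the generator.

## Pipeline defaults

All thresholds default to the study-style settings and are logged at run
time: pick 1.1-fold, analysis 1.5-fold, 50 ppm, 1 missed cleavage,
10% background occurrence, α = 0.05, network cap 35 and score cutoff 6,
MCMC target acceptance 0.4 and PSRF threshold 1.1. The demo completes in a
few seconds at the default synthetic sizes.

## Known limitations

- The three PMF scorers are surrogates; absolute scores are not comparable
  to commercial engine scores, only the ranks and the consensus rule are.
- The greedy network growth is optimal only in the connected, non-binding-
  cap regime; no claim is made for capped or disconnected growth.
- The background filter assumes contaminant masses recur within 100 ppm;
  heavily drifting instruments would need a wider gap threshold.
- P(R ≤ 0) is a posterior tail probability, not a frequentist p-value,
  although it plays the analogous reporting role.
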