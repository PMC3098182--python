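# Methods

## Model

`funmod` treats a collection of genome annotations as a text corpus: each
genome is a document, each annotated gene contributes one token, and the
token's "word" is the gene's functional descriptor (an orthologous-group
identifier such as a COG/NOG term, or any comparable vocabulary). Latent
Dirichlet allocation is fit over this corpus: k topics, each a multinomial
P(w|t) over the vocabulary V with a symmetric Dirichlet(β) prior;
document-specific topic weights P(t|d) with a symmetric Dirichlet(α) prior.
Because functionally coupled gene families co-occur across genomes, a
topic's high-probability terms are interpreted as a candidate functional
module. Topics are global while weights are per-genome, so one module can
generalize over organism-specific variants of a process, and one term can
belong to several modules (soft clustering).

## Inference

Collapsed Gibbs sampling: the multinomial parameters are integrated out and
each token's topic assignment is resampled from

    P(z = t | z_-i, w) ∝ (n_wt^-i + β) / (n_t^-i + |V|β) · (n_td^-i + α)

where n_wt, n_td, n_t are the term-topic, topic-document and topic-total
counts excluding the current token. Choices worth stating explicitly:

* **Scan order** is deterministic — documents in corpus order, tokens in
  document order — so a chain is exactly reproducible from its seed. One
  uniform variate per token per sweep is pre-drawn from a seeded PCG64
  generator; the compiled (numba) and plain NumPy sweep implementations
  consume the same variates and produce bitwise-identical chains.
* **Point estimates from the final sample.** After the fixed number of
  sweeps, φ̂ = (n_wt + β)/(n_t + |V|β) and θ̂ = (n_td + α)/(len(d) + kα)
  are taken from the last state. Averaging φ/θ over a trailing window of
  sweeps is available (`LDAConfig.average_last`) but off by default:
  per-run module sets are the unit of analysis and cross-run tracking
  handles chain-to-chain variation.
* **Fixed iteration count.** The collapsed log joint is logged every
  `log_every` sweeps for monitoring, but never used for early stopping;
  convergence is assessed across runs, not within one.
* Multiple runs are independent fits with seeds `master_seed + run_index`.

Defaults mirror the prokaryotic-genome analysis setting: k = 200, α = 0.5,
β = 0.01, 2,500 sweeps, 9 runs, with every value overridable.

## Preprocessing

Terms present in fewer than `min_doc_freq` genomes (default 10) are removed;
document frequency is presence-based, not token-count-based. Documents
emptied by filtering are kept (their θ row falls back to the uniform prior)
and logged, so document indices stay stable. The vocabulary is fixed in
lexicographic order after filtering, making matrix column indices
reproducible across runs.

## Module extraction and profiling

A PF-module is the set of terms with P(w|t) ≥ C for one topic; C = 0.01 by
default. The comparison is inclusive — exact equality is measure-zero on
real-valued φ, and an inclusive cut avoids floating-point fragility — with a
strict mode available. Topics in which no term reaches C yield no module.

Category profiling reports the modal functional category of a module's terms
and its fraction of the module size l, for modules with l ≥ 7; a term
carrying several categories (COG-style letter strings, e.g. "TN") counts
once per category while the denominator stays l; ties break to the
lexicographically smallest label. Pathway profiling maps terms to KO
identifiers and counts *distinct* member KOs per pathway, reporting pathways
with ≥ 6 hits; both maps may be partial.

## Stability across runs

Topic-term distributions from two runs are compared all-against-all with the
symmetrized Kullback–Leibler divergence. The Jeffreys form
KL(p‖q) + KL(q‖p) (natural log, nats, no ½ factor) is used; any positive
scaling of the divergence yields identical matchings, since only the order
of values matters to the matcher. Matching is **greedy best-first**: the
globally smallest divergence among still-unmatched topic pairs is accepted
repeatedly, with deterministic (row, column) tie-breaking. This is a local
optimum by construction and can be beaten by the optimal assignment; the
optimal (enumeration / Hungarian) solution is used only as a test oracle,
because greedy matching is the method's defined behavior and may
underestimate the true number of stable topics. Chains are composed in the
given run order, run1→run2→…→runN→run1; a run-1 topic is stable iff the
composition returns to it. Stable *modules* are the run-1 modules heading
closed chains.

## Reference network and evaluation

The reference is built from a STRING-style score table (seven evidence
channels per unordered term pair; integer 0–999 scores are normalized by
1000; "cooccurrence" is accepted as an alias of the data dialect's
"cooccurence"). Channels are recombined **excluding the co-occurrence
channel** so the evaluation is independent of the signal the topic model
itself uses, via the prior-corrected noisy-OR

    s_i' = max(0, (s_i − p)/(1 − p)),  S = (1 − Π(1 − s_i'))·(1 − p) + p,

with prior p = 0.063 by default. This combination rule is a reconstruction
of the standard channel-combination procedure; a bypass reads precomputed
combined scores instead. Pairs below 0.15 after recombination are dropped;
pairs with both terms in the model vocabulary and combined score ≥ 0.7
(inclusive) form the reference set U. The pair universe D is all
|V|(|V|−1)/2 vocabulary pairs.

Per module of size l (m = l(l−1)/2 pairs): pairs found in U are verified
pairwise couplings (pwf); an unmatched pair is a verified first-order
transitive coupling (trf) when a third module member has pwf couplings to
both its ends; coverage is the fraction of the module's terms in the largest
connected component of the pwf subgraph, with components counted over
edge-bearing vertices only (an edge-free module has coverage 0 and 0
components — isolated terms are not components). Significance uses the
hypergeometric distribution: P_hit = |U|/|D|, E[h] = m·|U|/|D|, and
P_mult_hit = P(X ≥ h) computed with `scipy.stats.hypergeom` (log-gamma
arithmetic internally; |D| ≈ 5.4×10⁷ at corpus scale overflows naive
binomial coefficients). The co-occurrence baseline takes pairs with
co-occurrence channel score ≥ 0.4 (the lower bound of the medium-confidence
range), and the comparison reports Venn sections over pair sets, distinct
terms per section, and recall against U for both methods.

## Synthetic data

The generator emulates the assumed generative process. A planted model
places k_true member sets of 5–60 terms (disjoint unless an overlap budget
is configured) and gives each module a distribution with ≥ 98% of its mass
near-uniform over members (Dirichlet with concentration 50 within members —
near-uniform rather than exactly uniform so that thresholded extraction is
exercised nontrivially) and a 2% background spread over the rest of V.
Documents draw sparse mixtures (1–3 active modules, mirroring genomes shaped
by one or a few processes) or Dirichlet mixtures; lengths are Poisson. The
matched reference table emits each within-module pair with probability
`tpr` = 0.6 with its signal in the "database" and "neighborhood" channels,
keeps the "cooccurence" channel independent (so the baseline comparison is
meaningful), and adds cross-module false positives at rate `fpr` = 1e-4.

What the generator does **not** emulate: phylogenetic correlation between
genomes (taxonomic bias makes real co-occurrence non-independent across
documents), pseudo-genes and spurious gene copies, and annotation noise that
is systematic rather than random. Passing recovery tests therefore shows
that the inference machinery is correct under the model's own assumptions,
not that real corpora satisfy those assumptions.

Recovery is scored by greedy one-to-one matching of recovered to planted
member sets in descending Jaccard order; the score is the mean Jaccard over
planted modules with unmatched planted sets scoring zero.

## Problem sizes used in tests and the acceptance script

The end-to-end "easy setting" uses a 500-term vocabulary, five planted
modules of 10–20 terms, 300 documents of mean length 200 tokens (the member
probabilities ≈ 1/15 then sit two orders of magnitude above the background
≈ 4×10⁻⁵, straddling C = 0.01), sparse mixtures, fits at k = k_true with
default priors and 500 sweeps. The sampler-correctness check enumerates the
collapsed posterior of a 2-document, 3-term, k = 2 corpus (16 states) and
compares it with 10,000 independently seeded 25-sweep chains.

## Numerical and degenerate-input choices

* φ/θ rows are strictly positive by Dirichlet smoothing; the symmetrized KL
  rejects non-positive entries rather than patching them.
* An empty document keeps a uniform θ row (prior only); a token-free topic
  keeps a uniform φ row.
* k = 1 degenerates gracefully: all assignments are topic 0 and φ is the
  smoothed empirical term-frequency vector.
* Duplicate unordered pairs in score tables keep the maximum score;
  self-pairs are dropped.
* All thresholds (C, 0.15, 0.4, 0.7) are inclusive.

## Known limitations

* Greedy topic matching underestimates the number of stable topics when an
  early low-divergence pair blocks a better global assignment; no correction
  is applied.
* The number of topics k is a user choice; hierarchical/nonparametric model
  selection is out of scope.
* The channel-combination prior (0.063) is a convention, not a fitted value;
  evaluation against a reference built with a different prior shifts |U|.
* Final-sample estimation leaves Monte-Carlo noise in φ near the extraction
  threshold; cross-run stability tracking, not within-run averaging, is the
  intended mitigation.
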