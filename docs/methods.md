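# Methods

## The question and the formalisation

The package operationalises "which speech register better supports
semantic-role learning?" as a probing problem. A *register* is a corpus
label; the learner is a small masked language model trained on that corpus
alone; the probe is a binary classifier that must recover the proto-role
(A = most agent-like, P = most patient-like argument of a bivalent verb)
from one argument representation at a time. Because the probe's training
sets are small (100 items) and verb-disjoint, high accuracy can only come
from cues that generalise across verbs: argument position, case
morphology, lexical identity of the argument, and whatever mixture of
these the contextual embeddings encode.

## The synthetic language

Utterances are single clauses built from a verb frame. Every verb assigns
nominative to its A slot; most verbs assign accusative to P, a minority
dative with an overt adposition (kept inside the argument span). Nouns are
CVC lemmas of fixed length (so paradigm forms of different lemmas can never
collide) in one of two declension classes: an animate-style class marking
all twelve (case × number) cells distinctly, and an inanimate-style class
with nominative/accusative syncretism in both numbers — mirroring the
classic contrast between case-transparent and case-ambiguous noun types.
Verbs agree in number with A. Pronouns include case-distinct forms and one
form that is deliberately ambiguous across case and number. Word order is
drawn per utterance from a distribution over {A,P,V} strings; omitted
arguments simply contribute no symbol, and every utterance keeps at least
one overt argument.

Role-conditional lexical choice uses Zipf-like base weights multiplied by a
per-noun role bias (animates favour A, inanimates P) and sharpened or
flattened by a per-role concentration parameter *c* (weights
*w*<sup>1/c</sup>, computed in log space): entropy is continuous and
non-decreasing in *c*, so a target entropy is found by bisection against
the closed-form entropy of the weights. A register *pair* shares the
lexicon and paradigm; the deltas name what differs. The default pair
differs only in role-conditional entropy, by −0.79 bits (A) and −0.55 bits
(P) on the CDS-like side — the size and direction of the argument-entropy
difference reported between natural child- and adult-directed Russian
speech. Other supported deltas (syncretic-class weighting, word-order
temperature, pronoun and omission rates) default to "no difference".

Defaults that the data do not pin down and that we therefore fixed once:
120 nouns and 12 verbs (large enough that the flat register has a genuine
low-frequency tail at the 20K-token corpus scale — the mechanism the
entropy manipulation is meant to engage), pronoun probability 0.2,
singular probability 0.7, filler probability 0.3, omission expressed
through one-argument order strings rather than a separate rate. These are
conditions of the simulation, not claims about any natural corpus.

What the generator does **not** emulate: discourse coherence, semantic
selection beyond animacy bias, morphophonological alternations,
age-conditioned adaptation, disfluencies. Passing results therefore show
that the *pipeline* detects the entropy contrast it was given; they do not
by themselves license claims about natural speech.

## Representations

* **Contextual**: a pre-norm transformer (2 layers, width 64, 2 heads,
  feed-forward 128, learned positions, tied output head) trained with the
  masked-token objective (15% targets; 80/10/10 mask/random/keep) by Adam,
  6 epochs, batch 64, on the register corpus only; BPE subword tokenizer
  (vocab cap 1200) fitted on the same corpus. Argument embedding = mean of
  final-layer states of the span's subwords (a two-level word-then-span
  average is available behind a switch; the single-level default is
  order-independent). Implemented in numpy with analytic gradients;
  training is bit-deterministic given the seed.
* **Static**: skip-gram with negative sampling (dim 64, window 2, 5
  negatives, unigram^0.75 noise) where a word vector is the mean of a
  word-level row and hashed character-3–5-gram rows, so unseen forms still
  compose a vector. One vector per form type, context-free by construction.
* **Position**: (first position, before verb, other argument present).
  "First position" means the first non-punctuation token, so an argument
  after a filler or question word is not first. The combination
  (first = 1, before-verb = 0) is impossible by definition: a verb
  preceding the argument would itself occupy first position.
* **Case**: multi-hot over the paradigm's twelve (case, number) cells; the
  set bits are exactly the cells whose realisation equals the surface
  form, so more than one bit ≡ syncretic form.

## Probing protocol

Verbs are shuffled and greedily pooled until 50 A + 50 P training items
are reachable; the exact items are sampled from the pool, surplus pool
items are recorded as `unused` (they can join neither side without
breaking balance or verb-disjointness). All instances of the remaining
verbs are shuffled into validation (min(300, available−1), at least 100)
and test. The perceptron probe keeps the lowest-*validation*-loss epoch
state (reading of "lowest loss"; training-loss selection is a config
switch — without it the validation set would play no role at all). SVMs
(RBF, C=1) serve the two feature representations, where they match the
perceptron at much lower cost.

Small-LM training is noisy run to run, and at desk scale a single encoder
pair can flip the sign of the register contrast. The study therefore pools
records from **two independent encoder runs per register** (5 split
versions each, ids offset per run); the split random intercept in the
statistical model absorbs run-level shifts. This is a scale decision of
this package, recorded here once.

## Statistical model

correct ~ Bernoulli(logit⁻¹(η)), η = β₀ + β_reg·reg + β_role·role +
β_int·reg·role (+ condition terms in the controlled study) + split
intercept + split×role slope + sentence intercept + sentence×role slope
(controlled study: sentence intercept per register level instead of split
terms). Priors: fixed effects Normal(0, σ) with σ walked up a ladder
{1, 2}, keeping the first fit whose reported parameters all have split-R̂
≤ 1.01; random-effect scales Exponential(1), sampled on the log axis with
the Jacobian term; random effects non-centered.

Sampling is a recursive No-U-Turn sampler with dual-averaging step-size
adaptation (target acceptance 0.95 — hierarchical logistic posteriors at
this size mix poorly at the conventional 0.8), a diagonal mass matrix
estimated from the middle warmup window, maximum tree depth 10, 2 chains ×
1000 draws after 700 warmup by default. R̂ and bulk ESS per reported
parameter come from arviz; a fit without diagnostics is unconstructible.
Posterior-predictive checks compare replicated to observed cell
accuracies.

**ΔP** is computed per sentence id: the linear predictor under
register = CDS and register = ADS with the sentence's own random
intercept and role slope (split effects at their population mean of zero;
each synthetic sentence exists in exactly one register corpus, yet the
counterfactual predicts both levels for it — the sentence's random effects
are the part that carries over), converted through the logistic function,
differenced per draw, averaged over sentence ids, summarised by the
posterior mean and central 95% interval. Swapping the register labels
flips ΔP's sign exactly.

Because the probing stage re-tests the same sentence in many split
versions, fits subsample the record table: up to three split appearances
per sentence (sentence random effects need a few observations each to
keep the posterior geometry well conditioned — with one observation per
sentence the sampler's R̂ degrades sharply) and as many sentences as fit a
cap of 5000 records. Entropy descriptives are plug-in (maximum-likelihood)
Shannon entropies in bits; the log base is a package convention, stated in
every output.

## Controlled generalization sets

Templates instantiate the full cross-product of conditions × permitted
noun pairings × number combinations (× pronoun variants in the
english-like mode), deduplicated on the token sequence. English-like:
basic and flipped-animacy (AVP), fronting and a relative clause with an
overt complementizer plus a two-word matrix continuation (PAV), passive
"is VERB-ed by" (PVA); agreement is a cue in the half of sentences whose
arguments differ in number. Russian-like: four syncretism conditions × all
six orders; the both-syncretic condition is generated only with an
agreement cue, since otherwise no cue distinguishes the roles.
Implausible pairings are admitted by design — the set probes the limits of
the learned representations, not naturalistic usage. Test composition is
exact, not approximate: 2 sentences (4 argument data points, two per role)
per special English condition with a basic remainder, and the fixed
word-order counts APV 52 / AVP 24 / PAV 18 / PVA 2 / VAP 2 / VPA 2 for the
russian-like mode; every condition appears at least once in training.

## Numerical and degenerate-input conventions

0-based half-open token spans; punctuation is a token but never argument
content; the labelled verb is the frame's lexical verb even under
auxiliaries (the passive's labelled verb is the participle). BPE merges
break count ties lexicographically, making tokenizer fits deterministic.
Probes with single-class training labels, empty corpora, corpora smaller
than one batch, case forms outside the paradigm, and split requests that
are infeasible under verb-disjointness all raise named errors rather than
degrading silently. Entropy of an all-zero count table is undefined and
raises.

## Problem sizes

Default study scale: 6000 utterances (~18K tokens) per register, two
encoder runs × five split versions, ≤5000 records per hierarchical fit,
2×1000 posterior draws. The acceptance script runs the same stages at
600 draws per fit. These sizes were chosen as the package's desk-scale
operating point; all of them are config fields.

## Known limitations

* The register effect at this scale is a few accuracy points; with a
  different seed the P-role cell can fail to resolve (its interval covers
  zero) even though the A-role and overall contrasts are credibly
  positive. This mirrors the general fact that low-entropy advantages are
  familiarity effects and shrink as the encoder sees more data.
* The contextual encoder is word-whole at the default corpus scale (BPE
  saturates before suffixes split), so case is learned per form, not as a
  decomposed suffix — intentional for the lexical-familiarity design, but
  a different tokenizer budget changes what "case knowledge" means.
* The NUTS implementation is single-threaded numpy; fits beyond ~10⁴
  records or ~10⁴ latent variables are better served by a dedicated PPL.
* Real-corpus ingestion (JSONL and CoNLL-U + case-frame table) is
  round-trip tested on synthetic data only; no natural corpus ships with
  the package.
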