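# roleprobe

Does one speech register support the learning of **semantic proto-roles**
better than another? When adults speak to children (child-directed speech,
CDS) they use fewer distinct words per grammatical function and a narrower
range of case forms than when they speak to other adults (ADS). `roleprobe`
asks whether such a low-variability register makes it easier for a purely
statistical learner to work out *who does what to whom* — to classify the
most agent-like argument (A) and most patient-like argument (P) of a
bivalent verb.

The package is aimed at computational psycholinguists who want a fully
controlled, simulation-based version of this question: every input is
synthetic, every cue (word order, case morphology, lexical bias, agreement,
argument omission) is a generator parameter, and the whole chain from corpus
to posterior contrast is reproducible from one seed.

## The method

1. **Synthetic registers.** An artificial verb-frame language (nominative A,
   accusative/dative P, declension classes with and without
   nominative/accusative syncretism, flexible word order over {A,P,V}
   strings, number agreement, argument omission, pronouns). A register pair
   shares its lexicon and paradigm and differs only in named statistics;
   the default CDS-like spec is calibrated **0.79 bits lower in A-role and
   0.55 bits lower in P-role lexical entropy** than its ADS-like partner,
   by bisection on a concentration parameter *c* (sampling weights
   *w*<sup>1/c</sup>).
2. **Four argument representations.** A small trainable masked-LM
   transformer encoder (contextual subword embeddings, span-averaged);
   subword character-n-gram skip-gram embeddings (static, one vector per
   form); a 3-bit position vector (first position, before verb, other
   argument present); and a multi-hot possible-case vector from the
   paradigm.
3. **Verb-disjoint probing.** Balanced 100-item training sets, validation
   100–300, test = remainder; no verb lemma crosses the train/eval
   boundary; several split versions per encoder run, several runs pooled.
   Perceptron probes (hidden 100, ≤20 epochs, lowest-validation-loss state
   kept) for embeddings; RBF-kernel SVMs for the feature vectors.
4. **Hierarchical Bayesian contrast.** Per-argument correctness
   ~ Bernoulli(logit⁻¹(η)) with register × role fixed effects, random
   intercepts for split and sentence id with random role slopes,
   Normal(0, σ∈{1,2}) and Exponential(1) priors, sampled by NUTS. The
   headline statistic is the counterfactual register contrast

   **ΔP = P(correct | CDS) − P(correct | ADS)**,

   predicted per sentence id under both register levels, differenced per
   posterior draw and averaged over sentences (95% credible interval
   attached). Positive ΔP means the low-entropy register supports role
   classification better.
5. **Controlled generalization.** Template-generated minimal pairs
   (syncretism condition × all six word orders for the russian-like mode;
   basic / flipped-animacy / fronted / relative-clause / passive for the
   english-like mode) scored by the encoders of both registers on an
   identical test set with a fixed composition (APV 52, AVP 24, PAV 18,
   PVA 2, VAP 2, VPA 2).

## Worked example

```python
from roleprobe import pipeline

specs = pipeline.default_register_pair("russian_like")
config = pipeline.RunConfig(seed=2, n_utterances=6000,
                            representations=("contextual",))
report = pipeline.run_study1(None, config, specs=specs)
print(report.delta_p[["representation", "role", "delta_p_mean",
                      "ci_2.5", "ci_97.5"]])
```

Output from this exact call (seed 2):

```
  representation     role  delta_p_mean    ci_2.5   ci_97.5
0     contextual  overall      0.064165  0.032675  0.096036
1     contextual        A      0.034243  0.000584  0.067673
2     contextual        P      0.098681  0.052566  0.144638
```

Reading: with the registers differing *only* in role-conditional lexical
entropy, arguments are classified correctly about 6 percentage points more
often from the low-entropy (CDS-like) register's contextual embeddings,
and both per-role contrasts are credibly positive (all split-R̂ ≤ 1.005 in
this run). The exact cell sizes vary with the seed — the direction is the
stable finding. Feeding the same corpus as both registers drives all ΔP
intervals back onto zero (the identity control in the test suite).

The numbered drivers under `analysis/` run the same stages as standalone
scripts (`01_simulate_registers.py`, `02_probe_study1.py`,
`03_controlled_study2.py`, `04_model_recovery.py`), each writing its tables
under `results/`. A thin `roleprobe` CLI (`simulate`, `train-lm`, `study1`,
`study2`, `controlled-gen`, `fit-stats`) wraps the same library calls.

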