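# Methods

## Model

The package scores how plausibly a candidate compound can be repurposed
toward a disease by averaging three component scores, each in [0, 1].

**Structural similarity (TC).** Molecules are encoded as ECFP4
fingerprints — Morgan circular fingerprints of radius 2, folded to 2048
bits (configurable). RDKit sanitizes and canonicalizes the SMILES first,
so alternative writings of one molecule give identical bits; unparseable
SMILES are excluded from scoring with a logged count. Similarity is the
Tanimoto coefficient on set bits. The degenerate 0/0 case (two empty
fingerprints) is defined as 0 rather than 1: a structureless match is
never promoted.

**Target overlap (OCTS).** A compound's potent-target set contains every
protein for which (a) any single quantitative measurement (IC50, Kd or
Ki, treated identically) is at or below the potency threshold, 1000 nM
by default, or (b) a curated unary interaction exists. Rule (a) is
deliberately permissive — databases report many measurements per pair
and no consensus rule is canonical; a median-based alternative is
available via `aggregate="median"`. OCTS between two potent-target sets
is `|A ∩ B| / min(|A|, |B|)` — the overlap (Szymkiewicz–Simpson)
coefficient. It is sometimes loosely called a Jaccard index in the
repurposing literature, but the denominator here is the smaller set
size, not the union: a compound whose few known targets all coincide
with a drug's profile scores 1 even though its full target space is
unexplored, which is the desired behaviour when most DTI profiles are
sparsely measured.

**Network proximity (CDS).** On an undirected PPI graph, the raw
distance between a compound's targets C_G and a disease's genes D_G is
the bidirectional closest-distance average: for each gene in either set,
the minimum unweighted shortest-path length to the other set, summed and
divided by the number of defined terms. This reading makes the
denominator |C_G| + |D_G| count exactly the summed terms (up to
exclusions, below), and is the standard closest-measure of the
interactome literature. Genes absent from the graph, or with no path to
the other set, are excluded from the average rather than given a penalty
distance, and `n_terms_used` records how many terms survived so data
loss is auditable; a pair with no defined term is flagged undefined.
Raw distances are min–max normalized over the batch and inverted,
`cds = 1 − (raw − min)/(max − min)`, so small distances map to high
scores; if all defined raw values coincide, every defined entry gets 1,
and undefined pairs get 0. Normalization runs globally over all scored
pairs by default (one score matrix per run); a per-disease mode is
available, since published descriptions of min–max normalized proximity
rarely state the population. No degree-preserving permutation z-score is
computed — the score is a relative ranking device, not a significance
test.

**Composite score.** The repurposing score is the arithmetic mean
`(TC + OCTS + CDS)/3`. For a disease with several approved drugs, TC and
OCTS are computed per (drug, candidate) pair; pairs with TC below
`tc_min` (default 0.2) are dropped first, a candidate survives if at
least one pair passes, and the surviving pairs' scores are averaged
(averaging over all pairs is available via `pairwise_tc_filter=False`).
Candidates below `score_min` (default 0.4) are dropped from the report.
Ties are broken lexicographically by candidate InChIKey so runs are
byte-reproducible. Approved drugs for the query disease are never their
own candidates; drugs approved only for other diseases are.

## Evaluation statistics

Against a reference association set, per-disease enrichment is the raw
excess `Sig_d = N_overlap − N_expected` with
`N_expected = |C_d|·|C_r|/|C_all|`, the mean overlap of a uniform random
draw of |C_r| compounds from the universe. `N_expected` uses exact
division; display rounds to the output precision. Sig_d carries no
variance or p-value by design; the test suite checks the closed form
against a seeded Monte-Carlo draw, which is a verification aid, not a
claim of the method. The hit ratio sweeps score thresholds and reports
the percentage of above-threshold predictions present in the reference;
thresholds with an empty denominator are omitted. Reference matching is
by exact (disease CUI, InChIKey) pair.

## Tunable parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| `potency_threshold_nm` | 1000 | nM | conventional cut between potent and weak bioactivity |
| `tc_min` | 0.2 | – | discards structurally unrelated pairs before averaging |
| `score_min` | 0.4 | – | reporting threshold below which predictions are noise-prone |
| `fingerprint_bits` | 2048 | bits | de-facto ECFP4 fold length |
| `cds_normalization` | global | – | one score matrix per run; per-disease optional |
| `aggregate` | any | – | permissive multi-measurement rule; median optional |

## Synthetic data generator

The generator emulates the five inputs at toy scale: a compound table
(InChIKey + SMILES), a bioactivity table, a PPI edge list, a
disease–gene map and approved indications. Chemistry comes from a
curated library of 20 drug-like scaffolds decorated at a fixed aromatic
position, so every SMILES parses by construction. Defaults: 60
candidates, 4 approved drugs, 4 diseases, a 40-protein target pool
inside a 150-node PPI graph (random spanning tree plus 1.5·n extra
edges, so one connected component contains every target), 6 targets per
compound, 6 genes per disease, 20% of decorative quantitative records
above the potency cutoff and 10% carrying extra unary evidence — sizes
chosen so every structural feature of the pipeline (multi-compound
normalization batches, potency mixing, unary evidence, background
candidates) is exercised while a full run takes seconds.

A *planted* candidate for a disease is built from the disease's approved
drug by a substituent-level edit — the drug's n-butyl chain is
homologated to n-pentyl — which keeps ECFP4 Tanimoto ≥ 0.89 across the
scaffold library while remaining a distinct molecule; its target set
shares a configurable fraction of the drug's targets (topped up outside
the drug's profile so OCTS equals that fraction exactly), and the
disease's gene set is the drug's target set, placing the planted
candidate at zero network distance. A *decoy* uses aliphatic or sugar
chemistry (Tanimoto ≤ 0.15 to every scaffold) and targets disjoint from
both the drug's profile and the disease genes; since its TC is below 0.2
and its OCTS is 0, its composite score is bounded above by
(0.2 + 0 + 1)/3 = 0.4 analytically. Approved-drug evidence is written as
unary curated records (as drug-focused databases provide), planted and
decoy evidence as always-potent quantitative records, and `potency_mix`
applies to the remaining decorative records only, so planted structure
is invariant to the potency mix.

All randomness flows from one `numpy` PCG64 stream seeded from the spec;
two runs with the same spec produce byte-identical files. The manifest
records the seed, the planted and decoy identities and every drug's
target set.

What the generator does **not** emulate: realistic bioactivity value
distributions, database-scale compound counts, scale-free PPI topology,
cross-database identifier noise, or partial structural overlap between
background candidates and drugs beyond what the shared scaffold library
induces. Passing tests on these fixtures therefore demonstrate the
correctness of the scoring arithmetic, filtering and ranking machinery —
not predictive performance on real pharmacological data.

## Numerical choices and degenerate inputs

- Tanimoto and OCTS of empty inputs: empty fingerprints score 0; empty
  target sets raise a typed error (callers exclude target-less
  compounds upstream).
- Proximity of gene sets fully absent/disconnected: flagged undefined,
  assigned cds 0 at normalization, never fatal mid-batch.
- A batch whose defined raw distances are all equal maps every defined
  entry to cds 1 (the degenerate min = max case).
- Output tables print 4 decimal places so golden-file comparisons are
  stable; internal arithmetic is double precision throughout.
- Identifier validation is shape-only (InChIKey 14-10-1 letter blocks,
  CUI `C` + 7 digits); invalid rows are skipped with row-numbered
  warnings, not fatal, so noisy dumps load.

## Limitations

- The composite score weighs its three components equally; no weighting
  or learning is attempted.
- OCTS inherits the sparsity of measured DTI profiles: compounds with
  one known shared target can score 1.
- CDS is a batch-relative quantity; scores are not comparable across
  runs with different candidate pools unless normalization inputs match.
- The significance statistic is an excess count without a null variance;
  treat it as a sanity check, not a hypothesis test.
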