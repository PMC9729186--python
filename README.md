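# drugrepo

Scores candidate compounds for drug repurposing by combining three
orthogonal lines of evidence — chemical structure, drug–target
interaction (DTI) profiles, and network proximity of targets to disease
genes — into a single composite score. It is aimed at computational
drug-discovery work where approved drugs for a disease are known and a
large pool of investigational compounds is to be ranked as repurposing
or rescue candidates.

## The score

For a disease *d* with approved drug *A* and candidate compound *C*:

- **TC** — Tanimoto coefficient between ECFP4 (Morgan radius-2, 2048-bit)
  fingerprints: `TC = N_AC / (N_A + N_C − N_AC)`, with `N_A`, `N_C` the set
  bits of each fingerprint and `N_AC` the shared bits.
- **OCTS** — overlap coefficient between potent-target sets
  (targets with any activity measurement ≤ 1000 nM, or a curated unary
  interaction): `OCTS = |Drug_T ∩ Compound_T| / min(|Drug_T|, |Compound_T|)`.
- **CDS** — compound–disease score. The raw distance averages, over every
  gene in the compound's target set C_G and the disease's gene set D_G,
  the minimum unweighted shortest-path length to the other set in a
  protein–protein interaction (PPI) network; the batch of raw distances is
  min–max normalized and inverted so the closest pair scores 1.

The composite score is the arithmetic mean `(TC + OCTS + CDS) / 3` in
[0, 1]. Pairs with TC < 0.2 are discarded before averaging over multiple
approved drugs, and candidates scoring ≥ 0.4 are reported, ranked per
disease. Predictions can be benchmarked against a reference association
set via the per-disease excess overlap
`Sig_d = N_overlap − |C_d|·|C_r|/|C_all|` and hit-ratio-vs-threshold
curves.

## Worked example

Generate a seeded synthetic dataset with one planted candidate (shares
the approved drug's scaffold and all of its targets for disease
C1000001) and score it:

```python
from drugrepo.synthetic import FixtureSpec, generate_fixture
from drugrepo.cli import RunConfig, run_score

fx = generate_fixture(FixtureSpec(seed=7), "example_data")
frame = run_score(RunConfig(
    compounds=fx.paths["compounds"],
    bioactivities=fx.paths["bioactivities"],
    ppi=fx.paths["ppi"],
    disease_genes=fx.paths["disease_genes"],
    indications=fx.paths["indications"],
    out_dir="example_out",
))
print(frame.head(5).round(4).to_string(index=False))
```

prints

```
disease_id                candidate_id     tc   octs    cds  drugrepo  rank
  C1000001 KFGSAZWOMTOMIL-TBASJUAXDK-Z 0.8966 1.0000 1.0000    0.9655     1
  C1000001 GZLMNPONZUUSQI-ZMFVEWPCBL-A 0.5750 0.3333 0.4500    0.4528     2
  C1000001 VTRLVJROHFNINS-UUNBETPVML-G 0.4524 0.3333 0.5548    0.4468     3
  C1000002 VTRLVJROHFNINS-UUNBETPVML-G 0.8421 0.5000 0.5810    0.6410     1
  C1000002 RAGKXZITOBKSSX-QZLSQWYVYJ-Z 0.6585 0.4000 0.6000    0.5528     2
```

The planted candidate `KFGSAZWOMTOMIL-…` tops its disease with a
near-perfect score: TC 0.8966 (one-carbon chain homolog of the approved
drug), OCTS 1.0 (identical potent-target set) and CDS 1.0 (its targets
*are* the disease genes, so its PPI distance is the batch minimum). The
other rows are background candidates that clear the 0.4 reporting
threshold; 17 of the 252 scoreable (candidate, disease) pairs survive.
`example_out/run.log` audits row counts at every filter stage, and
`repurposing.tsv` holds the same table with 4-decimal values.

The same pipeline is available from a shell:

```sh
drugrepo fixture --seed 7 --out-dir example_data
drugrepo score --compounds example_data/compounds.tsv \
    --bioactivities example_data/bioactivities.tsv \
    --ppi example_data/ppi_edges.tsv \
    --disease-genes example_data/disease_genes.tsv \
    --indications example_data/indications.tsv --out-dir example_out
drugrepo evaluate --predictions example_out/repurposing.tsv \
    --reference my_reference.tsv --universe-size 60 --out-dir example_eval
```

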