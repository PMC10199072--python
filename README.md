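# npforge

Generate, curate and characterize **natural-product-like SMILES libraries**
with a token-level LSTM language model.

Natural products — metabolites of living organisms — occupy a region of
chemical space that drug-discovery screening libraries cover poorly:
stereochemistry-rich polycyclic scaffolds, sugars, phenols, macrolactones.
Known collections hold only a few hundred thousand structures.  A language
model trained on the SMILES strings of known natural products can sample
*new* molecules from the same structural distribution, expanding the
searchable natural-product-like space by orders of magnitude.  `npforge`
implements that workflow end to end for computational chemists:

1. **prepare** — filter a SMILES corpus to valid, unique, stereo-free
   entries; split 72% / 8% / 20% into train / validation / held-out;
   optionally augment each molecule with randomized non-canonical writings;
2. **train / sample** — fit a stacked LSTM (teacher forcing, Adam, early
   stopping on validation loss, implemented in NumPy and verified against
   finite-difference gradients) and sample new SMILES autoregressively;
3. **curate** — four-stage syntactic validity (parse, canonical SMILES,
   InChI, InChIKey), dual-key deduplication (canonical SMILES **or** InChI),
   standardization, salt/solvent/isotope parent extraction, and a
   structure-quality checker whose penalties above 5 remove a record;
4. **characterize** — natural-product-likeness scores from atom-centred
   fragment log-ratios, 10- and 27-descriptor panels, KL divergence between
   library distributions, held-out recovery, and t-SNE chemical-space maps.

The core statistic, the NP-likeness score of a molecule *m* with heavy
atoms *a* and fragment table *c*, is

    score(m) = cap( (1/|m|) · Σ_a c(frag_2(a)) ),
    c(f) = log10 [ (n_f^NP + 1)(N_ref + 1) / ( (n_f^ref + 1)(N_NP + 1) ) ]

where `frag_2(a)` is the radius-2 circular environment of atom *a* and
`cap` compresses |raw| > 4 logarithmically into ≈ [−5, 5].  Library
similarity is measured by D(P‖Q) = Σ P(x) ln(P(x)/Q(x)) (nats) over binned
descriptor or score distributions (bin width 0.1).

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

Generate a synthetic corpus with planted defects, curate it, and inspect
the bookkeeping:

```python
from npforge.fixturegen import FixtureSpec, generate_corpus
from npforge.curator import curate

spec = FixtureSpec(200, seed=7, fragment_pool="np_like", corruption_plan={
    "syntactic_break": 15, "duplicate_rewrite": 20, "severe_valence": 5,
    "add_salt": 10, "add_stereo": 10})
smiles, manifest = generate_corpus(spec)
records, summary = curate(smiles)
print(summary)
```

```
CurationSummary(n_input=200, n_syntactic_invalid=15, n_duplicates=20,
                n_checker_removed=5, n_output=160)
```

The 15 unparseable strings fail the syntactic gate, the 20 duplicate
rewrites collapse onto their base molecules' canonical forms, and the 5
radical-bearing structures exceed the checker's removal threshold; the 20
salted/stereo-marked molecules are repaired (counter-ion stripped, stereo
stripped) and kept, so 160 curated records remain.  The same commands are
available from the shell via `npforge fixtures` and `npforge curate`.

Score a molecule against a table trained on the two fixture pools:

```python
from npforge.fixturegen import generate_clean_corpus
from npforge.nplikeness import train_score_table, np_score

np_pool  = generate_clean_corpus(150, seed=101, pool="np_like")
ref_pool = generate_clean_corpus(150, seed=202, pool="druglike")
table = train_score_table(np_pool, ref_pool)
print(round(np_score(np_pool[0], table), 3),
      round(np_score(ref_pool[0], table), 3))
```

```
1.005 -0.775
```

Positive scores indicate natural-product-flavoured environments (sugars,
phenolics), negative ones druglike environments (sulfonamides,
fluoroaromatics).

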