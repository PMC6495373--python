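# paleoferm

Analysis toolkit for microbiologists and bio-archaeologists asking whether
yeasts isolated from ancient vessels are descendants of the fermentation
cultures once kept in them — or just environmental bystanders.  It
implements, as a tested and reusable pipeline, the computational chain
that question requires:

- **Species delimitation on a barcode tree** — patristic distances
  (cumulative branch length, in substitutions per base) between a query
  isolate and its closest relative, tested against the distribution of
  intraspecific distances among labelled reference tips.  A query in the
  right tail (`p < α` under an empirical exceedance rule or the tail of a
  fitted lognormal) is a novel-species candidate.
- **Intertree comparison** — Robinson–Foulds distances (unweighted and
  branch-length-weighted) and DBSCAN clustering of gene trees over the
  precomputed distance matrix, for phylogenomic-conflict assessment.
- **Alignment curation** — greedy centroid dereplication at 99%
  identity, gap-proportion column trimming (strict "over 0.8" rule),
  parsimony-informative-column counting, and ortholog occupancy filters.
- **CNV signature scoring** — given an isolate-pair copy-number table and
  a signature of expected duplications/deletions characteristic of
  beverage-adapted yeasts, count direction-concordant clusters per
  isolate and test the split against the neutral (n/2, n/2) expectation
  (1-df χ²), plus a paired/Welch t test over the profiles.
- **Growth-curve fingerprinting** — replicate-wise fits of the logistic
  model N(t) = K / (1 + ((K − N0)/N0)·e^(−rt)) to OD600 series, Welch
  tests of r against a modern control strain, PCA of the fitted
  parameters, distance-to-control classification, and point-biserial
  correlation with vessel origin.
- **Isolation-frequency enrichment** — Fisher's exact test (complete
  margin-preserving enumeration in log-factorial arithmetic) on 2×2
  recovery tables built from categorised sample sheets.
- **Beverage analytics** — ethanol-normalised GC-MS relative peak areas,
  percent-of-max compound scaling, Ward (ward.D2) clustering with
  bootstrap (bp) and approximately-unbiased (AU) node support, beer
  colour scales (SRM = 12.7·A430, EBC = 25.0·A430), phenol–sulfuric
  carbohydrate quantitation, and taste-sheet aggregation.
- **Synthetic data** — seeded generators with planted ground truth for
  every input above, so the whole pipeline is testable without any
  external downloads.

See `docs/methods.md` for the models, assumptions, parameter defaults and
design choices.

## Worked example

Simulate a barcode tree with two planted queries — one grafted inside a
species, one hung on the backbone — and run the delimitation test:

```bash
$ paleoferm --seed 7 --out sim simulate --stage tree
$ paleoferm --out res delim sim/tree.nwk sim/species_map.csv query_cons1 query_novel1
INFO paleoferm: query_cons1: closest sp3_t4 at 0.007481 SPB, p=0.8622 -> conspecific
INFO paleoferm: query_novel1: closest sp3_t2 at 0.3339 SPB, p=3.151e-05 -> novel-species-candidate
```

`res/delim.json` holds the machine-readable result; for the first query:

```json
{
  "query_cons1": {
    "closest_relative": "sp3_t4",
    "d_obs": 0.00748129525314549,
    "n": 30,
    "p": 0.862153991948953,
    "verdict": "conspecific",
    "method": "parametric-lognormal"
  }
}
```

Read: the query's nearest tip sits 0.0075 substitutions per base away —
well inside the distribution of the 30 intraspecific reference distances
(tail probability 0.86 under the fitted lognormal), so the isolate is
called conspecific with its closest relative.  The second query, at 0.33
SPB, is far outside that distribution (p ≈ 3×10⁻⁵) and is flagged as a
novel-species candidate.

The same operations are available as a library.  Testing whether yeast
recovery is enriched in putative beverage vessels (6 positives among 21)
relative to control samples (2 among 110):

```python
from paleoferm import ContingencyTable2x2, fisher_exact_2x2, beer_color

table = ContingencyTable2x2(a=6, b=15, c=2, d=108)
print(f"odds ratio = {table.odds_ratio():.1f}")
print(f"two-sided p = {fisher_exact_2x2(table):.2e}")
srm, ebc = beer_color(0.37)
print(f"SRM = {srm:.2f}, EBC = {ebc:.2f}")
```

prints

```
odds ratio = 21.6
two-sided p = 1.96e-04
SRM = 4.70, EBC = 9.25
```

— recovery from beverage vessels is over twenty-fold enriched and far
from incidental, and a beer with 430-nm absorbance 0.37 sits at 4.7 SRM
(9.3 EBC), a pale colour.

Other subcommands follow the same shape: `treecluster` (gene-tree
conflict), `cnv` (signature concordance), `growth` (fingerprinting),
`enrich` (sample sheets), `flavor` (compound clustering with support
values), `simulate` (synthetic datasets).  `paleoferm COMMAND --help`
shows the expected file formats.

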