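# mitomatch

Mitochondrial DNA haplogroup profile matching and RBF-network cohort
classification, for researchers studying associations between mtDNA
haplogroups and complex traits (Alzheimer's disease, Parkinson's disease,
type 2 diabetes, longevity) in case-control cohorts.

All coordinates are 1-based rCRS positions over the 16,569-bp human
mitochondrial genome.

## What it computes

The package implements a two-stage workflow.

**Stage 1 — cohort analysis.** Each individual's mtDNA genotype over a locus
panel is encoded numerically (A, G, C, T → 1, 2, 3, 4; missing → 0) and a
radial basis function network

```
f(x) = b + Σᵢ wᵢ · exp(−‖x − Mᵢ‖² / 2σᵢ²)
```

is trained on a stratified 2/3–1/3 train/validation split with binary
targets: 1 for the target class (say, AD patients), 0 for every other class.
Centers `Mᵢ` come from k-means on the training rows, widths `σᵢ` from
nearest-center distances, and the readout `w, b` from ridge-regularised
least squares. Individuals are then ranked by predicted probability, the
top-N *modified cluster* (N = 15 by convention) is selected, its varying
loci are summarised in the `locus N>M (Y/X)` notation, and its members are
assigned to haplogroups by best profile match.

**Stage 2 — individual screening.** For a haplogroup with `k` defining
mutations (packaged tables cover eight study classes), a person's *match
ratio* is

```
ratio = (defining mutations carried) / k
```

kept as an exact rational. A ratio strictly greater than 0.8 flags the
person as resembling that haplogroup's study class. This is an initial
screen, not a calibrated clinical probability.

## Worked example

```python
from mitomatch import VariantSet, diagnose, load_packaged_tables

person = VariantSet("example_person", dict(zip(
    [194, 1382, 3010, 4883, 5178, 8020, 8414, 8964, 9824, 14668, 16519],
    "TCATAATTATC")))
report = diagnose(person, load_packaged_tables())
for e in report.flagged:
    print(e.class_label, e.haplogroup_name,
          f"{e.match.matched}/{e.match.total}", e.rendered_ratio())
```

prints

```
T2D patients D4b2b 11/13 0.846
Obese young males D4b2b 10/12 0.833
Non-obese young males D4b2b 9/11 0.818
```

The person carries 11 of the 13 mutations defining the D4b2b haplogroup in
the type-2-diabetes table — ratio 11/13 ≈ 0.846 > 0.8, so the screen flags
an elevated resemblance to the T2D class (D4b2b profiles in two other class
tables are flagged for the same underlying mutations). The same API drives
the shell interface:

```
mitomatch diagnose --variants person.tsv --out report.tsv
mitomatch simulate --config spec.yaml --seed 7 --out-prefix cohort
mitomatch train --genotypes cohort.genotypes.tsv --positive-class "AD patients" --out model.json
mitomatch select --model model.json --genotypes cohort.genotypes.tsv --top 15 --out top15.tsv
mitomatch associate --variants top15_variants.tsv --class "AD patients" --out assoc.tsv
```

The `examples/` directory holds three narrative scripts: `screen_person.py`
(the screening example above), `cohort_pipeline.py` (simulate → train →
select → associate on a synthetic cohort, recovering a planted dominant
haplogroup), and `position_summary.py` (the `16362 T>C (9/6)` position
notation).

## Scope notes

- Profiles are flat defining-SNP sets; no phylogenetic tree construction or
  hierarchical haplogroup nomenclature resolution.
- One allele per locus (haploid consensus); no heteroplasmy or indels.
- The bundled reference sequence is a synthetic stand-in (correct length,
  table-consistent bases at profile loci); supply the true rCRS FASTA for
  real-genome work. See `docs/methods.md` for the model details and caveats.
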