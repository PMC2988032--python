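# mtqc — phylogenetic quality control for mtDNA variant data

Human mitochondrial DNA is maternally inherited and does not recombine:
every mtDNA sequence sits on one branch of the worldwide maternal
genealogy, and the only way it changes is by sequentially accumulating
mutations along that branch. Clinical resequencing studies that call
"tumor-specific somatic mutations" by comparing a patient's tumor and
normal tissue therefore have a built-in sanity check — if the differences
between the two samples reconstruct the *evolutionary path between two
haplogroups*, the parsimonious explanation is not somatic mutagenesis but
a sample mix-up (artificial recombination), and if a single sample's
variants split cleanly into two lineage-consistent subsets, the sample is
a mixture of two individuals' DNA.

`mtqc` implements this check as a small, scriptable toolkit for anyone
who works with rCRS-anchored mtDNA variant lists (tumor/normal panels,
forensic casework, population surveys):

* **haplogroup classification** by motif matching against a
  motif-annotated haplogroup tree, scored with the symmetric two-way
  coverage (Kulczynski) score
  `s(P, E) = ½·M/|E| + ½·M/|P|`, where `E` is the haplogroup's cumulative
  motif, `P` the sample profile and `M` the (weighted) number of expected
  variants the profile matches;
* **pair concordance**: tumor/normal pairs whose calls land on divergent
  branches, with ≥ 70 % of their differences lying on the inter-lineage
  path, are flagged `SUSPECT_MIXUP`;
* **mixture detection**: a sample is flagged when the best *pair* of
  haplogroups explains a substantially larger fraction of its variants
  than the best single haplogroup (gain ≥ 0.2 by default), with each
  component uniquely supported by ≥ 3 variants;
* **synthetic cohorts** with planted swaps, mixtures and phantom calls
  plus truth tables, for end-to-end validation without any downloads.

Variant tokens follow the compact mtDNA notation: `A7146G` (transition),
`16318t` (transversion, lowercase suffix), `12519` (position only,
alleles unreported), `16166d` (deletion), `h` prefix for heteroplasmy.
A fixture haplogroup subtree ships with the package; external trees load
from a simple indentation-based text format with per-edge motifs and
`!`-prefixed back mutations.

## Worked example

The package bundles the profiles of a sessile serrated adenoma case
whose tumor tissue carried 22 "somatic/heteroplasmic" variants. Running
the pipeline:

```sh
mtqc run --profiles case11.tsv --out report.json
```

prints (to stderr):

```
mtqc summary
  pairs checked:    0 (0 flagged SUSPECT_MIXUP)
  samples screened: 2 (1 flagged as mixtures)
  [mixture] case11-tumor: components L2a + L1b1a3a, explained 55% -> 100%
```

The best single haplogroup explains only 55 % of the tumor's variants;
the pair L1b1a3a + L2a explains 100 % of them, with 12 variants on the
L1b path and 10 on the L2 path — two African lineages inside one
"patient", i.e. a sample mix-up rather than somatic mutation. The same
machinery attributes the much-discussed `A7146G` polymorphism to the L2
lineage rather than to tumor biology:

```python
>>> from mtqc import fixture_tree, make_profile, classify
>>> tree = fixture_tree()
>>> for c in classify(make_profile("adenoma", "tumor", ["A7146G"]), tree)[:3]:
...     print(c.node_name, round(c.score, 3))
L2 0.583
L2c 0.545
L2a 0.536
```

Other commands: `mtqc classify`, `mtqc check-pairs` (tumor/normal
verdicts from a pairs TSV), `mtqc detect-mixture`, `mtqc simulate`
(synthetic cohorts with truth tables). All take `--tree` to supply an
external phylogeny and `--strict` where a nonzero exit on QC findings is
wanted (exit codes: 0 clean, 2 parse error, 3 flagged findings).

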