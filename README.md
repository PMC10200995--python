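# polyorigin

Resolving the parentage of an allopolyploid clade from gene trees.

Allopolyploid species carry two or more diverged subgenomes acquired by
interspecific hybridization plus genome doubling.  Given hundreds of
per-gene-family maximum-likelihood trees that each contain the diploid
candidate donor lineages (taxonomic *sections*), one or two gene copies
(homeologs) per polyploid, and an outgroup, `polyorigin` answers: *which
diploid section did each homeolog come from, when did the donors diverge,
and how are the origins distributed along the polyploid's chromosomes?*
The motivating system is an almost all-Australian polyploid tobacco clade
whose nuclear genome mixes contributions from four diploid sections and
whose plastome is a recombinant of two of them — but every stage is
generic over a species→section map.

The package is aimed at phylogenomics practitioners; it operates on
standard text formats (one-tree-per-line Newick, TSV, FASTA, BED) and
ships a synthetic-data module so the whole pipeline is testable against a
known truth.

## Pipeline stages

1. **Tree QC** — keep a gene tree iff it has every diploid species, the
   outgroup, ≥ 2 copies of the reference polyploid, ≥ 1 copy of each other
   polyploid, and bootstrap support B > 70 on every internal node (strict;
   B = 70 fails).
2. **Origin tagging** — root on the outgroup, check each diploid section's
   monophyly, then for each polyploid leaf walk toward the root and stop
   at the first ancestor subtending a diploid leaf: the tag is the set of
   sections under that ancestor ({Sylvestres} = clean origin;
   {Alatae, Sylvestres} = the homeolog attaches above two sister sections;
   `unresolved` = no informative ancestor or a non-monophyletic section).
3. **Node census** — every internal node of every tree contributes its
   section combination with weight 1/(leaves under the node), summarizing
   which clades repeatedly co-occur across trees.
4. **Type classification** — trees sharing the same multiset of tags per
   polyploid form a *type*; trees where a control polyploid of known
   parentage gets the wrong tags are discarded; types with ≥ 3 trees get a
   majority-rule consensus (and ASTRAL-ready mapping files).
5. **Ks dating** — Gaussian-KDE the synonymous-substitution (Ks)
   distribution per species pair, take the mode ("peak"), and date splits
   linearly, `age = Ks · 29.5 / 0.279` Mya against the Solanum–Nicotiana
   calibration, or via a UPGMA tree built from the Ks-peak matrix.
6. **Recombination scan** — the pairwise homoplasy index Φ (mean
   four-gamete/state-graph incompatibility among informative-site pairs
   within *w* columns) with a permutation test; sliding windows with
   p < 0.01 merge into recombinant regions reported when > 5 kb.  Includes
   LSC/SSC/IR plastome partitioning.
7. **Chromosome painting** — per-chromosome percentages of homeolog
   origins over resolved loci, flagging origin combinations > 20%.

## Worked example

```python
from polyorigin import (default_scenario, simulate_gene_family_trees,
                        filter_trees, root_on_outgroup, assign_leaf_origins,
                        node_weight_census)

truth = default_scenario()          # 5 donor sections, 5 polyploids, outgroup
smap = truth.section_map()

trees = simulate_gene_family_trees(truth, n_families=100, noise=0.3, seed=1)
report = filter_trees(trees.trees, smap, min_support=70)
print(f"{len(report.kept)} of {len(report)} trees pass QC")

rooted = [root_on_outgroup(t, smap) for t in trees.trees]
tags = [assign_leaf_origins(t, smap) for t in rooted]
print(dict(sorted(tags[0].tags.items())))

census = node_weight_census(rooted, smap)
for combo, (raw, weight) in census.sorted_items()[:3]:
    print(f"{'+'.join(sorted(combo)):30s} raw={raw:4d} weight={weight:.2f}")
```

prints

```
100 of 100 trees pass QC
{'Nafr_1': ('Noctiflorae',), 'Nben_1': ('Alatae',), 'Nben_2': ('Noctiflorae',),
 'Ncav_1': ('Alatae',), 'Ncav_2': ('Petunioides',), 'Nfor_1': ('Alatae',),
 'Nfor_2': ('Sylvestres',), 'Ntab_1': ('Sylvestres',), 'Ntab_2': ('Tomentosae',)}
Ntab+Tomentosae                raw= 117 weight=42.17
Nben+Noctiflorae               raw=  98 weight=35.33
Ntab+Sylvestres                raw=  68 weight=34.00
```

Every homeolog of the first family is tagged with its simulated donor
section (e.g. the two reference-polyploid copies `Nben_1`/`Nben_2` trace
to Alatae and Noctiflorae), and the census ranks the polyploid–donor
pairings by how often, and how tightly, they share ancestral nodes.

Dating the donor splits from Ks peaks:

```python
from polyorigin import calibrate_dates
ages = calibrate_dates({("Alatae", "Sylvestres"): 0.068,
                        ("Noctiflorae", "Petunioides"): 0.052,
                        ("Solanum", "Nicotiana"): 0.279},
                       calibration_pair=("Solanum", "Nicotiana"),
                       calibration_age=29.5)
# {('Alatae','Sylvestres'): 7.19, ('Noctiflorae','Petunioides'): 5.50,
#  ('Nicotiana','Solanum'): 29.5}   # Mya
```

A command-line interface mirrors the stages:
`polyorigin simulate|filter|assign|classify|ksdate|phiscan|paint --help`.

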