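# hermesmap

A tested, reusable pipeline for the computational side of organelle
proteome profiling of the sperm **Hermes body** (the cytoplasmic droplet —
a ~2 µm organelle on the epididymal sperm flagellum containing unstacked
flattened membrane cisternae), and for the immunogold electron-microscopy
quantification used to localise its proteins. It is aimed at proteomics and
cell-biology groups who have scored peptide-spectrum matches (PSMs) for
several subcellular fractions and want the classic spectral-counting
workflow — parsimony inference, shared-peptide apportionment, % total
peptides, clustering/enrichment — plus stereological gold-particle counting,
as plain composable Python instead of a lab-internal database.

## What it computes

**Parsimony protein inference.** Given a peptide→protein map built by exact
substring search against a FASTA database, the minimal set of protein groups
explaining all confidently matched peptides is found by (1) merging proteins
with identical matched-peptide sets, (2) absorbing proteins whose peptide set
is a strict subset of another protein's, and (3) greedy set cover over the
rest. Peptides are then re-labelled *unique* to one retained group or
*shared* between several.

**Spectral-count quantification.** Each retained PSM counts once. For a
shared peptide with *s* spectra in a sample, group *g* receives
*s·u_g / Σ_h u_h*, where *u_g* is the group's unique spectral count in that
sample (equal split when no unique evidence exists; a flag switches the
weights to distinct unique-peptide counts). Apportioned counts are
normalised to **% total peptides** per sample and averaged over the *n* = 3
or 4 biological replicates of each fraction (mean ± s.d.). Conservation is
exact: per sample the apportioned counts sum to the retained PSM total.

**Profile analysis.** Hierarchical clustering of protein profiles with
uncentred correlation distance and average linkage (Cluster 3.0 defaults),
written as CDT/GTR files for standard tree viewers; enrichment calls for a
target fraction against reference fractions (enriched / unique / shared /
depleted at a configurable fold threshold); abundance ranking; and rollups
onto the closed 22-name functional-category vocabulary.

**Immunogold quantification.** For 2-D scene files (membrane polylines plus
gold-particle coordinates in nm), the pipeline histograms particle offsets
from the plasma membrane in 12 nm increments, derives the symmetric
reference band that holds most membrane-proximal gold (72 nm span — 36 nm
each side — for a membrane antigen), classifies every particle into five
areas (cross/oblique plasma membrane, intracytoplasmic cisternae,
cross/oblique flagellar components), and reports percentage distributions
over the three compartments, pooled per antibody dilution, mean ± s.d.
across units, with no-primary-antibody controls summarised separately.

**Synthetic ground truth.** Because every stage needs a known answer to be
testable, the package ships a first-class generator: random proteomes with
homologue/truncation/splice-variant families, Poisson–multinomial spectral
sampling at chosen depths, and gold scenes with particles jittered off their
generating structures. All randomness flows from one seed through a
documented stream-splitting rule.

## Worked example

```python
import pandas as pd
import hermesmap as hm

# 1. synthesise a ground-truth experiment
proteome = hm.generate_proteome(n_proteins=20, n_families=4, seed=1)
accessions = [acc for acc, _ in proteome.proteins]
abundance, truth = hm.planted_abundance(accessions, n_target_enriched=5,
                                        n_reference_enriched=5, seed=1)
design = hm.FractionDesign(hm.DEFAULT_FRACTIONS, abundance,
                           replicates=3, depth=5000, seed=1)
psms = pd.concat(hm.generate_psm_tables(proteome, design).values(),
                 ignore_index=True)

# 2. parsimony inference
pmap, orphans = hm.map_peptides(set(psms.peptide), proteome.proteins)
groups = hm.infer_minimal_set(pmap)
classification = hm.classify_peptides(groups)

# 3. quantification -> % total peptides, replicate-averaged
qm = hm.quantify_pipeline(psms, groups, classification,
                          fraction_order=hm.DEFAULT_FRACTIONS)
top = hm.rank_by_abundance(qm.profile_mean, "HermesBody")[:3]
print(qm.profile_mean.loc[top].round(2))

# 4. enrichment calls against the reference fractions
calls, _ = hm.classify_enrichment(qm.profile_mean, "HermesBody",
                                  list(hm.DEFAULT_FRACTIONS[1:]))
print(top[0], calls[top[0]].label, f"fold={calls[top[0]].fold:.1f}")

# 5. immunogold quantification
gold = hm.SyntheticGoldDesign(n_particles=500, n_micrographs=10, seed=1)
result = hm.distribution(hm.generate_gold_scenes(gold))
for comp, mean in result.mean.items():
    print(f"{comp}: {mean:.1f} +/- {result.sd[comp]:.1f} %")
```

prints

```
       HermesBody  TestisGolgi  LiverGolgi  LiverER  COPI
P0000       28.99         3.56        3.75     3.71  3.77
P0002       23.91         2.99        3.30     2.95  3.00
P0004       14.72         1.69        1.81     1.44  1.82
P0000 enriched_in_target fold=7.7
plasma_membrane: 22.2 +/- 1.0 %
intracytoplasmic_cisternae: 65.9 +/- 0.8 %
flagellum: 11.9 +/- 0.3 %
```

The three rows are the most abundant protein groups in the target fraction:
their replicate-mean % total peptides is ~8-fold higher there than in any
reference fraction, exactly as planted (P0000 absorbed its truncation
variant P0001, so odd accessions are missing). The gold distribution
recovers the generating composition — 67 % of particles on the cisternae,
21 % on the plasma membrane, 12 % on the flagellum — within sampling error
of 5 000 scored particles.

The same pipeline runs from the shell; every stage writes its artifacts and
a manifest into the output directory:

```sh
hermesmap all --outdir run1 --seed 1
hermesmap goldcount --outdir run1 --band-nm 36
```

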