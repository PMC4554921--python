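# Methods

This note records the models, conventions and design choices behind
`hermesmap`, in the order the pipeline runs.

## Inputs and filtering

The pipeline consumes already-scored PSMs (peptide, sample, replicate,
confidence); raw-spectrum processing and search-engine scoring are out of
scope. The default confidence filter is 0.95, matching the 95 % assignment
confidence conventional for this kind of resource; every dropped record is
counted and logged, and the count appears in the stage manifest. FASTA
accessions are the first whitespace-delimited header token; duplicates are a
hard error.

## Parsimony inference

Peptide→protein mapping is exact substring containment (optionally with
I = L equivalence, since many search engines cannot distinguish the two
residues; the flag is off by default because the synthetic data controls
residue identity). Peptides matching no database protein are *orphans*:
reported and excluded from quantification. A real search pipeline cannot
produce them, but toy databases can, so they are handled explicitly rather
than being an error.

Group construction runs in three phases: identical matched-peptide sets
merge; strict-subset proteins are absorbed as members (into the candidate
with the largest peptide set, ties to the lexicographically smallest
accession — every candidate superset shares all of the absorbed protein's
peptides, so overlap cannot discriminate); remaining candidates are chosen
by greedy set cover with the tie-break (most uncovered peptides, most total
peptides, smallest accession). All tie-breaks depend only on peptide sets
and accession strings, so the result is invariant to database order.

Greedy set cover is not optimal in the worst case. On unstructured random
bipartite instances (each peptide assigned to an independent random protein
subset) it exceeds the exhaustive minimum on roughly a tenth of dense draws.
That regime does not model shotgun redundancy, which is family-structured
(truncations, splice variants, homologues — nested and chained peptide
sets). On databases drawn from the synthetic proteome generator the greedy
cover has matched the exhaustive minimum on every instance tested (the
acceptance suite verifies 100 fresh instances of ≤ 12 proteins per run).

Cover-redundant proteins — explained by retained groups without being a
subset of any single one — are dropped, not absorbed: attributing them to
one of several covering groups would be arbitrary.

## Quantification

Each retained PSM contributes exactly one count. Shared-peptide spectra are
apportioned proportionally to unique evidence *within the same sample*;
profiles for different fractions therefore stay independent. "Unique
evidence" defaults to unique spectral counts (the same currency as the
quantity being apportioned); a `peptides` mode weights by distinct unique
peptides instead, since the field's phrasing is used both ways. With no
unique evidence among the involved groups, spectra split equally — the
least-assumption allocation.

Conservation is treated as exact, not approximate. Within each shared
peptide the last involved group receives `s − Σ(other allocations)`; the
remaining float-dust (from summing many rounded rationals) is folded into
the column's smallest positive entry, whose ulp is fine enough to absorb
it. Column sums of the apportioned matrix therefore equal the integer PSM
totals bit-for-bit, and percent columns sum to 100 within 1e-9.

Replicate averaging uses the arithmetic mean and sample s.d. (n − 1
denominator, 0 when n = 1); a group absent from a replicate contributes 0
for it. Groups with zero total evidence are dropped and listed in the run
report.

Apportionment by unique-evidence proportion is a razor-style estimator: it
is exact when family members are merged into one group (truncations) and
approximate when a splice variant or homologue retains its own group, since
unique-count ratios track abundance ratios only in expectation. The
parameter-recovery tests therefore use redundancy-free databases, where the
generating abundance is the unambiguous truth; family handling is exercised
by the inference and conservation tests instead.

## Profile analysis

Clustering defaults are uncentred correlation distance with average linkage
— the defaults of the Cluster 3.0 program whose CDT/GTR output format the
writer reproduces, chosen because the original heat maps were built with
that tool chain and its settings are otherwise unstated. Both are
configurable. Rows are log10(x + p) transformed first, with pseudocount p =
half the smallest non-zero percent, because fraction profiles span orders
of magnitude (flag to disable). An all-zero row has no direction for a
correlation-type distance and is placed at distance 1 from everything, with
a warning. Average linkage is monotone, so merge heights are non-decreasing.

Enrichment of a target fraction compares its mean % against the *maximum*
reference mean: `unique_to_target` when every reference is 0, enriched at
fold ≥ threshold, depleted at fold ≤ 1/threshold, shared otherwise. The
default threshold of 2 is a convention, not a reported criterion, and is
exposed everywhere. All-zero groups are excluded and reported.

Category rollups validate against the closed 22-name functional-category
vocabulary and pool unannotated groups under `unknown`; per fraction the
rollup conserves total percentage mass.

## Immunogold quantification

Scenes are 2-D vector reductions of micrographs: polylines labelled
plasma_membrane / cisterna / flagellum with a cross/oblique section kind
(an input label — inferring section orientation from a 2-D trace is
ill-posed), plus particle coordinates. All coordinates are nm, origin at
the image top-left, y increasing downward.

Signed distance to a closed plasma-membrane trace is negative inside
(intracellular). Offset histograms use half-open 12 nm bins
`[k·w, (k+1)·w)` — a particle at exactly +12 nm falls in the second
extracellular increment. The reference band is the smallest symmetric span,
in whole increments, holding ≥ 95 % (configurable) of membrane-proximal
particles; at the ~15 nm localisation displacement expected from
12 nm-gold/antibody geometry this yields the conventional 72 nm span (36 nm
each side), and that 36 nm half-width is the default band for
classification.

Classification: a particle within the band of ≥ 1 structure goes to the
*nearest* such structure (ties to the plasma membrane — the choice is a
convention; the source procedures do not state one); within the cell but
outside all bands it is intracytoplasmic; outside the cell and all bands it
is unassigned and excluded. Distributions collapse the five areas onto
three reporting compartments (plasma membrane, intracytoplasmic cisternae,
flagellum), pool counts within an aggregation unit — antibody dilution by
default, matching the per-antibody *n* = 3 style of reporting; animal or
micrograph are alternatives — and report mean ± sample s.d. of percentages
across units. Clustered particles count individually. Control scenes
(no primary antibody) are tallied separately and never pooled.

## Synthetic data

The generators define the conditions under which the pipeline is validated.

* **Proteomes.** Random sequences of 180–400 residues with K/R at 6 % each
  and P at 2 %, so fully tryptic 6–30-mers are common. Families are pairs:
  truncations are prefixes cut at a cleavage site past 60 % of the parent;
  splice variants delete the central ~30 % block; homologues share the
  N-terminal two-thirds. Digest is fully tryptic (cleave after K/R except
  before P, no missed cleavages), length 6–30 by default.
* **PSM sampling.** Per replicate, total spectra ~ Poisson(depth), allocated
  multinomially over proteins by the fraction's abundance column, then
  uniformly over each protein's peptides. Confidences are synthetic values
  at or above the filter threshold — scoring is not simulated. Default
  depths (10⁴ for recovery experiments, lower for smoke runs) are chosen for
  test power; the source resource does not state per-fraction depths.
* **Gold scenes.** One elliptical ~2 µm plasma-membrane profile, three
  internal cisternae and a flagellar circle, all separated by ≥ 150 nm so
  zero-jitter classification is unambiguous. Particles are placed
  arc-length-uniformly on a structure drawn from the compartment fractions
  (default 21/67/12 % — the membrane-antigen composition used as reference
  truth) and displaced by isotropic Gaussian jitter, default σ = 10 nm, the
  order of the antibody–gold displacement for 12 nm particles. Scenes used
  to *derive* the reference band use σ = 15 nm, the displacement scale at
  which 95 % coverage reproduces the 72 nm span. Controls carry ≤ 3
  uniformly scattered background particles.
* **Seeding.** Stage `name`, sub-stream `k` uses
  `SeedSequence(seed, spawn_key=(STAGE[name], *k))`; any replicate or scene
  can be regenerated independently, and identical seeds give byte-identical
  tables.

What the generators do **not** emulate: peptide detectability differences
(length/hydrophobicity bias), missed cleavages and modifications, search
score distributions, correlated replicate structure, membrane curvature in
3-D, or section-thickness effects. Passing tests therefore demonstrate the
correctness of the computations under the stated sampling models, not
robustness to those real-data effects.

## Pipeline orchestration

The CLI chains simulate → infer → quantify → profile → goldcount → report.
Stages communicate only through files; each writes a manifest with
parameters, relative input/output paths, seed, version and counts at every
filter step, so a run is reproducible from its manifest alone. Manifests
carry no timestamps: two runs with one seed are byte-identical (the
diagnostic `run.log` is the one file that may differ, since it echoes
absolute paths). Small default problem sizes (40 proteins, depth 2 000,
12 micrographs) keep a full run in seconds; all are configurable.

## Numerical conventions and degenerate inputs

Ties everywhere break lexicographically on accession. Distance-matrix
negatives from rounding are clipped at 0. Empty samples, empty histograms,
zero-length polylines, scenes without a plasma membrane, and categories
outside the 22-name vocabulary are hard errors naming the offending item;
orphan peptides, all-zero profile rows and unassigned particles are
reported exclusions, not errors.

## Known limitations

* Greedy cover optimality is an empirical property of family-structured
  instances, not a guarantee.
* Razor-style apportionment is biased for partially overlapping groups (see
  above); no length/NSAF normalisation, intensity quantification, protein
  FDR or differential-abundance testing is provided — the workflow being
  reproduced uses none of them.
* Gold scenes are 2-D; no tomography, no particle detection from images.
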