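# Methods

This note documents the models, conventions, and numerical choices behind
`abn`, and what the synthetic-data tests do and do not demonstrate about
real data.

## Coordinate and atlas conventions

Neuron coordinates live in the annotation volume's physical frame:
micrometers, origin at the corner of voxel `[0, 0, 0]`, 0-based indexing,
half-open voxels `[i*s, (i+1)*s)`. A point exactly on a voxel boundary
belongs to the higher-index voxel, which makes assignment deterministic;
no interpolation is performed — region assignment is a pure voxel lookup.
Points outside the volume, or on annotation value 0 inside it (white
matter, ventricles, unannotated tissue), get `region_id = 0`; they are
retained in tables but excluded from every denominator, and their count is
reported. The structure tree is the Allen structure-graph JSON dialect;
per-node ancestor paths are recomputed from parent links and validated
against the file's declared paths on load. NRRD I/O is implemented
in-package (`abn.nrrdio`) covering attached headers with raw/ascii/gzip
encodings and `spacings`/`space directions` voxel sizes.

Regions whose tissue is routinely damaged during extraction and clearing —
olfactory areas (OLF), cerebellum (CB), medulla (MY) — are excluded by
default as whole subtrees; the exclusion set is configurable.

## Composition statistics

All composition quantities are expressed over a *scope partition*: a set of
acronyms pairwise non-nested along any root path (major divisions, cortical
areas, or within-area layers). Each assigned neuron rolls up to the unique
scope member on its ancestor path. Ratios `n[A]/total` per brain absorb the
large brain-to-brain variability in total tagged-cell counts. Cortical
layers are parsed from the trailing layer token of the acronym
(`1, 2/3, 4, 5, 6a, 6b`).

Cross-condition z-scores are computed per region over the per-brain ratios
of **all** conditions pooled (mean 0, sd 1 per region; `ddof = 1`
everywhere). A per-condition-mean variant is available behind a flag; the
pooled form is the default because one z-value per brain is the more
informative display. Regions with zero variance are flagged and given
z = 0 rather than NaN.

Two-group comparisons use the two-sided Welch's t-test (unequal variances;
group sizes here are small per-condition brain counts). Raw p-values are
reported by default; Benjamini–Hochberg adjustment is available behind a
flag for multi-region screens. Groups with zero pooled variance are
flagged degenerate and reported at the appropriate p-limit (1 if means are
equal, 0 otherwise).

## Twin matching

Each neuron's *twin* is the reference cell minimizing Euclidean distance
among **neuronal** reference cells with the **same** region ID — exact
1-nearest-neighbor (k-d tree, no approximation), constrained to the
neuron's finest assigned region. The region constraint removes spurious
cross-boundary matches; a configurable roll-up level is available. Distance
ties are broken by the lexicographically smallest cell ID, making matching
deterministic and order-invariant. Non-neuronal reference cells are
excluded before matching; neurons in regions absent from the reference are
returned unmatched with a reason code, never silently dropped.

Because the reference covers one hemisphere, neurons on the other side are
reflected across a midline plane (default: half the annotation volume's
extent along the mediolateral axis; configurable), assuming bilateral
symmetry. Match-distance QC reports the 50/90/99% quantiles and counts
beyond 40 and 100 µm.

E/I ratio is the glutamatergic fraction divided by the GABAergic fraction
of matched neurons per scope region and brain; a zero GABAergic denominator
is flagged undefined rather than propagated as infinity.

**Accuracy caveat.** Spatial matching can only recover cell types that are
spatially organized. The invariant encoded in the tests: with types
segregated into clusters separated by several times their spread, planted
labels are recovered with accuracy >= 0.95; with types fully interleaved,
accuracy falls to the per-region majority-class baseline. Real cortical
layer 2/3, where subtypes are tightly mixed, sits near the second regime;
thalamic and hypothalamic nuclei sit near the first.

## Active connectivity

`W = diag(n) . rho . diag(n)` with the diagonal zeroed: the object of
interest is inter-regional communication, so within-region weight is
excluded by default (`keep_diagonal` for sensitivity). `rho` is used as
published — no row re-normalization — and counts are raw per-brain counts,
so W has units of neurons² x density and scales exactly quadratically when
counts scale. Density regions without counts get n = 0 (their row and
column vanish); counted regions absent from the density matrix are dropped
from the network, both with logged warnings. Per-condition matrices are
entry-wise means over that condition's brains.

## Network metrics

*Modularity.* W is directed, so Q is the directed Newman–Leicht
generalization with resolution gamma (out-strength x in-strength null
model). The one-community partition at gamma = 1 scores exactly 0; Q is
non-increasing in gamma at fixed partition. Module detection runs
networkx's directed Louvain `restarts` times (node orders seeded from one
integer seed), keeps the best candidate by our Q — including the singleton
and one-community baselines, so the returned Q never falls below either —
and breaks Q-ties by the lexicographically smallest canonical labeling.
The default gamma sweep is 21 points on [0.5, 2.0].

*Betweenness.* Edge length is `1/W` (strong connections are short), the
standard choice in weighted brain-network analysis; `neglog`
(`log(w_max/w)`) is available behind a flag. Node betweenness counts
all ordered source-target pairs with fractional credit for equal-length
paths, reported raw and normalized by `(R-1)(R-2)`; networks with fewer
than 3 nodes return all zeros by contract. Entries below `1e-12 x max(W)`
are treated as absent edges to avoid pathological near-infinite lengths.
Hub ranking averages betweenness per region across a condition's brains
(descending, ties alphabetical); set centrality (e.g. over the packaged
core DMN list `abn/data/dmn.txt`) is the per-brain mean over the set,
summarized per condition as mean ± sd.

By construction, every quantity in this module is invariant to `W -> cW`
for any c > 0 — partitions, Q values, centralities, and rankings are
unchanged — so a global increase in connection strength cannot change the
inferred network structure. This is asserted in the tests.

## Synthetic data generator

The generator emulates the statistical structure of the study's inputs at
fixture scale: 4 time windows x 3 brains x 5000 neurons per brain, a
24-region network (8 cortical areas with 6 layers each, 16 subcortical
nuclei, plus 3 excluded-division leaves that receive 3% of neurons to
exercise the exclusion path), a 60 000-cell single-hemisphere reference
(15% non-neuronal), and a 4-block density matrix. These sizes are large
enough for stable ratios and small enough for seconds-scale runs; they are
also the sizes at which the acceptance measurements are made.

Planted effects, chosen to mirror the qualitative structure the analysis
should detect:

- cortical share of in-scope neurons 0.50 / 0.40 / 0.30 / 0.45 across the
  four windows (a strong rest-onset vs. active-onset contrast);
- layer-5 share of cortical neurons 0.25 in three windows, 0.40 at the
  last window (end-of-dark-period L5 enrichment);
- per-region neurotransmitter mixes, including an almost purely GABAergic
  thalamic nucleus (RT, 0.98) and a dopaminergic-rich midbrain nucleus
  (VTA, 0.65) as matching-validation targets; cortical layers default to
  0.85 glutamatergic except layer 1 (0.90 GABAergic);
- spatial segregation of types defaults to 1.0 in subcortical nuclei
  (tight per-type Gaussian clusters spaced ~6 sd apart) and 0.3 in
  cortical layers (mostly interleaved), reflecting where spatial matching
  is and is not reliable; fully controllable per region;
- density blocks with a 10:1 within/between contrast and ±20% entry noise;
  optionally a bridge region strongly connected to all blocks (a planted
  betweenness hub).

Geometry is a lattice of 200 µm cubic parcels (50 µm voxels) in the left
half of the volume, mirrored onto the right; the midline is half the
x-extent. Neurons land in either hemisphere (p = 0.5), reference cells
only in the left. One seed drives everything through fixed-purpose
substreams (`[seed, k]`), so identical configs give byte-identical files
and adding a generator does not shift existing outputs.

**What passing tests show, and don't.** Recovery of planted effects shows
the estimators are unbiased and correctly calibrated under the generator's
assumptions: multinomial sampling of regions/layers/types, uniform or
Gaussian-cluster placement, no segmentation error, no registration error,
no spatial autocorrelation of activity within a region. Real data violate
all of these to some degree; in particular, passing the matching-accuracy
test under planted segregation says nothing about regions where real cell
types are intermixed (the interleaved test documents exactly that failure
mode), and the pipeline's statistical power at the real study's brain
counts is not established by these tests.

## Pipeline

`abn run` executes assign -> stats -> match -> connect -> network; stages
communicate only through documented CSV/JSON formats, a failed stage skips
its dependents but not independent stages, and the run manifest records
input checksums, seed, version, and per-stage row counts. Manifests contain
no timestamps, so identical inputs reproduce byte-identical outputs (the
run log carries timings instead).

## Known limitations

- The matcher transfers only the labels carried by the reference table; no
  expression-level imputation or taxonomy assignment.
- Counts (not ratios) enter W; with strongly varying totals, per-brain W
  magnitudes differ widely. All network metrics are scale-invariant, so
  this affects only quantities reported in W's units (total strength).
- Betweenness is computed on the thresholded graph; in near-complete
  uniform networks betweenness is degenerately zero and hub ranking falls
  back to the alphabetical tie rule.
- The voxel lookup assumes neurons are already registered to the atlas
  frame; registration error translates directly into boundary
  misassignment.
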