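# Methods

This note documents the models and numerical choices behind `fourc`: what
each processing step assumes, which parameters matter, what the synthetic
locus generator does and does not emulate, and where the design was
genuinely open.

## Fragment model

A chromosome is tiled by the fragments between consecutive occurrences of
the primary restriction enzyme's recognition sequence (NlaIII, `CATG`, in
the classical 4C protocol). Boundaries are placed at the **first base** of
each occurrence; the enzyme's true cut offset within the site is not
modelled, because a constant offset shifts every boundary identically and
cancels out of every per-fragment statistic. Occurrences are found by
scanning every position, so overlapping occurrences (e.g. `CATGCATG`)
each produce a boundary; `N` bases never match. A fragment is *blind*
when it contains no secondary-enzyme site (DpnII, `GATC`) fully within
its interval; the flag is carried through the pipeline and exposed as a
filter, but nothing is silently dropped — whether blind fragments should
be excluded from quantification is left to the caller.

Coordinates are 0-based half-open everywhere internally; BED and bedGraph
files are read and written in their on-disk conventions without shifting.
A read is an unstranded single position and is assigned to the unique
fragment containing it; out-of-bounds reads are counted and logged, never
silently ignored.

## Signal processing

**Random-library correction.** The correction divides raw counts by a
bait-free control library (BAC-derived in the original protocol) that
shares the fragment-specific capture and amplification biases:
s_f = raw_f / random_f. Fragments where the random library is zero or
outside its coverage interval are marked `UNCOVERED`; fragments
intersecting a blacklist are `ABERRANT`. The default blacklist holds the
three known aberrant mm9 fragments (chr2:74,597,000-74,597,732;
chr2:74,608,796-74,609,312; chr11:95,999,958-96,000,916) and only
applies on maps whose chromosome name matches.

**Masking discipline.** Masked fragments (viewpoint-proximal, aberrant,
uncovered, excluded) carry zero signal and are excluded — not imputed —
from every downstream sum, mean and correlation. The viewpoint mask
default is ±2 fragments around the bait; the original analyses shade a
region around each viewpoint without stating its width, so the halfwidth
is an explicit parameter.

**Normalization.** OK-fragment signal is scaled to sum to 10⁶. The
constant is arbitrary: every statistic in the package (ranks, ratios,
fractions, correlations) is invariant to global rescaling, which is
verified by test. Consequently no claim is made of numerically matching
tracks produced by other normalization conventions.

**Log2 ratios.** r_f = log2(a_f + c) − log2(b_f + c) on jointly OK
fragments, computed as a difference of logarithms so that swapping the
inputs negates the track exactly, bit for bit. The pseudocount default is
c = 1 on the per-million scale; zero-handling is not specified by the
upstream methodology, so c is a parameter and c ≤ 0 is rejected whenever
either track contains zeros.

**Smoothing.** The running mean (default window 11 fragments, matching
the published display convention) is centred; near array edges the window
shrinks symmetrically rather than zero-padding, and masked fragments are
skipped rather than averaged in. Skipping matters at region boundaries:
when the cluster is excluded before a long-range analysis, no cluster
signal leaks into the desert-edge windows.

## Compartment calling and the preference G-test

The compartment interval is the smallest contiguous fragment interval
containing the bait that captures at least a fraction (default 0.8) of
the total OK signal, grown one fragment at a time toward whichever flank
currently offers more signal (left wins exact ties, making the call
deterministic). The rule is monotone in the threshold. This calling rule
is this package's own construction — published figures draw compartment
boundaries matching the chromatin-mark domain without printing an
algorithm — so the threshold is exposed, and any externally defined
interval (e.g. a ChIP-domain extent) can be supplied instead wherever an
inside/outside partition is needed.

Fragments with r_f > 0 are labelled positive in condition A, r_f < 0 in
condition B; exact zeros are "tied" and excluded from the 2×2 table so
cells stay integral. Independence of location and preference is tested
with the G-test: G = 2·Σ O·ln(O/E), E from margin products, zero cells
contributing nothing, df = 1 for 2×2, p from the χ² upper tail. Williams'
continuity correction is available but off by default. A zero margin
makes the test undefined and raises.

## 4C × ChIP correlation

Each fragment fully inside the analysis region receives the
length-weighted mean ChIP coverage over its interval (uncovered bases
count as zero); fragments straddling the region edge are excluded.
Spearman's ρ is computed as Pearson on mid-ranks (ties share their mean
rank), via `scipy.stats.spearmanr`; an independent longhand rank oracle
guards it in the tests. The correlation table flags, per 4C profile, the
highest-correlating ChIP sample — the machine-readable analogue of
bolding the best match. No p-values are attached.

## Long-range analysis

Tropism is the split of desert-directed signal:
p_cen = Σ_cen s̃_f / (Σ_cen s̃_f + Σ_tel s̃_f), with the cluster excluded
and the remaining profile smoothed (window 11) before summation; raw
mode is a flag. Fractions are over fragments, not base pairs, since all
signal upstream is per-fragment. Viewpoint clustering computes pairwise
Spearman ρ over the desert fragments of the smoothed profiles, converts
to distance 1 − ρ, and applies average linkage (UPGMA); "conventional
hierarchical clustering" fixes neither linkage nor distance, so both are
stated here and the linkage is a parameter of `scipy.cluster.hierarchy`
under the hood. Dendrograms export to Newick.

## Virtual 4C

The virtual profile of a viewpoint interval is the sum of the Hi-C matrix
rows of every bin overlapping it, with those bins masked and the rest
normalized to sum to one. Multi-bin viewpoints are, pre-normalization,
exactly additive in their single-bin profiles. 4C profiles are binned to
matching resolution by base-pair-overlap splitting, conserving totals.
The comparison statistic (desert-bin Spearman ρ plus each profile's
tropism) is rank-based, so neither matrix balancing (ICE/KR) nor the
choice of global versus per-row normalization affects it; none is
applied. The sparse text format is a (bin_i, bin_j, count) triple list
with a bin-table BED.

## The synthetic locus model

`SimulationModel` generates every input from one parameterisation of a
silent-Hox-like locus: a cluster of `n_cluster` fragments (default 120)
split at `boundary` (default 60) into a negative and a positive
compartment, flanked by gene deserts of 400 fragments each side.

For a bait in compartment c, the bias-free contact mass is

    cluster:  m_f ∝ [1 if same compartment else α] · (1 + d)^(−γ)
              mixed with a uniform within-cluster floor (2%)
    deserts:  total desert mass 1 − cluster_mass, split exactly
              τ : (1 − τ) telomeric : centromeric; within a desert,
              (1 + d_edge)^(−γ_desert) mixed with a 15% uniform floor

with defaults α = 0.05, γ = 1, γ_desert = 0.5, τ = 0.5, cluster_mass
= 0.82. The gentler desert decay reflects that long-range desert
contacts are broad TAD-wide plateaus rather than sharply bait-centred;
it also keeps desert-edge fragments weaker than compartment-edge
fragments, as observed profiles show. Folding the background floor into
each region's mass (rather than adding a global floor afterwards) makes
the telomeric desert share exactly τ by construction, so tropism
recovery has an exact generative truth. Reads are multinomial at fixed
depth (default 10⁵) over p_f ∝ bias_f · m_f with lognormal(σ = 0.5)
fragment biases; the random library is multinomial (default depth 10⁶)
over the biases alone, so correction cancels the bias in expectation.
Sequences are built so that digestion reproduces the intended map
exactly: boundary sites are inserted verbatim and fragment bodies are
sampled base by base under the constraint that no stray primary or
secondary site can form, including across junctions.

ChIP tracks are per-fragment coverage: the repressive-like track is a
two-level step (high over the negative compartment), the active-like
track is baseline with narrow peaks at every sixth positive-compartment
fragment, both plus clipped Gaussian noise. Hi-C expected counts combine
(1 + |i − j|)^(−γ) decay with block attenuation — 1 within each of the
three TADs, `hic_cross_tad` (default 0.1) scaled by the 2τ/2(1 − τ)
split for cluster-desert blocks so the cluster row reproduces the
model's tropism, and 0.02 between deserts — Poisson-sampled on the upper
triangle and mirrored, at 32-kb bins (the final bin is clipped when the
resolution does not divide the span).

**What the generator does not emulate:** self-ligation and undigested
bait artefacts (hence compartment calling needs no viewpoint masking on
synthetic data, while real data does), PCR duplicates, mappability,
read-level errors, replicate structure, and any polymer physics. Passing
recovery tests therefore demonstrates that the estimators invert this
generative model at realistic depths — not that they are robust to every
artefact of real libraries.

## Problem sizes and determinism

All recovery analyses run on the default 920-fragment locus at 10⁵ reads
per viewpoint with 20 replicate seeds; the G-test calibration uses 1,000
simulated null tables of 200 fragments; exactness checks enumerate all
34,810 2×2 tables with margins ≤ 20. Every stochastic step consumes a
`numpy.random.default_rng` seed explicitly, and all outputs are pure
functions of (model, seed).

## Known limitations

- Single-chromosome analyses: trans contacts are out of scope, as in the
  fragment-level methodology this implements.
- One compartment interval per viewpoint; no multi-domain segmentation.
- The greedy compartment call assumes a unimodal signal mass around the
  bait; profiles with detached high-signal islands can stall its
  expansion short of the stated fraction.
- bigWig is not read or written; tracks move as bedGraph/BED text.
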