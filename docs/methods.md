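# Methods

This note documents the models, defaults and design choices behind the
package, and what the synthetic validation does and does not establish.

## Subtractive enrichment model

The pipeline assumes two pulldown conditions (treatment vs control) with
replicate label-free runs, and treats specificity as a deterministic
filtering rule rather than a hypothesis test: an entity is
treatment-specific when its fold change and total treatment evidence both
clear thresholds. There are deliberately no p-values at this stage — the
rule set is auditable and its operating characteristics are measured by
simulation instead.

Protein abundance is NSAF: spectral counts divided by molecular weight,
renormalized to sum to 1 per run. The phrase "normalized to total number
of IDs and molecular weight" that this index operationalizes is mildly
ambiguous (total spectra vs number of distinct proteins per run), but the
alternative reading only rescales each run by a constant and therefore
cannot change any fold change across conditions with equal run counts; NSAF
is the standard index consistent with both normalizers.

Defaults (`ThresholdPolicy`): protein fold ≥ 2 on NSAF condition means,
≥ 6 raw treatment spectra; site fold on mean raw counts (sites have no
molecular weight, so no NSAF analogue exists at site level), threshold
mean + 2·s.d. (sample s.d., n−1) of the finite fold changes or a fixed
ninefold floor — both rules are provided because a published ninefold
cutoff and a data-derived mean + 2 s.d. cutoff coincide only approximately
on any given dataset; ≥ 2 treatment spectra. Entities absent from control
have infinite fold change and satisfy any fold criterion: the biology of a
subtractive design is dominated by control-absent identifications, so
mapping 0-denominators to failure would discard the main signal. A
pseudocount mode (add c to both condition means) exists but is off by
default. All comparisons are inclusive (≥), matching "at least" semantics.
The s.d. rule is computed on the linear fold-change scale by default (a
log2 option exists) because the fixed-fold semantics it replaces are
linear. Sites are filtered after peptide→site aggregation (summing counts
per run over rows sharing accession and position); filtering at raw
peptide granularity instead is a read-level choice, not a config flag.

## Synthetic count model

Counts are negative binomial via a gamma–Poisson mixture with
`Var = m + φ·m²`; φ = 0 recovers Poisson exactly. The default φ = 0.01
(variance/mean ≈ 1.1 at the default baseline mean of 10) models the modest
extra-Poisson variation of biological replicates from a single cell line
processed in parallel; clearly noisier designs can be simulated by raising
φ (the overdispersion sanity test uses φ = 0.3). The default study shape is
2,000 proteins × (3 + 3) runs with 200 proteins enriched 8-fold in
treatment; non-enriched proteins form a contaminant background identical
across conditions, giving the filter realistic negatives. Molecular
weights are uniform on 10–300 kDa; they affect NSAF but not ground truth.

What this generator does *not* emulate: peptide-level missingness,
run-to-run normalization drift, shared-peptide protein inference, and
correlated contamination structure. Passing the recovery tests therefore
shows the filter implements its rule correctly and performs well under
idealized replicate noise — not that the thresholds are optimal for any
particular instrument or protocol.

## Phosphosites, hop structure and planted motifs

Simulated sites are assigned to proteins uniformly at random over the
interactome (preferential-attachment graphs, which reproduce the
hub-containing heavy-tailed degree structure of curated PPI networks, and
are connected by construction). Each site's residue is drawn from an
S/T/Y profile indexed by the protein's geodesic hop distance from a seed
node; profiles must cover every occurring hop (a `-1` key is an explicit
catch-all). The default profiles put pY ≈ 23% at ≤ 1 hop decaying to 5%
deep in the network, so the whole-dataset mixture lands near the canonical
~82/11/7 S/T/Y split of compartment phosphoproteomes. Hop bands for
composition are cumulative (≤ k), because "within k interactions" is the
natural reading of neighbourhood claims; exact-hop bands are emitted for
diagnostics, and the seed's own sites are never counted in its
neighbourhood. Distances are computed on the detected subgraph by default
(configurable), since neighbourhood sizes are usually quoted over
identified proteins.

A configurable fraction of sites copy a substrate window from a kinase
model (residue class respected), with independent per-position mutation;
the generating kinase is recorded in the ground truth.

## Term enrichment

The tail probability is computed with exact integer binomial coefficients
(`math.comb`), so it is exact to float rounding; tests cross-check against
both subset enumeration (all universes N ≤ 12) and `scipy.stats.hypergeom`.
EASE replaces the overlap k by k−1 (floored at 0), which can only increase
the tail. Bonferroni's m counts terms with non-zero query overlap — the
behaviour of chart-style reports — and is configurable to all annotated
terms. Term hierarchies are not modelled; annotation maps are flat sets
over an explicit universe, because the background construction of any
specific ontology service is environment-dependent and should be an input,
not an assumption.

## Kinase scoring and calibration

Scores are additive BLOSUM62 similarity summed over the 15 window
positions and averaged over a kinase's substrate windows; terminus gap
symbols contribute 0. BLOSUM62 is bundled as a plain-text table (the
matrix is data, not code). The bundled kinase library is synthetic —
idealized proline-directed, basophilic and tyrosine consensus substrates —
intended for simulation and demos, not curated biology; real substrate
libraries load from the same TSV format.

Cutoffs are empirical background quantiles: the smallest observed score t
with `P(score > t) ≤ target FPR`, ties broken upward so a run of equal
scores at the boundary is excluded rather than admitted. Targets default
to 2% (S/T) and 4% (Y). Strictly-greater passing matches "cutoff"
semantics: a score exactly at the cutoff does not pass. Calibration
requires ≥ 100 background windows of the matching residue class; the
pipeline uses the windows of non-passing candidate sites topped up with
random windows (uniform amino-acid composition), and the source is a
logged, configurable choice. Because the held-out FPR is an empirical
fraction at finite n, the calibration contract is checked as realized
FPR ≤ 1.5 × target.

The known-substrate validator classifies each curated (site, kinase) pair
as correct / different family member (optional credit) / kinase not in
tool / no prediction; pairs whose site only received passing calls
unrelated to the known kinase's family fall in "no prediction", since the
four-way scheme has no separate bucket for unrelated calls.

## Pipeline and problem sizes

A run is a pure function of its YAML config (paths, thresholds, seed); no
stage reads hidden state, outputs carry the stage name, config hash and
seed in a header comment, and no timestamps are written, so reruns are
byte-identical. The demo generator produces a 300-protein study; the
validation suite uses 2,000 proteins for filter recovery, 3,000 sites for
the hop gradient, 500 sites for motif recovery, and exhaustive enumeration
up to N = 12 for the hypergeometric oracle — sizes chosen so each check is
statistically decisive (binomial 99% CIs, 20-seed aggregates) while the
whole suite stays fast.

## Known limitations

- Accessions are opaque strings; namespace harmonization is the caller's
  job (a two-column mapping hook is provided).
- The filter is deterministic: no uncertainty is attached to a pass/fail
  call, and no multiple-testing notion applies at the filtering stage.
- The group-based kinase scorer is a transparent reimplementation of the
  scoring idea, not of any specific tool's trained matrices or
  hierarchical group/family levels; per-kinase site counts are therefore
  not comparable to any particular tool's output.
- Real interactomes are noisy and release-dependent; hop statistics should
  be read as relative gradients, not absolute neighbourhood sizes.
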