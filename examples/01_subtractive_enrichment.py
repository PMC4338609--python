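"""Subtractive spectral-count enrichment on a simulated two-condition study.

Simulates a 2,000-protein pulldown experiment (3 treatment + 3 control
replicates) in which 200 proteins are 8-fold enriched in the treatment
condition, then recovers them with the NSAF-based subtractive filter
(>= 2-fold enrichment and >= 6 treatment spectra).
"""

from phosphoadhesome import SimulationDesign, enrichment, simulate_counts

design = SimulationDesign(
    n_proteins=2000, n_enriched=200, enrichment_factor=8.0, baseline_mean=10.0, seed=1
)
matrix, truth = simulate_counts(design)

nsaf = enrichment.normalize(matrix)
results = enrichment.filter_proteins(enrichment.protein_fold_changes(nsaf, matrix))
passing = enrichment.passing_ids(results)

tp = len(passing & truth.enriched_accessions)
print(f"proteins passing the filter : {len(passing)}")
print(f"true enriched recovered     : {tp}/{len(truth.enriched_accessions)} "
      f"(sensitivity {tp / len(truth.enriched_accessions):.2f})")
print(f"false discoveries           : {len(passing) - tp} "
      f"(FDP {(len(passing) - tp) / len(passing):.3f})")
# Sensitivity near 1 with FDP near 0 means the two gates (fold change on
# normalized abundance + raw-spectra floor) separate the designed signal
# from the shared contaminant background almost perfectly at this effect size.
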