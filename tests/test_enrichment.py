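"""NSAF normalization, fold changes and the subtractive filters."""

import math

import numpy as np
import pandas as pd
import pytest

from phosphoadhesome import enrichment
from phosphoadhesome.enrichment import ThresholdPolicy
from phosphoadhesome.io import (
    CONTROL,
    TREATMENT,
    PhosphositeRecord,
    RunInfo,
    SpectralCountMatrix,
)
from tests.conftest import make_runs, random_matrix, random_sites


def _matrix(counts: dict, mw: dict, runs=None) -> SpectralCountMatrix:
    runs = runs or make_runs(1)
    df = pd.DataFrame(counts, index=[r.run_id for r in runs]).T
    df.index.name = "accession"
    return SpectralCountMatrix(
        counts=df, molecular_weight=pd.Series(mw), runs=runs
    )


def test_nsaf_hand_computed_example():
    """SC/MW shares: A=8/50=0.16, B=2/100=0.02 -> 0.888.../0.111..."""
    runs = [RunInfo("treatment_A", TREATMENT, "A")]
    m = _matrix({"A": [8], "B": [2]}, {"A": 50.0, "B": 100.0}, runs)
    nsaf = enrichment.normalize(m)
    assert nsaf.loc["A", "treatment_A"] == pytest.approx(0.16 / 0.18)
    assert nsaf.loc["B", "treatment_A"] == pytest.approx(0.02 / 0.18)


def test_nsaf_single_protein_is_one_and_scale_invariant(rng):
    runs = [RunInfo("treatment_A", TREATMENT, "A")]
    m = _matrix({"A": [7]}, {"A": 88.0}, runs)
    assert enrichment.normalize(m).loc["A", "treatment_A"] == 1.0

    m1 = random_matrix(rng, n_proteins=6)
    m10 = SpectralCountMatrix(
        counts=m1.counts * 10, molecular_weight=m1.molecular_weight, runs=m1.runs
    )
    pd.testing.assert_frame_equal(enrichment.normalize(m1), enrichment.normalize(m10))


def test_nsaf_all_zero_run_is_fatal():
    runs = make_runs(1)
    m = _matrix({"A": [0, 3], "B": [0, 1]}, {"A": 50.0, "B": 60.0}, runs)
    with pytest.raises(ValueError, match="treatment_A"):
        enrichment.normalize(m)


def test_protein_fold_change_ratio_null_and_infinite():
    runs = make_runs(1)
    m = _matrix({"A": [3, 1], "B": [5, 5], "C": [4, 0]}, {"A": 1.0, "B": 1.0, "C": 1.0}, runs)
    nsaf = enrichment.normalize(m)
    res = {r.entity_id: r for r in enrichment.protein_fold_changes(nsaf, m)}
    # identical MWs: NSAF ratios reduce to count-share ratios
    assert res["B"].fold_change == pytest.approx((5 / 12) / (5 / 6))
    assert math.isinf(res["C"].fold_change) and res["C"].control_absent


def test_protein_fold_change_identical_runs_give_fc_one(rng):
    runs = make_runs(2)
    counts = rng.integers(1, 20, size=5)
    m = _matrix(
        {f"P{i}": [c] * 4 for i, c in enumerate(counts)},
        {f"P{i}": 50.0 for i in range(5)},
        runs,
    )
    for r in enrichment.protein_fold_changes(enrichment.normalize(m), m):
        assert r.fold_change == pytest.approx(1.0)


def test_protein_filter_boundaries_are_inclusive():
    res = enrichment.EnrichmentResult(
        entity_id="A", mean_treatment=0.2, mean_control=0.1,
        fold_change=2.0, total_treatment_spectra=6,
    )
    out = enrichment.filter_proteins([res])[0]
    assert out.passes and out.fail_reason == "none"


def test_protein_filter_abundance_gate():
    res = enrichment.EnrichmentResult(
        entity_id="A", mean_treatment=0.5, mean_control=0.05,
        fold_change=10.0, total_treatment_spectra=5,
    )
    out = enrichment.filter_proteins([res])[0]
    assert not out.passes and out.fail_reason == "below_abundance"


def test_protein_filter_fold_gate_and_infinite_pass():
    below = enrichment.EnrichmentResult("A", 0.15, 0.1, 1.5, 20)
    inf = enrichment.EnrichmentResult("B", 0.1, 0.0, math.inf, 20, control_absent=True)
    out = enrichment.filter_proteins([below, inf])
    assert not out[0].passes and out[0].fail_reason == "below_fold"
    assert out[1].passes


def test_site_threshold_hand_computed_example():
    """FCs [2,2,2,2,2,20]: mean 5, sample sd sqrt(54), threshold 5+2*sqrt(54)."""
    thr = enrichment.site_fold_threshold([2, 2, 2, 2, 2, 20])
    assert thr == pytest.approx(5 + 2 * math.sqrt(54))
    assert thr == pytest.approx(19.6969, abs=1e-3)


def test_site_threshold_degenerate_and_fixed_rules():
    assert enrichment.site_fold_threshold([4.0, 4.0, 4.0]) == pytest.approx(4.0)
    fixed = ThresholdPolicy(site_fold_rule="fixed")
    assert enrichment.site_fold_threshold([1.0, 100.0], fixed) == 9.0
    with pytest.raises(ValueError, match="fixed"):
        enrichment.site_fold_threshold([math.inf, 3.0])


def test_site_threshold_excludes_infinite_fold_changes():
    thr = enrichment.site_fold_threshold([2, 2, 2, 2, 2, 20, math.inf])
    assert thr == pytest.approx(5 + 2 * math.sqrt(54))


def _site(acc, pos, t_counts, c_counts, runs):
    t_runs = [r.run_id for r in runs if r.condition == TREATMENT]
    c_runs = [r.run_id for r in runs if r.condition == CONTROL]
    counts = dict(zip(t_runs, t_counts)) | dict(zip(c_runs, c_counts))
    return PhosphositeRecord(
        accession=acc, position=pos, residue="S", window="AAAAAAASAAAAAAA", counts=counts
    )


def test_site_filter_control_absent_with_min_spectra_passes():
    runs = make_runs(3)
    sites = [
        _site("P1", 10, [2, 0, 0], [0, 0, 0], runs),
        _site("P2", 11, [3, 2, 1], [1, 1, 1], runs),
        _site("P3", 12, [4, 1, 1], [1, 1, 1], runs),
    ]
    results, _ = enrichment.filter_sites(sites, runs)
    by_id = {r.entity_id: r for r in results}
    assert by_id["P1:10"].passes  # infinite fold + 2 treatment spectra


def test_site_filter_fixed_ninefold_rejects_8_9():
    runs = make_runs(1)
    policy = ThresholdPolicy(site_fold_rule="fixed")
    sites = [_site("P1", 10, [89], [10], runs)]
    results, thr = enrichment.filter_sites(sites, runs, policy)
    assert thr == 9.0
    assert results[0].fold_change == pytest.approx(8.9)
    assert not results[0].passes and results[0].fail_reason == "below_fold"


def brute_force_protein_pass(matrix: SpectralCountMatrix, policy: ThresholdPolicy) -> set[str]:
    """Independent re-derivation of the protein filter from first principles."""
    t_runs = [r.run_id for r in matrix.runs if r.condition == TREATMENT]
    c_runs = [r.run_id for r in matrix.runs if r.condition == CONTROL]
    passing = set()
    for acc in matrix.proteins:
        shares_t, shares_c = [], []
        for run in t_runs + c_runs:
            denom = sum(
                matrix.counts.loc[q, run] / matrix.molecular_weight[q]
                for q in matrix.proteins
            )
            share = (matrix.counts.loc[acc, run] / matrix.molecular_weight[acc]) / denom
            (shares_t if run in t_runs else shares_c).append(share)
        mt = sum(shares_t) / len(shares_t)
        mc = sum(shares_c) / len(shares_c)
        if mt == 0 and mc == 0:
            continue
        fold_ok = mc == 0 or mt / mc >= policy.protein_min_fold
        spectra = sum(matrix.counts.loc[acc, r] for r in t_runs)
        if mt > 0 and fold_ok and spectra >= policy.protein_min_spectra:
            passing.add(acc)
    return passing


def brute_force_site_pass(sites, runs, policy: ThresholdPolicy) -> set[str]:
    """Independent re-derivation of the site filter, including the sd rule."""
    t_runs = [r.run_id for r in runs if r.condition == TREATMENT]
    c_runs = [r.run_id for r in runs if r.condition == CONTROL]
    stats = {}
    for rec in sites:
        mt = sum(rec.counts.get(r, 0) for r in t_runs) / len(t_runs)
        mc = sum(rec.counts.get(r, 0) for r in c_runs) / len(c_runs)
        if mt == 0 and mc == 0:
            continue
        fc = math.inf if mc == 0 else mt / mc
        stats[f"{rec.accession}:{rec.position}"] = (fc, int(mt * len(t_runs) + 0.5))
    if policy.site_fold_rule == "fixed":
        thr = policy.site_fixed_fold
    else:
        finite = [fc for fc, _ in stats.values() if math.isfinite(fc)]
        mean = sum(finite) / len(finite)
        sd = math.sqrt(sum((x - mean) ** 2 for x in finite) / (len(finite) - 1))
        thr = mean + policy.sd_multiplier * sd
    return {
        sid
        for sid, (fc, spectra) in stats.items()
        if (math.isinf(fc) or fc >= thr) and spectra >= policy.site_min_spectra
    }


def test_protein_filter_matches_bruteforce_on_random_tables():
    policy = ThresholdPolicy()
    for seed in range(40):
        r = np.random.default_rng(seed)
        m = random_matrix(r, n_proteins=int(r.integers(2, 11)), max_count=12)
        res = enrichment.filter_proteins(
            enrichment.protein_fold_changes(enrichment.normalize(m), m, policy), policy
        )
        assert enrichment.passing_ids(res) == brute_force_protein_pass(m, policy)


def test_site_filter_matches_bruteforce_on_random_tables():
    for seed in range(40):
        r = np.random.default_rng(seed)
        policy = ThresholdPolicy(
            site_fold_rule="fixed" if seed % 2 else "mean_plus_2sd"
        )
        sites, runs = random_sites(r, n=int(r.integers(3, 11)))
        try:
            results, _ = enrichment.filter_sites(sites, runs, policy)
        except ValueError:
            continue  # <2 finite fold changes under the sd rule
        assert enrichment.passing_ids(results) == brute_force_site_pass(sites, runs, policy)


def test_increasing_treatment_counts_never_flips_pass_to_fail(rng):
    """Monotonicity: more treatment spectra can only help a protein."""
    policy = ThresholdPolicy()
    for seed in range(20):
        r = np.random.default_rng(seed)
        m = random_matrix(r, n_proteins=6, max_count=15)
        target = m.proteins[0]
        run = m.run_ids(TREATMENT)[0]

        def passes(matrix):
            res = enrichment.filter_proteins(
                enrichment.protein_fold_changes(enrichment.normalize(matrix), matrix, policy),
                policy,
            )
            return {x.entity_id: x.passes for x in res}.get(target, False)

        before = passes(m)
        bumped = m.counts.copy()
        bumped.loc[target, run] += int(r.integers(1, 10))
        m2 = SpectralCountMatrix(
            counts=bumped, molecular_weight=m.molecular_weight, runs=m.runs
        )
        if before:
            assert passes(m2)


def test_results_frame_renders_inf_token():
    res = [enrichment.EnrichmentResult("A", 0.1, 0.0, math.inf, 8, True, "none", True)]
    df = enrichment.results_frame(res)
    assert df.loc[0, "fold_change"] == "Inf"
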