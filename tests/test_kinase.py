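"""Window scoring, FPR calibration, prediction and known-substrate recovery."""

import math

import numpy as np
import pytest

from phosphoadhesome import kinase, simulate
from phosphoadhesome.io import PhosphositeRecord
from phosphoadhesome.kinase import KinaseModel
from phosphoadhesome.simulate import SimulationDesign


@pytest.fixture(scope="module")
def matrix():
    return kinase.load_substitution_matrix()


def test_bundled_matrix_matches_biopython_blosum62(matrix):
    """Independent cross-check of the bundled table against Bio.Align's copy."""
    from Bio.Align import substitution_matrices

    ref = substitution_matrices.load("BLOSUM62")
    for a in "ACDEFGHIKLMNPQRSTVWY":
        for b in "ACDEFGHIKLMNPQRSTVWY":
            assert matrix[(a, b)] == ref[a][b]


def test_self_similarity_score(matrix):
    w = "AAAAAAASAAAAAAA"
    model = KinaseModel("K1", "other", "ST", [w])
    # BLOSUM62: A/A = 4, S/S = 4 -> 15 positions x 4
    assert kinase.score_window(w, model, matrix) == 60.0


def test_single_substitution_score(matrix):
    model = KinaseModel("K1", "other", "ST", ["AAAAAAASAAAAAAA"])
    assert kinase.score_window("CAAAAAASAAAAAAA", model, matrix) == 56.0  # A/C = 0


def test_score_is_mean_over_substrates(matrix):
    m1 = KinaseModel("K1", "other", "ST", ["AAAAAAASAAAAAAA"])
    m2 = KinaseModel("K2", "other", "ST", ["CAAAAAASAAAAAAA"])
    both = KinaseModel("K3", "other", "ST", m1.substrate_windows + m2.substrate_windows)
    w = "AAAAAAASAAAAAAA"
    s1 = kinase.score_window(w, m1, matrix)
    s2 = kinase.score_window(w, m2, matrix)
    assert kinase.score_window(w, both, matrix) == pytest.approx((s1 + s2) / 2)


def test_gap_positions_score_zero(matrix):
    model = KinaseModel("K1", "other", "ST", ["AAAAAAASAAAAAAA"])
    assert kinase.score_window("-AAAAAASAAAAAAA", model, matrix) == 56.0


def test_incompatible_central_residue_rejected(matrix):
    model = KinaseModel("K1", "other", "ST", ["AAAAAAASAAAAAAA"])
    with pytest.raises(ValueError, match="incompatible"):
        kinase.score_window("AAAAAAAYAAAAAAA", model, matrix)


def _window_key(j: int) -> str:
    """A syntactically valid ST-centred window carrying an integer tag."""
    return f"AAAAAAAS{j:07d}"


def test_calibrate_order_statistics(matrix, monkeypatch):
    """1..100 distinct scores, 2% target -> cutoff at the 98th score."""
    model = KinaseModel("K", "other", "ST", ["AAAAAAASAAAAAAA"])
    lookup = {_window_key(j): float(j + 1) for j in range(100)}
    monkeypatch.setattr(kinase, "score_window", lambda w, m, mat: lookup[w])
    thr = kinase.calibrate_threshold(model, list(lookup), 0.02, matrix)
    assert thr == 98.0


def test_calibrate_extreme_targets(matrix, monkeypatch):
    model = KinaseModel("K", "other", "ST", ["AAAAAAASAAAAAAA"])
    lookup = {_window_key(j): float(j) for j in range(150)}
    monkeypatch.setattr(kinase, "score_window", lambda w, m, mat: lookup[w])
    windows = list(lookup)
    assert kinase.calibrate_threshold(model, windows, 1.0, matrix) == -math.inf
    assert kinase.calibrate_threshold(model, windows, 0.0, matrix) == 149.0


def test_calibrate_requires_enough_backgrounds(matrix):
    model = KinaseModel("K", "other", "ST", ["AAAAAAASAAAAAAA"])
    with pytest.raises(ValueError, match="100"):
        kinase.calibrate_threshold(model, ["AAAAAAASAAAAAAA"] * 10, 0.02, matrix)


def test_calibrate_tie_breaking_is_conservative(matrix, monkeypatch):
    """With ties at the top score, the cutoff rises to absorb them."""
    model = KinaseModel("K", "other", "ST", ["AAAAAAASAAAAAAA"])
    # 90 windows at score 1, 10 tied at score 5: P(>5)=0 <= 2%, P(>1)=0.1
    lookup = {_window_key(j): (5.0 if j < 10 else 1.0) for j in range(100)}
    monkeypatch.setattr(kinase, "score_window", lambda w, m, mat: lookup[w])
    thr = kinase.calibrate_threshold(model, list(lookup), 0.02, matrix)
    assert thr == 5.0  # the tied mass itself sits at, not above, the cutoff


def test_residue_class_firewall(matrix):
    rng = np.random.default_rng(0)
    st_model = KinaseModel("ST_K", "other", "ST", ["AAAAAAASAAAAAAA"], threshold=-1e9)
    y_model = KinaseModel("Y_K", "TK", "Y", ["AAAAAAAYAAAAAAA"], threshold=-1e9)
    sites = [
        PhosphositeRecord("P1", 1, "S", "AAAAAAASAAAAAAA", {"treatment_A": 1}),
        PhosphositeRecord("P1", 2, "Y", "AAAAAAAYAAAAAAA", {"treatment_A": 1}),
    ]
    preds = kinase.predict(sites, [st_model, y_model], matrix)
    assigned = {(p.position, p.kinase_id) for p in preds}
    assert assigned == {(1, "ST_K"), (2, "Y_K")}


def test_prediction_requires_calibration(matrix):
    model = KinaseModel("K", "other", "ST", ["AAAAAAASAAAAAAA"])
    site = PhosphositeRecord("P1", 1, "S", "AAAAAAASAAAAAAA", {"treatment_A": 1})
    with pytest.raises(ValueError, match="calibrated"):
        kinase.predict([site], [model], matrix)


def test_planted_substrate_passes_its_kinase(matrix):
    """A site whose window equals a substrate beats the calibrated cutoff."""
    rng = np.random.default_rng(5)
    models = [m for m in kinase.load_kinase_library() if m.kinase_id == "PKA_SYN"]
    bg = kinase.random_background_windows(500, "ST", rng)
    kinase.calibrate_all(models, bg, matrix)
    w = models[0].substrate_windows[0]
    site = PhosphositeRecord("P1", 1, w[7], w, {"treatment_A": 1})
    preds = kinase.predict([site], models, matrix)
    assert any(p.kinase_id == "PKA_SYN" for p in preds)


def test_motif_recovery_with_mutation(matrix):
    """Planted, lightly mutated motifs are assigned to the right kinase."""
    names = ("CDK1_SYN", "PKA_SYN", "SRC_SYN")
    models = [m for m in kinase.load_kinase_library() if m.kinase_id in names]
    g = simulate.simulate_interactome(100, seed=11)
    recs, truth = simulate.simulate_phosphosites(
        SimulationDesign(seed=11), g, "P0001", n_sites=200,
        kinase_models=models, motif_fraction=0.6, mutation_prob=0.1,
        rng=np.random.default_rng(11),
    )
    rng = np.random.default_rng(11)
    bg = kinase.random_background_windows(400, "ST", rng) + kinase.random_background_windows(
        400, "Y", rng
    )
    kinase.calibrate_all(models, bg, matrix)
    top = kinase.top_predictions(kinase.predict(recs, models, matrix))
    planted = {k: v["kinase"] for k, v in truth.site_truth.items() if v["kinase"]}
    correct = sum(1 for s, kid in planted.items() if s in top and top[s].kinase_id == kid)
    assert correct / len(planted) >= 0.8


def test_validate_known_trivial_cases():
    models = [KinaseModel("K1", "other", "ST", ["AAAAAAASAAAAAAA"], family="F1", threshold=0.0)]
    known = [(("P1", 1), "MISSING_K")]
    report = kinase.validate_known([], known, models)
    assert report.counts["kinase_not_in_tool"] == 1

    preds = [kinase.SitePrediction("P1", 1, "K1", 10.0, 0.0)]
    report = kinase.validate_known(preds, [(("P1", 1), "K1")], models)
    assert report.fraction_correct == 1.0


def test_validate_known_family_credit():
    models = [
        KinaseModel("K1", "other", "ST", ["AAAAAAASAAAAAAA"], family="F1", threshold=0.0),
        KinaseModel("K2", "other", "ST", ["AAAAAAATAAAAAAA"], family="F1", threshold=0.0),
    ]
    preds = [kinase.SitePrediction("P1", 1, "K2", 5.0, 0.0)]
    with_credit = kinase.validate_known(preds, [(("P1", 1), "K1")], models, family_credit=True)
    assert with_credit.counts["different_family_member"] == 1
    without = kinase.validate_known(preds, [(("P1", 1), "K1")], models, family_credit=False)
    assert without.counts["no_prediction"] == 1


def test_validate_known_matches_bruteforce(rng):
    models = [
        KinaseModel(f"K{i}", "other", "ST", ["AAAAAAASAAAAAAA"],
                    family=f"F{i % 2}", threshold=0.0)
        for i in range(4)
    ]
    ids = [m.kinase_id for m in models] + ["ABSENT"]
    fams = {m.kinase_id: m.family for m in models}
    for seed in range(20):
        r = np.random.default_rng(seed)
        preds = [
            kinase.SitePrediction(f"P{r.integers(0, 5)}", int(r.integers(1, 4)),
                                  str(r.choice(ids[:-1])), 1.0, 0.0)
            for _ in range(10)
        ]
        known = [
            ((f"P{r.integers(0, 5)}", int(r.integers(1, 4))), str(r.choice(ids)))
            for _ in range(8)
        ]
        known = list({site: k for site, k in known}.items())
        report = kinase.validate_known(preds, known, models)
        hits = {}
        for p in preds:
            hits.setdefault((p.accession, p.position), set()).add(p.kinase_id)
        for site, kid in known:
            if kid == "ABSENT":
                expected = "kinase_not_in_tool"
            elif kid in hits.get(site, set()):
                expected = "correct"
            elif any(fams[h] == fams[kid] for h in hits.get(site, set())):
                expected = "different_family_member"
            else:
                expected = "no_prediction"
            assert report.categories[site] == expected


def test_library_models_are_well_formed():
    models = kinase.load_kinase_library()
    assert {m.residue_class for m in models} == {"ST", "Y"}
    for m in models:
        for w in m.substrate_windows:
            assert len(w) == 15 and w[7] in m.residue_class
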