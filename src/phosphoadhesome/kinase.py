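"""Group-based kinase–substrate prediction over ±7-residue site windows.

A kinase model is a set of known substrate 15-mers.  A candidate site window
is scored as the mean, over substrates, of the summed substitution-matrix
similarity at the 15 aligned positions (BLOSUM62 by default; terminus gap
symbols score 0).  Each kinase's score cutoff is calibrated on background
windows to a target empirical false-positive rate — the fraction of
background windows that would (falsely) exceed it — with separate
conventional targets for serine/threonine (2%) and tyrosine (4%) kinases.
A site passes a kinase strictly above the cutoff; multiple kinases may pass
one site, ranked by margin over their cutoffs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from math import inf
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GAP, WINDOW_CENTER, WINDOW_LENGTH, PhosphositeRecord

logger = logging.getLogger(__name__)

MIN_BACKGROUND_WINDOWS = 100

#: Conventional high-stringency FPR targets by kinase residue class.
DEFAULT_TARGET_FPR = {"ST": 0.02, "Y": 0.04}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def load_substitution_matrix(path: str | Path | None = None) -> dict[tuple[str, str], float]:
    """Load a square substitution matrix from a whitespace-separated table.

    Defaults to the bundled BLOSUM62.  Pairs involving the window gap symbol
    score 0.
    """
    if path is None:
        source = resources.files("phosphoadhesome.data").joinpath("blosum62.txt")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    alphabet = lines[0].split()
    matrix: dict[tuple[str, str], float] = {}
    for line in lines[1:]:
        fields = line.split()
        row = fields[0]
        for col, value in zip(alphabet, fields[1:]):
            matrix[(row, col)] = float(value)
    for sym in alphabet:
        matrix[(GAP, sym)] = 0.0
        matrix[(sym, GAP)] = 0.0
    matrix[(GAP, GAP)] = 0.0
    return matrix


@dataclass
class KinaseModel:
    """A named kinase with substrate windows and a calibrated cutoff."""

    kinase_id: str
    group: str
    residue_class: str  # "ST" or "Y"
    substrate_windows: list[str]
    family: str = ""
    threshold: float | None = None
    calibrated_fpr: float | None = None

    def __post_init__(self) -> None:
        if self.residue_class not in {"ST", "Y"}:
            raise ValueError(f"{self.kinase_id}: residue_class must be 'ST' or 'Y'")
        if not self.substrate_windows:
            raise ValueError(f"{self.kinase_id}: at least one substrate window required")
        for w in self.substrate_windows:
            if len(w) != WINDOW_LENGTH:
                raise ValueError(f"{self.kinase_id}: substrate window {w!r} is not 15 long")
            if w[WINDOW_CENTER] not in self.residue_class:
                raise ValueError(
                    f"{self.kinase_id}: substrate centre {w[WINDOW_CENTER]!r} "
                    f"does not match residue class {self.residue_class}"
                )

    def compatible(self, residue: str) -> bool:
        return residue in self.residue_class


def score_window(
    window: str, model: KinaseModel, matrix: dict[tuple[str, str], float]
) -> float:
    """Mean over substrates of the position-summed substitution similarity."""
    if window[WINDOW_CENTER] not in model.residue_class:
        raise ValueError(
            f"window centre {window[WINDOW_CENTER]!r} incompatible with "
            f"{model.kinase_id} ({model.residue_class})"
        )
    total = 0.0
    for substrate in model.substrate_windows:
        total += sum(matrix[(a, b)] for a, b in zip(window, substrate))
    return total / len(model.substrate_windows)


def calibrate_threshold(
    model: KinaseModel,
    background_windows: list[str],
    target_fpr: float,
    matrix: dict[tuple[str, str], float],
) -> float:
    """Smallest background score t with P(background score > t) <= target.

    The empirical quantile breaks ties upward (conservative: a run of equal
    scores at the boundary pushes the cutoff up rather than letting them
    through).  Sets ``model.threshold`` and ``model.calibrated_fpr``.
    """
    compatible = [w for w in background_windows if w[WINDOW_CENTER] in model.residue_class]
    if len(compatible) < MIN_BACKGROUND_WINDOWS:
        raise ValueError(
            f"{model.kinase_id}: need >= {MIN_BACKGROUND_WINDOWS} background windows "
            f"of class {model.residue_class}, got {len(compatible)}"
        )
    if target_fpr >= 1.0:
        model.threshold, model.calibrated_fpr = -inf, target_fpr
        return -inf
    scores = np.sort([score_window(w, model, matrix) for w in compatible])
    n = len(scores)
    threshold = scores[-1]
    for i, t in enumerate(scores):
        # fraction strictly above scores[i]; ties with t sit at or below it
        above = n - np.searchsorted(scores, t, side="right")
        if above / n <= target_fpr:
            threshold = float(t)
            break
    model.threshold = float(threshold)
    model.calibrated_fpr = target_fpr
    return float(threshold)


@dataclass
class SitePrediction:
    """A passing kinase call for one site."""

    accession: str
    position: int
    kinase_id: str
    score: float
    threshold: float

    @property
    def margin(self) -> float:
        return self.score - self.threshold


def predict(
    sites: list[PhosphositeRecord],
    models: list[KinaseModel],
    matrix: dict[tuple[str, str], float] | None = None,
) -> list[SitePrediction]:
    """Score every compatible (site, kinase) pair; keep strict-pass calls.

    A site may collect several passing kinases (shared-substrate residues are
    expected); predictions for each site are ordered by margin over the
    cutoff, best first.  Models must be calibrated.
    """
    if matrix is None:
        matrix = load_substitution_matrix()
    for model in models:
        if model.threshold is None:
            raise ValueError(f"model {model.kinase_id} has no calibrated threshold")
    out: list[SitePrediction] = []
    for rec in sites:
        hits = []
        for model in models:
            if not model.compatible(rec.residue):
                continue
            score = score_window(rec.window, model, matrix)
            if score > model.threshold:
                hits.append(
                    SitePrediction(
                        accession=rec.accession,
                        position=rec.position,
                        kinase_id=model.kinase_id,
                        score=score,
                        threshold=model.threshold,
                    )
                )
        hits.sort(key=lambda p: p.margin, reverse=True)
        out.extend(hits)
    return out


def top_predictions(predictions: list[SitePrediction]) -> dict[tuple[str, int], SitePrediction]:
    """Best (largest-margin) passing kinase per site."""
    best: dict[tuple[str, int], SitePrediction] = {}
    for p in predictions:
        key = (p.accession, p.position)
        if key not in best or p.margin > best[key].margin:
            best[key] = p
    return best


CATEGORY_CORRECT = "correct"
CATEGORY_NOT_IN_TOOL = "kinase_not_in_tool"
CATEGORY_FAMILY = "different_family_member"
CATEGORY_NO_PREDICTION = "no_prediction"


@dataclass
class ValidationReport:
    """Known-substrate recovery tallies."""

    categories: dict[tuple[str, int], str]
    counts: dict[str, int]
    fraction_correct: float


def validate_known(
    predictions: list[SitePrediction],
    known_pairs: list[tuple[tuple[str, int], str]],
    models: list[KinaseModel],
    family_credit: bool = True,
) -> ValidationReport:
    """Classify each known (site, kinase) pair against the predictions.

    Categories: ``correct`` (the known kinase passed for the site),
    ``kinase_not_in_tool`` (the known kinase has no model),
    ``different_family_member`` (with ``family_credit``: another model of the
    same family passed), ``no_prediction`` (residual — no passing call, or
    only calls unrelated to the known kinase's family).
    """
    by_id = {m.kinase_id: m for m in models}
    passed: dict[tuple[str, int], set[str]] = {}
    for p in predictions:
        passed.setdefault((p.accession, p.position), set()).add(p.kinase_id)
    categories: dict[tuple[str, int], str] = {}
    for site, kinase_id in known_pairs:
        if kinase_id not in by_id:
            categories[site] = CATEGORY_NOT_IN_TOOL
            continue
        hits = passed.get(site, set())
        if kinase_id in hits:
            categories[site] = CATEGORY_CORRECT
        elif family_credit and by_id[kinase_id].family and any(
            by_id[h].family == by_id[kinase_id].family for h in hits if h in by_id
        ):
            categories[site] = CATEGORY_FAMILY
        else:
            categories[site] = CATEGORY_NO_PREDICTION
    counts = {
        c: sum(1 for v in categories.values() if v == c)
        for c in (CATEGORY_CORRECT, CATEGORY_NOT_IN_TOOL, CATEGORY_FAMILY, CATEGORY_NO_PREDICTION)
    }
    total = len(categories)
    return ValidationReport(
        categories=categories,
        counts=counts,
        fraction_correct=counts[CATEGORY_CORRECT] / total if total else 0.0,
    )


def random_background_windows(
    n: int, residue_class: str, rng: np.random.Generator
) -> list[str]:
    """Random 15-mers with a class-matching central residue (uniform AAs)."""
    centers = list(residue_class)
    windows = []
    for _ in range(n):
        chars = rng.choice(list(AMINO_ACIDS), size=WINDOW_LENGTH)
        chars[WINDOW_CENTER] = centers[rng.integers(len(centers))]
        windows.append("".join(chars))
    return windows


def load_kinase_library(path: str | Path | None = None) -> list[KinaseModel]:
    """Load kinase models from a TSV (kinase_id, group, family, residue_class,
    substrate_window; one row per substrate window).

    The bundled default library is synthetic: a handful of kinases with
    idealized consensus substrates (proline-directed CDK-like, basophilic
    PKA-like and CAMK2-like, and an SH2-era SRC-like tyrosine kinase) meant
    for simulation and demonstration, not curated biology.
    """
    if path is None:
        source = resources.files("phosphoadhesome.data").joinpath("synthetic_kinases.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    models = []
    for (kid, group, family, rclass), sub in df.groupby(
        ["kinase_id", "group", "family", "residue_class"], sort=True
    ):
        models.append(
            KinaseModel(
                kinase_id=kid,
                group=group,
                family=family,
                residue_class=rclass,
                substrate_windows=sorted(sub["substrate_window"]),
            )
        )
    return models


def calibrate_all(
    models: list[KinaseModel],
    background_windows: list[str],
    matrix: dict[tuple[str, str], float] | None = None,
    target_fpr_by_class: dict[str, float] | None = None,
) -> list[KinaseModel]:
    """Calibrate every model at its class's target FPR; returns the models."""
    if matrix is None:
        matrix = load_substitution_matrix()
    targets = target_fpr_by_class or DEFAULT_TARGET_FPR
    for model in models:
        calibrate_threshold(model, background_windows, targets[model.residue_class], matrix)
        logger.info(
            "%s calibrated: threshold %.2f at FPR %.3f",
            model.kinase_id, model.threshold, model.calibrated_fpr,
        )
    return models
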