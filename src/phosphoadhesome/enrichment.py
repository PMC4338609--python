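"""Subtractive spectral-count comparison: NSAF, fold changes and filters.

Protein abundance per run is the normalized spectral abundance factor,

    NSAF_{p,r} = (SC_{p,r} / MW_p) / sum_q (SC_{q,r} / MW_q),

which sums to 1 over the proteins of each run.  A protein is called
treatment-specific when its fold change (mean treatment NSAF over mean
control NSAF, across replicates) is at least ``protein_min_fold`` and it
accumulates at least ``protein_min_spectra`` raw spectra over the treatment
runs.  Phosphosites are filtered on mean raw spectral counts per condition
with their own fold threshold — either a fixed fold or mean + k·s.d. of the
finite site fold-change distribution — and a minimum treatment spectra gate.
Entities absent from the control condition have infinite fold change and
satisfy any fold criterion; all boundary comparisons are inclusive
("at least").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import CONTROL, TREATMENT, PhosphositeRecord, RunInfo, SpectralCountMatrix

logger = logging.getLogger(__name__)

FAIL_NONE = "none"
FAIL_BELOW_FOLD = "below_fold"
FAIL_BELOW_ABUNDANCE = "below_abundance"


@dataclass(frozen=True)
class ThresholdPolicy:
    """Pass/fail thresholds for the subtractive comparison.

    Defaults encode the canonical rule set: proteins need >= 2-fold
    enrichment and >= 6 treatment spectra; sites need >= 2 treatment spectra
    and a fold threshold that is either fixed (ninefold) or mean + 2 s.d. of
    the finite fold changes.  ``pseudocount`` (off by default) is added to
    both condition means before the ratio.
    """

    protein_min_fold: float = 2.0
    protein_min_spectra: int = 6
    site_min_spectra: int = 2
    site_fold_rule: str = "mean_plus_2sd"  # or "fixed"
    site_fixed_fold: float = 9.0
    sd_multiplier: float = 2.0
    pseudocount: float = 0.0
    log_scale_sd: bool = False

    def __post_init__(self) -> None:
        if self.protein_min_fold <= 0 or self.site_fixed_fold <= 0:
            raise ValueError("fold thresholds must be positive")
        if self.protein_min_spectra <= 0 or self.site_min_spectra <= 0:
            raise ValueError("spectra thresholds must be positive")
        if self.site_fold_rule not in {"fixed", "mean_plus_2sd"}:
            raise ValueError(f"unknown site_fold_rule {self.site_fold_rule!r}")


@dataclass
class EnrichmentResult:
    """Per-entity means, fold change and pass/fail state with reason."""

    entity_id: str
    mean_treatment: float
    mean_control: float
    fold_change: float
    total_treatment_spectra: int
    passes: bool = False
    fail_reason: str = FAIL_NONE
    control_absent: bool = False


def normalize(matrix: SpectralCountMatrix) -> pd.DataFrame:
    """Compute per-run NSAF values (columns sum to 1)."""
    totals = matrix.counts.sum(axis=0)
    zero_runs = totals.index[totals == 0].tolist()
    if zero_runs:
        raise ValueError(f"run {zero_runs[0]!r} has no spectral counts; cannot normalize")
    saf = matrix.counts.div(matrix.molecular_weight, axis=0)
    return saf.div(saf.sum(axis=0), axis=1)


def _fold_change(mean_t: float, mean_c: float, pseudocount: float = 0.0) -> float:
    if pseudocount > 0:
        return (mean_t + pseudocount) / (mean_c + pseudocount)
    if mean_c == 0:
        return math.inf if mean_t > 0 else math.nan
    return mean_t / mean_c


def protein_fold_changes(
    nsaf: pd.DataFrame, matrix: SpectralCountMatrix, policy: ThresholdPolicy | None = None
) -> list[EnrichmentResult]:
    """Fold changes of mean treatment NSAF over mean control NSAF.

    Proteins with zero abundance in both conditions are dropped (logged).
    Raw (unnormalized) treatment spectra are totalled for the abundance gate.
    """
    policy = policy or ThresholdPolicy()
    t_runs = matrix.run_ids(TREATMENT)
    c_runs = matrix.run_ids(CONTROL)
    if not t_runs or not c_runs:
        raise ValueError("both a treatment and a control run are required")
    mean_t = nsaf[t_runs].mean(axis=1)
    mean_c = nsaf[c_runs].mean(axis=1)
    raw_t = matrix.counts[t_runs].sum(axis=1)

    results = []
    n_dropped = 0
    for acc in nsaf.index:
        mt, mc = float(mean_t[acc]), float(mean_c[acc])
        fc = _fold_change(mt, mc, policy.pseudocount)
        if math.isnan(fc) or (mt == 0 and mc == 0):
            n_dropped += 1
            continue
        results.append(
            EnrichmentResult(
                entity_id=acc,
                mean_treatment=mt,
                mean_control=mc,
                fold_change=fc,
                total_treatment_spectra=int(raw_t[acc]),
                control_absent=(mc == 0 and mt > 0),
            )
        )
    if n_dropped:
        logger.info("dropped %d protein(s) absent from both conditions", n_dropped)
    return results


def filter_proteins(
    results: list[EnrichmentResult], policy: ThresholdPolicy | None = None
) -> list[EnrichmentResult]:
    """Apply the protein fold and minimum-spectra gates (inclusive bounds)."""
    policy = policy or ThresholdPolicy()
    return [_apply_gates(r, policy.protein_min_fold, policy.protein_min_spectra) for r in results]


def _apply_gates(r: EnrichmentResult, min_fold: float, min_spectra: int) -> EnrichmentResult:
    if r.total_treatment_spectra < min_spectra:
        return replace(r, passes=False, fail_reason=FAIL_BELOW_ABUNDANCE)
    if not (math.isinf(r.fold_change) or r.fold_change >= min_fold):
        return replace(r, passes=False, fail_reason=FAIL_BELOW_FOLD)
    return replace(r, passes=True, fail_reason=FAIL_NONE)


def site_fold_threshold(
    fold_changes: list[float], policy: ThresholdPolicy | None = None
) -> float:
    """Site fold threshold under the configured rule.

    ``mean_plus_2sd`` returns mean + k × sample s.d. (n−1 denominator) of the
    finite fold changes (infinite values are excluded from the distribution;
    they satisfy the fold criterion regardless).  On the log-scale option the
    mean and s.d. are taken on log2 fold changes and the threshold mapped back.
    """
    policy = policy or ThresholdPolicy()
    if policy.site_fold_rule == "fixed":
        return policy.site_fixed_fold
    finite = [fc for fc in fold_changes if math.isfinite(fc)]
    if len(finite) < 2:
        raise ValueError(
            "mean_plus_2sd threshold needs at least 2 finite fold changes; "
            "use site_fold_rule='fixed'"
        )
    if policy.log_scale_sd:
        logs = np.log2(finite)
        return float(2 ** (logs.mean() + policy.sd_multiplier * logs.std(ddof=1)))
    arr = np.asarray(finite, dtype=float)
    return float(arr.mean() + policy.sd_multiplier * arr.std(ddof=1))


def site_fold_changes(
    records: list[PhosphositeRecord], runs: list[RunInfo], policy: ThresholdPolicy | None = None
) -> list[EnrichmentResult]:
    """Per-site fold changes on mean raw spectral counts per condition.

    Sites carry no molecular-weight normalization: the comparison is on mean
    raw counts across the runs of each condition.
    """
    policy = policy or ThresholdPolicy()
    t_runs = [r.run_id for r in runs if r.condition == TREATMENT]
    c_runs = [r.run_id for r in runs if r.condition == CONTROL]
    if not t_runs or not c_runs:
        raise ValueError("both a treatment and a control run are required")
    results = []
    n_dropped = 0
    for rec in records:
        mt = rec.total_count(t_runs) / len(t_runs)
        mc = rec.total_count(c_runs) / len(c_runs)
        fc = _fold_change(mt, mc, policy.pseudocount)
        if math.isnan(fc) or (mt == 0 and mc == 0):
            n_dropped += 1
            continue
        results.append(
            EnrichmentResult(
                entity_id=f"{rec.accession}:{rec.position}",
                mean_treatment=mt,
                mean_control=mc,
                fold_change=fc,
                total_treatment_spectra=rec.total_count(t_runs),
                control_absent=(mc == 0 and mt > 0),
            )
        )
    if n_dropped:
        logger.info("dropped %d site(s) absent from both conditions", n_dropped)
    return results


def filter_sites(
    records: list[PhosphositeRecord], runs: list[RunInfo], policy: ThresholdPolicy | None = None
) -> tuple[list[EnrichmentResult], float]:
    """Apply the site fold and minimum-spectra gates; returns (results, threshold)."""
    policy = policy or ThresholdPolicy()
    results = site_fold_changes(records, runs, policy)
    threshold = site_fold_threshold([r.fold_change for r in results], policy)
    gated = [_apply_gates(r, threshold, policy.site_min_spectra) for r in results]
    return gated, threshold


def passing_ids(results: list[EnrichmentResult]) -> set[str]:
    return {r.entity_id for r in results if r.passes}


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view; infinite fold changes rendered as the token ``Inf``."""
    df = pd.DataFrame(
        {
            "id": [r.entity_id for r in results],
            "mean_treatment": [r.mean_treatment for r in results],
            "mean_control": [r.mean_control for r in results],
            "fold_change": [
                "Inf" if math.isinf(r.fold_change) else r.fold_change for r in results
            ],
            "total_treatment_spectra": [r.total_treatment_spectra for r in results],
            "passes": [r.passes for r in results],
            "fail_reason": [r.fail_reason for r in results],
        }
    )
    return df
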