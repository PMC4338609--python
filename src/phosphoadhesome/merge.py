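"""Merging proteomic and phosphoproteomic catalogues; residue composition.

A "phosphoprotein" is any accession carrying at least one passing
phosphosite, whether or not the proteomic filter also detected it.  The
merged catalogue partitions accessions into proteomic-only, phospho-only and
both, and reports the percentage increase the phosphoproteomic arm adds over
the proteomic catalogue alone.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io import AdhesomeAnnotation, PhosphositeRecord


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (so 36.45 -> 36.5, not banker's 36.4).

    Goes through decimal so binary artefacts (82.35 stored as 82.3499…)
    do not flip the boundary direction.
    """
    from decimal import ROUND_HALF_UP, Decimal

    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class MergedCatalogue:
    """Venn partition of the proteomic and phosphoproteomic pass sets."""

    proteomic_only: set[str]
    phospho_only: set[str]
    both: set[str]
    sites_by_protein: dict[str, list[PhosphositeRecord]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return len(self.proteomic_only) + len(self.phospho_only) + len(self.both)

    @property
    def proteomic_set(self) -> set[str]:
        return self.proteomic_only | self.both

    @property
    def phospho_set(self) -> set[str]:
        return self.phospho_only | self.both

    @property
    def all_accessions(self) -> set[str]:
        return self.proteomic_only | self.phospho_only | self.both

    @property
    def increase_pct(self) -> float:
        """Percentage growth of the catalogue from merging in phospho-only hits."""
        n_prot = len(self.proteomic_set)
        if n_prot == 0:
            return float("inf") if self.phospho_only else 0.0
        return 100.0 * len(self.phospho_only) / n_prot


def merge_catalogues(
    proteomic_pass: set[str], site_pass: list[PhosphositeRecord]
) -> MergedCatalogue:
    """Merge the protein-filter pass set with proteins of passing sites."""
    sites_by_protein: dict[str, list[PhosphositeRecord]] = {}
    for rec in site_pass:
        sites_by_protein.setdefault(rec.accession, []).append(rec)
    phospho = set(sites_by_protein)
    return MergedCatalogue(
        proteomic_only=set(proteomic_pass) - phospho,
        phospho_only=phospho - set(proteomic_pass),
        both=set(proteomic_pass) & phospho,
        sites_by_protein=sites_by_protein,
    )


@dataclass
class AdhesomeSummary:
    """Adhesome membership tallies across the merged catalogue."""

    n_adhesome_total: int
    n_adhesome_proteomic_only: int
    n_adhesome_phospho_only: int
    n_adhesome_both: int
    n_adhesome_phosphorylated: int
    n_adhesome_sites: int
    max_sites_per_protein: int
    by_category: dict[str, dict[str, int]]


def crossref_adhesome(
    catalogue: MergedCatalogue, annotation: AdhesomeAnnotation
) -> AdhesomeSummary:
    """Tally adhesome members per Venn compartment and functional category."""
    adh = annotation.members
    detected_adh = catalogue.all_accessions & adh
    phospho_adh = catalogue.phospho_set & adh
    site_counts = {
        acc: len(recs) for acc, recs in catalogue.sites_by_protein.items() if acc in adh
    }
    by_category: dict[str, dict[str, int]] = {}
    for acc in sorted(detected_adh):
        cat = annotation.category(acc) or "other"
        entry = by_category.setdefault(
            cat, {"detected": 0, "phosphorylated": 0, "sites": 0}
        )
        entry["detected"] += 1
        if acc in phospho_adh:
            entry["phosphorylated"] += 1
            entry["sites"] += site_counts.get(acc, 0)
    return AdhesomeSummary(
        n_adhesome_total=len(detected_adh),
        n_adhesome_proteomic_only=len(catalogue.proteomic_only & adh),
        n_adhesome_phospho_only=len(catalogue.phospho_only & adh),
        n_adhesome_both=len(catalogue.both & adh),
        n_adhesome_phosphorylated=len(phospho_adh),
        n_adhesome_sites=sum(site_counts.values()),
        max_sites_per_protein=max(site_counts.values(), default=0),
        by_category=by_category,
    )


@dataclass
class ResidueComposition:
    """S/T/Y counts and percentages for a named protein subset."""

    label: str
    n_s: int
    n_t: int
    n_y: int

    @property
    def total(self) -> int:
        return self.n_s + self.n_t + self.n_y

    @property
    def defined(self) -> bool:
        return self.total > 0

    def percentages(self, ndigits: int = 1) -> tuple[float, float, float]:
        """(pS, pT, pY) in percent; zeros (with defined=False) when empty."""
        if not self.defined:
            return (0.0, 0.0, 0.0)
        return tuple(
            round_half_away(100.0 * n / self.total, ndigits)
            for n in (self.n_s, self.n_t, self.n_y)
        )


def residue_composition(
    sites: list[PhosphositeRecord], subset: set[str] | None = None, label: str = "all"
) -> ResidueComposition:
    """S/T/Y composition over sites whose accession is in ``subset`` (or all)."""
    counter = Counter(
        rec.residue for rec in sites if subset is None or rec.accession in subset
    )
    return ResidueComposition(
        label=label, n_s=counter.get("S", 0), n_t=counter.get("T", 0), n_y=counter.get("Y", 0)
    )
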