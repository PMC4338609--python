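"""Domain types and tabular/graph readers and writers.

All quantitative inputs are plain TSV/CSV with a header row.  Spectral-count
matrices hold one row per protein (columns ``accession``, ``molecular_weight``
and one column per MS run); phosphosite tables hold one row per
peptide-site observation and are aggregated to unique (accession, position)
records on read.  Interactomes are two-column edge lists; annotations are
keyed tabular files.

Run columns encode their condition in the column name: the text before the
first underscore must be ``treatment``/``control`` (the ligand aliases
``FN``/``Tf`` are accepted, case-insensitively).  Example header::

    accession  molecular_weight  FN_A  FN_B  FN_C  Tf_A  Tf_B  Tf_C
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

TREATMENT = "treatment"
CONTROL = "control"

#: Aliases accepted in run-column names, mapped to canonical conditions.
CONDITION_ALIASES = {
    "treatment": TREATMENT,
    "fn": TREATMENT,
    "control": CONTROL,
    "tf": CONTROL,
}

WINDOW_LENGTH = 15
#: 0-based index of the phosphorylated residue inside a sequence window.
WINDOW_CENTER = 7
#: Padding symbol used when a window extends past a protein terminus.
GAP = "-"

PHOSPHO_RESIDUES = frozenset("STY")

ADHESOME_CATEGORIES = frozenset(
    {
        "receptor",
        "adaptor",
        "actin_regulator",
        "actin",
        "GEF",
        "GAP",
        "kinase",
        "phosphatase",
        "other",
    }
)


def _sep(fmt: str) -> str:
    if fmt not in {"tsv", "csv"}:
        raise ValueError(f"unknown tabular format {fmt!r}; expected 'tsv' or 'csv'")
    return "\t" if fmt == "tsv" else ","


def parse_condition(run_id: str) -> str:
    """Return the canonical condition encoded in a run column name."""
    token = run_id.split("_", 1)[0].lower()
    try:
        return CONDITION_ALIASES[token]
    except KeyError:
        raise ValueError(
            f"run column {run_id!r} does not encode a condition: expected a "
            f"'treatment'/'control' (or 'FN'/'Tf') prefix before the first underscore"
        ) from None


@dataclass(frozen=True)
class RunInfo:
    """One MS run: identifier, condition and replicate label."""

    run_id: str
    condition: str
    replicate: str

    def __post_init__(self) -> None:
        if self.condition not in (TREATMENT, CONTROL):
            raise ValueError(
                f"run {self.run_id!r}: condition must be "
                f"'{TREATMENT}' or '{CONTROL}', got {self.condition!r}"
            )


def _runs_from_columns(run_columns: list[str]) -> list[RunInfo]:
    runs = []
    for rid in run_columns:
        cond = parse_condition(rid)
        rep = rid.split("_", 1)[1] if "_" in rid else rid
        runs.append(RunInfo(run_id=rid, condition=cond, replicate=rep))
    return runs


@dataclass
class SpectralCountMatrix:
    """Raw spectral counts per (protein, run) with protein molecular weights.

    ``counts`` is an integer DataFrame indexed by accession with one column
    per run; ``molecular_weight`` is in kDa.
    """

    counts: pd.DataFrame
    molecular_weight: pd.Series
    runs: list[RunInfo]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate accessions in count matrix: {dups}")
        run_ids = [r.run_id for r in self.runs]
        if list(self.counts.columns) != run_ids:
            raise ValueError("count columns do not match run metadata order")
        if len(set(run_ids)) != len(run_ids):
            raise ValueError("run_id values must be unique")
        for col in self.counts.columns:
            colvals = self.counts[col]
            bad = colvals[(colvals < 0) | (colvals != colvals.astype(int))]
            if len(bad):
                acc = bad.index[0]
                raise ValueError(
                    f"count for protein {acc!r}, run {col!r} is {bad.iloc[0]}: "
                    f"counts must be non-negative integers"
                )
        self.counts = self.counts.astype(int)
        missing = self.counts.index.difference(self.molecular_weight.index)
        if len(missing):
            raise ValueError(f"molecular weight missing for accession {missing[0]!r}")
        mw = self.molecular_weight.loc[self.counts.index].astype(float)
        if (mw <= 0).any() or mw.isna().any():
            acc = mw.index[(mw <= 0) | mw.isna()][0]
            raise ValueError(f"molecular weight for {acc!r} must be a positive number")
        self.molecular_weight = mw

    @property
    def proteins(self) -> list[str]:
        return list(self.counts.index)

    def run_ids(self, condition: str | None = None) -> list[str]:
        return [r.run_id for r in self.runs if condition is None or r.condition == condition]

    def write(self, path: str | Path, format: str = "tsv") -> None:
        df = self.counts.copy()
        df.insert(0, "molecular_weight", self.molecular_weight)
        df.index.name = "accession"
        df.to_csv(path, sep=_sep(format))


def read_spectral_counts(path: str | Path, format: str = "tsv") -> SpectralCountMatrix:
    """Read a protein × run spectral-count table.

    Raises ``ValueError`` naming the offending column/cell when the
    molecular-weight column is absent, a weight is missing or non-positive,
    or any count is negative or non-integral.
    """
    df = pd.read_csv(path, sep=_sep(format), comment="#")
    if "accession" not in df.columns:
        raise ValueError(f"{path}: required column 'accession' not found")
    if "molecular_weight" not in df.columns:
        raise ValueError(f"{path}: required column 'molecular_weight' not found")
    df = df.set_index("accession")
    run_cols = [c for c in df.columns if c != "molecular_weight"]
    if not run_cols:
        raise ValueError(f"{path}: no run columns found")
    mw = pd.to_numeric(df["molecular_weight"], errors="coerce")
    if mw.isna().any():
        acc = mw.index[mw.isna()][0]
        raise ValueError(f"{path}: molecular weight missing or non-numeric for {acc!r}")
    counts = df[run_cols].apply(pd.to_numeric)
    return SpectralCountMatrix(
        counts=counts, molecular_weight=mw, runs=_runs_from_columns(run_cols)
    )


@dataclass
class PhosphositeRecord:
    """A localized phosphorylation site and its per-run spectral counts.

    ``position`` is 1-based on the protein sequence (the field convention
    behind names like FAK pY397).  ``window`` is the 15-mer sequence context
    with the modified residue at the centre, padded with ``-`` at protein
    termini.  A score of −1 encodes infinite confidence.
    """

    accession: str
    position: int
    residue: str
    window: str
    counts: dict[str, int] = field(default_factory=dict)
    localization_score: float = -1.0
    identification_score: float = -1.0

    def __post_init__(self) -> None:
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValueError(
                f"{self.accession} position {self.position}: residue must be one of "
                f"S/T/Y, got {self.residue!r}"
            )
        if len(self.window) != WINDOW_LENGTH:
            raise ValueError(
                f"{self.accession} position {self.position}: window must be "
                f"{WINDOW_LENGTH} characters, got {len(self.window)}"
            )
        if self.window[WINDOW_CENTER] != self.residue:
            raise ValueError(
                f"{self.accession} position {self.position}: window centre "
                f"{self.window[WINDOW_CENTER]!r} does not match residue {self.residue!r}"
            )
        if self.position < 1:
            raise ValueError(f"{self.accession}: site position must be 1-based (>=1)")
        for run, c in self.counts.items():
            if c < 0 or int(c) != c:
                raise ValueError(
                    f"{self.accession} position {self.position}, run {run!r}: "
                    f"count {c} is not a non-negative integer"
                )

    @property
    def site_id(self) -> tuple[str, int]:
        return (self.accession, self.position)

    def total_count(self, run_ids: list[str] | None = None) -> int:
        if run_ids is None:
            return sum(self.counts.values())
        return sum(self.counts.get(r, 0) for r in run_ids)


def read_phosphosites(
    path: str | Path, format: str = "tsv"
) -> tuple[list[PhosphositeRecord], list[RunInfo]]:
    """Read a peptide/phosphosite table, aggregating to unique sites.

    Rows sharing (accession, position) — e.g. different peptide forms covering
    the same site — are merged by summing counts per run; the window and the
    best (most confident) scores are kept.  Total spectra are conserved.
    """
    df = pd.read_csv(path, sep=_sep(format), comment="#")
    required = {"accession", "position", "residue", "window"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: required column(s) missing: {sorted(missing)}")
    meta_cols = required | {"localization_score", "identification_score"}
    run_cols = [c for c in df.columns if c not in meta_cols]
    runs = _runs_from_columns(run_cols)

    merged: dict[tuple[str, int], PhosphositeRecord] = {}
    for _, row in df.iterrows():
        counts = {r: int(row[r]) for r in run_cols}
        rec = PhosphositeRecord(
            accession=str(row["accession"]),
            position=int(row["position"]),
            residue=str(row["residue"]),
            window=str(row["window"]),
            counts=counts,
            localization_score=float(row.get("localization_score", -1.0)),
            identification_score=float(row.get("identification_score", -1.0)),
        )
        key = rec.site_id
        if key in merged:
            prev = merged[key]
            if prev.residue != rec.residue:
                raise ValueError(
                    f"{path}: conflicting residues {prev.residue}/{rec.residue} "
                    f"for site {key}"
                )
            for r, c in rec.counts.items():
                prev.counts[r] = prev.counts.get(r, 0) + c
            # -1 means infinite confidence, so it dominates any finite score
            for attr in ("localization_score", "identification_score"):
                a, b = getattr(prev, attr), getattr(rec, attr)
                best = -1.0 if -1.0 in (a, b) else max(a, b)
                setattr(prev, attr, best)
        else:
            merged[key] = rec
    records = list(merged.values())
    logger.info("read %d site records (%d peptide rows) from %s", len(records), len(df), path)
    return records, runs


def write_phosphosites(
    records: list[PhosphositeRecord],
    runs: list[RunInfo],
    path: str | Path,
    format: str = "tsv",
) -> None:
    run_ids = [r.run_id for r in runs]
    rows = []
    for rec in records:
        row = {
            "accession": rec.accession,
            "position": rec.position,
            "residue": rec.residue,
            "window": rec.window,
            "localization_score": rec.localization_score,
            "identification_score": rec.identification_score,
        }
        row.update({r: rec.counts.get(r, 0) for r in run_ids})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep(format), index=False)


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a two-column edge list into a simple undirected graph.

    Self-loops are dropped (logged) and duplicate edges collapse; a line with
    a field count other than two is fatal, reported with its line number.
    """
    graph = nx.Graph()
    n_loops = 0
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-separated fields, got {len(fields)}"
                )
            a, b = fields
            n_lines += 1
            if a == b:
                n_loops += 1
                continue
            graph.add_edge(a, b)
    if n_loops:
        logger.info("%s: dropped %d self-loop(s)", path, n_loops)
    if n_lines == 0:
        logger.warning("%s: empty edge list", path)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


@dataclass
class AdhesomeAnnotation:
    """Adhesome membership and functional category per accession.

    Accessions absent from the table default to non-members.
    """

    categories: dict[str, str]

    def __post_init__(self) -> None:
        for acc, cat in self.categories.items():
            if cat not in ADHESOME_CATEGORIES:
                raise ValueError(
                    f"accession {acc!r}: category {cat!r} not in "
                    f"{sorted(ADHESOME_CATEGORIES)}"
                )

    def is_adhesome(self, accession: str) -> bool:
        return accession in self.categories

    def category(self, accession: str) -> str | None:
        return self.categories.get(accession)

    @property
    def members(self) -> set[str]:
        return set(self.categories)


def read_adhesome(path: str | Path, format: str = "tsv") -> AdhesomeAnnotation:
    df = pd.read_csv(path, sep=_sep(format), comment="#")
    for col in ("accession", "category"):
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} not found")
    return AdhesomeAnnotation(
        categories=dict(zip(df["accession"].astype(str), df["category"].astype(str)))
    )


def write_adhesome(annotation: AdhesomeAnnotation, path: str | Path) -> None:
    pd.DataFrame(
        sorted(annotation.categories.items()), columns=["accession", "category"]
    ).to_csv(path, sep="\t", index=False)


@dataclass
class TermAnnotationMap:
    """Flat term → member-set annotation over an explicit background universe."""

    terms: dict[str, set[str]]
    universe: set[str]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, members in self.terms.items():
            extra = members - self.universe
            if extra:
                raise ValueError(
                    f"term {term!r} has member(s) outside the universe, "
                    f"e.g. {sorted(extra)[0]!r}"
                )

    def name(self, term_id: str) -> str:
        return self.names.get(term_id, term_id)


def read_term_map(
    path: str | Path,
    universe: set[str] | None = None,
    names_path: str | Path | None = None,
    format: str = "tsv",
) -> TermAnnotationMap:
    """Read a two-column (term_id, accession) map.

    If ``universe`` is omitted the union of all members is used as background.
    """
    df = pd.read_csv(path, sep=_sep(format), comment="#")
    for col in ("term_id", "accession"):
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} not found")
    terms: dict[str, set[str]] = {}
    for term, acc in zip(df["term_id"].astype(str), df["accession"].astype(str)):
        terms.setdefault(term, set()).add(acc)
    if universe is None:
        universe = set().union(*terms.values()) if terms else set()
    names = {}
    if names_path is not None:
        ndf = pd.read_csv(names_path, sep=_sep(format), comment="#")
        names = dict(zip(ndf["term_id"].astype(str), ndf["name"].astype(str)))
    return TermAnnotationMap(terms=terms, universe=set(universe), names=names)


def write_term_map(annotation: TermAnnotationMap, path: str | Path) -> None:
    rows = [
        {"term_id": t, "accession": a}
        for t, members in sorted(annotation.terms.items())
        for a in sorted(members)
    ]
    pd.DataFrame(rows, columns=["term_id", "accession"]).to_csv(path, sep="\t", index=False)


def translate_ids(mapping_path: str | Path, accessions: list[str]) -> list[str]:
    """Translate accessions through an optional two-column (old, new) table.

    Accessions are otherwise opaque strings; this hook exists so data keyed in
    a retired identifier namespace can be rebased without touching the
    pipeline.  Unmapped accessions pass through unchanged.
    """
    df = pd.read_csv(mapping_path, sep="\t", header=None, names=["old", "new"], comment="#")
    table = dict(zip(df["old"].astype(str), df["new"].astype(str)))
    return [table.get(a, a) for a in accessions]
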