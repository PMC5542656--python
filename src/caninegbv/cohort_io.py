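"""Reading, validating, encoding and cross-tabulating cohort tables.

A cohort joins per-animal genotypes at the panel markers to ordinal hip
(CHD) and elbow (CED) dysplasia phenotypes.  Phenotypic classes 1-5 mirror
FCI grades A-E: class 1 is unaffected, class 5 severe.  Genotypes are stored
as unordered allele pairs ("A/G"); dosage encoding counts copies of the
CHD-associated allele.

The primary exchange format is CSV/TSV with one row per animal and columns
``animal_id, chd_class, ced_class, <marker_id>...``; ``.xlsx`` files in the
same layout are ingested via openpyxl (optionally with a column-heading map
for supplementary-table layouts).  Empty cells, ``NA`` and ``./.`` all mean
missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .marker_panel import MarkerDefinition, MarkerPanel

__all__ = [
    "CohortError",
    "Contingency2x2",
    "Cohort",
    "MISSING_TOKENS",
    "read_cohort",
    "write_cohort",
    "encode_dosage",
    "dosage_matrix",
    "dichotomize",
    "cross_tabulate",
    "contingency_2x2",
]

MISSING_TOKENS = frozenset({"", "NA", "./."})
_CLASSES = (1, 2, 3, 4, 5)
_SCHEMES = ("affected", "severe")


class CohortError(ValueError):
    """A cohort file or record is invalid."""


@dataclass(frozen=True)
class Contingency2x2:
    """2x2 count table in exposed/event layout.

    a = exposed & event, b = exposed & no event,
    c = unexposed & event, d = unexposed & no event.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise CohortError(f"counts must be non-negative integers, got {cells}")
        if sum(cells) == 0:
            raise CohortError("empty 2x2 table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


class Cohort:
    """Per-animal genotypes at the panel markers plus CHD/CED classes.

    Parameters
    ----------
    genotypes
        DataFrame indexed by animal_id with one column per panel marker,
        values ``"X/Y"`` allele-pair strings or NaN for missing calls.
    phenotypes
        DataFrame indexed by animal_id with nullable-integer columns
        ``chd_class`` and ``ced_class`` in 1..5.
    panel
        The marker panel the genotype columns refer to.
    """

    def __init__(
        self, genotypes: pd.DataFrame, phenotypes: pd.DataFrame, panel: MarkerPanel
    ) -> None:
        if genotypes.index.has_duplicates:
            dupes = genotypes.index[genotypes.index.duplicated()].unique().tolist()
            raise CohortError(f"duplicate animal_id: {dupes}")
        if len(genotypes) == 0:
            raise CohortError("empty cohort (no animals)")
        unknown = set(genotypes.columns) - set(panel.marker_ids)
        if unknown:
            raise CohortError(f"genotype columns not in panel: {sorted(unknown)}")
        phenotypes = phenotypes.reindex(genotypes.index)
        for col in ("chd_class", "ced_class"):
            if col not in phenotypes:
                phenotypes[col] = pd.array([pd.NA] * len(phenotypes), dtype="Int64")
            vals = pd.to_numeric(phenotypes[col], errors="raise").astype("Int64")
            bad = vals.dropna()[~vals.dropna().isin(_CLASSES)]
            if len(bad):
                raise CohortError(
                    f"{col} outside 1-5 for animals {bad.index.tolist()[:5]}"
                )
            phenotypes[col] = vals
        self._validate_alleles(genotypes, panel)
        self.genotypes = genotypes
        self.phenotypes = phenotypes[["chd_class", "ced_class"]]
        self.panel = panel

    @staticmethod
    def _validate_alleles(genotypes: pd.DataFrame, panel: MarkerPanel) -> None:
        for marker_id in genotypes.columns:
            marker = panel[marker_id]
            calls = genotypes[marker_id].dropna()
            for animal, call in calls.items():
                alleles = _split_call(call, marker_id)
                if alleles is None:
                    continue
                bad = set(alleles) - marker.alleles
                if bad:
                    raise CohortError(
                        f"animal {animal}, marker {marker_id}: allele(s) "
                        f"{sorted(bad)} not among {{{marker.wild_allele},"
                        f"{marker.mutant_allele}}}"
                    )

    @property
    def animal_ids(self) -> pd.Index:
        return self.genotypes.index

    @property
    def n_animals(self) -> int:
        return len(self.genotypes)


def _split_call(call: object, marker_id: str) -> tuple[str, str] | None:
    """Parse an "X/Y" allele pair; None for missing tokens."""
    if call is None or (isinstance(call, float) and np.isnan(call)):
        return None
    s = str(call).strip()
    if s in MISSING_TOKENS:
        return None
    parts = s.upper().split("/")
    if len(parts) != 2 or not all(len(p) == 1 for p in parts):
        raise CohortError(f"marker {marker_id}: malformed genotype call {call!r}")
    return parts[0], parts[1]


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path, dtype=str)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, dtype=str, comment="#")


def read_cohort(
    genotype_path: str | Path,
    panel: MarkerPanel,
    phenotype_path: str | Path | None = None,
    column_map: Mapping[str, str] | None = None,
) -> Cohort:
    """Read and validate a cohort from CSV/TSV/XLSX.

    Genotypes and phenotypes may live in one file (the default layout) or in
    two files joined on ``animal_id``.  ``column_map`` renames file headings
    to the canonical schema at ingest (for supplementary-table layouts).
    """
    genotype_path = Path(genotype_path)
    df = _read_table(genotype_path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    if phenotype_path is not None:
        pheno = _read_table(Path(phenotype_path))
        if column_map:
            pheno = pheno.rename(columns=dict(column_map))
        df = df.merge(pheno, on="animal_id", how="left")
    if "animal_id" not in df.columns:
        raise CohortError(f"{genotype_path}: no animal_id column")
    if len(df) == 0:
        raise CohortError(f"{genotype_path}: empty cohort file")
    df = df.set_index("animal_id")
    marker_cols = [c for c in df.columns if c in set(panel.marker_ids)]
    extra = set(df.columns) - set(marker_cols) - {"chd_class", "ced_class"}
    if extra:
        raise CohortError(f"unknown columns (not panel markers): {sorted(extra)}")
    geno = df[marker_cols].copy()
    for c in marker_cols:
        geno[c] = geno[c].map(
            lambda v: np.nan if v is None or str(v).strip() in MISSING_TOKENS else v,
            na_action="ignore",
        )
    pheno = df.reindex(columns=["chd_class", "ced_class"])
    pheno = pheno.mask(pheno.isin(list(MISSING_TOKENS)))
    return Cohort(geno, pheno, panel)


def write_cohort(cohort: Cohort, path: str | Path, header_comment: str | None = None) -> None:
    """Write a cohort in the canonical CSV/TSV layout (round-trips)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    out = pd.concat([cohort.phenotypes, cohort.genotypes], axis=1)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        out.to_csv(fh, sep=sep, index_label="animal_id")


def encode_dosage(
    call: object, marker: MarkerDefinition
) -> int | None:
    """Count of the CHD-associated (mutant) allele in a call: 0, 1 or 2.

    Symmetric in allele order; missing calls return None.
    """
    alleles = _split_call(call, marker.marker_id)
    if alleles is None:
        return None
    bad = set(alleles) - marker.alleles
    if bad:
        raise CohortError(
            f"marker {marker.marker_id}: allele(s) {sorted(bad)} not among "
            f"{{{marker.wild_allele},{marker.mutant_allele}}}"
        )
    return sum(a == marker.mutant_allele.upper() for a in alleles)


def dosage_matrix(cohort: Cohort, panel: MarkerPanel | None = None) -> pd.DataFrame:
    """Animals x markers matrix of mutant-allele dosages (Int64, NA = missing)."""
    panel = panel or cohort.panel
    out = {}
    for marker_id in cohort.genotypes.columns:
        marker = panel[marker_id]
        out[marker_id] = cohort.genotypes[marker_id].map(
            lambda c, m=marker: encode_dosage(c, m)
        )
    return pd.DataFrame(out, index=cohort.animal_ids).astype("Int64")


def dichotomize(cls: object, scheme: str) -> object:
    """Collapse a 1-5 class to 0/1.

    ``affected``: 1 iff class >= 2 (any dysplasia). ``severe``: 1 iff class = 5.
    Accepts scalars (missing propagates as None/NA) or pandas Series.
    """
    if scheme not in _SCHEMES:
        raise CohortError(f"unknown dichotomy scheme {scheme!r}")
    if isinstance(cls, pd.Series):
        vals = cls.astype("Int64")
        bad = vals.dropna()[~vals.dropna().isin(_CLASSES)]
        if len(bad):
            raise CohortError(f"class outside 1-5: {bad.unique().tolist()}")
        if scheme == "affected":
            return (vals >= 2).astype("Int64").where(vals.notna())
        return (vals == 5).astype("Int64").where(vals.notna())
    if cls is None or pd.isna(cls):
        return None
    cls = int(cls)
    if cls not in _CLASSES:
        raise CohortError(f"class {cls} outside 1-5")
    return int(cls >= 2) if scheme == "affected" else int(cls == 5)


def _resolve_spec(cohort: Cohort, spec: str) -> pd.Series:
    """Resolve a variable spec: 'chd' | 'ced' (classes) or 'chd:affected' etc."""
    parts = spec.split(":")
    disease = parts[0].lower()
    if disease not in ("chd", "ced"):
        raise CohortError(f"unknown phenotype spec {spec!r}")
    series = cohort.phenotypes[f"{disease}_class"]
    if len(parts) == 1:
        return series.rename(spec)
    if len(parts) == 2:
        return dichotomize(series, parts[1]).rename(spec)
    raise CohortError(f"unknown phenotype spec {spec!r}")


def cross_tabulate(
    cohort: Cohort, row: str, col: str | None = None
) -> tuple[pd.DataFrame, int]:
    """Cross-tabulate phenotype specs; returns (counts, n_excluded).

    Animals missing any involved variable are excluded and counted in the
    second return value.  With ``col=None`` a one-way class distribution is
    returned (a single-row frame).  Counts always sum to the included animals.
    """
    r = _resolve_spec(cohort, row)
    if col is None:
        included = r.dropna()
        counts = included.value_counts().sort_index().to_frame().T
        counts.index = [row]
        return counts, len(r) - len(included)
    c = _resolve_spec(cohort, col)
    both = pd.concat([r, c], axis=1).dropna()
    table = pd.crosstab(both.iloc[:, 0], both.iloc[:, 1])
    return table, len(r) - len(both)


def contingency_2x2(table: pd.DataFrame) -> Contingency2x2:
    """Convert a 2x2 cross-tabulation (0/1 x 0/1) to exposed/event layout.

    Rows are the exposure (1 = exposed), columns the event (1 = event):
    a = table[1,1], b = table[1,0], c = table[0,1], d = table[0,0].
    Absent rows/columns count as zero.
    """
    def cell(i: int, j: int) -> int:
        try:
            return int(table.loc[i, j])
        except KeyError:
            return 0

    return Contingency2x2(a=cell(1, 1), b=cell(1, 0), c=cell(0, 1), d=cell(0, 0))
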