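"""Definition, loading and validation of the 17-marker CHD SNP panel.

The genomic breeding value (GBV) test for canine hip dysplasia rests on a
panel of 17 biallelic autosomal markers (TiHo*).  Each marker is described by
its wild-type and CHD-associated (mutant) allele, a short flanking sequence
context for each allele with the variant base bracketed (``CAAGAGT[A]TCCAGTTCC``),
and two numerical weights: ``w_hom`` for mutant homozygotes (its negative is
assigned to wild-type homozygotes) and ``w_het`` for heterozygotes.

Sequence contexts are stored on the reference-assembly leading strand
(CanFam3.1).  Markers originally reported on the lagging strand must be
reverse-complemented before entering a panel file; :func:`reverse_complement`
is provided for that transformation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "PanelError",
    "ContextError",
    "MarkerDefinition",
    "MarkerPanel",
    "validate_context",
    "reverse_complement",
    "load_panel",
    "write_panel",
    "bundled_panel",
]

_NUCLEOTIDES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_BRACKET_RE = re.compile(r"\[([A-Za-z])\]")


class PanelError(ValueError):
    """A marker panel file or record is invalid."""


class ContextError(PanelError):
    """A pair of sequence contexts does not describe a single substitution."""


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a nucleotide string.

    Case is preserved; applying the function twice returns the input.
    Raises :class:`PanelError` on non-ACGT characters.
    """
    bad = set(seq.upper()) - _NUCLEOTIDES
    if bad:
        raise PanelError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def _strip_bracket(context: str) -> tuple[str, int | None]:
    """Return (plain sequence, index of the bracketed base or None)."""
    matches = list(_BRACKET_RE.finditer(context))
    if len(matches) > 1:
        raise ContextError(f"more than one bracketed base in {context!r}")
    if not matches:
        return context, None
    m = matches[0]
    seq = context[: m.start()] + m.group(1) + context[m.end() :]
    return seq, m.start()


def validate_context(
    wild_context: str, mutant_context: str
) -> tuple[int, str, str]:
    """Check that two bracketed contexts describe one single-base substitution.

    Returns ``(position, wild_allele, mutant_allele)`` where *position* indexes
    the plain (bracket-stripped) sequence.  Identical sequences — the defect the
    patent exhibits for TiHo19 and TiHo35, whose wild-type and mutant context
    descriptions coincide — raise :class:`ContextError`, as do multi-base
    differences, length mismatches and non-nucleotide characters.
    """
    if not wild_context or not mutant_context:
        raise ContextError("empty sequence context")
    wild_seq, wild_pos = _strip_bracket(wild_context)
    mut_seq, mut_pos = _strip_bracket(mutant_context)
    for seq in (wild_seq, mut_seq):
        bad = set(seq.upper()) - _NUCLEOTIDES
        if bad:
            raise ContextError(f"non-nucleotide characters: {sorted(bad)}")
    if len(wild_seq) != len(mut_seq):
        raise ContextError(
            f"context lengths differ ({len(wild_seq)} vs {len(mut_seq)})"
        )
    diffs = [
        i for i, (a, b) in enumerate(zip(wild_seq.upper(), mut_seq.upper())) if a != b
    ]
    if not diffs:
        raise ContextError(
            "wild-type and mutant contexts are identical (no substitution)"
        )
    if len(diffs) > 1:
        raise ContextError(f"contexts differ at {len(diffs)} positions: {diffs}")
    pos = diffs[0]
    for name, bracket in (("wild", wild_pos), ("mutant", mut_pos)):
        if bracket is not None and bracket != pos:
            raise ContextError(
                f"{name} context brackets position {bracket} but the "
                f"substitution is at position {pos}"
            )
    return pos, wild_seq[pos].upper(), mut_seq[pos].upper()


@dataclass(frozen=True)
class MarkerDefinition:
    """One panel marker: alleles, sequence contexts and numerical weights."""

    marker_id: str
    wild_allele: str
    mutant_allele: str
    wild_context: str
    mutant_context: str
    w_hom: float
    w_het: float

    def __post_init__(self) -> None:
        for name in ("wild_allele", "mutant_allele"):
            allele = getattr(self, name)
            if allele.upper() not in _NUCLEOTIDES:
                raise PanelError(f"{self.marker_id}: {name} {allele!r} is not a nucleotide")
        if self.wild_allele.upper() == self.mutant_allele.upper():
            raise PanelError(f"{self.marker_id}: wild and mutant alleles are identical")
        try:
            _, wild, mutant = validate_context(self.wild_context, self.mutant_context)
        except ContextError as exc:
            raise ContextError(f"{self.marker_id}: {exc}") from exc
        if (wild, mutant) != (self.wild_allele.upper(), self.mutant_allele.upper()):
            raise PanelError(
                f"{self.marker_id}: context alleles ({wild}/{mutant}) do not match "
                f"declared alleles ({self.wild_allele}/{self.mutant_allele})"
            )

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset({self.wild_allele.upper(), self.mutant_allele.upper()})


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered collection of markers with unique identifiers.

    The bundled CHD panel has exactly 17 markers; synthetic panels of any
    size are permitted.
    """

    markers: tuple[MarkerDefinition, ...]

    def __post_init__(self) -> None:
        ids = [m.marker_id for m in self.markers]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PanelError(f"duplicate marker ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self) -> Iterator[MarkerDefinition]:
        return iter(self.markers)

    def __getitem__(self, marker_id: str) -> MarkerDefinition:
        for m in self.markers:
            if m.marker_id == marker_id:
                return m
        raise KeyError(marker_id)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]


_COLUMNS = [f.name for f in fields(MarkerDefinition)]


def load_panel(path: str | Path) -> MarkerPanel:
    """Load a panel from a tab-separated file (``#`` lines are comments).

    Required columns: marker_id, wild_allele, mutant_allele, wild_context,
    mutant_context, w_hom, w_het.  Every record is validated on load; errors
    name the offending marker.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise PanelError(f"cannot parse panel file {path}: {exc}") from exc
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise PanelError(f"{path}: missing columns {sorted(missing)}")
    markers = []
    for _, row in df.iterrows():
        try:
            markers.append(
                MarkerDefinition(
                    marker_id=row["marker_id"],
                    wild_allele=row["wild_allele"],
                    mutant_allele=row["mutant_allele"],
                    wild_context=row["wild_context"],
                    mutant_context=row["mutant_context"],
                    w_hom=float(row["w_hom"]),
                    w_het=float(row["w_het"]),
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, PanelError):
                raise
            raise PanelError(f"{row.get('marker_id', '?')}: {exc}") from exc
    return MarkerPanel(tuple(markers))


def write_panel(panel: MarkerPanel, path: str | Path) -> None:
    """Write a panel to the tab-separated format read by :func:`load_panel`."""
    df = pd.DataFrame([[getattr(m, c) for c in _COLUMNS] for m in panel], columns=_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def bundled_panel() -> MarkerPanel:
    """The packaged 17-marker CHD panel.

    Sequence contexts for TiHo1, TiHo18, TiHo19 and TiHo35 are the published
    revised contexts, and the CHD-associated alleles of TiHo12 (T), TiHo25 (G)
    and TiHo26 (C) are as published.  All remaining contexts and all numerical
    weights are synthetic stand-ins (the patented weights are not in the public
    record shipped here); see the data file header.
    """
    with resources.as_file(
        resources.files("caninegbv.data") / "chd17_panel_synthetic.tsv"
    ) as p:
        return load_panel(p)
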