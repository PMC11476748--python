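"""Letter-code DNA fingerprint construction for SSR genotypes.

A fingerprint profile is one two-character block per primer: the letter
codes of the two allele sizes (ascending), or ``"00"`` where the locus
gave no clear band.  Primers are ordered by marker informativeness
(descending PIC), and within each primer the observed fragment sizes are
assigned letters A, B, C, … in ascending size order — so a profile is a
compact, sortable identifier of a genotype.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .diversity import locus_stats
from .genotypes import (
    CodeTable,
    GenotypeError,
    GenotypeMatrix,
    MISSING_CHAR,
    PrimerOrder,
)

__all__ = [
    "rank_primers_by_pic",
    "build_code_table",
    "fingerprint_string",
    "encode_fingerprints",
    "uniqueness_report",
    "UniquenessReport",
]


def rank_primers_by_pic(
    pic: Mapping[str, float] | GenotypeMatrix,
) -> PrimerOrder:
    """Primers in strictly descending PIC; ties broken by name ascending.

    Accepts either a precomputed locus→PIC mapping or a genotype matrix
    (PIC is then computed over all samples pooled).
    """
    if isinstance(pic, GenotypeMatrix):
        pic = {
            locus: locus_stats(pic, locus).pic for locus in pic.locus_names
        }
    ranked = sorted(pic, key=lambda l: (-pic[l], l))
    return PrimerOrder(tuple(ranked))


def build_code_table(
    matrix: GenotypeMatrix,
    primer_order: PrimerOrder | Iterable[str] | None = None,
) -> CodeTable:
    """Assign letters A, B, C, … to each primer's observed sizes, ascending.

    Raises if a primer shows more than 26 distinct fragment sizes (the
    single-letter scheme is exhausted) or has no scored sample.
    """
    loci = tuple(primer_order) if primer_order is not None else matrix.locus_names
    codes = {}
    for locus in loci:
        j = matrix.locus_index(locus)
        sizes = np.unique(matrix.calls[:, j, :])
        sizes = sizes[sizes > 0]
        if sizes.size == 0:
            raise GenotypeError(f"{locus}: no scored sample, cannot code")
        if sizes.size > 26:
            raise GenotypeError(
                f"{locus}: {sizes.size} distinct sizes, alphabet exhausted"
            )
        codes[locus] = tuple(
            (string.ascii_uppercase[i], int(s)) for i, s in enumerate(sizes)
        )
    return CodeTable(codes)


def fingerprint_string(
    sample: str,
    matrix: GenotypeMatrix,
    code_table: CodeTable,
    primer_order: PrimerOrder | Iterable[str],
) -> str:
    """Encode one sample; per locus the two codes ascending, or ``"00"``."""
    parts = []
    for locus in primer_order:
        g = matrix.get(sample, locus)
        if g is None:
            parts.append(MISSING_CHAR * 2)
            continue
        try:
            letters = sorted(code_table.letter_of(locus, s) for s in g)
        except GenotypeError as exc:
            raise GenotypeError(f"sample {sample!r}: {exc}") from None
        parts.append("".join(letters))
    return "".join(parts)


def encode_fingerprints(
    matrix: GenotypeMatrix,
    code_table: CodeTable | None = None,
    primer_order: PrimerOrder | Iterable[str] | None = None,
) -> dict[str, str]:
    """Profile strings for every sample.

    With no code table the codes are built from the matrix itself; with
    no primer order the primers are ranked by descending PIC.
    """
    if primer_order is None:
        primer_order = rank_primers_by_pic(matrix)
    if code_table is None:
        code_table = build_code_table(matrix, primer_order)
    return {
        s: fingerprint_string(s, matrix, code_table, primer_order)
        for s in matrix.sample_ids
    }


@dataclass(frozen=True)
class UniquenessReport:
    """Exact-string uniqueness of a set of fingerprint profiles."""

    n_profiles: int
    n_distinct: int
    duplicate_groups: tuple[tuple[str, ...], ...]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"group": i + 1, "sample": s, "n_members": len(g)}
            for i, g in enumerate(self.duplicate_groups)
            for s in g
        ]
        return pd.DataFrame(rows, columns=["group", "sample", "n_members"])


def uniqueness_report(profiles: Mapping[str, str]) -> UniquenessReport:
    """Group samples sharing an identical profile string.

    Groups (size ≥ 2) are ordered by first occurrence in the input;
    members keep input order — the report is deterministic.
    """
    by_string: dict[str, list[str]] = {}
    for sample, prof in profiles.items():
        by_string.setdefault(prof, []).append(sample)
    dupes = tuple(
        tuple(members)
        for members in by_string.values()
        if len(members) >= 2
    )
    return UniquenessReport(
        n_profiles=len(profiles),
        n_distinct=len(by_string),
        duplicate_groups=dupes,
    )
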