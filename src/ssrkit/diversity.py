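"""Per-locus and per-population genetic-diversity statistics.

For a locus with allele relative frequencies :math:`p_1, \\dots, p_k`
(computed over the scored samples of the chosen subset; missing calls are
excluded from the denominator):

* ``Na`` — number of distinct observed alleles;
* ``Ne`` — effective number of alleles, :math:`1/\\sum p_i^2`;
* ``He`` — expected heterozygosity (gene diversity), the plug-in form
  :math:`1 - \\sum p_i^2` (note the exact identity ``He = 1 - 1/Ne``);
* ``Ho`` — observed heterozygosity, heterozygous / scored samples;
* ``I``  — Shannon's diversity index, :math:`-\\sum p_i \\ln p_i` (nats);
* ``PIC`` — polymorphism information content (Botstein),
  :math:`1 - \\sum p_i^2 - \\sum_{i<j} 2 p_i^2 p_j^2`.

Two report layouts are provided: a per-locus summary pooling all samples
as one population (plus an arithmetic mean row), and a per-population
summary averaging each statistic over *all* loci, a locus with no scored
sample in the population contributing 0 to every statistic (so a
population scored at few loci can show mean Na below 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "AlleleFrequencies",
    "LocusStats",
    "allele_frequencies",
    "locus_stats",
    "locus_summary_table",
    "population_summary_table",
    "round_half_up",
]

STAT_COLUMNS = ("Na", "Ne", "I", "Ho", "He", "PIC")


@dataclass(frozen=True)
class AlleleFrequencies:
    """Relative allele frequencies at one locus for one sample subset."""

    locus: str
    freqs: dict[int, float]
    n_genes: int  #: scored gene copies (2 x scored samples)

    def __post_init__(self) -> None:
        if self.n_genes > 0:
            total = sum(self.freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies sum to {total}, not 1")
            if any(p <= 0 for p in self.freqs.values()):
                raise ValueError("all frequencies must be positive")


@dataclass(frozen=True)
class LocusStats:
    locus: str
    na: int
    ne: float
    shannon: float
    ho: float
    he: float
    pic: float
    n_scored: int

    def as_row(self) -> dict[str, float]:
        return {
            "Na": self.na, "Ne": self.ne, "I": self.shannon,
            "Ho": self.ho, "He": self.he, "PIC": self.pic,
        }


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding used for report output."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def allele_frequencies(
    matrix: GenotypeMatrix,
    locus: str,
    subset: Iterable[str] | None = None,
) -> AlleleFrequencies:
    """Count allele copies among scored samples of ``subset`` (default all)."""
    j = matrix.locus_index(locus)
    rows = (
        range(matrix.n_samples)
        if subset is None
        else [matrix.sample_index(s) for s in subset]
    )
    if subset is not None and not rows:
        raise ValueError("subset must be non-empty")
    counts: dict[int, int] = {}
    for i in rows:
        a, b = matrix.calls[i, j]
        if a == 0:
            continue
        counts[int(a)] = counts.get(int(a), 0) + 1
        counts[int(b)] = counts.get(int(b), 0) + 1
    n = sum(counts.values())
    freqs = {al: c / n for al, c in sorted(counts.items())} if n else {}
    return AlleleFrequencies(locus, freqs, n)


def _pic(p: np.ndarray) -> float:
    # Botstein: 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2
    sq = p * p
    s2 = sq.sum()
    cross = (s2 * s2 - (sq * sq).sum()) / 2.0
    return float(1.0 - s2 - 2.0 * cross)


def locus_stats(
    matrix: GenotypeMatrix,
    locus: str,
    subset: Iterable[str] | None = None,
    freqs: AlleleFrequencies | None = None,
) -> LocusStats:
    """All six diversity statistics at one locus.

    With zero scored samples every field is reported as 0 (the convention
    that lets per-population averages include unscored loci).
    """
    if freqs is None:
        freqs = allele_frequencies(matrix, locus, subset)
    j = matrix.locus_index(locus)
    rows = (
        range(matrix.n_samples)
        if subset is None
        else [matrix.sample_index(s) for s in subset]
    )
    scored = het = 0
    for i in rows:
        a, b = matrix.calls[i, j]
        if a == 0:
            continue
        scored += 1
        het += int(a != b)
    if freqs.n_genes == 0:
        return LocusStats(locus, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0)
    p = np.array(list(freqs.freqs.values()))
    s2 = float((p * p).sum())
    return LocusStats(
        locus=locus,
        na=len(p),
        ne=1.0 / s2,
        shannon=float(-(p * np.log(p)).sum()),
        ho=het / scored,
        he=1.0 - s2,
        pic=_pic(p),
        n_scored=scored,
    )


def locus_summary_table(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus statistics over all samples pooled, plus a mean row."""
    if matrix.n_loci < 1:
        raise ValueError("at least one locus required")
    rows = {
        locus: locus_stats(matrix, locus).as_row()
        for locus in matrix.locus_names
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=STAT_COLUMNS)
    df.loc["Mean"] = df.mean(axis=0)
    df.index.name = "locus"
    return df


def population_summary_table(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-population means of each statistic over all loci.

    Within a population, each statistic is computed per locus from that
    population's scored samples only, then averaged over *all* loci with
    unscored loci contributing 0.
    """
    columns = ("Na", "Ne", "I", "Ho", "He")  # PIC is a marker property,
    # not reported per population
    records = {}
    for pop in matrix.population_labels():
        members = matrix.samples_in_population(pop)
        acc = dict.fromkeys(columns, 0.0)
        for locus in matrix.locus_names:
            st = locus_stats(matrix, locus, subset=members)
            for key in columns:
                acc[key] += st.as_row()[key]
        row = {k: v / matrix.n_loci for k, v in acc.items()}
        row["n"] = len(members)
        records[pop] = row
    df = pd.DataFrame.from_dict(records, orient="index")
    df["n"] = df["n"].astype(int)
    df.index.name = "population"
    return df
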