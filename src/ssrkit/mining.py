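"""MISA-style perfect-SSR detection in nucleotide sequences.

A simple SSR is a maximal perfect tandem run of a primitive 1–6 bp motif
whose complete-repeat count reaches the per-unit-length threshold.
"Primitive" (the motif is not itself a repetition of a shorter unit)
guarantees that a run is reported once, at its smallest unit length.
Coordinates are 1-based inclusive and span complete repeats only.

Motifs are grouped into canonical classes: the lexicographically
smallest string among all rotations of the motif and of its reverse
complement, printed as ``"smallest/revcomp(smallest)"`` (e.g. GA, AG,
TC and CT all belong to class ``AG/CT``).

Simple records separated by at most ``max_interruption`` bases merge
into a compound record; the constituents still count individually in
summaries (the MISA convention, where a compound SSR is a presentation
of adjacent simple ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SSRRecord",
    "MinerConfig",
    "TABLE1_PRESET",
    "find_ssrs",
    "canonical_motif_class",
    "merge_compound",
    "mine_fasta",
    "summarize",
    "MiningSummary",
    "ssr_frequency",
    "ssr_density",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: repeat-count bins used in summary tables
_BINS = ("<5", "5", "6", "7", "8", "9", "10-15", "16-20", ">=21")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _is_primitive(motif: str) -> bool:
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


@dataclass(frozen=True)
class SSRRecord:
    """One mined repeat; ``start``/``end`` are 1-based inclusive."""

    seq_id: str
    motif: str
    motif_class: str
    unit: int
    repeats: int
    start: int
    end: int
    kind: str = "simple"  # "simple" or "compound"
    parts: tuple["SSRRecord", ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if self.kind == "simple" and (
            self.end - self.start + 1 != self.unit * self.repeats
        ):
            raise ValueError("span must equal unit length x repeat count")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MinerConfig:
    """Detection thresholds.

    ``min_repeats[u-1]`` is the minimum complete-repeat count for unit
    length u (defaults 8, 5, 4, 3, 2, 2 for mono- through hexanucleotide
    motifs); ``max_interruption`` is the largest gap (bp) across which
    adjacent simple SSRs merge into a compound record.
    """

    min_repeats: tuple[int, int, int, int, int, int] = (8, 5, 4, 3, 2, 2)
    max_interruption: int = 100

    def __post_init__(self) -> None:
        if len(self.min_repeats) != 6:
            raise ValueError("need one threshold per unit length 1..6")
        if any(t < 2 for t in self.min_repeats):
            raise ValueError("thresholds must be >= 2")
        if self.max_interruption < 0:
            raise ValueError("max_interruption must be >= 0")


#: stricter thresholds (MISA defaults) whose bins start at 5 repeats
TABLE1_PRESET = MinerConfig(min_repeats=(10, 6, 5, 5, 5, 5))


def canonical_motif_class(motif: str) -> str:
    """Canonical class label, e.g. ``canonical_motif_class("GA") == "AG/CT"``."""
    motif = motif.upper()
    if not 1 <= len(motif) <= 6:
        raise ValueError("motif length must be 1..6")
    if any(c not in "ACGT" for c in motif):
        raise ValueError(f"non-ACGT character in motif {motif!r}")
    rc = _revcomp(motif)
    candidates = [
        s[i:] + s[:i] for s in (motif, rc) for i in range(len(motif))
    ]
    smallest = min(candidates)
    return f"{smallest}/{_revcomp(smallest)}"


def find_ssrs(
    sequence: str,
    config: MinerConfig = MinerConfig(),
    seq_id: str = "",
) -> list[SSRRecord]:
    """All maximal perfect SSRs in ``sequence`` (A/C/G/T/N; N breaks runs).

    Records are sorted by start position, then unit length.
    """
    s = sequence.upper()
    n = len(s)
    out: list[SSRRecord] = []
    for u in range(1, 7):
        thr = config.min_repeats[u - 1]
        j = 0
        while j + u < n:
            if s[j] in "ACGT" and s[j] == s[j + u]:
                a = j
                while j + u < n and s[j] in "ACGT" and s[j] == s[j + u]:
                    j += 1
                # period-u run covers a .. j+u-1
                run_len = j + u - a
                count = run_len // u
                motif = s[a : a + u]
                if count >= thr and _is_primitive(motif):
                    out.append(
                        SSRRecord(
                            seq_id=seq_id,
                            motif=motif,
                            motif_class=canonical_motif_class(motif),
                            unit=u,
                            repeats=count,
                            start=a + 1,
                            end=a + u * count,
                        )
                    )
                j = a + run_len - u + 1  # first position after the run start
            else:
                j += 1
    out.sort(key=lambda r: (r.start, r.unit))
    return out


def merge_compound(
    records: Sequence[SSRRecord],
    config: MinerConfig = MinerConfig(),
) -> list[SSRRecord]:
    """Merge simple records ≤ ``max_interruption`` bp apart into compounds.

    Returns the record list with each merged chain replaced by one
    compound record (its ``parts`` holding the constituents, which MISA
    counts individually in summaries).  Records must belong to one
    sequence and be sorted by start.
    """
    if not records:
        return []
    if len({r.seq_id for r in records}) > 1:
        raise ValueError("merge one sequence at a time")
    chains: list[list[SSRRecord]] = [[records[0]]]
    for rec in records[1:]:
        gap = rec.start - chains[-1][-1].end - 1
        if gap <= config.max_interruption:
            chains[-1].append(rec)
        else:
            chains.append([rec])
    out: list[SSRRecord] = []
    for chain in chains:
        if len(chain) == 1:
            out.append(chain[0])
            continue
        motif = "*".join(f"({r.motif}){r.repeats}" for r in chain)
        out.append(
            SSRRecord(
                seq_id=chain[0].seq_id,
                motif=motif,
                motif_class="compound",
                unit=0,
                repeats=0,
                start=chain[0].start,
                end=max(r.end for r in chain),
                kind="compound",
                parts=tuple(chain),
            )
        )
    return out


def mine_fasta(
    path,
    config: MinerConfig = MinerConfig(),
    compound: bool = True,
) -> list[SSRRecord]:
    """Mine every sequence of a FASTA file."""
    from Bio import SeqIO

    out: list[SSRRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        simple = find_ssrs(str(rec.seq), config, seq_id=rec.id)
        out.extend(merge_compound(simple, config) if compound else simple)
    return out


def _bin_of(repeats: int) -> str:
    if repeats < 5:
        return "<5"
    if repeats <= 9:
        return str(repeats)
    if repeats <= 15:
        return "10-15"
    if repeats <= 20:
        return "16-20"
    return ">=21"


@dataclass(frozen=True)
class MiningSummary:
    """Motif-class × repeat-count-bin table with the headline rates."""

    table: pd.DataFrame
    n_ssrs: int
    n_compound: int
    n_unigenes: int | None
    total_bp: int | None
    frequency_pct: float | None
    density_bp: float | None
    n_multi_ssr_seqs: int


def ssr_frequency(n_ssrs: int, n_unigenes: int) -> float:
    """SSR frequency as a percentage: loci per 100 examined sequences."""
    return 100.0 * n_ssrs / n_unigenes


def ssr_density(total_bp: int, n_ssrs: int) -> float:
    """Base pairs of screened sequence per SSR locus."""
    if n_ssrs == 0:
        raise ZeroDivisionError("density undefined with zero SSRs")
    return total_bp / n_ssrs


def summarize(
    records: Iterable[SSRRecord],
    n_unigenes: int | None = None,
    total_bp: int | None = None,
) -> MiningSummary:
    """Tabulate simple records by canonical class and repeat-count bin.

    Compound records contribute their constituent simple parts (counted
    individually); ``frequency_pct`` and ``density_bp`` are filled when
    the sequence totals are given.
    """
    simple: list[SSRRecord] = []
    n_compound = 0
    for r in records:
        if r.kind == "compound":
            n_compound += 1
            simple.extend(r.parts)
        else:
            simple.append(r)
    classes = sorted({r.motif_class for r in simple})
    table = pd.DataFrame(0, index=classes, columns=list(_BINS))
    per_seq: dict[str, int] = {}
    for r in simple:
        table.loc[r.motif_class, _bin_of(r.repeats)] += 1
        per_seq[r.seq_id] = per_seq.get(r.seq_id, 0) + 1
    table["Total"] = table.sum(axis=1)
    table.index.name = "motif_class"
    n = len(simple)
    return MiningSummary(
        table=table,
        n_ssrs=n,
        n_compound=n_compound,
        n_unigenes=n_unigenes,
        total_bp=total_bp,
        frequency_pct=(
            ssr_frequency(n, n_unigenes) if n_unigenes else None
        ),
        density_bp=(
            ssr_density(total_bp, n) if total_bp and n else None
        ),
        n_multi_ssr_seqs=sum(1 for v in per_seq.values() if v > 1),
    )
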