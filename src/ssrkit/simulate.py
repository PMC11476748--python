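"""Synthetic genotype matrices and transcript FASTA with known truth.

The genotype generator emulates the statistical structure the diversity
and admixture analyses assume: K source populations, each with its own
allele-frequency vector per locus (drawn from a symmetric Dirichlet
whose concentration controls divergence — small values give
near-private alleles), individuals with (possibly admixed) ancestry
proportions, Hardy–Weinberg sampling of the two allele copies, and
whole-locus missingness at a fixed rate.  Allele sizes sit on a
realistic SSR ladder (offset + motif length × repeat index) so that
letter-code tables built from simulated data look like real ones.

The transcript generator plants perfect SSRs of known motif/count at
known positions in random background sequence and returns the implanted
records in the miner's own schema, so the miner can be scored against
an exact truth table.

Every generator takes an explicit seed and is bit-reproducible; there
is no hidden global randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .mining import MinerConfig, SSRRecord, canonical_motif_class, find_ssrs

__all__ = [
    "SimSpec",
    "SimulatedGenotypes",
    "simulate_genotypes",
    "simulate_transcripts",
    "to_fasta",
]


@dataclass(frozen=True)
class SimSpec:
    """Study design for the genotype generator.

    Defaults mirror a small germplasm panel: 3 source populations of 29
    diploids genotyped at 8 multi-allelic loci, strong between-population
    divergence (concentration 0.3 over 8 alleles), pure memberships and
    5 % whole-locus missing data.
    """

    n_populations: int = 3
    samples_per_population: int = 29
    n_loci: int = 8
    alleles_per_locus: int = 8
    concentration: float = 0.3  #: Dirichlet concentration; small = diverged
    admixture_alpha: float = 0.0  #: 0 = pure memberships
    missing_rate: float = 0.05
    #: zero-concentration limit: population k fixed for allele k at every
    #: locus (requires alleles_per_locus >= n_populations)
    fixed_private_alleles: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fixed_private_alleles and (
            self.alleles_per_locus < self.n_populations
        ):
            raise ValueError(
                "fixed_private_alleles needs alleles_per_locus >= K"
            )
        if min(
            self.n_populations,
            self.samples_per_population,
            self.n_loci,
            self.alleles_per_locus,
        ) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.concentration <= 0 or self.admixture_alpha < 0:
            raise ValueError("concentration > 0 and admixture_alpha >= 0")


@dataclass(frozen=True)
class SimulatedGenotypes:
    """Generator output: data plus the ground truth behind it."""

    matrix: GenotypeMatrix
    pop_frequencies: np.ndarray = field(repr=False)  #: (K, L, A)
    q_true: np.ndarray = field(repr=False)  #: (n, K) ancestry proportions
    allele_sizes: np.ndarray = field(repr=False)  #: (L, A) bp ladder


def simulate_genotypes(spec: SimSpec) -> SimulatedGenotypes:
    """Draw a genotype matrix under ``spec``; same spec+seed → same output."""
    rng = np.random.default_rng(spec.seed)
    K, L, A = spec.n_populations, spec.n_loci, spec.alleles_per_locus
    n = K * spec.samples_per_population

    units = rng.choice([2, 3, 4], size=L)
    offsets = rng.integers(80, 301, size=L)
    allele_sizes = offsets[:, None] + units[:, None] * np.arange(A)[None, :]

    if spec.fixed_private_alleles:
        pop_freqs = np.zeros((K, L, A))
        pop_freqs[np.arange(K), :, np.arange(K)] = 1.0
    else:
        pop_freqs = rng.dirichlet(
            np.full(A, spec.concentration), size=(K, L)
        )

    source = np.repeat(np.arange(K), spec.samples_per_population)
    if spec.admixture_alpha == 0.0:
        q_true = np.eye(K)[source]
    else:
        # admixed ancestry biased toward the sample's source population
        conc = np.full((n, K), spec.admixture_alpha)
        conc[np.arange(n), source] += 1.0
        q_true = np.vstack([rng.dirichlet(c) for c in conc])

    calls = np.zeros((n, L, 2), dtype=np.int64)
    for i in range(n):
        for l in range(L):
            anc = rng.choice(K, size=2, p=q_true[i])
            for c in range(2):
                a = rng.choice(A, p=pop_freqs[anc[c], l])
                calls[i, l, c] = allele_sizes[l, a]
    calls.sort(axis=2)  # report the smaller allele first

    if spec.missing_rate > 0:
        mask = rng.random((n, L)) < spec.missing_rate
        # a sample must keep >= 1 scored locus
        for i in np.flatnonzero(mask.all(axis=1)):
            mask[i, rng.integers(L)] = False
        calls[mask] = 0

    width = len(str(n))
    sample_ids = tuple(f"S{i + 1:0{width}d}" for i in range(n))
    populations = tuple(f"pop{g + 1}" for g in source)
    locus_names = tuple(f"loc{l + 1}" for l in range(L))
    matrix = GenotypeMatrix(sample_ids, populations, locus_names, calls)
    return SimulatedGenotypes(matrix, pop_freqs, q_true, allele_sizes)


def _clean_background(
    rng: np.random.Generator, length: int, config: MinerConfig
) -> str:
    """Random sequence with no SSR above the thresholds (rejection)."""
    for _ in range(1000):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if not find_ssrs(seq, config):
            return seq
    raise RuntimeError("could not draw a repeat-free background")


def simulate_transcripts(
    n: int,
    length: int,
    implants: list[tuple[int, int, str, int]],
    seed: int = 0,
    config: MinerConfig = MinerConfig(),
    max_tries: int = 200,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random transcripts with planted SSRs.

    Parameters
    ----------
    implants
        Tuples ``(seq_index, start, motif, repeats)`` with 1-based,
        non-overlapping start positions; each plants ``motif`` repeated
        ``repeats`` times.
    config
        Thresholds the background must stay below (and against which the
        truth table is valid).

    Returns
    -------
    sequences, truth
        ``sequences`` maps sequence id → sequence; ``truth`` lists the
        planted records in the miner's output schema.  Each sequence is
        redrawn until mining it yields exactly its planted records, so
        the truth table is guaranteed, not merely probable.
    """
    rng = np.random.default_rng(seed)
    ids = [f"seq{i + 1}" for i in range(n)]
    plan: dict[int, list[tuple[int, str, int]]] = {i: [] for i in range(n)}
    for si, start, motif, reps in implants:
        if not 0 <= si < n:
            raise ValueError(f"sequence index {si} out of range")
        if start < 1 or start - 1 + len(motif) * reps > length:
            raise ValueError("implant does not fit in the sequence")
        plan[si].append((start, motif.upper(), reps))
    for si, items in plan.items():
        items.sort()
        for (s1, m1, r1), (s2, _, _) in zip(items, items[1:]):
            if s1 - 1 + len(m1) * r1 > s2 - 1:
                raise ValueError("overlapping implants")

    sequences: dict[str, str] = {}
    truth_rows = []
    for i, sid in enumerate(ids):
        expected = [
            SSRRecord(
                seq_id=sid,
                motif=m,
                motif_class=canonical_motif_class(m),
                unit=len(m),
                repeats=r,
                start=s,
                end=s - 1 + len(m) * r,
            )
            for s, m, r in plan[i]
        ]
        for _ in range(max_tries):
            seq = list(_clean_background(rng, length, config))
            for s, m, r in plan[i]:
                seq[s - 1 : s - 1 + len(m) * r] = m * r
            candidate = "".join(seq)
            if find_ssrs(candidate, config, seq_id=sid) == expected:
                sequences[sid] = candidate
                break
        else:
            raise RuntimeError(f"{sid}: could not realise the implant plan")
        truth_rows.extend(
            {
                "seq_id": rec.seq_id,
                "motif": rec.motif,
                "motif_class": rec.motif_class,
                "unit": rec.unit,
                "repeats": rec.repeats,
                "start": rec.start,
                "end": rec.end,
            }
            for rec in expected
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "seq_id", "motif", "motif_class", "unit", "repeats",
            "start", "end",
        ],
    )
    return sequences, truth


def to_fasta(sequences: dict[str, str]) -> str:
    """Render simulated transcripts as FASTA text."""
    buf = StringIO()
    for sid, seq in sequences.items():
        buf.write(f">{sid}\n")
        for i in range(0, len(seq), 70):
            buf.write(seq[i : i + 70] + "\n")
    return buf.getvalue()
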