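"""Core genotype containers and I/O for codominant SSR (microsatellite) data.

The central object is :class:`GenotypeMatrix`: diploid, multi-allelic calls
(allele = fragment size in base pairs) for a set of samples scored at a set
of loci, with a population label per sample.  Missingness is whole-locus:
either both allele slots of a (sample, locus) call are present or the call
is missing entirely — the convention of letter-coded fingerprint profiles,
where ``"00"`` marks a locus with no clear band.

Two exchange representations are supported:

* a GenAlEx-style CSV dialect with two numeric columns per locus and 0 for
  a missing allele (:func:`read_genotype_csv` / :func:`write_genotype_csv`);
* concatenated two-letter fingerprint strings decoded against a per-primer
  letter→size :class:`CodeTable` (:func:`decode_fingerprints`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "CodeTable",
    "PrimerOrder",
    "GenotypeError",
    "read_genotype_csv",
    "write_genotype_csv",
    "decode_fingerprints",
]

#: reserved character marking the absence of a clear band in profile strings
MISSING_CHAR = "0"


class GenotypeError(ValueError):
    """Invalid genotype data (bad call, malformed table, broken invariant)."""


@dataclass(frozen=True)
class GenotypeMatrix:
    """Diploid allele-size calls for samples × loci.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, in input order.
    populations
        Population label per sample (parallel to ``sample_ids``).
    locus_names
        Ordered locus identifiers.
    calls
        Integer array of shape ``(n_samples, n_loci, 2)`` holding allele
        sizes in bp; a missing call stores 0 in *both* slots.
    """

    sample_ids: tuple[str, ...]
    populations: tuple[str, ...]
    locus_names: tuple[str, ...]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls, dtype=np.int64)
        object.__setattr__(self, "calls", calls)
        n, L = len(self.sample_ids), len(self.locus_names)
        if calls.shape != (n, L, 2):
            raise GenotypeError(
                f"calls shape {calls.shape} does not match "
                f"{n} samples x {L} loci x 2 alleles"
            )
        if len(self.populations) != n:
            raise GenotypeError("one population label required per sample")
        seen: set[str] = set()
        for sid in self.sample_ids:
            if sid in seen:
                raise GenotypeError(f"duplicate sample id {sid!r}")
            seen.add(sid)
        if len(set(self.locus_names)) != L:
            raise GenotypeError("locus names must be unique")
        if np.any(calls < 0):
            raise GenotypeError("allele sizes must be positive (0 = missing)")
        half = (calls == 0).sum(axis=2) == 1
        if np.any(half):
            i, j = np.argwhere(half)[0]
            raise GenotypeError(
                f"half-missing call at sample {self.sample_ids[i]!r}, "
                f"locus {self.locus_names[j]!r}: missingness is whole-locus"
            )
        if np.any(self.missing_mask().all(axis=1)):
            i = int(np.flatnonzero(self.missing_mask().all(axis=1))[0])
            raise GenotypeError(
                f"sample {self.sample_ids[i]!r} has no scored locus"
            )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def locus_index(self, locus: str) -> int:
        try:
            return self.locus_names.index(locus)
        except ValueError:
            raise GenotypeError(f"unknown locus {locus!r}") from None

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise GenotypeError(f"unknown sample {sample!r}") from None

    def population_of(self, sample: str) -> str:
        return self.populations[self.sample_index(sample)]

    def get(self, sample: str, locus: str) -> tuple[int, int] | None:
        """Return the (unordered) allele pair, or ``None`` if missing."""
        g = self.calls[self.sample_index(sample), self.locus_index(locus)]
        if g[0] == 0:
            return None
        return int(g[0]), int(g[1])

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_samples, n_loci)`` mask of missing calls."""
        return self.calls[:, :, 0] == 0

    def subset(self, samples: Iterable[str]) -> "GenotypeMatrix":
        """Restrict to the given samples (kept in matrix order)."""
        wanted = set(samples)
        idx = [i for i, s in enumerate(self.sample_ids) if s in wanted]
        if not idx:
            raise GenotypeError("subset selects no samples")
        return GenotypeMatrix(
            tuple(self.sample_ids[i] for i in idx),
            tuple(self.populations[i] for i in idx),
            self.locus_names,
            self.calls[idx],
        )

    def samples_in_population(self, population: str) -> list[str]:
        return [
            s for s, p in zip(self.sample_ids, self.populations)
            if p == population
        ]

    def population_labels(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        out: list[str] = []
        for p in self.populations:
            if p not in out:
                out.append(p)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        """Two columns per locus (``<locus>_1``, ``<locus>_2``), 0 = missing."""
        data: dict[str, object] = {
            "sample": list(self.sample_ids),
            "population": list(self.populations),
        }
        for j, locus in enumerate(self.locus_names):
            data[f"{locus}_1"] = self.calls[:, j, 0]
            data[f"{locus}_2"] = self.calls[:, j, 1]
        return pd.DataFrame(data)


@dataclass(frozen=True)
class CodeTable:
    """Per-primer ordered letter→fragment-size map.

    ``codes[locus]`` is a tuple of ``(letter, size_bp)`` pairs with sizes
    strictly increasing along the letter order A, B, C, …  The character
    ``'0'`` is reserved for missing and never a code.
    """

    codes: Mapping[str, tuple[tuple[str, int], ...]]

    def __post_init__(self) -> None:
        normalized = {}
        for locus, pairs in self.codes.items():
            pairs = tuple((str(c), int(s)) for c, s in pairs)
            letters = [c for c, _ in pairs]
            sizes = [s for _, s in pairs]
            if MISSING_CHAR in letters:
                raise GenotypeError(f"{locus}: '0' is reserved for missing")
            if len(set(letters)) != len(letters):
                raise GenotypeError(f"{locus}: duplicate code letters")
            if letters != sorted(letters):
                raise GenotypeError(f"{locus}: letters must be in A..Z order")
            if any(b <= a for a, b in zip(sizes, sizes[1:])):
                raise GenotypeError(
                    f"{locus}: sizes must increase strictly with letter order"
                )
            if any(s <= 0 for s in sizes):
                raise GenotypeError(f"{locus}: sizes must be positive")
            normalized[locus] = pairs
        object.__setattr__(self, "codes", normalized)

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.codes)

    def size_of(self, locus: str, letter: str) -> int:
        for c, s in self.codes[locus]:
            if c == letter:
                return s
        raise GenotypeError(
            f"letter {letter!r} is not coded for primer {locus!r}"
        )

    def letter_of(self, locus: str, size: int) -> str:
        for c, s in self.codes[locus]:
            if s == size:
                return c
        raise GenotypeError(
            f"fragment size {size} bp has no code for primer {locus!r}"
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (locus, c, s)
            for locus, pairs in self.codes.items()
            for c, s in pairs
        ]
        return pd.DataFrame(rows, columns=["locus", "code", "size_bp"])


@dataclass(frozen=True)
class PrimerOrder:
    """Ordered primer (locus) names used to segment fingerprint strings."""

    loci: tuple[str, ...]

    def __post_init__(self) -> None:
        loci = tuple(str(x) for x in self.loci)
        if len(set(loci)) != len(loci):
            raise GenotypeError("each primer appears once in the order")
        object.__setattr__(self, "loci", loci)

    def __iter__(self):
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)


# -- GenAlEx-style CSV dialect --------------------------------------------


def _locus_columns(columns: Sequence[str]) -> list[str]:
    cols = [c for c in columns if c not in ("sample", "population")]
    if len(cols) % 2:
        raise GenotypeError("expected two allele columns per locus")
    loci = []
    for a, b in zip(cols[::2], cols[1::2]):
        if not (a.endswith("_1") and b.endswith("_2") and a[:-2] == b[:-2]):
            raise GenotypeError(
                f"malformed locus column pair ({a!r}, {b!r}); expected "
                "'<locus>_1', '<locus>_2'"
            )
        loci.append(a[:-2])
    return loci


def read_genotype_csv(path) -> GenotypeMatrix:
    """Read the two-columns-per-locus CSV dialect.

    Header: ``sample,population,<locus>_1,<locus>_2,...``; 0 denotes a
    missing allele.  A call with exactly one zero allele is coerced to a
    whole-locus missing call with a warning.
    """
    df = pd.read_csv(path, dtype=str)
    if "sample" not in df.columns or "population" not in df.columns:
        raise GenotypeError("header must contain 'sample' and 'population'")
    loci = _locus_columns(df.columns)
    n = len(df)
    calls = np.zeros((n, len(loci), 2), dtype=np.int64)
    for j, locus in enumerate(loci):
        for k, col in enumerate((f"{locus}_1", f"{locus}_2")):
            try:
                calls[:, j, k] = pd.to_numeric(df[col], errors="raise")
            except (ValueError, TypeError):
                bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
                raise GenotypeError(
                    f"non-numeric allele in column {col!r}, row "
                    f"{bad.index[0] + 2} (value {bad.iloc[0]!r})"
                ) from None
    half = (calls == 0).sum(axis=2) == 1
    if np.any(half):
        for i, j in np.argwhere(half):
            warnings.warn(
                f"sample {df['sample'].iloc[i]!r}, locus {loci[j]!r}: "
                "half-missing call coerced to missing",
                stacklevel=2,
            )
        calls[half] = 0
    return GenotypeMatrix(
        tuple(df["sample"].astype(str)),
        tuple(df["population"].astype(str)),
        tuple(loci),
        calls,
    )


def write_genotype_csv(matrix: GenotypeMatrix, path) -> None:
    """Write ``matrix`` in the CSV dialect read by :func:`read_genotype_csv`."""
    matrix.to_dataframe().to_csv(path, index=False)


# -- fingerprint decoding --------------------------------------------------


def decode_fingerprints(
    profiles: Mapping[str, str],
    code_table: CodeTable,
    primer_order: PrimerOrder,
    populations: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Decode concatenated two-letter fingerprint strings into genotypes.

    Each profile has one consecutive character pair per primer in
    ``primer_order``; ``"00"`` marks a missing locus, letters map to
    fragment sizes through ``code_table``.

    Parameters
    ----------
    profiles
        Mapping sample id → profile string.
    populations
        Optional mapping sample id → population label (defaults to the
        sample id itself).
    """
    loci = tuple(primer_order)
    n = len(profiles)
    calls = np.zeros((n, len(loci), 2), dtype=np.int64)
    sample_ids = tuple(profiles)
    for i, sid in enumerate(sample_ids):
        s = profiles[sid]
        if len(s) != 2 * len(loci):
            raise GenotypeError(
                f"sample {sid!r}: profile length {len(s)} != "
                f"2 x {len(loci)} primers"
            )
        for j, locus in enumerate(loci):
            a, b = s[2 * j], s[2 * j + 1]
            if (a == MISSING_CHAR) != (b == MISSING_CHAR):
                raise GenotypeError(
                    f"sample {sid!r}, primer {locus!r}: half-missing pair "
                    f"{a + b!r} ('0' must appear as '00')"
                )
            if a == MISSING_CHAR:
                continue
            try:
                calls[i, j, 0] = code_table.size_of(locus, a)
                calls[i, j, 1] = code_table.size_of(locus, b)
            except GenotypeError as exc:
                raise GenotypeError(f"sample {sid!r}: {exc}") from None
    pops = tuple(
        (populations or {}).get(sid, sid) for sid in sample_ids
    )
    return GenotypeMatrix(sample_ids, pops, loci, calls)
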