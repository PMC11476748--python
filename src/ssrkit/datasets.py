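"""Packaged *Passiflora* SSR fingerprint dataset.

87 germplasm accessions from 22 species/cultivars of the genus
*Passiflora*, genotyped at 8 SSR loci.  The data ship as two plain-text
tables: the per-primer letter→fragment-size code map and the 16-character
fingerprint profile of each accession (two letters per primer, ``"00"``
marking a locus with no clear band).  Decoding the profiles against the
code map yields the diploid allele-size genotype matrix used throughout
the documentation and test suite.

Transcription conventions: the multiplication sign in hybrid names is
written as an ASCII ``x`` and curly quotes as straight quotes.  One
accession label ("87-P. suberosa", between samples 81 and 83) is printed
out of numeric sequence in the source material; it is preserved verbatim
and its row order kept.
"""

from __future__ import annotations

from importlib import resources

from .genotypes import (
    CodeTable,
    GenotypeMatrix,
    PrimerOrder,
    decode_fingerprints,
)

__all__ = [
    "passiflora_code_table",
    "passiflora_primer_order",
    "passiflora_profiles",
    "load_passiflora",
]

#: primer order used to build the published profiles (descending marker
#: informativeness as printed; see `fingerprint.rank_primers_by_pic` for
#: a strict PIC sort, which differs at positions 2-5)
PASSIFLORA_PRIMER_ORDER = (
    "ssr18", "ssr3", "ssr32", "ssr2", "ssr39", "ssr30", "ssr1", "ssr34",
)


def _read(name: str) -> list[list[str]]:
    text = (
        resources.files("ssrkit.data").joinpath(name).read_text("utf-8")
    )
    return [line.split("\t") for line in text.splitlines()[1:] if line]


def passiflora_code_table() -> CodeTable:
    """Letter→size (bp) code map for the eight core primers."""
    codes: dict[str, list[tuple[str, int]]] = {}
    for locus, letter, size in _read("passiflora_codes.tsv"):
        codes.setdefault(locus, []).append((letter, int(size)))
    return CodeTable({k: tuple(v) for k, v in codes.items()})


def passiflora_primer_order() -> PrimerOrder:
    """The published primer order segmenting the profile strings."""
    return PrimerOrder(PASSIFLORA_PRIMER_ORDER)


def passiflora_profiles() -> tuple[dict[str, str], dict[str, str]]:
    """Raw fingerprint strings.

    Returns
    -------
    profiles, species
        ``profiles`` maps accession label → 16-character profile string;
        ``species`` maps accession label → species/cultivar name.
    """
    profiles: dict[str, str] = {}
    species: dict[str, str] = {}
    for sample, sp, profile in _read("passiflora_fingerprints.tsv"):
        profiles[sample] = profile
        species[sample] = sp
    return profiles, species


def load_passiflora() -> GenotypeMatrix:
    """Decode the packaged fingerprints into an 87 × 8 genotype matrix.

    Population labels are the species/cultivar names.
    """
    profiles, species = passiflora_profiles()
    return decode_fingerprints(
        profiles,
        passiflora_code_table(),
        passiflora_primer_order(),
        populations=species,
    )
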