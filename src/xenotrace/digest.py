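"""In-silico tryptic digestion and species-unique peptide libraries.

A xenograft MS run mixes peptides from two homologous proteomes (e.g. human
graft and mouse host).  Because orthologous proteins share most of their
sequence, only peptides that occur in exactly one species' digest carry
species information.  This module digests both proteomes in silico, collapses
isobaric residues (I/L), and classifies every peptide as unique to one species
or shared — the "custom libraries of unique tryptic peptides" that downstream
species deconvolution matches observed evidence against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence

from pyteomics import mass as _pmass

__all__ = [
    "STANDARD_RESIDUES",
    "WATER_MONO",
    "Peptide",
    "Proteome",
    "LibraryEntry",
    "PeptideLibrary",
    "digest_protein",
    "cleavage_sites",
    "peptide_mass",
    "il_collapse",
    "build_libraries",
    "count_observable_peptides",
]

#: The 20 standard amino acids (one-letter codes).
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic mass of water (Da), the condensation term of a peptide bond.
WATER_MONO = _pmass.calculate_mass(formula="H2O")

#: Monoisotopic residue masses (Da), from pyteomics' standard table.
RESIDUE_MONO = {aa: _pmass.std_aa_mass[aa] for aa in STANDARD_RESIDUES}

_IL_TABLE = str.maketrans("IL", "JJ")

CleavageRule = Literal["trypsin", "trypsin/p"]
InvalidPolicy = Literal["error", "skip-peptide"]


def il_collapse(sequence: str) -> str:
    """Collapse isoleucine and leucine to the ambiguity code ``J``.

    I and L are isobaric and indistinguishable by mass spectrometry, so all
    uniqueness decisions and evidence matching operate on the collapsed key.
    """
    return sequence.translate(_IL_TABLE)


def peptide_mass(sequence: str) -> float:
    """Monoisotopic peptide mass: sum of residue masses plus one water."""
    try:
        return sum(RESIDUE_MONO[aa] for aa in sequence) + WATER_MONO
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in {sequence!r}") from exc


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide with its position and missed-cleavage count."""

    sequence: str
    start: int  # 0-based offset within the parent protein
    n_missed: int

    @property
    def il_key(self) -> str:
        return il_collapse(self.sequence)

    @property
    def monoisotopic_mass(self) -> float:
        return peptide_mass(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """A species-tagged collection of protein sequences.

    Parameters
    ----------
    species_tag:
        Short label ("human", "mouse", ...) attached to every peptide this
        proteome contributes to a library.
    entries:
        ``(protein_id, sequence)`` pairs.  Protein ids must be unique within
        the proteome; sequences must be non-empty.
    """

    species_tag: str
    entries: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.species_tag:
            raise ValueError("species_tag must be non-empty")
        seen: set[str] = set()
        for pid, seq in self.entries:
            if pid in seen:
                raise ValueError(f"duplicate protein id {pid!r} in proteome {self.species_tag!r}")
            seen.add(pid)
            if not seq:
                raise ValueError(f"empty sequence for protein {pid!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.entries)

    @property
    def protein_ids(self) -> list[str]:
        return [pid for pid, _ in self.entries]


def _validate_sequence(sequence: str, policy: InvalidPolicy) -> set[int]:
    """Return the positions of non-standard residues, or raise under ``error``."""
    bad = {i for i, aa in enumerate(sequence) if aa not in STANDARD_RESIDUES}
    if bad and policy == "error":
        pos = min(bad)
        raise ValueError(
            f"invalid residue {sequence[pos]!r} at position {pos} "
            "(policy 'skip-peptide' drops affected peptides instead)"
        )
    return bad


def cleavage_sites(sequence: str, rule: CleavageRule = "trypsin") -> list[int]:
    """Positions *after* which trypsin cleaves (0-based index of the K/R).

    ``trypsin`` applies the classical proline restriction (no cleavage when
    the next residue is P); ``trypsin/p`` cleaves regardless.
    """
    if rule not in ("trypsin", "trypsin/p"):
        raise ValueError(f"unknown cleavage rule {rule!r}")
    n = len(sequence)
    sites = []
    for i, aa in enumerate(sequence):
        if aa in "KR" and i < n - 1:
            if rule == "trypsin" and sequence[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def digest_protein(
    sequence: str,
    max_missed: int = 2,
    rule: CleavageRule = "trypsin",
    invalid_policy: InvalidPolicy = "error",
) -> list[Peptide]:
    """Digest one protein, enumerating peptides with 0..max_missed missed cleavages.

    Cleavage is C-terminal to K or R, by default suppressed before proline.
    Every peptide with ``k`` missed cleavages is the concatenation of ``k+1``
    adjacent fully-cleaved fragments.  Output order is deterministic:
    N- to C-terminal start position, then missed-cleavage count.

    Raises
    ------
    ValueError
        If ``max_missed`` is negative, or the sequence contains a residue
        outside the 20-letter alphabet under the default ``error`` policy.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if not sequence:
        raise ValueError("empty sequence")
    bad_positions = _validate_sequence(sequence, invalid_policy)

    sites = cleavage_sites(sequence, rule)
    # Fragment boundaries: starts of the fully-cleaved (0-missed) fragments.
    starts = [0] + [s + 1 for s in sites]
    ends = [s + 1 for s in sites] + [len(sequence)]

    peptides: list[Peptide] = []
    nfrag = len(starts)
    for i in range(nfrag):
        for k in range(min(max_missed, nfrag - 1 - i) + 1):
            a, b = starts[i], ends[i + k]
            if bad_positions and any(a <= p < b for p in bad_positions):
                continue
            peptides.append(Peptide(sequence[a:b], start=a, n_missed=k))
    peptides.sort(key=lambda p: (p.start, p.n_missed))
    return peptides


@dataclass
class LibraryEntry:
    """One I/L-collapsed peptide and everything known about it."""

    il_key: str
    sequence_example: str
    monoisotopic_mass: float
    min_n_missed: int
    parents: set[tuple[str, str]] = field(default_factory=set)  # (species_tag, protein_id)
    observable: bool = False

    def species_tags(self) -> set[str]:
        return {tag for tag, _ in self.parents}


@dataclass
class PeptideLibrary:
    """Peptide → species/protein index over two digested proteomes.

    ``uniqueness_class(il_key)`` returns ``unique_to_<tag>`` when every parent
    of the peptide carries one species tag, else ``shared``.  Uniqueness is
    evaluated over the union of all missed-cleavage variants of both
    proteomes, so a peptide unique at 0 missed cleavages cannot collide with a
    missed-cleavage peptide of the other species.

    ``observable`` marks peptides inside the length and mass windows; iBAQ
    denominators count 0-missed observable peptides only (standard iBAQ
    convention), held per protein in ``observable_counts``.
    """

    species_a: str
    species_b: str
    max_missed: int
    length_window: tuple[int, int]
    mass_window: tuple[float, float]
    entries: dict[str, LibraryEntry] = field(default_factory=dict)
    # (species_tag, protein_id) -> distinct observable 0-missed il_keys
    observable_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    # (species_tag, protein_id) -> set of observable 0-missed il_keys
    observable_peptides: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, il_key: str) -> bool:
        return il_key in self.entries

    def uniqueness_class(self, il_key: str) -> str:
        tags = self.entries[il_key].species_tags()
        if tags == {self.species_a}:
            return f"unique_to_{self.species_a}"
        if tags == {self.species_b}:
            return f"unique_to_{self.species_b}"
        return "shared"

    def unique_keys(self, species_tag: str) -> set[str]:
        """All il_keys whose every parent belongs to ``species_tag``."""
        if species_tag not in (self.species_a, self.species_b):
            raise KeyError(f"unknown species tag {species_tag!r}")
        return {
            k for k, e in self.entries.items() if e.species_tags() == {species_tag}
        }

    def class_counts(self) -> dict[str, int]:
        counts = {f"unique_to_{self.species_a}": 0, f"unique_to_{self.species_b}": 0, "shared": 0}
        for k in self.entries:
            counts[self.uniqueness_class(k)] += 1
        return counts


def _observable(il_key: str, mono_mass: float, length_window, mass_window) -> bool:
    lo, hi = length_window
    mlo, mhi = mass_window
    return lo <= len(il_key) <= hi and mlo <= mono_mass <= mhi


def build_libraries(
    proteome_a: Proteome,
    proteome_b: Proteome,
    max_missed: int = 2,
    length_window: tuple[int, int] = (7, 30),
    mass_window: tuple[float, float] = (700.0, 4600.0),
    rule: CleavageRule = "trypsin",
    invalid_policy: InvalidPolicy = "error",
) -> PeptideLibrary:
    """Digest two proteomes and build the joint species-uniqueness index.

    Defaults follow common practice for observable tryptic peptides: length
    7–30 residues, monoisotopic mass 700–4600 Da, up to 2 missed cleavages.
    """
    if proteome_a.species_tag == proteome_b.species_tag:
        raise ValueError("the two proteomes must carry distinct species tags")
    if len(proteome_a) == 0 or len(proteome_b) == 0:
        raise ValueError("cannot build a library from an empty proteome")

    lib = PeptideLibrary(
        species_a=proteome_a.species_tag,
        species_b=proteome_b.species_tag,
        max_missed=max_missed,
        length_window=length_window,
        mass_window=mass_window,
    )
    lo, hi = length_window
    mlo, mhi = mass_window

    for proteome in (proteome_a, proteome_b):
        tag = proteome.species_tag
        for pid, seq in proteome:
            obs_zero: set[str] = set()
            for pep in digest_protein(seq, max_missed, rule, invalid_policy):
                key = pep.il_key
                entry = lib.entries.get(key)
                if entry is None:
                    m = pep.monoisotopic_mass
                    entry = LibraryEntry(
                        il_key=key,
                        sequence_example=pep.sequence,
                        monoisotopic_mass=m,
                        min_n_missed=pep.n_missed,
                        observable=(lo <= len(key) <= hi and mlo <= m <= mhi),
                    )
                    lib.entries[key] = entry
                else:
                    entry.min_n_missed = min(entry.min_n_missed, pep.n_missed)
                entry.parents.add((tag, pid))
                if pep.n_missed == 0 and entry.observable:
                    obs_zero.add(key)
            lib.observable_peptides[(tag, pid)] = obs_zero
            lib.observable_counts[(tag, pid)] = len(obs_zero)
    return lib


def count_observable_peptides(
    protein_id: str, library: PeptideLibrary, species_tag: str | None = None
) -> int:
    """Distinct observable 0-missed peptides of a protein (the iBAQ denominator).

    ``species_tag`` disambiguates when the same accession exists in both
    proteomes; with one match it may be omitted.  A count of zero means the
    protein is non-quantifiable under the configured windows.
    """
    if species_tag is not None:
        try:
            return library.observable_counts[(species_tag, protein_id)]
        except KeyError:
            raise KeyError(f"protein {protein_id!r} ({species_tag}) not in library") from None
    matches = [k for k in library.observable_counts if k[1] == protein_id]
    if not matches:
        raise KeyError(f"protein {protein_id!r} not in library")
    if len(matches) > 1:
        raise KeyError(f"protein {protein_id!r} ambiguous across species; pass species_tag")
    return library.observable_counts[matches[0]]
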