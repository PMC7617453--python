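"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA goes through Biopython; tables are tab-separated and read into pandas.
All writers are deterministic so that identically-seeded runs produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .digest import PeptideLibrary, LibraryEntry, Proteome

LIBRARY_FORMAT_VERSION = "1"
_LIBRARY_HEADER = f"#xenotrace-peptide-library\tv{LIBRARY_FORMAT_VERSION}"


def parse_accession(header_id: str) -> str:
    """Accession from a FASTA id: the token between the first two '|' of a
    UniProt-style ``db|ACC|NAME`` id if present, else the id itself."""
    parts = header_id.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return header_id


def read_proteome(path: str | Path, species_tag: str) -> Proteome:
    """Load a proteome FASTA; accessions parsed from UniProt-style headers."""
    entries: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        entries.append((parse_accession(rec.id), seq))
    if not entries:
        raise ValueError(f"no FASTA records in {path}")
    return Proteome(species_tag=species_tag, entries=entries)


def write_proteome(proteome: Proteome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteome:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_library(library: PeptideLibrary, path: str | Path) -> None:
    """Export a peptide library as a versioned tab-separated table."""
    with open(path, "w") as fh:
        fh.write(_LIBRARY_HEADER + "\n")
        fh.write(
            f"#species_a={library.species_a}\tspecies_b={library.species_b}"
            f"\tmax_missed={library.max_missed}"
            f"\tlength_window={library.length_window[0]}-{library.length_window[1]}"
            f"\tmass_window={library.mass_window[0]}-{library.mass_window[1]}\n"
        )
        fh.write("il_key\tsequence_example\tspecies_class\tparents\tobservable\tmass\tn_missed\n")
        for key in sorted(library.entries):
            e = library.entries[key]
            parents = ";".join(f"{t}:{p}" for t, p in sorted(e.parents))
            fh.write(
                f"{key}\t{e.sequence_example}\t{library.uniqueness_class(key)}\t{parents}"
                f"\t{int(e.observable)}\t{e.monoisotopic_mass:.5f}\t{e.min_n_missed}\n"
            )


def read_library(path: str | Path) -> PeptideLibrary:
    """Re-load a library written by :func:`write_library`."""
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#xenotrace-peptide-library"):
            raise ValueError(f"{path} is not a xenotrace peptide library (missing header)")
        meta = dict(
            kv.split("=", 1) for kv in fh.readline().lstrip("#").rstrip("\n").split("\t")
        )
        lw = tuple(int(x) for x in meta["length_window"].split("-"))
        mw = tuple(float(x) for x in meta["mass_window"].split("-"))
        lib = PeptideLibrary(
            species_a=meta["species_a"],
            species_b=meta["species_b"],
            max_missed=int(meta["max_missed"]),
            length_window=(lw[0], lw[1]),
            mass_window=(mw[0], mw[1]),
        )
        header = fh.readline().rstrip("\n").split("\t")
        assert header[0] == "il_key"
        for line in fh:
            key, seq, _cls, parents, obs, mass, n_missed = line.rstrip("\n").split("\t")
            parent_set = {
                (tok.split(":", 1)[0], tok.split(":", 1)[1]) for tok in parents.split(";") if tok
            }
            lib.entries[key] = LibraryEntry(
                il_key=key,
                sequence_example=seq,
                monoisotopic_mass=float(mass),
                min_n_missed=int(n_missed),
                parents=parent_set,
                observable=bool(int(obs)),
            )
    # Rebuild per-protein observable 0-missed counts from entries.
    for key, e in lib.entries.items():
        if e.observable and e.min_n_missed == 0:
            for parent in e.parents:
                lib.observable_peptides.setdefault(parent, set()).add(key)
    lib.observable_counts = {p: len(s) for p, s in lib.observable_peptides.items()}
    return lib


def read_evidence(path: str | Path) -> pd.DataFrame:
    """Read a peptide-evidence table.

    Accepts the native tab-separated schema (``peptide``, ``intensity``,
    optional ``spectral_count``, optional ``sample``) or a MaxQuant-style
    peptide table (``Sequence``, ``Intensity``) mapped onto the same schema.
    Duplicate (peptide, sample) rows are aggregated by summing.
    """
    df = pd.read_csv(path, sep="\t")
    if "Sequence" in df.columns:  # MaxQuant peptides.txt dialect
        rename = {"Sequence": "peptide", "Intensity": "intensity"}
        df = df.rename(columns=rename)
    required = {"peptide", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    if "sample" not in df.columns:
        df["sample"] = "S1"
    df["intensity"] = pd.to_numeric(df["intensity"], errors="raise")
    if not np.isfinite(df["intensity"]).all():
        raise ValueError("evidence intensities must be finite")
    if (df["intensity"] < 0).any():
        row = int(df.index[df["intensity"] < 0][0])
        raise ValueError(f"negative intensity at row {row}")
    agg = {"intensity": "sum"}
    if "spectral_count" in df.columns:
        agg["spectral_count"] = "sum"
    out = df.groupby(["peptide", "sample"], as_index=False).agg(agg)
    return out


def write_evidence(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Protein × sample spectral-count matrix (first column = protein id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    # The study's own NA policy: NA values substituted for 0 at load time.
    return df.fillna(0.0)


def read_design(path: str | Path) -> pd.Series:
    """Two-column sample→group design file (TSV, with or without header)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise ValueError("design file must have exactly two columns: sample, group")
    if list(df.columns[:2]) != ["sample", "group"]:
        # treat the header row as data when unlabeled
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"])
    return df.set_index("sample")["group"]


def read_points(path: str | Path) -> pd.DataFrame:
    """Cell-coordinate table: id, x, y, class."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "x", "y", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"points table missing columns: {sorted(missing)}")
    return df


def read_gene_set(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def read_annotation(path: str | Path) -> dict[str, set[str]]:
    """Two-column term→gene TSV into a term → gene-set mapping."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["term", "gene"])
    mapping: dict[str, set[str]] = {}
    for term, gene in zip(df["term"], df["gene"]):
        mapping.setdefault(str(term), set()).add(str(gene))
    return mapping


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
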