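"""Species-of-origin deconvolution of xenograft peptide evidence.

Observed peptides are matched (I/L-collapsed) against the two-species
library, protein groups are formed by parsimony, each group is classified as
host-exclusive / graft-exclusive / conserved, quantified by iBAQ, and the
strongest candidates are flagged by the paper-style enrichment rule: both the
iBAQ score and the observed/expected peptide ratio strictly above their
species-class means.

Host-exclusive groups — proteins whose every observed peptide maps uniquely
to the host library — are the candidate microenvironment-transferred set: in
a pure graft cell population there is no reason to observe host-unique
peptides at all unless host protein physically entered the graft cells (or
contaminated the sort).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .digest import PeptideLibrary, il_collapse

__all__ = [
    "Assignments",
    "ProteinCall",
    "assign_peptides",
    "classify_proteins",
    "quantify_ibaq",
    "call_enriched",
    "category_composition",
    "marker_overlap",
    "calls_to_frame",
]

HOST_EXCLUSIVE = "host_exclusive"
GRAFT_EXCLUSIVE = "graft_exclusive"
CONSERVED = "conserved"


@dataclass
class Assignments:
    """Peptide-level species assignment of an evidence table."""

    table: pd.DataFrame  # peptide, il_key, intensity, label, parents
    library: PeptideLibrary
    unmatched_fraction: float

    @property
    def matched(self) -> pd.DataFrame:
        return self.table[self.table["label"] != "unmatched"]


@dataclass
class ProteinCall:
    """Per protein-group species class, quantification and enrichment flag."""

    protein_id: str
    species_tag: str
    species_class: str
    group_members: tuple[str, ...]  # accessions subsumed by parsimony
    n_observed_peptides: int
    n_expected_peptides: int = 0
    obs_exp_ratio: float = math.nan
    intensity_sum: float = math.nan
    ibaq: float = math.nan
    ibaq_ppm: float = math.nan
    ibaq_score: float = math.nan
    quantifiable: bool = True
    enriched: bool | None = None


def assign_peptides(evidence: pd.DataFrame, library: PeptideLibrary) -> Assignments:
    """Label each observed peptide as unique to one species, shared, or unmatched.

    Evidence rows are aggregated per peptide (summing intensity across
    samples — the label-free analysis pools measurements before
    quantification; use per-sample slices upstream for anything else).
    """
    if evidence.empty:
        raise ValueError("evidence table is empty")
    agg = {"intensity": "sum"}
    if "spectral_count" in evidence.columns:
        agg["spectral_count"] = "sum"
    per_pep = evidence.groupby("peptide", as_index=False).agg(agg)
    per_pep["il_key"] = [il_collapse(p) for p in per_pep["peptide"]]

    labels: list[str] = []
    parents: list[tuple] = []
    for key in per_pep["il_key"]:
        entry = library.entries.get(key)
        if entry is None:
            labels.append("unmatched")
            parents.append(())
        else:
            labels.append(library.uniqueness_class(key))
            parents.append(tuple(sorted(entry.parents)))
    per_pep["label"] = labels
    per_pep["parents"] = parents

    unmatched = float((per_pep["label"] == "unmatched").mean())
    if unmatched == 1.0:
        warnings.warn("no observed peptide matched the library", stacklevel=2)
    return Assignments(table=per_pep, library=library, unmatched_fraction=unmatched)


def _greedy_parsimony(
    protein_peptides: Mapping[tuple[str, str], set[str]],
) -> list[tuple[tuple[str, str], tuple[tuple[str, str], ...]]]:
    """Greedy minimal set cover of observed peptides by candidate proteins.

    Returns ``(lead, members)`` pairs in selection order; ``members`` are the
    candidate proteins whose entire observed peptide set is contained in the
    lead's (the indistinguishable/subset proteins grouped under the lead).
    Ties break lexicographically on (species_tag, protein_id) so grouping is
    deterministic.
    """
    import heapq

    if not protein_peptides:
        return []
    uncovered: set[str] = set().union(*protein_peptides.values())
    remaining = set(protein_peptides)
    by_peptide: dict[str, list[tuple[str, str]]] = {}
    for prot, peps in protein_peptides.items():
        for k in peps:
            by_peptide.setdefault(k, []).append(prot)

    # Lazy-deletion max-heap on (coverage of uncovered peptides, smallest id).
    heap = [(-len(s), p) for p, s in protein_peptides.items()]
    heapq.heapify(heap)
    groups: list[tuple[tuple[str, str], tuple[tuple[str, str], ...]]] = []
    while uncovered and heap:
        neg_cov, lead = heapq.heappop(heap)
        if lead not in remaining:
            continue
        true_cov = len(protein_peptides[lead] & uncovered)
        if true_cov != -neg_cov:  # stale entry: re-queue with current coverage
            if true_cov > 0:
                heapq.heappush(heap, (-true_cov, lead))
            else:
                remaining.discard(lead)
            continue
        lead_set = protein_peptides[lead]
        candidates = {p for k in lead_set for p in by_peptide[k] if p in remaining}
        members = tuple(sorted(p for p in candidates if protein_peptides[p] <= lead_set))
        groups.append((lead, members))
        uncovered -= lead_set
        remaining.difference_update(members)
        remaining.discard(lead)
    return groups


def classify_proteins(
    assignments: Assignments,
    min_peptides: int = 2,
    host_tag: str | None = None,
    mode: Literal["strict", "relaxed"] = "strict",
) -> list[ProteinCall]:
    """Group peptide evidence by parsimony and classify groups by species.

    A group is host-exclusive iff all of its distinct observed peptides are
    unique to the host library (``strict``; the ``relaxed`` mode requires at
    least one host-unique and zero graft-unique peptides), graft-exclusive
    symmetrically, conserved otherwise.  Groups with fewer than
    ``min_peptides`` distinct peptides are dropped, mirroring the common
    two-peptide identification rule.

    ``host_tag`` names which library species is the host (defaults to
    ``library.species_b``, i.e. the second proteome passed to
    :func:`~xenotrace.digest.build_libraries`).
    """
    if min_peptides < 1:
        raise ValueError("min_peptides must be >= 1")
    lib = assignments.library
    host = host_tag if host_tag is not None else lib.species_b
    if host not in (lib.species_a, lib.species_b):
        raise ValueError(f"host_tag {host!r} not among library species")
    graft = lib.species_a if host == lib.species_b else lib.species_b

    matched = assignments.matched
    protein_peptides: dict[tuple[str, str], set[str]] = {}
    for key, parents in zip(matched["il_key"], matched["parents"]):
        for parent in parents:
            protein_peptides.setdefault(parent, set()).add(key)

    label_by_key = dict(zip(matched["il_key"], matched["label"]))
    host_unique = f"unique_to_{host}"
    graft_unique = f"unique_to_{graft}"

    calls: list[ProteinCall] = []
    for (tag, pid), members in _greedy_parsimony(protein_peptides):
        peptides = protein_peptides[(tag, pid)]
        if len(peptides) < min_peptides:
            continue
        lbls = {label_by_key[k] for k in peptides}
        if mode == "strict":
            if lbls == {host_unique}:
                cls = HOST_EXCLUSIVE
            elif lbls == {graft_unique}:
                cls = GRAFT_EXCLUSIVE
            else:
                cls = CONSERVED
        else:
            if host_unique in lbls and graft_unique not in lbls:
                cls = HOST_EXCLUSIVE
            elif graft_unique in lbls and host_unique not in lbls:
                cls = GRAFT_EXCLUSIVE
            else:
                cls = CONSERVED
        calls.append(
            ProteinCall(
                protein_id=pid,
                species_tag=tag,
                species_class=cls,
                group_members=tuple(f"{t}:{p}" for t, p in members),
                n_observed_peptides=len(peptides),
            )
        )
    return calls


def quantify_ibaq(
    calls: list[ProteinCall],
    assignments: Assignments,
    library: PeptideLibrary | None = None,
) -> list[ProteinCall]:
    """Fill iBAQ quantities on classified protein groups (in place).

    iBAQ = summed intensity of the group's assigned peptides divided by the
    lead protein's count of theoretically observable peptides; iBAQ_ppm
    renormalizes iBAQ to parts-per-million of the run total; the iBAQ score
    is log10 of iBAQ_ppm.  Each peptide's intensity is credited to exactly
    one parsimony group (the first group, in selection order, containing one
    of its parents); groups with zero observable peptides are flagged
    non-quantifiable and excluded from the ppm normalization.
    """
    lib = library if library is not None else assignments.library
    matched = assignments.matched
    intens_by_key = dict(zip(matched["il_key"], matched["intensity"]))
    parents_by_key = dict(zip(matched["il_key"], matched["parents"]))

    member_to_call: dict[str, ProteinCall] = {}
    for call in calls:  # calls are in parsimony selection order
        for m in call.group_members:
            member_to_call.setdefault(m, call)
        member_to_call.setdefault(f"{call.species_tag}:{call.protein_id}", call)

    order = {id(c): i for i, c in enumerate(calls)}
    sums: dict[int, float] = {id(c): 0.0 for c in calls}
    for key, parents in parents_by_key.items():
        target: ProteinCall | None = None
        for t, p in parents:
            c = member_to_call.get(f"{t}:{p}")
            if c is not None and (target is None or order[id(c)] < order[id(target)]):
                target = c
        if target is not None:
            sums[id(target)] += float(intens_by_key[key])

    total_ibaq = 0.0
    for call in calls:
        n_exp = lib.observable_counts.get((call.species_tag, call.protein_id), 0)
        call.n_expected_peptides = n_exp
        call.intensity_sum = sums[id(call)]
        if n_exp > 0:
            call.obs_exp_ratio = call.n_observed_peptides / n_exp
            call.ibaq = call.intensity_sum / n_exp
            call.quantifiable = True
            total_ibaq += call.ibaq
        else:
            call.quantifiable = False
            call.obs_exp_ratio = math.nan
            call.ibaq = math.nan
    for call in calls:
        if call.quantifiable and total_ibaq > 0:
            call.ibaq_ppm = call.ibaq / total_ibaq * 1e6
            call.ibaq_score = math.log10(call.ibaq_ppm) if call.ibaq_ppm > 0 else -math.inf
        else:
            call.ibaq_ppm = math.nan
            call.ibaq_score = math.nan
    return calls


def call_enriched(
    calls: list[ProteinCall],
    class_filter: Iterable[str] | None = None,
    rule: Literal["both", "sum"] = "both",
) -> dict[str, dict[str, float]]:
    """Flag enriched proteins within each species class (in place).

    Default rule: a protein is enriched when its iBAQ score AND its
    observed/expected ratio are strictly above the arithmetic means of its
    species class.  The alternative ``sum`` rule thresholds the sum of the
    two metrics against the class mean sum.  Classes with fewer than two
    quantifiable members leave enrichment undefined (``None``).

    Returns the per-class thresholds used.
    """
    classes = sorted({c.species_class for c in calls})
    if class_filter is not None:
        classes = [c for c in classes if c in set(class_filter)]
    thresholds: dict[str, dict[str, float]] = {}
    for cls in classes:
        members = [c for c in calls if c.species_class == cls and c.quantifiable]
        if len(members) < 2:
            for c in members:
                c.enriched = None
            thresholds[cls] = {"n": len(members), "defined": False}
            continue
        mean_score = float(np.mean([c.ibaq_score for c in members]))
        mean_ratio = float(np.mean([c.obs_exp_ratio for c in members]))
        for c in members:
            if rule == "both":
                c.enriched = bool(c.ibaq_score > mean_score and c.obs_exp_ratio > mean_ratio)
            else:
                c.enriched = bool(
                    c.ibaq_score + c.obs_exp_ratio > mean_score + mean_ratio
                )
        thresholds[cls] = {
            "n": len(members),
            "defined": True,
            "mean_ibaq_score": mean_score,
            "mean_obs_exp_ratio": mean_ratio,
        }
    return thresholds


def category_composition(
    calls: list[ProteinCall], category_map: Mapping[str, str]
) -> pd.Series:
    """Percentage of enriched proteins per functional category.

    ``category_map`` maps protein accessions to category names; enriched
    proteins without a mapping are binned as ``other``.  Returns an empty
    series when nothing is enriched.
    """
    enriched = [c for c in calls if c.enriched]
    if not enriched:
        return pd.Series(dtype=float)
    cats = [category_map.get(c.protein_id, "other") for c in enriched]
    frac = pd.Series(cats).value_counts() / len(enriched) * 100.0
    return frac.sort_values(ascending=False)


def marker_overlap(
    detected_proteins: Iterable[str],
    marker_list: Sequence[str],
    case_insensitive: bool = True,
) -> tuple[int, list[str]]:
    """Count how many marker identifiers occur among detected proteins.

    Returns ``(n_detected, missing)`` — e.g. 93 of a 100-marker EV panel
    present, with the 7 absentees listed.
    """
    if not marker_list:
        raise ValueError("marker_list must be non-empty")
    norm = (lambda s: s.upper()) if case_insensitive else (lambda s: s)
    detected = {norm(p) for p in detected_proteins}
    missing = [m for m in marker_list if norm(m) not in detected]
    return len(marker_list) - len(missing), missing


def calls_to_frame(calls: list[ProteinCall]) -> pd.DataFrame:
    """Protein calls as a tidy DataFrame (one row per parsimony group)."""
    rows = []
    for c in calls:
        d = asdict(c)
        d["group_members"] = ";".join(c.group_members)
        rows.append(d)
    return pd.DataFrame(rows)
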