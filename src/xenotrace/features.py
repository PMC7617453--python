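"""Transcript-feature comparison and over-representation analysis.

Gene sets recovered by the proteomic deconvolution (e.g. genes encoding
transferred vs background proteins) are compared on transcript features —
5'UTR length, 3'UTR length, GC content — with Welch's unpaired two-tailed
t-test, and tested for functional over-representation with the
hypergeometric test.  Annotation (GO, KEGG, ...) is user-supplied as a
term→gene table, keeping results database-version independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "gc_content",
    "feature_table_from_fasta",
    "compare_feature",
    "FeatureComparison",
    "ora",
]

FEATURE_ALIASES = {
    "utr5": "utr5_length",
    "utr3": "utr3_length",
    "gc": "gc_percent",
    "utr5_length": "utr5_length",
    "utr3_length": "utr3_length",
    "gc_percent": "gc_percent",
}


def gc_content(sequence: str) -> float:
    """GC percentage of a nucleotide sequence; N is excluded, U equals T."""
    s = sequence.upper()
    counts = {b: s.count(b) for b in "ACGTUN"}
    if len(s) != sum(counts.values()):
        bad = sorted(set(s) - set("ACGTUN"))
        raise ValueError(f"invalid nucleotide(s) {bad} in sequence")
    denom = counts["A"] + counts["C"] + counts["G"] + counts["T"] + counts["U"]
    if denom == 0:
        raise ValueError("no countable nucleotides (sequence empty or all N)")
    return 100.0 * (counts["G"] + counts["C"]) / denom


def feature_table_from_fasta(
    transcripts: Mapping[str, str], utr_coords: pd.DataFrame
) -> pd.DataFrame:
    """Build a gene-feature table from transcript sequences plus UTR coordinates.

    ``utr_coords`` columns: gene, utr5_start, utr5_end, utr3_start, utr3_end
    (1-based inclusive positions on the transcript).  GC content is computed
    over the full transcript.
    """
    rows = []
    for _, r in utr_coords.iterrows():
        gene = r["gene"]
        seq = transcripts[gene]
        utr5 = int(r["utr5_end"]) - int(r["utr5_start"]) + 1 if r["utr5_end"] >= r["utr5_start"] else 0
        utr3 = int(r["utr3_end"]) - int(r["utr3_start"]) + 1 if r["utr3_end"] >= r["utr3_start"] else 0
        rows.append(
            {"gene_id": gene, "utr5_length": utr5, "utr3_length": utr3,
             "gc_percent": gc_content(seq)}
        )
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class FeatureComparison:
    feature: str
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int


def compare_feature(
    set_a: Iterable[str],
    set_b: Iterable[str],
    table: pd.DataFrame,
    feature: str,
) -> FeatureComparison:
    """Welch's unpaired two-tailed t-test of one transcript feature between
    two gene sets (genes absent from the table are ignored)."""
    col = FEATURE_ALIASES.get(feature)
    if col is None or col not in table.columns:
        raise ValueError(f"feature {feature!r} not available; have {list(table.columns)}")
    a = table.loc[table.index.intersection(list(set_a)), col].dropna().to_numpy(float)
    b = table.loc[table.index.intersection(list(set_b)), col].dropna().to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each gene set needs >= 2 genes present in the table")
    res = stats.ttest_ind(a, b, equal_var=False)
    return FeatureComparison(
        feature=col,
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n_a=len(a),
        n_b=len(b),
    )


def ora(
    selection: Iterable[str],
    universe: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation analysis of a gene selection.

    For each term with ``K`` genes in the universe and ``k`` in the selection
    of size ``n`` (universe size ``N``): upper-tail p = P[X >= k] under the
    hypergeometric null, fold enrichment = (k/n)/(K/N), and BH q-values
    across the tested terms.  Terms with no universe genes are skipped.
    """
    sel = set(selection)
    uni = set(universe)
    offenders = sorted(sel - uni)
    if offenders:
        raise ValueError(f"selection not contained in universe: {offenders[:10]}")
    if not sel:
        raise ValueError("empty selection")
    N, n = len(uni), len(sel)
    rows = []
    for term, genes in annotation.items():
        term_genes = set(genes) & uni
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & sel)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        rows.append({"term_id": term, "k": k, "K": K, "n": n, "N": N,
                     "fold_enrichment": fold, "p": min(p, 1.0)})
    if not rows:
        return pd.DataFrame(columns=["term_id", "k", "K", "n", "N", "fold_enrichment", "p", "q"])
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values(["p", "term_id"]).reset_index(drop=True)
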