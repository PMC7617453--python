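"""Synthetic xenograft-proteomics and niche-imaging data with ground truth.

Every generator is a pure function of its configuration (seed included), so
identical configs give identical outputs, and every emitted record is
traceable to ground truth.  The default configuration mirrors the scale of a
PDX label-free experiment: ~1,900 conserved ortholog pairs plus ~120
species-specific proteins per side, with a handful of host proteins planted
at high abundance in the graft sample to emulate microenvironmental protein
transfer.

What is emulated: homologous proteome pairs with controlled divergence,
log-normal protein abundances, abundance-dependent peptide detection,
multiplicative intensity noise, negative-binomial spectral counts with
planted effects, and spatial point patterns with exponential-decay niche
attraction.  What is not: real ortholog structure (substitutions are iid,
no indels), post-translational modifications, retention-time or spectrum
level effects, 3-D tissue geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .digest import Proteome, PeptideLibrary
from .spatial import PointPattern

__all__ = [
    "SimulationConfig",
    "AA_FREQUENCIES",
    "make_proteomes",
    "simulate_xenograft",
    "simulate_counts",
    "simulate_points",
]

# Approximate amino-acid background frequencies of well-curated protein
# databases (percent); normalized before sampling.
AA_FREQUENCIES: dict[str, float] = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.72, "G": 7.07, "H": 2.27, "I": 5.91,
    "L": 9.65, "K": 5.80, "M": 2.41, "F": 3.86, "P": 4.73,
    "S": 6.64, "T": 5.35, "W": 1.10, "Y": 2.92, "V": 6.86,
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with PDX-scale defaults."""

    seed: int = 0
    # proteome pair
    graft_tag: str = "human"
    host_tag: str = "mouse"
    n_conserved: int = 1900
    n_host_specific: int = 120
    n_graft_specific: int = 120
    substitution_rate: float = 0.15  # per-residue, conserved ortholog pairs
    length_log_mean: float = math.log(330.0)  # residues, log-normal
    length_log_sigma: float = 0.35
    min_length: int = 60
    max_length: int = 1500
    # xenograft MS run
    n_transferred: int = 8
    transfer_abundance_multiplier: float = 8.0
    abundance_sigma: float = 1.0  # natural-log sd of protein abundance
    detection_slope: float = 2.0  # logistic slope per decade of abundance
    detection_midpoint: float = 0.3  # abundance at 50% peptide detection
    intensity_cv: float = 0.3  # multiplicative peptide intensity noise
    # spectral-count matrix
    n_proteins: int = 1000
    n_per_group: int = 3
    count_log_mean: float = math.log(30.0)
    count_log_sigma: float = 1.0
    nb_size: float = 8.0  # negative-binomial dispersion (larger = tighter)
    effect_fraction: float = 0.05
    effect_log2fc: float = 2.0
    # spatial pattern
    field_size: tuple[float, float] = (1000.0, 1000.0)  # μm
    n_reference: int = 50
    n_query: int = 200
    n_background: int = 1000
    attraction_scale: float | None = 25.0  # λ (μm); None = CSR query points

    def __post_init__(self) -> None:
        for name in ("n_conserved", "n_host_specific", "n_graft_specific",
                     "n_transferred", "n_proteins", "n_per_group",
                     "n_reference", "n_query", "n_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")
        if self.attraction_scale is not None and self.attraction_scale <= 0:
            raise ValueError("attraction_scale must be positive")


_AAS = np.array(list(AA_FREQUENCIES))
_AAP = np.array(list(AA_FREQUENCIES.values()))
_AAP = _AAP / _AAP.sum()


def _random_protein(rng: np.random.Generator, cfg: SimulationConfig) -> str:
    for _ in range(100):
        n = int(np.clip(round(rng.lognormal(cfg.length_log_mean, cfg.length_log_sigma)),
                        cfg.min_length, cfg.max_length))
        if n > 0:
            return "".join(rng.choice(_AAS, size=n, p=_AAP))
    raise RuntimeError("failed to draw a non-empty protein length")  # pragma: no cover


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """iid substitutions at ``rate``; each hit becomes one of the 19 others."""
    if rate == 0:
        return seq
    arr = np.array(list(seq))
    hits = rng.random(len(arr)) < rate
    idx = np.where(hits)[0]
    for i in idx:
        choices = _AAS[_AAS != arr[i]]
        arr[i] = rng.choice(choices)
    return "".join(arr)


def make_proteomes(cfg: SimulationConfig) -> tuple[Proteome, Proteome, pd.DataFrame]:
    """Generate a homologous (graft, host) proteome pair with ground truth.

    Conserved pairs share an ancestor sequence with iid substitutions applied
    on the host copy; species-specific proteins are drawn independently.
    Returns ``(graft_proteome, host_proteome, truth)`` where ``truth`` has one
    row per protein: id, species, kind, pair id.
    """
    rng = np.random.default_rng(cfg.seed)
    graft_entries, host_entries, rows = [], [], []
    for i in range(cfg.n_conserved):
        base = _random_protein(rng, cfg)
        gid, hid = f"{cfg.graft_tag}_cons{i:04d}", f"{cfg.host_tag}_cons{i:04d}"
        graft_entries.append((gid, base))
        host_entries.append((hid, _mutate(rng, base, cfg.substitution_rate)))
        rows.append({"protein_id": gid, "species": cfg.graft_tag, "kind": "conserved", "pair": i})
        rows.append({"protein_id": hid, "species": cfg.host_tag, "kind": "conserved", "pair": i})
    for i in range(cfg.n_graft_specific):
        gid = f"{cfg.graft_tag}_spec{i:04d}"
        graft_entries.append((gid, _random_protein(rng, cfg)))
        rows.append({"protein_id": gid, "species": cfg.graft_tag, "kind": "graft_specific", "pair": -1})
    for i in range(cfg.n_host_specific):
        hid = f"{cfg.host_tag}_spec{i:04d}"
        host_entries.append((hid, _random_protein(rng, cfg)))
        rows.append({"protein_id": hid, "species": cfg.host_tag, "kind": "host_specific", "pair": -1})
    truth = pd.DataFrame(rows)
    return (
        Proteome(cfg.graft_tag, graft_entries),
        Proteome(cfg.host_tag, host_entries),
        truth,
    )


def simulate_xenograft(
    cfg: SimulationConfig,
    proteomes: tuple[Proteome, Proteome],
    library: PeptideLibrary,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a label-free MS run on sorted graft cells.

    All graft-side proteins are present with log-normal abundances (median
    1, in arbitrary intensity units).  ``n_transferred`` host-specific
    proteins are planted at ``transfer_abundance_multiplier`` × the median
    graft abundance — the transferred set; the remaining host proteins are
    absent, as expected for a pure sorted graft population.  Each observable
    0-missed peptide of a present protein is detected with probability
    logistic in log10 abundance, and detected peptides carry intensity =
    protein abundance × log-normal noise; peptides shared between present
    proteins are emitted once with summed contributions.

    Returns ``(evidence, truth)``: an evidence table (peptide, intensity,
    sample) and a per-protein ground-truth table (abundance, transferred).
    """
    graft, host = proteomes
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    host_specific = [pid for pid, _ in host if "_spec" in pid]
    host_conserved = [pid for pid, _ in host if pid not in set(host_specific)]
    if cfg.n_transferred > len(host_specific) + len(host_conserved):
        raise ValueError("n_transferred exceeds available host proteins")
    # Transfers are drawn from host-specific proteins first (they are the ones
    # recoverable as host-exclusive calls); conserved orthologs only if asked
    # for more than the host-specific pool holds.
    if cfg.n_transferred <= len(host_specific):
        transferred = [str(p) for p in
                       rng.choice(host_specific, size=cfg.n_transferred, replace=False)]
    else:
        extra = cfg.n_transferred - len(host_specific)
        transferred = list(host_specific) + [
            str(p) for p in rng.choice(host_conserved, size=extra, replace=False)]
    transferred = sorted(transferred)

    abundances: dict[tuple[str, str], float] = {}
    graft_ab = rng.lognormal(0.0, cfg.abundance_sigma, size=len(graft))
    for (pid, _), a in zip(graft, graft_ab):
        abundances[(cfg.graft_tag, pid)] = float(a)
    median_graft = float(np.median(graft_ab))
    for pid in transferred:
        abundances[(cfg.host_tag, pid)] = cfg.transfer_abundance_multiplier * median_graft

    sigma_noise = math.sqrt(math.log(1.0 + cfg.intensity_cv**2))
    log_mid = math.log10(cfg.detection_midpoint)
    intensity: dict[str, float] = {}
    sources: dict[str, list[str]] = {}
    truth_rows = []
    for (tag, pid), a in abundances.items():
        peps = library.observable_peptides.get((tag, pid), set())
        p_det = float(expit(cfg.detection_slope * (math.log10(a) - log_mid)))
        n_det = 0
        if peps:
            keys = sorted(peps)
            det = rng.random(len(keys)) < p_det
            noise = np.exp(rng.normal(0.0, sigma_noise, size=len(keys))) if sigma_noise > 0 \
                else np.ones(len(keys))
            for k, hit, nz in zip(keys, det, noise):
                if hit:
                    intensity[k] = intensity.get(k, 0.0) + a * float(nz)
                    sources.setdefault(k, []).append(f"{tag}:{pid}")
                    n_det += 1
        truth_rows.append({
            "protein_id": pid, "species": tag, "abundance": a,
            "transferred": tag == cfg.host_tag, "n_observable": len(peps),
            "n_detected": n_det, "detection_prob": p_det,
        })

    ev_rows = [
        {"peptide": library.entries[k].sequence_example, "intensity": v, "sample": "S1",
         "source_proteins": ";".join(sorted(sources[k]))}
        for k, v in sorted(intensity.items())
    ]
    evidence = pd.DataFrame(ev_rows, columns=["peptide", "intensity", "sample", "source_proteins"])
    truth = pd.DataFrame(truth_rows)
    return evidence, truth


def simulate_counts(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Negative-binomial spectral-count matrix with planted group effects.

    Two groups of ``n_per_group`` samples; per-protein baseline means are
    log-normal, a seeded ``effect_fraction`` of proteins carries a
    ``effect_log2fc`` shift in group B, and missingness (zero counts) arises
    naturally at low abundance from the counting distribution.

    Returns ``(counts, design, truth)``.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_proteins
    mu = rng.lognormal(cfg.count_log_mean, cfg.count_log_sigma, size=n)
    n_effect = int(round(cfg.effect_fraction * n))
    effect_idx = rng.choice(n, size=n_effect, replace=False) if n_effect else np.array([], int)
    log2fc = np.zeros(n)
    log2fc[effect_idx] = cfg.effect_log2fc

    samples = [f"A{i+1}" for i in range(cfg.n_per_group)] + \
              [f"B{i+1}" for i in range(cfg.n_per_group)]
    groups = ["A"] * cfg.n_per_group + ["B"] * cfg.n_per_group
    data = {}
    for s, g in zip(samples, groups):
        m = mu * (2.0 ** log2fc) if g == "B" else mu
        p = cfg.nb_size / (cfg.nb_size + m)
        data[s] = rng.negative_binomial(cfg.nb_size, p)
    counts = pd.DataFrame(data, index=[f"prot{i:04d}" for i in range(n)])
    design = pd.Series(groups, index=samples, name="group")
    truth = pd.DataFrame(
        {"protein_id": counts.index, "baseline_mean": mu, "true_log2fc": log2fc}
    ).set_index("protein_id")
    return counts, design, truth


def simulate_points(
    cfg: SimulationConfig, seed: int | None = None, max_tries_per_point: int = 2000
) -> tuple[PointPattern, pd.DataFrame]:
    """Spatial point pattern with optional niche attraction.

    Reference and background points are uniform in the field (CSR).  Query
    points are uniform when ``attraction_scale`` is None; otherwise a
    candidate at nearest-reference distance d is accepted with probability
    exp(−d/λ) — an exponential-decay attraction toward the niche.

    Returns ``(pattern, truth)`` where ``truth`` records each point's
    generative class.
    """
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    w, h = cfg.field_size

    def uniform(n: int) -> np.ndarray:
        return rng.uniform([0, 0], [w, h], size=(n, 2))

    ref = uniform(cfg.n_reference)
    bg = uniform(cfg.n_background)
    tree = cKDTree(ref)
    if cfg.attraction_scale is None:
        query = uniform(cfg.n_query)
    else:
        lam = cfg.attraction_scale
        pts = []
        budget = max_tries_per_point * max(cfg.n_query, 1)
        while len(pts) < cfg.n_query and budget > 0:
            chunk = min(4096, budget)
            cand = uniform(chunk)
            d, _ = tree.query(cand, k=1)
            accept = rng.random(chunk) < np.exp(-np.asarray(d) / lam)
            pts.extend(cand[accept])
            budget -= chunk
        if len(pts) < cfg.n_query:
            raise RuntimeError(
                "rejection sampling budget exhausted; increase attraction_scale, "
                "reference density, or max_tries_per_point"
            )
        query = np.array(pts[: cfg.n_query])

    rows = []
    for cls, pts_arr in (("reference", ref), ("query", query), ("background", bg)):
        for i, (x, y) in enumerate(pts_arr):
            rows.append({"id": f"{cls[0]}{i:05d}", "x": float(x), "y": float(y), "class": cls})
    df = pd.DataFrame(rows)
    pattern = PointPattern(points=df, bounds=(0.0, 0.0, float(w), float(h)))
    truth = df.assign(
        generative=np.where(
            (df["class"] == "query") & (cfg.attraction_scale is not None),
            "attraction", "csr",
        )
    )
    return pattern, truth
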