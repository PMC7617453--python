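"""End-to-end orchestration of the xenograft transfer analysis.

``run_pdx_analysis`` chains digestion → library → assignment →
classification → iBAQ → enrichment → (optional) category composition, ORA
and transcript-feature comparison, writing every stage output plus a run
manifest with config snapshot, input checksums and seeds — a rerun from the
same manifest and inputs reproduces identical deterministic outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as xio
from .deconv import (
    assign_peptides,
    call_enriched,
    calls_to_frame,
    category_composition,
    classify_proteins,
    quantify_ibaq,
)
from .digest import build_libraries
from .features import compare_feature, ora

logger = logging.getLogger("xenotrace")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_STAGE = 3


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    version: str = __version__
    input_checksums: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)  # name -> {status, outputs{path: sha}}

    def record_stage(self, name: str, status: str, outputs: dict[str, str] | None = None) -> None:
        self.stages[name] = {"status": status, "outputs": outputs or {}}

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "input_checksums": self.input_checksums,
            "seeds": self.seeds,
            "stages": self.stages,
        }

    def write(self, path: str | Path) -> None:
        xio.write_json(self.to_dict(), path)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def validate_inputs(paths: dict[str, str | Path]) -> list[str]:
    """Schema-check every configured input; returns violation messages.

    Recognized keys: fasta_a, fasta_b (FASTA), evidence (peptide TSV),
    points (coordinate TSV), feature_table, annotation.
    """
    violations: list[str] = []
    for key in ("fasta_a", "fasta_b"):
        p = paths.get(key)
        if p is None:
            continue
        try:
            prot = xio.read_proteome(p, species_tag="check")
            for pid, seq in prot:
                if not seq:
                    violations.append(f"{key}: record {pid!r} has no sequence")
        except Exception as exc:
            violations.append(f"{key}: {exc}")
    if "evidence" in paths:
        try:
            xio.read_evidence(paths["evidence"])
        except Exception as exc:
            violations.append(f"evidence: {exc}")
    if "points" in paths:
        try:
            df = xio.read_points(paths["points"])
            unknown = set(df["class"]) - {"query", "reference", "background"}
            if unknown:
                violations.append(f"points: unknown class label(s) {sorted(unknown)}")
        except Exception as exc:
            violations.append(f"points: {exc}")
    if "feature_table" in paths:
        try:
            t = pd.read_csv(paths["feature_table"], sep="\t", index_col=0)
            for col in ("utr5_length", "utr3_length", "gc_percent"):
                if col in t.columns and (t[col] < 0).any():
                    violations.append(f"feature_table: negative values in {col}")
            if "gc_percent" in t.columns and (t["gc_percent"] > 100).any():
                violations.append("feature_table: gc_percent above 100")
        except Exception as exc:
            violations.append(f"feature_table: {exc}")
    return violations


def run_pdx_analysis(config: dict, out_dir: str | Path) -> RunManifest:
    """Run the full xenograft deconvolution pipeline from a config mapping.

    Config keys (paths unless noted): ``fasta_a``/``tag_a`` (graft),
    ``fasta_b``/``tag_b`` (host), ``evidence``; optional ``category_map``,
    ``annotation`` + ``universe``, ``feature_table`` + ``feature``; numeric
    ``max_missed``, ``min_len``, ``max_len``, ``min_mass``, ``max_mass``,
    ``min_peptides``, ``mode``.  Outputs land in ``out_dir``; a failing
    stage aborts with the stage name while earlier outputs are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dict(config))
    for key in ("fasta_a", "fasta_b", "evidence", "category_map", "annotation", "feature_table"):
        if key in config and config[key]:
            manifest.input_checksums[key] = sha256_file(config[key])

    def _outputs(*paths: Path) -> dict[str, str]:
        return {str(p): sha256_file(p) for p in paths}

    stage = "digest"
    try:
        logger.info("stage %s: building libraries", stage)
        pa = xio.read_proteome(config["fasta_a"], config.get("tag_a", "human"))
        pb = xio.read_proteome(config["fasta_b"], config.get("tag_b", "mouse"))
        library = build_libraries(
            pa, pb,
            max_missed=int(config.get("max_missed", 2)),
            length_window=(int(config.get("min_len", 7)), int(config.get("max_len", 30))),
            mass_window=(float(config.get("min_mass", 700.0)),
                         float(config.get("max_mass", 4600.0))),
        )
        lib_path = out / "library.tsv"
        xio.write_library(library, lib_path)
        manifest.record_stage(stage, "ok", _outputs(lib_path))
    except Exception as exc:
        manifest.record_stage(stage, f"failed: {exc}")
        manifest.write(out / "manifest.json")
        raise StageError(stage, exc) from exc

    stage = "deconv"
    try:
        logger.info("stage %s: assigning and classifying", stage)
        evidence = xio.read_evidence(config["evidence"])
        assignments = assign_peptides(evidence, library)
        calls = classify_proteins(
            assignments,
            min_peptides=int(config.get("min_peptides", 2)),
            host_tag=config.get("tag_b", "mouse"),
            mode=config.get("mode", "strict"),
        )
        quantify_ibaq(calls, assignments)
        thresholds = call_enriched(calls)
        frame = calls_to_frame(calls)
        calls_path = out / "protein_calls.tsv"
        frame.to_csv(calls_path, sep="\t", index=False, float_format="%.6g")
        summary = {
            "n_groups": len(calls),
            "class_counts": frame["species_class"].value_counts().to_dict() if len(frame) else {},
            "n_enriched": int(frame["enriched"].fillna(False).sum()) if len(frame) else 0,
            "unmatched_peptide_fraction": assignments.unmatched_fraction,
            "enrichment_thresholds": thresholds,
        }
        summary_path = out / "run_summary.json"
        xio.write_json(summary, summary_path)
        manifest.record_stage(stage, "ok", _outputs(calls_path, summary_path))
    except Exception as exc:
        manifest.record_stage(stage, f"failed: {exc}")
        manifest.write(out / "manifest.json")
        raise StageError(stage, exc) from exc

    stage = "composition"
    if config.get("category_map"):
        cat_df = pd.read_csv(config["category_map"], sep="\t", header=None,
                             names=["protein", "category"])
        cat_map = dict(zip(cat_df["protein"], cat_df["category"]))
        comp = category_composition(calls, cat_map)
        comp_path = out / "composition.tsv"
        comp.rename("percent").to_csv(comp_path, sep="\t", header=True)
        manifest.record_stage(stage, "ok", _outputs(comp_path))
    else:
        manifest.record_stage(stage, "skipped")

    stage = "ora"
    if config.get("annotation") and config.get("universe"):
        try:
            annotation = xio.read_annotation(config["annotation"])
            universe = xio.read_gene_set(config["universe"])
            selection = [c.protein_id for c in calls if c.enriched]
            selection = [g for g in selection if g in set(universe)]
            if selection:
                res = ora(selection, universe, annotation)
                ora_path = out / "ora.tsv"
                res.to_csv(ora_path, sep="\t", index=False, float_format="%.6g")
                manifest.record_stage(stage, "ok", _outputs(ora_path))
            else:
                logger.warning("ORA skipped: no enriched proteins in universe")
                manifest.record_stage(stage, "skipped: empty selection")
        except Exception as exc:
            logger.warning("ORA failed (%s); continuing", exc)
            manifest.record_stage(stage, f"skipped: {exc}")
    else:
        if config.get("annotation") or config.get("universe"):
            logger.warning("ORA skipped: needs both annotation and universe")
        manifest.record_stage(stage, "skipped")

    stage = "features"
    if config.get("feature_table"):
        try:
            table = pd.read_csv(config["feature_table"], sep="\t", index_col=0)
            set_a = [c.protein_id for c in calls if c.enriched]
            set_b = [c.protein_id for c in calls if not c.enriched and c.protein_id in table.index]
            feat = config.get("feature", "gc")
            cmp_res = compare_feature(set_a, set_b, table, feat)
            feat_path = out / "feature_comparison.json"
            xio.write_json(vars(cmp_res), feat_path)
            manifest.record_stage(stage, "ok", _outputs(feat_path))
        except Exception as exc:
            logger.warning("feature comparison skipped (%s)", exc)
            manifest.record_stage(stage, f"skipped: {exc}")
    else:
        manifest.record_stage(stage, "skipped")

    manifest.write(out / "manifest.json")
    return manifest


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg
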