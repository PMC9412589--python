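"""End-to-end orchestration: ingest -> MDS -> network -> differential
expression -> ranking -> enrichment -> validation, as one reproducible run.

A run is driven by a :class:`RunConfig` (YAML round-trippable); every stage
writes self-describing TSVs into the output directory and a machine-readable
``manifest.json`` records the package version, seeds, every parameter used
and a SHA-256 checksum per output file, so a rerun with an identical config
is byte-verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from csfpanel import __version__
from csfpanel.errors import ConfigurationError
from csfpanel.ingest import (
    FRACTIONS,
    IntensityMatrix,
    normalize,
    read_annotations,
    read_gmt,
    read_protein_table,
    write_annotations,
    write_gmt,
    write_protein_table,
)
from csfpanel import diffexpr as de
from csfpanel import enrichment as enr
from csfpanel import mds
from csfpanel import network as net
from csfpanel import ranking as rk
from csfpanel import validation as val
from csfpanel.synthetic import SyntheticConfig, default_config, generate_dataset, write_truth

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters with the study's stated defaults."""

    proteins: str | None = None
    annotations: str | None = None
    gmt: str | None = None
    out: str = "run_out"
    seed: int = 0
    # mds stage
    k_clusters: int = 8
    # network stage
    min_module_size: int = 20
    fit_target: float = 0.8
    rho_threshold: float = 0.7
    cut_height: float | None = None
    signed: bool = False
    # differential expression
    alpha: float = 0.05
    fc: float = 2.0
    presence: float = 0.7
    auc: float = 0.7
    power: float = 0.8
    fractions: tuple[str, ...] = FRACTIONS
    # ranking
    split: float = 0.65
    folds: int = 4
    n_components: int = 2
    vip_threshold: float = 1.0
    # validation
    n_boot: int = 2000

    def validate(self) -> None:
        unit = {
            "fit_target": self.fit_target, "rho_threshold": self.rho_threshold,
            "alpha": self.alpha, "presence": self.presence, "auc": self.auc,
            "power": self.power, "split": self.split,
        }
        if self.cut_height is not None and not 0.0 <= self.cut_height <= 1.0:
            raise ConfigurationError(f"cut_height={self.cut_height} outside [0, 1]")
        for name, value in unit.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}={value} outside [0, 1]")
        if self.fc < 1.0:
            raise ConfigurationError(f"fc={self.fc} must be >= 1")
        if self.min_module_size < 2:
            raise ConfigurationError("min_module_size must be >= 2")
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if self.k_clusters < 1:
            raise ConfigurationError("k_clusters must be >= 1")
        if self.n_boot < 1:
            raise ConfigurationError("n_boot must be >= 1")
        bad = set(self.fractions) - set(FRACTIONS)
        if bad:
            raise ConfigurationError(f"unknown fractions {sorted(bad)}")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["fractions"] = list(data["fractions"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "fractions" in data:
            data["fractions"] = tuple(data["fractions"])
        config = cls(**data)
        config.validate()
        return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    """Stage executor writing TSV outputs and collecting the manifest."""

    def __init__(self, config: RunConfig):
        config.validate()
        self.config = config
        self.outdir = Path(config.out)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.outputs: list[Path] = []

    def _write(self, frame: pd.DataFrame, name: str) -> Path:
        path = self.outdir / name
        frame.to_csv(path, sep="\t", float_format="%.10g")
        self.outputs.append(path)
        return path

    def run(self, matrix: IntensityMatrix, gmt_terms=None) -> dict:
        cfg = self.config
        stage = "ingest"
        try:
            matrix = normalize(matrix)
            write_annotations(matrix.annotations, self.outdir / "annotations.tsv")
            self.outputs.append(self.outdir / "annotations.tsv")
            norm_path = self.outdir / "normalized_matrix.tsv"
            write_protein_table(matrix, norm_path)
            self.outputs.append(norm_path)

            stage = "mds"
            embedding = mds.embed_samples(matrix, k_clusters=cfg.k_clusters, seed=cfg.seed)
            emb = embedding.coordinates.copy()
            emb["cluster"] = embedding.cluster_labels
            emb["outlier"] = embedding.outlier_flags
            emb.index.name = "sample_id"
            self._write(emb, "mds_embedding.tsv")

            stage = "network"
            model, partition = net.build_network(
                matrix,
                fit_target=cfg.fit_target,
                min_module_size=cfg.min_module_size,
                cut_height=cfg.cut_height,
                signed=cfg.signed,
                rho_threshold=cfg.rho_threshold,
                alpha=cfg.alpha,
            )
            labels = partition.labels.to_frame()
            labels.index.name = "protein_id"
            self._write(labels, "modules.tsv")
            eig = partition.eigengenes.copy()
            eig.index.name = "sample_id"
            self._write(eig, "module_eigengenes.tsv")
            self._write(partition.trait_correlations, "module_trait_correlations.tsv")
            self._write(model.scale_free_fit, "scale_free_fit.tsv")

            stage = "diffexpr"
            criteria = de.DECriteria(
                alpha=cfg.alpha, fc_min=cfg.fc, presence_threshold=cfg.presence,
                auc_min=cfg.auc, power_min=cfg.power,
            )
            tables, significant = de.select_significant(matrix, cfg.fractions, criteria)
            for fraction, table in tables.items():
                out = table.copy()
                out.index.name = "protein_id"
                self._write(out, f"diffexpr_{fraction}.tsv")
            pooled = pd.DataFrame({"protein_id": significant}).set_index("protein_id")
            self._write(pooled, "significant_proteins.tsv")

            stage = "rank"
            pooled_panel = None
            candidates = {
                fraction: sorted(table.index[table["significant"]])
                for fraction, table in tables.items()
            }
            if any(len(c) >= 2 for c in candidates.values()):
                panels, pooled_panel = rk.rank_fractions(
                    matrix, candidates, seed=cfg.seed, n_components=cfg.n_components,
                    test_size=round(1.0 - cfg.split, 10), folds=cfg.folds,
                    vip_threshold=cfg.vip_threshold,
                )
                for fraction, panel in panels.items():
                    ptab = panel.table.copy()
                    ptab.index.name = "protein_id"
                    self._write(ptab, f"ranked_panel_{fraction}.tsv")
                    if panel.report is not None:
                        self._write(panel.report.confusion, f"svm_confusion_{fraction}.tsv")
                self._write(pooled_panel, "ranked_panel.tsv")
            else:
                logger.warning("fewer than 2 significant proteins in every fraction; ranking skipped")

            stage = "enrich"
            enrichment_table = None
            if gmt_terms:
                frames = []
                for fraction in cfg.fractions:
                    table = enr.enrich_terms(gmt_terms, tables[fraction])
                    table = table.copy()
                    table["fraction"] = fraction
                    frames.append(table)
                enrichment_table = pd.concat(frames)
                self._write(enrichment_table, "enrichment.tsv")

            stage = "validate"
            diagnostics = {}
            if pooled_panel is not None and len(pooled_panel) > 0:
                top = pooled_panel.index[0]
                scores_all = rk.impute_half_min(matrix).loc[top]
                best = None
                for fraction in cfg.fractions:
                    cols = matrix.samples_in(fraction=fraction)
                    labels_f = (matrix.annotations.loc[cols, "group"] == "MB").to_numpy()
                    summary = val.diagnostic_summary(
                        scores_all[cols].to_numpy(), labels_f, n_boot=cfg.n_boot, seed=cfg.seed,
                    )
                    if best is None or summary.auc > best[1].auc:
                        best = (fraction, summary)
                fraction, summary = best
                self._write(summary.roc, "roc_points.tsv")
                diagnostics = {
                    "protein": top,
                    "fraction": fraction,
                    "auc": summary.auc,
                    "auc_ci": list(summary.auc_ci),
                    "auc_class": summary.auc_class,
                    "cutoff": summary.cutoff,
                    "sensitivity": summary.sensitivity,
                    "specificity": summary.specificity,
                    "likelihood_ratio": summary.likelihood_ratio
                    if np.isfinite(summary.likelihood_ratio) else "inf",
                }
                diag_path = self.outdir / "diagnostics.json"
                diag_path.write_text(json.dumps(diagnostics, indent=2, sort_keys=True))
                self.outputs.append(diag_path)
        except Exception:
            logger.error("pipeline failed in stage '%s'; prior outputs preserved in %s", stage, self.outdir)
            raise

        manifest = {
            "version": __version__,
            "config": {**asdict(self.config), "fractions": list(self.config.fractions)},
            "outputs": {p.name: _sha256(p) for p in sorted(set(self.outputs))},
        }
        (self.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest


def demo_gmt(truth, universe: list[str], seed: int, n_random_terms: int = 10, term_size: int = 25):
    """Build a GMT mapping from the synthetic ground truth: one term holding
    the planted discriminant proteins plus seeded random terms."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xE17)))
    terms = {"PLANTED_DISCRIMINANT": ("planted group-discriminant proteins",
                                      tuple(sorted(truth.de_proteins)))}
    for i in range(1, n_random_terms + 1):
        members = rng.choice(universe, size=min(term_size, len(universe)), replace=False)
        terms[f"RANDOM_TERM_{i:02d}"] = ("random background term", tuple(sorted(members)))
    return terms


def synthetic_assay(seed: int, medians=(0.46, 1.4, 0.5, 0.56), sizes=(24, 12, 16, 9),
                    log_sd: float = 0.35) -> dict[str, np.ndarray]:
    """ELISA-like single-analyte values for four clinical groups
    (control, MB, LGG/GN, other), log-normal around the given medians."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA55A)))
    names = ("control", "MB", "LGG_GN", "other")
    return {
        name: np.exp(np.log(median) + log_sd * rng.standard_normal(size))
        for name, median, size in zip(names, medians, sizes)
    }


def run_demo(outdir: str | Path, seed: int = 0, n_samples_per_cell: int = 6,
             synthetic_config: SyntheticConfig | None = None,
             config: RunConfig | None = None) -> dict:
    """Generate a synthetic dataset and run the full pipeline on it.

    Returns the manifest.  The demo additionally writes the generator truth,
    a truth-derived GMT, and an ELISA-like four-group validation analysis.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    syn = synthetic_config or default_config(n_samples_per_cell=n_samples_per_cell, seed=seed)
    matrix, truth = generate_dataset(syn)
    write_protein_table(matrix, outdir / "synthetic_matrix.tsv")
    write_annotations(matrix.annotations, outdir / "synthetic_annotations.tsv")
    write_truth(truth, outdir / "synthetic_truth.tsv")
    gmt_terms = demo_gmt(truth, matrix.protein_ids, seed)
    write_gmt(gmt_terms, outdir / "synthetic_terms.gmt")

    cfg = config or RunConfig()
    cfg = replace(cfg, out=str(outdir), seed=seed)
    run = PipelineRun(cfg)
    run.outputs.extend(outdir / n for n in (
        "synthetic_matrix.tsv", "synthetic_annotations.tsv", "synthetic_truth.tsv", "synthetic_terms.gmt"))
    manifest = run.run(matrix, gmt_terms=gmt_terms)

    groups = synthetic_assay(seed)
    h, p_omnibus, pairwise, summaries = val.kruskal_dunn(groups)
    pooled = np.concatenate(list(groups.values()))
    is_mb = np.concatenate([np.full(v.size, name == "MB") for name, v in groups.items()])
    assay = val.diagnostic_summary(pooled, is_mb, n_boot=cfg.n_boot, seed=seed)
    assay_record = {
        "kruskal_h": h,
        "kruskal_p": p_omnibus,
        "pairwise": pairwise.to_dict(orient="records"),
        "medians": summaries["median"].to_dict(),
        "iqr": summaries["iqr"].to_dict(),
        "auc": assay.auc,
        "auc_ci": list(assay.auc_ci),
        "auc_class": assay.auc_class,
        "cutoff": assay.cutoff,
        "sensitivity": assay.sensitivity,
        "specificity": assay.specificity,
        "likelihood_ratio": assay.likelihood_ratio if np.isfinite(assay.likelihood_ratio) else "inf",
    }
    (outdir / "assay_validation.json").write_text(json.dumps(assay_record, indent=2, sort_keys=True))
    manifest["outputs"]["assay_validation.json"] = _sha256(outdir / "assay_validation.json")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_pipeline(config: RunConfig) -> dict:
    """Run the pipeline on user-supplied input files named in ``config``."""
    config.validate()
    if not config.proteins or not config.annotations:
        raise ConfigurationError("proteins and annotations paths are required")
    annotations = read_annotations(config.annotations)
    matrix = read_protein_table(config.proteins, annotations)
    gmt_terms = read_gmt(config.gmt) if config.gmt else None
    return PipelineRun(config).run(matrix, gmt_terms=gmt_terms)
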