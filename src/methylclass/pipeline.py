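"""End-to-end orchestration: rank -> IFS -> independent test -> enrichment.

``run_pipeline`` executes the full protocol on a configured set of inputs
and writes all artifacts plus a machine-readable manifest into a run
directory:

* ``ranking.tsv``            — the MCFS feature list (rank, probe_id, RI)
* ``ifs_results.tsv``        — MCC and accuracy per subset size and family
* ``ifs_curves.png``         — the IFS curves with per-family maxima marked
* ``optimal_probes.txt``     — the winning family's optimal probe prefix
* ``optimal_genes.txt``      — those probes mapped to gene symbols
* ``enrichment.tsv``         — per-namespace hypergeometric enrichment
* ``manifest.json``          — inputs, config, versions, seed, stage times,
  per-family optima and (when a test cohort is configured) the
  independent-test confusion matrices and scores

Every output is reproducible from (inputs, config, seed); only manifest
timestamps vary between identical runs.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .classifiers import ClassifierSpec, canonical_family
from .data_io import (
    map_probes_to_genes,
    read_annotation,
    read_beta_matrix,
    read_labels,
    write_gene_list,
    write_probe_list,
)
from .enrichment import enrich, read_gmt
from .exceptions import ConfigError
from .ifs import (
    evaluate_independent,
    ifs_sweep,
    mcc_multiclass,
    overall_accuracy,
    plot_ifs_curves,
)
from .mcfs import MCFSConfig, run_mcfs, write_ranking

logger = logging.getLogger(__name__)

DEFAULT_FAMILIES = ("svm", "random_forest", "rule_learner")


@dataclass
class PipelineConfig:
    """Everything one run needs: paths, stage settings and the master seed."""

    matrix: str
    labels: str
    annotation: str | None = None
    gene_sets: list[str] = field(default_factory=list)
    test_matrix: str | None = None
    test_labels: str | None = None
    universe: str | None = None

    mcfs: MCFSConfig = field(default_factory=MCFSConfig)
    step: int = 10
    folds: int = 10
    families: tuple[str, ...] = DEFAULT_FAMILIES
    max_features: int | None = None
    alpha: float = 0.05

    out_dir: str = "run"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.mcfs, dict):
            self.mcfs = MCFSConfig(**self.mcfs)
        self.families = tuple(canonical_family(f) for f in self.families)
        if not self.families:
            raise ConfigError("at least one classifier family is required")
        if bool(self.test_matrix) != bool(self.test_labels):
            raise ConfigError("test_matrix and test_labels must be given together")

    def validate_paths(self) -> None:
        required = [self.matrix, self.labels]
        required += [p for p in (self.annotation, self.test_matrix,
                                 self.test_labels, self.universe) if p]
        required += list(self.gene_sets)
        missing = [p for p in required if not Path(p).exists()]
        if missing:
            raise ConfigError(f"input path(s) do not exist: {missing}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _specs(config: PipelineConfig) -> list[ClassifierSpec]:
    return [
        ClassifierSpec(fam, seed=config.seed) for fam in config.families
    ]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full protocol; returns the run directory."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "package": "methylclass",
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "config": _config_dict(config),
        "stages": {},
    }

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, *exc):
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self_inner.t0, 3)
                }
                logger.info("stage %s: done", name)

        return _Timer()

    with stage("load"):
        matrix = read_beta_matrix(config.matrix)
        labels = read_labels(config.labels)

    with stage("rank"):
        mcfs_cfg = MCFSConfig(**{**asdict(config.mcfs), "seed": config.seed})
        ranking = run_mcfs(matrix, labels, mcfs_cfg)
        write_ranking(ranking, out / "ranking.tsv")

    with stage("ifs"):
        result = ifs_sweep(
            matrix,
            labels,
            ranking,
            _specs(config),
            step=config.step,
            folds=config.folds,
            seed=config.seed,
            max_features=config.max_features,
        )
        result.write(out / "ifs_results.tsv")
        plot_ifs_curves(result, out / "ifs_curves.png")
        manifest["optimal"] = {
            fam: {"n_features": n, "mcc": mcc}
            for fam, (n, mcc) in result.optimal.items()
        }

    # the winning family's prefix is "the optimal subset" downstream
    best_family = max(
        result.optimal, key=lambda f: (result.optimal[f][1], f)
    )
    best_n = result.optimal[best_family][0]
    optimal_probes = ranking.top(best_n)
    manifest["best_family"] = best_family
    write_probe_list(optimal_probes, out / "optimal_probes.txt")

    if config.test_matrix:
        with stage("independent_test"):
            test_matrix = read_beta_matrix(config.test_matrix)
            test_labels = read_labels(config.test_labels)
            report = {}
            for spec in _specs(config):
                n, _ = result.optimal[spec.family]
                cm = evaluate_independent(
                    matrix, labels, test_matrix, test_labels,
                    ranking.top(n), spec,
                )
                report[spec.family] = {
                    "n_features": n,
                    "overall_accuracy": overall_accuracy(cm),
                    "mcc": mcc_multiclass(cm),
                    "classes": cm.classes,
                    "confusion": cm.counts.tolist(),
                }
            manifest["independent_test"] = report

    with stage("genes"):
        if config.annotation:
            annotation = read_annotation(config.annotation)
            genes = map_probes_to_genes(optimal_probes, annotation)
        else:
            annotation, genes = None, set()
        write_gene_list(genes, out / "optimal_genes.txt")
        manifest["n_optimal_probes"] = len(optimal_probes)
        manifest["n_optimal_genes"] = len(genes)

    with stage("enrich"):
        enrichment_path = out / "enrichment.tsv"
        if config.gene_sets and genes:
            if config.universe:
                with open(config.universe, "r", encoding="utf-8") as fh:
                    universe = {ln.strip() for ln in fh if ln.strip()}
            elif annotation is not None:
                universe = annotation.gene_universe()
            else:
                raise ConfigError("enrichment needs an annotation or a universe")
            n_sig = {}
            for i, gmt in enumerate(config.gene_sets):
                res = enrich(genes, read_gmt(gmt), universe, alpha=config.alpha)
                res.write(enrichment_path, mode="w" if i == 0 else "a", header=i == 0)
                n_sig[res.namespace] = int(len(res.significant))
            manifest["n_significant_terms"] = n_sig
        else:
            enrichment_path.write_text(
                "namespace\tterm_id\tterm_name\tk\tK\tn\tN\tp\tfdr\n"
            )

    manifest["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["mcfs"] = asdict(config.mcfs)
    d["families"] = list(config.families)
    return d
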