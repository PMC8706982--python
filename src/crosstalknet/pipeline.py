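"""End-to-end pipeline orchestration.

preprocess -> SGCCA -> similarity network -> cluster scores -> associations,
reading the TSV fixtures written by :mod:`crosstalknet.synthetic` (or user
data of the same shape) and writing every artifact, a run log and a
manifest with input checksums into one output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import association as assoc
from . import network as net
from . import preprocess as prep
from . import score as score_mod
from .blocks import check_shared_samples
from .sgcca import SgccaConfig, fit_sgcca
from .synthetic import read_block, read_subjects

logger = logging.getLogger("crosstalknet")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything one run needs; parses-or-fails-loudly from YAML."""

    genus_path: str
    fecal_path: str
    plasma_path: str
    subjects_path: str
    output_dir: str
    max_missing_frac: float = 0.20
    min_prevalence: float = 0.10
    pseudocount: float = 1.0
    rf_trees: int = 100
    n_components: int = 2
    sparsity: dict | None = None
    scheme: str = "centroid"
    cutoff: float = 0.6
    damping: float = 0.85
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise PipelineError(f"config: {path} does not contain a mapping")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        missing = {"genus_path", "fecal_path", "plasma_path", "subjects_path", "output_dir"} - set(raw)
        if missing:
            raise PipelineError(f"config: missing required keys {sorted(missing)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df, path: Path, index_label="sample_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; return the output directory.

    Any stage failure raises :class:`PipelineError` naming the stage, after
    dropping a FAILED marker next to whatever partial outputs exist.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "setup"
    t0 = time.time()
    try:
        config.to_yaml(outdir / "config.yaml")

        stage = "load"
        inputs = {
            "genus": Path(config.genus_path),
            "fecal": Path(config.fecal_path),
            "plasma": Path(config.plasma_path),
            "subjects": Path(config.subjects_path),
        }
        for name, p in inputs.items():
            if not p.exists():
                raise FileNotFoundError(f"{name} input not found: {p}")
        blocks = {lab: read_block(inputs[lab], lab) for lab in ("genus", "fecal", "plasma")}
        covariates, outcomes = read_subjects(inputs["subjects"])
        check_shared_samples(blocks)
        logger.info(
            "loaded blocks: %s; %d subjects",
            {k: v.data.shape for k, v in blocks.items()},
            len(covariates),
        )

        stage = "preprocess"
        processed, reports = {}, {}
        processed["genus"], reports["genus"] = prep.preprocess_genus_block(
            blocks["genus"],
            min_prevalence=config.min_prevalence,
            pseudocount=config.pseudocount,
        )
        for lab in ("fecal", "plasma"):
            processed[lab], reports[lab] = prep.preprocess_metabolite_block(
                blocks[lab],
                seed=config.seed,
                max_frac=config.max_missing_frac,
                n_estimators=config.rf_trees,
            )
        for lab, rep in reports.items():
            logger.info(
                "preprocess %s: %d -> %d features (%d removed)",
                lab, rep["n_features_in"], rep["n_features_out"], len(rep["removed_features"]),
            )
            _write_tsv(processed[lab].data, outdir / f"processed_{lab}.tsv")
        with open(outdir / "preprocess_report.json", "w") as fh:
            json.dump(reports, fh, indent=1)

        stage = "sgcca"
        sg_config = SgccaConfig(
            n_components=config.n_components,
            sparsity=config.sparsity,
            scheme=config.scheme,
            seed=config.seed,
        )
        model = fit_sgcca(processed, sg_config)
        logger.info("sgcca: AVE %s; warnings %s", model.ave, model.warnings_)
        with open(outdir / "sgcca_model.json", "w") as fh:
            json.dump(model.to_dict(), fh, indent=1)
        for lab, W in model.weights.items():
            _write_tsv(W, outdir / f"weights_{lab}.tsv", index_label="feature")

        stage = "network"
        network = net.network_from_model(model, cutoff=config.cutoff)
        logger.info(
            "network: %d nodes, %d edges, %d clusters at cutoff %.2f",
            len(network.nodes), network.n_edges, network.n_clusters, config.cutoff,
        )
        network.edge_table().to_csv(outdir / "edges.tsv", sep="\t", index=False)
        network.composition().to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        network.to_graphml(outdir / "network.graphml")

        stage = "score"
        if network.n_clusters == 0:
            raise PipelineError("score: network has no clusters at this cutoff")
        score_set = score_mod.compute_cluster_scores(
            network, processed, damping=config.damping
        )
        _write_tsv(score_set.scores, outdir / "scores.tsv")
        score_set.weights.to_csv(outdir / "score_weights.tsv", sep="\t", index=False)

        stage = "association"
        table = assoc.fit_score_associations(score_set.scores, outcomes, covariates)
        table.table.to_csv(outdir / "associations.tsv", sep="\t", index=False)
        members = assoc.member_values(network.clusters, processed)
        pcm = assoc.partial_correlations(members, outcomes, covariates)
        pcm.r.to_csv(outdir / "partial_correlations.tsv", sep="\t", index_label="member")
        pcm.p_adj.to_csv(outdir / "partial_correlations_padj.tsv", sep="\t", index_label="member")
        logger.info(
            "association: %d significant score-outcome pairs at FDR 0.05",
            len(table.significant()),
        )

        stage = "manifest"
        manifest = {
            "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in inputs.items()},
            "n_subjects": len(covariates),
            "n_clusters": network.n_clusters,
            "n_edges": network.n_edges,
            "elapsed_s": round(time.time() - t0, 2),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        logger.info("pipeline finished in %.1fs", time.time() - t0)
        return outdir
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}: {exc}\n")
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
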