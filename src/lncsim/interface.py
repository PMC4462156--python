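"""Run configuration and pipeline driver behind the command-line interface.

A single declarative YAML file (plus CLI overrides, precedence CLI > file >
defaults) configures every stage: simulate -> disease-sim -> lncrna-sim ->
network / predict -> loocv.  Each stage writes its outputs alongside a
``manifest.json`` recording the parameters, seed, input checksums and
package version, which is sufficient to rerun the stage exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import pandas as pd
import yaml

from . import __version__
from .containers import AssociationTable, SimilarityMatrix
from .disease import similarity_matrix
from .evaluation import PipelineConfig, loocv
from .exceptions import ParameterError, ValidationError
from .functional import build_network, combine_functional_similarities, functional_similarity_matrix
from .kernels import (
    expression_similarity,
    gaussian_profile_kernel,
    integrate_disease_similarity,
    integrate_lncrna_similarity,
)
from .lrls import LRLSParams, predict, rank_candidates
from .ontology import parse_descriptor_table
from .synthetic import SimConfig, write_simulated_inputs

logger = logging.getLogger(__name__)

COMMANDS = ("simulate", "disease-sim", "lncrna-sim", "network", "predict", "loocv")


@dataclasses.dataclass
class RunConfig:
    """All paths and parameters for the pipeline stages."""

    ontology: str | None = None
    associations: str | None = None
    expression: str | None = None
    similarity: str | None = None  # precomputed functional-similarity TSV (network stage)
    model: int = 1
    delta: float = 0.5
    combine: str | None = None
    gamma_prime: float = 1.0
    eta_l: float = 1.0
    eta_d: float = 1.0
    w: float = 0.5
    jitter: float = 1e-8
    cutoff: float = 0.3
    candidate_scope: str = "global"
    refit_kernels: bool = True
    shrink_groups: bool = True
    kernel_only: bool = False
    rank_scope: str = "per-disease"
    seed: int = 0
    out: str = "lncsim-out"
    # simulator settings (used by `simulate`)
    depth: int = 3
    branching: int = 3
    n_lncrna: int = 40
    n_clusters: int = 4
    assoc_per_lncrna: int = 3
    noise_rate: float = 0.05
    n_samples: int = 20
    expression_noise: float = 0.5

    @classmethod
    def load(cls, path=None, **overrides) -> "RunConfig":
        """Build from YAML file and keyword overrides (CLI > file > defaults)."""
        data: dict = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown configuration fields: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def sim_config(self) -> SimConfig:
        return SimConfig(
            depth=self.depth,
            branching=self.branching,
            n_lncrna=self.n_lncrna,
            n_clusters=self.n_clusters,
            assoc_per_lncrna=self.assoc_per_lncrna,
            noise_rate=self.noise_rate,
            n_samples=self.n_samples,
            expression_noise=self.expression_noise,
            seed=self.seed,
        )

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(
            model=None if self.kernel_only else self.model,
            delta=self.delta,
            combine=None if self.kernel_only else self.combine,
            gamma_prime=self.gamma_prime,
            lrls=LRLSParams(self.eta_l, self.eta_d, self.w, self.jitter),
            candidate_scope=self.candidate_scope,
            refit_kernels=self.refit_kernels,
            shrink_groups=self.shrink_groups,
        )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(cfg: RunConfig, command: str, inputs: list[str], outputs: list[str]) -> None:
    manifest = {
        "command": command,
        "version": __version__,
        "seed": cfg.seed,
        "parameters": dataclasses.asdict(cfg),
        "inputs": {p: _sha256(p) for p in inputs if p and os.path.exists(p)},
        "outputs": [os.path.basename(p) for p in outputs],
    }
    with open(os.path.join(cfg.out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _require(cfg: RunConfig, *fields: str) -> None:
    for f in fields:
        path = getattr(cfg, f)
        if path is None:
            raise ParameterError(f"configuration field {f!r} is required for this command")
        if not os.path.exists(path):
            raise ValidationError(f"input file not found: {path} (field {f!r})")


def _load_semantic(cfg: RunConfig, ontology, disease_ids) -> SimilarityMatrix:
    if cfg.combine is not None:
        ss1 = similarity_matrix(ontology, disease_ids, model=1, delta=cfg.delta)
        ss2 = similarity_matrix(ontology, disease_ids, model=2)
        return combine_functional_similarities(ss1, ss2, cfg.combine)
    return similarity_matrix(ontology, disease_ids, model=cfg.model, delta=cfg.delta)


def run_pipeline(cfg: RunConfig, command: str) -> list[str]:
    """Execute one stage; returns the list of files written (manifest last)."""
    if command not in COMMANDS:
        raise ParameterError(f"unknown command {command!r}; expected one of {COMMANDS}")
    os.makedirs(cfg.out, exist_ok=True)
    outputs: list[str] = []
    inputs: list[str] = []

    if command == "simulate":
        paths = write_simulated_inputs(cfg.sim_config(), cfg.out)
        outputs = list(paths.values())

    elif command == "disease-sim":
        _require(cfg, "ontology", "associations")
        inputs = [cfg.ontology, cfg.associations]
        ontology = parse_descriptor_table(cfg.ontology)
        assoc = AssociationTable.from_tsv(cfg.associations)
        ss = _load_semantic(cfg, ontology, assoc.disease_ids)
        path = os.path.join(cfg.out, "disease_similarity.tsv")
        ss.to_tsv(path)
        outputs = [path]

    elif command == "lncrna-sim":
        _require(cfg, "ontology", "associations")
        inputs = [cfg.ontology, cfg.associations]
        ontology = parse_descriptor_table(cfg.ontology)
        assoc = AssociationTable.from_tsv(cfg.associations)
        ss = _load_semantic(cfg, ontology, assoc.disease_ids)
        fs = functional_similarity_matrix(assoc, ss)
        path = os.path.join(cfg.out, "functional_similarity.tsv")
        fs.to_tsv(path)
        outputs = [path]

    elif command == "network":
        _require(cfg, "similarity")
        inputs = [cfg.similarity]
        fs = SimilarityMatrix.from_tsv(cfg.similarity)
        net = build_network(fs, cutoff=cfg.cutoff)
        sif = os.path.join(cfg.out, "network.sif")
        edges = os.path.join(cfg.out, "network_edges.tsv")
        net.write_sif(sif)
        net.write_edgelist(edges)
        outputs = [sif, edges]

    elif command == "predict":
        _require(cfg, "ontology", "associations")
        inputs = [cfg.ontology, cfg.associations]
        ontology = parse_descriptor_table(cfg.ontology)
        assoc = AssociationTable.from_tsv(cfg.associations)
        kl = gaussian_profile_kernel(assoc, "lncrna", cfg.gamma_prime)
        kd = gaussian_profile_kernel(assoc, "disease", cfg.gamma_prime)
        es = None
        if cfg.expression is not None:
            _require(cfg, "expression")
            inputs.append(cfg.expression)
            es = expression_similarity(pd.read_csv(cfg.expression, sep="\t", index_col=0))
        if cfg.kernel_only:
            sl, sd = integrate_lncrna_similarity(kl, None, es), kd
        else:
            ss = _load_semantic(cfg, ontology, assoc.disease_ids)
            fs = functional_similarity_matrix(assoc, ss)
            sl = integrate_lncrna_similarity(kl, fs, es)
            sd = integrate_disease_similarity(ss, kd)
        scores = predict(assoc, sl, sd, LRLSParams(cfg.eta_l, cfg.eta_d, cfg.w, cfg.jitter))
        spath = os.path.join(cfg.out, "scores.tsv")
        scores.to_tsv(spath)
        ranked = rank_candidates(scores, assoc, scope=cfg.rank_scope)
        rpath = os.path.join(cfg.out, "ranked_candidates.tsv")
        ranked.to_csv(rpath, sep="\t", index=False, float_format="%.10g")
        outputs = [spath, rpath]

    elif command == "loocv":
        _require(cfg, "ontology", "associations")
        inputs = [cfg.ontology, cfg.associations]
        ontology = parse_descriptor_table(cfg.ontology)
        assoc = AssociationTable.from_tsv(cfg.associations)
        expr = None
        if cfg.expression is not None:
            _require(cfg, "expression")
            inputs.append(cfg.expression)
            expr = pd.read_csv(cfg.expression, sep="\t", index_col=0)
        result = loocv(assoc, ontology, cfg.pipeline_config(), expression=expr)
        fpath = os.path.join(cfg.out, "loocv_folds.tsv")
        rpath = os.path.join(cfg.out, "roc_points.tsv")
        result.to_tsv(fpath, rpath)
        spath = os.path.join(cfg.out, "summary.txt")
        with open(spath, "w") as fh:
            fh.write(f"AUC\t{result.auc:.10g}\nfolds\t{len(result.folds)}\n")
        logger.info("LOOCV AUC = %.4f over %d folds", result.auc, len(result.folds))
        outputs = [fpath, rpath, spath]

    _write_manifest(cfg, command, inputs, outputs)
    return outputs + [os.path.join(cfg.out, "manifest.json")]
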