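"""End-to-end pipeline stages behind the command-line interface.

Stages communicate through plain CSV tables in a run directory:
``simulate`` writes a synthetic cohort, ``fit`` derives the phenotype
table and fits the sparse PLS model (selecting the regularization by
the density and feature-cap rules when not pinned in the config),
``infer`` turns fitted connectivity coefficients into block tests,
strength profiles, top-region lists and circuit summaries, and
``loocv`` writes the stability tables. Every stage logs row/column
counts and stamps outputs with a hash of the resolved configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import edge_vector_to_frame
from .inference import (
    block_partition,
    circuit_summary,
    permutation_block_test,
    rebuild_matrix,
    signed_strengths,
    top_regions,
)
from .phenotype import PHENOTYPE_COLUMNS, assemble_phenotype_table
from .pls import RegularizedPLS, select_lambda_connectivity, select_lambda_phenotype
from .regions import restrict_to_tnm
from .simulate import GeneratorConfig, simulate_cohort
from .stability import align_components, coefficient_variability, loocv_fit

log = logging.getLogger("tnmpls")


@dataclass
class RunConfig:
    """All pipeline settings; defaults follow the reference analysis."""

    outdir: str = "tnmpls_run"
    seed: int = 0
    # generator
    n_subjects: int = 55
    network_sizes: tuple = (45, 50, 50)
    n_factors: int = 3
    edge_support_fraction: float = 0.05
    noise_sd_phenotype: float = 0.1
    noise_sd_connectivity: float = 1.0
    snr: float = 3.0
    timeseries: bool = False
    n_timepoints: int = 616
    # model
    n_components: int = 4
    lambda_connectivity: float | None = None  # None -> density rule
    lambda_phenotype: float | None = None  # None -> feature-cap rule
    target_density: float = 0.5
    max_features: int = 3
    lambda_grid_points: int = 100
    scale_connectivity: bool = True
    # inference
    n_permutations: int = 1000
    percentile: float = 99.0
    top_fraction: float = 0.05
    by_hemisphere: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "network_sizes" in data:
            data["network_sizes"] = tuple(data["network_sizes"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["network_sizes"] = list(d["network_sizes"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _write_provenance(cfg: RunConfig, outdir: Path, stage: str) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    record = {
        "stage": stage,
        "tnmpls_version": __version__,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
    }
    with open(outdir / f"provenance_{stage}.yaml", "w") as fh:
        yaml.safe_dump(record, fh, sort_keys=False)


def run_simulate(cfg: RunConfig) -> Path:
    """Generate a synthetic cohort and write its tables."""
    outdir = Path(cfg.outdir)
    gen = GeneratorConfig(
        n_subjects=cfg.n_subjects,
        network_sizes=tuple(cfg.network_sizes),
        n_factors=cfg.n_factors,
        edge_support_fraction=cfg.edge_support_fraction,
        noise_sd_phenotype=cfg.noise_sd_phenotype,
        noise_sd_connectivity=cfg.noise_sd_connectivity,
        snr=cfg.snr,
        timeseries=cfg.timeseries,
        n_timepoints=cfg.n_timepoints,
        seed=cfg.seed,
    )
    cohort = simulate_cohort(gen)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.raw_phenotypes.to_csv(outdir / "raw_phenotypes.csv")
    cohort.pedigree.to_csv(outdir / "pedigree.csv", index=False)
    cohort.connectivity.to_csv(outdir / "connectivity.csv")
    cohort.region_table.to_csv(outdir / "region_table.csv", index=False)
    cohort.edge_index.to_frame().to_csv(outdir / "edge_index.csv", index=False)
    gt = outdir / "ground_truth"
    gt.mkdir(exist_ok=True)
    truth = cohort.ground_truth
    pd.DataFrame(truth.latent,
                 index=cohort.connectivity.index).to_csv(gt / "latent.csv")
    pd.DataFrame(truth.phenotype_loadings,
                 index=list(PHENOTYPE_COLUMNS)).to_csv(
        gt / "phenotype_loadings.csv")
    pd.DataFrame(truth.edge_loadings).to_csv(gt / "edge_loadings.csv")
    _write_provenance(cfg, outdir, "simulate")
    log.info("simulate: %d subjects, %d edges -> %s",
             len(cohort.connectivity), cohort.edge_index.n_edges, outdir)
    return outdir


def _load_domains(cfg: RunConfig):
    outdir = Path(cfg.outdir)
    raw = pd.read_csv(outdir / "raw_phenotypes.csv", index_col=0)
    pedigree = pd.read_csv(outdir / "pedigree.csv")
    connectivity = pd.read_csv(outdir / "connectivity.csv", index_col=0)
    regions = restrict_to_tnm(pd.read_csv(outdir / "region_table.csv"))
    pheno, provenance = assemble_phenotype_table(raw, pedigree)
    mismatches = [s for s in pheno.index.astype(str)
                  if s not in set(connectivity.index.astype(str))]
    if mismatches or len(pheno) != len(connectivity):
        raise ValueError(
            f"subject ids differ between domains; unmatched: {mismatches}"
        )
    connectivity = connectivity.loc[pheno.index]
    log.info("domains: phenotype %s, connectivity %s",
             pheno.shape, connectivity.shape)
    return pheno, provenance, connectivity, regions


def run_fit(cfg: RunConfig) -> Path:
    """Derive domains, select regularization, fit, and export the model."""
    outdir = Path(cfg.outdir)
    pheno, provenance, connectivity, regions = _load_domains(cfg)
    X, Y = connectivity.to_numpy(), pheno.to_numpy()

    lam_p = cfg.lambda_phenotype
    if lam_p is None:
        lam_p, _ = select_lambda_phenotype(
            X, Y, max_features=cfg.max_features, scale=cfg.scale_connectivity)
        log.info("selected lambda_phenotype=%.3f", lam_p)
    lam_c = cfg.lambda_connectivity
    if lam_c is None:
        lam_c, _ = select_lambda_connectivity(
            X, Y, target_density=cfg.target_density,
            n_grid=cfg.lambda_grid_points, lambda_phenotype=lam_p,
            scale=cfg.scale_connectivity)
        log.info("selected lambda_connectivity=%.3f", lam_c)

    for tag, lc, lp in (("regularized", lam_c, lam_p),
                        ("unregularized", None, None)):
        model = RegularizedPLS(
            n_components=cfg.n_components, lambda_connectivity=lc,
            lambda_phenotype=lp, scale=cfg.scale_connectivity,
        ).fit(X, Y)
        mdir = outdir / f"model_{tag}"
        mdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(model.y_weights_, index=pheno.columns,
                     columns=[f"component_{k + 1}" for k in
                              range(cfg.n_components)]).to_csv(
            mdir / "phenotype_coefficients.csv")
        pd.DataFrame(model.x_weights_,
                     columns=[f"component_{k + 1}" for k in
                              range(cfg.n_components)]).to_csv(
            mdir / "connectivity_coefficients.csv", index_label="edge")
        pd.DataFrame(
            np.hstack([model.x_scores_, model.y_scores_]),
            index=pheno.index,
            columns=[f"phi_{k + 1}" for k in range(cfg.n_components)]
            + [f"psi_{k + 1}" for k in range(cfg.n_components)],
        ).to_csv(mdir / "latent_scores.csv")
        meta = {
            "lambda_connectivity": lc,
            "lambda_phenotype": lp,
            "covariance_scores": model.covariances_.tolist(),
            "covariance_percentages": model.covariance_percentages_.tolist(),
            "converged": model.converged_.tolist(),
            "config_hash": cfg.config_hash(),
            "phenotype_provenance": _jsonable(provenance),
        }
        with open(mdir / "metadata.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)
    _write_provenance(cfg, outdir, "fit")
    return outdir


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=lambda o: str(o)))


def run_infer(cfg: RunConfig) -> Path:
    """Block tests, strength profiles and circuits for the fitted model."""
    outdir = Path(cfg.outdir)
    regions = restrict_to_tnm(pd.read_csv(outdir / "region_table.csv"))
    from .connectome import build_edge_index

    edges = build_edge_index(regions)
    coeff = pd.read_csv(outdir / "model_regularized" /
                        "connectivity_coefficients.csv", index_col=0)
    partition = block_partition(edges, by_hemisphere=cfg.by_hemisphere)
    idir = outdir / "inference"
    idir.mkdir(parents=True, exist_ok=True)
    for k, col in enumerate(coeff.columns, start=1):
        u = coeff[col].to_numpy()
        test = permutation_block_test(
            u, partition, n_perm=cfg.n_permutations,
            percentile=cfg.percentile, seed=cfg.seed + k)
        test.table.to_csv(idir / f"block_test_component_{k}.csv")
        W = rebuild_matrix(u, edges)
        profile = signed_strengths(W, regions)
        profile.to_csv(idir / f"strengths_component_{k}.csv")
        top, threshold = top_regions(profile, cfg.top_fraction)
        top.to_csv(idir / f"top_regions_component_{k}.csv")
        if not cfg.by_hemisphere:
            circuit = circuit_summary(test)
            circuit.to_csv(idir / f"circuit_component_{k}.csv", index=False)
        edge_vector_to_frame(u, edges).to_csv(
            idir / f"edge_coefficients_component_{k}.csv", index=False)
        log.info("infer: component %d, strength threshold %.4f", k, threshold)
    _write_provenance(cfg, outdir, "infer")
    return idir


def run_loocv(cfg: RunConfig) -> Path:
    """Leave-one-out stability tables for the selected regularization."""
    outdir = Path(cfg.outdir)
    pheno, _, connectivity, _ = _load_domains(cfg)
    with open(outdir / "model_regularized" / "metadata.yaml") as fh:
        meta = yaml.safe_load(fh)
    ensemble = loocv_fit(
        connectivity.to_numpy(), pheno.to_numpy(),
        n_components=cfg.n_components,
        lambda_connectivity=meta["lambda_connectivity"],
        lambda_phenotype=meta["lambda_phenotype"],
        scale=cfg.scale_connectivity,
    )
    ensemble = align_components(ensemble)
    summary, edge_sd = coefficient_variability(
        ensemble, phenotype_names=pheno.columns)
    ldir = outdir / "loocv"
    ldir.mkdir(parents=True, exist_ok=True)
    summary.to_csv(ldir / "phenotype_coefficient_distributions.csv")
    pd.DataFrame(
        edge_sd,
        columns=[f"component_{k + 1}" for k in range(edge_sd.shape[1])],
    ).to_csv(ldir / "edge_coefficient_sd.csv", index_label="edge")
    pd.DataFrame(
        ensemble.alignment,
        columns=[f"component_{k + 1}" for k in
                 range(ensemble.alignment.shape[1])],
    ).to_csv(ldir / "alignment_signs.csv", index_label="run")
    long = []
    for r, run in enumerate(ensemble.runs):
        for k in range(run.y_weights_.shape[1]):
            for j, name in enumerate(pheno.columns):
                long.append((r, k + 1, name, run.y_weights_[j, k]))
    pd.DataFrame(
        long, columns=["run", "component", "variable", "coefficient"]
    ).to_csv(ldir / "phenotype_coefficients_long.csv", index=False)
    _write_provenance(cfg, outdir, "loocv")
    log.info("loocv: %d runs", ensemble.n_runs)
    return ldir


def run_report(cfg: RunConfig) -> Path:
    """Full pipeline: fit, infer and loocv on an existing cohort."""
    run_fit(cfg)
    run_infer(cfg)
    run_loocv(cfg)
    _write_provenance(cfg, Path(cfg.outdir), "report")
    return Path(cfg.outdir)
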