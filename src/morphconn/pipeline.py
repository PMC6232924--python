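"""End-to-end driver: cohort -> networks -> kernels -> similarity -> results.

``run_pipeline`` executes the full chain — feature construction, kernel
bank, similarity learning, embedding, clustering, purity, Laplacian-score
ranking and repeated k-fold evaluation — with structured per-stage logging,
and writes every artifact (similarity, latent, kernel weights, objective
trace, 2-D embedding, assignments, rates, ranked features) plus the
resolved configuration into one self-describing run directory.
"""

from __future__ import annotations

import json
import logging
import time
from contextlib import contextmanager
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .embedding import embed
from .evaluation import cv_evaluate, performance_rate
from .io import Cohort, read_cohort, write_matrix
from .networks import cohort_features
from .ranking import rank_features
from .simlr import SIMLR
from .simulate import SimSpec, generate_cohort

logger = logging.getLogger("morphconn")


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    logger.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:
        logger.error("stage %s failed: %s", name, exc)
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


def load_cohort(config: RunConfig) -> Cohort:
    if config.cohort_path is not None:
        cohort = read_cohort(config.cohort_path, format=config.cohort_format)
    else:
        spec = SimSpec(seed=config.seed, hemisphere=config.hemisphere,
                       **config.simulate)
        cohort = generate_cohort(spec)
    keep = [s for s in cohort if s.hemisphere == config.hemisphere]
    if not keep:
        raise ValueError(f"no subjects for hemisphere {config.hemisphere!r}")
    return Cohort(keep)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline; returns the result summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run config: %s", asdict(config))

    with _stage("load"):
        cohort = load_cohort(config)
    with _stage("features"):
        X, index_map = cohort_features(cohort, order=config.order)
        logger.info("feature matrix: %d subjects x %d features", *X.shape)
    with _stage("similarity"):
        model = SIMLR(**config.simlr_kwargs())
        model.fit(X)
    with _stage("embed"):
        Y = embed(model.similarity_, dims=2, seed=config.seed)
    with _stage("cluster"):
        assignments = model.labels_
        labels = cohort.labels
        have_labels = "unknown" not in set(labels)
        rate = performance_rate(assignments, labels) if have_labels else None
    with _stage("rank"):
        ranked = rank_features(X, model.similarity_, top_k=config.top_k,
                               index_map=index_map, roi_names=cohort.roi_names,
                               attribute_names=cohort.attribute_names)
    cv = None
    if have_labels:
        with _stage("evaluate"):
            cv = cv_evaluate(X, labels, method="simlr", k_folds=config.k_folds,
                             repeats=config.repeats, seed=config.seed,
                             n_clusters=config.n_clusters,
                             method_params={
                                 "sigma_grid": config.sigma_grid,
                                 "k_grid": config.k_grid,
                                 "beta": config.beta, "gamma": config.gamma,
                                 "rho": config.rho,
                                 "diffusion_steps": config.diffusion_steps,
                             })

    with _stage("write"):
        ids = cohort.subject_ids
        write_matrix(model.similarity_, out / "similarity.csv", ids, ids)
        write_matrix(model.latent_, out / "latent.csv", ids,
                     [f"dim_{i}" for i in range(config.n_clusters)])
        write_matrix(model.kernel_weights_[None, :], out / "kernel_weights.csv",
                     ["w"], [f"sigma={p.sigma}_k={p.k_neighbors}"
                             for p in model.kernel_params_])
        write_matrix(np.asarray(model.objective_trace_)[None, :],
                     out / "objective_trace.csv", ["F"],
                     [str(i) for i in range(len(model.objective_trace_))])
        write_matrix(Y, out / "embedding_2d.csv", ids, ["x", "y"])
        pd.DataFrame({"subject_id": ids, "cluster": assignments,
                      "label": labels}).to_csv(out / "assignments.csv", index=False)
        pd.DataFrame([asdict_ranked(r) for r in ranked]).to_csv(
            out / "ranked_features.csv", index=False)
        summary = {
            "n_subjects": cohort.n, "n_features": int(X.shape[1]),
            "order": config.order, "hemisphere": config.hemisphere,
            "performance_rate": rate,
            "cv_mean_rate": cv.mean_rate if cv else None,
            "cv_per_repeat": cv.per_repeat if cv else None,
        }
        (out / "rates.json").write_text(json.dumps(summary, indent=2))
        config.to_yaml(out / "config.yaml")
    return summary


def asdict_ranked(r) -> dict:
    return {"position": r.position, "score": r.score, "description": r.description}
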