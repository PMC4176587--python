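"""End-to-end pipeline orchestration: simulate/load -> preprocess -> DE ->
cluster both views -> compare -> enrich, writing every stage's outputs to
a run directory with a log and a config echo.

All randomness flows from one top-level seed: stage k draws its seed from
``numpy.random.SeedSequence([seed, STAGE_OFFSET[stage]])``, so any stage
can be reproduced in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, io, preprocess, simulate
from .enrichment import enrich_clusters
from .fuzzy import compare_clusterings, fcm_fit

logger = logging.getLogger("tempoclust")

STAGE_OFFSET = {"simulate": 0, "cluster_np": 10, "cluster_fc": 11}


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage integer seed derived from the run seed (documented scheme)."""
    ss = np.random.SeedSequence([int(seed), STAGE_OFFSET[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs.

    Either ``dataset``/``metadata`` paths are given, or the synthetic
    generator is used (``simulate=True``).  ``gmt`` is optional; without
    it the enrichment stage is skipped.
    """

    outdir: str
    seed: int = 0
    simulate: bool = True
    dataset: str | None = None
    metadata: str | None = None
    gmt: str | None = None
    producer: str = "producer"
    control: str = "control"
    n_genes_per_archetype: int = 200
    noise_sd: float = 0.2
    c_np: int = 5
    c_fc: int = 5
    m: float = 1.35
    p_cut: float = 1e-5
    lfc_cut: float = 1.0
    tol: float = 1e-6
    max_iter: int = 500
    log_level: str = "INFO"
    extras: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.m <= 1:
            raise ValueError(f"fuzziness exponent m must be > 1, got {self.m}")
        if self.c_np < 2 or self.c_fc < 2:
            raise ValueError("cluster counts must be >= 2")
        if not (0 < self.p_cut <= 1):
            raise ValueError("p_cut must be in (0, 1]")
        if self.noise_sd < 0 or self.tol <= 0 or self.max_iter < 1:
            raise ValueError("noise_sd >= 0, tol > 0, max_iter >= 1 required")
        if not self.simulate:
            for name in ("dataset", "metadata"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"{name} path missing or does not exist: {p}")
        if self.gmt is not None and not Path(self.gmt).exists():
            raise ValueError(f"gmt path does not exist: {self.gmt}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["extras"] = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d.pop("extras")
        return d


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    chash = io.config_hash(config.to_dict())
    try:
        logger.info("run start: seed=%d config_hash=%s", config.seed, chash)
        with open(outdir / "config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=2, default=str)

        if config.simulate:
            sim_cfg = simulate.default_config(
                seed=stage_seed(config.seed, "simulate"),
                n_genes_per_archetype=config.n_genes_per_archetype,
                noise_sd=config.noise_sd,
            )
            ds, truth = simulate.simulate_timecourse(sim_cfg)
            termmap = simulate.simulate_term_map(sim_cfg, truth)
            io.write_expression_tsv(ds, outdir / "expression.tsv", outdir / "samples.tsv")
            io.write_table(truth.to_frame(), outdir / "ground_truth.tsv",
                           index=True, index_label="gene",
                           comment=f"synthetic ground truth; config_hash={chash}")
            io.write_gmt(termmap, outdir / "terms.gmt")
        else:
            ds = io.read_expression_tsv(config.dataset, config.metadata)
            termmap = io.read_gmt(config.gmt) if config.gmt else None
        if config.gmt:
            termmap = io.read_gmt(config.gmt)
        logger.info("dataset: %d genes x %d samples", len(ds.genes), len(ds.samples))

        avg = preprocess.average_replicates(ds)
        np_view = preprocess.normalized_profiles(avg)
        fc_view = preprocess.fold_change_profiles(avg, config.producer, config.control)
        io.write_profile_tsv(np_view, outdir / "profiles_np.tsv")
        io.write_profile_tsv(fc_view, outdir / "profiles_fc.tsv")
        if np_view.degenerate:
            logger.info("NP: %d degenerate genes excluded", len(np_view.degenerate))

        design = diffexpr.DesignSpec.paired_timepoints(ds, config.producer, config.control)
        fits = diffexpr.fit_models(ds, design)
        de = diffexpr.moderate(fits)
        io.write_table(de.table, outdir / "diffexpr.tsv",
                       comment=f"moderated t; d0={de.d0:g} s0_sq={de.s0_sq:g}; "
                               f"config_hash={chash}")
        sig = diffexpr.select_significant(de, config.p_cut, config.lfc_cut)
        logger.info("significant genes per contrast: %s",
                    {k: len(v) for k, v in sig.items()})

        fit_np = fcm_fit(np_view, c=config.c_np, m=config.m,
                         seed=stage_seed(config.seed, "cluster_np"),
                         tol=config.tol, max_iter=config.max_iter)
        fit_fc = fcm_fit(fc_view, c=config.c_fc, m=config.m,
                         seed=stage_seed(config.seed, "cluster_fc"),
                         tol=config.tol, max_iter=config.max_iter)
        for name, fit, view in (("np", fit_np, np_view), ("fc", fit_fc, fc_view)):
            memberships = pd.DataFrame(
                fit.memberships, index=view.genes,
                columns=[f"{name.upper()}{j}" for j in range(fit.c)],
            )
            io.write_table(
                memberships, outdir / f"memberships_{name}.tsv",
                index=True, index_label="gene",
                comment=f"fcm c={fit.c} m={fit.m} seed={fit.seed} "
                        f"converged={fit.converged}; config_hash={chash}",
            )
        logger.info("clustering: NP converged=%s (%d iter), FC converged=%s (%d iter)",
                    fit_np.converged, fit_np.n_iter, fit_fc.converged, fit_fc.n_iter)

        # NP drops degenerate rows, so FC is refit on the shared universe
        # when the two views cover different gene sets
        shared = [g for g in fc_view.genes if g in set(np_view.genes)]
        if len(shared) < len(fc_view.genes):
            sub_fc = fcm_fit(fc_view.values.loc[shared], c=config.c_fc, m=config.m,
                             seed=stage_seed(config.seed, "cluster_fc"),
                             tol=config.tol, max_iter=config.max_iter)
            contingency = compare_clusterings(fit_np, sub_fc)
        else:
            contingency = compare_clusterings(fit_np, fit_fc)
        io.write_table(contingency.counts, outdir / "np_fc_contingency.tsv",
                       index=True, index_label="np_cluster",
                       comment=f"genes shared by NP x FC clusters; "
                               f"unassigned NP={contingency.unassigned_a} "
                               f"FC={contingency.unassigned_b}; config_hash={chash}")

        if termmap is not None:
            termmap = termmap.restricted_to(set(np_view.genes) | set(np_view.degenerate))
            enr = enrich_clusters(fit_np.hard_assignments(), termmap)
            io.write_table(enr, outdir / "enrichment_np.tsv",
                           comment=f"hypergeometric over-representation; config_hash={chash}")
        logger.info("run complete: outputs in %s", outdir)
    except Exception:
        logger.exception("run failed; partial outputs in %s", outdir)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outdir
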