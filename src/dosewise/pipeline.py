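"""End-to-end pipeline: qc -> normalize -> DE -> composition -> trajectory
-> enrichment -> regulons, with a machine-readable run log.

Each stage writes one TSV into the output directory; any stage error aborts
with the stage name attached.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import moderated_prop_test, proportions_table
from .enrichment import hypergeom_ora
from .io import read_cell_table, read_counts_mtx, read_gmt
from .preprocess import QCThresholds, apply_qc_filters, find_markers, normalize_log
from .pseudobulk import aggregate_pseudobulk, deg_burden, run_dose_lrt, run_pairwise_wald
from .regulons import aucell_scores, differential_regulons, regulon_specificity
from .simulate import SimConfig, simulate_dataset, write_dataset
from .trajectory import assign_pseudotime, kl_timing_test, ks_shift_test

logger = logging.getLogger(__name__)

STAGES = ["qc", "markers", "de", "composition", "trajectory", "enrichment", "regulons"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Flat parameter bundle for a full pipeline run."""

    outdir: str = "dosewise_out"
    dataset_dir: str | None = None  # None -> simulate
    seed: int = 1
    # qc
    umi_min: int = 800
    umi_max: int = 6000
    genes_min: int = 300
    genes_max: int = 3000
    mito_pct_max: float = 1.0
    log_ratio_min: float = 0.9
    scale_factor: float = 10000.0
    # de
    lfc_min: float = 0.2
    fdr: float = 0.05
    burden_n_cells: int = 700
    burden_reps: int = 10
    burden_seed: int | None = None
    # trajectory
    knn: int = 15
    kl_bins: int = 20
    kl_n_perm: int = 1000
    kl_seed: int | None = None
    kl_genes_max: int = 100
    # gene sets / regulons
    gmt_path: str | None = None
    regulon_gmt_path: str | None = None
    aucell_seed: int | None = None
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def validate(self) -> None:
        for name in ("seed", "burden_seed", "kl_seed", "aucell_seed"):
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"stochastic stage seed {name!r} is not set")


def _resolve_seeds(config: RunConfig) -> RunConfig:
    for name in ("burden_seed", "kl_seed", "aucell_seed"):
        if getattr(config, name) is None:
            setattr(config, name, config.seed)
    return config


def run_pipeline(config: RunConfig, strict_seeds: bool = False) -> Path:
    """Execute all stages in order; returns the output directory."""
    if strict_seeds:
        config.validate()
    config = _resolve_seeds(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": asdict(config),
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            def run(*args, **kwargs):
                try:
                    result = fn(*args, **kwargs)
                except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                    raise StageError(name, exc) from exc
                log["stages"][name] = "ok"
                return result

            return run

        return deco

    # --- inputs -----------------------------------------------------------
    if config.dataset_dir:
        counts = read_counts_mtx(Path(config.dataset_dir) / "matrix.mtx")
        cells = read_cell_table(Path(config.dataset_dir) / "cell_table.tsv")
        truth = None
        regulon_gmt = config.regulon_gmt_path or str(Path(config.dataset_dir) / "regulons.gmt")
    else:
        sim_cfg = SimConfig(**{**config.sim, "seed": config.seed})
        counts, cells, truth = simulate_dataset(sim_cfg)
        ds_dir = outdir / "dataset"
        write_dataset(ds_dir, counts, cells, truth, sim_cfg)
        regulon_gmt = config.regulon_gmt_path or str(ds_dir / "regulons.gmt")

    # --- qc ---------------------------------------------------------------
    @stage("qc")
    def _qc():
        thr = QCThresholds(
            umi_min=config.umi_min,
            umi_max=config.umi_max,
            genes_min=config.genes_min,
            genes_max=config.genes_max,
            mito_pct_max=config.mito_pct_max,
            log_ratio_min=config.log_ratio_min,
        )
        filt, fcells, report = apply_qc_filters(counts, cells, thr)
        report.to_csv(outdir / "qc.tsv", sep="\t", index_label="cell")
        return filt, fcells

    fcounts, fcells = _qc()

    # --- normalize + markers ---------------------------------------------
    @stage("markers")
    def _markers():
        norm = normalize_log(fcounts, scale=config.scale_factor)
        markers = find_markers(norm, fcells["cluster"].to_numpy())
        markers.to_csv(outdir / "markers.tsv", sep="\t", index=False)
        return norm

    norm = _markers()

    # --- pseudobulk DE ----------------------------------------------------
    @stage("de")
    def _de():
        frames = []
        pb_all = aggregate_pseudobulk(fcounts, fcells)
        for cl in sorted(fcells["cluster"].unique()):
            cols = pb_all.columns_for_cluster(cl)
            cd = pb_all.coldata.loc[cols]
            if cd.groupby("dose").size().min() < 2 or cd["dose"].nunique() < 2:
                continue
            sub = pb_all.counts[cols]
            try:
                res = run_dose_lrt(sub, cd)
            except ValueError as exc:
                logger.warning("cluster %s DE skipped: %s", cl, exc)
                continue
            res.insert(0, "cluster", cl)
            frames.append(res)
        table = pd.concat(frames) if frames else pd.DataFrame()
        table.to_csv(outdir / "de.tsv", sep="\t", index_label="gene")
        return table

    de_table = _de()

    # --- composition ------------------------------------------------------
    @stage("composition")
    def _composition():
        props = proportions_table(fcells)
        groups = fcells.groupby("sample")["dose"].first()
        res = moderated_prop_test(props, groups)
        res.to_csv(outdir / "composition.tsv", sep="\t")
        return res

    _composition()

    # --- trajectory -------------------------------------------------------
    @stage("trajectory")
    def _trajectory():
        emb = fcells[["embed_x", "embed_y"]]
        root = emb["embed_x"].idxmin()
        model = assign_pseudotime(emb, root=root, k=config.knn)
        ks = ks_shift_test(model.pseudotime, fcells)
        ks.to_csv(outdir / "trajectory.tsv", sep="\t", index=False)
        # timing test on the most variable genes (bounded for runtime)
        variances = norm.matrix.var(axis=0)
        top = np.argsort(variances)[::-1][: config.kl_genes_max]
        timing = kl_timing_test(
            norm,
            model.pseudotime,
            fcells["dose"],
            list(norm.genes[top]),
            bins=config.kl_bins,
            n_perm=config.kl_n_perm,
            seed=config.kl_seed,
        )
        timing.table.to_csv(outdir / "timing.tsv", sep="\t", index_label="gene")
        return model

    _trajectory()

    # --- enrichment -------------------------------------------------------
    @stage("enrichment")
    def _enrichment():
        universe = list(norm.genes[(fcounts.to_dense() > 0).any(axis=0)])
        if len(de_table):
            called = de_table.index[de_table["called"]].unique()
            query = [g for g in called if g in set(universe)]
        else:
            query = []
        if config.gmt_path:
            sets = read_gmt(config.gmt_path)
        else:
            # fall back to planted truth sets when simulating
            from .io import GeneSetCollection

            sets = GeneSetCollection()
            if truth is not None:
                for klass in ("repressed", "activated"):
                    genes = list(truth.genes_of_class(klass))
                    if genes:
                        sets.add(f"planted_{klass}", genes)
        res = (
            hypergeom_ora(query, universe, sets)
            if query and len(sets)
            else pd.DataFrame(columns=["set", "overlap", "pvalue", "qvalue"])
        )
        res.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        return res

    _enrichment()

    # --- regulons ---------------------------------------------------------
    @stage("regulons")
    def _regulons():
        if not regulon_gmt or not Path(regulon_gmt).exists():
            pd.DataFrame().to_csv(outdir / "regulons.tsv", sep="\t")
            return None
        regs = read_gmt(regulon_gmt)
        activity = aucell_scores(fcounts, regs, seed=config.aucell_seed)
        rss = regulon_specificity(activity, fcells["cluster"].to_numpy())
        rss.to_csv(outdir / "rss.tsv", sep="\t", index_label="regulon")
        diff = differential_regulons(activity, fcells)
        diff.to_csv(outdir / "regulons.tsv", sep="\t", index=False)
        return diff

    _regulons()

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return outdir
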