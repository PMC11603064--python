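"""Synthetic multi-genotype snRNA-seq generator with known ground truth.

Generates sparse count matrices for an allelic series (dose 0 = KO,
1 = Het, 2 = WT) in which gene programs vary along a latent
differentiation pseudotime:

* *repressed* genes: mean multiplied by ``2^(effect * (2 - dose))`` —
  de-repressed already at one lost allele;
* *activated* genes: reduced by ``2^(-effect)`` at dose 0 and only
  ``2^(-effect * attenuation)`` at dose 1 — threshold-like;
* *dynamic-neutral* genes: Gaussian bumps at a per-gene peak time
  (optionally peak-shifted in mutants to plant a timing disruption);
* *cell-cycle* genes: phase-gated programs active in early
  (progenitor-like) cells;
* *mito* genes: flagged with the reserved ``mt-`` prefix;
* everything else: flat nulls.

Mutant cells additionally progress along pseudotime with a maturation
lag proportional to the number of lost alleles. Counts are negative
binomial (variance = mu + alpha * mu^2) with log-normal library sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, GeneSetCollection, write_cell_table, write_counts_mtx, write_gmt

MITO_PREFIX = "mt-"

GENE_CLASSES = (
    "repressed",
    "activated",
    "dynamic-neutral",
    "cellcycle-S",
    "cellcycle-G2M",
    "mito",
    "null",
)


@dataclass
class SimConfig:
    """Parameters of one simulated dataset."""

    n_genes: int = 2000
    n_cells_per_sample: int = 500
    samples_per_dose: dict[int, int] = field(default_factory=lambda: {0: 3, 1: 3, 2: 3})
    frac_repressed: float = 0.05
    frac_activated: float = 0.05
    frac_dynamic: float = 0.20
    frac_cellcycle: float = 0.05
    frac_mito: float = 0.02
    effect_repressed_log2fc_per_lost_allele: float = 0.5
    effect_activated_log2fc_KO: float = 1.0
    het_activated_attenuation: float = 0.2
    maturation_lag: float = 0.1
    n_timeshift_genes: int = 0
    timeshift: float = 0.2
    dispersion_shape: tuple[float, float] = (math.log(0.05), 0.5)
    libsize_lognormal: tuple[float, float] = (math.log(2500.0), 0.3)
    n_segments: int = 5
    n_regulons: int = 5
    targets_per_regulon: int = 20
    seed: int = 1

    @property
    def doses(self) -> tuple[int, ...]:
        return tuple(sorted(self.samples_per_dose))

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_cells_per_sample <= 0:
            raise ValueError("n_genes and n_cells_per_sample must be > 0")
        if not self.samples_per_dose:
            raise ValueError("at least one dose is required")
        for dose, n in self.samples_per_dose.items():
            if dose not in (0, 1, 2):
                raise ValueError(f"dose must be in {{0,1,2}}, got {dose}")
            if n < 1:
                raise ValueError(f"dose {dose} has {n} samples; every dose needs >= 1")
        fracs = {
            "frac_repressed": self.frac_repressed,
            "frac_activated": self.frac_activated,
            "frac_dynamic": self.frac_dynamic,
            "frac_cellcycle": self.frac_cellcycle,
            "frac_mito": self.frac_mito,
        }
        for name, f in fracs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {f}")
        if sum(fracs.values()) > 1.0 + 1e-12:
            raise ValueError("archetype fractions sum to more than 1")
        if not 0.0 <= self.het_activated_attenuation <= 1.0:
            raise ValueError("het_activated_attenuation must be in [0, 1]")
        for name in (
            "effect_repressed_log2fc_per_lost_allele",
            "effect_activated_log2fc_KO",
            "maturation_lag",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        # a planted effect whose archetype rounds to zero genes is a config bug
        for frac, eff, label in (
            (self.frac_repressed, self.effect_repressed_log2fc_per_lost_allele, "repressed"),
            (self.frac_activated, self.effect_activated_log2fc_KO, "activated"),
        ):
            if frac > 0 and round(frac * self.n_genes) == 0 and eff != 0:
                raise ValueError(
                    f"frac_{label}={frac} rounds to 0 genes at n_genes={self.n_genes} "
                    f"but its effect parameter is nonzero"
                )
        if self.n_timeshift_genes > round(self.frac_dynamic * self.n_genes):
            raise ValueError("n_timeshift_genes exceeds the number of dynamic genes")


@dataclass
class SyntheticTruth:
    """Planted ground truth for parameter-recovery tests."""

    gene_class: pd.Series  # per gene, one of GENE_CLASSES
    gene_peak_time: pd.Series  # NaN for non-dynamic genes
    gene_timeshift: pd.Series  # mutant peak delay, 0 for unshifted genes
    true_log2fc_by_dose: pd.DataFrame  # genes x doses, log2 shift vs WT
    cell_true_pseudotime: pd.Series
    cell_true_type: pd.Series
    cell_true_phase: pd.Series
    regulon_truth: dict[str, dict]  # TF -> {"targets": [...], "segment": label}

    def genes_of_class(self, klass: str) -> pd.Index:
        return self.gene_class.index[self.gene_class == klass]


def _logistic(t: np.ndarray, midpoint: float, rate: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-rate * (t - midpoint)))


def _assign_gene_classes(config: SimConfig, rng: np.random.Generator) -> tuple[list[str], pd.Series]:
    G = config.n_genes
    n_rep = round(config.frac_repressed * G)
    n_act = round(config.frac_activated * G)
    n_dyn = round(config.frac_dynamic * G)
    n_cc = round(config.frac_cellcycle * G)
    n_cc_s = n_cc // 2
    n_cc_g2m = n_cc - n_cc_s
    n_mito = round(config.frac_mito * G)
    classes = (
        ["repressed"] * n_rep
        + ["activated"] * n_act
        + ["dynamic-neutral"] * n_dyn
        + ["cellcycle-S"] * n_cc_s
        + ["cellcycle-G2M"] * n_cc_g2m
        + ["mito"] * n_mito
    )
    classes += ["null"] * (G - len(classes))
    width = len(str(G))
    names = []
    counters: dict[str, int] = {}
    for klass in classes:
        counters[klass] = counters.get(klass, 0) + 1
        stem = {
            "repressed": "rep",
            "activated": "act",
            "dynamic-neutral": "dyn",
            "cellcycle-S": "ccs",
            "cellcycle-G2M": "ccg",
            "mito": "mito",
            "null": "gene",
        }[klass]
        prefix = MITO_PREFIX if klass == "mito" else ""
        names.append(f"{prefix}{stem}{counters[klass]:0{width}d}")
    return names, pd.Series(classes, index=pd.Index(names, name="gene"), name="gene_class")


def simulate_dataset(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Draw one dataset. Deterministic given ``config`` (including its seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    names, gene_class = _assign_gene_classes(config, rng)
    G = config.n_genes
    genes = gene_class.index
    klass = gene_class.to_numpy()

    # --- cells ------------------------------------------------------------
    sample_rows = []
    for dose in config.doses:
        for rep in range(1, config.samples_per_dose[dose] + 1):
            sample_rows.append((f"d{dose}_s{rep}", dose, rep))
    samples = pd.DataFrame(sample_rows, columns=["sample", "dose", "rep"]).set_index("sample")
    samples["sex"] = ["F", "M"][: 2] * (len(samples) // 2) + ["F"] * (len(samples) % 2)
    samples["age"] = "E14"

    C = config.n_cells_per_sample * len(samples)
    cell_sample = np.repeat(samples.index.to_numpy(), config.n_cells_per_sample)
    cell_dose = np.repeat(samples["dose"].to_numpy(), config.n_cells_per_sample)
    cell_ids = pd.Index(
        [f"{s}_c{i % config.n_cells_per_sample + 1:04d}" for i, s in enumerate(cell_sample)],
        name="cell",
    )

    true_t = rng.uniform(0.0, 1.0, size=C)
    eff_t = np.clip(true_t - config.maturation_lag * (2 - cell_dose), 0.0, 1.0)

    # cell types = fixed quantile segments of TRUE pseudotime
    edges = np.quantile(true_t, np.linspace(0, 1, config.n_segments + 1))
    seg_idx = np.clip(np.searchsorted(edges, true_t, side="right") - 1, 0, config.n_segments - 1)
    seg_labels = np.array([f"T{i + 1}" for i in range(config.n_segments)])
    cell_type = seg_labels[seg_idx]

    # latent cycle phase: early cells cycle, late cells are post-mitotic
    phase = np.where(
        true_t < 0.45, np.where(rng.uniform(size=C) < 0.5, "S", "G2M"), "G1/G0"
    )

    # --- per-gene baselines ----------------------------------------------
    base = rng.lognormal(mean=0.0, sigma=0.8, size=G)
    base[klass == "mito"] *= 0.3  # keep mito% low so QC passes by default
    peak = np.full(G, np.nan)
    dyn_mask = klass == "dynamic-neutral"
    peak[dyn_mask] = rng.uniform(0.0, 1.0, size=dyn_mask.sum())

    timeshift = np.zeros(G)
    dyn_idx = np.flatnonzero(dyn_mask)
    if config.n_timeshift_genes:
        timeshift[dyn_idx[: config.n_timeshift_genes]] = config.timeshift

    # --- regulon truth ----------------------------------------------------
    regulon_truth: dict[str, dict] = {}
    n_reg = min(config.n_regulons, len(dyn_idx) // (config.targets_per_regulon + 1))
    if n_reg > 0:
        # reserve the tail of the dynamic block (the head may be time-shifted)
        pool = list(dyn_idx)
        seg_centers = (edges[:-1] + edges[1:]) / 2.0
        for r in range(n_reg):
            tf = pool.pop()
            targets = [pool.pop() for _ in range(config.targets_per_regulon)]
            seg = r % config.n_segments
            center = seg_centers[seg]
            peak[tf] = center
            peak[targets] = np.clip(center + rng.normal(0.0, 0.02, size=len(targets)), 0.0, 1.0)
            regulon_truth[str(genes[tf])] = {
                "targets": [str(genes[t]) for t in targets],
                "segment": seg_labels[seg],
            }

    # --- expression surface ----------------------------------------------
    expr = np.empty((C, G))
    flat = np.isin(klass, ["repressed", "activated", "mito", "null"])
    expr[:, flat] = base[flat]

    if dyn_mask.any():
        pk = peak[dyn_mask][None, :] + timeshift[dyn_mask][None, :] * (cell_dose[:, None] < 2)
        bump = np.exp(-((eff_t[:, None] - pk) ** 2) / (2 * 0.1**2))
        expr[:, dyn_mask] = base[dyn_mask] * (0.15 + 3.0 * bump)

    cyc = _logistic(eff_t, midpoint=0.45, rate=-12.0)  # decreasing: progenitors cycle
    for cc_class, cc_phase in (("cellcycle-S", "S"), ("cellcycle-G2M", "G2M")):
        mask = klass == cc_class
        if mask.any():
            gate = 1.0 + 4.0 * (phase == cc_phase)
            expr[:, mask] = base[mask] * (0.05 + cyc * gate)[:, None]

    # --- genotype effects -------------------------------------------------
    lost = 2 - cell_dose
    rep_mask = klass == "repressed"
    if rep_mask.any():
        expr[:, rep_mask] *= 2.0 ** (
            config.effect_repressed_log2fc_per_lost_allele * lost[:, None]
        )
    act_mask = klass == "activated"
    if act_mask.any():
        shift = np.zeros(C)
        shift[cell_dose == 0] = -config.effect_activated_log2fc_KO
        shift[cell_dose == 1] = (
            -config.effect_activated_log2fc_KO * config.het_activated_attenuation
        )
        expr[:, act_mask] *= (2.0**shift)[:, None]

    # --- sampling ---------------------------------------------------------
    p = expr / expr.sum(axis=1, keepdims=True)
    libsize = rng.lognormal(*config.libsize_lognormal, size=C)
    mu = libsize[:, None] * p
    alpha = rng.lognormal(*config.dispersion_shape, size=G)
    lam = rng.gamma(shape=1.0 / alpha[None, :], scale=mu * alpha[None, :])
    counts = rng.poisson(lam)
    matrix = sp.csr_matrix(counts)

    # --- outputs ----------------------------------------------------------
    cells = pd.DataFrame(
        {
            "sample": cell_sample,
            "dose": cell_dose,
            "cluster": cell_type,
            "sex": samples.loc[cell_sample, "sex"].to_numpy(),
            "age": samples.loc[cell_sample, "age"].to_numpy(),
            "true_pseudotime": true_t,
            "true_phase": phase,
            "embed_x": eff_t + rng.normal(0.0, 0.02, size=C),
            "embed_y": rng.normal(0.0, 0.05, size=C),
        },
        index=cell_ids,
    )

    lfc = pd.DataFrame(0.0, index=genes, columns=pd.Index(config.doses, name="dose"))
    for d in config.doses:
        lfc.loc[rep_mask, d] = config.effect_repressed_log2fc_per_lost_allele * (2 - d)
        if d == 0:
            lfc.loc[act_mask, d] = -config.effect_activated_log2fc_KO
        elif d == 1:
            lfc.loc[act_mask, d] = (
                -config.effect_activated_log2fc_KO * config.het_activated_attenuation
            )
    if 2 in config.doses:
        lfc[2] = 0.0
    if len(config.doses) == 1:
        lfc.loc[:, :] = 0.0

    truth = SyntheticTruth(
        gene_class=gene_class,
        gene_peak_time=pd.Series(peak, index=genes, name="gene_peak_time"),
        gene_timeshift=pd.Series(timeshift, index=genes, name="gene_timeshift"),
        true_log2fc_by_dose=lfc,
        cell_true_pseudotime=pd.Series(true_t, index=cell_ids, name="true_pseudotime"),
        cell_true_type=pd.Series(cell_type, index=cell_ids, name="true_type"),
        cell_true_phase=pd.Series(phase, index=cell_ids, name="true_phase"),
        regulon_truth=regulon_truth,
    )
    return CountMatrix(matrix, cell_ids, genes), cells, truth


def simulate_null_dataset(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Same machinery with every genotype effect forced to zero.

    Genotype labels are exchangeable by construction; the truth contains
    no repressed/activated genes.
    """
    null_cfg = replace(
        config,
        frac_repressed=0.0,
        frac_activated=0.0,
        effect_repressed_log2fc_per_lost_allele=0.0,
        effect_activated_log2fc_KO=0.0,
        maturation_lag=0.0,
        n_timeshift_genes=0,
    )
    return simulate_dataset(null_cfg)


def write_dataset(
    outdir,
    counts: CountMatrix,
    cells: pd.DataFrame,
    truth: SyntheticTruth,
    config: SimConfig | None = None,
) -> Path:
    """Persist a simulated dataset as MTX + TSV sidecars (text only)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts_mtx(counts, outdir)
    write_cell_table(cells, outdir / "cell_table.tsv")
    gene_truth = pd.DataFrame(
        {
            "gene_class": truth.gene_class,
            "gene_peak_time": truth.gene_peak_time,
            "gene_timeshift": truth.gene_timeshift,
        }
    )
    gene_truth = gene_truth.join(truth.true_log2fc_by_dose.add_prefix("log2fc_dose"))
    gene_truth.to_csv(outdir / "gene_truth.tsv", sep="\t", index_label="gene")
    if truth.regulon_truth:
        coll = GeneSetCollection()
        for tf, info in truth.regulon_truth.items():
            coll.add(tf, [tf, *info["targets"]], description=info["segment"])
        write_gmt(coll, outdir / "regulons.gmt")
    if config is not None:
        with open(outdir / "sim_config.txt", "w") as fh:
            for key, value in vars(config).items():
                fh.write(f"{key}\t{value}\n")
    return outdir
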