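"""Seeded synthetic GEBV + expression data with planted, recorded ground truth.

The generator emulates the structure of a livestock muscle transcriptome
study with multi-trait breeding values:

* a samples x traits GEBV matrix whose first ``block_traits`` traits form a
  highly correlated block (pairwise r roughly 0.77-0.97, produced by a
  one-factor loading structure, which is positive semi-definite by
  construction) while the remaining traits are independent;
* expression features that are mostly background Gaussian noise, with a
  configurable number of planted features linearly tied to one trait's GEBV
  (``beta * Z(gebv) + noise``, so the population correlation is
  ``beta / sqrt(beta^2 + noise_sd^2)``);
* planted candidate *regulators* that are differentially co-expressed: they
  track the overall trait score in the high-score half of the samples and
  are pure noise in the other half;
* optionally, zero-inflated negative-binomial count matrices for exercising
  the low-expression filter.

Everything is driven by one integer seed and a :class:`SimConfig`; the same
config + seed reproduce byte-identical TSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CountMatrix, ExpressionMatrix, GEBVMatrix

__all__ = ["SimConfig", "SyntheticTruth", "simulate_gebv",
           "simulate_expression", "simulate_counts", "simulate_dataset"]


@dataclass
class SimConfig:
    """Generator settings; defaults reflect the study-scale conditions.

    113 samples, 1,000 genes + 100 miRNAs, 10 traits of which 6 form the
    correlated block, 20 planted feature-trait associations with
    ``beta = 0.75`` against unit noise (population r = 0.6), and one planted
    differentially co-expressed regulator.
    """

    n_samples: int = 113
    n_genes: int = 1000
    n_mirnas: int = 100
    n_traits: int = 10
    block_traits: int | None = None  # default: min(6, n_traits)
    block_loading_range: tuple = (0.88, 0.985)
    n_planted_assoc: int = 20
    assoc_beta: float = 0.75
    n_planted_regulators: int = 1
    regulator_beta: float = 2.0
    regulator_noise_sd: float = 0.5
    noise_sd: float = 1.0
    gebv_sd: float = 1.0
    # count-model settings (filter tests only)
    count_mean: float = 50.0
    count_dispersion: float = 2.0
    zero_inflation: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.block_traits is None:
            self.block_traits = min(6, self.n_traits)
        if self.block_traits > self.n_traits:
            raise ValueError("block_traits cannot exceed n_traits")
        for name in ("n_samples", "n_genes", "n_mirnas", "n_traits"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must be in [0, 1]")

    def trait_correlation(self) -> np.ndarray:
        """The trait-trait correlation matrix implied by the config."""
        lam = np.zeros(self.n_traits)
        if self.block_traits:
            lo, hi = self.block_loading_range
            lam[: self.block_traits] = np.linspace(lo, hi, self.block_traits)
        corr = np.outer(lam, lam)
        np.fill_diagonal(corr, 1.0)
        return corr

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "block_loading_range" in d:
            d["block_loading_range"] = tuple(d["block_loading_range"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a simulated dataset."""

    planted_pairs: list = field(default_factory=list)   # (feature_id, trait_id, beta)
    regulator_ids: list = field(default_factory=list)
    high_half_samples: list = field(default_factory=list)
    trait_correlation: np.ndarray | None = None
    seed: int = 0

    @property
    def planted_feature_ids(self) -> list:
        return [f for f, _, _ in self.planted_pairs]

    def to_tsv(self, path) -> None:
        rows = [{"feature_id": f, "trait_id": t, "beta": b, "kind": "association"}
                for f, t, b in self.planted_pairs]
        rows += [{"feature_id": r, "trait_id": "", "beta": "", "kind": "regulator"}
                 for r in self.regulator_ids]
        pd.DataFrame(rows, columns=["feature_id", "trait_id", "beta", "kind"]
                     ).to_csv(path, sep="\t", index=False)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    # independent streams per stage so adding a stage never shifts another
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


def simulate_gebv(cfg: SimConfig) -> GEBVMatrix:
    """Draw the samples x traits GEBV matrix from the configured MVN."""
    corr = cfg.trait_correlation()
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise ValueError("trait correlation matrix is not positive semi-definite")
    rng = _rng(cfg, stream=1)
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(cfg.n_traits))
    raw = rng.standard_normal((cfg.n_samples, cfg.n_traits))
    values = (raw @ L.T) * cfg.gebv_sd
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    traits = [f"trait{j:02d}" for j in range(cfg.n_traits)]
    return GEBVMatrix(pd.DataFrame(values, index=samples, columns=traits))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_expression(cfg: SimConfig, gebv: GEBVMatrix):
    """Generate gene + miRNA expression with planted structure.

    Returns ``(genes, mirnas, truth)``. Planted trait-associated features are
    ``beta * Z(gebv_trait) + N(0, noise_sd)``; planted regulators follow the
    standardized block-trait score in the high-score half of the samples and
    are pure noise in the other half (differential co-expression by
    construction). Features and traits for planting are chosen by the seeded
    generator.
    """
    n_feat = cfg.n_genes + cfg.n_mirnas
    if cfg.n_planted_assoc + cfg.n_planted_regulators > n_feat:
        raise ValueError("more planted features than features available")
    rng = _rng(cfg, stream=2)
    samples = gebv.sample_ids
    n = len(samples)

    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    mirna_ids = [f"miR{i:04d}" for i in range(cfg.n_mirnas)]
    all_ids = gene_ids + mirna_ids
    values = rng.normal(0.0, cfg.noise_sd, size=(n_feat, n))

    planted_idx = rng.choice(n_feat, size=cfg.n_planted_assoc + cfg.n_planted_regulators,
                             replace=False)
    assoc_idx = planted_idx[: cfg.n_planted_assoc]
    reg_idx = planted_idx[cfg.n_planted_assoc:]

    pairs = []
    for i in assoc_idx:
        trait = gebv.trait_ids[int(rng.integers(cfg.n_traits))]
        z = _standardize(gebv.data[trait].to_numpy())
        values[i] = cfg.assoc_beta * z + rng.normal(0.0, cfg.noise_sd, size=n)
        pairs.append((all_ids[i], trait, cfg.assoc_beta))

    # generator-side overall score: sum of standardized block-trait GEBVs
    block = gebv.trait_ids[: cfg.block_traits] or gebv.trait_ids
    score = np.sum([_standardize(gebv.data[t].to_numpy()) for t in block], axis=0)
    order = np.argsort(score, kind="stable")
    half = n // 2
    high_half = sorted(samples[i] for i in order[n - half:]) if half else []
    high_mask = np.isin(np.array(samples), np.array(high_half)) if half else np.zeros(n, bool)

    score_z = _standardize(score)
    for i in reg_idx:
        expr = rng.normal(0.0, cfg.regulator_noise_sd, size=n)
        expr[high_mask] += cfg.regulator_beta * score_z[high_mask]
        # keep overall scale comparable to background features
        values[i] = expr

    df = pd.DataFrame(values, index=all_ids, columns=samples)
    genes = ExpressionMatrix(df.loc[gene_ids], "gene") if cfg.n_genes else \
        ExpressionMatrix(pd.DataFrame(index=pd.Index([]), columns=samples, dtype=float), "gene")
    mirnas = ExpressionMatrix(df.loc[mirna_ids], "mirna") if cfg.n_mirnas else \
        ExpressionMatrix(pd.DataFrame(index=pd.Index([]), columns=samples, dtype=float), "mirna")
    truth = SyntheticTruth(planted_pairs=pairs,
                           regulator_ids=[all_ids[i] for i in reg_idx],
                           high_half_samples=list(high_half),
                           trait_correlation=cfg.trait_correlation(),
                           seed=cfg.seed)
    return genes, mirnas, truth


def simulate_counts(cfg: SimConfig) -> CountMatrix:
    """Zero-inflated negative-binomial counts for the low-expression filter."""
    rng = _rng(cfg, stream=3)
    n_feat = cfg.n_genes + cfg.n_mirnas
    shape = (n_feat, cfg.n_samples)
    p = cfg.count_dispersion / (cfg.count_dispersion + cfg.count_mean)
    counts = rng.negative_binomial(cfg.count_dispersion, p, size=shape)
    zeros = rng.random(shape) < cfg.zero_inflation
    counts = np.where(zeros, 0, counts)
    ids = [f"G{i:05d}" for i in range(cfg.n_genes)] + \
          [f"miR{i:04d}" for i in range(cfg.n_mirnas)]
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    roles = pd.Series(["gene"] * cfg.n_genes + ["mirna"] * cfg.n_mirnas,
                      index=ids, dtype=object)
    return CountMatrix(pd.DataFrame(counts, index=ids, columns=samples), roles)


def simulate_dataset(cfg: SimConfig):
    """Convenience: GEBVs + expression + truth in one call."""
    gebv = simulate_gebv(cfg)
    genes, mirnas, truth = simulate_expression(cfg, gebv)
    return gebv, genes, mirnas, truth
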