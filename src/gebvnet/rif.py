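"""Regulatory impact factors (RIF) with GEBVs as the regulated targets.

RIF ranks candidate regulators by how differently they co-vary with a set of
targets between two contrasting sample groups. In the classical use the
targets are differentially expressed genes and the candidates are
transcription factors; here the targets are genomic estimated breeding
values (GEBVs) for quantitative traits, and the candidates are the genes and
miRNAs whose expression an association network tied to those traits.

For candidate i and target trait j, with high/low group means ``eH_j`` and
``eL_j`` of the trait's GEBV, ``a_j = (eH_j + eL_j) / 2``,
``d_j = eH_j - eL_j``, and within-group Pearson correlations ``rH_ij`` and
``rL_ij`` between candidate expression and the trait GEBV:

    RIF1_i = (1/n_t) * sum_j  a_j * d_j * (rH_ij - rL_ij)^2
    RIF2_i = (1/n_t) * sum_j  (eH_j * rH_ij)^2 - (eL_j * rL_ij)^2

Raw scores are z-standardized across candidates; a candidate is significant
when either |z| reaches 1.96.

Contrast groups are the two tails of a single trait's GEBV distribution, or
— for an all-traits analysis — of a PCA-derived per-sample score
(variance-fraction-weighted sum of the sample's principal-component scores
over the standardized GEBV matrix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GEBVMatrix

logger = logging.getLogger(__name__)

DEFAULT_GROUP_SIZE = 15
DEFAULT_Z_CUTOFF = 1.96

__all__ = [
    "ContrastDesign",
    "select_contrast_by_trait",
    "select_contrast_by_score",
    "pca_scores",
    "RIF",
    "RIFResults",
    "rif_per_trait",
    "rif_overall",
]


@dataclass
class ContrastDesign:
    """Two disjoint, non-empty sample groups for one trait (or the PCA score)."""

    label: str
    high_samples: list = field(default_factory=list)
    low_samples: list = field(default_factory=list)

    def __post_init__(self):
        high, low = set(self.high_samples), set(self.low_samples)
        if not high or not low:
            raise ValueError("contrast groups must be non-empty")
        if high & low:
            raise ValueError(f"contrast groups overlap: {sorted(high & low)[:5]}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.high_samples) + list(self.low_samples),
             "group": ["high"] * len(self.high_samples) + ["low"] * len(self.low_samples)})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _select_extremes(values: pd.Series, group_size: int, label: str) -> ContrastDesign:
    if group_size <= 0:
        raise ValueError("group_size must be positive")
    n = len(values)
    if 2 * group_size > n:
        raise ValueError(f"group_size={group_size} too large for {n} samples")
    if values.nunique() == 1:
        logger.warning("all values equal for %r; contrast groups filled by id order", label)
    order = sorted(values.index, key=lambda s: (values[s], str(s)))
    low = order[:group_size]
    high = order[-group_size:]
    return ContrastDesign(label=label, high_samples=high, low_samples=low)


def select_contrast_by_trait(gebv: GEBVMatrix, trait: str,
                             group_size: int = DEFAULT_GROUP_SIZE) -> ContrastDesign:
    """Top/bottom ``group_size`` samples by one trait's GEBV; ties by sample id."""
    if trait not in gebv.data.columns:
        raise KeyError(f"unknown trait {trait!r}")
    return _select_extremes(gebv.data[trait], group_size, label=trait)


def select_contrast_by_score(scores: pd.Series,
                             group_size: int = DEFAULT_GROUP_SIZE) -> ContrastDesign:
    """Top/bottom ``group_size`` samples by the PCA-derived overall score."""
    return _select_extremes(scores, group_size, label="pca_score")


def pca_scores(gebv: GEBVMatrix, variance_weight: str = "proportion") -> pd.Series:
    """Per-sample overall score from a PCA of the standardized GEBV matrix.

    Each trait column is standardized to mean 0, sd 1; PCA is performed on
    the resulting correlation structure, and a sample's score is the sum of
    its principal-component scores weighted by each component's share of the
    total variance:

        A_i = sum_j w_j * (Z_i . v_j),   w_j = lambda_j / sum(lambda)

    With ``variance_weight="eigenvalue"`` the raw eigenvalue is used as the
    weight instead of the proportion. Eigenvector signs are fixed by making
    the largest-magnitude loading of each component positive, so the scores
    are reproducible.
    """
    if variance_weight not in ("proportion", "eigenvalue"):
        raise ValueError("variance_weight must be 'proportion' or 'eigenvalue'")
    X = gebv.data.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 or p < 1:
        raise ValueError("need at least 2 samples and 1 trait")
    sd = X.std(axis=0)
    if (sd == 0).all():
        # fully degenerate input: every standardized value is 0, so every score is 0
        logger.warning("all trait columns constant; PCA scores defined as 0")
        return pd.Series(0.0, index=gebv.data.index, name="score")
    if (sd == 0).any():
        bad = [gebv.trait_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant trait column(s): {bad} (standardization undefined)")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / n
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0.0, None)
    # deterministic sign: largest-|loading| entry of each PC made positive
    for j in range(p):
        k = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    weights = eigvals / eigvals.sum() if variance_weight == "proportion" else eigvals
    pc_scores = Z @ eigvecs  # samples x components
    scores = pc_scores @ weights
    return pd.Series(scores, index=gebv.data.index, name="score")


def _group_correlations(expr: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Pearson r between each candidate row and each target column.

    expr: candidates x samples; targets: samples x traits. Candidates or
    targets with zero variance within the group contribute r = 0.
    """
    n = expr.shape[1]
    ec = expr - expr.mean(axis=1, keepdims=True)
    tc = targets - targets.mean(axis=0, keepdims=True)
    e_sd = ec.std(axis=1)
    t_sd = tc.std(axis=0)
    cov = (ec @ tc) / n
    denom = np.outer(e_sd, t_sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    if (e_sd == 0).any():
        logger.warning("%d candidate(s) constant within a contrast group; "
                       "their correlations set to 0", int((e_sd == 0).sum()))
    return np.clip(r, -1.0, 1.0)


class RIF:
    """RIF model: candidates x targets x a high/low contrast design.

    Parameters
    ----------
    candidates : ExpressionMatrix or pandas.DataFrame
        Candidate regulators (features x samples).
    targets : GEBVMatrix or pandas.DataFrame
        Target values (samples x traits); all columns are used.
    design : ContrastDesign
        The high/low sample groups. Every design sample must be present in
        both matrices, and each group needs at least 3 samples.
    z_cutoff : float
        Significance threshold on |z| (default 1.96).
    """

    def __init__(self, candidates, targets, design: ContrastDesign,
                 z_cutoff: float = DEFAULT_Z_CUTOFF):
        cand = candidates.data if isinstance(candidates, ExpressionMatrix) else candidates
        targ = targets.data if isinstance(targets, GEBVMatrix) else targets
        for grp, name in ((design.high_samples, "high"), (design.low_samples, "low")):
            if len(grp) < 3:
                raise ValueError(f"{name} group has {len(grp)} samples; need >= 3")
            missing = [s for s in grp if s not in cand.columns or s not in targ.index]
            if missing:
                raise ValueError(f"design samples absent from the data: {missing[:5]}")
        if cand.shape[0] < 2:
            raise ValueError("need at least 2 candidates to z-standardize RIF scores")
        self.candidates = cand.astype(float)
        self.targets = targ.astype(float)
        self.design = design
        self.z_cutoff = z_cutoff

    def fit(self) -> "RIFResults":
        H, L = list(self.design.high_samples), list(self.design.low_samples)
        eH = self.targets.loc[H].mean(axis=0).to_numpy()
        eL = self.targets.loc[L].mean(axis=0).to_numpy()
        a = (eH + eL) / 2.0
        d = eH - eL
        rH = _group_correlations(self.candidates[H].to_numpy(),
                                 self.targets.loc[H].to_numpy())
        rL = _group_correlations(self.candidates[L].to_numpy(),
                                 self.targets.loc[L].to_numpy())
        rif1 = np.mean(a * d * (rH - rL) ** 2, axis=1)
        rif2 = np.mean((eH * rH) ** 2 - (eL * rL) ** 2, axis=1)
        table = pd.DataFrame({
            "candidate_id": list(self.candidates.index),
            "rif1_raw": rif1,
            "rif2_raw": rif2,
            "rif1_z": _zscore(rif1),
            "rif2_z": _zscore(rif2),
        })
        table["significant"] = significance_call(table["rif1_z"], table["rif2_z"],
                                                 self.z_cutoff)
        return RIFResults(table, self.design, self.z_cutoff)


def significance_call(rif1_z, rif2_z, cutoff: float = DEFAULT_Z_CUTOFF):
    """A candidate is significant when either |z| reaches the cutoff (inclusive)."""
    return (np.abs(rif1_z) >= cutoff) | (np.abs(rif2_z) >= cutoff)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        logger.warning("raw RIF scores have zero spread; z-scores set to 0")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


class RIFResults:
    """RIF score table plus the design that produced it."""

    def __init__(self, table: pd.DataFrame, design: ContrastDesign, z_cutoff: float):
        self.table = table
        self.design = design
        self.z_cutoff = z_cutoff

    @property
    def significant_ids(self) -> list:
        return self.table.loc[self.table["significant"], "candidate_id"].tolist()

    def summary(self) -> str:
        t = self.table
        lines = [
            "RIF Results",
            "=" * 46,
            f"contrast:        {self.design.label}",
            f"group sizes:     {len(self.design.high_samples)} high / "
            f"{len(self.design.low_samples)} low",
            f"candidates:      {len(t)}",
            f"significant:     {len(self.significant_ids)} (|z| >= {self.z_cutoff})",
        ]
        if len(t):
            top = t.reindex(t["rif1_z"].abs().sort_values(ascending=False).index).head(5)
            lines.append("top |RIF1 z|:")
            for _, row in top.iterrows():
                lines.append(f"  {row['candidate_id']:<20} rif1_z={row['rif1_z']:+.3f} "
                             f"rif2_z={row['rif2_z']:+.3f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _empty_rif_table() -> pd.DataFrame:
    return pd.DataFrame(columns=["candidate_id", "rif1_raw", "rif2_raw",
                                 "rif1_z", "rif2_z", "significant"])


def rif_per_trait(candidates_per_trait: dict, expr: ExpressionMatrix,
                  gebv: GEBVMatrix, group_size: int = DEFAULT_GROUP_SIZE,
                  z_cutoff: float = DEFAULT_Z_CUTOFF) -> dict:
    """One RIF analysis per trait: that trait's correlated features vs its GEBV.

    ``candidates_per_trait`` maps trait id -> feature-id list (typically from
    the combined PCIT feature-trait table). Traits with fewer than two
    candidates yield an empty table with a warning.
    """
    results = {}
    for trait in gebv.trait_ids:
        cand_ids = [c for c in candidates_per_trait.get(trait, [])
                    if c in set(expr.feature_ids)]
        if len(cand_ids) < 2:
            logger.warning("trait %r has %d candidate(s); RIF skipped",
                           trait, len(cand_ids))
            design = None
            results[trait] = RIFResults(_empty_rif_table(),
                                        _trivial_design(trait, gebv, group_size),
                                        z_cutoff)
            continue
        design = select_contrast_by_trait(gebv, trait, group_size)
        model = RIF(expr.data.loc[cand_ids], gebv.data[[trait]], design, z_cutoff)
        results[trait] = model.fit()
    return results


def _trivial_design(label, gebv, group_size):
    # placeholder design for empty results; selection is still deterministic
    return select_contrast_by_trait(gebv, label, min(group_size, gebv.n_samples // 2))


def rif_overall(candidate_ids, expr: ExpressionMatrix, gebv: GEBVMatrix,
                group_size: int = DEFAULT_GROUP_SIZE,
                z_cutoff: float = DEFAULT_Z_CUTOFF,
                variance_weight: str = "proportion"):
    """RIF against all traits at once, with PCA-score contrast groups.

    Candidates are the features correlated to at least one trait; the
    targets are all GEBV columns. Returns ``(RIFResults, scores, design)``.
    """
    scores = pca_scores(gebv, variance_weight=variance_weight)
    design = select_contrast_by_score(scores, group_size)
    cand_ids = [c for c in candidate_ids if c in set(expr.feature_ids)]
    if len(cand_ids) < 2:
        logger.warning("overall RIF: %d candidate(s); skipped", len(cand_ids))
        return RIFResults(_empty_rif_table(), design, z_cutoff), scores, design
    model = RIF(expr.data.loc[cand_ids], gebv.data, design, z_cutoff)
    return model.fit(), scores, design
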