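"""PCIT: partial-correlation-with-information-theory network inference.

The algorithm examines every trio of variables (x, y, z). For each trio it
computes the three first-order partial correlations and a data-driven
tolerance

    eps_xyz = mean over the trio of (partial correlation / direct correlation)

and rejects the edge (x, y) *locally* when its direct correlation is no
larger (in magnitude) than the tolerance-scaled correlations through z:

    |r_xy| <= |eps * r_xz|   and   |r_xy| <= |eps * r_yz|.

An edge is significant when **no** third variable rejects it. The novelty of
this package is the node set: genomic estimated breeding values (GEBVs) for
quantitative traits enter the network alongside gene and miRNA expression,
so significant feature-trait edges read as expression-phenotype association.

Degenerate trios are handled conservatively: ratio terms with a zero direct
correlation are dropped from the tolerance mean (a trio whose three direct
correlations are all zero rejects nothing), and a trio containing a perfect
correlation (|r| = 1) is skipped entirely — the perfect edge itself is
always reported significant.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GEBVMatrix
from .preprocess import align_samples

logger = logging.getLogger(__name__)

#: |r| at or above this is treated as a perfect correlation (trio degeneracy).
PERFECT = 1.0 - 1e-12

__all__ = [
    "partial_correlation",
    "pearson_all",
    "PCIT",
    "PCITResults",
    "run_pcit_general",
    "run_pcit_mirna",
    "combine_feature_trait_edges",
]


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation of x and y given z.

    ``(r_xy - r_xz*r_yz) / sqrt((1 - r_xz^2) * (1 - r_yz^2))``
    """
    for name, r in (("r_xy", r_xy), ("r_xz", r_xz), ("r_yz", r_yz)):
        if abs(r) > 1.0:
            raise ValueError(f"{name}={r} outside [-1, 1]")
    if abs(r_xz) >= PERFECT or abs(r_yz) >= PERFECT:
        raise ValueError("partial correlation undefined: conditioning pair has |r| = 1")
    return (r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))


def pearson_all(values: np.ndarray, node_ids=None) -> np.ndarray:
    """Pairwise Pearson correlation of the rows of ``values`` (nodes x samples).

    Raises if any row has zero variance — constant nodes must be dropped by
    the caller (see :meth:`PCIT.fit`).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D nodes x samples array")
    if values.shape[1] < 3:
        raise ValueError(f"need at least 3 samples, got {values.shape[1]}")
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)
        names = [node_ids[i] for i in bad] if node_ids is not None else bad.tolist()
        raise ValueError(f"zero-variance node(s): {names[:5]}")
    r = np.corrcoef(values)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def pcit_significance(r: np.ndarray) -> np.ndarray:
    """Boolean significance matrix for a correlation matrix, by the trio test.

    Vectorized over node pairs for each conditioning node z; decisions are
    taken on the upper triangle and mirrored, so the result is exactly
    symmetric. Runs in O(n^3) time but O(n^2) memory.
    """
    r = np.asarray(r, dtype=float)
    n = r.shape[0]
    if n < 3:
        raise ValueError(f"PCIT needs at least 3 nodes, got {n}")

    absr = np.abs(r)
    perfect_edge = absr >= PERFECT
    rejected = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)

    with np.errstate(divide="ignore", invalid="ignore"):
        for z in range(n):
            c = r[:, z]
            c2 = 1.0 - c**2
            a2 = 1.0 - r**2
            # partials: (x,y | z), (x,z | y), (y,z | x) for every pair (x, y)
            p1 = (r - c[:, None] * c[None, :]) / np.sqrt(c2[:, None] * c2[None, :])
            p2 = (c[:, None] - r * c[None, :]) / np.sqrt(a2 * c2[None, :])
            p3 = (c[None, :] - r * c[:, None]) / np.sqrt(a2 * c2[:, None])

            d1, d2, d3 = r, c[:, None], c[None, :]
            v1, v2, v3 = d1 != 0, d2 != 0, d3 != 0
            ssum = (
                np.where(v1, p1 / d1, 0.0)
                + np.where(v2, p2 / d2, 0.0)
                + np.where(v3, p3 / d3, 0.0)
            )
            cnt = v1.astype(np.int64) + v2 + v3
            eps = np.where(cnt > 0, ssum / np.maximum(cnt, 1), 0.0)

            degenerate = (
                perfect_edge
                | (np.abs(c) >= PERFECT)[:, None]
                | (np.abs(c) >= PERFECT)[None, :]
            )
            active = (cnt > 0) & ~degenerate
            active[z, :] = False
            active[:, z] = False
            active[idx, idx] = False

            rej = active & (absr <= np.abs(eps * d2)) & (absr <= np.abs(eps * d3))
            rejected |= rej

    significant = ~rejected
    significant[r == 0] = False
    significant |= perfect_edge
    np.fill_diagonal(significant, False)
    upper = np.triu(significant, k=1)
    return upper | upper.T


class PCIT:
    """PCIT model over a node set (expression vectors and/or GEBV columns).

    Parameters
    ----------
    data : pandas.DataFrame
        Nodes on rows, samples on columns.
    roles : str or pandas.Series, optional
        Node role per row: ``gene``, ``mirna`` or ``trait``.
    rank_transform : bool
        If True, correlate ranks (Spearman-style) instead of raw values.
        Off by default — PCIT is defined on Pearson correlations.
    source_run : str
        Label recorded on the results (e.g. ``"general"`` or ``"mirna"``).

    Examples
    --------
    >>> model = PCIT(node_df, roles)
    >>> res = model.fit()
    >>> res.significant_edges().head()
    """

    VALID_NODE_ROLES = ("gene", "mirna", "trait")

    def __init__(self, data: pd.DataFrame, roles: str | pd.Series = "gene",
                 rank_transform: bool = False, source_run: str = "pcit"):
        if data.index.has_duplicates:
            raise ValueError("duplicate node ids")
        if isinstance(roles, str):
            roles = pd.Series(roles, index=data.index, dtype=object)
        else:
            roles = roles.reindex(data.index).astype(object)
            if roles.isna().any():
                raise ValueError("role missing for some nodes")
        bad = set(roles.unique()) - set(self.VALID_NODE_ROLES)
        if bad:
            raise ValueError(f"invalid node roles {sorted(bad)}")
        self.data = data.astype(float)
        self.roles = roles
        self.rank_transform = rank_transform
        self.source_run = source_run

    def fit(self, subset=None) -> "PCITResults":
        """Run the trio test and return a :class:`PCITResults`.

        Parameters
        ----------
        subset : iterable of node ids, optional
            Restrict the analysis to these nodes (order preserved from the
            model's node order).
        """
        data = self.data
        roles = self.roles
        if subset is not None:
            keep = [i for i in data.index if i in set(subset)]
            data = data.loc[keep]
            roles = roles.loc[keep]
        values = data.to_numpy()
        sd = values.std(axis=1) if values.size else np.array([])
        if values.size and (sd == 0).any():
            dropped = data.index[sd == 0].tolist()
            logger.warning("dropping %d constant node(s) before PCIT: %s",
                           len(dropped), dropped[:5])
            data = data.loc[sd != 0]
            roles = roles.loc[data.index]
            values = data.to_numpy()
        if data.shape[0] < 3:
            raise ValueError(f"PCIT needs at least 3 non-constant nodes, got {data.shape[0]}")
        if self.rank_transform:
            from scipy.stats import rankdata

            values = rankdata(values, axis=1)
        corr = pearson_all(values, node_ids=list(data.index))
        sig = pcit_significance(corr)
        logger.info("PCIT(%s): %d nodes, %d significant edges",
                    self.source_run, data.shape[0], int(sig.sum() // 2))
        return PCITResults(list(data.index), roles, corr, sig, self.source_run)


class PCITResults:
    """Significance decisions and the correlation matrix behind them."""

    def __init__(self, node_ids, roles: pd.Series, corr: np.ndarray,
                 significant: np.ndarray, source_run: str = "pcit"):
        self.node_ids = list(node_ids)
        self.roles = roles
        self.corr = pd.DataFrame(corr, index=self.node_ids, columns=self.node_ids)
        self.significant = pd.DataFrame(significant, index=self.node_ids,
                                        columns=self.node_ids)
        self.source_run = source_run

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def edges(self, significant_only: bool = False) -> pd.DataFrame:
        """Upper-triangle edge list: node_a, node_b, r, significant, source_run."""
        n = self.n_nodes
        iu = np.triu_indices(n, k=1)
        df = pd.DataFrame({
            "node_a": [self.node_ids[i] for i in iu[0]],
            "node_b": [self.node_ids[j] for j in iu[1]],
            "r": self.corr.to_numpy()[iu],
            "significant": self.significant.to_numpy()[iu],
            "source_run": self.source_run,
        })
        if significant_only:
            df = df[df["significant"]].reset_index(drop=True)
        return df

    def significant_edges(self) -> pd.DataFrame:
        return self.edges(significant_only=True)

    def feature_trait_edges(self) -> pd.DataFrame:
        """Significant edges joining a gene/miRNA to a trait node."""
        edges = self.significant_edges()
        role = self.roles
        a_trait = edges["node_a"].map(role).eq("trait")
        b_trait = edges["node_b"].map(role).eq("trait")
        sel = edges[a_trait ^ b_trait].copy()
        sel["feature_id"] = np.where(a_trait[sel.index], sel["node_b"], sel["node_a"])
        sel["trait_id"] = np.where(a_trait[sel.index], sel["node_a"], sel["node_b"])
        sel["feature_role"] = sel["feature_id"].map(role)
        return sel[["feature_id", "feature_role", "trait_id", "r", "source_run"]].reset_index(drop=True)

    def summary(self) -> str:
        """Plain-text summary in the spirit of a model-results table."""
        edges = self.significant_edges()
        role = self.roles
        lines = [
            "PCIT Results",
            "=" * 46,
            f"run label:          {self.source_run}",
            f"nodes:              {self.n_nodes}",
        ]
        for r in ("gene", "mirna", "trait"):
            k = int((role == r).sum())
            if k:
                lines.append(f"  {r:<17} {k}")
        lines.append(f"significant edges:  {len(edges)}")
        ft = self.feature_trait_edges()
        lines.append(f"feature-trait edges: {len(ft)}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def to_tsv(self, edge_path, node_path=None) -> None:
        """Write the edge list, and optionally a node-role companion table."""
        self.edges().to_csv(edge_path, sep="\t", index=False)
        if node_path is not None:
            pd.DataFrame({"node_id": self.node_ids,
                          "role": [self.roles[n] for n in self.node_ids]}
                         ).to_csv(node_path, sep="\t", index=False)

    def significance_matrix_tsv(self, path) -> None:
        self.significant.astype(int).to_csv(path, sep="\t", index_label="node_id")

    @classmethod
    def from_tsv(cls, edge_path, node_path) -> "PCITResults":
        """Rebuild results from the edge + node tables written by :meth:`to_tsv`."""
        nodes = pd.read_csv(node_path, sep="\t")
        edges = pd.read_csv(edge_path, sep="\t")
        ids = nodes["node_id"].astype(str).tolist()
        roles = pd.Series(nodes["role"].tolist(), index=ids, dtype=object)
        pos = {n: i for i, n in enumerate(ids)}
        n = len(ids)
        corr = np.eye(n)
        sig = np.zeros((n, n), dtype=bool)
        ia = edges["node_a"].astype(str).map(pos).to_numpy()
        ib = edges["node_b"].astype(str).map(pos).to_numpy()
        corr[ia, ib] = corr[ib, ia] = edges["r"].to_numpy()
        sig[ia, ib] = sig[ib, ia] = edges["significant"].to_numpy().astype(bool)
        source = edges["source_run"].iloc[0] if len(edges) else "pcit"
        return cls(ids, roles, corr, sig, source)


def _stack_nodes(parts) -> tuple[pd.DataFrame, pd.Series]:
    frames, roles = [], []
    for df, role in parts:
        if df.shape[0] == 0:
            continue
        frames.append(df)
        roles.append(pd.Series(role, index=df.index, dtype=object))
    data = pd.concat(frames, axis=0)
    if data.index.has_duplicates:
        dup = data.index[data.index.duplicated()].unique().tolist()
        raise ValueError(f"node ids shared across inputs: {dup[:5]}")
    return data, pd.concat(roles)


def run_pcit_general(genes: ExpressionMatrix, mirnas: ExpressionMatrix,
                     gebv: GEBVMatrix, rank_transform: bool = False) -> PCITResults:
    """PCIT over genes + miRNAs + GEBV trait nodes ("general" run)."""
    merged = _merge_expression(genes, mirnas)
    merged, gebv = align_samples(merged, gebv)
    parts = [(merged.data[merged.feature_role == "gene"], "gene"),
             (merged.data[merged.feature_role == "mirna"], "mirna"),
             (gebv.data.T, "trait")]
    data, roles = _stack_nodes(parts)
    return PCIT(data, roles, rank_transform=rank_transform, source_run="general").fit()


def run_pcit_mirna(mirnas: ExpressionMatrix, gebv: GEBVMatrix,
                   rank_transform: bool = False) -> PCITResults:
    """PCIT over miRNAs + GEBV trait nodes only ("miRNA" run)."""
    mirnas, gebv = align_samples(mirnas, gebv)
    data, roles = _stack_nodes([(mirnas.data, "mirna"), (gebv.data.T, "trait")])
    return PCIT(data, roles, rank_transform=rank_transform, source_run="mirna").fit()


def _merge_expression(genes: ExpressionMatrix, mirnas: ExpressionMatrix) -> ExpressionMatrix:
    if mirnas.n_features == 0:
        return genes
    if genes.n_features == 0:
        return mirnas
    common = [s for s in genes.sample_ids if s in set(mirnas.sample_ids)]
    if not common:
        raise ValueError("gene and miRNA matrices share no samples")
    df = pd.concat([genes.data[common], mirnas.data[common]])
    roles = pd.concat([pd.Series("gene", index=genes.data.index, dtype=object),
                       pd.Series("mirna", index=mirnas.data.index, dtype=object)])
    return ExpressionMatrix(df, roles)


def combine_feature_trait_edges(general: PCITResults | None,
                                mirna_only: PCITResults | None) -> pd.DataFrame:
    """Union of significant feature-trait edges across the two PCIT runs.

    Returns one record per (feature, trait) pair with columns
    ``feature_id, feature_role, trait_id, r, source_runs, in_both`` —
    ``source_runs`` is ``general``, ``mirna`` or ``both``; ``r`` comes from
    the general run when present in both (the runs can disagree slightly on
    correlations only through floating noise; they use the same samples).
    """
    frames = []
    role_seen: dict = {}
    for res in (general, mirna_only):
        if res is None:
            continue
        for node, role in res.roles.items():
            if node in role_seen and role_seen[node] != role:
                raise ValueError(
                    f"node {node!r} has conflicting roles across runs: "
                    f"{role_seen[node]!r} vs {role!r}")
            role_seen[node] = role
        frames.append(res.feature_trait_edges())
    if not frames:
        return pd.DataFrame(columns=["feature_id", "feature_role", "trait_id",
                                     "r", "source_runs", "in_both"])
    allr = pd.concat(frames, ignore_index=True)
    grouped = allr.groupby(["feature_id", "trait_id"], sort=False)
    records = []
    for (fid, tid), grp in grouped:
        runs = sorted(grp["source_run"].unique())
        records.append({
            "feature_id": fid,
            "feature_role": grp["feature_role"].iloc[0],
            "trait_id": tid,
            "r": grp.loc[grp["source_run"] == "general", "r"].iloc[0]
                 if "general" in runs else grp["r"].iloc[0],
            "source_runs": "both" if len(runs) > 1 else runs[0],
            "in_both": len(runs) > 1,
        })
    return pd.DataFrame.from_records(
        records, columns=["feature_id", "feature_role", "trait_id", "r",
                          "source_runs", "in_both"])


def correlated_features_per_trait(combined: pd.DataFrame) -> dict:
    """Split the combined table into {trait_id: feature-id list}."""
    out: dict = {}
    for tid, grp in combined.groupby("trait_id", sort=False):
        out[tid] = grp["feature_id"].tolist()
    return out
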