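"""Build binary trait networks from significance-thresholded correlations.

Traits are nodes. For every trait pair the Pearson product-moment
coefficient and its two-sided p-value are computed; an (undirected,
unweighted) edge is present exactly when the correlation is significant
at level ``alpha`` (default 0.05). The sign and magnitude of ``r`` are
deliberately discarded: the network encodes only the presence or
absence of trait coordination.

P-values come from the exact t transform ``t = r * sqrt((n-2)/(1-r^2))``
on ``n-2`` degrees of freedom. Pairs are evaluated on pairwise-complete
rows; pairs with fewer than three complete rows or a constant trait are
flagged undefined and never become edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .trait_data import TraitMatrix


@dataclass
class CorrelationResult:
    """Pairwise Pearson r, two-sided p, and per-pair sample counts.

    All three matrices are symmetric with ``r`` diagonal 1 and ``p``
    diagonal 0. Undefined entries (constant trait, n < 3) are NaN.
    """

    r: np.ndarray
    p: np.ndarray
    n_pairs: np.ndarray
    trait_names: list[str]
    group: object = None

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)


@dataclass
class TraitNetwork:
    """Binary undirected trait network: a_ij = 1 iff p_ij < alpha."""

    adjacency: np.ndarray
    trait_names: list[str]
    alpha: float
    group: object = None

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(i.tolist(), j.tolist()))


def _pearson_p(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p from the t transform on n-2 df; NaN where undefined."""
    r = np.asarray(r, float)
    n = np.asarray(n, float)
    p = np.full(r.shape, np.nan)
    ok = np.isfinite(r) & (n >= 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = np.clip(r[ok], -1.0, 1.0)
        df = n[ok] - 2
        t = rr * np.sqrt(df / np.maximum(1.0 - rr * rr, 0.0))
        p[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    # perfect correlation: t is infinite, sf gives 0
    p[ok & np.isclose(np.abs(r), 1.0)] = 0.0
    return p


def pearson_with_pvalues(tm: TraitMatrix, group=None) -> CorrelationResult:
    """All pairwise Pearson correlations with two-sided p-values.

    ``group`` restricts to one water body; ``None`` uses all rows.
    Each pair uses its pairwise-complete rows. Pairs where either trait
    has zero variance are returned as NaN (undefined), never as 0 or 1.
    """
    if group is not None:
        tm = tm.subset(group)
    X = tm.values
    n, k = X.shape
    finite = np.isfinite(X)

    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n_pairs = np.zeros((k, k), dtype=int)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    np.fill_diagonal(n_pairs, finite.sum(axis=0))

    if finite.all():
        # fast vectorised path: no missing data
        n_pairs[:, :] = n
        sd = X.std(axis=0, ddof=1)
        valid = sd > 0
        if valid.any():
            with np.errstate(invalid="ignore"):
                c = np.corrcoef(X, rowvar=False)
            bad = ~valid[:, None] | ~valid[None, :]
            c[bad] = np.nan
            np.fill_diagonal(c, 1.0)
            r = c
        p = _pearson_p(r, n_pairs)
        np.fill_diagonal(p, 0.0)
        # restore diagonal of r for constant columns: self-correlation stays 1
        np.fill_diagonal(r, 1.0)
        return CorrelationResult(r, p, n_pairs, list(tm.trait_names), group)

    for i in range(k):
        for j in range(i + 1, k):
            mask = finite[:, i] & finite[:, j]
            m = int(mask.sum())
            n_pairs[i, j] = n_pairs[j, i] = m
            if m < 3:
                continue
            xi, xj = X[mask, i], X[mask, j]
            if xi.std(ddof=1) == 0 or xj.std(ddof=1) == 0:
                continue  # undefined, stays NaN
            rij = float(np.corrcoef(xi, xj)[0, 1])
            r[i, j] = r[j, i] = rij
            pij = float(_pearson_p(np.array([rij]), np.array([m]))[0])
            p[i, j] = p[j, i] = pij
    return CorrelationResult(r, p, n_pairs, list(tm.trait_names), group)


def build_network(
    cr: CorrelationResult,
    alpha: float = 0.05,
    correction: str | None = None,
) -> TraitNetwork:
    """Threshold the p-value matrix into a binary adjacency matrix.

    An edge joins traits i and j exactly when ``p_ij < alpha``
    (strict); undefined pairs never produce edges. ``correction`` may
    name a multiple-testing adjustment ("holm" or "bh") applied to the
    off-diagonal p-values before thresholding; the default is none,
    i.e. raw p-values are binarised.
    """
    if not (0.0 < alpha < 1.0):
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    k = cr.n_traits
    p = cr.p.copy()
    iu = np.triu_indices(k, 1)
    if correction is not None:
        from statsmodels.stats.multitest import multipletests

        method = {"holm": "holm", "bh": "fdr_bh"}.get(correction)
        if method is None:
            raise ConfigurationError(f"unknown correction {correction!r}")
        flat = p[iu]
        ok = np.isfinite(flat)
        adj = flat.copy()
        if ok.any():
            adj[ok] = multipletests(flat[ok], method=method)[1]
        p[iu] = adj
        p.T[iu] = adj
    with np.errstate(invalid="ignore"):
        adjacency = (p < alpha).astype(int)
    np.fill_diagonal(adjacency, 0)
    return TraitNetwork(adjacency, list(cr.trait_names), alpha, cr.group)


def networks_per_group(
    tm: TraitMatrix, alpha: float = 0.05, correction: str | None = None
) -> dict:
    """One trait network per water body."""
    return {
        g: build_network(pearson_with_pvalues(tm, g), alpha, correction)
        for g in tm.groups
    }


def edge_table(net: TraitNetwork, cr: CorrelationResult | None = None) -> pd.DataFrame:
    """Edge list as a tidy frame (trait_i, trait_j[, r, p])."""
    rows = []
    for i, j in net.edge_list():
        row = {"trait_i": net.trait_names[i], "trait_j": net.trait_names[j]}
        if cr is not None:
            row["r"] = cr.r[i, j]
            row["p"] = cr.p[i, j]
        rows.append(row)
    cols = ["trait_i", "trait_j"] + (["r", "p"] if cr is not None else [])
    return pd.DataFrame(rows, columns=cols)


def write_network(
    net: TraitNetwork,
    out_dir: str | Path,
    stem: str,
    cr: CorrelationResult | None = None,
) -> None:
    """Write edge-list CSV, GraphML, and the adjacency matrix CSV."""
    import networkx as nx

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edge_table(net, cr).to_csv(out_dir / f"{stem}_edges.csv", index=False)
    pd.DataFrame(
        net.adjacency, index=net.trait_names, columns=net.trait_names
    ).to_csv(out_dir / f"{stem}_adjacency.csv")
    g = nx.Graph()
    g.add_nodes_from(net.trait_names)
    g.add_edges_from(
        (net.trait_names[i], net.trait_names[j]) for i, j in net.edge_list()
    )
    nx.write_graphml(g, out_dir / f"{stem}.graphml")
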