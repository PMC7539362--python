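"""Phylogeny-aware statistics for tip traits.

Species are not independent samples: trait covariance is structured by
shared evolutionary history. Under Brownian motion (BM) the expected
covariance of two tips is proportional to the shared path length from
the root to their most recent common ancestor, collected in the tree
covariance matrix C. This module provides

* simulation-based phylogenetic ANOVA: the observed F statistic is
  compared to a null distribution of F values from BM trait simulation
  on the tree (groups held fixed), with pairwise post-hoc t statistics
  judged against their own simulated nulls and Holm-adjusted; and
* phylogenetic generalised least squares (PGLS) with Pagel's λ scaling
  the off-diagonal covariances, λ estimated by maximum likelihood.

Trees are handled through dendropy; only rooted trees with branch
lengths are meaningful here (ultrametricity is not required).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PhyloError",
    "read_newick",
    "write_newick",
    "tip_labels",
    "phylo_vcv",
    "bm_simulate",
    "PhylANOVAResult",
    "phyl_anova",
    "PGLSResult",
    "pgls_fit",
]


class PhyloError(ValueError):
    """Raised for malformed trees or invalid comparative analyses."""


# ---------------------------------------------------------------------------
# trees


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse a rooted Newick tree (file path or literal string).

    Tip labels must be unique: the covariance construction indexes by
    label, so duplicates would silently alias tips.
    """
    if str(source).lstrip().startswith("("):
        text = str(source)
    else:
        p = Path(str(source))
        if not p.exists():
            raise PhyloError(f"no such tree file: {source}")
        text = p.read_text(encoding="utf-8")
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise PhyloError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dup = {l for l in labels if labels.count(l) > 1}
    if dup:
        raise PhyloError(f"duplicate tip labels: {sorted(dup)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise PhyloError("negative branch length")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True), encoding="utf-8"
    )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def phylo_vcv(tree: dendropy.Tree, order: list[str] | None = None) -> pd.DataFrame:
    """Brownian-motion covariance matrix of the tree's tips.

    C[i, j] is the root-to-MRCA path length shared by tips i and j;
    the diagonal holds each tip's root-to-tip depth. Multifurcations
    and zero-length branches are handled naturally.
    """
    # root distance per node (edge lengths default to 0 when missing)
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        el = node.edge.length or 0.0
        depth[id(node)] = el + (depth[id(parent)] if parent is not None else 0.0)

    labels = tip_labels(tree)
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._tipset = [index[node.taxon.label]]
            C[node._tipset[0], node._tipset[0]] = depth[id(node)]
            continue
        children = node.child_nodes()
        sets = [c._tipset for c in children]
        d = depth[id(node)]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                for i in sets[a]:
                    C[i, sets[b]] = d
                    C[sets[b], i] = d
        node._tipset = [i for s in sets for i in s]
    df = pd.DataFrame(C, index=labels, columns=labels)
    if order is not None:
        missing = set(order) - set(labels)
        if missing:
            raise PhyloError(f"tips absent from tree: {sorted(missing)}")
        df = df.loc[order, order]
    return df


def bm_simulate(
    tree: dendropy.Tree | pd.DataFrame,
    sigma2: float = 1.0,
    n_sims: int = 1,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate BM tip values: draws from N(0, sigma2 * C), one row per replicate."""
    if sigma2 <= 0:
        raise PhyloError("sigma2 must be positive")
    C = tree if isinstance(tree, pd.DataFrame) else phylo_vcv(tree)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = _safe_cholesky(C.to_numpy())
    z = rng.standard_normal((n_sims, C.shape[0]))
    sims = np.sqrt(sigma2) * (z @ L.T)
    return pd.DataFrame(sims, columns=C.columns)


def _safe_cholesky(C: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        # zero-length terminal branches give a PSD (not PD) matrix
        w, V = np.linalg.eigh(C)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise PhyloError("tree covariance is not positive semidefinite")
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


# ---------------------------------------------------------------------------
# phylogenetic ANOVA


@dataclass
class PhylANOVAResult:
    F_obs: float
    p_phyl: float
    n_sims: int
    sigma2_hat: float
    group_means: pd.Series
    posthoc_t: pd.DataFrame | None
    posthoc_p: pd.DataFrame | None


def _anova_F(Y: np.ndarray, G: np.ndarray, n_per: np.ndarray) -> np.ndarray:
    """One-way ANOVA F for each row of Y given one-hot group matrix G."""
    n = Y.shape[1]
    g = G.shape[1]
    sums = Y @ G
    means = sums / n_per
    grand = Y.mean(axis=1, keepdims=True)
    ssb = ((means - grand) ** 2 * n_per).sum(axis=1)
    sst = ((Y - grand) ** 2).sum(axis=1)
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (g - 1)) / (ssw / (n - g))
    return np.where(sst <= 0, 0.0, F)


def _pairwise_t(Y: np.ndarray, G: np.ndarray, n_per: np.ndarray) -> np.ndarray:
    """Pairwise t statistics (pooled MSE) for each row of Y; shape (m, g, g)."""
    n = Y.shape[1]
    g = G.shape[1]
    means = (Y @ G) / n_per
    grand = Y.mean(axis=1, keepdims=True)
    ssb = ((means - grand) ** 2 * n_per).sum(axis=1)
    ssw = ((Y - grand) ** 2).sum(axis=1) - ssb
    mse = ssw / (n - g)
    t = np.zeros((Y.shape[0], g, g))
    for a in range(g):
        for b in range(a + 1, g):
            se = np.sqrt(mse * (1.0 / n_per[0, a] + 1.0 / n_per[0, b]))
            with np.errstate(divide="ignore", invalid="ignore"):
                tt = np.where(se > 0, (means[:, a] - means[:, b]) / np.where(se > 0, se, 1.0), 0.0)
            t[:, a, b] = tt
            t[:, b, a] = -tt
    return t


def phylogenetic_mean_and_rate(y: np.ndarray, C: np.ndarray) -> tuple[float, float]:
    """GLS phylogenetic mean and the ML Brownian rate estimate.

    mu_hat = (1' C^-1 1)^-1 1' C^-1 y ; sigma2_hat = r' C^-1 r / n with
    r = y - mu_hat.
    """
    n = y.size
    one = np.ones(n)
    Ci_one = np.linalg.solve(C, one)
    Ci_y = np.linalg.solve(C, y)
    mu = float(one @ Ci_y / (one @ Ci_one))
    r = y - mu
    sigma2 = float(r @ np.linalg.solve(C, r) / n)
    return mu, sigma2


def phyl_anova(
    tree: dendropy.Tree | pd.DataFrame,
    traits: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    n_sims: int = 1000,
    posthoc: str | None = "holm",
    seed: int | np.random.Generator | None = None,
) -> PhylANOVAResult:
    """Simulation-based phylogenetic ANOVA.

    The observed one-way ANOVA F statistic on tip values is referred to
    a null distribution obtained by simulating BM traits on the tree
    (rate estimated from the data by the phylogenetic ML estimator,
    group membership held fixed): p = (1 + #{F_sim >= F_obs}) /
    (n_sims + 1), which cannot be exactly zero. Pairwise post-hoc t
    statistics are compared to their own simulated nulls (two-sided)
    and Holm-adjusted.

    ``traits`` is indexed by tip label with a value and a group column.
    """
    C = tree if isinstance(tree, pd.DataFrame) else phylo_vcv(tree)
    tips = list(traits.index)
    C = C.loc[tips, tips]
    y = traits[value_col].to_numpy(float)
    if np.any(~np.isfinite(y)):
        raise PhyloError("missing or non-finite trait values")
    groups = traits[group_col].astype(str)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise PhyloError("phylogenetic ANOVA needs at least two groups")
    counts = groups.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise PhyloError(f"groups with fewer than two tips: {list(small.index)}")

    G = np.stack([(groups == lv).to_numpy(float) for lv in levels], axis=1)
    n_per = G.sum(axis=0, keepdims=True)

    F_obs = float(_anova_F(y[None, :], G, n_per)[0])
    t_obs = _pairwise_t(y[None, :], G, n_per)[0]

    mu, sigma2 = phylogenetic_mean_and_rate(y, C.to_numpy())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sims = bm_simulate(C, sigma2=max(sigma2, 1e-12), n_sims=n_sims, seed=rng).to_numpy()
    F_sim = _anova_F(sims, G, n_per)
    p_phyl = (1.0 + float(np.sum(F_sim >= F_obs))) / (n_sims + 1.0)

    posthoc_t = posthoc_p = None
    if posthoc is not None:
        t_sim = _pairwise_t(sims, G, n_per)
        g = len(levels)
        raw = []
        pairs = [(a, b) for a in range(g) for b in range(a + 1, g)]
        for a, b in pairs:
            exceed = np.sum(np.abs(t_sim[:, a, b]) >= abs(t_obs[a, b]))
            raw.append((1.0 + float(exceed)) / (n_sims + 1.0))
        adj = multipletests(raw, method=posthoc)[1] if raw else []
        posthoc_t = pd.DataFrame(0.0, index=levels, columns=levels)
        posthoc_p = pd.DataFrame(1.0, index=levels, columns=levels)
        for (a, b), padj in zip(pairs, adj):
            posthoc_t.iloc[a, b] = t_obs[a, b]
            posthoc_t.iloc[b, a] = -t_obs[a, b]
            posthoc_p.iloc[a, b] = posthoc_p.iloc[b, a] = padj

    means = pd.Series(
        {lv: y[(groups == lv).to_numpy()].mean() for lv in levels}, name="mean"
    )
    return PhylANOVAResult(
        F_obs=F_obs,
        p_phyl=p_phyl,
        n_sims=n_sims,
        sigma2_hat=sigma2,
        group_means=means,
        posthoc_t=posthoc_t,
        posthoc_p=posthoc_p,
    )


# ---------------------------------------------------------------------------
# PGLS with Pagel's lambda


@dataclass
class PGLSResult:
    beta: np.ndarray
    se: np.ndarray
    lambda_hat: float
    R2: float
    p_slope: float
    loglik: float
    df_resid: int
    sigma2: float


def _lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _gls_profile(y: np.ndarray, X: np.ndarray, V: np.ndarray, reml: bool):
    """GLS fit with fixed covariance; returns (beta, RSS, loglik, Li)."""
    n, p = X.shape
    L = np.linalg.cholesky(V)
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    if reml:
        sigma2 = rss / (n - p)
        _, logdetXX = np.linalg.slogdet(Xw.T @ Xw)
        ll = -0.5 * (
            (n - p) * np.log(2.0 * np.pi * sigma2)
            + logdetV
            + logdetXX
            + (n - p)
        )
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdetV + n)
    return beta, rss, sigma2, ll, (L, Xw, yw)


def pgls_fit(
    tree: dendropy.Tree | pd.DataFrame,
    y: pd.Series,
    X: pd.DataFrame | None = None,
    lam: float | str = "ML",
    reml: bool = False,
) -> PGLSResult:
    """Phylogenetic GLS regression with Pagel's λ correlation scaling.

    V(λ) multiplies the off-diagonal elements of the tree covariance C
    by λ ∈ [0, 1]; λ = 0 gives ordinary least squares, λ = 1 the full
    BM covariance. With ``lam="ML"`` λ is chosen to maximise the
    (profile) log-likelihood by bounded scalar optimisation (tolerance
    1e-6); a float fixes it. ``X`` gains an intercept column if it
    lacks a constant; ``X=None`` fits the intercept-only model. R² is
    computed in the whitened space (1 - RSS/TSS around the GLS mean)
    and ``p_slope`` is the two-sided t-test on the last non-intercept
    coefficient.
    """
    C = tree if isinstance(tree, pd.DataFrame) else phylo_vcv(tree)
    tips = list(y.index)
    C = C.loc[tips, tips].to_numpy()
    yv = y.to_numpy(float)
    n = yv.size
    if X is None:
        Xm = np.ones((n, 1))
        names = ["intercept"]
    else:
        X = X.loc[tips]
        Xm = X.to_numpy(float)
        names = list(X.columns)
        if not np.any(np.all(Xm == Xm[0, :], axis=0) & (Xm[0, :] != 0)):
            Xm = np.column_stack([np.ones(n), Xm])
            names = ["intercept"] + names

    def negll(l: float) -> float:
        V = _lambda_transform(C, l)
        try:
            return -_gls_profile(yv, Xm, V, reml)[3]
        except np.linalg.LinAlgError:
            return np.inf

    if lam == "ML":
        res = minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-6})
        lam_hat = float(res.x)
        # the profile can be maximised at a boundary the bounded search
        # approaches only to tolerance; snap if the boundary is better
        for edge in (0.0, 1.0):
            if negll(edge) <= res.fun:
                lam_hat = edge
                res.fun = negll(edge)
    else:
        lam_hat = float(lam)
        if not 0.0 <= lam_hat <= 1.0:
            raise PhyloError("lambda must lie in [0, 1]")

    V = _lambda_transform(C, lam_hat)
    try:
        beta, rss, sigma2, ll, (L, Xw, yw) = _gls_profile(yv, Xm, V, reml)
    except np.linalg.LinAlgError as exc:
        raise PhyloError(
            "singular phylogenetic covariance; reduce lambda or repair the tree"
        ) from exc

    p = Xm.shape[1]
    df_resid = n - p
    s2_resid = rss / df_resid if df_resid > 0 else np.nan
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.clip(np.diag(XtX_inv) * s2_resid, 0.0, None))

    # TSS about the GLS intercept-only fit, in the whitened space
    onew = solve_triangular(L, np.ones((n, 1)), lower=True)
    mu = float(np.linalg.lstsq(onew, yw, rcond=None)[0][0])
    tss = float(((yw - onew[:, 0] * mu) ** 2).sum())
    R2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss < 1e-12 else 0.0)

    if p > 1 and df_resid > 0 and se[-1] > 0:
        t_stat = beta[-1] / se[-1]
        p_slope = 2.0 * stats.t.sf(abs(t_stat), df_resid)
    elif p > 1 and rss < 1e-12:
        p_slope = 0.0
    else:
        p_slope = np.nan

    return PGLSResult(
        beta=np.asarray(beta),
        se=se,
        lambda_hat=lam_hat,
        R2=float(np.clip(R2, 0.0, 1.0)),
        p_slope=float(p_slope),
        loglik=float(ll),
        df_resid=df_resid,
        sigma2=float(sigma2),
    )
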