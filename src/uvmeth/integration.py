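"""Multi-OMICs integration: eQTM, driver scores, PLS-DA, clustering.

Couples the methylome to the transcriptome (Pearson eQTM correlations),
summarizes per-gene alteration load across copy number, mutation, expression
and methylation into a driver score in [0, 4], and discriminates UV-mutant
from non UV-mutant tumors with (sparse) PLS-DA after MAD-based feature
filtering. A simplified multi-block integration concatenates per-block sparse
selections. Hierarchical clustering supports cluster-enrichment analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# eQTM


def eqtm_correlate(
    beta: pd.DataFrame,
    expression: pd.DataFrame,
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Pearson correlation of CpG methylation with gene expression per pair.

    For each (cpg, gene) pair the correlation is computed over the shared
    samples, with a two-sided p-value from the t reference on n-2 df and BH
    adjustment across pairs. Zero-variance vectors yield a flagged NA row.
    """
    samples = beta.columns.intersection(expression.columns)
    if len(samples) < 3:
        raise ValueError("need at least 3 shared samples")
    rows = []
    for cpg, gene in pairs:
        x = beta.loc[cpg, samples].to_numpy(dtype=float)
        y = expression.loc[gene, samples].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            rows.append({"cpg": cpg, "gene": gene, "r": np.nan, "p": np.nan,
                         "n": len(samples), "flagged": True})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"cpg": cpg, "gene": gene, "r": float(r), "p": float(p),
                     "n": len(samples), "flagged": False})
    out = pd.DataFrame(rows)
    ok = ~out["flagged"]
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Driver score


def driver_scores(
    cnv: pd.DataFrame,
    mutations: pd.DataFrame,
    expression: pd.DataFrame,
    beta: pd.DataFrame,
    cpg_to_gene: pd.DataFrame,
    groups: pd.Series,
    genes: list[str],
    logfc_threshold: float = 2.0,
    delta_beta_threshold: float = 0.1,
) -> pd.DataFrame:
    """Multi-OMICs driver score per gene: CNV + MUT + EXP + METH, each in [0,1].

    Per-layer event counts over the analysed gene set, each normalized by the
    layer's maximum count:

    - CNV: samples with a deep amplification (>= +2) or deep deletion (<= -2);
    - MUT: samples carrying at least one mutation in the gene;
    - EXP: UV-mutant samples whose log2 expression deviates from the non-UV
      group mean by more than ``logfc_threshold`` in absolute value;
    - METH: UV-mutant samples whose gene-averaged beta deviates from the
      non-UV group mean by more than ``delta_beta_threshold``.

    The total driver score is the sum of the four normalized layers. A gene
    absent from a layer contributes 0 there.
    """
    if not genes:
        raise ValueError("empty gene set")
    uv = groups[groups.astype(str) == "uv"].index
    non = groups[groups.astype(str) == "nonuv"].index
    if len(uv) == 0 or len(non) == 0:
        raise ValueError("both UV groups required for EXP/METH scores")

    gene_beta = _gene_level_beta(beta, cpg_to_gene)
    counts = {layer: pd.Series(0.0, index=genes) for layer in ("cnv", "mut", "exp", "meth")}
    for g in genes:
        if g in cnv.index:
            counts["cnv"][g] = int((cnv.loc[g].abs() >= 2).sum())
        if g in mutations.index:
            counts["mut"][g] = int((mutations.loc[g] > 0).sum())
        if g in expression.index:
            ref = expression.loc[g, expression.columns.intersection(non)].mean()
            dev = (expression.loc[g, expression.columns.intersection(uv)] - ref).abs()
            counts["exp"][g] = int((dev > logfc_threshold).sum())
        if g in gene_beta.index:
            ref = gene_beta.loc[g, gene_beta.columns.intersection(non)].mean()
            dev = (gene_beta.loc[g, gene_beta.columns.intersection(uv)] - ref).abs()
            counts["meth"][g] = int((dev > delta_beta_threshold).sum())

    out = pd.DataFrame(index=pd.Index(sorted(genes), name="gene"))
    for layer, c in counts.items():
        mx = c.max()
        out[f"{layer}_score"] = (c / mx if mx > 0 else c * 0.0).reindex(out.index)
    out["total"] = out[[f"{l}_score" for l in ("cnv", "mut", "exp", "meth")]].sum(axis=1)
    return out.sort_values("total", ascending=False)


def _gene_level_beta(beta: pd.DataFrame, cpg_to_gene: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean beta over each gene's CpGs (cpg -> gene map)."""
    mapping = cpg_to_gene.set_index("cpg")["gene"]
    common = beta.index.intersection(mapping.index)
    if len(common) == 0:
        return pd.DataFrame(columns=beta.columns)
    return beta.loc[common].groupby(mapping.loc[common]).mean()


# ---------------------------------------------------------------------------
# MAD filter and PLS-DA


def mad_filter(matrix: pd.DataFrame, k: int = 100) -> pd.DataFrame:
    """Keep the k rows with the largest (unscaled) median absolute deviation.

    Ties are broken by lexicographic row id, so the selection is
    deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds {len(matrix)} rows")
    x = matrix.to_numpy(dtype=float)
    mad = np.median(np.abs(x - np.median(x, axis=1, keepdims=True)), axis=1)
    order = pd.DataFrame({"mad": mad, "id": matrix.index.astype(str)}).sort_values(
        ["mad", "id"], ascending=[False, True], kind="mergesort"
    )
    return matrix.loc[matrix.index[order.index[:k]]]


@dataclass
class PlsdaModel:
    """Fitted (sparse) PLS-DA: weights, loadings, scores and centroids."""

    n_components: int
    feature_ids: list[str]
    sample_ids: list[str]
    classes: list[str]
    weights: np.ndarray  # features x components (x-weights, unit norm)
    loadings: np.ndarray  # features x components (x-loadings)
    scores: np.ndarray  # samples x components
    y_loadings: np.ndarray  # classes x components
    centroids: np.ndarray  # classes x components
    x_mean: np.ndarray = field(repr=False, default=None)
    x_scale: np.ndarray = field(repr=False, default=None)

    @property
    def selected_features(self) -> list[list[str]]:
        """Feature ids with non-zero weight, per component."""
        return [
            [self.feature_ids[i] for i in np.flatnonzero(self.weights[:, c])]
            for c in range(self.n_components)
        ]

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Project new samples (features x samples) into the score space."""
        Z = ((X.loc[self.feature_ids].to_numpy(dtype=float).T - self.x_mean)
             / self.x_scale)
        rotation = self.weights @ np.linalg.pinv(self.loadings.T @ self.weights)
        return Z @ rotation

    def predict(self, X: pd.DataFrame) -> list[str]:
        """Nearest class centroid (Euclidean) in latent space."""
        scores = self.transform(X)
        d = ((scores[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return [self.classes[i] for i in d.argmin(axis=1)]

    def accuracy(self, X: pd.DataFrame, labels: pd.Series) -> float:
        pred = self.predict(X)
        return float(np.mean([p == t for p, t in zip(pred, labels.astype(str))]))


def _one_hot(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    classes = sorted(labels.astype(str).unique())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    Y = np.array([[1.0 if l == c else 0.0 for c in classes] for l in labels.astype(str)])
    return Y, classes


def plsda_fit(
    X: pd.DataFrame,
    labels: pd.Series,
    n_components: int = 2,
    keep: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> PlsdaModel:
    """NIPALS PLS-DA of a features x samples matrix against one-hot labels.

    Features are mean-centered and unit-variance scaled internally; class
    membership is regressed as a centered one-hot matrix with X-deflation, so
    successive score vectors are mutually orthogonal. With ``keep`` set, each
    component's weight vector is soft-thresholded so exactly ``keep`` features
    stay non-zero (largest magnitudes retained) before renormalization — the
    standard sparse-PLS realization of a LASSO constraint.
    """
    Z = X.to_numpy(dtype=float).T  # samples x features
    labels = labels.reindex(X.columns) if labels.index.isin(X.columns).all() else labels
    Y, classes = _one_hot(labels)
    n, m = Z.shape
    mean, sd = Z.mean(axis=0), Z.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (Z - mean) / sd
    Yc = Y - Y.mean(axis=0)

    W = np.zeros((m, n_components))
    P = np.zeros((m, n_components))
    Q = np.zeros((Y.shape[1], n_components))
    T = np.zeros((n, n_components))
    for comp in range(n_components):
        u = Yc[:, np.argmax(Yc.var(axis=0))].copy()
        w = np.zeros(m)
        for _ in range(max_iter):
            w_new = Z.T @ u
            norm = np.linalg.norm(w_new)
            if norm == 0:
                break
            w_new /= norm
            t = Z @ w_new
            q = Yc.T @ t / (t @ t)
            u_new = Yc @ q / (q @ q) if (q @ q) > 0 else u
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w, u = w_new, u_new
        if keep is not None and keep < m:
            lam = np.sort(np.abs(w))[::-1][keep]  # (keep+1)-th largest magnitude
            w = np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)
            norm = np.linalg.norm(w)
            if norm > 0:
                w /= norm
        t = Z @ w
        denom = t @ t
        if denom == 0:
            raise ValueError("degenerate component: zero scores")
        p = Z.T @ t / denom
        q = Yc.T @ t / denom
        Z = Z - np.outer(t, p)
        Yc = Yc - np.outer(t, q)
        W[:, comp], P[:, comp], Q[:, comp], T[:, comp] = w, p, q, t

    centroids = np.array(
        [T[labels.astype(str).to_numpy() == c].mean(axis=0) for c in classes]
    )
    return PlsdaModel(
        n_components=n_components,
        feature_ids=list(X.index.astype(str)),
        sample_ids=list(X.columns.astype(str)),
        classes=classes,
        weights=W,
        loadings=P,
        scores=T,
        y_loadings=Q,
        centroids=centroids,
        x_mean=mean,
        x_scale=sd,
    )


def splsda_select(
    X: pd.DataFrame, labels: pd.Series, keep: int = 25, n_components: int = 2
) -> PlsdaModel:
    """Sparse PLS-DA keeping exactly ``keep`` features per component."""
    if keep <= 0:
        raise ValueError("keep must be positive")
    if keep > len(X):
        raise ValueError(f"keep={keep} exceeds {len(X)} features")
    return plsda_fit(X, labels, n_components=n_components, keep=keep)


def integrate_blocks(
    blocks: list[tuple[str, pd.DataFrame]],
    labels: pd.Series,
    keep: int = 25,
    n_components: int = 2,
) -> tuple[PlsdaModel, dict[str, list[list[str]]]]:
    """Simplified multi-block integration.

    Runs sparse PLS-DA per block, concatenates the union of each block's
    selected features (standardized within the final fit) and fits a plain
    PLS-DA on the concatenation. Returns the integrated model and the
    per-block selections. This is a deliberately simple, deterministic
    stand-in for full multi-block covariance optimization.
    """
    samples = None
    for name, mat in blocks:
        samples = mat.columns if samples is None else samples
        if not mat.columns.equals(samples):
            raise ValueError(f"block {name!r} sample mismatch")
    selections: dict[str, list[list[str]]] = {}
    parts = []
    for name, mat in blocks:
        model = splsda_select(mat, labels, keep=min(keep, len(mat)), n_components=n_components)
        selections[name] = model.selected_features
        union = sorted({f for comp in model.selected_features for f in comp})
        part = mat.loc[union].copy()
        part.index = [f"{name}:{f}" for f in part.index]
        parts.append(part)
    stacked = pd.concat(parts, axis=0)
    model = plsda_fit(stacked, labels, n_components=n_components)
    return model, selections


def cv_accuracy(
    X: pd.DataFrame,
    labels: pd.Series,
    n_components: int = 2,
    keep: int | None = None,
) -> float:
    """Leave-one-out cross-validated PLS-DA classification accuracy.

    Training accuracy of a many-feature PLS-DA overfits far above chance;
    LOO accuracy is the honest measure of discriminative signal and sits at
    ~0.5 under permuted two-class labels.
    """
    correct = 0
    for s in X.columns:
        model = plsda_fit(
            X.drop(columns=s), labels.drop(s), n_components=n_components, keep=keep
        )
        correct += model.predict(X[[s]])[0] == str(labels[s])
    return correct / X.shape[1]


# ---------------------------------------------------------------------------
# Hierarchical clustering


def hier_cluster(
    matrix: pd.DataFrame,
    n_clusters: int,
    method: str = "complete",
) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering of samples (columns) on Euclidean distance.

    Samples are ordered by id before linkage so ties resolve
    deterministically. Returns (cluster labels per sample, scipy linkage
    matrix).
    """
    if matrix.shape[1] < 2:
        if n_clusters != 1:
            raise ValueError("single sample admits only one cluster")
        return pd.Series([1], index=matrix.columns), np.empty((0, 4))
    if n_clusters > matrix.shape[1]:
        raise ValueError("more clusters than samples")
    ordered = matrix[sorted(matrix.columns.astype(str))]
    Z = linkage(ordered.to_numpy(dtype=float).T, method=method, metric="euclidean")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=ordered.columns).reindex(matrix.columns), Z
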