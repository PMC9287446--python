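"""Differential DNA-methylome analysis: DMPs, DMRs and prioritization.

Beta values (methylation fractions) are logit2-transformed to M-values and
tested probe-by-probe with a Huber robust linear regression of M on group
membership plus optional covariates (the crude model is the default).
Per-CpG results (DMPs) are aggregated into differentially methylated regions
(DMRs) by chaining FDR-significant probes within a ±1000 bp proximity window
and combining their z-statistics with a correlation-corrected Stouffer sum.
A prioritization cascade then keeps regions with >= 3 CpGs, direction-
consistent member effects, |mean delta-beta| >= 0.10 and no SNP enrichment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

BETA_CLIP = 1e-6
CHI2_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549364...

REGULATORY_CLASSES = ("promoter", "5utr", "exon_intron_boundary", "1to5kb", "other")
DENSITY_CLASSES = ("island", "shore", "shelf", "open_sea")

ANNOTATION_COLUMNS = [
    "probe",
    "chrom",
    "pos",
    "gene",
    "regulatory_class",
    "density_class",
    "snp_flag",
    "cross_reactive_flag",
    "sex_chrom_flag",
]


def mvalue_transform(beta: pd.DataFrame | np.ndarray):
    """M = log2(beta / (1 - beta)), after clipping beta into (0, 1)."""
    b = np.clip(np.asarray(beta, dtype=float), BETA_CLIP, 1 - BETA_CLIP)
    m = np.log2(b / (1 - b))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    return m


def beta_from_m(m: pd.DataFrame | np.ndarray):
    """Inverse of :func:`mvalue_transform`: beta = 2^M / (1 + 2^M)."""
    x = np.asarray(m, dtype=float)
    b = 1.0 / (1.0 + np.exp2(-x))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    return b


def filter_probes(beta: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Drop cross-reactive and sex-chromosome probes.

    Every probe in the matrix must be annotated; returns the retained matrix
    and logs retention counts.
    """
    ann = annotation.set_index("probe")
    missing = beta.index.difference(ann.index)
    if len(missing):
        raise ValueError(f"{len(missing)} probes lack annotation, e.g. {missing[0]!r}")
    ann = ann.loc[beta.index]
    keep = ~(ann["cross_reactive_flag"].astype(bool) | ann["sex_chrom_flag"].astype(bool))
    out = beta.loc[keep[keep].index]
    if out.empty:
        logger.warning("all %d probes were flagged; empty matrix returned", len(beta))
    logger.info("filter_probes: retained %d / %d probes", len(out), len(beta))
    return out


# ---------------------------------------------------------------------------
# Per-CpG models


def _huber_irls(
    X: np.ndarray,
    Y: np.ndarray,
    c: float = 1.345,
    max_iter: int = 50,
    tol: float = 1e-8,
):
    """Vectorized Huber IRLS of many responses on one shared design.

    X is n x p, Y is n x m (one column per probe). Scale is re-estimated each
    iteration as MAD(residuals)/0.6745. Returns (beta p x m, se p x m,
    df_resid). Standard errors use the Huber sandwich with the standard
    small-sample correction; when no observation is downweighted the result
    coincides with OLS.
    """
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)

    def _scale(E):
        return np.maximum(
            np.median(np.abs(E - np.median(E, axis=0)), axis=0) / 0.6745, 1e-10
        )

    for _ in range(max_iter):
        E = Y - X @ beta
        U = E / _scale(E)
        W = np.where(np.abs(U) <= c, 1.0, c / np.abs(U))
        A = np.einsum("ni,nm,nj->mij", X, W, X)
        b = np.einsum("ni,nm,nm->mi", X, W, Y)
        new = np.linalg.solve(A, b[..., None])[..., 0].T
        if np.max(np.abs(new - beta)) < tol * (1 + np.max(np.abs(beta))):
            beta = new
            break
        beta = new

    E = Y - X @ beta
    s = _scale(E)
    U = E / s
    psi = np.clip(U, -c, c)
    dpsi = (np.abs(U) <= c).astype(float)
    m1 = dpsi.mean(axis=0)
    k = 1 + (p / n) * dpsi.var(axis=0) / m1**2
    sigma2 = (s**2 * (psi**2).sum(axis=0)) / (n - p)
    xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))
    se = np.sqrt(np.outer(xtx_inv_diag, k**2 * sigma2 / m1**2))
    return beta, se, n - p


def _ols(X: np.ndarray, Y: np.ndarray):
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    E = Y - X @ beta
    sigma2 = (E**2).sum(axis=0) / (n - p)
    se = np.sqrt(np.outer(np.diag(np.linalg.inv(X.T @ X)), sigma2))
    return beta, se, n - p


def build_design(
    groups: pd.Series, covariates: pd.DataFrame | None = None
) -> tuple[np.ndarray, list[str]]:
    """Intercept + UV indicator (+ numeric/encoded covariate columns)."""
    g = (groups.astype(str) == "uv").astype(float).to_numpy()
    cols = [np.ones(len(g)), g]
    names = ["intercept", "uv"]
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype == object or str(col.dtype) == "category":
                col = pd.factorize(col)[0].astype(float)
            cols.append(np.asarray(col, dtype=float))
            names.append(name)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    return X, names


def fit_dmp(
    mvalues: pd.DataFrame,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
    beta: pd.DataFrame | None = None,
    method: str = "huber",
) -> pd.DataFrame:
    """Per-probe differential-methylation model (the DMP analysis).

    Fits M ~ group (+ covariates) per probe, robust (Huber) by default with
    OLS as an option; two-sided p-values from the t reference on residual df,
    BH-adjusted across probes. ``delta_beta`` is the difference of group mean
    beta values (UV minus non-UV); when the beta matrix is not supplied it is
    recovered from the M-values.

    Constant (zero-variance) probes are returned flagged with p = 1.
    """
    if not groups.index.equals(pd.Index(mvalues.columns)):
        groups = groups.reindex(mvalues.columns)
    counts = groups.astype(str).value_counts()
    if counts.get("uv", 0) < 2 or counts.get("nonuv", 0) < 2:
        raise ValueError("need at least 2 samples per group")
    X, _ = build_design(groups, covariates)
    Y = mvalues.to_numpy(dtype=float).T  # samples x probes

    constant = Y.std(axis=0) < 1e-12
    fit = _huber_irls if method == "huber" else _ols
    if method not in ("huber", "ols"):
        raise ValueError(f"unknown method {method!r}")
    coef, se, df = fit(X, Y)

    b1, se1 = coef[1].copy(), se[1].copy()
    tstat = np.divide(b1, se1, out=np.zeros_like(b1), where=se1 > 0)
    pvals = 2 * stats.t.sf(np.abs(tstat), df)
    b1[constant] = 0.0
    tstat[constant] = 0.0
    pvals[constant] = 1.0
    qvals = multipletests(pvals, method="fdr_bh")[1]

    if beta is None:
        beta = beta_from_m(mvalues)
    uv_cols = groups[groups.astype(str) == "uv"].index
    non_cols = groups[groups.astype(str) == "nonuv"].index
    delta_beta = (
        beta[uv_cols].mean(axis=1) - beta[non_cols].mean(axis=1)
    ).to_numpy()

    return pd.DataFrame(
        {
            "probe": mvalues.index,
            "coef": b1,
            "se": se1,
            "stat": tstat,
            "p": pvals,
            "q": qvals,
            "delta_beta": delta_beta,
            "flagged": constant,
        }
    ).set_index("probe")


def genomic_inflation_lambda(pvalues) -> float:
    """Median-based genomic inflation factor of a p-value vector.

    lambda = median(qchisq(1 - p, 1)) / qchisq(0.5, 1); 1.0 means no
    inflation.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("empty p-value vector")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / CHI2_MEDIAN)


# ---------------------------------------------------------------------------
# Regions


def call_dmrs(
    dmps: pd.DataFrame,
    annotation: pd.DataFrame,
    mvalues: pd.DataFrame | None = None,
    max_gap: int = 1000,
    min_cpgs: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Chain FDR-significant probes into proximity-based regions.

    Per chromosome, probes with per-CpG FDR < ``alpha`` are chained while
    consecutive inter-probe gaps are <= ``max_gap`` bp; chains with at least
    ``min_cpgs`` members become candidate regions. The region statistic is a
    Stouffer sum of member z-scores with a Brown-style correction for the
    mean pairwise M-value correlation r̄ (clipped to [0, 1)):

        Z_region = sum(z_i) / sqrt(n + n(n-1) * r̄)

    with a two-sided normal p-value and BH adjustment across regions. The
    reported pooled coefficient and SE reuse the same correction so regions
    can be meta-analysed downstream.
    """
    ann = annotation.set_index("probe")
    d = dmps.join(ann[["chrom", "pos", "snp_flag"]], how="inner")
    sig = d[d["q"] < alpha]
    rows = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        if not grp["pos"].is_monotonic_increasing:  # pragma: no cover
            logger.info("positions on %s sorted internally", chrom)
        pos = grp["pos"].to_numpy()
        breaks = np.where(np.diff(pos) > max_gap)[0]
        start_idx = np.r_[0, breaks + 1]
        end_idx = np.r_[breaks, len(pos) - 1]
        for s, e in zip(start_idx, end_idx):
            members = grp.iloc[s : e + 1]
            n = len(members)
            if n < min_cpgs:
                continue
            z = np.sign(members["coef"].to_numpy()) * stats.norm.isf(
                np.clip(members["p"].to_numpy(), 1e-300, 1.0) / 2
            )
            rbar = 0.0
            if mvalues is not None and n > 1:
                sub = mvalues.loc[members.index].to_numpy(dtype=float)
                corr = np.corrcoef(sub)
                rbar = float(
                    np.clip(np.nanmean(corr[np.triu_indices(n, k=1)]), 0.0, 1 - 1e-9)
                )
            denom = np.sqrt(n + n * (n - 1) * rbar)
            z_region = float(z.sum() / denom)
            coef_sum = members["coef"].sum()
            se_sum = members["se"].sum()
            se_sq = (members["se"] ** 2).sum()
            # Var(mean coef) with equicorrelated members at r̄
            se_region = float(np.sqrt(se_sq + rbar * (se_sum**2 - se_sq)) / n)
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(members["pos"].min()),
                    "end": int(members["pos"].max()),
                    "n_cpgs": n,
                    "members": ",".join(members.index),
                    "z": z_region,
                    "p": float(2 * stats.norm.sf(abs(z_region))),
                    "coef": float(coef_sum / n),
                    "se": se_region,
                    "mean_delta_beta": float(members["delta_beta"].mean()),
                    "direction_consistent": bool(
                        (members["delta_beta"] > 0).all()
                        or (members["delta_beta"] < 0).all()
                    ),
                    "snp_fraction": float(members["snp_flag"].astype(bool).mean()),
                    "rbar": rbar,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "n_cpgs", "members", "z", "p", "coef",
            "se", "mean_delta_beta", "direction_consistent", "snp_fraction", "rbar",
        ],
    )
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def prioritize_dmrs(
    dmrs: pd.DataFrame,
    dmps: pd.DataFrame | None = None,
    min_cpgs: int = 3,
    min_abs_delta_beta: float = 0.10,
    snp_fraction_max: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Prioritization cascade over called regions.

    Keeps regions with at least ``min_cpgs`` CpGs, all member effects sharing
    one direction, |mean delta-beta| >= ``min_abs_delta_beta`` and a member
    SNP fraction below ``snp_fraction_max``. Returns the retained regions and
    per-filter attrition counts.
    """
    attrition = {"input": len(dmrs)}
    step = dmrs[dmrs["n_cpgs"] >= min_cpgs]
    attrition["min_cpgs"] = len(step)
    step = step[step["direction_consistent"]]
    attrition["direction_consistent"] = len(step)
    step = step[step["mean_delta_beta"].abs() >= min_abs_delta_beta]
    attrition["effect_size"] = len(step)
    step = step[step["snp_fraction"] < snp_fraction_max]
    attrition["snp_fraction"] = len(step)
    return step.reset_index(drop=True), attrition


def region_class_enrichment(
    selected_probes,
    annotation: pd.DataFrame,
    class_axis: str = "regulatory",
    direction: str | None = None,
    dmps: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-class 2x2 chi-square enrichment of selected probes vs the array.

    For every class on the chosen axis (regulatory or CpG density) a 2x2
    table of (selected vs not) x (in class vs not) is tested with an
    uncorrected chi-square. With ``direction`` set to ``hyper``/``hypo`` the
    selection is restricted by the sign of the probes' delta-beta (requires
    ``dmps``).
    """
    column = {"regulatory": "regulatory_class", "density": "density_class"}[class_axis]
    selected = pd.Index(selected_probes)
    if direction is not None:
        if dmps is None:
            raise ValueError("direction filtering requires dmp results")
        sign = dmps.loc[selected.intersection(dmps.index), "delta_beta"]
        selected = sign[sign > 0].index if direction == "hyper" else sign[sign < 0].index
    if len(selected) == 0:
        raise ValueError("empty probe selection")
    ann = annotation.set_index("probe")
    in_sel = ann.index.isin(selected)
    rows = []
    for cls in ann[column].unique():
        in_cls = (ann[column] == cls).to_numpy()
        a = int((in_sel & in_cls).sum())
        b = int((in_sel & ~in_cls).sum())
        c = int((~in_sel & in_cls).sum())
        d = int((~in_sel & ~in_cls).sum())
        table = np.array([[a, b], [c, d]])
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            chi2, p = np.nan, np.nan
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append({"class": cls, "n_selected": a, "odds_ratio": odds, "chi2": chi2, "p": p})
    return pd.DataFrame(rows).sort_values("class").reset_index(drop=True)
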