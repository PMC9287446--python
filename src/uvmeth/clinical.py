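"""Clinical statistics: contingency, survival, power, gene-set enrichment.

Thin, well-specified wrappers over scipy/lifelines plus a matched-resampling
gene-set enrichment that corrects for the probe-count-per-gene bias of
methylation arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Contingency


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction.

    Returns (statistic, df, upper-tail p). The table must have positive row
    and column margins.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (t < 0).any():
        raise ValueError("negative counts")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        raise ValueError("zero margin")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("Fisher test requires a 2x2 table")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U with exact small-sample p, asymptotic otherwise.

    Exact enumeration when n1 + n2 <= 16 and there are no ties; otherwise a
    normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    exact = len(pooled) <= 16 and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


def dichotomize_by_mean(values: pd.Series) -> pd.Series:
    """Label samples "low" (< mean) or "high" (>= mean)."""
    v = values.astype(float)
    if len(v) < 2:
        raise ValueError("need at least 2 samples")
    mean = v.mean()
    labels = pd.Series(np.where(v < mean, "low", "high"), index=v.index)
    if (labels == "high").all():
        logger.warning("constant values: every sample labelled 'high'")
    logger.info("dichotomize_by_mean: low=%d high=%d",
                (labels == "low").sum(), (labels == "high").sum())
    return labels


# ---------------------------------------------------------------------------
# Survival


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate with Greenwood variance.

    Ties are handled with events processed before censorings at equal times
    (the standard convention, as in lifelines). Returns a step table with
    columns ``time``, ``survival`` and ``variance``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    surv = kmf.survival_function_["KM_estimate"]
    # Greenwood variance: Var = S(t)^2 * sum d/(n(n-d))
    table = kmf.event_table
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = table["observed"] / (table["at_risk"] * (table["at_risk"] - table["observed"]))
    cum = terms.replace([np.inf, -np.inf], 0).fillna(0).cumsum()
    return pd.DataFrame(
        {"time": surv.index, "survival": surv.to_numpy(),
         "variance": (surv.to_numpy() ** 2) * cum.reindex(surv.index).to_numpy()}
    ).reset_index(drop=True)


def logrank_test(times, events, groups) -> tuple[float, int, float]:
    """Log-rank test across two or more groups.

    Returns (chi-square, df, p) with df = number of groups - 1.
    """
    groups = pd.Series(groups).astype(str)
    labels = groups.unique()
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    res = multivariate_logrank_test(np.asarray(times, dtype=float), groups.to_numpy(),
                                    np.asarray(events, dtype=int))
    return float(res.test_statistic), len(labels) - 1, float(res.p_value)


# ---------------------------------------------------------------------------
# Power


@dataclass(frozen=True)
class PowerSpec:
    n_per_group: int
    mean_difference: float  # beta-value units
    sd: float  # beta-value units
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_per_group <= 0 or self.sd <= 0:
            raise ValueError("n and sd must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def power_two_sample(spec: PowerSpec) -> float:
    """Power of the two-sided two-sample t-test via the noncentral t.

    df = 2n - 2, noncentrality = delta / (sigma * sqrt(2/n)).
    """
    df = 2 * spec.n_per_group - 2
    ncp = abs(spec.mean_difference) / (spec.sd * np.sqrt(2.0 / spec.n_per_group))
    tcrit = stats.t.ppf(1 - spec.alpha / 2, df)
    upper = stats.nct.sf(tcrit, df, ncp)
    # wrong-side rejection mass; scipy underflows it to nan at large ncp
    lower = np.nan_to_num(stats.nct.cdf(-tcrit, df, ncp), nan=0.0)
    return float(upper + lower)


# ---------------------------------------------------------------------------
# Gene sets


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def geneset_enrichment_adjusted(
    significant_cpgs,
    annotation: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    B: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Probe-count-bias-adjusted gene-set enrichment by matched resampling.

    Genes with more array probes are more likely to carry a significant CpG,
    which biases naive enrichment. For each set, the observed count of
    significant genes in the set is compared against ``B`` resampled gene
    sets matched on per-gene probe-count decile; the empirical p-value uses
    the plus-one estimator (1 + #null >= observed) / (B + 1), BH-adjusted
    across sets.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    ann = annotation[annotation["gene"].astype(str) != ""]
    probe_counts = ann.groupby("gene")["probe"].count()
    universe = probe_counts.index.to_numpy()
    sig_genes = set(
        ann.set_index("probe").reindex(pd.Index(significant_cpgs))["gene"].dropna()
    )
    deciles = pd.qcut(probe_counts.rank(method="first"), 10, labels=False)
    bins = {d: universe[(deciles == d).to_numpy()] for d in range(10)}
    gene_decile = dict(zip(universe, deciles))
    is_sig = np.array([g in sig_genes for g in universe])
    sig_by_gene = dict(zip(universe, is_sig))

    rng = np.random.default_rng(seed)
    rows = []
    for name, members in gene_sets.items():
        members = [g for g in members if g in gene_decile]
        if not members:
            raise ValueError(f"gene set {name!r} is empty within the universe")
        observed = sum(sig_by_gene[g] for g in members)
        null = np.zeros(B, dtype=int)
        decile_counts = pd.Series([gene_decile[g] for g in members]).value_counts()
        for b in range(B):
            total = 0
            for d, k in decile_counts.items():
                pick = rng.choice(bins[d], size=int(k), replace=False)
                total += int(sum(sig_by_gene[g] for g in pick))
            null[b] = total
        p = (1 + int((null >= observed).sum())) / (B + 1)
        rows.append({"set": name, "n_genes": len(members), "observed": observed,
                     "expected": float(null.mean()), "p": p})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def cluster_enrichment(
    cluster_labels: pd.Series,
    group_labels: pd.Series,
    target_clusters,
) -> tuple[float, int, float, np.ndarray]:
    """Chi-square enrichment of the non-UV group in target clusters.

    Builds the 2x2 table (in target clusters vs not) x (non-UV vs UV) and
    delegates to :func:`chi_square_test`. Returns (chi2, df, p, table).
    """
    cluster_labels = cluster_labels.reindex(group_labels.index)
    in_target = cluster_labels.isin(list(np.atleast_1d(target_clusters)))
    non_uv = group_labels.astype(str) != "uv"
    table = np.array(
        [
            [int((in_target & non_uv).sum()), int((in_target & ~non_uv).sum())],
            [int((~in_target & non_uv).sum()), int((~in_target & ~non_uv).sum())],
        ]
    )
    chi2, df, p = chi_square_test(table)
    return chi2, df, p, table


def load_table1_counts() -> dict:
    """Packaged transcription of the published cohort contingency tables."""
    text = resources.files("uvmeth.data").joinpath("table1_counts.yaml").read_text()
    return yaml.safe_load(text)
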