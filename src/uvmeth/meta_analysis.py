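"""Fixed-effects inverse-variance-weighted meta-analysis across cohorts.

Pools per-CpG (or region-level) coefficients and standard errors from two or
more studies with weights 1/SE^2, reporting BH-FDR and Bonferroni-adjusted
p-values, Cochran's Q as heterogeneity annotation, and direction-concordance
summaries. Probes absent from any study are reported unpooled.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def _check_estimates(study: pd.DataFrame, name: str) -> pd.DataFrame:
    if not {"coef", "se"}.issubset(study.columns):
        raise ValueError(f"study {name!r} needs 'coef' and 'se' columns")
    if (study["se"] <= 0).any():
        raise ValueError(f"study {name!r} has non-positive standard errors")
    return study


def ivw_meta(estimates: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance-weighted fixed-effects pooling.

    ``estimates`` maps study id -> DataFrame indexed by probe/region id with
    ``coef`` and ``se`` columns. Only ids present in every study are pooled:
    w_i = 1/SE_i^2, b = sum(w b)/sum(w), SE = 1/sqrt(sum w), Z = b/SE, with
    two-sided normal p, BH-FDR and Bonferroni columns, plus Cochran's Q and
    a same-direction flag. Ids missing from some study are returned with
    ``pooled=False`` carrying their single-study estimate.
    """
    if not estimates:
        raise ValueError("no studies supplied")
    studies = {k: _check_estimates(v, k) for k, v in estimates.items()}
    common = None
    for df in studies.values():
        common = df.index if common is None else common.intersection(df.index)
    all_ids = pd.Index([])
    for df in studies.values():
        all_ids = all_ids.union(df.index)

    coefs = np.column_stack([df.reindex(common)["coef"].to_numpy() for df in studies.values()])
    ses = np.column_stack([df.reindex(common)["se"].to_numpy() for df in studies.values()])
    w = 1.0 / ses**2
    pooled = (w * coefs).sum(axis=1) / w.sum(axis=1)
    pooled_se = 1.0 / np.sqrt(w.sum(axis=1))
    z = pooled / pooled_se
    p = 2 * stats.norm.sf(np.abs(z))
    q_het = (w * (coefs - pooled[:, None]) ** 2).sum(axis=1)
    same_dir = np.all(np.sign(np.where(coefs == 0, 1, coefs)) == np.sign(
        np.where(coefs[:, [0]] == 0, 1, coefs[:, [0]])), axis=1)

    out = pd.DataFrame(
        {
            "coef": pooled,
            "se": pooled_se,
            "z": z,
            "p": p,
            "q": multipletests(p, method="fdr_bh")[1] if len(p) else p,
            "p_bonferroni": np.minimum(p * len(p), 1.0),
            "n_studies": len(studies),
            "cochran_q": q_het,
            "same_direction": same_dir,
            "pooled": True,
        },
        index=common,
    )

    leftovers = all_ids.difference(common)
    if len(leftovers):
        logger.info("%d ids missing from some study reported unpooled", len(leftovers))
        rows = []
        for pid in leftovers:
            for name, df in studies.items():
                if pid in df.index:
                    b, s = float(df.loc[pid, "coef"]), float(df.loc[pid, "se"])
                    zz = b / s
                    rows.append(
                        {
                            "id": pid, "coef": b, "se": s, "z": zz,
                            "p": 2 * stats.norm.sf(abs(zz)), "q": np.nan,
                            "p_bonferroni": np.nan, "n_studies": 1,
                            "cochran_q": 0.0, "same_direction": True, "pooled": False,
                        }
                    )
                    break
        out = pd.concat([out, pd.DataFrame(rows).set_index("id")])
    out.index.name = "id"
    return out


def direction_concordance(estimates: dict[str, pd.DataFrame]) -> float:
    """Fraction of shared probes whose coefficients agree in sign everywhere.

    A zero coefficient counts as positive (logged when present).
    """
    if len(estimates) < 2:
        raise ValueError("need at least two studies")
    common = None
    for df in estimates.values():
        common = df.index if common is None else common.intersection(df.index)
    signs = np.column_stack(
        [np.sign(df.reindex(common)["coef"].to_numpy()) for df in estimates.values()]
    )
    n_zero = int((signs == 0).sum())
    if n_zero:
        logger.info("%d zero coefficients treated as positive", n_zero)
    signs[signs == 0] = 1
    return float(np.mean(np.all(signs == signs[:, [0]], axis=1)))


def overlap_enrichment(
    set_a: Sequence, set_b: Sequence, universe_size: int
) -> dict[str, float]:
    """Significance of the overlap of two feature sets within a universe.

    Reports both a 2x2 chi-square (no continuity correction) and the
    hypergeometric upper-tail probability of observing at least the overlap.
    """
    a, b = set(set_a), set(set_b)
    k = len(a & b)
    if k > min(len(a), len(b)):  # pragma: no cover - set logic guarantees this
        raise ValueError("overlap exceeds set size")
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set larger than universe")
    n11 = k
    n12 = len(a) - k
    n21 = len(b) - k
    n22 = universe_size - len(a) - len(b) + k
    table = np.array([[n11, n12], [n21, n22]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        chi2, chi2_p = np.nan, np.nan
    else:
        chi2, chi2_p, _, _ = stats.chi2_contingency(table, correction=False)
    hyper_p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return {
        "overlap": k,
        "chi2": float(chi2),
        "chi2_p": float(chi2_p),
        "hypergeom_p": hyper_p,
    }


def read_study_estimates(path, study: str | None = None) -> pd.DataFrame:
    """Read one study's estimates TSV (id, coef, se)."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index.name = "id"
    return _check_estimates(df, study or str(path))
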