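"""Simulation-based validation scenarios with planted ground truth.

Each function generates synthetic cohorts under the package's default study
conditions, runs the corresponding pipeline stage end-to-end and measures
calibration or parameter recovery against the planted truth. The problem
sizes are the package's validation defaults; both the test suite and the
reproduction script call these entry points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .integration import cv_accuracy, eqtm_correlate, mad_filter
from .methylation import (
    call_dmrs,
    filter_probes,
    fit_dmp,
    genomic_inflation_lambda,
    mvalue_transform,
)
from .signatures import call_samples
from .synthetic_cohort import CohortConfig, generate_cohort


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent per-replicate seeds below 2^31, derived from one seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def null_calibration(
    seed: int = 0,
    n_seeds: int = 20,
    n_probes: int = 20000,
    n_per_group: int = 25,
    alpha: float = 0.05,
) -> dict:
    """Genomic inflation and DMR false-discovery control on null cohorts.

    Cohorts carry no planted effects, so every called DMR is a false
    discovery. Returns the mean median-based lambda across seeds and the
    mean per-seed false-discovery proportion (false regions over called
    regions, 0 when nothing is called) at nominal region FDR ``alpha``.
    """
    lambdas, fdps = [], []
    for s in _child_seeds(seed, n_seeds):
        cohort = generate_cohort(
            CohortConfig(seed=s, n_uv=n_per_group, n_nonuv=n_per_group,
                         n_probes=n_probes, n_genes=10)
        )
        beta = filter_probes(cohort.beta, cohort.annotation)
        mv = mvalue_transform(beta)
        dmps = fit_dmp(mv, cohort.groups, beta=beta)
        lambdas.append(genomic_inflation_lambda(dmps["p"]))
        dmrs = call_dmrs(dmps, cohort.annotation, mvalues=mv)
        called = int((dmrs["q"] < alpha).sum()) if len(dmrs) else 0
        fdps.append(called / called if called else 0.0)
    return {
        "lambda_mean": float(np.mean(lambdas)),
        "lambdas": lambdas,
        "dmr_empirical_fdr": float(np.mean(fdps)),
    }


def _recovery_config(seed: int, delta_beta: float, n_cpgs: int, n_per_group: int,
                     n_probes: int, n_dmrs: int) -> CohortConfig:
    specs = [
        dict(chrom=f"chr{i + 1}", start=1_000_000 * (i + 1), n_cpgs=n_cpgs,
             spacing=200, delta_beta=delta_beta,
             direction="hyper" if i % 2 == 0 else "hypo")
        for i in range(n_dmrs)
    ]
    return CohortConfig(seed=seed, n_uv=n_per_group, n_nonuv=n_per_group,
                        n_probes=n_probes, n_genes=10, dmr_specs=specs)


def dmr_recovery(
    seed: int = 0,
    n_seeds: int = 10,
    delta_beta: float = 0.15,
    n_cpgs: int = 5,
    n_per_group: int = 25,
    n_probes: int = 5000,
    n_dmrs: int = 6,
) -> dict:
    """Sensitivity and effect-size accuracy for planted DMRs.

    A planted region counts as recovered when a called region at FDR < 0.05
    overlaps it. The effect error is |recovered mean delta-beta - planted
    delta| averaged over recovered regions.
    """
    recovered, total, errors = 0, 0, []
    for s in _child_seeds(seed, n_seeds):
        cohort = generate_cohort(
            _recovery_config(s, delta_beta, n_cpgs, n_per_group, n_probes, n_dmrs)
        )
        beta = filter_probes(cohort.beta, cohort.annotation)
        mv = mvalue_transform(beta)
        dmps = fit_dmp(mv, cohort.groups, beta=beta)
        dmrs = call_dmrs(dmps, cohort.annotation, mvalues=mv)
        sig = dmrs[dmrs["q"] < 0.05] if len(dmrs) else dmrs
        for t in cohort.truth.dmrs:
            total += 1
            hit = sig[
                (sig["chrom"] == t["chrom"])
                & (sig["start"] <= t["end"])
                & (sig["end"] >= t["start"])
            ] if len(sig) else sig
            if len(hit):
                recovered += 1
                errors.append(abs(float(hit["mean_delta_beta"].iloc[0]) - t["delta_beta"]))
    return {
        "sensitivity": recovered / total,
        "mean_effect_error": float(np.mean(errors)) if errors else float("nan"),
    }


def eqtm_recovery(
    seed: int = 0,
    n_seeds: int = 50,
    slope: float = -3.0,
    n_per_group: int = 29,
    n_probes: int = 400,
    n_genes: int = 50,
) -> dict:
    """Fraction of seeds in which a planted eQTM coupling reaches FDR < 0.05.

    Each cohort plants one methylation-coupled gene (negative slope on
    log2 expression) inside a planted DMR plus null pairs for the FDR
    denominator; detection requires the planted pair's q < 0.05 with the
    correct (negative) correlation sign.
    """
    detected = 0
    for s in _child_seeds(seed, n_seeds):
        cfg = _recovery_config(s, 0.15, 5, n_per_group, n_probes, 2)
        cfg.eqtm_genes = [dict(gene="gene00001", slope=slope)]
        cfg.n_genes = n_genes
        cfg.__post_init__()  # re-validate and coerce the added spec
        cohort = generate_cohort(cfg)
        link = cohort.truth.eqtm[0]
        null_pairs = [
            (cohort.annotation["probe"].iloc[i], f"gene{j:05d}")
            for i, j in zip(range(5, 30, 5), range(10, 15))
        ]
        pairs = [(link["cpg"], link["gene"])] + null_pairs
        res = eqtm_correlate(cohort.beta, cohort.expression, pairs)
        row = res[(res["cpg"] == link["cpg"]) & (res["gene"] == link["gene"])].iloc[0]
        if row["q"] < 0.05 and row["r"] < 0:
            detected += 1
    return {"detection_rate": detected / n_seeds}


def uv_caller_performance(
    seed: int = 0,
    n_seeds: int = 50,
    uv_signature_weight: float = 0.7,
    burden_mean: float = 200.0,
    n_per_group: int = 4,
    min_burden: int = 100,
) -> dict:
    """Sensitivity/specificity of the rule-based UV call vs planted status.

    Samples below ``min_burden`` total events are excluded, mirroring the
    burden floor at which the classification rule is meaningful.
    """
    tp = fn = tn = fp = 0
    for s in _child_seeds(seed, n_seeds):
        cohort = generate_cohort(
            CohortConfig(seed=s, n_uv=n_per_group, n_nonuv=n_per_group,
                         n_probes=50, n_genes=5,
                         uv_signature_weight=uv_signature_weight,
                         burden_mean_uv=burden_mean, burden_mean_nonuv=burden_mean)
        )
        calls = call_samples(cohort.mutations).set_index("sample")
        for sample, is_uv in cohort.truth.uv_status.items():
            if calls.loc[sample, "total_burden"] < min_burden:
                continue
            called = bool(calls.loc[sample, "uv_mutant"])
            if is_uv:
                tp += called
                fn += not called
            else:
                fp += called
                tn += not called
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "n_uv": tp + fn,
        "n_nonuv": tn + fp,
    }


def discrimination(
    seed: int = 0,
    n_per_group: int = 25,
    n_probes: int = 2000,
    n_genes: int = 500,
    mad_top: int = 100,
) -> dict:
    """Methylome vs transcriptome PLS-DA with methylome-only planted signal.

    The cohort plants DMRs but no eQTM couplings, so expression carries no
    group information. Accuracy is leave-one-out cross-validated after MAD
    filtering to the ``mad_top`` most variable features per block.
    """
    cohort = generate_cohort(_recovery_config(seed, 0.2, 5, n_per_group, n_probes, 8))
    groups = cohort.groups
    meth_block = mad_filter(cohort.beta, mad_top)
    expr_block = mad_filter(cohort.expression, min(mad_top, len(cohort.expression)))
    return {
        "methylome_accuracy": cv_accuracy(meth_block, groups.loc[meth_block.columns]),
        "transcriptome_accuracy": cv_accuracy(expr_block, groups.loc[expr_block.columns]),
    }
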