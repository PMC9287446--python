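import logging

import pandas as pd
import pytest

import uvmeth as uv

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def small_cohort() -> uv.MultiOmicsCohort:
    """Shared cohort: 5 planted DMRs, 2 eQTM couplings, 20+20 samples."""
    cfg = uv.CohortConfig(
        seed=0,
        n_uv=20,
        n_nonuv=20,
        n_probes=3000,
        n_genes=200,
        dmr_specs=[
            dict(chrom=f"chr{i}", start=1_000_000 * i, n_cpgs=5, spacing=200,
                 delta_beta=0.2, direction="hyper" if i % 2 else "hypo")
            for i in range(1, 6)
        ],
        eqtm_genes=[
            dict(gene="gene00010", slope=-3.0),
            dict(gene="gene00020", slope=-3.0),
        ],
    )
    return uv.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_dmps(small_cohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(dmps, mvalues) for the shared cohort, crude model."""
    beta = uv.filter_probes(small_cohort.beta, small_cohort.annotation)
    mv = uv.mvalue_transform(beta)
    return uv.fit_dmp(mv, small_cohort.groups, beta=beta), mv
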