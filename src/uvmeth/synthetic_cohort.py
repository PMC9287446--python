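"""Synthetic multi-OMICs melanoma cohorts with known ground truth.

Emulates the statistical structure of a two-group (UV-mutant vs non
UV-mutant) melanoma cohort profiled on a 450K-style methylation array, with
somatic SBS96 mutation catalogs, gene expression, copy-number calls and
melanoma-specific survival:

- beta values follow the bimodal distribution of Infinium arrays, generated
  as a two-component Gaussian mixture on the M (logit2) scale and
  back-transformed, so values stay strictly inside (0, 1);
- differentially methylated regions are planted as equally spaced CpG runs
  whose UV-group mean is shifted by a configurable delta-beta;
- UV samples draw mutation channels from a mixture of a UV-like 96-profile
  (C>T at dipyrimidines) and a flat background, plus tandem CC>TT events;
- expression is negative-binomial with log2-mean optionally coupled to the
  beta value of a linked CpG (planted eQTMs);
- survival is exponential with group-dependent hazards and independent
  censoring.

One global seed drives independent per-layer substreams, so changing one
layer's parameters does not perturb the others. The planted truth (DMRs,
eQTM couplings, per-sample UV status) ships with the cohort for
parameter-recovery testing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .methylation import beta_from_m, mvalue_transform, REGULATORY_CLASSES, DENSITY_CLASSES
from .signatures import (
    CHANNELS,
    MutationRecord,
    _revcomp,
    flat_profile,
    records_to_frame,
    uv_reference_profile,
)

CHROMS = tuple(f"chr{i}" for i in range(1, 23))
CHROM_LENGTH = 200_000_000  # uniform toy extent per autosome

# Baseline beta mixture on the M scale: low mode ~0.10, high mode ~0.85,
# SD 0.5 on the M scale, equal mixture weight — the classic bimodal shape of
# 450K arrays.
BETA_MODES = (0.10, 0.85)
M_SD = 0.5
MIX_WEIGHT = 0.5
# Planted DMR baselines stay mid-range so the full delta is realizable in
# either direction without clipping at the (0.001, 0.999) bounds.
PLANTED_BASELINE_RANGE = (0.25, 0.60)
BETA_BOUNDS = (0.001, 0.999)

# Substream keys (layer -> offset mixed into the seed)
_STREAMS = {"meth": 0, "mutation": 1, "expression": 2, "survival": 3, "layout": 4}


@dataclass(frozen=True)
class DmrSpec:
    """One planted differentially methylated region."""

    chrom: str
    start: int
    n_cpgs: int
    spacing: int  # bp between consecutive CpGs
    delta_beta: float  # unsigned magnitude
    direction: str = "hyper"  # "hyper" | "hypo" (UV relative to non-UV)

    def __post_init__(self):
        if self.chrom not in CHROMS:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.n_cpgs <= 0 or self.spacing <= 0 or self.start <= 0:
            raise ValueError("n_cpgs, spacing and start must be positive")
        if not 0 < self.delta_beta < 1:
            raise ValueError("delta_beta must be in (0, 1)")
        if self.direction not in ("hyper", "hypo"):
            raise ValueError("direction must be 'hyper' or 'hypo'")
        if self.start + (self.n_cpgs - 1) * self.spacing > CHROM_LENGTH:
            raise ValueError("DMR extends beyond chromosome extent")

    @property
    def signed_delta(self) -> float:
        return self.delta_beta if self.direction == "hyper" else -self.delta_beta


@dataclass(frozen=True)
class EqtmSpec:
    """A gene whose log2 expression is coupled to a CpG's beta value."""

    gene: str
    slope: float  # log2-expression change per unit beta
    cpg: str | None = None  # auto-linked to a planted DMR probe when None


@dataclass
class CohortConfig:
    """Generator settings; defaults describe the emulated study conditions."""

    seed: int = 0
    n_uv: int = 25
    n_nonuv: int = 25
    n_probes: int = 20000
    n_genes: int = 2000
    dmr_specs: list[DmrSpec] = field(default_factory=list)
    uv_signature_weight: float = 0.8
    burden_mean_uv: float = 200.0
    burden_mean_nonuv: float = 100.0
    cctt_rate: float = 0.05  # fraction of a UV sample's events that are CC>TT
    eqtm_genes: list[EqtmSpec] = field(default_factory=list)
    hazard_uv: float = 0.02  # events per month
    hazard_nonuv: float = 0.05
    censor_rate: float = 0.3
    snp_flag_rate: float = 0.03
    cross_reactive_rate: float = 0.01
    sex_chrom_rate: float = 0.02

    def __post_init__(self):
        if min(self.n_uv, self.n_nonuv, self.n_probes, self.n_genes) <= 0:
            raise ValueError("all counts must be positive")
        if not 0 <= self.uv_signature_weight <= 1:
            raise ValueError("uv_signature_weight must be in [0, 1]")
        if self.burden_mean_uv <= 0 or self.burden_mean_nonuv <= 0:
            raise ValueError("burden means must be positive")
        if self.hazard_uv <= 0 or self.hazard_nonuv <= 0:
            raise ValueError("hazards must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        self.dmr_specs = [
            d if isinstance(d, DmrSpec) else DmrSpec(**d) for d in self.dmr_specs
        ]
        self.eqtm_genes = [
            e if isinstance(e, EqtmSpec) else EqtmSpec(**e) for e in self.eqtm_genes
        ]

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SyntheticTruth:
    """Planted ground truth enabling parameter-recovery tests."""

    dmrs: list[dict]  # chrom, start, end, probes, delta_beta (signed)
    eqtm: list[dict]  # gene, cpg, slope
    uv_status: dict[str, bool]


@dataclass
class MultiOmicsCohort:
    clinical: pd.DataFrame  # sample, group, sex, age, tumor_type, surv_months, event
    beta: pd.DataFrame  # probes x samples
    annotation: pd.DataFrame  # ProbeAnnotation columns
    expression: pd.DataFrame  # genes x samples, log2 scale
    cnv: pd.DataFrame  # genes x samples, integer calls in [-2, 2]
    mutation_gene: pd.DataFrame  # genes x samples, 0/1 presence
    mutations: list[MutationRecord]
    truth: SyntheticTruth

    @property
    def samples(self) -> list[str]:
        return list(self.clinical["sample"])

    @property
    def groups(self) -> pd.Series:
        return self.clinical.set_index("sample")["group"]


def _rng(config: CohortConfig, layer: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[layer]])


# ---------------------------------------------------------------------------
# Layer generators


def _probe_layout(config: CohortConfig, rng: np.random.Generator):
    """Background + planted probe ids, positions and annotation."""
    n_bg = config.n_probes - sum(d.n_cpgs for d in config.dmr_specs)
    if n_bg < 0:
        raise ValueError("planted DMR CpGs exceed n_probes")
    per_chrom = np.full(len(CHROMS), n_bg // len(CHROMS))
    per_chrom[: n_bg % len(CHROMS)] += 1
    rows = []
    pid = 0
    genes = [f"gene{i:05d}" for i in range(config.n_genes)]
    for chrom, n in zip(CHROMS, per_chrom):
        pos = np.sort(rng.choice(CHROM_LENGTH, size=n, replace=False)) + 1
        for p in pos:
            rows.append((f"cg{pid:08d}", chrom, int(p), False))
            pid += 1
    planted_ids: list[list[str]] = []
    for d in config.dmr_specs:
        ids = []
        for j in range(d.n_cpgs):
            name = f"cg{pid:08d}"
            rows.append((name, d.chrom, d.start + j * d.spacing, True))
            ids.append(name)
            pid += 1
        planted_ids.append(ids)
    ann = pd.DataFrame(rows, columns=["probe", "chrom", "pos", "planted"])
    n = len(ann)
    ann["gene"] = rng.choice(genes, size=n)
    ann["regulatory_class"] = rng.choice(
        REGULATORY_CLASSES, size=n, p=[0.25, 0.10, 0.15, 0.10, 0.40]
    )
    ann["density_class"] = rng.choice(
        DENSITY_CLASSES, size=n, p=[0.30, 0.20, 0.10, 0.40]
    )
    bg = ~ann["planted"].to_numpy()
    ann["snp_flag"] = (rng.random(n) < config.snp_flag_rate) & bg
    ann["cross_reactive_flag"] = (rng.random(n) < config.cross_reactive_rate) & bg
    sex = (rng.random(n) < config.sex_chrom_rate) & bg
    ann["sex_chrom_flag"] = sex
    ann.loc[sex, "chrom"] = "chrX"
    ann = ann.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return ann, planted_ids


def _methylation(config, ann, planted_ids, samples, uv_mask, rng):
    n_probes, n_samples = len(ann), len(samples)
    planted_all = set(p for ids in planted_ids for p in ids)
    is_planted = ann["probe"].isin(planted_all).to_numpy()
    base_beta = np.where(
        rng.random(n_probes) < MIX_WEIGHT, BETA_MODES[0], BETA_MODES[1]
    )
    base_beta[is_planted] = rng.uniform(*PLANTED_BASELINE_RANGE, size=is_planted.sum())
    base_m = mvalue_transform(base_beta)

    shift_m = np.zeros(n_probes)
    probe_pos = {p: i for i, p in enumerate(ann["probe"])}
    for d, ids in zip(config.dmr_specs, planted_ids):
        for p in ids:
            i = probe_pos[p]
            b0 = base_beta[i]
            b1 = np.clip(b0 + d.signed_delta, *BETA_BOUNDS)
            shift_m[i] = mvalue_transform(b1) - base_m[i]

    M = (
        base_m[:, None]
        + shift_m[:, None] * uv_mask[None, :]
        + rng.normal(0.0, M_SD, size=(n_probes, n_samples))
    )
    beta = np.clip(beta_from_m(M), *BETA_BOUNDS)
    return pd.DataFrame(beta, index=ann["probe"].to_numpy(), columns=samples)


def _sample_mutations(config, sample, is_uv, rng) -> list[MutationRecord]:
    mean = config.burden_mean_uv if is_uv else config.burden_mean_nonuv
    n_events = int(rng.poisson(mean))
    if n_events == 0:
        return []
    w = config.uv_signature_weight if is_uv else 0.0
    profile = w * uv_reference_profile() + (1 - w) * flat_profile()
    n_cctt = int(rng.binomial(n_events, config.cctt_rate * w)) if is_uv else 0
    n_snv = n_events - n_cctt
    counts = rng.multinomial(n_snv, profile)
    records = []
    # well-spaced positions so no accidental adjacency merges
    positions = iter(rng.choice(CHROM_LENGTH // 10, size=n_events, replace=False) * 10 + 5)
    for idx in np.flatnonzero(counts):
        ch = CHANNELS[idx]
        five, ref, alt, three = ch[0], ch[2], ch[4], ch[6]
        for _ in range(counts[idx]):
            chrom = CHROMS[rng.integers(len(CHROMS))]
            pos = int(next(positions))
            rec = MutationRecord(sample, chrom, pos, ref, alt, five + ref + three, "SNV")
            if rng.random() < 0.5:  # emit on the purine strand half the time
                rec = MutationRecord(
                    sample, chrom, pos, _revcomp(ref), _revcomp(alt),
                    _revcomp(five + ref + three), "SNV",
                )
            records.append(rec)
    for _ in range(n_cctt):
        chrom = CHROMS[rng.integers(len(CHROMS))]
        pos = int(next(positions))
        if rng.random() < 0.5:
            records.append(MutationRecord(sample, chrom, pos, "CC", "TT", "", "DNP"))
        else:
            records.append(MutationRecord(sample, chrom, pos, "GG", "AA", "", "DNP"))
    return records


def _expression(config, beta, ann, samples, rng, eqtm_links):
    genes = [f"gene{i:05d}" for i in range(config.n_genes)]
    base_log2 = rng.normal(6.0, 1.0, size=config.n_genes)
    log2_mu = np.tile(base_log2[:, None], (1, len(samples)))
    gene_idx = {g: i for i, g in enumerate(genes)}
    for link in eqtm_links:
        g = link["gene"]
        if g not in gene_idx:
            raise ValueError(f"eQTM gene {g!r} outside the gene universe")
        log2_mu[gene_idx[g]] = base_log2[gene_idx[g]] + link["slope"] * beta.loc[
            link["cpg"]
        ].to_numpy(dtype=float)
    mu = np.exp2(log2_mu)
    r = 10.0  # NB dispersion (size)
    counts = rng.negative_binomial(r, r / (r + mu))
    return pd.DataFrame(np.log2(counts + 1.0), index=genes, columns=samples)


def generate_cohort(config: CohortConfig) -> MultiOmicsCohort:
    """Generate a complete cohort; identical config => bit-identical output."""
    samples = [f"S{j:03d}" for j in range(config.n_uv + config.n_nonuv)]
    uv_mask = np.r_[np.ones(config.n_uv, dtype=bool), np.zeros(config.n_nonuv, dtype=bool)]

    layout_rng = _rng(config, "layout")
    ann, planted_ids = _probe_layout(config, layout_rng)

    meth_rng = _rng(config, "meth")
    beta = _methylation(config, ann, planted_ids, samples, uv_mask, meth_rng)

    # resolve eQTM links: unlinked specs attach to planted DMR probes in turn
    planted_flat = [p for ids in planted_ids for p in ids]
    links = []
    auto = iter(planted_flat)
    for spec in config.eqtm_genes:
        cpg = spec.cpg
        if cpg is None:
            cpg = next(auto, None)
            if cpg is None:  # no planted probes left: couple to a background CpG
                cpg = ann["probe"].iloc[0]
        links.append({"gene": spec.gene, "cpg": cpg, "slope": spec.slope})

    mut_rng = _rng(config, "mutation")
    mutations: list[MutationRecord] = []
    for sample, is_uv in zip(samples, uv_mask):
        mutations.extend(_sample_mutations(config, sample, bool(is_uv), mut_rng))
    genes = [f"gene{i:05d}" for i in range(config.n_genes)]
    mutation_gene = pd.DataFrame(
        (mut_rng.random((config.n_genes, len(samples))) < 0.05).astype(int),
        index=genes, columns=samples,
    )
    cnv_draw = mut_rng.choice(
        [-2, -1, 0, 1, 2], size=(config.n_genes, len(samples)),
        p=[0.02, 0.05, 0.86, 0.05, 0.02],
    )
    cnv = pd.DataFrame(cnv_draw, index=genes, columns=samples)

    expr_rng = _rng(config, "expression")
    expression = _expression(config, beta, ann, samples, expr_rng, links)

    surv_rng = _rng(config, "survival")
    hazards = np.where(uv_mask, config.hazard_uv, config.hazard_nonuv)
    times = surv_rng.exponential(1.0 / hazards)
    censored = surv_rng.random(len(samples)) < config.censor_rate
    observed = np.where(censored, times * surv_rng.random(len(samples)), times)
    clinical = pd.DataFrame(
        {
            "sample": samples,
            "group": np.where(uv_mask, "uv", "nonuv"),
            "sex": surv_rng.choice(["male", "female"], size=len(samples), p=[0.6, 0.4]),
            "age": np.round(surv_rng.normal(57.0, 15.0, size=len(samples)), 1),
            "tumor_type": surv_rng.choice(
                ["primary", "metastatic"], size=len(samples), p=[0.3, 0.7]
            ),
            "surv_months": np.round(observed, 3),
            "event": (~censored).astype(int),
        }
    )

    truth = SyntheticTruth(
        dmrs=[
            {
                "chrom": d.chrom,
                "start": d.start,
                "end": d.start + (d.n_cpgs - 1) * d.spacing,
                "probes": ids,
                "delta_beta": d.signed_delta,
            }
            for d, ids in zip(config.dmr_specs, planted_ids)
        ],
        eqtm=links,
        uv_status={s: bool(u) for s, u in zip(samples, uv_mask)},
    )
    return MultiOmicsCohort(
        clinical=clinical,
        beta=beta,
        annotation=ann.drop(columns="planted"),
        expression=expression,
        cnv=cnv,
        mutation_gene=mutation_gene,
        mutations=mutations,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# I/O


_MATRIX_FILES = {
    "beta": "beta.tsv",
    "expression": "expression.tsv",
    "cnv": "cnv.tsv",
    "mutation_gene": "mutation_gene.tsv",
}


def write_cohort(cohort: MultiOmicsCohort, directory) -> dict:
    """Write every downstream input format plus truth.json and a manifest.

    Matrices go out as TSV with 6-decimal floats; the manifest records a
    sha256 checksum per emitted file.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    for attr, fname in _MATRIX_FILES.items():
        df = getattr(cohort, attr)
        df.to_csv(directory / fname, sep="\t", float_format="%.6f",
                  index_label="id")
        files[attr] = fname
    cohort.clinical.to_csv(directory / "clinical.tsv", sep="\t", index=False)
    files["clinical"] = "clinical.tsv"
    cohort.annotation.to_csv(directory / "probe_annotation.tsv", sep="\t", index=False)
    files["annotation"] = "probe_annotation.tsv"
    records_to_frame(cohort.mutations).to_csv(
        directory / "mutations.tsv", sep="\t", index=False
    )
    files["mutations"] = "mutations.tsv"
    with open(directory / "truth.json", "w") as fh:
        json.dump(asdict(cohort.truth), fh, indent=1)
    files["truth"] = "truth.json"

    manifest = {"files": {}, "n_samples": len(cohort.samples)}
    for key, fname in files.items():
        digest = hashlib.sha256((directory / fname).read_bytes()).hexdigest()
        manifest["files"][key] = {"path": fname, "sha256": digest}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def read_cohort(directory) -> MultiOmicsCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    from .signatures import read_maf

    directory = Path(directory)
    mats = {
        attr: pd.read_csv(directory / fname, sep="\t", index_col="id")
        for attr, fname in _MATRIX_FILES.items()
    }
    clinical = pd.read_csv(directory / "clinical.tsv", sep="\t")
    annotation = pd.read_csv(directory / "probe_annotation.tsv", sep="\t")
    with open(directory / "truth.json") as fh:
        truth = SyntheticTruth(**json.load(fh))
    for attr in mats:
        mats[attr].index.name = None
        mats[attr].columns.name = None
    return MultiOmicsCohort(
        clinical=clinical,
        beta=mats["beta"],
        annotation=annotation,
        expression=mats["expression"],
        cnv=mats["cnv"].astype(int),
        mutation_gene=mats["mutation_gene"].astype(int),
        mutations=read_maf(directory / "mutations.tsv"),
        truth=truth,
    )
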