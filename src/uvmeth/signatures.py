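"""SBS96 mutation spectra and UV mutational-signature calling.

Somatic single-base substitutions are folded onto the pyrimidine strand and
counted over the 96 canonical (substitution x trinucleotide-context) channels.
A sample is called UV-mutant when C>T transitions at dipyrimidine sites exceed
60% of the total mutation burden, or CC>TT tandem events exceed 5% of it.
De-novo signatures can be extracted by seeded multiplicative-update NMF and
annotated with their cosine similarity to a reference signature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
PYRIMIDINES = frozenset("CT")

#: Canonical lexicographic SBS96 channel order: substitutions C>A, C>G, C>T,
#: T>A, T>C, T>G; within each, 5' then 3' flank in A,C,G,T order.
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)
CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS)}

#: Channels counting toward the C>T-at-dipyrimidine fraction: C>T with a
#: pyrimidine on either flank of the folded context.
DIPYRIMIDINE_CT_CHANNELS: tuple[str, ...] = tuple(
    ch
    for ch in CHANNELS
    if ch[2:5] == "C>T" and (ch[0] in PYRIMIDINES or ch[6] in PYRIMIDINES)
)
_DIPY_MASK = np.array([ch in set(DIPYRIMIDINE_CT_CHANNELS) for ch in CHANNELS])


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant: an SNV or a dinucleotide (DNP) substitution."""

    sample: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    context: str = ""  # trinucleotide around an SNV; empty for DNPs
    variant_class: str = "SNV"  # "SNV" | "DNP"


@dataclass(frozen=True)
class SpectrumVector:
    """Per-sample SBS96 channel counts plus tandem CC>TT events."""

    sample: str
    counts: np.ndarray  # length 96, order = CHANNELS
    cctt_count: int
    total_burden: int

    def channel(self, name: str) -> int:
        return int(self.counts[CHANNEL_INDEX[name]])


@dataclass(frozen=True)
class UvCall:
    sample: str
    frac_ct_dipyrimidine: float
    frac_cctt: float
    uv_mutant: bool
    total_burden: int
    cosine_to_uv: float | None = None
    flagged: bool = False  # zero burden: call undefined


def _revcomp(seq: str) -> str:
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:  # pragma: no cover - message path
        raise ValueError(f"non-ACGT base in {seq!r}") from exc


def fold_to_pyrimidine(record: MutationRecord) -> MutationRecord:
    """Fold a record onto the pyrimidine strand (ref in {C, T}).

    Records whose reference allele is a purine are reverse-complemented
    (ref, alt and context); pyrimidine-strand records are returned unchanged.
    DNPs are folded on their first reference base. Idempotent.
    """
    for b in record.ref + record.alt:
        if b not in COMPLEMENT:
            raise ValueError(f"non-ACGT base {b!r} in {record}")
    if record.ref[0] in PYRIMIDINES:
        return record
    return replace(
        record,
        ref=_revcomp(record.ref),
        alt=_revcomp(record.alt),
        context=_revcomp(record.context) if record.context else "",
    )


def build_spectrum(records: Sequence[MutationRecord], sample: str) -> SpectrumVector:
    """Count a sample's folded records into the 96 channels.

    Tandem CC>TT events are gathered from two encodings: explicit DNP records
    with ref CC / alt TT after folding, and pairs of genomically adjacent
    (distance 1) C>T SNVs, which are merged into a single event and removed
    from the SNV channels. ``total_burden`` is the number of remaining SNV
    events plus all DNP events.
    """
    folded = [fold_to_pyrimidine(r) for r in records if r.sample == sample]
    snvs = [r for r in folded if r.variant_class == "SNV"]
    dnps = [r for r in folded if r.variant_class == "DNP"]

    # merge adjacent C>T SNV pairs (left-to-right, each SNV used once)
    ct = sorted(
        (r for r in snvs if r.ref == "C" and r.alt == "T"),
        key=lambda r: (r.chrom, r.pos),
    )
    merged_pairs = 0
    drop: set[tuple[str, int]] = set()
    i = 0
    while i < len(ct) - 1:
        a, b = ct[i], ct[i + 1]
        if a.chrom == b.chrom and b.pos - a.pos == 1:
            merged_pairs += 1
            drop.add((a.chrom, a.pos))
            drop.add((b.chrom, b.pos))
            i += 2
        else:
            i += 1

    counts = np.zeros(96, dtype=int)
    n_snv = 0
    for r in snvs:
        if r.ref == "C" and r.alt == "T" and (r.chrom, r.pos) in drop:
            continue
        if len(r.context) != 3 or r.context[1] != r.ref:
            raise ValueError(
                f"record {r} not folded or context inconsistent with ref"
            )
        counts[CHANNEL_INDEX[f"{r.context[0]}[{r.ref}>{r.alt}]{r.context[2]}"]] += 1
        n_snv += 1

    cctt = merged_pairs + sum(1 for r in dnps if r.ref == "CC" and r.alt == "TT")
    burden = n_snv + merged_pairs + len(dnps)
    return SpectrumVector(sample=sample, counts=counts, cctt_count=cctt, total_burden=burden)


def classify_uv(spectrum: SpectrumVector, cosine_to_uv: float | None = None) -> UvCall:
    """Apply the rule-based UV call to a spectrum.

    UV-mutant iff C>T at dipyrimidine sites exceeds 60% of total burden or
    CC>TT events exceed 5% of it (strict inequalities). A zero-burden sample
    yields a flagged non-call.
    """
    if spectrum.total_burden <= 0:
        return UvCall(spectrum.sample, 0.0, 0.0, False, 0, cosine_to_uv, flagged=True)
    frac_ct = float(spectrum.counts[_DIPY_MASK].sum() / spectrum.total_burden)
    frac_cctt = float(spectrum.cctt_count / spectrum.total_burden)
    return UvCall(
        sample=spectrum.sample,
        frac_ct_dipyrimidine=frac_ct,
        frac_cctt=frac_cctt,
        uv_mutant=(frac_ct > 0.60) or (frac_cctt > 0.05),
        total_burden=spectrum.total_burden,
        cosine_to_uv=cosine_to_uv,
    )


def uv_reference_profile() -> np.ndarray:
    """Shipped UV-like SBS96 profile (synthetic, not a COSMIC table).

    0.95 of the mass sits on the 12 dipyrimidine C>T channels — twice the
    weight on contexts with a 5' pyrimidine, where UV photoproducts form —
    and the remaining 0.05 is uniform over the other 84 channels. This
    reproduces the C>T-at-dipyrimidine dominance of UV exposure.
    """
    p = np.full(96, 0.05 / 84)
    dip = [CHANNEL_INDEX[ch] for ch in DIPYRIMIDINE_CT_CHANNELS]
    w = np.array([2.0 if CHANNELS[i][0] in PYRIMIDINES else 1.0 for i in dip])
    p[dip] = 0.95 * w / w.sum()
    return p


def flat_profile() -> np.ndarray:
    """Uniform background over all 96 channels."""
    return np.full(96, 1.0 / 96)


def nmf_decompose(
    spectra: np.ndarray,
    rank: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded multiplicative-update NMF of a samples x 96 count matrix.

    Minimizes the Frobenius loss ||V - WH||_F with Lee-Seung multiplicative
    updates, keeping the best of ``n_restarts`` random initializations.
    H rows are normalized to sum 1 (scale moved into W), so each row is a
    signature profile. The loss is non-increasing across iterations.
    """
    V = np.asarray(spectra, dtype=float)
    if np.any(V < 0):
        raise ValueError("NMF input must be nonnegative")
    if not np.any(V > 0):
        raise ValueError("NMF input is all zero")
    n, m = V.shape
    if rank >= min(n, m):
        raise ValueError(f"rank {rank} must be < min(dims) = {min(n, m)}")

    rng = np.random.default_rng(seed)
    eps = 1e-12
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    scale = np.sqrt(V.mean() / rank)
    for _ in range(n_restarts):
        W = scale * rng.random((n, rank)) + eps
        H = scale * rng.random((rank, m)) + eps
        prev = np.inf
        for _ in range(max_iter):
            H *= (W.T @ V) / (W.T @ W @ H + eps)
            W *= (V @ H.T) / (W @ H @ H.T + eps)
            loss = float(np.linalg.norm(V - W @ H))
            if prev - loss < tol * max(prev, eps):
                break
            prev = loss
        loss = float(np.linalg.norm(V - W @ H))
        if best is None or loss < best[0]:
            best = (loss, W, H)
    assert best is not None
    _, W, H = best
    row_sums = H.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    W = W * row_sums.T
    H = H / row_sums
    return W, H


def cosine_match(
    signature: np.ndarray, reference: pd.DataFrame, threshold: float = 0.8
) -> tuple[str, float, bool]:
    """Best cosine match of a 96-vector against reference signature columns.

    Returns (best column name, cosine, cosine > threshold).
    """
    v = np.asarray(signature, dtype=float)
    if np.linalg.norm(v) == 0:
        raise ValueError("zero signature vector")
    best_name, best_cos = "", -np.inf
    for name in reference.columns:
        r = reference[name].to_numpy(dtype=float)
        nr = np.linalg.norm(r)
        if nr == 0:
            raise ValueError(f"zero reference column {name!r}")
        c = float(v @ r / (np.linalg.norm(v) * nr))
        if c > best_cos:
            best_name, best_cos = name, c
    return best_name, best_cos, best_cos > threshold


# ---------------------------------------------------------------------------
# I/O


def read_maf(path) -> list[MutationRecord]:
    """Read a MAF-like TSV (sample, chrom, pos, ref, alt, context, class)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "context": str})
    df["context"] = df["context"].fillna("")
    return [
        MutationRecord(
            sample=str(r["sample"]),
            chrom=str(r["chrom"]),
            pos=int(r["pos"]),
            ref=str(r["ref"]),
            alt=str(r["alt"]),
            context=str(r["context"]),
            variant_class=str(r["class"]),
        )
        for r in df.to_dict("records")
    ]


def records_to_frame(records: Sequence[MutationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [r.sample for r in records],
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "ref": [r.ref for r in records],
            "alt": [r.alt for r in records],
            "context": [r.context for r in records],
            "class": [r.variant_class for r in records],
        }
    )


def context_from_fasta(fasta_path, chrom: str, pos: int) -> str:
    """Trinucleotide context looked up from an indexed genome FASTA."""
    from pyfaidx import Fasta  # optional dependency, only needed here

    genome = Fasta(str(fasta_path))
    return str(genome[chrom][pos - 2 : pos + 1]).upper()


def call_samples(
    records: Sequence[MutationRecord],
    reference: pd.DataFrame | None = None,
    nmf_rank: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Rule-based UV calls for every sample in a catalog.

    When a reference signature matrix is supplied, a consensus signature is
    extracted by NMF across samples and its best cosine similarity to the
    reference is attached as annotation; the 60%/5% rule stays authoritative
    for the call itself.
    """
    samples = sorted({r.sample for r in records})
    spectra = [build_spectrum(records, s) for s in samples]
    cosines: dict[str, float] = {}
    if reference is not None and len(samples) > nmf_rank:
        V = np.array([sp.counts for sp in spectra], dtype=float)
        W, H = nmf_decompose(V, rank=nmf_rank, seed=seed)
        consensus = H[np.argmax(W.sum(axis=0))]
        _, cos, _ = cosine_match(consensus, reference)
        cosines = {s: cos for s in samples}
    calls = [classify_uv(sp, cosines.get(sp.sample)) for sp in spectra]
    return pd.DataFrame(
        {
            "sample": [c.sample for c in calls],
            "frac_ct_dipyrimidine": [c.frac_ct_dipyrimidine for c in calls],
            "frac_cctt": [c.frac_cctt for c in calls],
            "total_burden": [c.total_burden for c in calls],
            "cosine_to_uv": [c.cosine_to_uv for c in calls],
            "uv_mutant": [c.uv_mutant for c in calls],
            "flagged": [c.flagged for c in calls],
        }
    )
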