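"""96-channel mutational spectra and expected lesion/artefact signatures.

Channel order follows the COSMIC convention: substitutions C>A, C>G,
C>T, T>A, T>C, T>G (pyrimidine strand), within each substitution the 16
flank combinations ordered 5' A,C,G,T (outer) by 3' A,C,G,T (inner).
MAV pair-profiles use the 6 unordered alt-pair combinations per
reference pyrimidine crossed with the same 16 flank combinations.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from lesionphylo.phasing_loh import binomial_matching_test

__all__ = [
    "CHANNELS",
    "MAV_CHANNELS",
    "PYRIMIDINE_CONTEXTS",
    "fold_snv",
    "spectrum_96",
    "likelihood_signature",
    "expected_mav_signature",
    "expected_independent_pvv_signature",
    "expected_reversion_signature",
    "cosine_similarity",
    "strand_bias_test",
    "fit_exposures",
    "tabulate_indels",
    "read_signature_tsv",
    "write_signature_tsv",
]

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

CHANNELS = [
    f"{f5}[{sub}]{f3}"
    for sub in SUBSTITUTIONS
    for f5 in BASES
    for f3 in BASES
]
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}

# unordered alt pairs sharing a reference pyrimidine, in spec order:
# {CA,CG},{CA,CT},{CG,CT},{TA,TC},{TA,TG},{TC,TG}
MAV_PAIR_COMBOS = [
    ("C", "A", "G"),
    ("C", "A", "T"),
    ("C", "G", "T"),
    ("T", "A", "C"),
    ("T", "A", "G"),
    ("T", "C", "G"),
]
MAV_CHANNELS = [
    f"{f5}[{ref}>{a1}/{ref}>{a2}]{f3}"
    for ref, a1, a2 in MAV_PAIR_COMBOS
    for f5 in BASES
    for f3 in BASES
]

PYRIMIDINE_CONTEXTS = [
    f"{f5}{ref}{f3}" for ref in "CT" for f5 in BASES for f3 in BASES
]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fold_snv(context: str, ref: str, alt: str) -> tuple[str, str, str]:
    """Fold an SNV with trinucleotide context to the pyrimidine strand."""
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not center on ref {ref!r}")
    if ref == alt or ref not in BASES or alt not in BASES:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if ref in "AG":
        return revcomp(context), revcomp(ref), revcomp(alt)
    return context, ref, alt


def channel_of(context: str, ref: str, alt: str) -> str:
    ctx, r, a = fold_snv(context, ref, alt)
    return f"{ctx[0]}[{r}>{a}]{ctx[2]}"


def spectrum_96(variants: pd.DataFrame) -> np.ndarray:
    """Count SNVs per 96 channel (pyrimidine-strand folded).

    ``variants`` must hold columns ``ref``, ``alt`` and ``context``
    (reference-strand trinucleotide centred on the mutated base).
    """
    out = np.zeros(96)
    for _, row in variants.iterrows():
        ctx = row.get("context")
        if not isinstance(ctx, str) or len(ctx) != 3:
            raise ValueError(f"missing/invalid trinucleotide context: {ctx!r}")
        out[_CHANNEL_INDEX[channel_of(ctx, str(row["ref"]), str(row["alt"]))]] += 1
    return out


def _context_of_channel(i: int) -> str:
    ch = CHANNELS[i]
    return ch[0] + ch[2] + ch[6]


def _freq_vector(genome_freqs: Mapping[str, float]) -> np.ndarray:
    """Per-channel frequency of each channel's pyrimidine context."""
    folded: dict[str, float] = {}
    for ctx, f in genome_freqs.items():
        key = ctx if ctx[1] in "CT" else revcomp(ctx)
        folded[key] = folded.get(key, 0.0) + float(f)
    out = np.zeros(96)
    for i in range(96):
        out[i] = folded.get(_context_of_channel(i), 0.0)
    return out


def likelihood_signature(
    sig: np.ndarray, genome_freqs: Mapping[str, float]
) -> np.ndarray:
    """Per-site mutation likelihoods: spectrum / context frequency.

    Defined only where the genome frequency is positive; channels on
    absent contexts get likelihood zero.
    """
    sig = np.asarray(sig, dtype=float)
    if sig.shape != (96,):
        raise ValueError("signature must have 96 channels")
    if sig.sum() <= 0:
        raise ValueError("empty signature")
    freqs = _freq_vector(genome_freqs)
    lik = np.zeros(96)
    nz = freqs > 0
    lik[nz] = sig[nz] / freqs[nz]
    total = lik.sum()
    return lik / total if total > 0 else lik


def expected_mav_signature(
    sig: np.ndarray, genome_freqs: Mapping[str, float]
) -> np.ndarray:
    """Expected MAV pair-profile from a single-SNV signature.

    Each of the 96 MAV channels (alt pair x flank combination) gets
    weight proportional to the product of the two per-site likelihoods
    at that context, weighted by the genome abundance of the context.
    """
    lik = likelihood_signature(sig, genome_freqs)
    freqs = _freq_vector(genome_freqs)
    out = np.zeros(96)
    k = 0
    for ref, a1, a2 in MAV_PAIR_COMBOS:
        for f5 in BASES:
            for f3 in BASES:
                c1 = _CHANNEL_INDEX[f"{f5}[{ref}>{a1}]{f3}"]
                c2 = _CHANNEL_INDEX[f"{f5}[{ref}>{a2}]{f3}"]
                out[k] = lik[c1] * lik[c2] * freqs[c1]
                k += 1
    total = out.sum()
    if total <= 0:
        warnings.warn(
            "signature admits no two-alt combination; expected MAV "
            "profile is all zero"
        )
        return out
    return out / total


def expected_independent_pvv_signature(
    sig: np.ndarray, genome_freqs: Mapping[str, float]
) -> np.ndarray:
    """Expected spectrum of the same mutation occurring independently twice.

    Likelihood squared, multiplied back by the context frequency,
    normalized.
    """
    lik = likelihood_signature(sig, genome_freqs)
    freqs = _freq_vector(genome_freqs)
    out = lik**2 * freqs
    total = out.sum()
    if total <= 0:
        warnings.warn("expected independent-PVV signature is all zero")
        return out
    return out / total


def expected_reversion_signature(
    sig: np.ndarray, genome_freqs: Mapping[str, float]
) -> np.ndarray:
    """Expected spectrum of PVVs caused by somatic reversion.

    The variant detected as a PVV is the *original* mutation (present in
    the clade, lost in the reverted subclade), so the spectrum is over
    the original channel.  A mutation changes its own context: C>T at
    ACG can only be reverted by T>C at ATG.  Each original channel is
    weighted by the product of its likelihood and the likelihood of its
    reversion, times the original context frequency; a signature with a
    highly likely reversion (C>T at CpG) therefore peaks at the
    corresponding T>C originals.
    """
    lik = likelihood_signature(sig, genome_freqs)
    freqs = _freq_vector(genome_freqs)
    out = np.zeros(96)
    for i in range(96):
        if lik[i] == 0:
            continue
        ch = CHANNELS[i]
        f5, ref, alt, f3 = ch[0], ch[2], ch[4], ch[6]
        rev_channel = channel_of(f5 + alt + f3, alt, ref)
        j = _CHANNEL_INDEX[rev_channel]
        out[i] += lik[i] * lik[j] * freqs[i]
    total = out.sum()
    if total <= 0:
        warnings.warn(
            "no reverse mutation has positive likelihood; expected "
            "reversion signature is all zero"
        )
        return out
    return out / total


def cosine_similarity(a, b) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors differ in length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(a @ b / (na * nb))


def strand_bias_test(n_transcribed: int, n_untranscribed: int) -> float:
    """Exact conditional two-sided test for transcriptional strand bias."""
    return binomial_matching_test(n_transcribed, n_transcribed + n_untranscribed)


def fit_exposures(
    target: np.ndarray, references: np.ndarray | Mapping[str, np.ndarray]
) -> tuple[np.ndarray, float]:
    """Non-negative least-squares signature exposures.

    References are normalized to unit mass so exposures are on the
    target's count scale.  Returns (exposures, reconstruction residual).
    """
    target = np.asarray(target, dtype=float)
    if isinstance(references, Mapping):
        mat = np.column_stack([np.asarray(v, float) for v in references.values()])
    else:
        mat = np.asarray(references, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
    if mat.shape[0] != target.shape[0]:
        raise ValueError("reference and target dimensions differ")
    sums = mat.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("empty reference signature")
    mat = mat / sums
    exposures, residual = optimize.nnls(mat, target)
    return exposures, float(residual)


def tabulate_indels(
    variants: pd.DataFrame, max_size: int = 5, max_repeats: int = 6
) -> pd.DataFrame:
    """Plain tabulation of indels by size and reference repeat-unit count.

    Size is signed (negative = deletion).  The repeat count is how many
    additional copies of the inserted/deleted unit follow the event in
    the reference (requires a ``repeat_units`` column when present,
    otherwise 0).  This is reporting, not a signature model.
    """
    rows = []
    for _, v in variants.iterrows():
        if v["vclass"] != "indel":
            continue
        size = len(str(v["alt"])) - len(str(v["ref"]))
        size = int(np.clip(size, -max_size, max_size))
        reps = int(min(v.get("repeat_units", 0) or 0, max_repeats))
        rows.append({"size": size, "repeat_units": reps})
    if not rows:
        return pd.DataFrame(columns=["size", "repeat_units", "count"])
    return (
        pd.DataFrame(rows)
        .groupby(["size", "repeat_units"])
        .size()
        .rename("count")
        .reset_index()
    )


def read_signature_tsv(path_or_buf, channels: Sequence[str] = CHANNELS
                       ) -> np.ndarray:
    df = pd.read_csv(path_or_buf, sep="\t")
    if not {"channel", "weight"} <= set(df.columns):
        raise ValueError("signature TSV needs 'channel' and 'weight' columns")
    weights = dict(zip(df["channel"], df["weight"]))
    missing = set(channels) - set(weights)
    if missing:
        raise ValueError(f"signature TSV missing channels: {sorted(missing)[:5]}...")
    return np.array([float(weights[c]) for c in channels])


def write_signature_tsv(path, sig: np.ndarray,
                        channels: Sequence[str] = CHANNELS) -> None:
    pd.DataFrame({"channel": list(channels), "weight": np.asarray(sig)}).to_csv(
        path, sep="\t", index=False
    )
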