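"""96-context mutation counting and nonnegative signature-exposure fitting.

Somatic single-base substitutions are binned into the canonical 96 channels:
six pyrimidine-centred substitution classes (C>A, C>G, C>T, T>A, T>C, T>G)
crossed with the 16 combinations of 5' and 3' flanking bases. Substitutions
reported on a purine reference base are reverse-complemented into pyrimidine
space first, so the counting is strand-symmetric.

Exposures to a supplied reference signature matrix (e.g. a COSMIC layout with
one column designated as the BRCA-associated signature 3) are fitted by
nonnegative least squares — a single deterministic solve, not a de-novo
signature extraction. The downstream biomarker is the cohort ranking of the
signature-3 *fraction*: samples in the top quintile carry the "high BRCA
signature" flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"
#: Canonical channel order: substitution class major, then 5' flank, then 3' flank.
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
)
CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}
N_CHANNELS = 96

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class ContextVector96:
    """Counts of substitutions in the 96 canonical contexts.

    ``counts`` follows :data:`CHANNELS`; ``n_skipped`` tallies input records
    dropped for ambiguous bases.
    """

    counts: np.ndarray
    n_skipped: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (N_CHANNELS,):
            raise ValueError(f"expected {N_CHANNELS} channels, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("channel counts must be nonnegative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNELS), name="count")

    def write_tsv(self, path: str | Path) -> None:
        self.to_series().rename_axis("channel").to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ContextVector96":
        series = pd.read_csv(path, sep="\t", index_col=0)["count"]
        return cls(counts=series.reindex(list(CHANNELS)).fillna(0).to_numpy())


@dataclass(frozen=True)
class SignatureMatrix:
    """96 x K reference signature matrix; columns are probability vectors."""

    probabilities: np.ndarray
    signature_ids: tuple[str, ...]
    brca_id: str = "SBS3"

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != N_CHANNELS:
            raise ValueError(f"expected a {N_CHANNELS} x K matrix, got {probs.shape}")
        if probs.shape[1] != len(self.signature_ids):
            raise ValueError("signature_ids length must match the number of columns")
        if (probs < 0).any():
            raise ValueError("signature probabilities must be nonnegative")
        sums = probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each signature column must sum to 1")
        object.__setattr__(self, "probabilities", probs)
        object.__setattr__(self, "signature_ids", tuple(self.signature_ids))

    @property
    def n_signatures(self) -> int:
        return self.probabilities.shape[1]

    def column(self, signature_id: str) -> np.ndarray:
        return self.probabilities[:, self.signature_ids.index(signature_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.probabilities, index=list(CHANNELS), columns=list(self.signature_ids)
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("channel").to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, brca_id: str = "SBS3") -> "SignatureMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0).reindex(list(CHANNELS))
        return cls(
            probabilities=frame.to_numpy(float),
            signature_ids=tuple(frame.columns),
            brca_id=brca_id,
        )


@dataclass(frozen=True)
class ExposureVector:
    """Nonnegative signature exposures plus the cosine of the reconstruction."""

    exposures: np.ndarray
    signature_ids: tuple[str, ...]
    reconstruction_cosine: float

    @property
    def total(self) -> float:
        return float(np.sum(self.exposures))

    @property
    def normalized(self) -> np.ndarray:
        total = self.total
        if total == 0:
            return np.zeros_like(np.asarray(self.exposures, float))
        return np.asarray(self.exposures, float) / total

    def fraction(self, signature_id: str) -> float:
        return float(self.normalized[self.signature_ids.index(signature_id)])


def _pyrimidine_context(ref: str, alt: str, flank5: str, flank3: str) -> str | None:
    """Map one substitution to its canonical channel; None for ambiguous bases."""
    ref, alt, flank5, flank3 = (b.upper() for b in (ref, alt, flank5, flank3))
    bases = {ref, alt, flank5, flank3}
    if not bases <= set("ACGT"):
        return None
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref})")
    if ref in "AG":  # purine reference: reverse-complement the whole context
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        flank5, flank3 = _COMPLEMENT[flank3], _COMPLEMENT[flank5]
    return f"{flank5}[{ref}>{alt}]{flank3}"


def count_contexts(substitutions: pd.DataFrame) -> ContextVector96:
    """Bin a substitution table into the 96 channels.

    Expects columns ``ref``, ``alt``, ``flank5``, ``flank3`` (single bases;
    flanks come from the input table, not a reference genome). Records with
    ambiguous bases (e.g. N) are skipped and tallied in ``n_skipped``.
    """
    required = {"ref", "alt", "flank5", "flank3"}
    missing = required - set(substitutions.columns)
    if missing:
        raise ValueError(f"substitution table missing columns: {sorted(missing)}")
    counts = np.zeros(N_CHANNELS, dtype=np.int64)
    skipped = 0
    for row in substitutions.itertuples(index=False):
        channel = _pyrimidine_context(row.ref, row.alt, row.flank5, row.flank3)
        if channel is None:
            skipped += 1
            continue
        counts[CHANNEL_INDEX[channel]] += 1
    return ContextVector96(counts=counts, n_skipped=skipped)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(np.dot(a, b) / (na * nb), 0.0, 1.0))


def fit_exposures_nnls(vector: ContextVector96, signatures: SignatureMatrix) -> ExposureVector:
    """Fit exposures minimising ||counts - S e||_2 subject to e >= 0."""
    counts = vector.counts.astype(float)
    if counts.sum() == 0:
        raise ValueError("empty catalog: cannot fit exposures to a zero count vector")
    exposures, _ = scipy.optimize.nnls(signatures.probabilities, counts)
    reconstruction = signatures.probabilities @ exposures
    return ExposureVector(
        exposures=exposures,
        signature_ids=signatures.signature_ids,
        reconstruction_cosine=_cosine(reconstruction, counts),
    )


def rank_brca_signature(sig3_fractions: pd.Series) -> pd.DataFrame:
    """Rank a cohort by signature-3 fraction and flag the top quintile.

    ``sig3_fractions`` is indexed by sample id. The top ``ceil(n/5)`` samples
    are flagged; ties are broken by ascending sample id (deterministic).
    With fewer than 5 samples the quintile flag is withheld (all-NA column)
    with a warning, since a quintile is not meaningful.
    """
    table = (
        sig3_fractions.rename("sig3_fraction")
        .rename_axis("sample_id")
        .reset_index()
        .sort_values(["sig3_fraction", "sample_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    table["rank"] = np.arange(1, len(table) + 1)
    n = len(table)
    if n < 5:
        warnings.warn(
            f"cohort of {n} samples is too small for quintile semantics; "
            "top_quintile flag withheld",
            stacklevel=2,
        )
        table["top_quintile"] = pd.NA
    else:
        n_top = ceil(n / 5)
        table["top_quintile"] = table["rank"] <= n_top
    return table
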