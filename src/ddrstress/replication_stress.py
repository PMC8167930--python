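"""Composite replication-stress signature scoring of expression cohorts.

Replication stress — impaired replication-fork progression — is read out
transcriptomically: nine DNA-maintenance / cell-cycle pathway gene sets
(ATR activation, chromosomal maintenance, E2F targets, homologous
recombination, Fanconi anaemia, base-excision repair, p53 signalling,
ER stress, RNA processing) are each scored per sample with a weighted-mean
z-score ("sig-score"), and the composite replication-stress score is their
unweighted sum. The cohort is then stratified by ranking (top quintile, top
quartile, or median split — cohorts in the field use different cut points,
so none is privileged as a default).

The per-term score for sample j over a gene set with direction weights
w_g in {+1, -1} is

    score_j = sum_g w_g * z_gj / sum_g |w_g|

where z_gj is gene g's expression standardised across samples. Z-scoring
makes every score invariant to per-gene affine rescaling of the input, so
any variance-stabilised log-scale matrix is acceptable; a log2(1+CPM)
normaliser is provided for raw counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRATIFY_SCHEMES = ("top_quintile", "top_quartile", "median")
_SCHEME_MIN_N = {"top_quintile": 5, "top_quartile": 4, "median": 2}


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with per-gene direction weights in {+1, -1}."""

    term_id: str
    genes: tuple[str, ...]
    weights: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        weights = tuple(self.weights) if self.weights else (1,) * len(genes)
        if not genes:
            raise ValueError(f"gene set {self.term_id!r} is empty")
        if len(weights) != len(genes):
            raise ValueError(f"gene set {self.term_id!r}: weights do not align with genes")
        if any(w not in (1, -1) for w in weights):
            raise ValueError(f"gene set {self.term_id!r}: weights must be +1 or -1")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "weights", weights)


@dataclass(frozen=True)
class GeneSetCollection:
    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sets", tuple(self.sets))

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def term_ids(self) -> tuple[str, ...]:
        return tuple(s.term_id for s in self.sets)


# ---------------------------------------------------------------------------
# GMT I/O: term <TAB> weights=+1,-1,... <TAB> gene1 <TAB> gene2 ...
# An empty or "na" description means all-+1 weights.
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs term, description, genes")
            term, description, genes = fields[0], fields[1], tuple(fields[2:])
            if description.startswith("weights="):
                weights = tuple(int(w) for w in description[len("weights="):].split(","))
            else:
                weights = (1,) * len(genes)
            sets.append(GeneSet(term_id=term, genes=genes, weights=weights))
    return GeneSetCollection(sets=tuple(sets))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            description = "weights=" + ",".join(f"{w:+d}" for w in gs.weights)
            fh.write("\t".join([gs.term_id, description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# Normalisation and scoring
# ---------------------------------------------------------------------------

def normalize_expression(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(1 + CPM) library-size normalisation of a genes x samples count matrix."""
    counts = counts.astype(float)
    if (counts < 0).to_numpy().any():
        raise ValueError("counts must be nonnegative")
    lib = counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    return np.log2(1.0 + 1e6 * counts / lib)


def sig_score(matrix: pd.DataFrame, gene_set: GeneSet) -> pd.Series:
    """Weighted-mean z-score of a gene set per sample.

    Genes absent from the matrix are logged and dropped; a zero-variance gene
    contributes z = 0 (logged) but stays in the weight normaliser. Requires
    at least one set gene present and >= 2 samples.
    """
    if matrix.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    present = [(g, w) for g, w in zip(gene_set.genes, gene_set.weights) if g in matrix.index]
    if not present:
        raise ValueError(f"no gene of set {gene_set.term_id!r} is present in the matrix")
    if len(present) < len(gene_set.genes):
        dropped = set(gene_set.genes) - {g for g, _ in present}
        logger.info("set %s: %d gene(s) absent, dropped: %s",
                    gene_set.term_id, len(dropped), sorted(dropped))

    genes = [g for g, _ in present]
    weights = np.array([w for _, w in present], dtype=float)
    values = matrix.loc[genes].to_numpy(float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.info("set %s: %d zero-variance gene(s) scored as z=0",
                    gene_set.term_id, int(flat.sum()))
    sd[sd == 0] = np.inf  # zero-variance gene -> z = 0
    z = (values - mean) / sd
    scores = (weights @ z) / np.abs(weights).sum()
    return pd.Series(scores, index=matrix.columns, name=gene_set.term_id)


def replication_stress_score(
    matrix: pd.DataFrame,
    sets: GeneSetCollection,
    scheme: str | None = None,
) -> pd.DataFrame:
    """Per-term sig-scores, their sum as the composite score, and the ranking.

    Returns a samples-indexed frame with one column per term, ``composite``,
    ``rank`` (1 = highest composite), and — when ``scheme`` is given —
    a ``stratum`` column from :func:`stratify_scores`.
    """
    if len(sets) == 0:
        raise ValueError("need at least one gene set")
    table = pd.DataFrame({gs.term_id: sig_score(matrix, gs) for gs in sets})
    table["composite"] = table.sum(axis=1)
    order = table["composite"].rename("score").rename_axis("sample_id").reset_index()
    order = order.sort_values(["score", "sample_id"], ascending=[False, True])
    table["rank"] = pd.Series(
        np.arange(1, len(order) + 1), index=order["sample_id"]
    )
    if scheme is not None:
        table["stratum"] = stratify_scores(table["composite"], scheme)
    return table


def stratify_scores(scores: pd.Series, scheme: str) -> pd.Series:
    """Label the top of a score ranking "high", the rest "low".

    top_quintile flags ceil(n/5) samples, top_quartile ceil(n/4), median
    ceil(n/2). Ties are broken by ascending sample id, so exactly the target
    number is flagged even on constant scores.
    """
    if scheme not in STRATIFY_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {STRATIFY_SCHEMES}")
    n = len(scores)
    if n < _SCHEME_MIN_N[scheme]:
        raise ValueError(f"scheme {scheme!r} needs at least {_SCHEME_MIN_N[scheme]} samples")
    n_high = ceil(n / {"top_quintile": 5, "top_quartile": 4, "median": 2}[scheme])
    order = scores.rename("score").rename_axis("sample_id").reset_index()
    order = order.sort_values(["score", "sample_id"], ascending=[False, True])
    high = set(order["sample_id"].head(n_high))
    return pd.Series(
        ["high" if s in high else "low" for s in scores.index],
        index=scores.index,
        name="stratum",
    )


def assign_subtype_centroid(
    matrix: pd.DataFrame, squamous_set: GeneSet, classical_set: GeneSet
) -> pd.Series:
    """Two-class subtype call: the larger of the two marker sig-scores wins.

    A plumbing classifier standing in for consensus clustering; exact ties
    go to "classical" (documented, deterministic).
    """
    squamous = sig_score(matrix, squamous_set)
    classical = sig_score(matrix, classical_set)
    return pd.Series(
        np.where(squamous > classical, "squamous", "classical"),
        index=matrix.columns,
        name="subtype",
    )
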