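"""Structural-variant catalogs, genome-stability classes and the rule-based HRD test.

A tumour that has lost homologous-recombination repair accumulates a genomic
"scar": many small, dispersed deletions and tandem duplications. The test
implemented here calls that scar from a structural-variant (SV) catalog with
five printed decision rules:

1. more than 50 SVs in total;
2. more than 70% of the SVs are deletions, duplications or translocations;
3. the SV pattern is not focal (not a chromothripsis/amplification cluster);
4. if deletions/translocations predominate, the median deletion size is
   below 10 kb, OR
5. if duplications predominate, the median duplication size is below 50 kb.

All four size/count thresholds are strict inequalities. A separate
genome-stability label calls >200 dispersed SVs an *unstable* genome,
<=50 a *stable* one, the focal pattern *locally rearranged*, and the
remainder *scattered*.

Focality itself has no published detector; the gap-merge breakpoint
clustering used here is this package's own reimplementation choice, with its
thresholds exposed as parameters (see the methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

SV_TYPES = ("DEL", "DUP", "INV", "TRA")
#: SV types counted in the numerator of the composition criterion.
QUALIFYING_TYPES = ("DEL", "DUP", "TRA")

STABILITY_CLASSES = ("stable", "scattered", "unstable", "locally_rearranged")

#: Strict thresholds of the five-criterion HRD test and the stability rule.
MIN_TOTAL_SV = 50            # criterion 1: count must exceed this
MIN_QUALIFYING_FRACTION = 0.70   # criterion 2: fraction must exceed this
MAX_MEDIAN_DEL_KB = 10.0     # criterion 4: median must be below this
MAX_MEDIAN_DUP_KB = 50.0     # criterion 5: median must be below this
UNSTABLE_SV_COUNT = 200      # stability: count must exceed this


@dataclass(frozen=True)
class SVRecord:
    """One rearrangement: a breakpoint pair with a type.

    Intra-chromosomal records (DEL/DUP/INV) have ``chrom1 == chrom2`` and a
    size equal to the breakpoint distance; translocations (TRA) join two
    chromosomes and carry no size.
    """

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sv_type: str

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.pos1 < 1 or self.pos2 < 1:
            raise ValueError("positions are 1-based and must be >= 1")
        if self.sv_type == "TRA":
            if self.chrom1 == self.chrom2:
                raise ValueError("TRA requires two different chromosomes")
        elif self.chrom1 != self.chrom2:
            raise ValueError(f"{self.sv_type} must be intra-chromosomal")

    @property
    def size_bp(self) -> int | None:
        """Breakpoint distance in bp; ``None`` for translocations."""
        if self.sv_type == "TRA":
            return None
        return abs(self.pos2 - self.pos1)

    def breakpoints(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return (self.chrom1, self.pos1), (self.chrom2, self.pos2)


@dataclass(frozen=True)
class SVCatalog:
    """Per-sample collection of :class:`SVRecord`.

    Every classification downstream is invariant to record order.
    """

    sample_id: str
    records: tuple[SVRecord, ...] = ()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SVRecord]:
        return iter(self.records)

    def type_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in SV_TYPES}
        for rec in self.records:
            counts[rec.sv_type] += 1
        return counts

    def sizes_bp(self, sv_type: str) -> np.ndarray:
        return np.array(
            [r.size_bp for r in self.records if r.sv_type == sv_type and r.size_bp is not None],
            dtype=float,
        )


@dataclass(frozen=True)
class BreakpointCluster:
    chrom: str
    span_bp: int
    n_breakpoints: int


@dataclass(frozen=True)
class FocalityReport:
    """Outcome of breakpoint clustering.

    ``clustered_fraction`` is the fraction of all breakpoints that fall in a
    qualifying cluster (span below the cap, at least the minimum number of
    breakpoints); the catalog is *focal* when that fraction reaches the
    configured threshold.
    """

    focal: bool
    clusters: tuple[BreakpointCluster, ...]
    clustered_fraction: float


@dataclass(frozen=True)
class HRDTestResult:
    """Five-criterion HRD call with a per-criterion breakdown.

    ``positive`` is criteria 1 AND 2 AND 3 AND the branch criterion (4 for a
    deletion/translocation-predominant catalog, 5 for duplication-predominant;
    on a tie either branch may satisfy the call). ``insufficient`` lists SV
    types whose branch criterion could not be evaluated for lack of sized
    records.
    """

    positive: bool
    criteria: dict[int, bool]
    predominant_branch: str  # "del_tra" | "dup" | "none"
    median_del_kb: float | None
    median_dup_kb: float | None
    insufficient: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# BEDPE I/O
#
# Dialect: 11 tab-separated columns
#   chrom1 start1 end1 chrom2 start2 end2 name score strand1 strand2 sv_type
# Coordinates are 0-based half-open single-base intervals (end = start + 1);
# they are converted to 1-based breakpoint positions internally.
# ---------------------------------------------------------------------------

def read_bedpe(path: str | Path, sample_id: str | None = None) -> SVCatalog:
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    records: list[SVRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: expected 11 BEDPE columns, got {len(fields)}")
            try:
                start1, start2 = int(fields[1]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            sv_type = fields[10]
            if sv_type not in SV_TYPES:
                raise ValueError(f"{path}:{lineno}: unknown SV type token {sv_type!r}")
            records.append(
                SVRecord(
                    chrom1=fields[0],
                    pos1=start1 + 1,
                    chrom2=fields[3],
                    pos2=start2 + 1,
                    sv_type=sv_type,
                )
            )
    return SVCatalog(sample_id=sample_id, records=tuple(records))


def write_bedpe(catalog: SVCatalog, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for i, rec in enumerate(catalog.records):
            fh.write(
                "\t".join(
                    [
                        rec.chrom1,
                        str(rec.pos1 - 1),
                        str(rec.pos1),
                        rec.chrom2,
                        str(rec.pos2 - 1),
                        str(rec.pos2),
                        f"sv{i}",
                        ".",
                        "+",
                        "+",
                        rec.sv_type,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Focality, stability, HRD test
# ---------------------------------------------------------------------------

def detect_focality(
    catalog: SVCatalog,
    gap_bp: float = 1_000_000,
    max_cluster_span_bp: float = 10_000_000,
    focal_fraction: float = 0.5,
    min_cluster_breakpoints: int = 10,
) -> FocalityReport:
    """Cluster breakpoints per chromosome and call a focal pattern.

    Consecutive sorted breakpoints on a chromosome are merged into one
    cluster while their gap is at most ``gap_bp``. A cluster *qualifies* when
    its span is at most ``max_cluster_span_bp`` and it contains at least
    ``min_cluster_breakpoints`` breakpoints. Translocations contribute one
    breakpoint to each partner chromosome; intra-chromosomal records
    contribute both ends.
    """
    if gap_bp <= 0 or max_cluster_span_bp <= 0 or focal_fraction <= 0:
        raise ValueError("focality parameters must be positive")

    by_chrom: dict[str, list[int]] = {}
    total = 0
    for rec in catalog:
        for chrom, pos in rec.breakpoints():
            by_chrom.setdefault(chrom, []).append(pos)
            total += 1

    clusters: list[BreakpointCluster] = []
    clustered = 0
    for chrom, positions in by_chrom.items():
        positions.sort()
        start = 0
        for i in range(1, len(positions) + 1):
            if i == len(positions) or positions[i] - positions[i - 1] > gap_bp:
                members = positions[start:i]
                span = members[-1] - members[0]
                if len(members) >= min_cluster_breakpoints and span <= max_cluster_span_bp:
                    clusters.append(BreakpointCluster(chrom, int(span), len(members)))
                    clustered += len(members)
                start = i

    fraction = clustered / total if total else 0.0
    return FocalityReport(
        focal=fraction >= focal_fraction,
        clusters=tuple(sorted(clusters, key=lambda c: (-c.n_breakpoints, c.chrom))),
        clustered_fraction=fraction,
    )


def classify_genome_stability(
    catalog: SVCatalog, focality: FocalityReport | None = None
) -> str:
    """Label a catalog stable (<=50 SVs), scattered, unstable (>200, dispersed)
    or locally rearranged (focal)."""
    if focality is None:
        focality = detect_focality(catalog)
    n = len(catalog)
    if focality.focal:
        return "locally_rearranged"
    if n > UNSTABLE_SV_COUNT:
        return "unstable"
    if n <= MIN_TOTAL_SV:
        return "stable"
    return "scattered"


def _median_kb(sizes_bp: np.ndarray) -> float | None:
    if sizes_bp.size == 0:
        return None
    # np.median uses the mean of the two central values for even cardinality
    return float(np.median(sizes_bp)) / 1000.0


def gpol_hrd_test(
    catalog: SVCatalog, focality: FocalityReport | None = None
) -> HRDTestResult:
    """Apply the five-criterion HRD test to an SV catalog.

    The predominant type is the single most frequent among DEL, DUP and TRA.
    A DEL/TRA-predominant catalog is judged on the median deletion size
    (criterion 4, <10 kb), a DUP-predominant one on the median duplication
    size (criterion 5, <50 kb); when DUP ties with DEL or TRA, both branch
    criteria are evaluated and either may carry the call. Translocations are
    sizeless and never enter the medians.
    """
    if focality is None:
        focality = detect_focality(catalog)

    n = len(catalog)
    counts = catalog.type_counts()
    n_qualifying = sum(counts[t] for t in QUALIFYING_TYPES)

    c1 = n > MIN_TOTAL_SV
    c2 = n > 0 and n_qualifying / n > MIN_QUALIFYING_FRACTION
    c3 = not focality.focal

    median_del_kb = _median_kb(catalog.sizes_bp("DEL"))
    median_dup_kb = _median_kb(catalog.sizes_bp("DUP"))

    top = max(counts[t] for t in ("DEL", "DUP", "TRA"))
    predominant = {t for t in ("DEL", "DUP", "TRA") if counts[t] == top and top > 0}
    del_tra_branch = bool(predominant & {"DEL", "TRA"})
    dup_branch = "DUP" in predominant

    insufficient: list[str] = []
    c4 = False
    if del_tra_branch:
        if median_del_kb is None:
            insufficient.append("DEL")
        else:
            c4 = median_del_kb < MAX_MEDIAN_DEL_KB
    c5 = False
    if dup_branch:
        if median_dup_kb is None:
            insufficient.append("DUP")
        else:
            c5 = median_dup_kb < MAX_MEDIAN_DUP_KB

    if del_tra_branch and dup_branch:
        branch = "del_tra"  # tie display; both criteria were evaluated
    elif dup_branch:
        branch = "dup"
    elif del_tra_branch:
        branch = "del_tra"
    else:
        branch = "none"

    positive = c1 and c2 and c3 and (c4 or c5)
    return HRDTestResult(
        positive=positive,
        criteria={1: c1, 2: c2, 3: c3, 4: c4, 5: c5},
        predominant_branch=branch,
        median_del_kb=median_del_kb,
        median_dup_kb=median_dup_kb,
        insufficient=tuple(insufficient),
    )


def hrd_summary_row(catalog: SVCatalog, focality: FocalityReport | None = None) -> dict:
    """Flat per-sample summary used by the CLI and pipeline reports."""
    if focality is None:
        focality = detect_focality(catalog)
    result = gpol_hrd_test(catalog, focality)
    n = len(catalog)
    counts = catalog.type_counts()
    n_qual = sum(counts[t] for t in QUALIFYING_TYPES)
    return {
        "sample_id": catalog.sample_id,
        "n_sv": n,
        "pct_del_dup_tra": round(100.0 * n_qual / n, 3) if n else float("nan"),
        "focal": focality.focal,
        "median_del_kb": result.median_del_kb,
        "median_dup_kb": result.median_dup_kb,
        "stability_class": classify_genome_stability(catalog, focality),
        "hrd_positive": result.positive,
    }
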