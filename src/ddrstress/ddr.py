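"""Composite DNA-damage-response (DDR) deficiency call and hierarchical ranking.

A sample is called DDR deficient when it carries *any* of four biomarkers:

1. an unstable genome (more than 200 dispersed structural variants);
2. a high BRCA mutational signature (top quintile of the cohort's
   signature-3 fraction);
3. a positive five-criterion HRD test;
4. a deleterious mutation in a key DDR gene (BRCA1, BRCA2, ATM, ATR, RPA1,
   RAD51, RAD54, FANCA) — germline or somatic.

The hierarchical rank score orders a cohort for plotting/stratification:
HRD-test positives above negatives, then by descending SV burden, then by
descending signature-3 fraction, mapped to [0, 1]. The published description
lists the components without weights, so a lexicographic ordering is used;
the 2x2 therapeutic quadrant depends only on the binary call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_DDR_PANEL = ("BRCA1", "BRCA2", "ATM", "ATR", "RPA1", "RAD51", "RAD54", "FANCA")

CONSEQUENCES = ("nonsense", "frameshift", "missense_deleterious", "splice", "other")
#: Consequences that count as deleterious for the biomarker flag.
DELETERIOUS_CONSEQUENCES = frozenset({"nonsense", "frameshift", "missense_deleterious", "splice"})
#: Loss-of-function consequences that, when biallelic, give a "strong" tier.
LOF_CONSEQUENCES = frozenset({"nonsense", "frameshift", "splice"})


@dataclass
class BiomarkerProfile:
    """Per-sample fusion of the four DDR biomarkers.

    Flags may be ``None`` ("unknown"); an unknown flag leaves the composite
    call unknown unless another flag is already true (OR semantics).
    ``rs_high`` and ``quadrant`` are filled later by the replication-stress
    and pharmacotyping stages.
    """

    sample_id: str
    unstable_genome: bool | None
    hrd_test_positive: bool | None
    brca_sig_top_quintile: bool | None
    ddr_gene_mutation: bool | None
    biomarker_count: int = 0
    ddr_deficient: bool | None = None
    ddr_rank_score: float | None = None
    rs_high: bool | None = None
    quadrant: str | None = None

    def flags(self) -> dict[str, bool | None]:
        return {
            "unstable_genome": self.unstable_genome,
            "hrd_test_positive": self.hrd_test_positive,
            "brca_sig_top_quintile": self.brca_sig_top_quintile,
            "ddr_gene_mutation": self.ddr_gene_mutation,
        }


def flag_ddr_gene_mutations(
    variants: pd.DataFrame,
    panel: Sequence[str] = DEFAULT_DDR_PANEL,
    samples: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-sample DDR-gene mutation flag with a strength tier.

    ``variants`` columns: sample_id, gene, consequence, zygosity
    (heterozygous | homozygous_or_biallelic), germline (bool). Both germline
    and somatic hits qualify. The flag is true for any deleterious hit in the
    panel; the tier is "strong" for a biallelic loss-of-function hit
    (nonsense/frameshift/splice), "weak" otherwise, "none" without a hit.
    Unknown consequence tokens are warned about and treated as "other".
    """
    if not panel:
        raise ValueError("gene panel must be nonempty")
    panel_set = set(panel)

    variants = variants.copy()
    if len(variants):
        unknown = ~variants["consequence"].isin(CONSEQUENCES)
        if unknown.any():
            tokens = sorted(variants.loc[unknown, "consequence"].unique())
            warnings.warn(f"unknown consequence tokens treated as 'other': {tokens}", stacklevel=2)
            variants.loc[unknown, "consequence"] = "other"

    tiers: dict[str, str] = {}
    for row in variants.itertuples(index=False):
        if row.gene not in panel_set or row.consequence not in DELETERIOUS_CONSEQUENCES:
            continue
        strong = (
            row.zygosity == "homozygous_or_biallelic" and row.consequence in LOF_CONSEQUENCES
        )
        current = tiers.get(row.sample_id, "none")
        if strong or current == "none":
            tiers[row.sample_id] = "strong" if strong else "weak"

    if samples is None:
        samples = sorted(set(variants["sample_id"])) if len(variants) else []
    rows = [
        {
            "sample_id": s,
            "ddr_gene_mutation": tiers.get(s, "none") != "none",
            "tier": tiers.get(s, "none"),
        }
        for s in samples
    ]
    return pd.DataFrame(rows, columns=["sample_id", "ddr_gene_mutation", "tier"])


def ddr_composite_call(
    sample_id: str,
    unstable_genome: bool | None,
    hrd_test_positive: bool | None,
    brca_sig_top_quintile: bool | None,
    ddr_gene_mutation: bool | None,
) -> BiomarkerProfile:
    """OR of the four biomarker flags, with unknown propagation."""
    profile = BiomarkerProfile(
        sample_id=sample_id,
        unstable_genome=unstable_genome,
        hrd_test_positive=hrd_test_positive,
        brca_sig_top_quintile=brca_sig_top_quintile,
        ddr_gene_mutation=ddr_gene_mutation,
    )
    flags = list(profile.flags().values())
    profile.biomarker_count = sum(bool(f) for f in flags if f is not None)
    if any(f is True for f in flags):
        profile.ddr_deficient = True
    elif any(f is None for f in flags):
        profile.ddr_deficient = None  # unknown input, no positive flag
    else:
        profile.ddr_deficient = False
    return profile


def ddr_hierarchical_score(table: pd.DataFrame) -> pd.Series:
    """Rank score in [0, 1] ordering a cohort by DDR evidence.

    ``table`` columns: sample_id, hrd_test_positive, n_sv, sig3_fraction.
    Ordering is lexicographic — HRD-test positives first, then descending SV
    count, then descending signature-3 fraction, then ascending sample id —
    and the rank r in 1..n maps to 1 - (r - 1)/(n - 1).
    """
    n = len(table)
    if n < 2:
        raise ValueError("hierarchical score needs a cohort of at least 2 samples")
    ordered = table.sort_values(
        ["hrd_test_positive", "n_sv", "sig3_fraction", "sample_id"],
        ascending=[False, False, False, True],
    ).reset_index(drop=True)
    scores = 1.0 - np.arange(n) / (n - 1)
    return pd.Series(scores, index=ordered["sample_id"], name="ddr_rank_score")
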