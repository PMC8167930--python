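from __future__ import annotations

import numpy as np
import pytest

from ddrstress.sv import SVCatalog, SVRecord
from ddrstress.genome import CHROMOSOMES


def make_dispersed_catalog(
    n: int,
    sv_type: str = "DEL",
    sizes_bp=None,
    sample_id: str = "t",
    type_sequence=None,
) -> SVCatalog:
    """Deterministic non-focal catalog: records spaced 2 Mb apart, cycling
    over chromosomes, so no breakpoint cluster ever reaches 10 members."""
    records = []
    types = type_sequence if type_sequence is not None else [sv_type] * n
    sizes = list(sizes_bp) if sizes_bp is not None else [5000] * n
    size_iter = iter(sizes)
    per_chrom = {c: 0 for c in CHROMOSOMES}
    for i, t in enumerate(types):
        chrom = CHROMOSOMES[i % len(CHROMOSOMES)]
        pos = 1_000_000 + per_chrom[chrom] * 2_000_000
        per_chrom[chrom] += 1
        if t == "TRA":
            partner = CHROMOSOMES[(i + 1) % len(CHROMOSOMES)]
            if partner == chrom:
                partner = CHROMOSOMES[(i + 2) % len(CHROMOSOMES)]
            records.append(SVRecord(chrom, pos, partner, pos + 777, "TRA"))
        else:
            size = int(next(size_iter))
            records.append(SVRecord(chrom, pos, chrom, pos + size, t))
    return SVCatalog(sample_id=sample_id, records=tuple(records))


@pytest.fixture
def dispersed_catalog_factory():
    return make_dispersed_catalog


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
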