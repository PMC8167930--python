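"""Seeded synthetic cohorts with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes —
not real sequencing data:

* SV catalogs: an HRD "scar" profile (many small dispersed deletions /
  duplications), a quiet genome, a high-burden dispersed profile, and a
  chromothripsis-like focal profile, over a 22-autosome model genome with
  uniform breakpoints and log-normal sizes (sigma = 0.5 in log space).
* mutation catalogs: multinomial draws from a known signature mixture.
* expression cohorts: a planted replication-stress gradient over the nine
  pathway gene sets, with a squamous/classical subtype association
  (squamous samples have a higher mean planted stress level), Gaussian
  noise on the log scale.
* viability plates: 4PL curves with multiplicative log-normal noise plus
  media-blank, vehicle, and actinomycin-D control wells, so normalisation
  is exercised end to end.
* full cohort bundles: all four quadrants of the DDR x replication-stress
  grid populated, with planted EC50s coupled to the planted biology
  (DDR-deficient -> 10x lower platinum/PARP-inhibitor EC50; high stress ->
  10x lower ATR/WEE1-inhibitor EC50). The 10x ratio is this package's
  default, configurable in :class:`CohortDesign`.

All randomness flows from one integer seed through spawned child generators;
no global state is touched, and equal seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import AUTOSOME_LENGTHS_BP, CHROMOSOMES, CHROMOSOME_WEIGHTS
from .replication_stress import GeneSet, GeneSetCollection, write_gmt
from .signatures import CHANNELS, N_CHANNELS, ContextVector96, SignatureMatrix
from .sv import SVCatalog, SVRecord, write_bedpe

SV_PROFILES = ("hrd_scar", "quiet", "unstable_nonfocal", "chromothripsis_focal")

#: Per-profile defaults: (type mix, median size in kb).
_PROFILE_DEFAULTS: dict[str, tuple[dict[str, float], float]] = {
    "hrd_scar": ({"DEL": 0.60, "DUP": 0.25, "TRA": 0.15}, 5.0),
    "quiet": ({"DEL": 0.40, "DUP": 0.25, "INV": 0.20, "TRA": 0.15}, 50.0),
    "unstable_nonfocal": ({"DEL": 0.45, "DUP": 0.25, "INV": 0.15, "TRA": 0.15}, 100.0),
    "chromothripsis_focal": ({"DEL": 0.35, "DUP": 0.30, "INV": 0.35}, 0.5),
}

_LOG_SIZE_SIGMA = 0.5  # log-space sd of SV sizes

RS_TERM_IDS = (
    "atr_activation",
    "chromosomal_maintenance",
    "e2f_targets",
    "homologous_recombination",
    "fanconi_anemia",
    "base_excision_repair",
    "p53_signaling",
    "er_stress",
    "rna_processing",
)


# ---------------------------------------------------------------------------
# SV catalogs
# ---------------------------------------------------------------------------

def _draw_sizes(rng: np.random.Generator, n: int, median_kb: float, exact_median: bool) -> np.ndarray:
    sizes = np.exp(rng.normal(np.log(median_kb * 1000.0), _LOG_SIZE_SIGMA, size=n))
    if exact_median and n:
        sizes *= (median_kb * 1000.0) / np.median(sizes)
    return np.maximum(sizes, 2.0)


def _place_interval(rng: np.random.Generator, size_bp: float) -> tuple[str, int, int]:
    while True:
        chrom = rng.choice(CHROMOSOMES, p=CHROMOSOME_WEIGHTS)
        length = AUTOSOME_LENGTHS_BP[chrom]
        if size_bp < length:
            pos1 = int(rng.integers(1, length - int(size_bp)))
            return chrom, pos1, pos1 + int(round(size_bp))


def generate_sv_catalog(
    profile: str,
    n_sv: int,
    median_size_kb: float | None = None,
    type_mix: Mapping[str, float] | None = None,
    seed: int = 0,
    sample_id: str = "sim",
    exact_median: bool = False,
) -> SVCatalog:
    """Simulate one SV catalog under a named rearrangement profile.

    ``hrd_scar``, ``quiet`` and ``unstable_nonfocal`` scatter breakpoints
    uniformly (length-weighted) over the model genome with log-normal sizes
    around ``median_size_kb``; ``chromothripsis_focal`` confines >= 85% of
    records to one 5-Mb window on a single chromosome. ``exact_median``
    rescales the drawn sizes so the sample median hits the request exactly
    (used by boundary sweeps). Deterministic given the seed.
    """
    if profile not in SV_PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {SV_PROFILES}")
    if n_sv < 0:
        raise ValueError("n_sv must be nonnegative")
    default_mix, default_median = _PROFILE_DEFAULTS[profile]
    mix = dict(type_mix) if type_mix is not None else default_mix
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("type_mix fractions must sum to 1")
    unknown = set(mix) - {"DEL", "DUP", "INV", "TRA"}
    if unknown:
        raise ValueError(f"unknown SV types in mix: {sorted(unknown)}")
    median_kb = median_size_kb if median_size_kb is not None else default_median

    rng = np.random.default_rng((seed, SV_PROFILES.index(profile)))
    types = list(mix)
    # largest-remainder apportionment keeps the mix exact for the sweep tests
    raw = np.array([mix[t] * n_sv for t in types])
    counts = np.floor(raw).astype(int)
    remainder = n_sv - counts.sum()
    for i in np.argsort(-(raw - np.floor(raw)))[:remainder]:
        counts[i] += 1

    type_labels = np.repeat(types, counts)
    rng.shuffle(type_labels)
    n_sized = int(np.sum(type_labels != "TRA"))
    sizes = iter(_draw_sizes(rng, n_sized, median_kb, exact_median))

    focal_window: tuple[str, int, int] | None = None
    focal_flags = np.zeros(n_sv, dtype=bool)
    if profile == "chromothripsis_focal" and n_sv:
        chrom = rng.choice(CHROMOSOMES, p=CHROMOSOME_WEIGHTS)
        span = 5_000_000
        start = int(rng.integers(1, AUTOSOME_LENGTHS_BP[chrom] - span))
        focal_window = (chrom, start, start + span)
        focal_flags = rng.random(n_sv) < 0.90

    records: list[SVRecord] = []
    for i, sv_type in enumerate(type_labels):
        if focal_window is not None and focal_flags[i] and sv_type != "TRA":
            chrom, lo, hi = focal_window
            size = min(next(sizes), (hi - lo) / 2)
            pos1 = int(rng.integers(lo, hi - int(size)))
            records.append(SVRecord(chrom, pos1, chrom, pos1 + int(round(size)), sv_type))
        elif sv_type == "TRA":
            c1 = rng.choice(CHROMOSOMES, p=CHROMOSOME_WEIGHTS)
            c2 = rng.choice([c for c in CHROMOSOMES if c != c1])
            p1 = int(rng.integers(1, AUTOSOME_LENGTHS_BP[c1]))
            p2 = int(rng.integers(1, AUTOSOME_LENGTHS_BP[c2]))
            records.append(SVRecord(c1, p1, c2, p2, "TRA"))
        else:
            chrom, pos1, pos2 = _place_interval(rng, next(sizes))
            records.append(SVRecord(chrom, pos1, chrom, pos2, sv_type))
    return SVCatalog(sample_id=sample_id, records=tuple(records))


# ---------------------------------------------------------------------------
# Mutation catalogs
# ---------------------------------------------------------------------------

def synthetic_signature_matrix(n_signatures: int = 3, seed: int = 0) -> SignatureMatrix:
    """Sparse, well-separated synthetic reference signatures.

    Columns are Dirichlet(0.1) draws over the 96 channels (sparse, low mutual
    coherence, like real substitution signatures). One column is designated
    ``SBS3`` as the BRCA-associated signature.
    """
    if not 2 <= n_signatures <= 30:
        raise ValueError("n_signatures must be in [2, 30]")
    rng = np.random.default_rng((seed, 96))
    probs = rng.dirichlet(np.full(N_CHANNELS, 0.1), size=n_signatures).T
    names = ["SBS1", "SBS3", "SBS5", "SBS8", "SBS13", "SBS17", "SBS18", "SBS2"]
    extra = [f"SBSx{i}" for i in range(max(0, n_signatures - len(names)))]
    ids = tuple((names + extra)[:n_signatures])
    return SignatureMatrix(probabilities=probs, signature_ids=ids, brca_id="SBS3")


def generate_mutation_catalog(
    exposures: Sequence[float],
    n_mut: int,
    signatures: SignatureMatrix,
    seed: int = 0,
) -> ContextVector96:
    """Multinomial draw of ``n_mut`` substitutions from a signature mixture."""
    exposures = np.asarray(exposures, dtype=float)
    if exposures.shape != (signatures.n_signatures,):
        raise ValueError("exposures must align with the signature matrix columns")
    if (exposures < 0).any():
        raise ValueError("exposures must be nonnegative")
    total = exposures.sum()
    if total == 0:
        raise ValueError("exposures sum to zero")
    if n_mut < 0:
        raise ValueError("n_mut must be nonnegative")
    p = signatures.probabilities @ (exposures / total)
    rng = np.random.default_rng((seed, 3))
    return ContextVector96(counts=rng.multinomial(n_mut, p))


# ---------------------------------------------------------------------------
# Expression cohorts
# ---------------------------------------------------------------------------

def synthetic_gene_sets(
    genes_per_set: int = 20, n_negative: int = 2, seed: int = 0
) -> GeneSetCollection:
    """The nine replication-stress pathway gene sets, with a few -1 weights
    per set so direction handling is exercised."""
    rng = np.random.default_rng((seed, 9))
    sets = []
    for term in RS_TERM_IDS:
        genes = tuple(f"{term.upper()}_G{i:02d}" for i in range(genes_per_set))
        weights = [1] * genes_per_set
        for idx in rng.choice(genes_per_set, size=n_negative, replace=False):
            weights[idx] = -1
        sets.append(GeneSet(term_id=term, genes=genes, weights=tuple(weights)))
    return GeneSetCollection(sets=tuple(sets))


def synthetic_subtype_sets(genes_per_set: int = 15) -> tuple[GeneSet, GeneSet]:
    """Marker sets for the squamous / classical centroid classifier."""
    squamous = GeneSet(
        "squamous_markers", tuple(f"SQ_M{i:02d}" for i in range(genes_per_set))
    )
    classical = GeneSet(
        "classical_markers", tuple(f"CL_M{i:02d}" for i in range(genes_per_set))
    )
    return squamous, classical


def generate_expression_cohort(
    n_samples: int,
    gene_sets: GeneSetCollection,
    n_background_genes: int = 500,
    rs_effect: float = 2.0,
    subtype_fraction_squamous: float = 0.5,
    noise_sd: float = 1.0,
    seed: int = 0,
    subtype_sets: tuple[GeneSet, GeneSet] | None = None,
    rs_levels: Sequence[float] | None = None,
    subtypes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-scale expression cohort with a planted replication-stress gradient.

    Each sample gets a latent stress level ``rs_level_truth`` (standard-normal
    spread; squamous mean +1, classical mean -1, planting the subtype
    association). Gene g in a stress set with weight w shifts by
    ``w * rs_effect * rs_level``; subtype marker genes shift by +2 in their
    own subtype; everything gets N(0, noise_sd) noise. Values are already on
    a variance-stabilised log scale. Callers may pin ``rs_levels`` and
    ``subtypes`` (the cohort bundle does, to populate quadrants exactly).

    Returns (genes x samples matrix, truth table with sample_id,
    subtype_truth, rs_level_truth).
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if rs_effect < 0:
        raise ValueError("rs_effect must be nonnegative")
    if len(gene_sets) == 0:
        raise ValueError("need at least one gene set")
    rng = np.random.default_rng((seed, 17))
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]

    if subtypes is None:
        subtypes = np.where(
            rng.random(n_samples) < subtype_fraction_squamous, "squamous", "classical"
        )
    subtypes = np.asarray(subtypes)
    if rs_levels is None:
        rs_levels = rng.normal(0.0, 1.0, n_samples) + np.where(subtypes == "squamous", 1.0, -1.0)
    rs_levels = np.asarray(rs_levels, dtype=float)

    if subtype_sets is None:
        subtype_sets = synthetic_subtype_sets()
    squamous_set, classical_set = subtype_sets

    gene_rows: dict[str, np.ndarray] = {}
    baseline = lambda: rng.normal(5.0, 1.0)  # noqa: E731 - per-gene basal level
    for gs in gene_sets:
        for gene, w in zip(gs.genes, gs.weights):
            gene_rows[gene] = baseline() + w * rs_effect * rs_levels
    for gene in squamous_set.genes:
        gene_rows[gene] = baseline() + 2.0 * (subtypes == "squamous")
    for gene in classical_set.genes:
        gene_rows[gene] = baseline() + 2.0 * (subtypes == "classical")
    for i in range(n_background_genes):
        gene_rows[f"BG_{i:04d}"] = np.full(n_samples, baseline())

    matrix = pd.DataFrame.from_dict(gene_rows, orient="index", columns=sample_ids)
    if noise_sd > 0:
        matrix += rng.normal(0.0, noise_sd, matrix.shape)
    truth = pd.DataFrame(
        {"sample_id": sample_ids, "subtype_truth": subtypes, "rs_level_truth": rs_levels}
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Dose-response plates
# ---------------------------------------------------------------------------

#: Raw-signal anchors of the simulated MTS plate (arbitrary absorbance units).
_BLANK_LEVEL = 0.05
_ACTD_NET = 0.10
_VEHICLE_NET = 1.00


def half_log_doses(center: float = 1.0, n: int = 8) -> tuple[float, ...]:
    """Half-log dose series bracketing ``center`` (µmol/L)."""
    start = center * 10 ** (-(n - 1) / 4)
    return tuple(start * 10 ** (i / 2) for i in range(n))


def generate_dose_response(
    ec50: float,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    doses: Sequence[float] | None = None,
    replicates: int = 3,
    cv: float = 0.05,
    seed: int = 0,
    sample_id: str = "sim",
    compound: str = "drug",
) -> pd.DataFrame:
    """Raw plate table following a 4PL viability curve with control wells.

    Treated-well net signal is the curve value mapped onto the vehicle/kill
    anchor scale, with multiplicative log-normal noise of the requested
    coefficient of variation; control wells carry the same noise model.
    cv = 0 yields exact curve values, so noiseless fits recover the
    parameters to numerical precision.
    """
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    if doses is None:
        doses = half_log_doses(center=ec50)
    doses = tuple(float(d) for d in doses)
    if any(d <= 0 for d in doses):
        raise ValueError("doses must be positive")
    if len(set(doses)) < 4:
        raise ValueError("need at least 4 distinct doses")
    rng = np.random.default_rng((seed, 11))
    sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
    noise = lambda: np.exp(rng.normal(-sigma**2 / 2, sigma)) if sigma else 1.0  # noqa: E731

    rows = []
    for dose in doses:
        v = bottom + (top - bottom) / (1.0 + (dose / ec50) ** hill)
        net = _ACTD_NET + (v / 100.0) * (_VEHICLE_NET - _ACTD_NET)
        for rep in range(1, replicates + 1):
            rows.append((sample_id, compound, dose, "treated", rep, _BLANK_LEVEL + net * noise()))
    for rep in range(1, replicates + 1):
        rows.append((sample_id, compound, 0.0, "vehicle", rep,
                     _BLANK_LEVEL + _VEHICLE_NET * noise()))
        rows.append((sample_id, compound, 0.0, "actD_kill", rep,
                     _BLANK_LEVEL + _ACTD_NET * noise()))
        rows.append((sample_id, compound, 0.0, "media_blank", rep, _BLANK_LEVEL))
    return pd.DataFrame(
        rows, columns=["sample_id", "compound", "dose", "well_role", "replicate", "raw_signal"]
    )


# ---------------------------------------------------------------------------
# Full cohort bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDesign:
    """Study conditions planted by :func:`generate_cohort`.

    EC50s are in µmol/L; the sensitive:resistant ratio defaults to 10x.
    Noise defaults (expression sd 1.0, viability cv 0.1) are the package's
    standard synthetic conditions; :meth:`noiseless` zeroes them for exact
    recovery contracts.
    """

    n_sv_deficient: int = 300
    n_sv_proficient: int = 30
    sig3_high: float = 0.5
    sig3_low: float = 0.03
    n_mut: int = 10_000
    rs_effect: float = 2.0
    noise_sd: float = 1.0
    n_background_genes: int = 300
    cv: float = 0.1
    replicates: int = 3
    hill: float = 1.0
    ec50_resistant: dict[str, float] = field(
        default_factory=lambda: {
            "cisplatin": 20.0, "olaparib": 10.0, "AZD6738": 10.0, "AZD1775": 10.0
        }
    )
    sensitivity_ratio: float = 10.0
    p_squamous_given_rs_high: float = 0.8

    @classmethod
    def noiseless(cls, **overrides) -> "CohortDesign":
        return cls(noise_sd=0.0, cv=0.0, **overrides)


#: Compounds whose sensitivity is coupled to DDR deficiency vs high stress.
DDR_COMPOUNDS = ("cisplatin", "olaparib")
RS_COMPOUNDS = ("AZD6738", "AZD1775")  # ATR inhibitor, WEE1 inhibitor


@dataclass(frozen=True)
class CohortBundle:
    """Everything the pipeline consumes, plus the planted truth table."""

    truth: pd.DataFrame
    sv_catalogs: dict[str, SVCatalog]
    context_vectors: dict[str, ContextVector96]
    signatures: SignatureMatrix
    variants: pd.DataFrame
    expression: pd.DataFrame
    gene_sets: GeneSetCollection
    squamous_set: GeneSet
    classical_set: GeneSet
    plates: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        """Write the bundle in the same text formats the analysis reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "sv").mkdir(exist_ok=True)
        for sample, catalog in self.sv_catalogs.items():
            write_bedpe(catalog, outdir / "sv" / f"{sample}.bedpe")
        (outdir / "mutsig").mkdir(exist_ok=True)
        for sample, vector in self.context_vectors.items():
            vector.write_tsv(outdir / "mutsig" / f"{sample}.tsv")
        self.signatures.write_tsv(outdir / "signatures.tsv")
        self.variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
        self.expression.rename_axis("gene").to_csv(outdir / "expression.tsv", sep="\t")
        write_gmt(self.gene_sets, outdir / "rs_terms.gmt")
        write_gmt(
            GeneSetCollection((self.squamous_set, self.classical_set)),
            outdir / "subtype_markers.gmt",
        )
        self.plates.to_csv(outdir / "plates.csv", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def generate_cohort(
    n: int = 40, design: CohortDesign | None = None, seed: int = 1
) -> CohortBundle:
    """Simulate a full cohort populating all four DDR x stress quadrants.

    Samples cycle through the four quadrants so each holds ~n/4. DDR-deficient
    samples receive an HRD-scar SV catalog (also >200 SVs), a high planted
    signature-3 fraction, and (every other one) a biallelic BRCA2 frameshift;
    proficient samples receive quiet catalogs and near-zero signature 3.
    High-stress samples sit on the upper branch of the planted expression
    gradient, and the subtype is drawn with
    P(squamous | high stress) = ``p_squamous_given_rs_high``. EC50s follow the
    quadrant per the coupling described in the module docstring.
    """
    if n < 8:
        raise ValueError("need n >= 8 so each quadrant is populated")
    design = design or CohortDesign()
    rng = np.random.default_rng((seed, 40))

    sample_ids = [f"S{i:03d}" for i in range(n)]
    ddr_truth = np.array([i % 4 in (0, 1) for i in range(n)])
    rs_truth = np.array([i % 4 in (0, 2) for i in range(n)])

    signatures = synthetic_signature_matrix(n_signatures=3, seed=seed)
    gene_sets = synthetic_gene_sets(seed=seed)
    squamous_set, classical_set = synthetic_subtype_sets()
    sig3_idx = signatures.signature_ids.index(signatures.brca_id)

    # distinct, well-separated stress levels: high in [1, 2], low in [-2, -1]
    offsets = np.linspace(0.0, 1.0, n)
    rs_levels = np.where(rs_truth, 1.0 + offsets, -2.0 + offsets)
    subtypes = np.where(
        rng.random(n) < np.where(rs_truth, design.p_squamous_given_rs_high,
                                 1.0 - design.p_squamous_given_rs_high),
        "squamous",
        "classical",
    )

    sv_catalogs: dict[str, SVCatalog] = {}
    context_vectors: dict[str, ContextVector96] = {}
    variant_rows: list[dict] = []
    plate_frames: list[pd.DataFrame] = []
    truth_rows: list[dict] = []

    for i, sample in enumerate(sample_ids):
        child = int(rng.integers(0, 2**31 - 1))
        deficient = bool(ddr_truth[i])
        profile = "hrd_scar" if deficient else "quiet"
        n_sv = design.n_sv_deficient if deficient else design.n_sv_proficient
        sv_catalogs[sample] = generate_sv_catalog(
            profile, n_sv=n_sv, seed=child, sample_id=sample
        )

        base = design.sig3_high if deficient else design.sig3_low
        sig3 = base + 0.1 * (i / n)  # distinct fractions, order-preserving
        exposures = np.full(signatures.n_signatures, (1.0 - sig3) / (signatures.n_signatures - 1))
        exposures[sig3_idx] = sig3
        context_vectors[sample] = generate_mutation_catalog(
            exposures, n_mut=design.n_mut, signatures=signatures, seed=child
        )

        if deficient and i % 4 == 0:
            variant_rows.append(
                {
                    "sample_id": sample, "gene": "BRCA2", "consequence": "frameshift",
                    "zygosity": "homozygous_or_biallelic", "germline": bool(i % 8),
                }
            )

        ec50s: dict[str, float] = {}
        for k, (compound, resistant) in enumerate(design.ec50_resistant.items()):
            sensitive_flag = (
                deficient if compound in DDR_COMPOUNDS else bool(rs_truth[i])
            )
            ec50s[compound] = resistant / design.sensitivity_ratio if sensitive_flag else resistant
            # one dose series per compound, bracketing both planted EC50s
            center = resistant / np.sqrt(design.sensitivity_ratio)
            plate_frames.append(
                generate_dose_response(
                    ec50=ec50s[compound],
                    hill=design.hill,
                    doses=half_log_doses(center=center),
                    replicates=design.replicates,
                    cv=design.cv,
                    seed=child + k,
                    sample_id=sample,
                    compound=compound,
                )
            )

        truth_rows.append(
            {
                "sample_id": sample,
                "hrd_truth": deficient,
                "stability_truth": "unstable" if deficient else "stable",
                "sig3_fraction_truth": sig3,
                "ddr_gene_hit_truth": deficient and i % 4 == 0,
                "ddr_deficient_truth": deficient,
                "rs_high_truth": bool(rs_truth[i]),
                "subtype_truth": subtypes[i],
                "rs_level_truth": rs_levels[i],
                **{f"ec50_{c}_truth": v for c, v in ec50s.items()},
            }
        )

    expression, _ = generate_expression_cohort(
        n_samples=n,
        gene_sets=gene_sets,
        n_background_genes=design.n_background_genes,
        rs_effect=design.rs_effect,
        noise_sd=design.noise_sd,
        seed=seed,
        subtype_sets=(squamous_set, classical_set),
        rs_levels=rs_levels,
        subtypes=subtypes,
    )
    expression.columns = sample_ids

    variants = pd.DataFrame(
        variant_rows, columns=["sample_id", "gene", "consequence", "zygosity", "germline"]
    )
    return CohortBundle(
        truth=pd.DataFrame(truth_rows),
        sv_catalogs=sv_catalogs,
        context_vectors=context_vectors,
        signatures=signatures,
        variants=variants,
        expression=expression,
        gene_sets=gene_sets,
        squamous_set=squamous_set,
        classical_set=classical_set,
        plates=pd.concat(plate_frames, ignore_index=True),
    )
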