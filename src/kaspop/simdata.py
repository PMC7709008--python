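"""Synthetic inputs with the statistical structure the analyses assume.

Three generators:

* :func:`simulate_genotype_matrix` — island-model genotype matrices with
  exact differentiation (F_ST) and inbreeding (F_IS) truth, via the
  Balding–Nichols beta model: for a locus with ancestral frequency p,
  each population draws its own frequency ``p_k ~ Beta(p(1-F)/F,
  (1-p)(1-F)/F)`` whose expectation is p and whose among-population
  variance is exactly ``F p (1-p)``.  Genotypes within a population
  follow the inbreeding-adjusted Hardy-Weinberg proportions.
* :func:`simulate_variant_call_table` — two-parent transcriptome variant
  tables with a known number of clean SNPs plus planted rows that each
  violate exactly one rule of the marker-filter cascade; the planted
  class of every candidate row is returned for testing.
* :func:`simulate_loglik_table` — mean/SD model log-likelihood per
  cluster count K with a slope change (elbow) at a chosen K, feeding the
  Evanno delta-K computation.

All randomness flows from a single integer seed through one independent
counter-based stream per locus/contig, so outputs do not depend on
iteration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, HOM_REF, HET, HOM_ALT, MISSING, METADATA_COLUMNS

FAILURE_CLASSES = (
    "low_coverage",
    "parent_heterozygous",
    "both_parents_differ",
    "neither_parent_differs",
    "proximal_variant",
    "parent_indel",
    "no_homolog_hit",
    "shared_homolog_hit",
)

BASES = np.array(list("ACGT"))


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-based substream: one generator per (seed, key...)."""
    return np.random.default_rng([int(seed), *map(int, key)])


# ---------------------------------------------------------------------
# Genotype matrices


@dataclass(frozen=True)
class SimGenotypeSpec:
    """Parameters of the island-model genotype simulation.

    ``n_individuals_per_population`` may be a single count or one count
    per population (accession sizes in real panels are unequal).
    ``fst_target`` < 1 is the among-population differentiation truth;
    ``fis_target`` in [-1, 1] the within-population inbreeding truth.
    Ancestral minor-allele frequencies are uniform on
    ``ancestral_maf_range`` with random allele labeling.
    """

    n_populations: int
    n_individuals_per_population: int | tuple[int, ...]
    n_loci: int
    fst_target: float = 0.0
    fis_target: float = 0.0
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1 or self.n_loci < 1:
            raise ValueError("counts must be >= 1")
        sizes = self.sizes()
        if any(s < 1 for s in sizes):
            raise ValueError("population sizes must be >= 1")
        if not (0 <= self.fst_target < 1):
            raise ValueError("fst_target must lie in [0, 1)")
        if not (-1 <= self.fis_target <= 1):
            raise ValueError("fis_target must lie in [-1, 1]")
        lo, hi = self.ancestral_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie within (0, 0.5]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")

    def sizes(self) -> tuple[int, ...]:
        n = self.n_individuals_per_population
        if isinstance(n, int):
            return (n,) * self.n_populations
        if len(n) != self.n_populations:
            raise ValueError(
                "n_individuals_per_population must be an int or one count "
                "per population"
            )
        return tuple(int(x) for x in n)


def default_accession_metadata(accessions: list[str]) -> pd.DataFrame:
    """Deterministic accession metadata for simulated panels.

    Regions and altitude classes cycle over the accessions; the last
    three accessions are typed cultivar/cultivar/breeding when there are
    at least six accessions (mirroring a landrace-dominated panel),
    otherwise all are landraces.
    """
    n = len(accessions)
    region6 = [f"R{1 + i % 6}" for i in range(n)]
    region2 = ["West" if r in ("R1", "R2", "R3") else "East" for r in region6]
    altitude = [("low", "mid", "high")[i % 3] for i in range(n)]
    types = ["landrace"] * n
    if n >= 6:
        types[-3:] = ["cultivar", "cultivar", "breeding"]
    return pd.DataFrame(
        {
            "region6": region6,
            "region2": region2,
            "altitude_class": altitude,
            "type": types,
        },
        index=pd.Index(accessions, name="accession"),
    )[METADATA_COLUMNS]


def simulate_genotype_matrix(spec: SimGenotypeSpec) -> GenotypeMatrix:
    """Draw a genotype matrix under the Balding-Nichols island model.

    Per locus: ancestral frequency from ``ancestral_maf_range`` (uniform
    then random allele labeling); per population a beta-distributed
    frequency with mean p and variance ``fst_target * p * (1-p)``
    (``p_k = p`` exactly when fst_target is 0); per individual genotype
    probabilities ``P(AA) = p_k^2 + F_IS p_k q_k``, ``P(AB) =
    2 p_k q_k (1 - F_IS)``, ``P(BB) = q_k^2 + F_IS p_k q_k``; calls then
    masked to missing independently at ``missing_rate``.

    Raises ``ValueError`` if a negative ``fis_target`` drives any
    genotype probability below zero for a realized ``p_k``.
    """
    sizes = spec.sizes()
    n_total = sum(sizes)
    fst, fis = spec.fst_target, spec.fis_target
    lo, hi = spec.ancestral_maf_range

    calls = np.empty((n_total, spec.n_loci), dtype=np.int8)
    pop_slices = []
    start = 0
    for m in sizes:
        pop_slices.append(slice(start, start + m))
        start += m

    for locus in range(spec.n_loci):
        rng = _rng(spec.seed, locus)
        p = rng.uniform(lo, hi)
        if rng.random() < 0.5:  # random allele labeling
            p = 1.0 - p
        for k, sl in enumerate(pop_slices):
            if fst == 0.0:
                pk = p
            else:
                a = p * (1 - fst) / fst
                b = (1 - p) * (1 - fst) / fst
                pk = rng.beta(a, b)
            qk = 1.0 - pk
            p_aa = pk * pk + fis * pk * qk
            p_ab = 2 * pk * qk * (1 - fis)
            if p_aa < 0 or (qk * qk + fis * pk * qk) < 0:
                raise ValueError(
                    f"fis_target={fis} makes a genotype probability negative "
                    f"at locus {locus}, population {k} (p_k={pk:.4f}); "
                    "inbreeding cannot be that negative at this frequency"
                )
            u = rng.random(sl.stop - sl.start)
            g = np.where(u < p_aa, HOM_REF, np.where(u < p_aa + p_ab, HET, HOM_ALT))
            calls[sl, locus] = g
        if spec.missing_rate > 0:
            mask = rng.random(n_total) < spec.missing_rate
            calls[mask, locus] = MISSING

    accessions = [f"ACC{k + 1:03d}" for k in range(spec.n_populations)]
    sample_ids = []
    accession_of_sample = []
    for acc, m in zip(accessions, sizes):
        for i in range(m):
            sample_ids.append(f"{acc}_{i + 1:02d}")
            accession_of_sample.append(acc)
    return GenotypeMatrix(
        sample_ids=sample_ids,
        accession_of_sample=accession_of_sample,
        locus_ids=[f"L{j + 1:04d}" for j in range(spec.n_loci)],
        calls=calls,
        metadata=default_accession_metadata(accessions),
    )


# ---------------------------------------------------------------------
# Variant-call tables with planted filter failures


@dataclass(frozen=True)
class SimVariantSpec:
    """Layout of a simulated two-parent variant-call table.

    ``planted_failures`` maps failure-class name -> count of candidate
    SNP rows violating exactly that one cascade rule.  The classes
    ``proximal_variant`` and ``shared_homolog_hit`` involve paired rows
    (a variant needs a neighbour to be proximal to; a homolog must be
    shared between two contigs), so their counts must be >= 2 when
    nonzero.
    """

    n_contigs: int
    contig_length: int = 400
    n_clean_snps: int = 10
    planted_failures: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs < 1 or self.contig_length < 60:
            raise ValueError("need n_contigs >= 1 and contig_length >= 60")
        if self.n_clean_snps < 0:
            raise ValueError("n_clean_snps must be >= 0")
        unknown = set(self.planted_failures) - set(FAILURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown failure classes: {sorted(unknown)}")
        if any(c < 0 for c in self.planted_failures.values()):
            raise ValueError("failure counts must be >= 0")
        for cls in ("proximal_variant", "shared_homolog_hit"):
            if self.planted_failures.get(cls, 0) == 1:
                raise ValueError(f"{cls} rows come in groups; count must be >= 2")


def _random_contig(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(BASES, size=length)


def _other_base(rng: np.random.Generator, *exclude: str) -> str:
    choices = [b for b in "ACGT" if b not in exclude]
    return str(rng.choice(choices))


def simulate_variant_call_table(
    spec: SimVariantSpec, window: int = 10, min_coverage: int = 6
):
    """Build (references, variant table, homology map, planted ledger).

    Clean SNP rows satisfy all seven cascade rules; each planted failure
    row violates exactly the rule named by its class.  ``parent_indel``
    failures are a clean-looking SNP accompanied by an indel record
    within the proximity window; the companion indel record is part of
    the variant table but not a filter candidate and therefore not in
    the ledger.  Returns ``(references, table, homology, ledger)`` where
    ``references`` maps contig id -> sequence string and ``ledger`` maps
    each candidate row (contig_id, position) to 'clean' or its class.
    """
    failures = {c: spec.planted_failures.get(c, 0) for c in FAILURE_CLASSES}
    spacing = 2 * window + 5
    margin = window + 5
    per_contig = max(1, (spec.contig_length - 2 * margin) // spacing + 1)
    n_clean_contigs = math.ceil(spec.n_clean_snps / per_contig) if spec.n_clean_snps else 0
    n_shared_contigs = failures["shared_homolog_hit"]
    n_single_contigs = sum(
        failures[c]
        for c in (
            "low_coverage",
            "parent_heterozygous",
            "both_parents_differ",
            "neither_parent_differs",
            "parent_indel",
            "no_homolog_hit",
        )
    )
    n_prox_contigs = math.ceil(failures["proximal_variant"] / 2)
    needed = n_clean_contigs + n_shared_contigs + n_single_contigs + n_prox_contigs
    if spec.n_contigs < needed:
        raise ValueError(
            f"infeasible packing: {needed} contigs required "
            f"({n_clean_contigs} for clean SNPs at {spacing}-bp spacing, "
            f"{n_single_contigs + n_shared_contigs + n_prox_contigs} for "
            f"planted failures) but n_contigs={spec.n_contigs}"
        )

    references: dict[str, str] = {}
    seqs: dict[str, np.ndarray] = {}
    rows: list[dict] = []
    ledger: dict[tuple[str, int], str] = {}
    homolog_of: dict[str, str | None] = {}
    contig_counter = 0
    homolog_counter = 0

    def new_contig() -> str:
        nonlocal contig_counter
        contig_counter += 1
        cid = f"CTG{contig_counter:04d}"
        seqs[cid] = _random_contig(_rng(spec.seed, 1, contig_counter), spec.contig_length)
        return cid

    def new_homolog() -> str:
        nonlocal homolog_counter
        homolog_counter += 1
        return f"HELI{homolog_counter:04d}"

    def add_snp_row(
        cid: str,
        pos: int,
        rng: np.random.Generator,
        *,
        depth1: int | None = None,
        depth2: int | None = None,
        parent_pattern: str = "one_divergent",
    ) -> dict:
        ref = str(seqs[cid][pos - 1])
        alt = _other_base(rng, ref)
        d1 = int(depth1 if depth1 is not None else rng.integers(min_coverage, 60))
        d2 = int(depth2 if depth2 is not None else rng.integers(min_coverage, 60))
        if parent_pattern == "one_divergent":
            diverging = int(rng.integers(1, 3))
            c1 = f"{alt}/{alt}" if diverging == 1 else f"{ref}/{ref}"
            c2 = f"{alt}/{alt}" if diverging == 2 else f"{ref}/{ref}"
        elif parent_pattern == "heterozygous":
            c1, c2 = f"{ref}/{alt}", f"{ref}/{ref}"
        elif parent_pattern == "both_differ":
            c1 = c2 = f"{alt}/{alt}"
        elif parent_pattern == "neither_differs":
            c1 = c2 = f"{ref}/{ref}"
        else:  # pragma: no cover
            raise AssertionError(parent_pattern)
        row = {
            "contig_id": cid,
            "position": pos,
            "reference_allele": ref,
            "parent1_call": c1,
            "parent2_call": c2,
            "depth_parent1": d1,
            "depth_parent2": d2,
            "is_indel": False,
        }
        rows.append(row)
        return row

    # clean SNPs packed onto dedicated contigs
    placed = 0
    while placed < spec.n_clean_snps:
        cid = new_contig()
        homolog_of[cid] = new_homolog()
        rng = _rng(spec.seed, 2, contig_counter)
        pos = margin
        while placed < spec.n_clean_snps and pos <= spec.contig_length - margin:
            add_snp_row(cid, pos, rng)
            ledger[(cid, pos)] = "clean"
            placed += 1
            pos += spacing

    # single-row failure classes, one contig each
    single_classes = {
        "low_coverage": {},
        "parent_heterozygous": {"parent_pattern": "heterozygous"},
        "both_parents_differ": {"parent_pattern": "both_differ"},
        "neither_parent_differs": {"parent_pattern": "neither_differs"},
    }
    for cls, kwargs in single_classes.items():
        for i in range(failures[cls]):
            cid = new_contig()
            homolog_of[cid] = new_homolog()
            rng = _rng(spec.seed, 3, contig_counter)
            pos = int(rng.integers(margin, spec.contig_length - margin))
            if cls == "low_coverage":
                which = int(rng.integers(1, 3))
                kwargs = {
                    "depth1": int(rng.integers(0, min_coverage)) if which == 1 else None,
                    "depth2": int(rng.integers(0, min_coverage)) if which == 2 else None,
                }
            add_snp_row(cid, pos, rng, **kwargs)
            ledger[(cid, pos)] = cls

    # parent_indel: clean SNP + companion indel record within the window
    for i in range(failures["parent_indel"]):
        cid = new_contig()
        homolog_of[cid] = new_homolog()
        rng = _rng(spec.seed, 4, contig_counter)
        pos = int(rng.integers(margin, spec.contig_length - margin))
        add_snp_row(cid, pos, rng)
        ledger[(cid, pos)] = "parent_indel"
        ipos = pos + int(rng.integers(1, window + 1)) * int(rng.choice([-1, 1]))
        which = int(rng.integers(1, 3))
        ins = f"+{_other_base(rng)}"
        rows.append(
            {
                "contig_id": cid,
                "position": ipos,
                "reference_allele": str(seqs[cid][ipos - 1]),
                "parent1_call": ins if which == 1 else "ref",
                "parent2_call": ins if which == 2 else "ref",
                "depth_parent1": int(rng.integers(min_coverage, 60)),
                "depth_parent2": int(rng.integers(min_coverage, 60)),
                "is_indel": True,
            }
        )

    # no_homolog_hit: clean SNP on a contig without a homolog
    for i in range(failures["no_homolog_hit"]):
        cid = new_contig()
        homolog_of[cid] = None
        rng = _rng(spec.seed, 5, contig_counter)
        pos = int(rng.integers(margin, spec.contig_length - margin))
        add_snp_row(cid, pos, rng)
        ledger[(cid, pos)] = "no_homolog_hit"

    # shared_homolog_hit: groups of contigs hitting the same homolog
    remaining = failures["shared_homolog_hit"]
    while remaining > 0:
        group = 3 if remaining == 3 else 2
        shared = new_homolog()
        for _ in range(group):
            cid = new_contig()
            homolog_of[cid] = shared
            rng = _rng(spec.seed, 6, contig_counter)
            pos = int(rng.integers(margin, spec.contig_length - margin))
            add_snp_row(cid, pos, rng)
            ledger[(cid, pos)] = "shared_homolog_hit"
        remaining -= group

    # proximal_variant: pairs (or one triple) of otherwise-clean SNPs
    remaining = failures["proximal_variant"]
    while remaining > 0:
        group = 3 if remaining == 3 else 2
        cid = new_contig()
        homolog_of[cid] = new_homolog()
        rng = _rng(spec.seed, 7, contig_counter)
        base = int(rng.integers(margin, spec.contig_length - margin - group * window))
        for j in range(group):
            pos = base + j * max(2, window // 2)
            add_snp_row(cid, pos, rng)
            ledger[(cid, pos)] = "proximal_variant"
        remaining -= group

    # variant-free padding contigs up to the requested count
    while contig_counter < spec.n_contigs:
        cid = new_contig()
        homolog_of[cid] = new_homolog()

    references = {cid: "".join(seq) for cid, seq in seqs.items()}
    table = pd.DataFrame(
        rows,
        columns=[
            "contig_id",
            "position",
            "reference_allele",
            "parent1_call",
            "parent2_call",
            "depth_parent1",
            "depth_parent2",
            "is_indel",
        ],
    )
    homology = pd.DataFrame(
        {
            "contig_id": list(homolog_of),
            "homolog_id": [homolog_of[c] for c in homolog_of],
        }
    )
    ledger_df = pd.DataFrame(
        {
            "contig_id": [c for c, _ in ledger],
            "position": [p for _, p in ledger],
            "planted_class": list(ledger.values()),
        }
    )
    return references, table, homology, ledger_df


# ---------------------------------------------------------------------
# Log-likelihood tables for the Evanno elbow


def simulate_loglik_table(
    k_max: int,
    elbow_k: int,
    seed: int,
    *,
    n_runs: int = 20,
    base_lnp: float = -15000.0,
    slope_before: float = 600.0,
    slope_after: float = 60.0,
    noise_sd: float = 10.0,
    sd_range: tuple[float, float] = (10.0, 30.0),
) -> pd.DataFrame:
    """Mean/SD log-likelihood per K with a slope change at ``elbow_k``.

    The mean curve is piecewise linear (steep up to the elbow, shallow
    after) plus small Gaussian noise; run-to-run SDs are positive.
    ``elbow_k`` must be interior (1 < elbow_k < k_max) because the
    second-difference statistic is undefined at the boundary.
    """
    if not (1 < elbow_k < k_max):
        raise ValueError(
            f"elbow_k={elbow_k} must be strictly inside (1, {k_max}); "
            "delta-K is undefined at boundary K"
        )
    rng = _rng(seed, 8)
    ks = np.arange(1, k_max + 1)
    mean = base_lnp + np.where(
        ks <= elbow_k,
        slope_before * ks,
        slope_before * elbow_k + slope_after * (ks - elbow_k),
    )
    mean = mean + rng.normal(0.0, noise_sd, size=k_max)
    sd = rng.uniform(*sd_range, size=k_max)
    return pd.DataFrame(
        {"K": ks, "mean_lnP": mean, "sd_lnP": sd, "n_runs": n_runs}
    )
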