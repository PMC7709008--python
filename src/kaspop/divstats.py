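"""Per-locus and per-accession diversity statistics for biallelic SNPs.

Closed forms (p = reference-allele frequency, q = 1 - p, N = called
individuals):

* expected heterozygosity He = 2pq, unbiased uHe = 2N/(2N-1) * He;
* observed heterozygosity Ho = n_het / N;
* Shannon index I = -(p ln p + q ln q), with 0 ln 0 := 0;
* effective allele number Ne = 1 / (p^2 + q^2) = 1 / (1 - He);
* polymorphism information content (Hildebrand / Botstein form for two
  alleles) PIC = 1 - (p^2 + q^2) - 2 p^2 q^2, maximal (0.375) at p = 0.5;
* fixation index F = (He - Ho) / He;
* theta under the stepwise mutation model (Ohta-Kimura back-transform)
  theta_H = 0.5 * ((1/(1-h))^2 - 1);
* island-model gene flow Nm = 0.25 (1 - F_ST) / F_ST.

The Hardy-Weinberg test is the exact conditional test: given the
observed allele counts, every compatible heterozygote count is
enumerated and the two-sided p-value sums the probabilities of
configurations no more probable than the observed one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import (
    GenotypeMatrix,
    HOM_REF,
    HET,
    HOM_ALT,
    MISSING,
)

__all__ = [
    "pic_biallelic",
    "hwe_exact",
    "theta_smm",
    "gene_flow_nm",
    "locus_diversity",
    "accession_summary",
    "private_alleles",
    "hwe_tier_table",
]


def pic_biallelic(p):
    """Polymorphism information content of a biallelic locus.

    PIC = 1 - (p^2 + q^2) - 2 p^2 q^2; equals He - 2 p^2 q^2 and is
    bounded by 0.375 (attained at p = 0.5). Accepts scalars or arrays.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency must lie in [0, 1]")
    q = 1.0 - p
    out = 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2
    return float(out) if out.ndim == 0 else out


def _hwe_log_probs(n_a: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of all heterozygote counts compatible with
    ``n_a`` copies of allele A among ``2n`` alleles (Levene/Haldane)."""
    n_b = 2 * n - n_a
    h_min = n_a % 2
    h_max = min(n_a, n_b)
    hs = np.arange(h_min, h_max + 1, 2)
    n_aa = (n_a - hs) // 2
    n_bb = (n_b - hs) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(hs + 1)
        - gammaln(n_bb + 1)
        + hs * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    return hs, logp


def hwe_exact(n_homref: int, n_het: int, n_homalt: int) -> tuple[float, str]:
    """Exact conditional Hardy-Weinberg test for one biallelic locus.

    Returns ``(p_value, direction)`` with direction 'excess' when the
    observed heterozygote count exceeds its conditional expectation
    given the allele counts (n_A n_B / (2n - 1)), 'deficit' when below,
    'none' for a monomorphic input (p = 1).
    """
    if min(n_homref, n_het, n_homalt) < 0 or (n_homref + n_het + n_homalt) == 0:
        raise ValueError("genotype counts must be >= 0 with at least one nonzero")
    n = n_homref + n_het + n_homalt
    n_a = 2 * n_homref + n_het
    n_b = 2 * n_homalt + n_het
    if n_a == 0 or n_b == 0:
        return 1.0, "none"
    hs, logp = _hwe_log_probs(n_a, n)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.searchsorted(hs, n_het)]
    p_value = float(probs[probs <= obs * (1 + 1e-12)].sum())
    expected = n_a * n_b / (2 * n - 1)
    if n_het > expected:
        direction = "excess"
    elif n_het < expected:
        direction = "deficit"
    else:
        direction = "none"
    return min(p_value, 1.0), direction


def theta_smm(h: float) -> float:
    """Mutation-drift theta back-transformed from heterozygosity under
    the stepwise mutation model: theta = 0.5 ((1/(1-h))^2 - 1)."""
    h = float(h)
    if not (0 <= h < 1):
        raise ValueError("heterozygosity must lie in [0, 1)")
    return 0.5 * ((1.0 / (1.0 - h)) ** 2 - 1.0)


def gene_flow_nm(fst: float) -> float:
    """Island-model gene-flow estimate Nm = 0.25 (1 - F_ST)/F_ST.

    Undefined (NaN) for F_ST <= 0 rather than infinite.
    """
    fst = float(fst)
    if fst <= 0 or fst > 1:
        return float("nan")
    return 0.25 * (1.0 - fst) / fst


def _shannon(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0) + np.where(
            (1 - p) > 0, (1 - p) * np.log(1 - p), 0.0
        )
    return -terms


def locus_diversity(
    matrix: GenotypeMatrix, accession: str | None = None
) -> pd.DataFrame:
    """Per-locus diversity table, overall or within one accession.

    Columns: Na, Ne, Ho, He, uHe, I, PIC, p, MAF, hwe_p, hwe_direction,
    n_called. Loci with zero called genotypes get NaN statistics and
    ``defined=False``.
    """
    calls = matrix.calls
    if accession is not None:
        calls = calls[matrix.sample_indices_of(accession)]
    called = calls != MISSING
    n_called = called.sum(axis=0)
    n_het = (calls == HET).sum(axis=0)
    n_rr = (calls == HOM_REF).sum(axis=0)
    n_aa = (calls == HOM_ALT).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, (2 * n_rr + n_het) / np.maximum(2 * n_called, 1), np.nan)
        q = 1 - p
        he = 2 * p * q
        uhe = np.where(n_called > 0, 2 * n_called / np.maximum(2 * n_called - 1, 1) * he, np.nan)
        ho = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
        ne = np.where(n_called > 0, 1.0 / (p**2 + q**2), np.nan)
    na = (( (2 * n_rr + n_het) > 0).astype(int) + ((2 * n_aa + n_het) > 0).astype(int))
    na = np.where(n_called > 0, na, 0)
    hwe_p = np.full(len(p), np.nan)
    hwe_dir = np.full(len(p), "none", dtype=object)
    for j in range(len(p)):
        if n_called[j] > 0:
            hwe_p[j], hwe_dir[j] = hwe_exact(int(n_rr[j]), int(n_het[j]), int(n_aa[j]))
    return pd.DataFrame(
        {
            "locus_id": matrix.locus_ids,
            "Na": na,
            "Ne": ne,
            "Ho": ho,
            "He": he,
            "uHe": uhe,
            "I": np.where(n_called > 0, _shannon(p), np.nan),
            "PIC": np.where(n_called > 0, pic_biallelic(np.nan_to_num(p, nan=0.0)), np.nan),
            "p": p,
            "MAF": np.minimum(p, q),
            "hwe_p": hwe_p,
            "hwe_direction": hwe_dir,
            "n_called": n_called,
            "defined": n_called > 0,
        }
    ).set_index("locus_id")


def accession_summary(
    matrix: GenotypeMatrix, f_convention: str = "mean_of_ratios"
) -> pd.DataFrame:
    """Per-accession diversity summary over the analysis loci.

    PPL is the percentage of loci with two observed alleles within the
    accession; I, Ho, He, uHe are means over *all* analysis loci
    (within-accession-monomorphic loci contribute zeros); F is by
    default the mean of per-locus (He - Ho)/He over loci with He > 0
    (the mean-of-ratios convention of GenAlEx), with
    ``f_convention='ratio_of_means'`` for 1 - mean(Ho)/mean(He);
    theta_H is the stepwise-mutation-model transform of the mean uHe.
    Accessions with fewer than 2 samples are flagged (``n < 2``) but
    still summarised.
    """
    if f_convention not in ("mean_of_ratios", "ratio_of_means"):
        raise ValueError(f"unknown F convention {f_convention!r}")
    rows = []
    for acc in matrix.accessions:
        stats = locus_diversity(matrix, accession=acc)
        defined = stats["defined"]
        he = stats.loc[defined, "He"]
        ho = stats.loc[defined, "Ho"]
        uhe = stats.loc[defined, "uHe"]
        shannon = stats.loc[defined, "I"]
        n_loci = int(defined.sum())
        ppl = 100.0 * (stats.loc[defined, "Na"] >= 2).mean() if n_loci else np.nan
        poly = he > 0
        if f_convention == "mean_of_ratios":
            f = ((he[poly] - ho[poly]) / he[poly]).mean() if poly.any() else np.nan
        else:
            f = 1 - ho.mean() / he.mean() if he.mean() > 0 else np.nan
        mean_uhe = uhe.mean() if n_loci else np.nan
        rows.append(
            {
                "accession": acc,
                "n": len(matrix.sample_indices_of(acc)),
                "PPL": ppl,
                "I": shannon.mean() if n_loci else np.nan,
                "Ho": ho.mean() if n_loci else np.nan,
                "He": he.mean() if n_loci else np.nan,
                "uHe": mean_uhe,
                "F": f,
                "theta_H": theta_smm(mean_uhe) if np.isfinite(mean_uhe) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("accession")


def private_alleles(matrix: GenotypeMatrix, grouping) -> pd.Series:
    """Count group-exclusive alleles per group.

    ``grouping`` is either a metadata column name (groups of
    accessions) or a mapping sample id -> group covering all samples.
    An allele is private to a group when it is observed in at least one
    called genotype of that group and in no other group.
    """
    if isinstance(grouping, str):
        col = matrix.metadata[grouping]
        group_of = {
            s: col[a] for s, a in zip(matrix.sample_ids, matrix.accession_of_sample)
        }
    else:
        group_of = dict(grouping)
    missing = [s for s in matrix.sample_ids if s not in group_of]
    if missing:
        raise ValueError(f"samples without a group: {missing[:5]}")
    groups = sorted(set(group_of.values()))
    counts = {g: 0 for g in groups}
    sample_groups = np.array([group_of[s] for s in matrix.sample_ids])
    for j in range(matrix.n_loci):
        col = matrix.calls[:, j]
        for allele_obs in (
            np.isin(col, [HOM_REF, HET]),  # reference allele observed
            np.isin(col, [HOM_ALT, HET]),  # alternate allele observed
        ):
            present = set(sample_groups[allele_obs])
            if len(present) == 1:
                counts[present.pop()] += 1
    return pd.Series(counts, name="private_alleles")


def hwe_tier_table(locus_stats: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate HWE deviation by direction and significance tier.

    Tiers: highly significant p <= 0.01, significant 0.01 < p <= 0.05
    (a p exactly at a boundary falls in the more significant tier),
    in_hwe p > 0.05. Percentages are of all defined loci.
    """
    stats = locus_stats[locus_stats.get("defined", True) == True]  # noqa: E712
    p = stats["hwe_p"].to_numpy()
    direction = stats["hwe_direction"].to_numpy()
    tier = np.where(p <= 0.01, "highly_significant", np.where(p <= 0.05, "significant", "in_hwe"))
    rows = []
    total = len(stats)
    for d in ("deficit", "excess"):
        for t in ("highly_significant", "significant"):
            k = int(((direction == d) & (tier == t)).sum())
            rows.append(
                {"direction": d, "tier": t, "n_loci": k,
                 "pct": round(100 * k / total, 1) if total else np.nan}
            )
    k = int((tier == "in_hwe").sum())
    rows.append({"direction": "none", "tier": "in_hwe", "n_loci": k,
                 "pct": round(100 * k / total, 1) if total else np.nan})
    return pd.DataFrame(rows)
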