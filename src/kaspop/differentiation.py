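"""F-statistics, AMOVA and pairwise F_ST across accessions.

Two estimator families are provided:

* Nei's heterozygosity-based F-statistics (the default): per locus,
  ``Hs`` is the within-accession expected heterozygosity 2 p_k q_k
  averaged over accessions weighted by called sample size, ``Ht`` the
  expected heterozygosity of the pooled allele frequencies, ``Ho`` the
  average observed heterozygosity; then ``F_IS = 1 - Ho/Hs``,
  ``F_ST = 1 - Hs/Ht``, ``F_IT = 1 - Ho/Ht`` and the multiplicative
  identity ``(1-F_IT) = (1-F_IS)(1-F_ST)`` holds exactly.  Overall
  values use the sums of the heterozygosity components across loci.
* Weir & Cockerham's variance-component estimators (option, used in
  cross-checks), with the usual a/b/c components per locus and the
  ratio-of-sums overall estimate.

AMOVA follows the genotypic-data convention with an intra-individual
level: each individual is expanded into its two allele vectors, the
squared distance between two allele vectors is the count of loci with
differing alleles (missing excluded pairwise), and sums of squares are
partitioned within individuals / among individuals within accessions /
among accessions (/ among groups when a hierarchy is given).  Variance
components come from the expected mean squares with unequal-sample-size
coefficients; significance from permutation schemes appropriate to each
level.  Phase is irrelevant under this distance: a heterozygote
contributes symmetrically whichever haplotype carries the alternate
allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, HET, MISSING

__all__ = [
    "nei_f_statistics",
    "weir_cockerham_fst",
    "amova",
    "pairwise_fst",
    "AmovaResult",
    "PairwiseFstResult",
]


# ---------------------------------------------------------------------
# Nei F-statistics


def nei_f_statistics(
    matrix: GenotypeMatrix, corrected: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Per-locus and overall Nei F-statistics.

    With ``corrected=True`` (default) the within- and total-gene
    diversities use the Nei-Chesser small-sample corrections:
    ``Hs`` multiplies each accession's 2 p_k q_k by 2n_k/(2n_k - 1),
    and ``Ht`` adds the ``Hs/(2 n~ r)`` term (n~ the harmonic-mean
    sample size, r the number of accessions), which removes the
    ~1/(2n) upward bias of the raw plug-in G_ST at small accession
    sizes.  ``corrected=False`` gives the plain 2 p_k q_k / 2 p q
    plug-in forms.

    Returns ``(per_locus, overall)``; loci monomorphic overall
    (``Ht = 0``) have undefined indices and are excluded from the
    overall sums.  In either form the multiplicative identity
    ``(1 - F_IT) = (1 - F_IS)(1 - F_ST)`` is exact.
    """
    accs = matrix.accessions
    if len(accs) < 1:
        raise ValueError("at least one accession required")
    calls = matrix.calls
    n_loci = matrix.n_loci
    hs = np.zeros(n_loci)
    ho = np.zeros(n_loci)
    weight = np.zeros(n_loci)
    n_ref_tot = np.zeros(n_loci)
    n_tot = np.zeros(n_loci)
    inv_n = np.zeros(n_loci)
    n_pops_called = np.zeros(n_loci)
    for acc in accs:
        sub = calls[matrix.sample_indices_of(acc)]
        called = sub != MISSING
        n_k = called.sum(axis=0)
        n_het = (sub == HET).sum(axis=0)
        n_ref = 2 * (sub == 0).sum(axis=0) + n_het
        with np.errstate(invalid="ignore", divide="ignore"):
            p_k = np.where(n_k > 0, n_ref / np.maximum(2 * n_k, 1), np.nan)
            h_k = 2 * p_k * (1 - p_k)
            if corrected:
                h_k = 2 * n_k / np.maximum(2 * n_k - 1, 1) * h_k
            hs += np.where(n_k > 0, n_k * h_k, 0.0)
            ho += np.where(n_k > 0, n_het, 0.0)
            inv_n += np.where(n_k > 0, 1.0 / np.maximum(n_k, 1), 0.0)
        weight += n_k
        n_ref_tot += n_ref
        n_tot += 2 * n_k
        n_pops_called += n_k > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        hs = np.where(weight > 0, hs / np.maximum(weight, 1), np.nan)
        ho = np.where(weight > 0, ho / np.maximum(weight, 1), np.nan)
        p_bar = np.where(n_tot > 0, n_ref_tot / np.maximum(n_tot, 1), np.nan)
        ht = 2 * p_bar * (1 - p_bar)
        if corrected:
            n_harm = n_pops_called / np.where(inv_n > 0, inv_n, 1.0)
            ht = ht + np.where(
                n_pops_called > 0,
                hs / np.maximum(2 * n_harm * n_pops_called, 1e-300),
                0.0,
            )
        fis = np.where(hs > 0, 1 - ho / np.where(hs > 0, hs, 1), np.nan)
        fst = np.where(ht > 0, 1 - hs / np.where(ht > 0, ht, 1), np.nan)
        fit = np.where(ht > 0, 1 - ho / np.where(ht > 0, ht, 1), np.nan)
    per_locus = pd.DataFrame(
        {
            "locus_id": matrix.locus_ids,
            "Ho": ho,
            "Hs": hs,
            "Ht": ht,
            "F_IS": fis,
            "F_ST": fst,
            "F_IT": fit,
        }
    ).set_index("locus_id")
    informative = ht > 0
    if informative.any():
        sho, shs, sht = ho[informative].sum(), hs[informative].sum(), ht[informative].sum()
        overall = {
            "F_IS": 1 - sho / shs if shs > 0 else float("nan"),
            "F_ST": 1 - shs / sht,
            "F_IT": 1 - sho / sht,
            "n_loci": int(informative.sum()),
        }
    else:
        overall = {"F_IS": float("nan"), "F_ST": float("nan"),
                   "F_IT": float("nan"), "n_loci": 0}
    return per_locus, overall


def weir_cockerham_fst(matrix: GenotypeMatrix) -> tuple[pd.DataFrame, float]:
    """Weir-Cockerham theta per locus and the overall ratio-of-sums."""
    accs = matrix.accessions
    r = len(accs)
    if r < 2:
        raise ValueError("Weir-Cockerham theta needs >= 2 accessions")
    calls = matrix.calls
    n_loci = matrix.n_loci
    n_i = np.zeros((r, n_loci))
    p_i = np.zeros((r, n_loci))
    h_i = np.zeros((r, n_loci))
    for k, acc in enumerate(accs):
        sub = calls[matrix.sample_indices_of(acc)]
        called = sub != MISSING
        n_k = called.sum(axis=0)
        n_het = (sub == HET).sum(axis=0)
        n_ref = 2 * (sub == 0).sum(axis=0) + n_het
        n_i[k] = n_k
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(n_k > 0, n_ref / np.maximum(2 * n_k, 1), np.nan)
            h_i[k] = np.where(n_k > 0, n_het / np.maximum(n_k, 1), np.nan)
    present = n_i > 0
    r_eff = present.sum(axis=0).astype(float)
    n_sum = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n_sum / r_eff
        n_c = (n_sum - (n_i**2).sum(axis=0) / n_sum) / (r_eff - 1)
        p_bar = np.nansum(n_i * p_i, axis=0) / n_sum
        s2 = np.nansum(n_i * (p_i - p_bar) ** 2, axis=0) / ((r_eff - 1) * n_bar)
        h_bar = np.nansum(n_i * h_i, axis=0) / n_sum
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - s2 * (r_eff - 1) / r_eff - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - s2 * (r_eff - 1) / r_eff
            - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2.0
        theta = np.where((a + b + c) != 0, a / (a + b + c), np.nan)
    per_locus = pd.DataFrame(
        {"locus_id": matrix.locus_ids, "a": a, "b": b, "c": c, "theta": theta}
    ).set_index("locus_id")
    denom = np.nansum(a + b + c)
    overall = float(np.nansum(a) / denom) if denom != 0 else float("nan")
    return per_locus, overall


# ---------------------------------------------------------------------
# AMOVA machinery


def _haplotype_distances(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Squared-distance matrix between all 2n allele vectors and the
    per-individual within-individual distance vector.

    ``D[i, j]`` counts loci with differing alleles between haplotypes i
    and j (haplotypes 2a and 2a+1 belong to individual a); loci missing
    in either haplotype are excluded pairwise.  The within-individual
    distance is simply the individual's count of heterozygous loci.
    """
    calls = matrix.calls
    n, n_loci = calls.shape
    hap = np.empty((2 * n, n_loci), dtype=np.int8)
    # allele split: hom_ref -> (0,0); het -> (0,1); hom_alt -> (1,1)
    hap[0::2] = np.where(calls == MISSING, -1, np.where(calls == 2, 1, 0))
    hap[1::2] = np.where(calls == MISSING, -1, np.where(calls >= 1, 1, 0))
    called = (hap >= 0)
    x0 = ((hap == 0) & called).astype(np.float32)
    x1 = ((hap == 1) & called).astype(np.float32)
    d = x0 @ x1.T + x1 @ x0.T
    w = (calls == HET).sum(axis=1).astype(float)
    return d, w


def _block_sum(d: np.ndarray) -> np.ndarray:
    """Aggregate a 2n x 2n haplotype matrix to n x n individual blocks."""
    n2 = d.shape[0]
    n = n2 // 2
    return d.reshape(n, 2, n, 2).sum(axis=(1, 3))


def _ss_groups(e: np.ndarray, groups: list[np.ndarray]) -> float:
    """Sum over groups of SS within group, from the individual-block
    matrix ``e`` (e[a, b] = sum of the four haplotype distances)."""
    total = 0.0
    for idx in groups:
        sub = e[np.ix_(idx, idx)]
        total += sub.sum() / (2.0 * (2 * len(idx)))
    return total


def _variance_coefficient(hap_counts: np.ndarray) -> float:
    n = hap_counts.sum()
    p = len(hap_counts)
    return (n - (hap_counts**2).sum() / n) / (p - 1)


@dataclass
class AmovaResult:
    """AMOVA table plus fixation indices and permutation p-values."""

    table: pd.DataFrame
    indices: dict[str, float]
    pvalues: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    seed: int | None = None
    negative_components: list[str] = field(default_factory=list)

    @property
    def fst(self) -> float:
        return self.indices.get("F_ST", float("nan"))


def _flat_components(
    e: np.ndarray, w: np.ndarray, pop_of: np.ndarray, n_pops: int
) -> tuple[float, float, float, dict[str, float]]:
    """Variance components (Va, Vb, Vc) of the three-level flat design
    given the individual-block matrix, within-individual distances and
    a population index per individual."""
    n_ind = len(pop_of)
    groups = [np.flatnonzero(pop_of == k) for k in range(n_pops)]
    sizes = np.array([len(g) for g in groups])
    hap_counts = 2 * sizes
    ss_wi = w.sum() / 2.0
    ss_wa = _ss_groups(e, groups)
    ss_total = e.sum() / (2.0 * (2 * n_ind))
    ss_ai = ss_wa - ss_wi
    ss_ap = ss_total - ss_wa
    df_ap = n_pops - 1
    df_ai = n_ind - n_pops
    df_wi = n_ind
    ms_wi = ss_wi / df_wi
    ms_ai = ss_ai / df_ai if df_ai > 0 else float("nan")
    ms_ap = ss_ap / df_ap if df_ap > 0 else float("nan")
    n_c = _variance_coefficient(hap_counts.astype(float)) if n_pops > 1 else float("nan")
    vc = ms_wi
    vb = (ms_ai - vc) / 2.0 if df_ai > 0 else float("nan")
    va = (ms_ap - ms_ai) / n_c if df_ap > 0 and df_ai > 0 else float("nan")
    ss = {"ap": ss_ap, "ai": ss_ai, "wi": ss_wi, "total": ss_total,
          "df_ap": df_ap, "df_ai": df_ai, "df_wi": df_wi}
    return va, vb, vc, ss


def _indices_from_components(va: float, vb: float, vc: float) -> dict[str, float]:
    total = va + vb + vc
    return {
        "F_ST": va / total if total != 0 else float("nan"),
        "F_IS": vb / (vb + vc) if (vb + vc) != 0 else float("nan"),
        "F_IT": (va + vb) / total if total != 0 else float("nan"),
    }


def _pair_within(
    rng: np.random.Generator, d: np.ndarray, hap_groups: list[np.ndarray]
) -> float:
    """SS within individuals after randomly re-pairing haplotypes
    within each group (the F_IS permutation scheme)."""
    total = 0.0
    for haps in hap_groups:
        perm = rng.permutation(haps)
        total += d[perm[0::2], perm[1::2]].sum()
    return total / 2.0


def amova(
    matrix: GenotypeMatrix,
    hierarchy: str | None = None,
    n_perm: int = 1023,
    seed: int | None = None,
) -> AmovaResult:
    """Analysis of molecular variance over accessions.

    ``hierarchy`` is None for the flat three-level design or the name of
    an accession-metadata column assigning accessions to groups (the
    four-level hierarchical design).  ``n_perm`` random permutations per
    level-appropriate scheme give p-values with floor
    ``1/(n_perm + 1)``; ``n_perm=0`` skips permutation testing.

    Negative variance components are reported as computed (listed in
    ``negative_components``), never clamped.
    """
    accs = matrix.accessions
    if len(accs) < 2:
        raise ValueError("AMOVA needs at least two accessions")
    d, w = _haplotype_distances(matrix)
    e = _block_sum(d)
    acc_index = {a: k for k, a in enumerate(accs)}
    pop_of = np.array([acc_index[a] for a in matrix.accession_of_sample])
    n_ind = matrix.n_samples
    n_pops = len(accs)
    rng = np.random.default_rng(seed)

    if hierarchy is None:
        va, vb, vc, ss = _flat_components(e, w, pop_of, n_pops)
        idx = _indices_from_components(va, vb, vc)
        pvals: dict[str, float] = {}
        if n_perm > 0:
            # F_ST: permute individuals among accessions
            count_fst = 0
            obs_fst = idx["F_ST"]
            for _ in range(n_perm):
                perm_pop = rng.permutation(pop_of)
                pva, pvb, pvc, _ = _flat_components(e, w, perm_pop, n_pops)
                stat = _indices_from_components(pva, pvb, pvc)["F_ST"]
                if stat >= obs_fst:
                    count_fst += 1
            pvals["F_ST"] = (count_fst + 1) / (n_perm + 1)
            # F_IS: re-pair haplotypes within accessions
            hap_groups = [
                np.concatenate([[2 * a, 2 * a + 1] for a in np.flatnonzero(pop_of == k)])
                for k in range(n_pops)
            ]
            ss_wa = ss["ai"] + ss["wi"]
            count_fis = 0
            obs_fis = idx["F_IS"]
            for _ in range(n_perm):
                ss_wi_p = _pair_within(rng, d, hap_groups)
                ms_wi = ss_wi_p / ss["df_wi"]
                ms_ai = (ss_wa - ss_wi_p) / ss["df_ai"]
                pvc = ms_wi
                pvb = (ms_ai - pvc) / 2.0
                stat = pvb / (pvb + pvc) if (pvb + pvc) != 0 else float("nan")
                if stat >= obs_fis:
                    count_fis += 1
            pvals["F_IS"] = (count_fis + 1) / (n_perm + 1)
            # F_IT: re-pair haplotypes over the whole sample and permute
            # the resulting individuals among accessions
            all_haps = np.arange(2 * n_ind)
            count_fit = 0
            obs_fit = idx["F_IT"]
            for _ in range(n_perm):
                perm = rng.permutation(all_haps)
                d_perm = d[np.ix_(perm, perm)]
                e_p = _block_sum(d_perm)
                w_p = d_perm[np.arange(0, 2 * n_ind, 2), np.arange(1, 2 * n_ind, 2)]
                pva, pvb, pvc, _ = _flat_components(e_p, w_p, pop_of, n_pops)
                stat = _indices_from_components(pva, pvb, pvc)["F_IT"]
                if stat >= obs_fit:
                    count_fit += 1
            pvals["F_IT"] = (count_fit + 1) / (n_perm + 1)

        total_var = va + vb + vc
        table = pd.DataFrame(
            [
                {
                    "source": "Among accessions",
                    "df": ss["df_ap"],
                    "sum_of_squares": ss["ap"],
                    "variance_component": va,
                    "pct_of_total": 100 * va / total_var if total_var else float("nan"),
                    "index": "F_ST",
                    "index_value": idx["F_ST"],
                    "p_value": pvals.get("F_ST", float("nan")),
                },
                {
                    "source": "Among individuals within accessions",
                    "df": ss["df_ai"],
                    "sum_of_squares": ss["ai"],
                    "variance_component": vb,
                    "pct_of_total": 100 * vb / total_var if total_var else float("nan"),
                    "index": "F_IS",
                    "index_value": idx["F_IS"],
                    "p_value": pvals.get("F_IS", float("nan")),
                },
                {
                    "source": "Within individuals",
                    "df": ss["df_wi"],
                    "sum_of_squares": ss["wi"],
                    "variance_component": vc,
                    "pct_of_total": 100 * vc / total_var if total_var else float("nan"),
                    "index": "F_IT",
                    "index_value": idx["F_IT"],
                    "p_value": pvals.get("F_IT", float("nan")),
                },
                {
                    "source": "Total",
                    "df": ss["df_ap"] + ss["df_ai"] + ss["df_wi"],
                    "sum_of_squares": ss["total"],
                    "variance_component": total_var,
                    "pct_of_total": 100.0,
                    "index": "",
                    "index_value": float("nan"),
                    "p_value": float("nan"),
                },
            ]
        )
        negatives = [
            name for name, v in zip(("Va", "Vb", "Vc"), (va, vb, vc)) if v < 0
        ]
        return AmovaResult(table, idx, pvals, n_perm, seed, negatives)

    # -- hierarchical design ------------------------------------------
    group_col = matrix.metadata[hierarchy]
    group_of_acc = {a: group_col[a] for a in accs}
    if any(pd.isna(g) for g in group_of_acc.values()):
        missing = [a for a, g in group_of_acc.items() if pd.isna(g)]
        raise ValueError(f"accessions without a {hierarchy!r} group: {missing}")
    groups_list = sorted(set(group_of_acc.values()))
    group_index = {g: i for i, g in enumerate(groups_list)}
    group_of_pop = np.array([group_index[group_of_acc[a]] for a in accs])
    comp = _hier_components(e, w, pop_of, n_pops, group_of_pop, len(groups_list))
    va, vb, vc, vd, ss = comp
    total_var = va + vb + vc + vd
    idx = {
        "F_CT": va / total_var if total_var else float("nan"),
        "F_SC": vb / (vb + vc + vd) if (vb + vc + vd) else float("nan"),
        "F_ST": (va + vb) / total_var if total_var else float("nan"),
        "F_IS": vc / (vc + vd) if (vc + vd) else float("nan"),
        "F_IT": (va + vb + vc) / total_var if total_var else float("nan"),
    }
    pvals = {}
    if n_perm > 0:
        # F_CT: permute whole accessions among groups
        count = 0
        for _ in range(n_perm):
            perm_groups = rng.permutation(group_of_pop)
            pva, pvb, pvc, pvd, _ = _hier_components(
                e, w, pop_of, n_pops, perm_groups, len(groups_list)
            )
            tot = pva + pvb + pvc + pvd
            stat = pva / tot if tot else float("nan")
            if stat >= idx["F_CT"]:
                count += 1
        pvals["F_CT"] = (count + 1) / (n_perm + 1)
        # F_SC: permute individuals among accessions within groups
        count = 0
        for _ in range(n_perm):
            perm_pop = pop_of.copy()
            for gi in range(len(groups_list)):
                pops_in_g = np.flatnonzero(group_of_pop == gi)
                members = np.flatnonzero(np.isin(pop_of, pops_in_g))
                perm_pop[members] = pop_of[rng.permutation(members)]
            pva, pvb, pvc, pvd, _ = _hier_components(
                e, w, perm_pop, n_pops, group_of_pop, len(groups_list)
            )
            denom = pvb + pvc + pvd
            stat = pvb / denom if denom else float("nan")
            if stat >= idx["F_SC"]:
                count += 1
        pvals["F_SC"] = (count + 1) / (n_perm + 1)
        # F_ST: permute individuals among all accessions
        count = 0
        for _ in range(n_perm):
            perm_pop = rng.permutation(pop_of)
            pva, pvb, pvc, pvd, _ = _hier_components(
                e, w, perm_pop, n_pops, group_of_pop, len(groups_list)
            )
            tot = pva + pvb + pvc + pvd
            stat = (pva + pvb) / tot if tot else float("nan")
            if stat >= idx["F_ST"]:
                count += 1
        pvals["F_ST"] = (count + 1) / (n_perm + 1)

    rows = [
        ("Among groups", ss["df_ag"], ss["ag"], va, "F_CT"),
        ("Among accessions within groups", ss["df_ap"], ss["ap"], vb, "F_SC"),
        ("Among individuals within accessions", ss["df_ai"], ss["ai"], vc, "F_IS"),
        ("Within individuals", ss["df_wi"], ss["wi"], vd, "F_IT"),
    ]
    table = pd.DataFrame(
        [
            {
                "source": src,
                "df": dfv,
                "sum_of_squares": ssv,
                "variance_component": v,
                "pct_of_total": 100 * v / total_var if total_var else float("nan"),
                "index": name,
                "index_value": idx[name],
                "p_value": pvals.get(name, float("nan")),
            }
            for src, dfv, ssv, v, name in rows
        ]
        + [
            {
                "source": "Total",
                "df": ss["df_ag"] + ss["df_ap"] + ss["df_ai"] + ss["df_wi"],
                "sum_of_squares": ss["total"],
                "variance_component": total_var,
                "pct_of_total": 100.0,
                "index": "",
                "index_value": float("nan"),
                "p_value": float("nan"),
            }
        ]
    )
    negatives = [
        name
        for name, v in zip(("Va", "Vb", "Vc", "Vd"), (va, vb, vc, vd))
        if v < 0
    ]
    return AmovaResult(table, idx, pvals, n_perm, seed, negatives)


def _hier_components(
    e: np.ndarray,
    w: np.ndarray,
    pop_of: np.ndarray,
    n_pops: int,
    group_of_pop: np.ndarray,
    n_groups: int,
):
    """Variance components of the four-level hierarchical design."""
    n_ind = len(pop_of)
    pop_groups = [np.flatnonzero(pop_of == k) for k in range(n_pops)]
    present = [k for k in range(n_pops) if len(pop_groups[k])]
    hap_pop = np.array([2 * len(pop_groups[k]) for k in present], dtype=float)
    grp_members = [
        np.flatnonzero(np.isin(pop_of, np.flatnonzero(group_of_pop == gi)))
        for gi in range(n_groups)
    ]
    ss_wi = w.sum() / 2.0
    ss_wa = _ss_groups(e, [pop_groups[k] for k in present])
    ss_wg = _ss_groups(e, [m for m in grp_members if len(m)])
    ss_total = e.sum() / (2.0 * (2 * n_ind))
    ss_ai = ss_wa - ss_wi
    ss_ap = ss_wg - ss_wa
    ss_ag = ss_total - ss_wg
    p_eff = len(present)
    df_ag = n_groups - 1
    df_ap = p_eff - n_groups
    df_ai = n_ind - p_eff
    df_wi = n_ind
    ms_wi = ss_wi / df_wi
    ms_ai = ss_ai / df_ai if df_ai > 0 else float("nan")
    ms_ap = ss_ap / df_ap if df_ap > 0 else float("nan")
    ms_ag = ss_ag / df_ag if df_ag > 0 else float("nan")
    n_hap = hap_pop.sum()
    grp_of_present = group_of_pop[present]
    hap_grp = np.array(
        [hap_pop[grp_of_present == gi].sum() for gi in range(n_groups)]
    )
    sum_sq_within_grp = sum(
        (hap_pop[grp_of_present == gi] ** 2).sum() / hap_grp[gi]
        for gi in range(n_groups)
        if hap_grp[gi] > 0
    )
    n1 = (n_hap - sum_sq_within_grp) / df_ap if df_ap > 0 else float("nan")
    n2 = (sum_sq_within_grp - (hap_pop**2).sum() / n_hap) / df_ag
    n3 = (n_hap - (hap_grp**2).sum() / n_hap) / df_ag
    vd = ms_wi
    vc = (ms_ai - vd) / 2.0 if df_ai > 0 else float("nan")
    vb = (ms_ap - ms_ai) / n1 if df_ap > 0 else float("nan")
    va = (ms_ag - ms_ai - n2 * vb) / n3 if df_ag > 0 else float("nan")
    ss = {
        "ag": ss_ag, "ap": ss_ap, "ai": ss_ai, "wi": ss_wi, "total": ss_total,
        "df_ag": df_ag, "df_ap": df_ap, "df_ai": df_ai, "df_wi": df_wi,
    }
    return va, vb, vc, vd, ss


# ---------------------------------------------------------------------
# Pairwise F_ST


@dataclass
class PairwiseFstResult:
    """Pairwise AMOVA F_ST between accessions.

    ``matrix`` holds pairwise F_ST off the diagonal and each accession's
    mean F_ST against all others on the diagonal (``diagonal='mean'``,
    the reporting convention) or zeros (``diagonal='zero'``).
    """

    ids: list[str]
    matrix: pd.DataFrame
    pvalues: pd.DataFrame
    significant: pd.DataFrame
    mean_fst: pd.Series
    alpha: float
    n_permutations: int

    @property
    def n_pairs(self) -> int:
        k = len(self.ids)
        return k * (k - 1) // 2


def pairwise_fst(
    matrix: GenotypeMatrix,
    n_perm: int = 1023,
    seed: int | None = None,
    alpha: float = 0.05,
    diagonal: str = "mean",
) -> PairwiseFstResult:
    """Two-accession AMOVA F_ST for every pair of accessions.

    For each of the k(k-1)/2 pairs the flat AMOVA is run on the two
    accessions' samples; significance is the F_ST permutation test at
    ``alpha``.  Pairs with no locus called in both accessions are
    flagged with NaN.
    """
    accs = matrix.accessions
    if len(accs) < 2:
        raise ValueError("pairwise F_ST needs >= 2 accessions")
    k = len(accs)
    fst = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    acc_arr = np.asarray(matrix.accession_of_sample)
    for i in range(k):
        for j in range(i + 1, k):
            keep = np.isin(acc_arr, [accs[i], accs[j]])
            sub = matrix.subset_samples(keep)
            shared = (
                ((sub.calls[np.asarray(sub.accession_of_sample) == accs[i]] != MISSING).any(axis=0))
                & ((sub.calls[np.asarray(sub.accession_of_sample) == accs[j]] != MISSING).any(axis=0))
            )
            if not shared.any():
                continue
            res = _pair_amova(sub, n_perm, rng)
            fst[i, j] = fst[j, i] = res[0]
            pval[i, j] = pval[j, i] = res[1]
    off = fst.copy()
    mean_fst = pd.Series(np.nanmean(off, axis=1), index=accs, name="mean_fst")
    if diagonal == "mean":
        np.fill_diagonal(fst, mean_fst.to_numpy())
    else:
        np.fill_diagonal(fst, 0.0)
    sig = pd.DataFrame(pval <= alpha, index=accs, columns=accs)
    np.fill_diagonal(sig.values, False)
    return PairwiseFstResult(
        ids=accs,
        matrix=pd.DataFrame(fst, index=accs, columns=accs),
        pvalues=pd.DataFrame(pval, index=accs, columns=accs),
        significant=sig,
        mean_fst=mean_fst,
        alpha=alpha,
        n_permutations=n_perm,
    )


def _pair_amova(
    sub: GenotypeMatrix, n_perm: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Flat AMOVA F_ST and its permutation p for a two-accession
    matrix (F_ST scheme only, for speed)."""
    d, w = _haplotype_distances(sub)
    e = _block_sum(d)
    accs = sub.accessions
    acc_index = {a: i for i, a in enumerate(accs)}
    pop_of = np.array([acc_index[a] for a in sub.accession_of_sample])
    va, vb, vc, _ = _flat_components(e, w, pop_of, len(accs))
    obs = _indices_from_components(va, vb, vc)["F_ST"]
    if n_perm <= 0:
        return obs, float("nan")
    count = 0
    for _ in range(n_perm):
        perm_pop = rng.permutation(pop_of)
        pva, pvb, pvc, _ = _flat_components(e, w, perm_pop, len(accs))
        stat = _indices_from_components(pva, pvb, pvc)["F_ST"]
        if stat >= obs:
            count += 1
    return obs, (count + 1) / (n_perm + 1)
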