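"""SNP pseudo-sequence distances, trees, ordination and the Evanno
elbow statistic.

Genotypes are re-expressed as one-character-per-locus pseudo-sequences
(hom-ref -> reference base, hom-alt -> alternate base, heterozygote ->
the two-base IUPAC ambiguity code, missing -> N).  The Tajima-Nei
distance corrects the mismatch proportion for unequal base composition:
over the compared sites of a pair,

    h = sum_{i<j} x_ij^2 / (2 g_i g_j)
    b = (1 - sum_i g_i^2 + p^2 / h) / 2
    d = -b ln(1 - p / b)

with p the mismatch proportion, g_i the base frequencies averaged over
the pair and x_ij the frequency of (i, j) site patterns.  At uniform
base composition this reduces exactly to the Jukes-Cantor distance.
Ambiguous characters and N are excluded pairwise by default (so
heterozygous sites do not enter the distance); an allele-sharing
alternative is exposed but non-default.

Neighbor joining is delegated to scikit-bio's implementation (exact on
additive matrices); PCoA is the classical Gower double-centering
eigendecomposition; the Evanno delta-K is the SD-standardised absolute
second difference of mean log-likelihood across cluster counts.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio

from .genotypes import GenotypeMatrix, HOM_REF, HET, HOM_ALT, MISSING

__all__ = [
    "encode_pseudosequences",
    "tajima_nei_distance",
    "distance_matrix",
    "accession_distance_matrix",
    "eaed",
    "neighbor_joining",
    "pcoa",
    "evanno_delta_k",
    "DistanceMatrix",
    "PcoaResult",
]

IUPAC_PAIR = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-pair site counts."""

    ids: list[str]
    values: np.ndarray
    n_sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.ids)
        if self.values.shape != (k, k):
            raise ValueError("distance matrix shape does not match ids")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def undefined_pairs(self) -> list[tuple[str, str]]:
        k = len(self.ids)
        return [
            (self.ids[i], self.ids[j])
            for i in range(k)
            for j in range(i + 1, k)
            if not np.isfinite(self.values[i, j])
        ]


def encode_pseudosequences(
    matrix: GenotypeMatrix,
    panel: pd.DataFrame,
    loci_subset: list[str] | None = None,
) -> dict[str, str]:
    """One pseudo-sequence per sample over the (optionally subset)
    loci, using the panel's reference/alternate bases.

    ``panel`` must carry ``locus_id``, ``reference_allele`` and
    ``alternate_allele`` for every encoded locus.
    """
    pan = panel.set_index("locus_id") if "locus_id" in panel.columns else panel
    loci = list(loci_subset) if loci_subset is not None else list(matrix.locus_ids)
    missing = [l for l in loci if l not in pan.index]
    if missing:
        raise KeyError(f"loci absent from the marker panel: {missing[:5]}")
    col_of = {l: i for i, l in enumerate(matrix.locus_ids)}
    chars = {}
    for locus in loci:
        ref = pan.at[locus, "reference_allele"]
        alt = pan.at[locus, "alternate_allele"]
        het = IUPAC_PAIR[frozenset((ref, alt))]
        chars[locus] = {HOM_REF: ref, HET: het, HOM_ALT: alt, MISSING: "N"}
    out = {}
    for i, sid in enumerate(matrix.sample_ids):
        row = matrix.calls[i]
        out[sid] = "".join(chars[l][int(row[col_of[l]])] for l in loci)
    return out


def _tn_from_arrays(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Tajima-Nei distance between two index-encoded sequences
    (indices 0-3 = ACGT, -1 = excluded). Returns (distance, n_sites)."""
    ok = (a >= 0) & (b >= 0)
    n = int(ok.sum())
    if n == 0:
        return float("nan"), 0
    aa, bb = a[ok], b[ok]
    mism = aa != bb
    p_hat = mism.mean()
    if p_hat == 0.0:
        return 0.0, n
    counts = np.bincount(aa, minlength=4) + np.bincount(bb, minlength=4)
    g = counts / (2.0 * n)
    # pair-mismatch frequencies over unordered base pairs
    h = 0.0
    pair_counts = np.zeros((4, 4))
    lo = np.minimum(aa[mism], bb[mism])
    hi = np.maximum(aa[mism], bb[mism])
    np.add.at(pair_counts, (lo, hi), 1)
    for i, j in itertools.combinations(range(4), 2):
        x_ij = pair_counts[i, j] / n
        if x_ij > 0:
            if g[i] == 0 or g[j] == 0:  # cannot happen if x_ij > 0
                continue
            h += x_ij**2 / (2.0 * g[i] * g[j])
    b_coef = 0.5 * (1.0 - float(g @ g) + p_hat**2 / h)
    if p_hat >= b_coef:
        return float("nan"), n
    return float(-b_coef * np.log(1.0 - p_hat / b_coef)), n


def _encode_for_distance(seq: str, mode: str) -> np.ndarray:
    """Map a pseudo-sequence to ACGT indices; ambiguity codes and N
    become -1 (pairwise exclusion) under the default mode."""
    if mode != "exclude_ambiguous":
        raise ValueError(f"unknown ambiguity mode {mode!r}")
    return np.array([_BASE_INDEX.get(c, -1) for c in seq], dtype=np.int8)


def tajima_nei_distance(seq_a: str, seq_b: str, mode: str = "exclude_ambiguous") -> float:
    """Tajima-Nei distance between two equal-length sequences.

    Sites where either character is N or an ambiguity code are excluded
    pairwise.  Returns NaN when no sites can be compared or when the
    log argument is non-positive (saturation), both flagged conditions.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    d, _ = _tn_from_arrays(
        _encode_for_distance(seq_a, mode), _encode_for_distance(seq_b, mode)
    )
    return d


def distance_matrix(
    sequences: dict[str, str], mode: str = "exclude_ambiguous"
) -> DistanceMatrix:
    """All pairwise Tajima-Nei distances over a set of sequences."""
    ids = list(sequences)
    enc = [_encode_for_distance(sequences[i], mode) for i in ids]
    k = len(ids)
    values = np.zeros((k, k))
    n_sites = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            d, n = _tn_from_arrays(enc[i], enc[j])
            values[i, j] = values[j, i] = d
            n_sites[i, j] = n_sites[j, i] = n
    return DistanceMatrix(ids=ids, values=values, n_sites=n_sites)


def accession_distance_matrix(
    matrix: GenotypeMatrix,
    panel: pd.DataFrame,
    loci_subset: list[str] | None = None,
    method: str = "average",
) -> DistanceMatrix:
    """Accession-level distances as averages of inter-accession
    individual Tajima-Nei distances.

    ``method='average'`` (default) is the plain mean over cross pairs;
    ``method='net'`` subtracts half the two within-accession means
    (net divergence d_A = d_XY - (d_X + d_Y)/2).
    """
    if method not in ("average", "net"):
        raise ValueError(f"unknown method {method!r}")
    seqs = encode_pseudosequences(matrix, panel, loci_subset)
    ind_dm = distance_matrix(seqs)
    idx_of = {s: i for i, s in enumerate(ind_dm.ids)}
    accs = matrix.accessions
    members = {
        a: [idx_of[matrix.sample_ids[i]] for i in matrix.sample_indices_of(a)]
        for a in accs
    }
    k = len(accs)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            block = ind_dm.values[np.ix_(members[accs[i]], members[accs[j]])]
            d = float(np.nanmean(block))
            if method == "net":
                d -= 0.5 * (
                    _within_mean(ind_dm.values, members[accs[i]])
                    + _within_mean(ind_dm.values, members[accs[j]])
                )
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=accs, values=values)


def _within_mean(d: np.ndarray, idx: list[int]) -> float:
    if len(idx) < 2:
        return 0.0
    sub = d[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(np.nanmean(sub[iu]))


# ---------------------------------------------------------------------
# EAED: average evolutionary divergence within accessions


def eaed(
    matrix: GenotypeMatrix,
    panel: pd.DataFrame,
    max_missing: float = 0.07,
    maf_threshold: float = 0.3,
) -> pd.DataFrame:
    """Within-accession mean pairwise Tajima-Nei divergence, overall
    and partitioned by minor-allele-frequency class.

    Samples with more than ``max_missing`` missing calls are excluded
    first.  EAED1 uses all loci; EAED2 the loci with overall MAF >=
    ``maf_threshold`` (allele frequency between 0.3 and 0.7); EAED3 the
    loci with MAF below it.  Every locus contributes to exactly one of
    EAED2/EAED3.  Accessions left with fewer than two samples get NaN
    (not computable).
    """
    missing_frac = (matrix.calls == MISSING).mean(axis=1)
    kept = matrix.subset_samples(missing_frac <= max_missing)
    from .genotypes import allele_frequencies

    freqs = allele_frequencies(matrix, scope="overall")
    maf = freqs["maf"].reindex(matrix.locus_ids).to_numpy()
    subsets = {
        "EAED1": list(matrix.locus_ids),
        "EAED2": [l for l, m in zip(matrix.locus_ids, maf) if m >= maf_threshold],
        "EAED3": [l for l, m in zip(matrix.locus_ids, maf) if m < maf_threshold],
    }
    rows = {}
    for name, loci in subsets.items():
        col = {}
        if loci:
            seqs = encode_pseudosequences(kept, panel, loci)
        for acc in matrix.accessions:
            idx = kept.sample_indices_of(acc)
            if len(idx) < 2 or not loci:
                col[acc] = float("nan")
                continue
            ids = [kept.sample_ids[i] for i in idx]
            sub = distance_matrix({s: seqs[s] for s in ids})
            pair_vals = sub.values[np.triu_indices(len(ids), k=1)]
            defined = pair_vals[np.isfinite(pair_vals)]
            col[acc] = float(defined.mean()) if defined.size else float("nan")
        rows[name] = col
    out = pd.DataFrame(rows)
    out.index.name = "accession"
    out["n_retained"] = [
        len(kept.sample_indices_of(a)) for a in out.index
    ]
    return out


# ---------------------------------------------------------------------
# Neighbor joining


def _sanitize(label: str) -> str:
    return re.sub(r"\s+", "_", label.strip())


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = False):
    """Neighbor-joining tree from a distance matrix.

    Ties in the Q criterion break deterministically by lexicographic id
    order (ids are sorted before agglomeration). Negative branch
    lengths are retained (and reported via the returned ``flags``)
    unless ``clamp_negative`` is set.  Returns ``(tree, newick,
    flags)`` with ``tree`` a ``skbio.TreeNode``.
    """
    undefined = dm.undefined_pairs()
    if undefined:
        raise ValueError(f"undefined distances for pairs: {undefined[:5]}")
    order = np.argsort([_sanitize(i) for i in dm.ids], kind="stable")
    ids = [_sanitize(dm.ids[i]) for i in order]
    values = dm.values[np.ix_(order, order)]
    if len(ids) < 2:
        raise ValueError("at least two ids required")
    if len(ids) == 2:
        newick = f"({ids[0]}:{values[0, 1] / 2:g},{ids[1]}:{values[0, 1] / 2:g});"
        tree = skbio.TreeNode.read([newick])
        return tree, newick, {"negative_branch_lengths": False}
    sk_dm = skbio.DistanceMatrix(values, ids=ids)
    tree = skbio.tree.nj(sk_dm, neg_as_zero=False)
    has_negative = any(
        n.length is not None and n.length < 0 for n in tree.traverse()
    )
    if clamp_negative and has_negative:
        for n in tree.traverse():
            if n.length is not None and n.length < 0:
                n.length = 0.0
    newick = str(tree)
    return tree, newick.strip(), {"negative_branch_lengths": has_negative}


# ---------------------------------------------------------------------
# Principal coordinate analysis


@dataclass
class PcoaResult:
    ids: list[str]
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    pct_variance: np.ndarray  # per returned axis, of the positive spectrum


def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> PcoaResult:
    """Classical metric ordination of a distance matrix.

    Gower double-centering of -d^2/2, eigendecomposition, axes ordered
    by eigenvalue.  Percent variance uses the sum of *positive*
    eigenvalues as denominator; negative eigenvalues are reported in
    ``eigenvalues`` but excluded from axes.  Requested axes beyond the
    positive spectrum are truncated.
    """
    if not np.all(np.isfinite(dm.values)):
        raise ValueError("distance matrix contains undefined entries")
    d2 = dm.values**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10, 1e-10 * abs(eigvals[0])) if n else 0.0
    positive = eigvals > tol
    n_pos = int(positive.sum())
    k = min(n_axes, n_pos)
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    pct = 100.0 * eigvals[:k] / eigvals[positive].sum() if n_pos else np.array([])
    return PcoaResult(
        ids=list(dm.ids),
        coordinates=pd.DataFrame(
            coords, index=dm.ids, columns=[f"PCo{i + 1}" for i in range(k)]
        ),
        eigenvalues=eigvals,
        pct_variance=np.asarray(pct),
    )


# ---------------------------------------------------------------------
# Evanno delta-K


def evanno_delta_k(table: pd.DataFrame) -> pd.DataFrame:
    """Second-difference elbow statistic on clustering log-likelihoods.

    ``table`` needs columns K, mean_lnP, sd_lnP with consecutive K.
    For each interior K: L'(K) = mean_lnP(K) - mean_lnP(K-1), |L''(K)| =
    |mean_lnP(K+1) - 2 mean_lnP(K) + mean_lnP(K-1)|, delta_K =
    |L''(K)| / sd_lnP(K).  The optimal K is the argmax of delta_K over
    interior K with sd > 0; rows with sd = 0 are excluded with a
    warning.  The result carries ``optimal_k`` in ``.attrs``.
    """
    t = table.sort_values("K").reset_index(drop=True)
    ks = t["K"].to_numpy()
    if len(ks) < 3:
        raise ValueError("delta-K needs at least three consecutive K values")
    if not np.all(np.diff(ks) == 1):
        raise ValueError("K values must be consecutive integers")
    mean = t["mean_lnP"].to_numpy(dtype=float)
    sd = t["sd_lnP"].to_numpy(dtype=float)
    lprime = np.diff(mean)  # L'(K) for K = ks[1:]
    lsecond = np.abs(np.diff(mean, 2))  # |L''(K)| for interior K
    interior = ks[1:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(sd[1:-1] > 0, lsecond / sd[1:-1], np.nan)
    if np.any(sd[1:-1] <= 0):
        import warnings

        warnings.warn(
            "delta-K undefined at interior K with sd_lnP = 0; excluded from argmax",
            stacklevel=2,
        )
    out = pd.DataFrame(
        {
            "K": interior,
            "L_prime": lprime[:-1],
            "abs_L_second": lsecond,
            "delta_K": delta,
        }
    )
    if np.all(np.isnan(delta)):
        out.attrs["optimal_k"] = None
    else:
        out.attrs["optimal_k"] = int(interior[np.nanargmax(delta)])
    return out
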