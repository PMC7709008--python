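"""Canonical genotype-matrix data model, I/O and the QC ladder.

The matrix holds unphased diploid calls at biallelic SNP loci, coded
relative to the marker panel's reference/alternate alleles:

* ``0`` hom-ref (``0/0``), ``1`` het (``0/1``), ``2`` hom-alt (``1/1``),
  ``-1`` missing (``./.``).

Every sample belongs to an accession (a seed lot from one collection
site); accession-level metadata (geographic region at two granularities,
altitude class, landrace/cultivar/breeding type) drives grouped analyses.

The QC ladder mirrors a KASP genotyping campaign: loci that produced no
calls at all are *failed*; loci where only one allele was ever observed
are *monomorphic*; polymorphic loci with too much missing data are
dropped before analysis.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

CALL_TOKENS = {"0/0": HOM_REF, "0/1": HET, "1/1": HOM_ALT, "./.": MISSING}
CODE_TOKENS = {v: k for k, v in CALL_TOKENS.items()}

METADATA_COLUMNS = ["region6", "region2", "altitude_class", "type"]
ACCESSION_TYPES = {"landrace", "cultivar", "breeding"}


class GenotypeMatrixError(ValueError):
    """Raised on malformed genotype or metadata inputs."""


@dataclass
class GenotypeMatrix:
    """Samples x loci matrix of biallelic genotype calls.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row.
    accession_of_sample : list of str
        Accession label per sample (parallel to ``sample_ids``).
    locus_ids : list of str
        Unique locus identifiers, one per column.
    calls : ndarray of int8, shape (n_samples, n_loci)
        Genotype codes (0/1/2/-1).
    metadata : DataFrame
        Indexed by accession, columns ``region6, region2,
        altitude_class, type``; must cover every accession present.
    """

    sample_ids: list[str]
    accession_of_sample: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        ns, nl = len(self.sample_ids), len(self.locus_ids)
        if self.calls.shape != (ns, nl):
            raise GenotypeMatrixError(
                f"calls shape {self.calls.shape} does not match "
                f"{ns} samples x {nl} loci"
            )
        if len(self.accession_of_sample) != ns:
            raise GenotypeMatrixError("one accession label required per sample")
        if len(set(self.sample_ids)) != ns:
            raise GenotypeMatrixError("duplicate sample ids")
        if len(set(self.locus_ids)) != nl:
            raise GenotypeMatrixError("duplicate locus ids")
        bad = ~np.isin(self.calls, [HOM_REF, HET, HOM_ALT, MISSING])
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise GenotypeMatrixError(
                f"invalid call code {self.calls[i, j]} at sample "
                f"{self.sample_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )
        if len(self.metadata):
            missing = set(self.accession_of_sample) - set(self.metadata.index)
            if missing:
                raise GenotypeMatrixError(
                    f"accessions without metadata: {sorted(missing)}"
                )

    # -- basic views ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def accessions(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.accession_of_sample:
            seen.setdefault(a)
        return list(seen)

    def sample_indices_of(self, accession: str) -> np.ndarray:
        acc = np.asarray(self.accession_of_sample)
        return np.flatnonzero(acc == accession)

    def subset_loci(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            accession_of_sample=list(self.accession_of_sample),
            locus_ids=[self.locus_ids[i] for i in keep],
            calls=self.calls[:, keep].copy(),
            metadata=self.metadata,
        )

    def subset_samples(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in keep],
            accession_of_sample=[self.accession_of_sample[i] for i in keep],
            locus_ids=list(self.locus_ids),
            calls=self.calls[keep, :].copy(),
            metadata=self.metadata,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.accession_of_sample == other.accession_of_sample
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls)
        )


# -- I/O ---------------------------------------------------------------
#
# Canonical CSV dialect: first column sample id, second column accession,
# one column per locus with tokens 0/0, 0/1, 1/1, ./.


def write_genotype_csv(matrix: GenotypeMatrix, path) -> None:
    buf = io.StringIO()
    buf.write("sample_id,accession," + ",".join(matrix.locus_ids) + "\n")
    for i, (sid, acc) in enumerate(
        zip(matrix.sample_ids, matrix.accession_of_sample)
    ):
        tokens = [CODE_TOKENS[int(c)] for c in matrix.calls[i]]
        buf.write(f"{sid},{acc}," + ",".join(tokens) + "\n")
    with open(path, "w", newline="") as fh:
        fh.write(buf.getvalue())


def write_metadata_csv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, index_label="accession")


def load_metadata_csv(path) -> pd.DataFrame:
    md = pd.read_csv(path, dtype=str).set_index("accession")
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise GenotypeMatrixError(f"metadata file lacks columns: {missing}")
    bad = set(md["type"]) - ACCESSION_TYPES
    if bad:
        raise GenotypeMatrixError(f"unknown accession types: {sorted(bad)}")
    return md


def load_genotype_matrix(path, metadata_path=None) -> GenotypeMatrix:
    """Read the canonical genotype CSV (and optional metadata CSV).

    Round-trips byte-identically with :func:`write_genotype_csv`.
    Unknown call tokens and ragged rows are rejected with the offending
    row/column named.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        if header[:2] != ["sample_id", "accession"]:
            raise GenotypeMatrixError(
                f"{path}: expected header starting 'sample_id,accession'"
            )
        locus_ids = header[2:]
        sample_ids: list[str] = []
        accessions: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(",")
            if len(parts) != len(header):
                raise GenotypeMatrixError(
                    f"{path}:{lineno}: ragged row ({len(parts)} fields, "
                    f"expected {len(header)})"
                )
            sample_ids.append(parts[0])
            accessions.append(parts[1])
            row = []
            for j, tok in enumerate(parts[2:]):
                try:
                    row.append(CALL_TOKENS[tok])
                except KeyError:
                    raise GenotypeMatrixError(
                        f"{path}:{lineno}: invalid call token {tok!r} at "
                        f"locus {locus_ids[j]!r}"
                    ) from None
            rows.append(row)
    metadata = load_metadata_csv(metadata_path) if metadata_path else pd.DataFrame()
    return GenotypeMatrix(
        sample_ids=sample_ids,
        accession_of_sample=accessions,
        locus_ids=locus_ids,
        calls=np.asarray(rows, dtype=np.int8).reshape(len(sample_ids), len(locus_ids)),
        metadata=metadata,
    )


def load_vcf_genotypes(path, metadata_path=None,
                       accession_of_sample: dict[str, str] | None = None
                       ) -> GenotypeMatrix:
    """GT-only import of an uncompressed VCF onto the same call model.

    Only biallelic records are accepted; phase separators are ignored.
    Accession labels come from ``accession_of_sample`` (sample id ->
    accession), defaulting to the sample id itself.
    """
    locus_ids: list[str] = []
    columns: list[list[int]] = []
    samples: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:
                raise GenotypeMatrixError(
                    f"{path}: multi-allelic record {chrom}:{pos} not supported"
                )
            locus_ids.append(vid if vid != "." else f"{chrom}_{pos}")
            fmt = fields[8].split(":")
            gt_idx = fmt.index("GT")
            col = []
            for cell in fields[9:]:
                gt = cell.split(":")[gt_idx].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles:
                    col.append(MISSING)
                else:
                    col.append(sum(int(a) for a in alleles))
            columns.append(col)
    calls = np.asarray(columns, dtype=np.int8).T
    accmap = accession_of_sample or {}
    metadata = load_metadata_csv(metadata_path) if metadata_path else pd.DataFrame()
    return GenotypeMatrix(
        sample_ids=samples,
        accession_of_sample=[accmap.get(s, s) for s in samples],
        locus_ids=locus_ids,
        calls=calls,
        metadata=metadata,
    )


# -- QC ladder ---------------------------------------------------------


def classify_loci(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Classify every locus as failed / monomorphic / polymorphic.

    failed: all calls missing. monomorphic: at least one call but a
    single allele observed. polymorphic: both alleles observed (a single
    heterozygote suffices). Also reports the missing-call fraction and
    the minor-allele frequency over called genotypes.
    """
    calls = matrix.calls
    n = matrix.n_samples
    called = calls != MISSING
    n_called = called.sum(axis=0)
    n_het = (calls == HET).sum(axis=0)
    n_ref = 2 * (calls == HOM_REF).sum(axis=0) + n_het
    n_tot = 2 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_tot > 0, n_ref / np.maximum(n_tot, 1), np.nan)
    maf = np.minimum(p, 1 - p)
    has_ref = n_ref > 0
    has_alt = (n_tot - n_ref) > 0
    status = np.where(
        n_called == 0,
        "failed",
        np.where(has_ref & has_alt, "polymorphic", "monomorphic"),
    )
    return pd.DataFrame(
        {
            "locus_id": matrix.locus_ids,
            "status": status,
            "missing_fraction": (n - n_called) / n,
            "maf": maf,
        }
    ).set_index("locus_id")


def classification_summary(classification: pd.DataFrame) -> dict:
    """Count arithmetic of the QC ladder, percentages to one decimal.

    ``success_rate_pct`` = non-failed / assayed; ``polymorphic_pct`` and
    ``monomorphic_pct`` are relative to successfully genotyped loci.
    """
    total = len(classification)
    counts = classification["status"].value_counts()
    failed = int(counts.get("failed", 0))
    mono = int(counts.get("monomorphic", 0))
    poly = int(counts.get("polymorphic", 0))
    genotyped = total - failed
    return {
        "assayed": total,
        "failed": failed,
        "genotyped": genotyped,
        "monomorphic": mono,
        "polymorphic": poly,
        "success_rate_pct": round(100 * genotyped / total, 1) if total else float("nan"),
        "monomorphic_pct": round(100 * mono / genotyped, 1) if genotyped else float("nan"),
        "polymorphic_pct": round(100 * poly / genotyped, 1) if genotyped else float("nan"),
    }


def filter_loci(
    matrix: GenotypeMatrix,
    classification: pd.DataFrame | None = None,
    max_missing_fraction: float = 0.10,
) -> GenotypeMatrix:
    """Keep polymorphic loci whose missingness does not exceed the cap.

    The cap is a strict bound: a locus with missing fraction exactly
    ``max_missing_fraction`` is kept; only strictly greater is dropped.
    Column order is preserved; the operation is idempotent.
    """
    if classification is None:
        classification = classify_loci(matrix)
    cls = classification.loc[matrix.locus_ids]
    keep = (cls["status"] == "polymorphic").to_numpy() & (
        cls["missing_fraction"].to_numpy() <= max_missing_fraction
    )
    return matrix.subset_loci(keep)


def allele_frequencies(matrix: GenotypeMatrix, scope: str = "overall") -> pd.DataFrame:
    """Reference-allele frequency per locus, overall or per accession.

    p = (2 n_homref + n_het) / (2 n_called); loci with zero called
    genotypes in scope get NaN frequencies and ``defined=False``.
    """
    if scope not in ("overall", "per_accession"):
        raise ValueError(f"unknown scope {scope!r}")

    def _freqs(calls: np.ndarray) -> pd.DataFrame:
        called = calls != MISSING
        n_called = called.sum(axis=0)
        n_het = (calls == HET).sum(axis=0)
        n_ref = 2 * (calls == HOM_REF).sum(axis=0) + n_het
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_called > 0, n_ref / np.maximum(2 * n_called, 1), np.nan)
        return pd.DataFrame(
            {
                "locus_id": matrix.locus_ids,
                "p": p,
                "q": 1 - p,
                "maf": np.minimum(p, 1 - p),
                "n_called": n_called,
                "defined": n_called > 0,
            }
        )

    if scope == "overall":
        return _freqs(matrix.calls).set_index("locus_id")
    frames = []
    for acc in matrix.accessions:
        sub = _freqs(matrix.calls[matrix.sample_indices_of(acc)])
        sub.insert(0, "accession", acc)
        frames.append(sub)
    return pd.concat(frames, ignore_index=True).set_index(["accession", "locus_id"])


def select_complete_individuals(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Retain samples with zero missing calls across the current loci."""
    complete = (matrix.calls != MISSING).all(axis=1)
    if not complete.any():
        warnings.warn("no sample has complete genotype data", stacklevel=2)
    return matrix.subset_samples(complete)
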