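"""SNP candidate filtering cascade and KASP flank extraction.

Input is a per-contig, per-position table of two-parent calls against
reference transcript contigs (1-based, fully closed coordinates), plus a
contig -> homolog mapping from a BLAST search against a related genome.
Candidate SNPs must survive seven rules before assay design:

1.  read depth >= ``min_coverage`` in both parents;
2.  both parents homozygous;
3.  the contig has a homolog hit;
4.  exactly one parent's allele differs from the reference;
5.  no other varying site within ``proximity_window`` bases on either
    side on the same contig (computed on the full pre-filtering row set:
    a nearby variant disturbs the assay whether or not it survives);
6.  no parental indel record at or within ``proximity_window`` of the
    site;
7.  the contig's homolog is not shared with another contig (close
    paralogs).

Rules 1-4 and 6 are per-row predicates; rule 5 operates on the row set
and rule 7 on the homology map, so the stage order is part of the
contract.  A per-stage attrition report is always returned.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

_CALL_RE = re.compile(r"^([ACGT])/([ACGT])$")

STAGE_NAMES = [
    "min_coverage",
    "parents_homozygous",
    "homolog_hit",
    "single_parent_divergent",
    "no_proximal_variant",
    "no_indel_near",
    "unique_homolog",
]


@dataclass(frozen=True)
class FilterConfig:
    min_coverage: int = 6
    proximity_window: int = 10


def _parse_call(call: str) -> tuple[str, str] | None:
    """Return the two allele characters of a diploid base call, or None
    for indel/other tokens."""
    m = _CALL_RE.match(str(call))
    return (m.group(1), m.group(2)) if m else None


def apply_filter_cascade(
    table: pd.DataFrame,
    homology: pd.DataFrame,
    config: FilterConfig = FilterConfig(),
    stage_order: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the seven-rule cascade; return (marker panel, stage report).

    ``table`` columns: contig_id, position, reference_allele,
    parent1_call, parent2_call, depth_parent1, depth_parent2 and
    optionally is_indel (rows flagged True are indel records: they are
    not candidates, feed rule 6, and are excluded from rule 5's varying
    set).  ``homology`` columns: contig_id, homolog_id (null = no hit).

    The panel has one row per surviving locus: locus_id, contig_id,
    position, reference_allele, alternate_allele, diverging_parent.
    The report records rows_in / rows_removed / rows_out per stage.
    """
    table = table.copy()
    if "is_indel" not in table.columns:
        table["is_indel"] = False
    dup = table.duplicated(subset=["contig_id", "position"])
    if dup.any():
        offender = table.loc[dup, ["contig_id", "position"]].iloc[0]
        raise ValueError(
            f"duplicate variant row at {offender.contig_id}:{offender.position}"
        )

    homolog_of = dict(zip(homology["contig_id"], homology["homolog_id"]))
    unmapped = set(table["contig_id"]) - set(homolog_of)
    if unmapped:
        logger.warning(
            "%d contig(s) absent from the homology map; treated as no hit: %s",
            len(unmapped), ", ".join(sorted(unmapped)[:5]),
        )

    hom_counts: dict[str, int] = {}
    for h in homolog_of.values():
        if pd.notna(h) and h is not None:
            hom_counts[h] = hom_counts.get(h, 0) + 1

    candidates = table[~table["is_indel"].astype(bool)].reset_index(drop=True)
    indels = table[table["is_indel"].astype(bool)]

    # rule 5 neighbourhood: pre-filter varying (non-indel) rows
    parsed1 = candidates["parent1_call"].map(_parse_call)
    parsed2 = candidates["parent2_call"].map(_parse_call)

    def _varies(row_idx: int) -> bool:
        ref = candidates.at[row_idx, "reference_allele"]
        for parsed in (parsed1[row_idx], parsed2[row_idx]):
            if parsed is None or set(parsed) != {ref}:
                return True
        return False

    varying = candidates.index[[_varies(i) for i in candidates.index]]
    varying_pos: dict[str, list[int]] = {}
    for i in varying:
        varying_pos.setdefault(candidates.at[i, "contig_id"], []).append(
            int(candidates.at[i, "position"])
        )
    indel_pos: dict[str, list[int]] = {}
    for _, r in indels.iterrows():
        indel_pos.setdefault(r["contig_id"], []).append(int(r["position"]))

    w = config.proximity_window

    def stage_min_coverage(df: pd.DataFrame) -> pd.Series:
        return (df["depth_parent1"] >= config.min_coverage) & (
            df["depth_parent2"] >= config.min_coverage
        )

    def stage_parents_homozygous(df: pd.DataFrame) -> pd.Series:
        def ok(i: int) -> bool:
            a, b = parsed1[i], parsed2[i]
            return a is not None and b is not None and a[0] == a[1] and b[0] == b[1]

        return pd.Series([ok(i) for i in df.index], index=df.index)

    def stage_homolog_hit(df: pd.DataFrame) -> pd.Series:
        return df["contig_id"].map(
            lambda c: pd.notna(homolog_of.get(c)) and homolog_of.get(c) is not None
        )

    def stage_single_parent_divergent(df: pd.DataFrame) -> pd.Series:
        def ok(i: int) -> bool:
            ref = df.at[i, "reference_allele"]
            a, b = parsed1[i], parsed2[i]
            if a is None or b is None:
                return False
            d1, d2 = set(a) != {ref}, set(b) != {ref}
            return d1 != d2  # exactly one parent diverges

        return pd.Series([ok(i) for i in df.index], index=df.index)

    def stage_no_proximal_variant(df: pd.DataFrame) -> pd.Series:
        def ok(i: int) -> bool:
            c, p = df.at[i, "contig_id"], int(df.at[i, "position"])
            return not any(
                q != p and abs(q - p) <= w for q in varying_pos.get(c, ())
            )

        return pd.Series([ok(i) for i in df.index], index=df.index)

    def stage_no_indel_near(df: pd.DataFrame) -> pd.Series:
        def ok(i: int) -> bool:
            c, p = df.at[i, "contig_id"], int(df.at[i, "position"])
            return not any(abs(q - p) <= w for q in indel_pos.get(c, ()))

        return pd.Series([ok(i) for i in df.index], index=df.index)

    def stage_unique_homolog(df: pd.DataFrame) -> pd.Series:
        def ok(c: str) -> bool:
            h = homolog_of.get(c)
            return pd.notna(h) and h is not None and hom_counts.get(h, 0) == 1

        return df["contig_id"].map(ok)

    stage_fns = {
        "min_coverage": stage_min_coverage,
        "parents_homozygous": stage_parents_homozygous,
        "homolog_hit": stage_homolog_hit,
        "single_parent_divergent": stage_single_parent_divergent,
        "no_proximal_variant": stage_no_proximal_variant,
        "no_indel_near": stage_no_indel_near,
        "unique_homolog": stage_unique_homolog,
    }
    order = stage_order if stage_order is not None else STAGE_NAMES
    if sorted(order) != sorted(STAGE_NAMES):
        raise ValueError("stage_order must be a permutation of the seven stages")
    stages = [(name, stage_fns[name]) for name in order]

    current = candidates
    report_rows = []
    for name, fn in stages:
        rows_in = len(current)
        keep = fn(current) if rows_in else pd.Series([], dtype=bool)
        current = current[keep] if rows_in else current
        report_rows.append(
            {
                "stage_name": name,
                "rows_in": rows_in,
                "rows_removed": rows_in - len(current),
                "rows_out": len(current),
            }
        )

    panel_rows = []
    for i in current.index:
        ref = current.at[i, "reference_allele"]
        a, b = parsed1[i], parsed2[i]
        diverging = 1 if a[0] != ref else 2
        alt = a[0] if diverging == 1 else b[0]
        cid, pos = current.at[i, "contig_id"], int(current.at[i, "position"])
        panel_rows.append(
            {
                "locus_id": f"{cid}_{pos}",
                "contig_id": cid,
                "position": pos,
                "reference_allele": ref,
                "alternate_allele": alt,
                "diverging_parent": diverging,
            }
        )
    panel = pd.DataFrame(
        panel_rows,
        columns=[
            "locus_id",
            "contig_id",
            "position",
            "reference_allele",
            "alternate_allele",
            "diverging_parent",
        ],
    )
    report = pd.DataFrame(report_rows)
    return panel, report


def panel_to_variant_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Re-express a marker panel as a variant-call table (for
    idempotence checks and re-filtering)."""
    rows = []
    for _, r in panel.iterrows():
        alt = f"{r.alternate_allele}/{r.alternate_allele}"
        ref = f"{r.reference_allele}/{r.reference_allele}"
        rows.append(
            {
                "contig_id": r.contig_id,
                "position": r.position,
                "reference_allele": r.reference_allele,
                "parent1_call": alt if r.diverging_parent == 1 else ref,
                "parent2_call": alt if r.diverging_parent == 2 else ref,
                "depth_parent1": 10_000,
                "depth_parent2": 10_000,
                "is_indel": False,
            }
        )
    return pd.DataFrame(
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


def extract_kasp_context(
    panel: pd.DataFrame, reference: dict[str, str], flank: int = 50
) -> pd.DataFrame:
    """Per locus, the assay context ``left[ref/alt]right``.

    Flanks of up to ``flank`` bases are truncated at contig ends (the
    ``truncated`` flag records it).  A mismatch between the panel's
    reference allele and the contig base at the (1-based) position is an
    error: it almost always means an off-by-one coordinate convention.
    """
    records = []
    for _, r in panel.iterrows():
        seq = reference[r.contig_id]
        pos = int(r.position)
        base = seq[pos - 1]
        if base != r.reference_allele:
            raise ValueError(
                f"locus {r.locus_id}: reference allele {r.reference_allele} "
                f"does not match contig base {base} at {r.contig_id}:{pos} "
                "(check the 1-based coordinate convention)"
            )
        left = seq[max(0, pos - 1 - flank): pos - 1]
        right = seq[pos: pos + flank]
        records.append(
            {
                "locus_id": r.locus_id,
                "context": f"{left}[{r.reference_allele}/{r.alternate_allele}]{right}",
                "left_flank_len": len(left),
                "right_flank_len": len(right),
                "truncated": len(left) < flank or len(right) < flank,
            }
        )
    return pd.DataFrame(
        records,
        columns=["locus_id", "context", "left_flank_len", "right_flank_len", "truncated"],
    )


# -- TSV I/O -----------------------------------------------------------


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_variant_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_homology_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
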