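"""End-to-end orchestration: filter -> QC -> stats -> differentiation ->
distances, from one configuration, with seeded reproducibility.

The pipeline consumes either real input files (variant table + homology
map + reference FASTA, genotype CSV + metadata CSV, log-likelihood
table) or, for a self-contained demonstration, simulated inputs.  Every
stage writes its table under the output directory and a manifest
records package version, parameters and seed.  Stage failures abort
with the stage name attached.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import simdata, markerfilter, genotypes, divstats, differentiation, distances

logger = logging.getLogger(__name__)

EXIT_VALIDATION = 2
EXIT_COMPUTATION = 3


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Defaults mirror the standard assay-design and QC settings: 6x
    minimum parental coverage, 10-bp proximity window, 10% maximum
    locus missingness, 1023 permutations.
    """

    output_dir: str = "results"
    seed: int = 0
    # inputs (all optional; simulate when genotypes_csv is absent)
    variants_tsv: str | None = None
    homology_tsv: str | None = None
    reference_fasta: str | None = None
    genotypes_csv: str | None = None
    metadata_csv: str | None = None
    logliks_tsv: str | None = None
    # simulation fallback
    sim_n_populations: int = 24
    sim_n_individuals: int = 12
    sim_n_loci: int = 202
    sim_fst: float = 0.045
    sim_fis: float = 0.06
    sim_missing_rate: float = 0.02
    # stage parameters
    min_coverage: int = 6
    proximity_window: int = 10
    max_missing_fraction: float = 0.10
    n_perm: int = 1023
    # toggles
    run_filter: bool = True
    run_stats: bool = True
    run_differentiation: bool = True
    run_distances: bool = True
    run_deltak: bool = True
    hierarchy: str | None = "altitude_class"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _write_fasta(references: dict[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=cid, description="") for cid, seq in references.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; return a manifest of outputs.

    Two runs with identical config and seed produce byte-identical
    outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "kaspop",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "parameters": asdict(config),
        "outputs": [],
    }

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index, float_format="%.6g")
        manifest["outputs"].append(name)

    # -- marker filtering ---------------------------------------------
    panel = None
    if config.run_filter:
        try:
            if config.variants_tsv:
                table = markerfilter.read_variant_table(config.variants_tsv)
                homology = markerfilter.read_homology_map(config.homology_tsv)
                references = read_fasta(config.reference_fasta) if config.reference_fasta else None
            else:
                spec = simdata.SimVariantSpec(
                    n_contigs=40,
                    n_clean_snps=20,
                    planted_failures={
                        "low_coverage": 2,
                        "parent_heterozygous": 2,
                        "both_parents_differ": 1,
                        "neither_parent_differs": 1,
                        "proximal_variant": 2,
                        "parent_indel": 2,
                        "no_homolog_hit": 2,
                        "shared_homolog_hit": 2,
                    },
                    seed=config.seed,
                )
                references, table, homology, ledger = simdata.simulate_variant_call_table(
                    spec, window=config.proximity_window, min_coverage=config.min_coverage
                )
                emit("planted_classes.tsv", ledger)
            cfg = markerfilter.FilterConfig(
                min_coverage=config.min_coverage,
                proximity_window=config.proximity_window,
            )
            panel, report = markerfilter.apply_filter_cascade(table, homology, cfg)
            emit("marker_panel.tsv", panel)
            emit("filter_report.tsv", report)
            if references:
                _write_fasta(references, out / "reference.fasta")
                manifest["outputs"].append("reference.fasta")
                assays = markerfilter.extract_kasp_context(panel, references)
                emit("kasp_contexts.tsv", assays)
            logger.info("filter: %d candidate loci retained", len(panel))
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("filter", str(exc)) from exc

    # -- genotype QC ---------------------------------------------------
    try:
        if config.genotypes_csv:
            matrix = genotypes.load_genotype_matrix(
                config.genotypes_csv, config.metadata_csv
            )
        else:
            gspec = simdata.SimGenotypeSpec(
                n_populations=config.sim_n_populations,
                n_individuals_per_population=config.sim_n_individuals,
                n_loci=config.sim_n_loci,
                fst_target=config.sim_fst,
                fis_target=config.sim_fis,
                missing_rate=config.sim_missing_rate,
                seed=config.seed,
            )
            matrix = simdata.simulate_genotype_matrix(gspec)
            genotypes.write_genotype_csv(matrix, out / "genotypes.csv")
            genotypes.write_metadata_csv(matrix.metadata, out / "metadata.csv")
            manifest["outputs"] += ["genotypes.csv", "metadata.csv"]
        classification = genotypes.classify_loci(matrix)
        summary = genotypes.classification_summary(classification)
        filtered = genotypes.filter_loci(
            matrix, classification, config.max_missing_fraction
        )
        emit("locus_classification.tsv", classification, index=True)
        ladder = pd.DataFrame(
            [
                {**summary,
                 "dropped_missingness": summary["polymorphic"] - filtered.n_loci,
                 "analysis_loci": filtered.n_loci}
            ]
        )
        emit("qc_ladder.tsv", ladder)
        logger.info(
            "qc: %d assayed -> %d analysis loci", matrix.n_loci, filtered.n_loci
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("qc", str(exc)) from exc

    # -- diversity statistics -----------------------------------------
    if config.run_stats:
        try:
            locus_stats = divstats.locus_diversity(filtered)
            emit("locus_stats.tsv", locus_stats, index=True)
            emit("hwe_tiers.tsv", divstats.hwe_tier_table(locus_stats))
            emit("accession_stats.tsv", divstats.accession_summary(filtered), index=True)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("stats", str(exc)) from exc

    # -- differentiation ----------------------------------------------
    if config.run_differentiation:
        try:
            per_locus, overall = differentiation.nei_f_statistics(filtered)
            emit("nei_fstats_per_locus.tsv", per_locus, index=True)
            with open(out / "nei_fstats_overall.json", "w") as fh:
                json.dump(overall, fh, indent=1)
            manifest["outputs"].append("nei_fstats_overall.json")
            res = differentiation.amova(
                filtered, hierarchy=None, n_perm=config.n_perm, seed=config.seed
            )
            emit("amova_flat.tsv", res.table)
            if config.hierarchy:
                hres = differentiation.amova(
                    filtered,
                    hierarchy=config.hierarchy,
                    n_perm=config.n_perm,
                    seed=config.seed,
                )
                emit(f"amova_{config.hierarchy}.tsv", hres.table)
            pw = differentiation.pairwise_fst(
                filtered, n_perm=config.n_perm, seed=config.seed
            )
            emit("pairwise_fst.tsv", pw.matrix, index=True)
            emit("pairwise_fst_p.tsv", pw.pvalues, index=True)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("differentiation", str(exc)) from exc

    # -- distances / trees / ordination -------------------------------
    if config.run_distances:
        try:
            if panel is not None and set(filtered.locus_ids) <= set(panel["locus_id"]):
                pan = panel
            else:  # loci without assay context: synthesize ref/alt bases
                pan = pd.DataFrame(
                    {
                        "locus_id": filtered.locus_ids,
                        "reference_allele": "A",
                        "alternate_allele": "C",
                    }
                )
            complete = genotypes.select_complete_individuals(filtered)
            freqs = genotypes.allele_frequencies(filtered)
            low_maf = [
                l for l in filtered.locus_ids if freqs.at[l, "maf"] < 0.3
            ]
            if complete.n_samples >= 3 and low_maf:
                seqs = distances.encode_pseudosequences(complete, pan, low_maf)
                dm = distances.distance_matrix(seqs)
                tree, newick, flags = distances.neighbor_joining(dm)
                (out / "individual_nj.nwk").write_text(newick + "\n")
                manifest["outputs"].append("individual_nj.nwk")
            acc_dm = distances.accession_distance_matrix(filtered, pan)
            emit("accession_distances.tsv", acc_dm.to_dataframe(), index=True)
            if len(acc_dm.ids) >= 3 and np.all(np.isfinite(acc_dm.values)):
                tree, newick, flags = distances.neighbor_joining(acc_dm)
                (out / "accession_nj.nwk").write_text(newick + "\n")
                manifest["outputs"].append("accession_nj.nwk")
                ord_res = distances.pcoa(acc_dm, n_axes=2)
                emit("pcoa_coordinates.tsv", ord_res.coordinates, index=True)
                emit(
                    "pcoa_eigenvalues.tsv",
                    pd.DataFrame(
                        {
                            "axis": np.arange(1, len(ord_res.eigenvalues) + 1),
                            "eigenvalue": ord_res.eigenvalues,
                        }
                    ),
                )
            emit("eaed.tsv", distances.eaed(filtered, pan), index=True)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("distances", str(exc)) from exc

    # -- delta-K -------------------------------------------------------
    if config.run_deltak:
        try:
            if config.logliks_tsv:
                lltable = pd.read_csv(config.logliks_tsv, sep="\t")
            else:
                lltable = simdata.simulate_loglik_table(15, 3, config.seed)
                emit("logliks.tsv", lltable)
            profile = distances.evanno_delta_k(lltable)
            emit("delta_k.tsv", profile)
            manifest["optimal_k"] = profile.attrs.get("optimal_k")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("deltak", str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
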