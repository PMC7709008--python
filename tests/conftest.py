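import numpy as np
import pandas as pd
import pytest

import kaspop as kp
from kaspop.genotypes import GenotypeMatrix, HOM_REF, HET, HOM_ALT, MISSING


def make_matrix(calls, accessions=None, metadata=True):
    """GenotypeMatrix from a dense call array (rows = samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, l = calls.shape
    if accessions is None:
        accessions = ["A1"] * n
    md = (
        kp.simdata.default_accession_metadata(sorted(set(accessions)))
        if metadata
        else pd.DataFrame()
    )
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        accession_of_sample=list(accessions),
        locus_ids=[f"L{j}" for j in range(l)],
        calls=calls,
        metadata=md,
    )


@pytest.fixture(scope="session")
def island_matrix():
    """24 accessions x 12 individuals x 202 loci at F_ST 0.045,
    F_IS 0.06 — the reference study design."""
    spec = kp.SimGenotypeSpec(
        n_populations=24,
        n_individuals_per_population=12,
        n_loci=202,
        fst_target=0.045,
        fis_target=0.06,
        seed=20260928,
    )
    return kp.simulate_genotype_matrix(spec)


@pytest.fixture(scope="session")
def small_matrix():
    """6 accessions x 8 individuals x 60 loci with missing data."""
    spec = kp.SimGenotypeSpec(
        n_populations=6,
        n_individuals_per_population=8,
        n_loci=60,
        fst_target=0.08,
        fis_target=0.05,
        missing_rate=0.03,
        seed=77,
    )
    return kp.simulate_genotype_matrix(spec)


@pytest.fixture(scope="session")
def qc_ladder_matrix():
    """Composition-matched KASP QC fixture: 931 assayed loci of which
    377 produced no calls, 286 are monomorphic and 268 polymorphic,
    66 of the polymorphic with >10% missing data; 281 samples of which
    exactly 126 are complete over the analysis loci."""
    rng = np.random.default_rng(1373)
    n = 281
    cols = []
    for _ in range(377):  # failed
        cols.append(np.full(n, MISSING))
    for _ in range(286):  # monomorphic, full call rate
        cols.append(np.full(n, HOM_REF))
    analysis_start = 377 + 286
    for j in range(268):  # polymorphic
        col = rng.choice([HOM_REF, HET, HOM_ALT], size=n)
        if j < 66:  # > 10% missing
            k = int(np.ceil(0.10 * n)) + 1 + int(rng.integers(0, 20))
            col[rng.choice(n, size=k, replace=False)] = MISSING
        cols.append(col)
    calls = np.column_stack(cols).astype(np.int8)
    # plant missingness in the 202 analysis loci so that exactly 126
    # samples are complete over them
    analysis = np.arange(377 + 286 + 66, 931)
    incomplete = rng.choice(n, size=n - 126, replace=False)
    for s in incomplete:
        j = analysis[rng.integers(0, len(analysis))]
        calls[s, j] = MISSING
    # keep those analysis loci under the 10% missingness cap
    assert ((calls[:, analysis] == MISSING).mean(axis=0) <= 0.10).all()
    accessions = [f"ACC{1 + i % 24:03d}" for i in range(n)]
    return make_matrix(calls, accessions)
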