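import numpy as np
import pandas as pd
import pytest

from strainflow.data_model import SampleTable, SNVProfile
from strainflow.synthetic_cohort import SimulationConfig, SpeciesSpec, simulate_cohort


def make_samples(n_subjects=4, n_timepoints=1, n_cohorts=1, family=None):
    rows = []
    for i in range(n_subjects):
        subj = f"S{i + 1:02d}"
        cohort = f"C{(i % n_cohorts) + 1}"
        fam = family.get(subj) if family else None
        for tp in range(n_timepoints):
            for site in ("oral", "gut"):
                rows.append((f"{subj}_{site}_t{tp}", subj, cohort, site, tp,
                             fam, None))
    return SampleTable(pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "cohort", "site",
                       "timepoint", "family_id", "village_id"]))


def make_profile(matrix, sample_ids, taxon="t1"):
    """Profile from a dense ternary matrix with auto-generated allele ids."""
    matrix = np.asarray(matrix, dtype=np.int8)
    allele_ids = [f"{taxon}:{i + 1}:A>C" for i in range(matrix.shape[0])]
    return SNVProfile(taxon, allele_ids, list(sample_ids), matrix)


def random_profile(rng, n_alleles=30, n_oral=12, n_gut=12, taxon="t1",
                   p_present=0.3, p_uncovered=0.2):
    """Random ternary profile guaranteed to pass informative-SNV selection."""
    n = n_oral + n_gut
    m = np.where(rng.random((n_alleles, n)) < p_present, 1, 0).astype(np.int8)
    m[rng.random((n_alleles, n)) < p_uncovered] = -1
    # force full coverage and at least one present per site on a safety row
    m[:, 0] = np.maximum(m[:, 0], 0)
    m[:, n_oral] = np.maximum(m[:, n_oral], 0)
    sample_ids = [f"S{i + 1:02d}_oral_t0" for i in range(n_oral)] + [
        f"S{i + 1:02d}_gut_t0" for i in range(n_gut)]
    return make_profile(m, sample_ids, taxon)


def samples_for_profile(n_oral=12, n_gut=12):
    rows = []
    for i in range(max(n_oral, n_gut)):
        subj = f"S{i + 1:02d}"
        if i < n_oral:
            rows.append((f"{subj}_oral_t0", subj, "C1", "oral", 0, None, None))
        if i < n_gut:
            rows.append((f"{subj}_gut_t0", subj, "C1", "gut", 0, None, None))
    return SampleTable(pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "cohort", "site",
                       "timepoint", "family_id", "village_id"]))


@pytest.fixture(scope="session")
def small_cohort():
    """Mixed-class cohort reused by read-only tests."""
    cfg = SimulationConfig.default_panel(
        n_frequent=3, n_occasional=1, n_none=3, n_oral_only=1, n_gut_only=1,
        n_subjects=30, n_cohorts=2, dropout=0.2, seed=11,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def longitudinal_cohort():
    """Two-timepoint cohort with oral-sourced fecal turnover (r=0.6)."""
    cfg = SimulationConfig(
        species=[SpeciesSpec(f"sp{i:02d}", "none", 200) for i in range(1, 5)],
        n_subjects=30, n_cohorts=2, n_timepoints=2, dropout=0.0,
        turnover=0.2, oral_source_rate=0.6, seed=5,
    )
    return cfg, simulate_cohort(cfg)
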