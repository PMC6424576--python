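"""Taxon inclusion, informative-SNV selection, and pair-eligibility rules.

A taxon enters the analysis only where its genome is actually observable:
it must simultaneously reach a horizontal coverage (breadth) of >= 0.05,
a vertical coverage (depth) of >= 0.25 and a relative abundance of >= 1e-6
in at least 10% of samples. SNVs are informative only if their position is
covered in enough samples of both body sites to estimate background
incidence frequencies, and oral-gut sample pairs are comparable only with
coverage at >= 20 matching positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import SampleTable, SNVProfile, AbundanceMatrix

__all__ = ["TaxonFilterResult", "filter_taxa", "select_informative_snvs",
           "eligible_pairs", "detected_mask"]


@dataclass
class TaxonFilterResult:
    kept: list[str]
    prevalence: pd.DataFrame  # per taxon: prevalence_all/_oral/_gut, kept flag


def detected_mask(abund: AbundanceMatrix, min_hcov: float = 0.05,
                  min_vcov: float = 0.25, min_relab: float = 1e-6) -> pd.DataFrame:
    """Boolean taxon x sample mask of per-sample detection.

    A taxon counts as detected in a sample when breadth, depth and relative
    abundance all reach their thresholds simultaneously.
    """
    return (
        (abund.horizontal_coverage >= min_hcov)
        & (abund.vertical_coverage >= min_vcov)
        & (abund.rel_abundance >= min_relab)
    )


def filter_taxa(
    abund: AbundanceMatrix,
    samples: SampleTable,
    min_prevalence: float = 0.10,
    min_hcov: float = 0.05,
    min_vcov: float = 0.25,
    min_relab: float = 1e-6,
) -> TaxonFilterResult:
    """Keep taxa detected in at least ``min_prevalence`` of all samples.

    Prevalence is computed over all samples pooled across sites; per-site
    prevalences (fraction of oral and of gut samples with detection) are
    returned alongside for the prevalent-in-both / single-site
    categorisation of taxa.
    """
    if not abund.sample_ids:
        raise ValueError("abundance matrix has no samples")
    det = detected_mask(abund, min_hcov, min_vcov, min_relab)
    oral = [s for s in abund.sample_ids if samples.site_of(s) == "oral"]
    gut = [s for s in abund.sample_ids if samples.site_of(s) == "gut"]
    prev_all = det.mean(axis=1)
    prev_oral = det[oral].mean(axis=1) if oral else pd.Series(0.0, index=det.index)
    prev_gut = det[gut].mean(axis=1) if gut else pd.Series(0.0, index=det.index)
    kept_flag = prev_all >= min_prevalence
    frame = pd.DataFrame(
        {
            "taxon_id": det.index,
            "prevalence_all": prev_all.to_numpy(),
            "prevalence_oral": prev_oral.to_numpy(),
            "prevalence_gut": prev_gut.to_numpy(),
            "kept": kept_flag.to_numpy(),
        }
    ).reset_index(drop=True)
    return TaxonFilterResult(kept=det.index[kept_flag].tolist(), prevalence=frame)


def select_informative_snvs(
    profile: SNVProfile,
    samples: SampleTable,
    min_cov_oral: int = 10,
    min_cov_gut: int = 10,
    min_present_oral: int = 1,
    min_present_gut: int = 1,
) -> SNVProfile:
    """Retain alleles with enough coverage and observations at both sites.

    An allele is informative when its position is covered (PRESENT or
    ABSENT) in >= ``min_cov_oral`` oral and >= ``min_cov_gut`` gut samples,
    and the allele itself is PRESENT in at least one sample of each site.
    Counts are over all samples of each site in the dataset. Idempotent.
    """
    profile.validate_against(samples)
    oral_idx = [profile.column_index(s) for s in profile.sample_ids
                if samples.site_of(s) == "oral"]
    gut_idx = [profile.column_index(s) for s in profile.sample_ids
               if samples.site_of(s) == "gut"]
    cov = profile.covered()
    pres = profile.present()
    keep = (
        (cov[:, oral_idx].sum(axis=1) >= min_cov_oral)
        & (cov[:, gut_idx].sum(axis=1) >= min_cov_gut)
        & (pres[:, oral_idx].sum(axis=1) >= min_present_oral)
        & (pres[:, gut_idx].sum(axis=1) >= min_present_gut)
    )
    return profile.subset_alleles(keep)


def eligible_pairs(
    profile: SNVProfile,
    samples: SampleTable,
    min_shared: int = 20,
) -> pd.DataFrame:
    """All oral x gut sample pairs with coverage at >= ``min_shared`` positions.

    Both intra- and inter-individual pairs are returned; the count of
    mutually covered alleles is annotated per pair.
    """
    oral = [s for s in profile.sample_ids if samples.site_of(s) == "oral"]
    gut = [s for s in profile.sample_ids if samples.site_of(s) == "gut"]
    cov = profile.covered().astype(np.int32)
    o_idx = [profile.column_index(s) for s in oral]
    g_idx = [profile.column_index(s) for s in gut]
    shared = cov[:, o_idx].T @ cov[:, g_idx]  # oral x gut counts
    rows = [
        (oral[i], gut[j], int(shared[i, j]))
        for i, j in np.argwhere(shared >= min_shared)
    ]
    return pd.DataFrame(rows, columns=["oral_sample_id", "gut_sample_id",
                                       "n_shared_positions"])
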