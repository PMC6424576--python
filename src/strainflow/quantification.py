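"""Transmitted-abundance quantification and small reporting statistics.

Classification tells us *which* species move from mouth to gut; this module
converts that into *how much* of a sample's microbial abundance is involved.
The *potential* fraction of a sample is the classifiable relative abundance
held by frequent and occasional transmitters. The *realized* fraction keeps
only species whose strain populations can actually be traced within the
focal subject, and discounts each by the oral-gut strain population
overlap, estimated as the Jaccard index of the subject's present-allele
sets over mutually covered positions.

Also here: the physiological expectation for purely passive oral-fecal
translocation (ingestion without colonization), rarefied species richness,
and Cohen's d effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    AbundanceMatrix,
    SampleTable,
    SNVProfile,
    TaxonClassification,
)
from .filtering import detected_mask

__all__ = [
    "snv_jaccard",
    "transmissible_abundance",
    "realized_abundance",
    "quantify_cohort",
    "passive_expectation",
    "rarefied_richness",
    "cohens_d",
]


def snv_jaccard(
    profile: SNVProfile,
    oral_sample_id: str,
    gut_sample_id: str,
    min_shared: int = 20,
) -> float:
    """Jaccard overlap of present-allele sets over mutually covered positions.

    Requires >= ``min_shared`` mutually covered alleles. An empty union
    (no allele present in either sample) is defined as overlap 0.
    """
    o = profile.column(oral_sample_id)
    g = profile.column(gut_sample_id)
    covered = (o >= 0) & (g >= 0)
    if covered.sum() < min_shared:
        raise ValueError(
            f"pair ({oral_sample_id}, {gut_sample_id}) shares coverage at only "
            f"{int(covered.sum())} positions (< {min_shared})"
        )
    po = covered & (o == 1)
    pg = covered & (g == 1)
    union = int((po | pg).sum())
    if union == 0:
        return 0.0
    return float((po & pg).sum() / union)


def _classifiable(abund: AbundanceMatrix, sample_id: str,
                  panel: Sequence[str]) -> pd.Series:
    col = abund.rel_abundance.loc[list(panel), sample_id]
    return col


def transmissible_abundance(
    sample_id: str,
    classifications: Sequence[TaxonClassification],
    abund: AbundanceMatrix,
    panel: Sequence[str] | None = None,
) -> float:
    """Potential transmitted fraction of one sample.

    The classifiable denominator is the summed relative abundance of the
    filtered taxon panel in the sample; the numerator sums the transmissible
    (frequent or occasional) species. Returns NaN when the sample carries no
    classifiable abundance.
    """
    if panel is None:
        panel = [c.taxon_id for c in classifications]
    col = _classifiable(abund, sample_id, panel)
    total = float(col.sum())
    if total <= 0:
        return float("nan")
    transmissible = {
        c.taxon_id for c in classifications if c.status in ("frequent", "occasional")
    }
    num = float(col[col.index.isin(transmissible)].sum())
    return num / total


def realized_abundance(
    subject_id: str,
    classifications: Sequence[TaxonClassification],
    abund: AbundanceMatrix,
    profiles: Mapping[str, SNVProfile],
    samples: SampleTable,
    panel: Sequence[str] | None = None,
    alpha: float = 0.05,
    min_shared: int = 20,
    min_hcov: float = 0.05,
    min_vcov: float = 0.25,
    min_relab: float = 1e-6,
) -> dict[str, float]:
    """Realized transmitted fraction per site for one subject.

    Uses the subject's earliest timepoint with both sites sampled. A species
    qualifies when it is a frequent transmitter detected (above the
    filtering thresholds) in both paired samples, or an occasional
    transmitter that is additionally individually significant in this
    subject (BH-adjusted per-subject Z-test p < ``alpha``). Each qualifying
    species contributes its classified relative abundance multiplied by the
    subject's oral-gut SNV Jaccard overlap for that species.

    Returns ``{"oral": fraction, "gut": fraction}`` (NaN when the subject
    lacks a paired timepoint or classifiable abundance).
    """
    if panel is None:
        panel = [c.taxon_id for c in classifications]
    tps = samples.paired_timepoints(subject_id)
    if not tps:
        return {"oral": float("nan"), "gut": float("nan")}
    tp = tps[0]
    oral_s = samples.sample_for(subject_id, "oral", tp)
    gut_s = samples.sample_for(subject_id, "gut", tp)
    det = detected_mask(abund, min_hcov, min_vcov, min_relab)

    out: dict[str, float] = {}
    for site, sid in (("oral", oral_s), ("gut", gut_s)):
        col = _classifiable(abund, sid, panel)
        total = float(col.sum())
        if total <= 0:
            out[site] = float("nan")
            continue
        realized = 0.0
        for c in classifications:
            if c.status not in ("frequent", "occasional"):
                continue
            if c.taxon_id not in det.index:
                continue
            if not (det.at[c.taxon_id, oral_s] and det.at[c.taxon_id, gut_s]):
                continue
            if c.status == "occasional":
                p = c.z_p_adj.get(subject_id, float("nan"))
                if not (np.isfinite(p) and p < alpha):
                    continue
            profile = profiles.get(c.taxon_id)
            if profile is None:
                continue
            o = profile.column(oral_s)
            g = profile.column(gut_s)
            if int(((o >= 0) & (g >= 0)).sum()) < min_shared:
                continue
            overlap = snv_jaccard(profile, oral_s, gut_s, min_shared=min_shared)
            realized += float(col.get(c.taxon_id, 0.0)) * overlap
        out[site] = realized / total
    return out


def quantify_cohort(
    classifications: Sequence[TaxonClassification],
    abund: AbundanceMatrix,
    profiles: Mapping[str, SNVProfile],
    samples: SampleTable,
    panel: Sequence[str] | None = None,
    alpha: float = 0.05,
    min_shared: int = 20,
) -> pd.DataFrame:
    """Per-sample potential and realized transmitted fractions.

    Potential fractions are computed for every sample; realized fractions
    only for samples at a subject's earliest paired timepoint (NaN
    elsewhere).
    """
    if panel is None:
        panel = [c.taxon_id for c in classifications]
    realized_by_subject = {
        subj: realized_abundance(
            subj, classifications, abund, profiles, samples,
            panel=panel, alpha=alpha, min_shared=min_shared,
        )
        for subj in samples.subject_ids
    }
    rows = []
    for sid in samples.sample_ids:
        if sid not in abund.sample_ids:
            continue
        subj = samples.subject_of(sid)
        site = samples.site_of(sid)
        tp = samples.timepoint_of(sid)
        paired = samples.paired_timepoints(subj)
        potential = transmissible_abundance(sid, classifications, abund, panel)
        realized = (
            realized_by_subject[subj][site]
            if paired and tp == paired[0]
            else float("nan")
        )
        rows.append((sid, subj, site, tp, potential, realized))
    return pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "site", "timepoint",
                       "potential_fraction", "realized_fraction"]
    )


def passive_expectation(
    swallowed_per_day: float = 1.5e12,
    log10_reduction: float = 5.0,
    gut_cells: float = 3.8e13,
) -> float:
    """Expected fecal relative abundance of purely passively transmitted cells.

    An average person swallows ~1.5e12 oral bacteria per day; gastric
    passage reduces the viable load by 5-6 orders of magnitude; the large
    intestine holds ~3.8e13 bacterial cells. Ingestion without colonization
    therefore dilutes salivary microbes to roughly 4e-7 relative abundance
    (at the default, conservative 5-order reduction):

        swallowed_per_day * 10**(-log10_reduction) / gut_cells
    """
    if swallowed_per_day <= 0 or gut_cells <= 0:
        raise ValueError("swallowed_per_day and gut_cells must be positive")
    return swallowed_per_day * 10.0 ** (-log10_reduction) / gut_cells


def rarefied_richness(
    abundances,
    depth: int = 1000,
    reps: int = 100,
    seed: int | None = 0,
) -> float:
    """Mean species count over repeated rarefactions to a fixed depth.

    Relative abundances are renormalized and ``depth`` observations drawn
    multinomially per repetition; richness is the number of species hit at
    least once, averaged over ``reps`` draws.
    """
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any() or a.sum() <= 0:
        raise ValueError("abundances must be non-negative with positive sum")
    p = a / a.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, p, size=reps)
    return float((counts > 0).sum(axis=1).mean())


def cohens_d(group_a, group_b) -> float:
    """Cohen's d: difference in means normalised by pooled standard deviation."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))
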