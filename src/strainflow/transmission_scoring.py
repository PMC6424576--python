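"""Transmission scores from oral-gut SNV profile overlap.

The central statistic asks, for one species in one subject: how unlikely is
the observed agreement between the subject's salivary and fecal SNV
profiles under a background model in which the two sites are populated
independently with the dataset-wide allele incidence frequencies?

For every allele ``i`` with background incidences ``f_oral(i)`` and
``f_gut(i)``, the four outcomes of a paired observation have probabilities

    p_11 = f_oral * f_gut          (present in both)
    p_00 = (1 - f_oral)(1 - f_gut) (absent in both)
    p_10 = f_oral (1 - f_gut)      (present orally only)
    p_01 = (1 - f_oral) f_gut      (present in the gut only)

Over the alleles covered in both samples of a pair, agreement log-terms add
and disagreement log-terms subtract:

    L_obs = sum_{1,1} ln p_11 + sum_{0,0} ln p_00
            - sum_{1,0} ln p_10 - sum_{0,1} ln p_01

and the likelihood of the least likely full-agreement configuration is

    L_min = sum_i min(ln p_11(i), ln p_00(i)).

The raw score ``P_raw = L_obs / L_min`` is bounded above by 1, reached only
when every shared allele agrees in its least-likely configuration; shared
observations of rare alleles weigh heavily, shared common variants little.
The transmission score ``S_T = (P_raw(subject) - mu_raw) / sigma_raw``
standardizes the intra-individual score against the distribution of
``P_raw`` over permuted inter-individual oral-gut pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    AlleleBackground,
    PairScore,
    SampleTable,
    ScoreResult,
    SNVProfile,
    TaxonClassification,
)

__all__ = [
    "BackgroundMode",
    "allele_incidence",
    "pair_likelihood",
    "pair_likelihood_matrix",
    "TaxonPairScores",
    "score_taxon_pairs",
    "background_distribution",
    "transmission_score",
    "score_taxon",
    "classify_taxa",
    "bh_adjust",
]

BackgroundMode = Literal["global", "cohort", "subject_global", "subject_cohort"]

MIN_BACKGROUND_PAIRS = 10


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-tolerant)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        from statsmodels.stats.multitest import multipletests
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Background incidence
# ---------------------------------------------------------------------------


def allele_incidence(
    profile: SNVProfile,
    samples: SampleTable,
) -> AlleleBackground:
    """Global background incidence of each allele across oral and gut samples.

    ``f_site(i)`` is the number of site samples with the allele PRESENT
    divided by the number of site samples covered at the position. To keep
    all four log-probabilities finite, frequencies are clamped into
    ``[1/(2 n), 1 - 1/(2 n)]`` with ``n`` the site-specific covered-sample
    count for that allele (a half-count pseudofrequency).

    Raises if any allele has zero covered samples in a site — impossible
    after :func:`strainflow.filtering.select_informative_snvs`.
    """
    oral_idx = [profile.column_index(s) for s in profile.sample_ids
                if samples.site_of(s) == "oral"]
    gut_idx = [profile.column_index(s) for s in profile.sample_ids
               if samples.site_of(s) == "gut"]
    cov = profile.covered()
    pres = profile.present()

    def site_freq(idx: list[int]) -> tuple[np.ndarray, np.ndarray]:
        n = cov[:, idx].sum(axis=1).astype(float)
        if (n == 0).any():
            bad = [profile.allele_ids[i] for i in np.flatnonzero(n == 0)[:5]]
            raise ValueError(
                f"taxon {profile.taxon_id}: alleles with zero covered samples "
                f"in a site (run select_informative_snvs first): {bad}"
            )
        f = pres[:, idx].sum(axis=1) / n
        lo = 1.0 / (2.0 * n)
        return np.clip(f, lo, 1.0 - lo), n.astype(int)

    f_oral, n_oral = site_freq(oral_idx)
    f_gut, n_gut = site_freq(gut_idx)
    return AlleleBackground(
        taxon_id=profile.taxon_id,
        allele_ids=list(profile.allele_ids),
        f_oral=f_oral,
        f_gut=f_gut,
        n_oral_covered=n_oral,
        n_gut_covered=n_gut,
    )


# ---------------------------------------------------------------------------
# Pair likelihoods
# ---------------------------------------------------------------------------


def pair_likelihood(
    oral_sample_id: str,
    gut_sample_id: str,
    profile: SNVProfile,
    background: AlleleBackground,
    min_shared: int = 20,
) -> PairScore:
    """L_obs, L_min and P_raw for one oral-gut sample pair.

    Only alleles covered in both samples contribute. Natural logarithm
    throughout. Requires >= ``min_shared`` mutually covered alleles.
    """
    o = profile.column(oral_sample_id)
    g = profile.column(gut_sample_id)
    shared = (o >= 0) & (g >= 0)
    n_shared = int(shared.sum())
    if n_shared < min_shared:
        raise ValueError(
            f"pair ({oral_sample_id}, {gut_sample_id}) shares coverage at only "
            f"{n_shared} positions (< {min_shared})"
        )
    lp11 = np.log(background.p_11)
    lp00 = np.log(background.p_00)
    lp10 = np.log(background.p_10)
    lp01 = np.log(background.p_01)
    po, pg = o == 1, g == 1
    ao, ag = o == 0, g == 0
    L_obs = float(
        lp11[shared & po & pg].sum()
        + lp00[shared & ao & ag].sum()
        - lp10[shared & po & ag].sum()
        - lp01[shared & ao & pg].sum()
    )
    L_min = float(np.minimum(lp11, lp00)[shared].sum())
    if L_min == 0.0:
        raise ValueError("L_min is zero; clamped frequencies cannot produce this")
    return PairScore(
        taxon_id=profile.taxon_id,
        oral_sample_id=oral_sample_id,
        gut_sample_id=gut_sample_id,
        n_shared_positions=n_shared,
        L_obs=L_obs,
        L_min=L_min,
        P_raw=L_obs / L_min,
    )


def pair_likelihood_matrix(
    profile: SNVProfile,
    background: AlleleBackground,
    oral_samples: Sequence[str],
    gut_samples: Sequence[str],
    min_shared: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """P_raw and shared-coverage counts for all oral x gut sample pairs.

    Vectorized over pairs via four rank-one-weighted matrix products; pairs
    below the shared-coverage threshold get ``P_raw = NaN``. Returns
    ``(P_raw, n_shared)`` arrays of shape (n_oral, n_gut).
    """
    o_idx = [profile.column_index(s) for s in oral_samples]
    g_idx = [profile.column_index(s) for s in gut_samples]
    M = profile.matrix
    Po = (M[:, o_idx] == 1).astype(float)
    Ao = (M[:, o_idx] == 0).astype(float)
    Pg = (M[:, g_idx] == 1).astype(float)
    Ag = (M[:, g_idx] == 0).astype(float)
    Co, Cg = Po + Ao, Pg + Ag

    lp11 = np.log(background.p_11)
    lp00 = np.log(background.p_00)
    lp10 = np.log(background.p_10)
    lp01 = np.log(background.p_01)
    lmin = np.minimum(lp11, lp00)

    L_obs = (
        (Po * lp11[:, None]).T @ Pg
        + (Ao * lp00[:, None]).T @ Ag
        - (Po * lp10[:, None]).T @ Ag
        - (Ao * lp01[:, None]).T @ Pg
    )
    L_min = (Co * lmin[:, None]).T @ Cg
    n_shared = np.rint(Co.T @ Cg).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        P_raw = L_obs / L_min
    P_raw[n_shared < min_shared] = np.nan
    return P_raw, n_shared


# ---------------------------------------------------------------------------
# Backgrounds and scores
# ---------------------------------------------------------------------------


@dataclass
class TaxonPairScores:
    """All pairwise P_raw values of one taxon plus pair metadata."""

    taxon_id: str
    oral_samples: list[str]
    gut_samples: list[str]
    P_raw: np.ndarray  # n_oral x n_gut, NaN where ineligible
    n_shared: np.ndarray
    samples: SampleTable

    def intra_pair(self, subject_id: str) -> tuple[str, str] | None:
        """The subject's oral-gut pair at the earliest timepoint with both
        sites available and eligible."""
        for tp in self.samples.paired_timepoints(subject_id):
            o = self.samples.sample_for(subject_id, "oral", tp)
            g = self.samples.sample_for(subject_id, "gut", tp)
            if o in self._o_pos and g in self._g_pos:
                if np.isfinite(self.P_raw[self._o_pos[o], self._g_pos[g]]):
                    return o, g
        return None

    def __post_init__(self) -> None:
        self._o_pos = {s: i for i, s in enumerate(self.oral_samples)}
        self._g_pos = {s: j for j, s in enumerate(self.gut_samples)}

    def value(self, oral_sample_id: str, gut_sample_id: str) -> float:
        return float(
            self.P_raw[self._o_pos[oral_sample_id], self._g_pos[gut_sample_id]]
        )


def score_taxon_pairs(
    profile: SNVProfile,
    samples: SampleTable,
    background: AlleleBackground | None = None,
    min_shared: int = 20,
) -> TaxonPairScores:
    """Compute P_raw for every oral x gut pair of one (filtered) taxon."""
    if background is None:
        background = allele_incidence(profile, samples)
    oral = [s for s in profile.sample_ids if samples.site_of(s) == "oral"]
    gut = [s for s in profile.sample_ids if samples.site_of(s) == "gut"]
    P_raw, n_shared = pair_likelihood_matrix(
        profile, background, oral, gut, min_shared=min_shared
    )
    return TaxonPairScores(profile.taxon_id, oral, gut, P_raw, n_shared, samples)


def _background_mask(
    pairs: TaxonPairScores,
    subject_id: str,
    mode: BackgroundMode,
) -> np.ndarray:
    """Boolean (oral x gut) mask of background pairs for one focal subject.

    Background pairs are inter-individual: the two samples must come from
    different subjects, and pairs within a family or village are excluded
    (same-subject pairs across timepoints are excluded by construction).
    """
    st = pairs.samples
    o_subj = np.array([st.subject_of(s) for s in pairs.oral_samples])
    g_subj = np.array([st.subject_of(s) for s in pairs.gut_samples])
    o_coh = np.array([st.cohort_of(s) for s in pairs.oral_samples])
    g_coh = np.array([st.cohort_of(s) for s in pairs.gut_samples])
    o_fam = np.array([st.family_of(s) or "" for s in pairs.oral_samples])
    g_fam = np.array([st.family_of(s) or "" for s in pairs.gut_samples])
    o_vil = np.array([st.village_of(s) or "" for s in pairs.oral_samples])
    g_vil = np.array([st.village_of(s) or "" for s in pairs.gut_samples])

    inter = o_subj[:, None] != g_subj[None, :]
    same_family = (o_fam[:, None] == g_fam[None, :]) & (o_fam[:, None] != "")
    same_village = (o_vil[:, None] == g_vil[None, :]) & (o_vil[:, None] != "")
    mask = inter & ~same_family & ~same_village

    focal_cohort = None
    subj_rows = st.frame[st.frame.subject_id == subject_id]
    if not subj_rows.empty:
        focal_cohort = subj_rows["cohort"].iloc[0]
    if mode in ("cohort", "subject_cohort"):
        mask &= (o_coh[:, None] == focal_cohort) & (g_coh[None, :] == focal_cohort)
    if mode in ("subject_global", "subject_cohort"):
        involves = (o_subj[:, None] == subject_id) | (g_subj[None, :] == subject_id)
        mask &= involves
    return mask


def background_distribution(
    pairs: TaxonPairScores,
    subject_id: str,
    mode: BackgroundMode = "cohort",
    min_background_pairs: int = MIN_BACKGROUND_PAIRS,
) -> tuple[float, float, np.ndarray]:
    """Mean and SD (n-1 denominator) of background P_raw for one subject.

    Returns ``(mu_raw, sigma_raw, values)``; ``mu``/``sigma`` are NaN when
    fewer than ``min_background_pairs`` eligible background pairs exist.
    """
    mask = _background_mask(pairs, subject_id, mode)
    values = pairs.P_raw[mask]
    values = values[np.isfinite(values)]
    if len(values) < min_background_pairs:
        return float("nan"), float("nan"), values
    return float(values.mean()), float(values.std(ddof=1)), values


def transmission_score(p_raw_intra: float, mu_raw: float, sigma_raw: float) -> float:
    """Standard Z score of the intra-individual P_raw against its background."""
    return (p_raw_intra - mu_raw) / sigma_raw


def score_taxon(
    profile: SNVProfile,
    samples: SampleTable,
    mode: BackgroundMode = "cohort",
    min_shared: int = 20,
    min_background_pairs: int = MIN_BACKGROUND_PAIRS,
) -> list[ScoreResult]:
    """Transmission scores for every subject with an intra-individual pair.

    The intra-individual pair uses the subject's earliest timepoint with
    both sites present and eligible. Subjects without such a pair, with
    fewer than ``min_background_pairs`` background pairs, or with a
    degenerate background (sigma == 0) are returned flagged unavailable.
    """
    pairs = score_taxon_pairs(profile, samples, min_shared=min_shared)
    results: list[ScoreResult] = []
    for subject in samples.subject_ids:
        intra = pairs.intra_pair(subject)
        if intra is None:
            continue
        p_raw = pairs.value(*intra)
        mu, sigma, values = background_distribution(
            pairs, subject, mode, min_background_pairs
        )
        if np.isnan(mu):
            results.append(ScoreResult(
                profile.taxon_id, subject, p_raw, mu, sigma, float("nan"),
                mode, len(values), available=False,
                reason="too_few_background_pairs"))
            continue
        if sigma == 0.0:
            results.append(ScoreResult(
                profile.taxon_id, subject, p_raw, mu, sigma, float("nan"),
                mode, len(values), available=False, reason="zero_sigma"))
            continue
        results.append(ScoreResult(
            profile.taxon_id, subject, p_raw, mu, sigma,
            transmission_score(p_raw, mu, sigma), mode, len(values)))
    return results


# ---------------------------------------------------------------------------
# Transmitter classification
# ---------------------------------------------------------------------------


def classify_taxa(
    score_results: Sequence[ScoreResult],
    alpha: float = 0.05,
    min_subjects: int = 5,
    frequent_test: Literal["signed_rank", "rank_sum"] = "signed_rank",
    prevalence: pd.DataFrame | None = None,
    background_values: dict[str, np.ndarray] | None = None,
) -> list[TaxonClassification]:
    """Classify taxa as frequent, occasional or non-transmitters.

    *Frequent*: subject-level transmission scores are significantly above
    zero across subjects — one-sided (greater) Wilcoxon signed-rank test of
    the S_T values against 0, Benjamini-Hochberg corrected across taxa,
    adjusted p < ``alpha``. Requires >= ``min_subjects`` scored subjects.

    *Occasional*: not frequent, but at least one subject is individually
    significant — one-sided upper-tail normal p of S_T, BH-corrected across
    subjects within the taxon, minimum adjusted p < ``alpha``.

    ``frequent_test="rank_sum"`` swaps the cohort-wide branch for a
    two-sample Mann-Whitney test of intra-individual P_raw against the
    pooled background P_raw values (pass them per taxon via
    ``background_values``); the default one-sample test acts on scores that
    are already background-standardized.
    """
    by_taxon: dict[str, list[ScoreResult]] = {}
    for r in score_results:
        by_taxon.setdefault(r.taxon_id, []).append(r)
    taxa = sorted(by_taxon)

    raw_w = np.full(len(taxa), np.nan)
    for k, taxon in enumerate(taxa):
        st = np.array([r.S_T for r in by_taxon[taxon] if r.available])
        st = st[np.isfinite(st)]
        if len(st) < min_subjects:
            continue
        if frequent_test == "signed_rank":
            nz = st[st != 0]
            if len(nz) == 0:
                raw_w[k] = 1.0
            else:
                raw_w[k] = stats.wilcoxon(nz, alternative="greater").pvalue
        else:
            if background_values is None or taxon not in background_values:
                raise ValueError(
                    "frequent_test='rank_sum' needs per-taxon background_values"
                )
            intra = np.array([r.P_raw_intra for r in by_taxon[taxon] if r.available])
            raw_w[k] = stats.mannwhitneyu(
                intra, background_values[taxon], alternative="greater"
            ).pvalue
    adj_w = bh_adjust(raw_w)

    prev_oral = prev_gut = {}
    if prevalence is not None:
        prev_oral = dict(zip(prevalence.taxon_id, prevalence.prevalence_oral))
        prev_gut = dict(zip(prevalence.taxon_id, prevalence.prevalence_gut))

    out: list[TaxonClassification] = []
    for k, taxon in enumerate(taxa):
        scored = [r for r in by_taxon[taxon] if r.available and np.isfinite(r.S_T)]
        z_raw = np.array([stats.norm.sf(r.S_T) for r in scored])
        z_adj = bh_adjust(z_raw) if len(z_raw) else np.array([])
        z_map = {r.subject_id: float(p) for r, p in zip(scored, z_adj)}
        if np.isfinite(adj_w[k]) and adj_w[k] < alpha:
            status = "frequent"
        elif len(z_adj) and np.nanmin(z_adj) < alpha:
            status = "occasional"
        else:
            status = "none"
        out.append(TaxonClassification(
            taxon_id=taxon,
            status=status,
            wilcoxon_p_adj=float(adj_w[k]) if np.isfinite(adj_w[k]) else float("nan"),
            z_p_adj=z_map,
            prevalence_oral=float(prev_oral.get(taxon, np.nan)),
            prevalence_gut=float(prev_gut.get(taxon, np.nan)),
        ))
    return out
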