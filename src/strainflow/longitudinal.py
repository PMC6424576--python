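"""Temporal stability, source-sink coupling and transmission-rate estimates.

Subjects sampled at multiple timepoints let us ask whether fecal strain
turnover is fed by the oral reservoir. For a (source t0, sink t0, sink t1)
sample triplet sharing coverage at >= 100 SNV positions, alleles *gained*
in the sink (covered and absent at t0, present at t1) are tested for
association with presence in the source at t0 by Fisher's exact test; the
oral-to-gut and gut-to-oral directions are tested independently and
Benjamini-Hochberg corrected as one family. The transmission rate is the
fraction of gained fecal alleles that were present in the paired oral
sample at t0 — a conservative lower estimate, since constant dispersal
pressure could also stabilise existing fecal alleles. Observed rates are
Z-standardized against two randomized backgrounds: shuffling fecal t1
samples within cohorts (*longitudinal*) and shuffling oral t0 samples
(*coupled*).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    CouplingResult,
    RateResult,
    SampleTable,
    SNVProfile,
)
from .transmission_scoring import bh_adjust

__all__ = [
    "stability",
    "coupling_test",
    "run_coupling_tests",
    "transmission_rate",
    "run_transmission_rates",
    "rate_background",
]


# ---------------------------------------------------------------------------
# Temporal stability
# ---------------------------------------------------------------------------


def _jaccard(a: np.ndarray, b: np.ndarray, covered: np.ndarray) -> float:
    pa = (a == 1) & covered
    pb = (b == 1) & covered
    union = (pa | pb).sum()
    if union == 0:
        return 0.0
    return float((pa & pb).sum() / union)


def stability(
    profile: SNVProfile,
    samples: SampleTable,
    site: str,
    min_shared: int = 20,
) -> pd.DataFrame:
    """Within- vs between-subject SNV profile similarity over time.

    For every subject with >= 2 timepoints at ``site``, the similarity of
    consecutive profiles (Jaccard of PRESENT sets over mutually covered
    positions) is contrasted with the similarity of the subject's earlier
    sample to other subjects' later samples at the matched timepoints.
    Returns a long table with columns ``subject_id, other_subject_id,
    t0, t1, kind (within|between), similarity``; pairs sharing coverage at
    fewer than ``min_shared`` positions are skipped.
    """
    rows = []
    site_subjects = [
        s for s in samples.subject_ids
        if len(samples.timepoints_of(s, site)) >= 2
    ]
    for subj in site_subjects:
        tps = samples.timepoints_of(subj, site)
        for t0, t1 in zip(tps[:-1], tps[1:]):
            s0 = samples.sample_for(subj, site, t0)
            a = profile.column(s0)
            for other in site_subjects:
                s1 = samples.sample_for(other, site, t1)
                if s1 is None:
                    continue
                b = profile.column(s1)
                covered = (a >= 0) & (b >= 0)
                if covered.sum() < min_shared:
                    continue
                rows.append((
                    subj, other, t0, t1,
                    "within" if other == subj else "between",
                    _jaccard(a, b, covered),
                ))
    return pd.DataFrame(
        rows, columns=["subject_id", "other_subject_id", "t0", "t1",
                       "kind", "similarity"]
    )


# ---------------------------------------------------------------------------
# Coupling tests
# ---------------------------------------------------------------------------


def _triplet_table(
    profile: SNVProfile,
    source_t0: str,
    sink_t0: str,
    sink_t1: str,
) -> tuple[np.ndarray, int]:
    """Eligible-allele mask and count for a (source, sink_t0, sink_t1) triplet."""
    cov = (
        (profile.column(source_t0) >= 0)
        & (profile.column(sink_t0) >= 0)
        & (profile.column(sink_t1) >= 0)
    )
    return cov, int(cov.sum())


def coupling_test(
    profile: SNVProfile,
    source_t0: str,
    sink_t0: str,
    sink_t1: str,
    min_positions: int = 100,
    alternative: Literal["two-sided", "greater"] = "two-sided",
) -> CouplingResult:
    """Fisher's exact test of gained sink alleles against the source profile.

    Over alleles covered in all three samples, builds the 2x2 table
    {gained in sink: present at t1 and absent at t0} x {present in source
    at t0} and computes the exact p-value and odds ratio. A zero gained
    margin leaves the odds ratio undefined; the result is flagged
    degenerate and not coupled. ``p_adj`` is NaN until BH correction over
    the full test family (see :func:`run_coupling_tests`).
    """
    eligible, n = _triplet_table(profile, source_t0, sink_t0, sink_t1)
    if n < min_positions:
        raise ValueError(
            f"triplet ({source_t0}, {sink_t0}, {sink_t1}) shares coverage at "
            f"{n} positions (< {min_positions})"
        )
    gained = eligible & (profile.column(sink_t1) == 1) & (profile.column(sink_t0) == 0)
    in_source = eligible & (profile.column(source_t0) == 1)
    a = int((gained & in_source).sum())
    b = int((gained & ~in_source).sum())
    c = int((~gained & eligible & in_source).sum())
    d = int((~gained & eligible & ~in_source).sum())
    if a + b == 0:
        return CouplingResult(
            taxon_id=profile.taxon_id, subject_id="", direction="",
            transition=0, contingency=(a, b, c, d),
            odds_ratio=float("nan"), p_value=float("nan"),
            p_adj=float("nan"), coupled=False, degenerate=True,
        )
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    return CouplingResult(
        taxon_id=profile.taxon_id, subject_id="", direction="",
        transition=0, contingency=(a, b, c, d),
        odds_ratio=float(odds), p_value=float(p), p_adj=float("nan"),
        coupled=False, degenerate=False,
    )


def _transitions(samples: SampleTable, subject: str) -> list[tuple[int, int, int]]:
    """Consecutive paired-timepoint transitions (index, t_k, t_{k+1})."""
    tps = samples.paired_timepoints(subject)
    return [(k + 1, t0, t1) for k, (t0, t1) in enumerate(zip(tps[:-1], tps[1:]))]


def run_coupling_tests(
    profiles: Iterable[SNVProfile],
    samples: SampleTable,
    min_positions: int = 100,
    alpha: float = 0.05,
    alternative: Literal["two-sided", "greater"] = "two-sided",
) -> list[CouplingResult]:
    """All (taxon, subject, transition, direction) coupling tests, BH-corrected.

    Both directions are tested per transition: oral as source with the gut
    as sink, and vice versa. Consecutive transitions of three-timepoint
    subjects are analyzed independently. BH correction spans every
    non-degenerate test; a result is coupled iff its odds ratio exceeds 1
    at adjusted p <= ``alpha``.
    """
    results: list[CouplingResult] = []
    for profile in profiles:
        for subject in samples.subject_ids:
            for k, t0, t1 in _transitions(samples, subject):
                for direction, src_site, sink_site in (
                    ("oral_to_gut", "oral", "gut"),
                    ("gut_to_oral", "gut", "oral"),
                ):
                    src = samples.sample_for(subject, src_site, t0)
                    sk0 = samples.sample_for(subject, sink_site, t0)
                    sk1 = samples.sample_for(subject, sink_site, t1)
                    if None in (src, sk0, sk1):
                        continue
                    _, n = _triplet_table(profile, src, sk0, sk1)
                    if n < min_positions:
                        continue
                    r = coupling_test(profile, src, sk0, sk1,
                                      min_positions=min_positions,
                                      alternative=alternative)
                    r.subject_id = subject
                    r.direction = direction
                    r.transition = k
                    results.append(r)
    p_adj = bh_adjust(np.array([r.p_value for r in results]))
    for r, p in zip(results, p_adj):
        r.p_adj = float(p)
        r.coupled = (
            not r.degenerate
            and np.isfinite(p)
            and r.odds_ratio > 1.0
            and p <= alpha
        )
    return results


# ---------------------------------------------------------------------------
# Transmission rates
# ---------------------------------------------------------------------------


def transmission_rate(
    profile: SNVProfile,
    oral_t0: str,
    gut_t0: str,
    gut_t1: str,
    min_positions: int = 100,
) -> RateResult:
    """Fraction of gained fecal alleles present in the paired oral t0 sample.

    Gained alleles require gut coverage at both timepoints (ABSENT at t0,
    PRESENT at t1); membership in the oral reservoir requires PRESENT in the
    oral t0 sample. Eligibility mirrors the coupling test (>= 100 positions
    covered in all three samples). With zero gained alleles the rate is
    undefined (NaN) and the result flagged via ``n_gained == 0``.
    """
    eligible, n = _triplet_table(profile, oral_t0, gut_t0, gut_t1)
    if n < min_positions:
        raise ValueError(
            f"triplet ({oral_t0}, {gut_t0}, {gut_t1}) shares coverage at "
            f"{n} positions (< {min_positions})"
        )
    gained = eligible & (profile.column(gut_t1) == 1) & (profile.column(gut_t0) == 0)
    in_oral = gained & (profile.column(oral_t0) == 1)
    n_gained = int(gained.sum())
    n_in_oral = int(in_oral.sum())
    return RateResult(
        taxon_id=profile.taxon_id, subject_id="", transition=0,
        n_gained=n_gained, n_gained_in_oral=n_in_oral,
        rate=n_in_oral / n_gained if n_gained else float("nan"),
    )


def run_transmission_rates(
    profiles: Iterable[SNVProfile],
    samples: SampleTable,
    min_positions: int = 100,
) -> list[RateResult]:
    """Observed transmission rates for all (taxon, subject, transition)."""
    results: list[RateResult] = []
    for profile in profiles:
        for subject in samples.subject_ids:
            for k, t0, t1 in _transitions(samples, subject):
                o = samples.sample_for(subject, "oral", t0)
                g0 = samples.sample_for(subject, "gut", t0)
                g1 = samples.sample_for(subject, "gut", t1)
                if None in (o, g0, g1):
                    continue
                _, n = _triplet_table(profile, o, g0, g1)
                if n < min_positions:
                    continue
                r = transmission_rate(profile, o, g0, g1,
                                      min_positions=min_positions)
                r.subject_id = subject
                r.transition = k
                results.append(r)
    return results


def rate_background(
    profiles: Sequence[SNVProfile],
    samples: SampleTable,
    observed: Sequence[RateResult] | None = None,
    mode: Literal["longitudinal", "coupled"] = "longitudinal",
    n_shuffles: int = 100,
    seed: int = 0,
    min_positions: int = 100,
    min_valid_shuffles: int = 10,
) -> list[RateResult]:
    """Z-standardize observed rates against within-cohort shuffled backgrounds.

    ``mode="longitudinal"`` shuffles which gut t1 sample is paired with each
    subject's (oral t0, gut t0) — a background on fecal strain turnover;
    ``mode="coupled"`` shuffles the oral t0 sample — a background on the
    oral reservoir. Shuffles permute samples among subjects within the same
    cohort and transition, preserving the per-cohort sample multiset. Rates
    are recomputed per shuffle; a Z score requires >= ``min_valid_shuffles``
    defined shuffled rates and a non-zero shuffled SD, otherwise the Z is
    left NaN.
    """
    if observed is None:
        observed = run_transmission_rates(profiles, samples, min_positions)
    rng = np.random.default_rng(seed)
    profile_of = {p.taxon_id: p for p in profiles}

    # group subjects by (cohort, transition) with complete triplets
    triplet: dict[tuple[str, int], dict[str, tuple[str, str, str]]] = {}
    for subject in samples.subject_ids:
        cohort = samples.frame.loc[
            samples.frame.subject_id == subject, "cohort"].iloc[0]
        for k, t0, t1 in _transitions(samples, subject):
            o = samples.sample_for(subject, "oral", t0)
            g0 = samples.sample_for(subject, "gut", t0)
            g1 = samples.sample_for(subject, "gut", t1)
            if None in (o, g0, g1):
                continue
            triplet.setdefault((cohort, k), {})[subject] = (o, g0, g1)

    shuffled: dict[tuple[str, str, int], list[float]] = {
        (r.taxon_id, r.subject_id, r.transition): [] for r in observed
    }
    for _ in range(n_shuffles):
        for (cohort, k), members in triplet.items():
            subjects = sorted(members)
            if len(subjects) < 2:
                continue
            perm = rng.permutation(len(subjects))
            for i, subject in enumerate(subjects):
                o, g0, g1 = members[subject]
                o_sh, g0_sh, g1_sh = members[subjects[perm[i]]]
                if mode == "longitudinal":
                    trip = (o, g0, g1_sh)
                else:
                    trip = (o_sh, g0, g1)
                for taxon, profile in profile_of.items():
                    key = (taxon, subject, k)
                    if key not in shuffled:
                        continue
                    _, n = _triplet_table(profile, *trip)
                    if n < min_positions:
                        continue
                    r = transmission_rate(profile, *trip,
                                          min_positions=min_positions)
                    if r.n_gained > 0:
                        shuffled[key].append(r.rate)

    out: list[RateResult] = []
    for r in observed:
        key = (r.taxon_id, r.subject_id, r.transition)
        vals = np.array(shuffled.get(key, []), dtype=float)
        z = float("nan")
        if r.defined and len(vals) >= min_valid_shuffles:
            sd = vals.std(ddof=1)
            if sd > 0:
                z = (r.rate - vals.mean()) / sd
        rr = RateResult(
            taxon_id=r.taxon_id, subject_id=r.subject_id,
            transition=r.transition, n_gained=r.n_gained,
            n_gained_in_oral=r.n_gained_in_oral, rate=r.rate,
            n_shuffles=n_shuffles,
        )
        if mode == "longitudinal":
            rr.z_longitudinal = z
        else:
            rr.z_coupled = z
        out.append(rr)
    return out
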