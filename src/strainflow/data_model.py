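"""Domain types and tabular I/O for oral-gut strain transmission analysis.

The pipeline operates on three kinds of input:

* a sample metadata table mapping metagenomic samples to subjects,
  cohorts, body sites (oral / gut) and timepoints;
* per-taxon SNV incidence tables in a metaSNV-like tabular dialect,
  with a ternary cell encoding distinguishing *uncovered* positions
  from positions that are covered but carry no alternative allele;
* a taxon relative-abundance matrix together with per-taxon horizontal
  (breadth) and vertical (depth) genome coverage.

All tables are plain TSV with ``#``-prefixed comment lines permitted.
Floats are written with 17 significant digits so result tables round-trip
bit-exactly through their writers and readers.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UNCOVERED",
    "ABSENT",
    "PRESENT",
    "SITES",
    "DataModelError",
    "SampleTable",
    "SNVProfile",
    "AbundanceMatrix",
    "AlleleBackground",
    "PairScore",
    "ScoreResult",
    "TaxonClassification",
    "CouplingResult",
    "RateResult",
    "read_sample_metadata",
    "read_snv_table",
    "write_snv_table",
    "read_abundance_table",
    "write_tsv",
    "read_tsv",
    "pair_scores_to_frame",
    "score_results_to_frame",
    "score_results_from_frame",
    "classifications_to_frame",
    "coupling_results_to_frame",
    "coupling_results_from_frame",
    "rate_results_to_frame",
    "rate_results_from_frame",
]

# Ternary cell codes. PRESENT/ABSENT both imply read coverage >= 1 at the
# position; UNCOVERED means no observation, hence no statement about the
# allele can be made for that sample.
UNCOVERED: int = -1
ABSENT: int = 0
PRESENT: int = 1

SITES = ("oral", "gut")

_FLOAT_FMT = "%.17g"

_ALLELE_RE = re.compile(r"^(?P<taxon>.+):(?P<pos>\d+):(?P<ref>[ACGT])>(?P<alt>[ACGT])$")


class DataModelError(ValueError):
    """Raised when an input table violates the format contract."""


# ---------------------------------------------------------------------------
# SampleTable
# ---------------------------------------------------------------------------


class SampleTable:
    """Registry of samples with subject, cohort, site and timepoint.

    Parameters
    ----------
    frame
        DataFrame with at least the columns ``sample_id``, ``subject_id``,
        ``cohort``, ``site`` and ``timepoint``. Optional ``family_id`` and
        ``village_id`` columns group subjects for background exclusion;
        unknown columns are preserved as opaque metadata.
    """

    REQUIRED = ("sample_id", "subject_id", "cohort", "site", "timepoint")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise DataModelError(f"sample table missing required columns: {missing}")
        frame = frame.copy()
        dup = frame["sample_id"][frame["sample_id"].duplicated()].unique().tolist()
        if dup:
            raise DataModelError(f"duplicate sample_id values: {dup}")
        bad_site = sorted(set(frame["site"]) - set(SITES))
        if bad_site:
            raise DataModelError(f"site must be one of {SITES}, got: {bad_site}")
        frame["timepoint"] = frame["timepoint"].astype(int)
        if (frame["timepoint"] < 0).any():
            raise DataModelError("timepoints must be non-negative integers")
        for opt in ("family_id", "village_id"):
            if opt not in frame.columns:
                frame[opt] = pd.NA
        key = frame[["subject_id", "site", "timepoint"]]
        if key.duplicated().any():
            dupes = key[key.duplicated()].to_records(index=False).tolist()
            raise DataModelError(
                f"(subject_id, site, timepoint) must be unique; duplicates: {dupes}"
            )
        self.frame = frame.reset_index(drop=True)
        self._by_sample = self.frame.set_index("sample_id")

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:
        return (
            f"SampleTable({len(self)} samples, {self.frame.subject_id.nunique()} "
            f"subjects, {self.frame.cohort.nunique()} cohorts)"
        )

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.frame["subject_id"].unique())

    def site_samples(self, site: str) -> list[str]:
        return self.frame.loc[self.frame["site"] == site, "sample_id"].tolist()

    def subject_of(self, sample_id: str) -> str:
        return self._by_sample.at[sample_id, "subject_id"]

    def cohort_of(self, sample_id: str) -> str:
        return self._by_sample.at[sample_id, "cohort"]

    def site_of(self, sample_id: str) -> str:
        return self._by_sample.at[sample_id, "site"]

    def timepoint_of(self, sample_id: str) -> int:
        return int(self._by_sample.at[sample_id, "timepoint"])

    def family_of(self, sample_id: str):
        v = self._by_sample.at[sample_id, "family_id"]
        return None if pd.isna(v) else v

    def village_of(self, sample_id: str):
        v = self._by_sample.at[sample_id, "village_id"]
        return None if pd.isna(v) else v

    def sample_for(self, subject_id: str, site: str, timepoint: int) -> str | None:
        sel = self.frame[
            (self.frame.subject_id == subject_id)
            & (self.frame.site == site)
            & (self.frame.timepoint == timepoint)
        ]
        if sel.empty:
            return None
        return sel["sample_id"].iloc[0]

    def timepoints_of(self, subject_id: str, site: str) -> list[int]:
        sel = self.frame[
            (self.frame.subject_id == subject_id) & (self.frame.site == site)
        ]
        return sorted(sel["timepoint"].tolist())

    def paired_timepoints(self, subject_id: str) -> list[int]:
        """Timepoints at which the subject has both an oral and a gut sample."""
        oral = set(self.timepoints_of(subject_id, "oral"))
        gut = set(self.timepoints_of(subject_id, "gut"))
        return sorted(oral & gut)

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_sample_metadata(path: str | Path) -> SampleTable:
    """Read a TSV sample metadata table into a validated :class:`SampleTable`."""
    frame = pd.read_csv(
        path, sep="\t", comment="#", dtype={"sample_id": str, "subject_id": str},
        na_values=["NA"], keep_default_na=True,
    )
    return SampleTable(frame)


# ---------------------------------------------------------------------------
# SNVProfile
# ---------------------------------------------------------------------------


@dataclass
class SNVProfile:
    """Ternary SNV incidence matrix for one taxon.

    ``matrix`` holds one row per allele (keyed ``taxon:position:ref>alt``)
    and one column per sample, with cells in {-1 (uncovered), 0 (covered,
    allele absent), 1 (allele present)}. PRESENT and ABSENT both imply the
    position is covered in that sample.
    """

    taxon_id: str
    allele_ids: list[str]
    sample_ids: list[str]
    matrix: np.ndarray  # int8, alleles x samples

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.allele_ids), len(self.sample_ids)):
            raise DataModelError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.allele_ids)} alleles x {len(self.sample_ids)} samples"
            )
        bad = ~np.isin(self.matrix, (UNCOVERED, ABSENT, PRESENT))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataModelError(
                f"invalid cell code {self.matrix[i, j]} at allele "
                f"{self.allele_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        seen: set[str] = set()
        for aid in self.allele_ids:
            if aid in seen:
                raise DataModelError(f"duplicate allele id {aid!r}")
            seen.add(aid)
            m = _ALLELE_RE.match(aid)
            if m is None:
                raise DataModelError(
                    f"malformed allele id {aid!r}; expected 'taxon:position:ref>alt'"
                )
            if m["taxon"] != self.taxon_id:
                raise DataModelError(
                    f"allele {aid!r} does not belong to taxon {self.taxon_id!r}"
                )
            if int(m["pos"]) < 1:
                raise DataModelError(f"allele {aid!r}: positions are 1-based")
            if m["ref"] == m["alt"]:
                raise DataModelError(f"allele {aid!r}: ref equals alt")
        self._col = {s: j for j, s in enumerate(self.sample_ids)}

    @property
    def n_alleles(self) -> int:
        return len(self.allele_ids)

    def column(self, sample_id: str) -> np.ndarray:
        return self.matrix[:, self._col[sample_id]]

    def column_index(self, sample_id: str) -> int:
        return self._col[sample_id]

    def covered(self) -> np.ndarray:
        """Boolean alleles x samples matrix of positions with coverage >= 1."""
        return self.matrix != UNCOVERED

    def present(self) -> np.ndarray:
        return self.matrix == PRESENT

    def absent(self) -> np.ndarray:
        return self.matrix == ABSENT

    def subset_alleles(self, keep: np.ndarray) -> "SNVProfile":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return SNVProfile(
            taxon_id=self.taxon_id,
            allele_ids=[self.allele_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            matrix=self.matrix[idx, :],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "SNVProfile":
        idx = [self._col[s] for s in sample_ids]
        return SNVProfile(
            taxon_id=self.taxon_id,
            allele_ids=list(self.allele_ids),
            sample_ids=list(sample_ids),
            matrix=self.matrix[:, idx],
        )

    def validate_against(self, samples: SampleTable) -> None:
        unknown = set(self.sample_ids) - set(samples.sample_ids)
        if unknown:
            raise DataModelError(
                f"taxon {self.taxon_id}: sample columns not in metadata: {sorted(unknown)}"
            )


def read_snv_table(path: str | Path) -> list[SNVProfile]:
    """Read a ternary SNV incidence TSV into one :class:`SNVProfile` per taxon.

    The first column holds allele ids ``taxon:position:ref>alt``; remaining
    columns are samples with cells in {-1, 0, 1}. Rows of different taxa may
    be interleaved; grouping is by the taxon prefix of the allele id.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    sample_ids = [str(c) for c in frame.columns]
    values = frame.to_numpy()
    if values.size and not np.isin(values, (-1, 0, 1)).all():
        bad = np.argwhere(~np.isin(values, (-1, 0, 1)))[0]
        raise DataModelError(
            f"cell code {values[bad[0], bad[1]]!r} outside {{-1,0,1}} at row "
            f"{frame.index[bad[0]]!r}, column {sample_ids[bad[1]]!r}"
        )
    taxa: dict[str, list[int]] = {}
    for i, aid in enumerate(frame.index):
        m = _ALLELE_RE.match(str(aid))
        if m is None:
            raise DataModelError(f"malformed allele id {aid!r} at row {i + 1}")
        taxa.setdefault(m["taxon"], []).append(i)
    profiles = []
    for taxon, rows in taxa.items():
        profiles.append(
            SNVProfile(
                taxon_id=taxon,
                allele_ids=[str(frame.index[i]) for i in rows],
                sample_ids=sample_ids,
                matrix=values[rows, :].astype(np.int8),
            )
        )
    return profiles


def write_snv_table(profiles: Iterable[SNVProfile], path: str | Path) -> None:
    """Write one or more profiles (sharing a sample set) to a ternary TSV."""
    profiles = list(profiles)
    if not profiles:
        raise DataModelError("no profiles to write")
    sample_ids = profiles[0].sample_ids
    for p in profiles[1:]:
        if p.sample_ids != sample_ids:
            raise DataModelError("profiles do not share a common sample set")
    blocks = [
        pd.DataFrame(p.matrix, index=p.allele_ids, columns=sample_ids)
        for p in profiles
    ]
    out = pd.concat(blocks)
    out.index.name = "allele_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# AbundanceMatrix
# ---------------------------------------------------------------------------


@dataclass
class AbundanceMatrix:
    """Taxon x sample relative abundance plus genome-coverage layers.

    ``rel_abundance`` holds per-sample relative abundances in [0, 1] whose
    column sums may be below 1 (an unclassified remainder is allowed).
    ``horizontal_coverage`` is genome breadth in [0, 1]; ``vertical_coverage``
    is mean depth (>= 0). All three share identical taxon/sample labels.
    """

    rel_abundance: pd.DataFrame
    horizontal_coverage: pd.DataFrame
    vertical_coverage: pd.DataFrame

    def __post_init__(self) -> None:
        a, h, v = self.rel_abundance, self.horizontal_coverage, self.vertical_coverage
        for name, m in (("horizontal_coverage", h), ("vertical_coverage", v)):
            if not (m.index.equals(a.index) and m.columns.equals(a.columns)):
                mism = (set(a.columns) ^ set(m.columns)) or (set(a.index) ^ set(m.index))
                raise DataModelError(
                    f"{name} labels do not match rel_abundance: {sorted(mism)}"
                )
        if (a.to_numpy() < 0).any():
            raise DataModelError("negative relative abundances")
        sums = a.sum(axis=0)
        over = sums[sums > 1 + 1e-9]
        if not over.empty:
            raise DataModelError(
                f"per-sample relative abundance sums exceed 1: {over.to_dict()}"
            )
        if (h.to_numpy() < 0).any() or (h.to_numpy() > 1 + 1e-12).any():
            raise DataModelError("horizontal coverage must lie in [0, 1]")
        if (v.to_numpy() < 0).any():
            raise DataModelError("vertical coverage must be non-negative")

    @property
    def taxa(self) -> list[str]:
        return self.rel_abundance.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.rel_abundance.columns.tolist()

    def write(self, path_abund, path_hcov, path_vcov) -> None:
        for frame, path in (
            (self.rel_abundance, path_abund),
            (self.horizontal_coverage, path_hcov),
            (self.vertical_coverage, path_vcov),
        ):
            out = frame.copy()
            out.index.name = "taxon_id"
            out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_abundance_table(path_abund, path_hcov, path_vcov) -> AbundanceMatrix:
    """Read abundance + coverage TSVs that share taxon/sample labels."""
    read = lambda p: pd.read_csv(p, sep="\t", comment="#", index_col=0)
    return AbundanceMatrix(read(path_abund), read(path_hcov), read(path_vcov))


# ---------------------------------------------------------------------------
# Derived/result records
# ---------------------------------------------------------------------------


@dataclass
class AlleleBackground:
    """Background incidence frequencies and agreement probabilities per allele.

    ``f_oral`` / ``f_gut`` are the fractions of covered oral / gut samples in
    which the allele is present, clamped away from {0, 1} (see
    :func:`strainflow.transmission_scoring.allele_incidence`). The four
    probabilities partition the paired-observation outcome space per allele:
    present in both (``p_11``), absent in both (``p_00``), present only
    orally (``p_10``), present only in the gut (``p_01``).
    """

    taxon_id: str
    allele_ids: list[str]
    f_oral: np.ndarray
    f_gut: np.ndarray
    n_oral_covered: np.ndarray
    n_gut_covered: np.ndarray

    @property
    def p_11(self) -> np.ndarray:
        return self.f_oral * self.f_gut

    @property
    def p_00(self) -> np.ndarray:
        return (1.0 - self.f_oral) * (1.0 - self.f_gut)

    @property
    def p_10(self) -> np.ndarray:
        return self.f_oral * (1.0 - self.f_gut)

    @property
    def p_01(self) -> np.ndarray:
        return (1.0 - self.f_oral) * self.f_gut


@dataclass
class PairScore:
    """Likelihood summary for one oral-gut sample pair of one taxon."""

    taxon_id: str
    oral_sample_id: str
    gut_sample_id: str
    n_shared_positions: int
    L_obs: float
    L_min: float
    P_raw: float


@dataclass
class ScoreResult:
    """Z-standardized transmission score for one (taxon, subject)."""

    taxon_id: str
    subject_id: str
    P_raw_intra: float
    mu_raw: float
    sigma_raw: float
    S_T: float
    background_mode: str
    n_background_pairs: int
    available: bool = True
    reason: str = ""


@dataclass
class TaxonClassification:
    """Transmitter status of one taxon across the cohort."""

    taxon_id: str
    status: str  # frequent | occasional | none
    wilcoxon_p_adj: float
    z_p_adj: dict[str, float] = field(default_factory=dict)
    prevalence_oral: float = float("nan")
    prevalence_gut: float = float("nan")


@dataclass
class CouplingResult:
    """Fisher coupling test of gained sink alleles against the source profile."""

    taxon_id: str
    subject_id: str
    direction: str  # oral_to_gut | gut_to_oral
    transition: int  # index of the t_k -> t_{k+1} transition
    contingency: tuple[int, int, int, int]  # (a, b, c, d) row-major
    odds_ratio: float
    p_value: float
    p_adj: float
    coupled: bool
    degenerate: bool = False


@dataclass
class RateResult:
    """Oral-sourced fraction of newly gained fecal alleles for one transition."""

    taxon_id: str
    subject_id: str
    transition: int
    n_gained: int
    n_gained_in_oral: int
    rate: float  # nan when n_gained == 0
    z_longitudinal: float = float("nan")
    z_coupled: float = float("nan")
    n_shuffles: int = 0

    @property
    def defined(self) -> bool:
        return self.n_gained > 0


# ---------------------------------------------------------------------------
# Result table I/O
# ---------------------------------------------------------------------------


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a result table with full float precision (round-trip safe)."""
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="NA")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"],
                       float_precision="round_trip")


def pair_scores_to_frame(scores: Iterable[PairScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.taxon_id, s.oral_sample_id, s.gut_sample_id,
             s.n_shared_positions, s.L_obs, s.L_min, s.P_raw)
            for s in scores
        ],
        columns=["taxon_id", "oral_sample_id", "gut_sample_id",
                 "n_shared_positions", "L_obs", "L_min", "P_raw"],
    )


_SCORE_COLS = ["taxon_id", "subject_id", "P_raw_intra", "mu_raw", "sigma_raw",
               "S_T", "background_mode", "n_background_pairs", "available", "reason"]


def score_results_to_frame(results: Iterable[ScoreResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [[getattr(r, c) for c in _SCORE_COLS] for r in results], columns=_SCORE_COLS
    )


def score_results_from_frame(frame: pd.DataFrame) -> list[ScoreResult]:
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            ScoreResult(
                taxon_id=row.taxon_id, subject_id=row.subject_id,
                P_raw_intra=float(row.P_raw_intra), mu_raw=float(row.mu_raw),
                sigma_raw=float(row.sigma_raw), S_T=float(row.S_T),
                background_mode=row.background_mode,
                n_background_pairs=int(row.n_background_pairs),
                available=bool(row.available),
                reason="" if pd.isna(row.reason) else str(row.reason),
            )
        )
    return out


def classifications_to_frame(cls: Iterable[TaxonClassification]) -> pd.DataFrame:
    rows = []
    for c in cls:
        n_sig = sum(1 for p in c.z_p_adj.values() if p < 0.05)
        rows.append(
            (c.taxon_id, c.status, c.wilcoxon_p_adj, n_sig,
             c.prevalence_oral, c.prevalence_gut)
        )
    return pd.DataFrame(
        rows,
        columns=["taxon_id", "status", "wilcoxon_p_adj",
                 "n_subjects_significant", "prevalence_oral", "prevalence_gut"],
    )


def z_padj_to_frame(cls: Iterable[TaxonClassification]) -> pd.DataFrame:
    rows = [
        (c.taxon_id, subj, p) for c in cls for subj, p in sorted(c.z_p_adj.items())
    ]
    return pd.DataFrame(rows, columns=["taxon_id", "subject_id", "z_p_adj"])


_COUPLING_COLS = ["taxon_id", "subject_id", "direction", "transition",
                  "a", "b", "c", "d", "odds_ratio", "p_value", "p_adj",
                  "coupled", "degenerate"]


def coupling_results_to_frame(results: Iterable[CouplingResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        a, b, c, d = r.contingency
        rows.append((r.taxon_id, r.subject_id, r.direction, r.transition,
                     a, b, c, d, r.odds_ratio, r.p_value, r.p_adj,
                     r.coupled, r.degenerate))
    return pd.DataFrame(rows, columns=_COUPLING_COLS)


def coupling_results_from_frame(frame: pd.DataFrame) -> list[CouplingResult]:
    return [
        CouplingResult(
            taxon_id=row.taxon_id, subject_id=row.subject_id,
            direction=row.direction, transition=int(row.transition),
            contingency=(int(row.a), int(row.b), int(row.c), int(row.d)),
            odds_ratio=float(row.odds_ratio), p_value=float(row.p_value),
            p_adj=float(row.p_adj), coupled=bool(row.coupled),
            degenerate=bool(row.degenerate),
        )
        for row in frame.itertuples(index=False)
    ]


_RATE_COLS = ["taxon_id", "subject_id", "transition", "n_gained",
              "n_gained_in_oral", "rate", "z_longitudinal", "z_coupled",
              "n_shuffles"]


def rate_results_to_frame(results: Iterable[RateResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [[getattr(r, c) for c in _RATE_COLS] for r in results], columns=_RATE_COLS
    )


def rate_results_from_frame(frame: pd.DataFrame) -> list[RateResult]:
    return [
        RateResult(
            taxon_id=row.taxon_id, subject_id=row.subject_id,
            transition=int(row.transition), n_gained=int(row.n_gained),
            n_gained_in_oral=int(row.n_gained_in_oral), rate=float(row.rate),
            z_longitudinal=float(row.z_longitudinal),
            z_coupled=float(row.z_coupled), n_shuffles=int(row.n_shuffles),
        )
        for row in frame.itertuples(index=False)
    ]
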