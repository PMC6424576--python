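"""Synthetic cohorts with known oral-gut transmission structure.

The simulator emulates the data shape the scoring pipeline consumes: paired
salivary and fecal SNV incidence profiles per subject, per-allele incidence
frequencies drawn from a Beta law, intra-individual allele sharing for
transmitter species, independent site populations for non-transmitters,
per-position coverage dropout, longitudinal fecal allele turnover with a
controllable oral-sourcing rate, and compositional abundance profiles with
site preference. Every latent variable needed for recovery tests is recorded
in a :class:`TruthRecord`.

Model sketch, per species with per-allele incidence ``q_i ~ Beta(a, b)``:

* a subject's oral population carries allele ``i`` with probability ``q_i``;
* for transmitter species the gut population copies the oral carriage state
  of each allele with probability ``tau`` and otherwise draws independently
  from ``Bernoulli(q_i)``, so the marginal gut incidence stays ``q_i`` while
  oral-gut agreement rises with ``tau``; non-transmitters draw the gut
  population fully independently;
* between consecutive timepoints a fraction ``theta`` of the gut allele set
  is replaced; each gained allele is copied from the subject's baseline oral
  set (probability ``r``, the oral-sourcing rate) or drawn from an
  environmental pool disjoint from that oral set;
* coverage dropout is independent Bernoulli per (allele, sample), producing
  UNCOVERED cells.

Oral populations are held constant over time: salivary strain populations
are temporally stable in the regime this generator mimics, and the rate
estimators only require turnover on the fecal side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ABSENT,
    PRESENT,
    UNCOVERED,
    AbundanceMatrix,
    SampleTable,
    SNVProfile,
)

__all__ = [
    "SpeciesSpec",
    "SimulationConfig",
    "TruthRecord",
    "simulate_cohort",
    "simulate_longitudinal_turnover",
]

CLASSES = ("frequent", "occasional", "none", "oral_only", "gut_only")


@dataclass
class SpeciesSpec:
    """Panel entry: one simulated species and its transmission behaviour."""

    taxon_id: str
    transmitter_class: str = "none"
    n_alleles: int = 200
    tau: float | None = None  # defaults by class, see SimulationConfig.resolve_tau
    occasional_subject_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.transmitter_class not in CLASSES:
            raise ValueError(
                f"{self.taxon_id}: unknown class {self.transmitter_class!r}"
            )
        if self.n_alleles < 2:
            raise ValueError(f"{self.taxon_id}: species needs >= 2 alleles")
        if self.tau is not None and not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"{self.taxon_id}: tau must lie in [0, 1]")
        if self.transmitter_class in ("none", "oral_only", "gut_only") and self.tau:
            raise ValueError(
                f"{self.taxon_id}: tau > 0 is inconsistent with class "
                f"{self.transmitter_class!r}"
            )


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator; the seed fully determines output."""

    n_subjects: int = 50
    n_cohorts: int = 2
    species: Sequence[SpeciesSpec] = field(default_factory=list)
    beta_a: float = 0.7
    beta_b: float = 3.0
    dropout: float = 0.1
    n_timepoints: int = 1
    turnover: float = 0.2  # theta: fraction of gut alleles replaced per transition
    oral_source_rate: float = 0.5  # r: P(gained gut allele copied from oral t0)
    family_fraction: float = 0.0  # fraction of subjects paired into families
    family_sharing: float = 0.5  # oral-state copy probability within a family pair
    abundance_sigma: float = 1.0  # log-normal spread of abundance draws
    site_preference: float = 4.0  # fold preference of oral_only/gut_only species
    unclassified_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout", "turnover", "oral_source_rate",
                     "family_fraction", "family_sharing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_subjects < 1 or self.n_timepoints < 1 or self.n_cohorts < 1:
            raise ValueError("n_subjects, n_cohorts, n_timepoints must be >= 1")
        self.species = [
            sp if isinstance(sp, SpeciesSpec) else SpeciesSpec(**sp)
            for sp in self.species
        ]

    @staticmethod
    def resolve_tau(spec: SpeciesSpec) -> float:
        if spec.tau is not None:
            return spec.tau
        return 0.8 if spec.transmitter_class in ("frequent", "occasional") else 0.0

    @classmethod
    def default_panel(
        cls, n_frequent=4, n_occasional=2, n_none=4, n_oral_only=1, n_gut_only=1,
        n_alleles=200, **kwargs,
    ) -> "SimulationConfig":
        """Convenience panel covering all transmitter classes."""
        species, k = [], 0
        for klass, n in (("frequent", n_frequent), ("occasional", n_occasional),
                         ("none", n_none), ("oral_only", n_oral_only),
                         ("gut_only", n_gut_only)):
            for _ in range(n):
                k += 1
                species.append(SpeciesSpec(f"sp{k:03d}", klass, n_alleles))
        return cls(species=species, **kwargs)


@dataclass
class TruthRecord:
    """Ground truth sampled by the simulator, for recovery tests.

    ``transmitter_class`` maps taxon -> simulated class;
    ``shared_fraction`` maps (taxon, subject) -> fraction of the subject's
    baseline oral alleles also in the baseline gut population;
    ``gain_sources`` maps (taxon, subject, transition) -> list of
    ``(allele_id, source, fallback)`` where source is ``"oral"`` or
    ``"pool"`` and fallback marks oral-sourcing requests that had to fall
    back to the pool because the oral-private set was exhausted.
    """

    transmitter_class: dict[str, str] = field(default_factory=dict)
    shared_fraction: dict[tuple[str, str], float] = field(default_factory=dict)
    gain_sources: dict[tuple[str, str, int], list[tuple[str, str, bool]]] = field(
        default_factory=dict
    )
    occasional_subjects: dict[str, list[str]] = field(default_factory=dict)

    def oral_source_fraction(self, taxon_id: str | None = None) -> float:
        """Realized fraction of gained gut alleles that were oral-sourced."""
        total = oral = 0
        for (t, _, _), gains in self.gain_sources.items():
            if taxon_id is not None and t != taxon_id:
                continue
            for _, source, _ in gains:
                total += 1
                oral += source == "oral"
        return oral / total if total else float("nan")

    def write(self, path: str | Path) -> None:
        payload = {
            "transmitter_class": self.transmitter_class,
            "shared_fraction": [
                [t, s, v] for (t, s), v in sorted(self.shared_fraction.items())
            ],
            "gain_sources": [
                [t, s, k, [[a, src, bool(fb)] for a, src, fb in gains]]
                for (t, s, k), gains in sorted(self.gain_sources.items())
            ],
            "occasional_subjects": self.occasional_subjects,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "TruthRecord":
        payload = json.loads(Path(path).read_text())
        return cls(
            transmitter_class=payload["transmitter_class"],
            shared_fraction={
                (t, s): v for t, s, v in payload["shared_fraction"]
            },
            gain_sources={
                (t, s, k): [(a, src, bool(fb)) for a, src, fb in gains]
                for t, s, k, gains in payload["gain_sources"]
            },
            occasional_subjects=payload.get("occasional_subjects", {}),
        )


# ---------------------------------------------------------------------------


def simulate_longitudinal_turnover(
    gut_present: np.ndarray,
    oral_t0_present: np.ndarray,
    theta: float,
    r: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[int, str, bool]]]:
    """Advance one gut allele population by one timepoint.

    A fraction ``theta`` of the current gut allele set is removed and replaced
    by the same number of newly gained alleles. Each gained allele is copied
    from the subject's baseline oral set minus the current gut set with
    probability ``r`` ("oral"-sourced), otherwise drawn from the environmental
    pool of alleles carried by neither site ("pool"-sourced). If the eligible
    oral set is exhausted while oral sourcing was requested, the draw falls
    back to the pool and the fallback is recorded.

    Returns the next-timepoint boolean presence vector and a provenance list
    of ``(allele_index, source, fallback)`` for every gained allele.
    """
    if not 0.0 <= theta <= 1.0 or not 0.0 <= r <= 1.0:
        raise ValueError("theta and r must lie in [0, 1]")
    current = gut_present.copy()
    carried = np.flatnonzero(current)
    n_replace = int(round(theta * len(carried)))
    gains: list[tuple[int, str, bool]] = []
    if n_replace == 0:
        return current, gains
    lost = rng.choice(carried, size=n_replace, replace=False)
    current[lost] = False
    for _ in range(n_replace):
        want_oral = rng.random() < r
        oral_eligible = np.flatnonzero(oral_t0_present & ~current)
        pool = np.flatnonzero(~oral_t0_present & ~current)
        if want_oral and len(oral_eligible):
            idx = int(rng.choice(oral_eligible))
            gains.append((idx, "oral", False))
        elif len(pool):
            idx = int(rng.choice(pool))
            gains.append((idx, "pool", want_oral))
        elif len(oral_eligible):  # pool exhausted, oral still available
            idx = int(rng.choice(oral_eligible))
            gains.append((idx, "oral", not want_oral))
        else:
            continue  # nothing left to gain
        current[idx] = True
    return current, gains


def _sample_id(subject: str, site: str, tp: int) -> str:
    return f"{subject}_{site}_t{tp}"


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[SampleTable, list[SNVProfile], AbundanceMatrix, TruthRecord]:
    """Generate a full synthetic cohort.

    Returns the sample registry, one ternary SNV profile per species, the
    abundance/coverage matrix and the ground-truth record. Identical configs
    (including the seed) produce byte-identical outputs.
    """
    if not config.species:
        raise ValueError("config.species must list at least one species")
    rng = np.random.default_rng(config.seed)
    subjects = [f"S{i:04d}" for i in range(1, config.n_subjects + 1)]
    cohorts = {s: f"C{(i % config.n_cohorts) + 1}" for i, s in enumerate(subjects)}

    # Optional family pairing: consecutive same-cohort subjects share a family
    # id and the later member's oral draw copies the earlier member's state
    # with probability family_sharing (elevated between-subject sharing).
    family_of: dict[str, str] = {}
    family_partner: dict[str, str] = {}
    if config.family_fraction > 0:
        n_pairs = int(config.family_fraction * config.n_subjects / 2)
        by_cohort: dict[str, list[str]] = {}
        for s in subjects:
            by_cohort.setdefault(cohorts[s], []).append(s)
        made = 0
        for members in by_cohort.values():
            for a, b in zip(members[::2], members[1::2]):
                if made >= n_pairs:
                    break
                fid = f"F{made + 1:03d}"
                family_of[a] = family_of[b] = fid
                family_partner[b] = a
                made += 1

    rows = []
    for s in subjects:
        for tp in range(config.n_timepoints):
            for site in ("oral", "gut"):
                rows.append(
                    (_sample_id(s, site, tp), s, cohorts[s], site, tp,
                     family_of.get(s), None)
                )
    samples = SampleTable(
        pd.DataFrame(
            rows,
            columns=["sample_id", "subject_id", "cohort", "site",
                     "timepoint", "family_id", "village_id"],
        )
    )
    sample_ids = samples.sample_ids
    col = {sid: j for j, sid in enumerate(sample_ids)}

    truth = TruthRecord()
    profiles: list[SNVProfile] = []
    bases = np.array(["A", "C", "G", "T"])

    for spec in config.species:
        tau = SimulationConfig.resolve_tau(spec)
        truth.transmitter_class[spec.taxon_id] = spec.transmitter_class
        n_all = spec.n_alleles
        q = rng.beta(config.beta_a, config.beta_b, size=n_all)

        if spec.transmitter_class == "occasional":
            n_occ = max(1, int(round(spec.occasional_subject_fraction
                                     * config.n_subjects)))
            occ = sorted(rng.choice(subjects, size=n_occ, replace=False).tolist())
            truth.occasional_subjects[spec.taxon_id] = occ
            occ_set = set(occ)
        else:
            occ_set = set()

        ref = bases[rng.integers(0, 4, size=n_all)]
        alt = np.array([
            bases[(np.flatnonzero(bases != r0))[rng.integers(0, 3)]] for r0 in ref
        ])
        allele_ids = [
            f"{spec.taxon_id}:{pos + 1}:{r0}>{a0}"
            for pos, (r0, a0) in enumerate(zip(ref, alt))
        ]

        truth_matrix = np.zeros((n_all, len(sample_ids)), dtype=bool)
        detected = np.zeros(len(sample_ids), dtype=bool)
        oral_t0: dict[str, np.ndarray] = {}

        for s in subjects:
            oral = rng.random(n_all) < q
            if s in family_partner and config.family_sharing > 0:
                partner_oral = oral_t0.get(_sample_id(family_partner[s], "oral", 0))
                if partner_oral is not None:
                    copy = rng.random(n_all) < config.family_sharing
                    oral = np.where(copy, partner_oral, oral)
            subject_tau = tau if (
                spec.transmitter_class == "frequent"
                or (spec.transmitter_class == "occasional" and s in occ_set)
            ) else 0.0
            if subject_tau > 0:
                copy = rng.random(n_all) < subject_tau
                gut = np.where(copy, oral, rng.random(n_all) < q)
            else:
                gut = rng.random(n_all) < q

            n_oral = int(oral.sum())
            truth.shared_fraction[(spec.taxon_id, s)] = (
                float((oral & gut).sum() / n_oral) if n_oral else float("nan")
            )
            oral_t0[_sample_id(s, "oral", 0)] = oral

            has_oral = spec.transmitter_class != "gut_only"
            has_gut = spec.transmitter_class != "oral_only"
            gut_state = gut
            for tp in range(config.n_timepoints):
                if tp > 0 and has_gut:
                    gut_state, gains = simulate_longitudinal_turnover(
                        gut_state, oral, config.turnover,
                        config.oral_source_rate, rng,
                    )
                    truth.gain_sources[(spec.taxon_id, s, tp)] = [
                        (allele_ids[i], src, fb) for i, src, fb in gains
                    ]
                if has_oral:
                    j = col[_sample_id(s, "oral", tp)]
                    truth_matrix[:, j] = oral
                    detected[j] = True
                if has_gut:
                    j = col[_sample_id(s, "gut", tp)]
                    truth_matrix[:, j] = gut_state
                    detected[j] = True

        matrix = np.where(truth_matrix, PRESENT, ABSENT).astype(np.int8)
        if config.dropout > 0:
            drop = rng.random(matrix.shape) < config.dropout
            matrix[drop] = UNCOVERED
        matrix[:, ~detected] = UNCOVERED  # species not detected at that site
        profiles.append(
            SNVProfile(spec.taxon_id, allele_ids, list(sample_ids), matrix)
        )

    abundance = _simulate_abundance(config, samples, profiles, rng)
    for p in profiles:
        p.validate_against(samples)
    return samples, profiles, abundance, truth


def _simulate_abundance(
    config: SimulationConfig,
    samples: SampleTable,
    profiles: list[SNVProfile],
    rng: np.random.Generator,
) -> AbundanceMatrix:
    """Compositional log-normal abundances with per-class site preference."""
    taxa = [p.taxon_id for p in profiles]
    sample_ids = samples.sample_ids
    shape = (len(taxa), len(sample_ids))
    covered_any = np.stack([p.covered().any(axis=0) for p in profiles])

    raw = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=shape)
    # single-site specialists are enriched at their home site
    is_oral = np.array([samples.site_of(s) == "oral" for s in sample_ids])
    class_of = {sp.taxon_id: sp.transmitter_class for sp in config.species}
    for i, p in enumerate(profiles):
        klass = class_of.get(p.taxon_id)
        if klass == "oral_only":
            raw[i, is_oral] *= config.site_preference
        elif klass == "gut_only":
            raw[i, ~is_oral] *= config.site_preference
    # coverage layers: detected taxa have ample breadth/depth, undetected fall
    # below the filtering thresholds
    hcov = np.where(covered_any, rng.uniform(0.3, 0.95, shape),
                    rng.uniform(0.0, 0.04, shape))
    vcov = np.where(covered_any, rng.uniform(0.5, 5.0, shape),
                    rng.uniform(0.0, 0.2, shape))
    raw[~covered_any] = 0.0  # undetected at this site/sample
    sums = raw.sum(axis=0)
    sums[sums == 0] = 1.0
    rel = raw / sums * (1.0 - config.unclassified_fraction)
    frame = lambda m: pd.DataFrame(m, index=taxa, columns=sample_ids)
    return AbundanceMatrix(frame(rel), frame(hcov), frame(vcov))


def write_cohort(
    outdir: str | Path,
    samples: SampleTable,
    profiles: list[SNVProfile],
    abundance: AbundanceMatrix,
    truth: TruthRecord,
) -> dict[str, Path]:
    """Write all simulator outputs into ``outdir``; returns the path map."""
    from .data_model import write_snv_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": outdir / "samples.tsv",
        "snv": outdir / "snv_profiles.tsv",
        "abundance": outdir / "abundance.tsv",
        "hcov": outdir / "horizontal_coverage.tsv",
        "vcov": outdir / "vertical_coverage.tsv",
        "truth": outdir / "truth.json",
    }
    samples.write(paths["samples"])
    write_snv_table(profiles, paths["snv"])
    abundance.write(paths["abundance"], paths["hcov"], paths["vcov"])
    truth.write(paths["truth"])
    return paths
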