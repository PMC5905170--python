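"""Synthetic multi-run plasma LC-MS/MS studies with known ground truth.

The generator emulates the statistical structure the downstream pipeline
assumes in real per-sample search-engine exports:

* a fixed roster of true peptide features per protein, each with a
  tryptic-like sequence, its monoisotopic mass (computed with pyteomics)
  and a true elution time;
* per-sample monotone retention-time drift (affine trend plus a smooth
  bounded sinusoidal perturbation) and small per-observation rt jitter;
* ppm-scale Gaussian mass measurement error;
* log-normal peak areas with per-subject biological variation shared by
  all peptides of a protein, multiplicative technical noise, and a
  multiplicative group effect on designated differential proteins in
  case samples;
* missingness at the identification level (a feature simply absent from
  a run) and at the area level (identified, but no area retrieved); and
* run-unique spurious singleton features ("decoys") that no other run
  shares.

Distinct true features are kept separated by at least three clustering
windows in mass or rt so that the ground-truth feature <-> cluster
correspondence is well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as pyt_mass
from scipy.optimize import brentq

from .exceptions import ConfigError
from .io_formats import PeptideRecord, SampleInfo, StudyDesign

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# retention-time drift
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DriftSpec:
    """Monotone rt distortion: affine trend + smooth sinusoid.

    drift(rt) = slope * rt + intercept + amplitude * sin(2*pi*(rt + phase)/period)

    Monotonicity requires slope > amplitude * 2*pi / period.
    """

    slope: float = 1.0
    intercept: float = 0.0
    amplitude: float = 0.0
    period: float = 200.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ConfigError("drift period must be positive")
        if self.slope <= abs(self.amplitude) * 2.0 * math.pi / self.period:
            raise ConfigError(
                "drift spec is not strictly monotone: slope must exceed "
                "amplitude * 2*pi / period"
            )

    @classmethod
    def identity(cls) -> "DriftSpec":
        return cls()


def apply_drift(rt: float | np.ndarray, spec: DriftSpec):
    """Distort true rt (minutes) through a sample's monotone drift."""
    rt = np.asarray(rt, dtype=float)
    out = (
        spec.slope * rt
        + spec.intercept
        + spec.amplitude * np.sin(2.0 * np.pi * (rt + spec.phase) / spec.period)
    )
    return float(out) if out.ndim == 0 else out


def invert_drift(observed_rt: float, spec: DriftSpec, bracket: tuple[float, float] = (-1e4, 1e5)) -> float:
    """Numerically invert a monotone drift (root bracketing)."""
    return brentq(lambda x: apply_drift(x, spec) - observed_rt, *bracket, xtol=1e-9)


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DriftConfig:
    """Per-sample drift parameters are drawn uniformly from these ranges."""

    slope_range: tuple[float, float] = (0.97, 1.03)
    intercept_range: tuple[float, float] = (-3.0, 3.0)
    amplitude_range: tuple[float, float] = (0.0, 1.5)
    period: float = 200.0


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic generator.

    Defaults reproduce the study layout: a 13-case/8-control discovery
    set and a 6-case/5-control test set, an eight-hour-class gradient
    (rt 20-480 min), 2 ppm mass error, and six true differential
    proteins at |log2 effect| = 1.5.
    """

    n_cases_discovery: int = 13
    n_controls_discovery: int = 8
    n_cases_test: int = 6
    n_controls_test: int = 5
    n_proteins: int = 40
    peptides_per_protein: tuple[int, int] = (2, 6)
    n_de_proteins: int = 6
    de_log2_effect: float = 1.5
    true_de_proteins: tuple[tuple[str, float], ...] | None = None
    rt_range: tuple[float, float] = (20.0, 480.0)
    rt_noise_sd: float = 0.05  # minutes, per-observation apex jitter
    drift: DriftConfig = field(default_factory=DriftConfig)
    mass_error_sd_ppm: float = 2.0
    base_area_lognormal: tuple[float, float] = (16.0, 1.5)  # (mu, sigma) of ln(area)
    biological_sigma: float = 0.4  # per-(protein, sample) ln-scale variation
    technical_sigma: float = 0.2  # per-(peptide, sample) ln-scale noise
    identification_dropout_rate: float = 0.1
    area_missing_rate: float = 0.02
    decoy_singleton_rate: float = 0.05
    shared_peptide_rate: float = 0.05
    min_feature_separation_windows: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "identification_dropout_rate",
            "area_missing_rate",
            "decoy_singleton_rate",
            "shared_peptide_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.rt_range[0] <= 0 or self.rt_range[1] <= self.rt_range[0]:
            raise ConfigError("rt_range must be positive and increasing")
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ConfigError("peptides_per_protein range invalid")
        if min(
            self.n_cases_discovery,
            self.n_controls_discovery,
            self.n_cases_test,
            self.n_controls_test,
        ) < 1:
            raise ConfigError("every group/set needs at least one sample")
        if self.n_de_proteins > self.n_proteins:
            raise ConfigError("n_de_proteins exceeds n_proteins")
        if not math.isfinite(self.de_log2_effect):
            raise ConfigError("de_log2_effect must be finite")

    def zero_noise(self) -> "SynthConfig":
        """Noise-free copy: identity drift, no measurement error, no
        dropout, no decoys, no shared peptides (protein assignment is
        then unambiguous) — the perfect-recovery regime."""
        return replace(
            self,
            shared_peptide_rate=0.0,
            rt_noise_sd=0.0,
            drift=DriftConfig((1.0, 1.0), (0.0, 0.0), (0.0, 0.0), 200.0),
            mass_error_sd_ppm=0.0,
            biological_sigma=0.0,
            technical_sigma=0.0,
            identification_dropout_rate=0.0,
            area_missing_rate=0.0,
            decoy_singleton_rate=0.0,
        )


@dataclass(frozen=True)
class TrueFeature:
    feature_id: str
    accession: str
    sequence: str
    theoretical_mass: float
    true_rt: float
    base_area: float
    candidates: tuple[str, ...]  # candidate accessions, true protein first


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    features: list[TrueFeature]
    #: (sample_id, record_index) -> feature_id; decoy records are absent
    record_to_feature: dict[tuple[str, int], str]
    #: proteins x samples, noiseless per-sample protein amounts
    protein_abundance: pd.DataFrame
    #: accession -> log2 effect (case vs control); non-DE proteins absent
    de_effects: dict[str, float]
    #: per-sample drift specs used (for calibration checks)
    drift_specs: dict[str, DriftSpec]

    @property
    def de_proteins(self) -> set[str]:
        return set(self.de_effects)


def _random_tryptic_sequence(rng: np.random.Generator) -> str:
    length = int(rng.integers(7, 21))
    body = "".join(rng.choice(list(_AMINO_ACIDS), size=length - 1))
    return body + ("K" if rng.random() < 0.5 else "R")


def _separated(
    mass: float,
    rt: float,
    masses: list[float],
    rts: list[float],
    sep_windows: float,
    mass_window_ppm: float = 5.0,
    rt_window_frac: float = 0.05,
) -> bool:
    for m, r in zip(masses, rts):
        mass_ok = abs(mass - m) / m > sep_windows * mass_window_ppm * 1e-6
        rt_ok = abs(rt - r) > sep_windows * rt_window_frac * r
        if not (mass_ok or rt_ok):
            return False
    return True


def default_design(config: SynthConfig) -> StudyDesign:
    """Study layout with deterministic sample ids; the first discovery
    control is the rt-calibration reference run."""
    samples: list[SampleInfo] = []
    counter = 1

    def add(n: int, group: str, set_name: str) -> None:
        nonlocal counter
        for _ in range(n):
            samples.append(SampleInfo(f"S{counter:02d}", group, set_name))
            counter += 1

    add(config.n_cases_discovery, "case", "discovery")
    add(config.n_controls_discovery, "control", "discovery")
    add(config.n_cases_test, "case", "test")
    add(config.n_controls_test, "control", "test")
    ref_id = next(
        s.sample_id
        for s in samples
        if s.group == "control" and s.set_name == "discovery"
    )
    samples = [
        replace(s, is_reference=(s.sample_id == ref_id)) for s in samples
    ]
    return StudyDesign(tuple(samples))


def generate_study(
    config: SynthConfig,
) -> tuple[dict[str, list[PeptideRecord]], StudyDesign, GroundTruth]:
    """Generate per-sample peptide exports, the design, and ground truth.

    Deterministic under a fixed ``config.seed``: all randomness flows
    through one seeded generator and iteration order is fixed.
    """
    rng = np.random.default_rng(config.seed)
    design = default_design(config)

    # --- protein roster and DE effects -----------------------------------
    accessions = [f"P{i:05d}" for i in range(1, config.n_proteins + 1)]
    if config.true_de_proteins is not None:
        de_effects = {acc: eff for acc, eff in config.true_de_proteins}
        unknown = set(de_effects) - set(accessions)
        if unknown:
            raise ConfigError(f"true_de_proteins not in roster: {sorted(unknown)}")
    else:
        # half up-, half down-regulated at the configured |log2| effect
        de_effects = {}
        for i in range(config.n_de_proteins):
            sign = 1.0 if i < (config.n_de_proteins + 1) // 2 else -1.0
            de_effects[accessions[i]] = sign * config.de_log2_effect

    # --- true feature roster ----------------------------------------------
    lo, hi = config.peptides_per_protein
    mu, sigma = config.base_area_lognormal
    features: list[TrueFeature] = []
    used_mass: list[float] = []
    used_rt: list[float] = []
    seen_seq: set[str] = set()
    fid = 0
    for acc in accessions:
        k = int(rng.integers(lo, hi + 1))
        for _ in range(k):
            for _attempt in range(1000):
                seq = _random_tryptic_sequence(rng)
                if seq in seen_seq:
                    continue
                theo = pyt_mass.fast_mass(seq)
                rt = float(rng.uniform(*config.rt_range))
                if _separated(
                    theo, rt, used_mass, used_rt, config.min_feature_separation_windows
                ):
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise ConfigError("could not place a separated feature")
            seen_seq.add(seq)
            used_mass.append(theo)
            used_rt.append(rt)
            candidates = (acc,)
            if config.shared_peptide_rate > 0 and rng.random() < config.shared_peptide_rate:
                other = accessions[int(rng.integers(0, config.n_proteins))]
                if other != acc:
                    candidates = (acc, other)
            features.append(
                TrueFeature(
                    feature_id=f"F{fid:05d}",
                    accession=acc,
                    sequence=seq,
                    theoretical_mass=theo,
                    true_rt=rt,
                    base_area=float(np.exp(rng.normal(mu, sigma))),
                    candidates=candidates,
                )
            )
            fid += 1

    # --- per-sample drift specs -------------------------------------------
    drift_specs: dict[str, DriftSpec] = {}
    for s in design.samples:
        d = config.drift
        drift_specs[s.sample_id] = DriftSpec(
            slope=float(rng.uniform(*d.slope_range)),
            intercept=float(rng.uniform(*d.intercept_range)),
            amplitude=float(rng.uniform(*d.amplitude_range)),
            period=d.period,
            phase=float(rng.uniform(0.0, d.period)),
        )

    # --- per-sample records -----------------------------------------------
    manifest: dict[str, list[PeptideRecord]] = {}
    record_to_feature: dict[tuple[str, int], str] = {}
    truth = pd.DataFrame(
        0.0, index=accessions, columns=[s.sample_id for s in design.samples]
    )
    for s in design.samples:
        spec = drift_specs[s.sample_id]
        records: list[PeptideRecord] = []
        # biological per-subject protein levels, shared across peptides
        bio = {
            acc: float(np.exp(rng.normal(0.0, config.biological_sigma)))
            if config.biological_sigma > 0
            else 1.0
            for acc in accessions
        }
        for f in features:
            effect = (
                2.0 ** de_effects[f.accession]
                if s.group == "case" and f.accession in de_effects
                else 1.0
            )
            true_area = f.base_area * bio[f.accession] * effect
            truth.loc[f.accession, s.sample_id] += true_area
            if rng.random() < config.identification_dropout_rate:
                continue
            eps_ppm = rng.normal(0.0, config.mass_error_sd_ppm) if config.mass_error_sd_ppm > 0 else 0.0
            measured = f.theoretical_mass * (1.0 + eps_ppm * 1e-6)
            rt_obs = apply_drift(f.true_rt, spec)
            if config.rt_noise_sd > 0:
                rt_obs += rng.normal(0.0, config.rt_noise_sd)
            tech = (
                float(np.exp(rng.normal(0.0, config.technical_sigma)))
                if config.technical_sigma > 0
                else 1.0
            )
            area: float | None = true_area * tech
            if rng.random() < config.area_missing_rate:
                area = None
            conf = rng.choice(["high", "medium", "low"], p=[0.8, 0.15, 0.05])
            rank = 1 if rng.random() < 0.9 else int(rng.integers(2, 6))
            record_to_feature[(s.sample_id, len(records))] = f.feature_id
            records.append(
                PeptideRecord(
                    sample_id=s.sample_id,
                    sequence=f.sequence,
                    measured_mass=float(measured),
                    theoretical_mass=f.theoretical_mass,
                    rt=float(max(rt_obs, 1e-3)),
                    area=area,
                    xcorr=float(rng.uniform(1.0, 6.0)),
                    confidence=str(conf),
                    rank=rank,
                    proteins=f.candidates,
                )
            )
        # run-unique spurious singletons
        n_decoys = int(rng.binomial(len(features), config.decoy_singleton_rate))
        for j in range(n_decoys):
            seq = _random_tryptic_sequence(rng) + "X"  # never matches a true sequence
            theo = float(rng.uniform(600.0, 5000.0))
            records.append(
                PeptideRecord(
                    sample_id=s.sample_id,
                    sequence=seq,
                    measured_mass=theo * (1.0 + rng.normal(0.0, config.mass_error_sd_ppm) * 1e-6)
                    if config.mass_error_sd_ppm > 0
                    else theo,
                    theoretical_mass=theo,
                    rt=float(rng.uniform(*config.rt_range)),
                    area=float(np.exp(rng.normal(mu, sigma))),
                    xcorr=float(rng.uniform(1.0, 6.0)),
                    confidence="high",
                    rank=1,
                    proteins=(f"Q9{int(rng.integers(0, 1000)):03d}9",),
                )
            )
        manifest[s.sample_id] = records

    truth = truth.sort_index()
    ground_truth = GroundTruth(
        features=features,
        record_to_feature=record_to_feature,
        protein_abundance=truth,
        de_effects=de_effects,
        drift_specs=drift_specs,
    )
    return manifest, design, ground_truth


def annotation_table(truth: GroundTruth) -> dict[str, tuple[str, str]]:
    """Synthetic accession -> (name, gene) table for the roster."""
    accs = sorted({f.accession for f in truth.features})
    return {
        acc: (f"Synthetic protein {acc[1:].lstrip('0') or '0'}", f"SYN{acc[1:]}")
        for acc in accs
    }
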