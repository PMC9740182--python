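"""Synthetic cohort generator for single-strand elemental time series.

Emulates the data layer of a hair exposomics study: each subject contributes
one hair strand scanned along ~10 mm of growth (roughly one month), yielding
>650 sampling points per element channel.  Each element's intensity trace is
built from

* a slowly varying baseline (long-period modulation of the element's level),
* one or two quasi-periodic (circadian-like) sinusoidal components whose
  per-sample period is drawn from a configurable range,
* multiplicative lognormal measurement noise, and
* a per-site multiplicative batch factor shared by all subjects at a site.

The case/control contrast is an *amplitude attenuation* of the periodic
components in a configurable subset of elements (default Zn, Cu, Li): in
cases the sinusoidal amplitudes of those elements are multiplied by
``1 - effect_size``.  Mean levels are untouched, so any downstream separation
must come from signal dynamics rather than concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DEFAULT_PANEL",
    "CohortConfig",
    "SubjectRecord",
    "StrandProfile",
    "generate_cohort",
    "generate_replicate_pair",
]

#: Default 15-element panel (sulfur is carried separately as the normalizer).
DEFAULT_PANEL: tuple[str, ...] = (
    "Li", "Mg", "Al", "P", "Ca", "Cr", "Mn", "Fe",
    "Co", "Cu", "Zn", "As", "Sr", "Ba", "Pb",
)

# Typical relative intensity scale per element (arbitrary counts units);
# only used to make raw traces look like a multi-element ICP-MS panel --
# the sulfur ratio and the RQA features are insensitive to these scales.
_ELEMENT_SCALE: dict[str, float] = {
    "Li": 0.02, "Mg": 50.0, "Al": 5.0, "P": 80.0, "Ca": 300.0,
    "Cr": 0.5, "Mn": 1.0, "Fe": 10.0, "Co": 0.05, "Cu": 8.0,
    "Zn": 120.0, "As": 0.1, "Sr": 2.0, "Ba": 1.5, "Pb": 0.8,
}

# Per-site age profiles (months): a prospective infant cohort, an adolescent
# twin cohort and a mixed-age clinic sample, cycled when n_sites differs.
_SITE_AGE_PROFILES: tuple[tuple[float, float], ...] = ((1.0, 0.25), (170.8, 36.9), (61.6, 33.4))


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_subjects: int = 100
    case_fraction: float = 0.5
    n_sites: int = 3
    points_per_strand: int = 660
    n_elements: int = 15
    perturbed_elements: frozenset[str] = frozenset({"Zn", "Cu", "Li"})
    effect_size: float = 0.0
    noise_sd: float = 0.008
    batch_shift_sd: float = 0.15
    period_range: tuple[float, float] = (18.0, 26.0)
    amp_range: tuple[float, float] = (0.3, 0.5)
    phase_drift_sd: float = 0.05  # rad per sqrt(sample): circadian phase diffusion
    age_case_shift: float = 0.0  # optional age/diagnosis confounding, months
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError(f"case_fraction must be in (0, 1), got {self.case_fraction}")
        if self.points_per_strand < 2:
            raise ValueError("points_per_strand must be >= 2")
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        if self.n_elements < 1 or self.n_elements > len(DEFAULT_PANEL):
            raise ValueError(f"n_elements must be in 1..{len(DEFAULT_PANEL)}")
        if not (0.0 <= self.effect_size <= 1.0):
            raise ValueError("effect_size must be in [0, 1]")
        if min(self.noise_sd, self.batch_shift_sd) < 0:
            raise ValueError("noise scales must be >= 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        object.__setattr__(self, "perturbed_elements", frozenset(self.perturbed_elements))
        panel = set(self.panel)
        extra = self.perturbed_elements - panel
        if extra:
            raise ValueError(f"perturbed_elements not in the element panel: {sorted(extra)}")

    @property
    def panel(self) -> tuple[str, ...]:
        """The element labels this cohort measures (first ``n_elements`` of the panel)."""
        labels = DEFAULT_PANEL[: self.n_elements]
        # Guarantee that the canonical perturbed trio stays on small panels.
        missing = [e for e in ("Zn", "Cu", "Li") if e in self.perturbed_elements and e not in labels]
        if missing:
            keep = [e for e in labels if e not in self.perturbed_elements]
            labels = tuple(sorted(self.perturbed_elements) + keep)[: self.n_elements]
        return tuple(labels)


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    diagnosis: str  # "case" | "control"
    sex: str  # "male" | "female"
    age_months: float
    site: str
    batch: str

    def __post_init__(self) -> None:
        if self.diagnosis not in ("case", "control"):
            raise ValueError(f"diagnosis must be case/control, got {self.diagnosis!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if self.age_months < 0:
            raise ValueError("age_months must be >= 0")

    @property
    def is_case(self) -> bool:
        return self.diagnosis == "case"


@dataclass
class StrandProfile:
    """Raw multi-element intensity series along one hair strand.

    ``latent`` carries the subject's generative parameters (baselines,
    periods, phases, amplitudes) so that replicate strands can share them;
    it is not part of the on-disk representation.
    """

    subject_id: str
    channels: dict[str, np.ndarray]
    sulfur: np.ndarray
    scan_length_mm: float = 10.0
    latent: dict | None = None
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.sulfur)
        for el, series in self.channels.items():
            if len(series) != n:
                raise ValueError(f"channel {el} length {len(series)} != sulfur length {n}")
            if np.any(np.asarray(series) < 0):
                raise ValueError(f"negative intensity in channel {el}")

    @property
    def n_points(self) -> int:
        return len(self.sulfur)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self.channels)


def _draw_latent(rng: np.random.Generator, config: CohortConfig,
                 is_case: bool) -> dict:
    """Per-subject generative parameters for every channel and for sulfur.

    The circadian-like component carries a phase random walk (diffusion
    coefficient ``phase_drift_sd`` rad per sqrt(sample)); the walk is part of
    the latent biology, so replicate strands from the same subject share it.
    """
    p_lo, p_hi = config.period_range
    a_lo, a_hi = config.amp_range
    n = config.points_per_strand
    latent: dict = {"elements": {}}
    for el in config.panel:
        base = _ELEMENT_SCALE.get(el, 1.0) * float(rng.lognormal(0.0, 0.2))
        amp = float(rng.uniform(a_lo, a_hi))
        amp2 = 0.3 * amp
        if is_case and el in config.perturbed_elements:
            amp *= 1.0 - config.effect_size
            amp2 *= 1.0 - config.effect_size
        phase_walk = np.cumsum(rng.normal(0.0, config.phase_drift_sd, size=n))
        latent["elements"][el] = {
            "base": base,
            "slow_period": float(rng.uniform(200.0, 400.0)),
            "slow_phase": float(rng.uniform(0.0, 2 * np.pi)),
            "slow_amp": 0.1,
            "period": float(rng.uniform(p_lo, p_hi)),
            "phase": float(rng.uniform(0.0, 2 * np.pi)),
            "amp": amp,
            "period2": float(rng.uniform(p_lo, p_hi)),
            "phase2": float(rng.uniform(0.0, 2 * np.pi)),
            "amp2": amp2,
            "phase_walk": phase_walk,
            # Monotone baseline drift across the strand (fractional change
            # over the scan), emulating slow dietary/seasonal level shifts.
            "drift": float(rng.uniform(0.1, 0.3) * rng.choice([-1.0, 1.0])),
        }
    latent["sulfur"] = {
        "base": 1000.0 * float(rng.lognormal(0.0, 0.1)),
        "slow_period": float(rng.uniform(200.0, 400.0)),
        "slow_phase": float(rng.uniform(0.0, 2 * np.pi)),
        "slow_amp": 0.05,
    }
    return latent


def _deterministic_channel(params: Mapping[str, object], t: np.ndarray) -> np.ndarray:
    slow = (1.0 + params["slow_amp"] * np.sin(2 * np.pi * t / params["slow_period"] + params["slow_phase"])
            + params["drift"] * (t / max(len(t), 1) - 0.5))
    walk = params["phase_walk"][: len(t)]
    periodic = (
        params["amp"] * np.sin(2 * np.pi * t / params["period"] + params["phase"] + walk)
        + params["amp2"] * np.sin(2 * np.pi * t / params["period2"] + params["phase2"] + walk)
    )
    return params["base"] * slow * (1.0 + periodic).clip(min=0.0)


def _render_strand(subject_id: str, latent: dict, batch_factors: Mapping[str, float],
                   n_points: int, noise_sd: float,
                   rng: np.random.Generator) -> StrandProfile:
    t = np.arange(n_points, dtype=float)
    channels: dict[str, np.ndarray] = {}
    for el, params in latent["elements"].items():
        clean = _deterministic_channel(params, t)
        noise = np.exp(rng.normal(0.0, noise_sd, size=n_points)) if noise_sd > 0 else 1.0
        channels[el] = clean * noise * batch_factors[el]
    sp = latent["sulfur"]
    s_clean = sp["base"] * (1.0 + sp["slow_amp"] * np.sin(2 * np.pi * t / sp["slow_period"] + sp["slow_phase"]))
    s_noise = np.exp(rng.normal(0.0, 0.5 * noise_sd, size=n_points)) if noise_sd > 0 else 1.0
    sulfur = s_clean * s_noise
    return StrandProfile(
        subject_id=subject_id,
        channels=channels,
        sulfur=sulfur,
        latent={**latent, "batch_factors": dict(batch_factors)},
        noise_sd=noise_sd,
    )


def generate_cohort(config: CohortConfig) -> tuple[list[SubjectRecord], list[StrandProfile]]:
    """Generate a full synthetic cohort: metadata records plus one strand each.

    Deterministic under ``config.seed``; exactly ``round(case_fraction * n)``
    cases.  Sex and age are independent of diagnosis unless
    ``age_case_shift`` is nonzero.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    n_cases = int(round(config.case_fraction * n))
    diagnoses = np.array(["case"] * n_cases + ["control"] * (n - n_cases))
    rng.shuffle(diagnoses)

    sites = [f"site{1 + i % config.n_sites}" for i in range(n)]
    rng.shuffle(sites)

    # Per-site multiplicative batch factor for each element channel.
    batch_factors: dict[str, dict[str, float]] = {}
    for k in range(config.n_sites):
        site = f"site{k + 1}"
        batch_factors[site] = {
            el: float(np.exp(rng.normal(0.0, config.batch_shift_sd))) for el in config.panel
        }

    records: list[SubjectRecord] = []
    profiles: list[StrandProfile] = []
    width = len(str(n))
    for i in range(n):
        sid = f"S{i:0{width}d}"
        site = sites[i]
        mean_age, sd_age = _SITE_AGE_PROFILES[(int(site[4:]) - 1) % len(_SITE_AGE_PROFILES)]
        age = float(max(0.0, rng.normal(mean_age, sd_age)))
        is_case = diagnoses[i] == "case"
        if is_case:
            age = max(0.0, age + config.age_case_shift)
        records.append(
            SubjectRecord(
                subject_id=sid,
                diagnosis=str(diagnoses[i]),
                sex="male" if rng.random() < 0.5 else "female",
                age_months=age,
                site=site,
                batch=site,
            )
        )
        latent = _draw_latent(rng, config, is_case)
        profiles.append(
            _render_strand(sid, latent, batch_factors[site],
                           config.points_per_strand, config.noise_sd, rng)
        )
    return records, profiles


def generate_replicate_pair(profile: StrandProfile, replicate_noise_sd: float | None = None,
                            seed: int = 0) -> StrandProfile:
    """Second strand from the same subject: shared latent dynamics, fresh noise.

    The replicate reuses the subject's latent generative parameters (baseline,
    periods, phases, amplitudes, batch factors) and redraws only the
    multiplicative measurement noise, with scale ``replicate_noise_sd``
    (default: the original strand's noise scale).  ``replicate_noise_sd=0``
    yields the noiseless latent signal.
    """
    if profile.latent is None:
        raise ValueError("profile carries no latent parameters; replicate generation "
                         "requires a strand produced by generate_cohort")
    if replicate_noise_sd is None:
        replicate_noise_sd = profile.noise_sd
    if replicate_noise_sd < 0:
        raise ValueError("replicate_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    return _render_strand(
        profile.subject_id,
        {k: v for k, v in profile.latent.items() if k != "batch_factors"},
        profile.latent["batch_factors"],
        profile.n_points,
        replicate_noise_sd,
        rng,
    )
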