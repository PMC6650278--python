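"""Synthetic longitudinal multi-omic cohorts with known ground truth.

Emulates the structure of a year-long IBD cohort: subjects in three
diagnosis groups (nonIBD, UC, CD) sampled every two weeks, each carrying a
latent two-state (eubiotic/dysbiotic) process with memoryless sojourns,
subject-specific compositional baselines with AR(1) temporal autocorrelation,
group-configurable dysbiosis effects on designated taxa, a coupled secondary
measurement type (metabolite-like), and per-sample missingness.

Ground truth — state series, sojourn means, responsive features, effect
sizes — is retained so every downstream stage (scoring, episode statistics,
shift detection, differential abundance, networks) can be validated without
external data.

State-process time scale
------------------------
The default state process is a discrete-time two-state Markov chain on the
sampling grid: per step of ``sampling_interval`` weeks the chain leaves its
state with probability ``interval / mean``, giving geometric sojourns with
the configured means in weeks — the memoryless distribution at the
observation resolution.  This plants episode-duration ground truth at the
scale at which episodes are observed and estimated.  A continuous-time
alternating-renewal variant with exponential sojourns
(``state_process="continuous"``) is also provided; note that discretizing it
to a 2-week grid inflates observed episode lengths (sojourns shorter than
the sampling interval are missed and merge adjacent runs), so the observed
episodes of that variant are biased upward relative to the configured means.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles import AbundanceTable

DIAGNOSES = ("nonIBD", "UC", "CD")

_SITES = ("siteA", "siteB", "siteC", "siteD", "siteE")


class ParameterError(ValueError):
    """Raised when a generator parameter violates its contract."""


@dataclasses.dataclass
class CohortConfig:
    """Configuration of the synthetic cohort generator.

    Defaults encode the emulated study conditions: a ~130-subject cohort
    (65 CD, 38 UC, 27 nonIBD) followed for 52 weeks at 2-weekly stool
    sampling; dysbiotic episode duration/interval means of 7.8/12.8 weeks
    (CD) and 4.1/17.2 weeks (UC); nonIBD subjects share the same process
    with a long interval (stationary dysbiotic-state fraction ~6%, safely
    below the 10% classification quantile so the threshold falls in the gap
    between the state score distributions).
    """

    n_subjects_per_group: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"nonIBD": 27, "UC": 38, "CD": 65}
    )
    study_length: float = 52.0
    sampling_interval: float = 2.0
    mean_episode_duration: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"nonIBD": 4.0, "UC": 4.1, "CD": 7.8}
    )
    mean_episode_interval: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"nonIBD": 60.0, "UC": 17.2, "CD": 12.8}
    )
    n_taxa: int = 100
    n_dysbiosis_responsive_taxa: int = 40  # split evenly depleted/enriched
    effect_size: float = 3.0  # log-scale shift on responsive taxa when dysbiotic
    subject_sd: float = 0.7  # log-scale between-subject dispersion
    temporal_sd: float = 0.6  # log-scale AR(1) innovation sd
    ar_coefficient: float = 0.7
    missingness_prob: float = 0.1
    coupling_strength: float = 0.8
    state_process: str = "grid"  # "grid" | "continuous"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_subjects_per_group:
            raise ParameterError("n_subjects_per_group must be non-empty")
        for group, n in self.n_subjects_per_group.items():
            if group not in DIAGNOSES:
                raise ParameterError(f"unknown diagnosis group {group!r}")
            if n < 0:
                raise ParameterError("subject counts must be nonnegative")
        if self.study_length <= 0 or self.sampling_interval <= 0:
            raise ParameterError("study_length and sampling_interval must be positive")
        n_steps = self.study_length / self.sampling_interval
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ParameterError("sampling_interval must divide study_length")
        for name in ("mean_episode_duration", "mean_episode_interval"):
            means = getattr(self, name)
            for group, m in means.items():
                if not (m > 0):
                    raise ParameterError(f"{name}[{group}] must be positive")
                if self.state_process == "grid" and m < self.sampling_interval:
                    raise ParameterError(
                        f"{name}[{group}]={m} below the sampling interval is not "
                        "representable by the grid state process"
                    )
        if self.subject_sd < 0 or self.temporal_sd < 0:
            raise ParameterError("dispersions must be nonnegative")
        if not 0 <= self.ar_coefficient < 1:
            raise ParameterError("ar_coefficient must be in [0, 1)")
        if not 0 <= self.missingness_prob < 1:
            raise ParameterError("missingness_prob must be in [0, 1)")
        if not 0 <= self.coupling_strength <= 1:
            raise ParameterError("coupling_strength must be in [0, 1]")
        if self.n_taxa <= 0:
            raise ParameterError("n_taxa must be positive")
        if self.n_dysbiosis_responsive_taxa > self.n_taxa:
            raise ParameterError("more responsive taxa than taxa")
        if self.state_process not in ("grid", "continuous"):
            raise ParameterError("state_process must be 'grid' or 'continuous'")

    @property
    def sampling_weeks(self) -> np.ndarray:
        return np.arange(0.0, self.study_length + 1e-9, self.sampling_interval)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_subjects_per_group"] = dict(self.n_subjects_per_group)
        d["mean_episode_duration"] = dict(self.mean_episode_duration)
        d["mean_episode_interval"] = dict(self.mean_episode_interval)
        return d


@dataclasses.dataclass
class DysbiosisStateSeries:
    """Latent dysbiosis states of one subject at the scheduled sampling times."""

    subject_id: str
    weeks: np.ndarray  # scheduled sampling times
    states: np.ndarray  # bool, True = dysbiotic, aligned with weeks
    transition_times: np.ndarray  # state-change times (weeks), alternating

    def __post_init__(self) -> None:
        self.weeks = np.asarray(self.weeks, dtype=float)
        self.states = np.asarray(self.states, dtype=bool)
        if self.weeks.shape != self.states.shape:
            raise ParameterError("weeks and states must align")


def _subject_rng(seed: int, *key: int) -> np.random.Generator:
    """Named RNG stream: stable per subject, unaffected by other subjects."""
    return np.random.default_rng([seed, *key])


def simulate_state_process(
    config: CohortConfig, diagnosis: str, rng: np.random.Generator, subject_id: str = ""
) -> DysbiosisStateSeries:
    """Simulate one subject's eubiotic/dysbiotic state series.

    The process starts eubiotic.  Sojourn times alternate with the
    configured per-diagnosis means: on the sampling grid (default) sojourns
    are geometric with mean ``mean/sampling_interval`` steps; in continuous
    time they are exponential, and the series records the state holding at
    each scheduled sampling time.
    """
    try:
        dur_mean = config.mean_episode_duration[diagnosis]
        int_mean = config.mean_episode_interval[diagnosis]
    except KeyError as exc:
        raise ParameterError(f"no sojourn means configured for {diagnosis!r}") from exc
    weeks = config.sampling_weeks
    if config.state_process == "grid":
        p_enter = config.sampling_interval / int_mean
        p_exit = config.sampling_interval / dur_mean
        states = np.empty(len(weeks), dtype=bool)
        s = False
        flips = rng.random(len(weeks))
        for i in range(len(weeks)):
            states[i] = s
            if flips[i] < (p_exit if s else p_enter):
                s = not s
        changes = np.nonzero(np.diff(states.astype(int)))[0]
        transition_times = weeks[changes + 1]
    else:
        t = 0.0
        dysbiotic = False
        transitions = []
        while t <= config.study_length:
            t += rng.exponential(dur_mean if dysbiotic else int_mean)
            transitions.append(t)
            dysbiotic = not dysbiotic
        transition_times = np.array(transitions)
        states = (np.searchsorted(transition_times, weeks, side="right") % 2).astype(bool)
    return DysbiosisStateSeries(subject_id, weeks, states, np.asarray(transition_times))


def _taxon_basenames(n_taxa: int) -> list[str]:
    phyla = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria")
    return [
        f"k__Bacteria|p__{phyla[i % len(phyla)]}|g__Genus{i:03d}|s__Species{i:03d}"
        for i in range(n_taxa)
    ]


def responsive_taxa(config: CohortConfig) -> tuple[list[str], list[str]]:
    """Ground-truth (depleted, enriched) taxon IDs for a configuration."""
    names = _taxon_basenames(config.n_taxa)
    k = config.n_dysbiosis_responsive_taxa
    return names[: k // 2], names[k // 2 : k]


def simulate_profiles(
    config: CohortConfig, states: Mapping[str, DysbiosisStateSeries]
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Generate taxonomic relative-abundance profiles from latent states.

    Per subject, the log-scale abundance of taxon f at time t is
    ``base_f + subject_f + z_{t,f} + delta_f(state_t)`` where ``base_f`` are
    cohort-level taxon means, ``subject_f ~ N(0, subject_sd)``, ``z`` is an
    AR(1) process (coefficient ``ar_coefficient``, innovation sd
    ``temporal_sd``, stationary initialisation) and ``delta_f`` is
    ``-effect_size`` for depleted and ``+effect_size`` for enriched
    responsive taxa when the state is dysbiotic.  Exponentiation and
    total-sum scaling close each sample to relative abundances.  Scheduled
    samples are dropped independently with ``missingness_prob``.
    """
    if not states:
        raise ParameterError("empty subject list")
    names = _taxon_basenames(config.n_taxa)
    depleted, enriched = responsive_taxa(config)
    delta = np.zeros(config.n_taxa)
    delta[[names.index(f) for f in depleted]] = -config.effect_size
    delta[[names.index(f) for f in enriched]] = config.effect_size

    cohort_rng = _subject_rng(config.seed, 0)
    base = cohort_rng.normal(0.0, 1.5, size=config.n_taxa)

    subject_meta = _subject_attributes(config, list(states))

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    ar = config.ar_coefficient
    innov_sd = config.temporal_sd
    stat_sd = innov_sd / np.sqrt(1.0 - ar**2) if innov_sd > 0 else 0.0
    for si, (subject, series) in enumerate(states.items()):
        rng = _subject_rng(config.seed, 1, si)
        offset = rng.normal(0.0, config.subject_sd, size=config.n_taxa)
        n_t = len(series.weeks)
        z = np.empty((n_t, config.n_taxa))
        z[0] = rng.normal(0.0, stat_sd, size=config.n_taxa) if stat_sd else 0.0
        innov = rng.normal(0.0, innov_sd, size=(n_t - 1, config.n_taxa)) if innov_sd else np.zeros((n_t - 1, config.n_taxa))
        for t in range(1, n_t):
            z[t] = ar * z[t - 1] + innov[t - 1]
        keep = rng.random(n_t) >= config.missingness_prob
        attrs = subject_meta[subject]
        for t in range(n_t):
            if not keep[t]:
                continue
            week = series.weeks[t]
            logab = base + offset + z[t] + (delta if series.states[t] else 0.0)
            ab = np.exp(logab)
            sample_id = f"{subject}_wk{int(round(week)):03d}"
            columns[sample_id] = ab / ab.sum()
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "subject_id": subject,
                    "week": float(week),
                    "diagnosis": attrs["diagnosis"],
                    "dysbiotic": bool(series.states[t]),
                    "consent_age": attrs["consent_age"],
                    "antibiotic_use": attrs["antibiotic_use"][t],
                    "recruitment_site": attrs["recruitment_site"],
                }
            )
    table = AbundanceTable(
        pd.DataFrame(columns, index=pd.Index(names, name="#FeatureID")), "MGX-taxa"
    )
    return table, pd.DataFrame(meta_rows)


def _subject_attributes(config: CohortConfig, subjects: Sequence[str]) -> dict:
    """Covariates: age and site constant per subject, antibiotics time-varying."""
    out = {}
    n_t = len(config.sampling_weeks)
    for si, subject in enumerate(subjects):
        rng = _subject_rng(config.seed, 2, si)
        diagnosis = subject.rsplit("-", 1)[0]
        out[subject] = {
            "diagnosis": diagnosis,
            "consent_age": float(np.round(rng.uniform(18, 70), 1)),
            "recruitment_site": _SITES[int(rng.integers(len(_SITES)))],
            "antibiotic_use": (rng.random(n_t) < 0.05).astype(int),
        }
    return out


def simulate_coupled_measurement(
    primary_table: AbundanceTable,
    metadata: pd.DataFrame,
    coupling_strength: float,
    rng: np.random.Generator,
    n_features: int = 80,
    n_responsive: int = 16,
    effect_size: float = 3.0,
    subject_sd: float = 0.7,
    noise_sd: float = 1.0,
    normalize: bool = True,
) -> AbundanceTable:
    """A second (metabolite-like) feature space coupled to the latent state.

    Responsive features shift on the log scale by
    ``+/- coupling_strength * effect_size`` when the sample's latent state
    is dysbiotic; all other variation (subject offsets, per-sample noise) is
    independent of the primary table.  ``coupling_strength = 0`` gives an
    independent measurement type; 1 gives fully coupled responsive features.
    """
    if not 0 <= coupling_strength <= 1:
        raise ParameterError("coupling_strength must be in [0, 1]")
    meta = metadata.set_index("sample_id").loc[[str(s) for s in primary_table.samples]]
    names = [f"metabolite{i:03d}" for i in range(n_features)]
    delta = np.zeros(n_features)
    delta[: n_responsive // 2] = -coupling_strength * effect_size
    delta[n_responsive // 2 : n_responsive] = coupling_strength * effect_size
    base = rng.normal(0.0, 1.0, size=n_features)
    subjects = meta["subject_id"].unique()
    offsets = {s: rng.normal(0.0, subject_sd, size=n_features) for s in subjects}
    cols = {}
    for sample_id, row in meta.iterrows():
        noise = rng.normal(0.0, noise_sd, size=n_features) if noise_sd else 0.0
        logab = base + offsets[row["subject_id"]] + noise
        logab = logab + (delta if bool(row["dysbiotic"]) else 0.0)
        ab = np.exp(logab)
        cols[sample_id] = ab / ab.sum() if normalize else ab
    data = pd.DataFrame(cols, index=pd.Index(names, name="#FeatureID"))
    return AbundanceTable(data, "MBX")


@dataclasses.dataclass
class SyntheticCohort:
    """A fully generated cohort: profiles, coupled table, metadata, truth."""

    config: CohortConfig
    taxa_table: AbundanceTable
    coupled_table: AbundanceTable
    metadata: pd.DataFrame
    states: Dict[str, DysbiosisStateSeries]

    @property
    def truth_depleted(self) -> list[str]:
        return responsive_taxa(self.config)[0]

    @property
    def truth_enriched(self) -> list[str]:
        return responsive_taxa(self.config)[1]


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a complete cohort from a configuration (deterministic in seed)."""
    states: Dict[str, DysbiosisStateSeries] = {}
    for gi, (group, n) in enumerate(sorted(config.n_subjects_per_group.items())):
        for si in range(n):
            subject = f"{group}-{si:03d}"
            rng = _subject_rng(config.seed, 3, gi, si)
            states[subject] = simulate_state_process(config, group, rng, subject)
    taxa_table, metadata = simulate_profiles(config, states)
    coupled = simulate_coupled_measurement(
        taxa_table,
        metadata,
        config.coupling_strength,
        _subject_rng(config.seed, 4),
        effect_size=config.effect_size,
        subject_sd=config.subject_sd,
    )
    return SyntheticCohort(config, taxa_table, coupled, metadata, states)


def states_frame(states: Mapping[str, DysbiosisStateSeries]) -> pd.DataFrame:
    """Sample-level view of latent state series (one row per scheduled sample).

    Gives the metadata layout episode extraction expects, with the latent
    state as the ``dysbiotic`` label; useful for studying the state process
    itself, before profiles and classification enter.
    """
    rows = []
    for subject, series in states.items():
        for week, state in zip(series.weeks, series.states):
            rows.append(
                {
                    "sample_id": f"{subject}_wk{int(round(week)):03d}",
                    "subject_id": subject,
                    "week": float(week),
                    "dysbiotic": bool(state),
                }
            )
    return pd.DataFrame(rows)
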