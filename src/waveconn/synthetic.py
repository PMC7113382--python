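"""Synthetic resting-state cohorts with known ground truth.

Generates cohorts that emulate a two-group case-control resting-state study:
inhalant-consuming adolescents (IC) versus healthy controls (HC), with

* block-structured inter-regional correlation — pairs inside the same named
  network (DMN/SN/FPN) share a within-network correlation that can differ by
  group (weaker for the consumer group), all other pairs share a background
  correlation;
* band-limited signal content: white block-covariance draws are shaped in the
  frequency domain so the level-4 MODWT band for the configured TR
  (0.043–0.087 Hz at 0.72 s) carries a dominant spectral peak — by default
  30% of total power in a band spanning 1/16 of the spectrum, i.e. about six
  times the spectral density of the broadband remainder. Concentrating much
  more power in so narrow a band would make the signal unrealistically
  narrowband and inflate the sampling variability of correlation estimates
  far beyond the white-noise 1/sqrt(T) scale. Filtering every region with
  the same zero-phase response leaves the planted cross-regional
  correlations intact;
* cognitive scores drawn from a linear structural model with a direct group
  path (c) and a path mediated by a latent DMN-efficiency construct
  (group --a--> efficiency --b--> score), so the planted indirect effect is
  exactly a*b.

Every stochastic choice descends from a single integer seed through
``numpy.random.SeedSequence``, so identical configs give bit-identical
cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .parcellation import ParcelTable, make_parcel_table
from .wavelets import band_for_level

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "SubjectTimeSeries",
    "GroundTruth",
    "Cohort",
    "build_block_covariance",
    "simulate_subject_timeseries",
    "simulate_cognition",
    "generate_cohort",
]

GROUPS = ("IC", "HC")

#: Proportion of male participants used for the synthetic demographics,
#: loosely matched to the study template (IC 24/30 male, HC 16/27 male).
_P_MALE = {"IC": 0.80, "HC": 0.59}

_DEFAULT_NETWORK_SIZES = {"DMN": 58, "SN": 18, "FPN": 25}

# Default structural model: mediated paths to the inhibition/planning scores,
# direct-only paths to working memory and card sorting.
_DEFAULT_PATHS = {
    "score_working_memory": {"a": -0.5, "b": 0.0, "c": -0.53},
    "score_wisconsin": {"a": -0.5, "b": 0.0, "c": -0.58},
    "score_stroop": {"a": -0.5, "b": 0.4, "c": 0.0},
    "score_tower_of_hanoi": {"a": -0.5, "b": 0.4, "c": 0.0},
}


def _normalize_rho_within(rho_within, network_names) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for group in GROUPS:
        try:
            value = rho_within[group]
        except (KeyError, TypeError):
            raise ValueError(f"rho_within must provide a value for group {group!r}") from None
        if isinstance(value, Mapping):
            missing = [n for n in network_names if n not in value]
            if missing:
                raise ValueError(f"rho_within[{group!r}] missing networks {missing}")
            out[group] = {n: float(value[n]) for n in network_names}
        else:
            out[group] = {n: float(value) for n in network_names}
    return out


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic study, with study-template defaults.

    ``n_per_group`` is (IC, HC); the default (30, 27) mirrors a cohort of 30
    consumers and 30 controls of whom 3 were excluded. ``rho_within`` maps
    each group to either a scalar or a per-network within-network correlation;
    the default plants a weaker DMN (and mildly weaker SN/FPN) for the IC
    group. ``path_coeffs`` maps each score name to {a, b, c}: a is the group
    effect on the latent DMN-efficiency construct (shared across scores), b
    the construct's effect on the score, c the direct group effect.
    """

    n_per_group: tuple[int, int] = (30, 27)
    n_regions: int = 264
    network_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_NETWORK_SIZES)
    )
    n_timepoints: int = 500
    tr_seconds: float = 0.72
    rho_within: Mapping = field(
        default_factory=lambda: {
            "HC": 0.6,
            "IC": {"DMN": 0.35, "SN": 0.45, "FPN": 0.45},
        }
    )
    rho_between: float = 0.1
    path_coeffs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_PATHS.items()}
    )
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"efficiency": 0.97, "score": 1.0}
    )
    in_band_power: float = 0.3
    level_of_interest: int = 4
    wavelet_levels: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("n_per_group entries must be positive")
        if self.n_timepoints < 2**self.wavelet_levels:
            raise ValueError(
                f"n_timepoints must be >= 2^{self.wavelet_levels} for the downstream decomposition"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not 0 < self.in_band_power < 1:
            raise ValueError("in_band_power must be in (0, 1)")
        if not -1 < self.rho_between < 1:
            raise ValueError("rho_between must be in (-1, 1)")
        for sd in self.noise_sd.values():
            if sd < 0:
                raise ValueError("noise standard deviations must be nonnegative")
        a_values = {float(v["a"]) for v in self.path_coeffs.values()}
        if len(a_values) > 1:
            raise ValueError(
                "all scores must share the same group->efficiency coefficient 'a' "
                "(one mediator construct)"
            )

    @property
    def path_a(self) -> float:
        return float(next(iter(self.path_coeffs.values()))["a"])

    def rho_within_for(self, parcels: ParcelTable) -> dict[str, dict[str, float]]:
        return _normalize_rho_within(self.rho_within, parcels.network_names)


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    sex: str
    age: float
    covariates: dict[str, float]
    cognitive_scores: dict[str, float]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")


@dataclass(frozen=True)
class SubjectTimeSeries:
    """One subject's (T, R) signal matrix with its sampling interval."""

    subject_id: str
    data: np.ndarray
    region_ids: np.ndarray
    tr_seconds: float

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.data, columns=np.asarray(self.region_ids)).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read_tsv(cls, path, tr_seconds: float, subject_id: str | None = None) -> "SubjectTimeSeries":
        df = pd.read_csv(path, sep="\t")
        return cls(
            subject_id=subject_id or Path(path).stem,
            data=df.to_numpy(dtype=float),
            region_ids=np.asarray([int(c) for c in df.columns]),
            tr_seconds=tr_seconds,
        )


def build_block_covariance(
    parcels: ParcelTable, rho_within: Mapping[str, float], rho_between: float
) -> np.ndarray:
    """Block covariance: rho_within[net] inside each named network,
    rho_between elsewhere, 1 on the diagonal. Raises if not positive definite."""
    n = parcels.n_regions
    cov = np.full((n, n), float(rho_between))
    for name in parcels.network_names:
        members = parcels.nodes_in(name)
        cov[np.ix_(members, members)] = float(rho_within[name])
    np.fill_diagonal(cov, 1.0)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError(
            "correlation targets do not yield a positive-definite block covariance"
        ) from None
    return cov


def _band_shaping_gain(n_timepoints: int, tr_seconds: float, level: int, in_band_power: float):
    """Two-level zero-phase magnitude response over rfft bins: concentrate
    ``in_band_power`` of total power in the level's dyadic band."""
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_seconds)
    band = band_for_level(tr_seconds, level)
    in_band = (freqs >= band.f_low) & (freqs <= band.f_high)
    # Parseval weights: interior rfft bins count twice.
    weights = np.full(freqs.size, 2.0)
    weights[0] = 1.0
    if n_timepoints % 2 == 0:
        weights[-1] = 1.0
    weights[0] = 0.0  # DC removed: signals are mean-free
    w_in = float(weights[in_band].sum())
    w_out = float(weights.sum()) - w_in
    gain = np.zeros(freqs.size)
    gain[in_band] = np.sqrt(in_band_power / w_in)
    gain[~in_band] = np.sqrt((1.0 - in_band_power) / w_out)
    gain[0] = 0.0
    return gain


def simulate_subject_timeseries(
    config: CohortConfig,
    parcels: ParcelTable,
    group: str,
    subject_seed,
    subject_id: str = "sub-000",
) -> SubjectTimeSeries:
    """Draw one subject's (T, R) band-limited block-correlated signal matrix.

    White multivariate-normal draws with the group's block covariance are
    shaped in the frequency domain (same zero-phase gain for every region, so
    cross-regional correlations are untouched), then rescaled to unit
    variance per region.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    rho = config.rho_within_for(parcels)[group]
    cov = build_block_covariance(parcels, rho, config.rho_between)
    chol = np.linalg.cholesky(cov)
    rng = np.random.default_rng(subject_seed)
    white = rng.standard_normal((config.n_timepoints, parcels.n_regions))
    correlated = white @ chol.T
    gain = _band_shaping_gain(
        config.n_timepoints, config.tr_seconds, config.level_of_interest, config.in_band_power
    )
    shaped = np.fft.irfft(np.fft.rfft(correlated, axis=0) * gain[:, None], n=config.n_timepoints, axis=0)
    shaped /= shaped.std(axis=0)
    return SubjectTimeSeries(
        subject_id=subject_id,
        data=shaped,
        region_ids=np.asarray(parcels.region_ids),
        tr_seconds=config.tr_seconds,
    )


def simulate_cognition(
    config: CohortConfig,
    group_indicator: np.ndarray,
    dmn_efficiency: np.ndarray,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Scores from the linear structural model: c*group + b*efficiency + noise."""
    g = np.asarray(group_indicator, dtype=float)
    eff = np.asarray(dmn_efficiency, dtype=float)
    if g.shape != eff.shape:
        raise ValueError("group_indicator and dmn_efficiency must have the same length")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sd = float(config.noise_sd["score"])
    cols = {}
    for score, coeffs in config.path_coeffs.items():
        cols[score] = coeffs["c"] * g + coeffs["b"] * eff + rng.normal(0.0, sd, g.size)
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters, kept alongside the cohort for recovery tests."""

    rho_within: dict
    rho_between: float
    path_coeffs: dict
    noise_sd: dict
    efficiency_construct: dict[str, float]  # per-subject latent mediator values
    seed: int

    def indirect_effect(self, score: str) -> float:
        coeffs = self.path_coeffs[score]
        return float(coeffs["a"] * coeffs["b"])

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


@dataclass(frozen=True)
class Cohort:
    config: CohortConfig
    parcels: ParcelTable
    subjects: tuple[SubjectRecord, ...]
    timeseries: dict[str, SubjectTimeSeries]
    ground_truth: GroundTruth

    def manifest(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {"subject_id": s.subject_id, "group": s.group, "sex": s.sex, "age": s.age}
            row.update({f"cov_{k}": v for k, v in s.covariates.items()})
            row.update(s.cognitive_scores)
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, directory) -> None:
        """Write manifest TSV, parcel TSV, per-subject series TSVs and the
        ground-truth JSON under ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.manifest().to_csv(directory / "manifest.tsv", sep="\t", index=False)
        self.parcels.to_tsv(directory / "parcels.tsv")
        ts_dir = directory / "timeseries"
        ts_dir.mkdir(exist_ok=True)
        for sid, ts in self.timeseries.items():
            ts.to_tsv(ts_dir / f"{sid}.tsv")
        self.ground_truth.to_json(directory / "ground_truth.json")


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full synthetic cohort: records, time series, ground truth."""
    parcels = make_parcel_table(config.n_regions, dict(config.network_sizes))
    rho = config.rho_within_for(parcels)
    for group in GROUPS:  # fail fast before any sampling
        build_block_covariance(parcels, rho[group], config.rho_between)

    n_ic, n_hc = config.n_per_group
    groups = ["IC"] * n_ic + ["HC"] * n_hc
    subject_ids = [f"sub-{i:03d}" for i in range(len(groups))]
    group_ind = np.asarray([1.0 if g == "IC" else 0.0 for g in groups])

    root = np.random.SeedSequence(config.seed)
    demo_ss, eff_ss, cog_ss, ts_ss = root.spawn(4)
    demo_rng = np.random.default_rng(demo_ss)
    eff_rng = np.random.default_rng(eff_ss)

    sex = np.where(
        demo_rng.random(len(groups)) < [_P_MALE[g] for g in groups], "M", "F"
    )
    age = np.clip(demo_rng.normal(15.0, 1.35, len(groups)), 12.0, 17.0)
    # Nuisance-only covariate, deliberately independent of group so that
    # residualizing on it does not absorb the planted group effect.
    other_months = demo_rng.gamma(shape=2.0, scale=9.0, size=len(groups))

    construct = config.path_a * group_ind + eff_rng.normal(
        0.0, float(config.noise_sd["efficiency"]), len(groups)
    )
    scores = simulate_cognition(config, group_ind, construct, np.random.default_rng(cog_ss))

    subjects = tuple(
        SubjectRecord(
            subject_id=sid,
            group=grp,
            sex=str(sx),
            age=float(a),
            covariates={"other_substance_months": float(m)},
            cognitive_scores={k: float(scores[k].iloc[i]) for k in scores.columns},
        )
        for i, (sid, grp, sx, a, m) in enumerate(
            zip(subject_ids, groups, sex, age, other_months)
        )
    )

    ts_children = ts_ss.spawn(len(groups))
    timeseries = {
        sid: simulate_subject_timeseries(config, parcels, grp, child, subject_id=sid)
        for sid, grp, child in zip(subject_ids, groups, ts_children)
    }

    ground_truth = GroundTruth(
        rho_within=rho,
        rho_between=config.rho_between,
        path_coeffs={k: dict(v) for k, v in config.path_coeffs.items()},
        noise_sd=dict(config.noise_sd),
        efficiency_construct={sid: float(v) for sid, v in zip(subject_ids, construct)},
        seed=config.seed,
    )
    return Cohort(
        config=config,
        parcels=parcels,
        subjects=subjects,
        timeseries=timeseries,
        ground_truth=ground_truth,
    )
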