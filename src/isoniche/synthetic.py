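"""Synthetic whisker isotope data with the statistical structure of an
Antarctic fur seal colony study.

The generator stands in for an unreleased field dataset.  It emulates, per
seal: an annual δ13C oscillation along the whisker (one cycle per year of
growth, so the spatial period in mm equals growth rate × 365.25), a linear
ontogenetic decline in δ13C and rise in δ15N with age, sex-specific whisker
growth rates (males ≈ 0.096 mm/day, females ≈ 0.063 mm/day), two female
foraging groups separated along the δ13C axis, a δ15N suckling peak at the
tips of unworn female whiskers, multi-reader tooth-age error for males, prey
δ13C samples from the Polar Front, and group-wise morphometrics.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` so that repeated runs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import DAYS_PER_YEAR, EmptySeriesError, WhiskerSeries

GROUPS = ("male", "female_g1", "female_g2")

#: group-level whisker means, ‰ (δ13C, δ15N)
DEFAULT_GROUP_MEANS = {
    "male": (-21.68, 8.98),
    "female_g1": (-19.71, 8.96),
    "female_g2": (-17.89, 10.89),
}

#: group-level total SDs of whisker values, ‰ (δ13C, δ15N); segment noise is
#: calibrated per individual so pooled group SDs land near these
DEFAULT_GROUP_SDS = {
    "male": (1.20, 1.04),
    "female_g1": (1.44, 1.06),
    "female_g2": (1.13, 1.46),
}

#: between-individual SD of whisker-mean values, ‰ (δ13C, δ15N).  Chosen so
#: that the between:total variance ratio matches the specialisation indices
#: the analysis is built to estimate (≈0.1-0.25); see docs/methods.md.
DEFAULT_BETWEEN_SD = (0.45, 0.60)

#: sex-specific whisker growth rate distributions, mm/day (mean, sd)
GROWTH_RATE = {"male": (0.096, 0.026), "female": (0.063, 0.013)}

#: sex-specific whisker length distributions, mm (mean, sd)
WHISKER_LENGTH = {"male": (257.5, 69.5), "female": (162.9, 45.3)}

#: morphometric means by sex (mass kg, length cm, span cm, girth cm)
MORPHO_MEANS = {
    "male": (160.0, 180.0, 185.0, 130.0),
    "female": (35.0, 125.0, 130.0, 95.0),
}
MORPHO_SDS = {"male": (25.0, 10.0, 10.0, 12.0), "female": (4.0, 6.0, 6.0, 8.0)}
MORPHO_COLS = ("mass_kg", "length_cm", "span_cm", "girth_cm")


@dataclass
class IndividualParams:
    """Ground-truth parameters of one simulated seal."""

    seal_id: str
    sex: str
    group: str
    true_growth_rate: float  # mm/day
    age_at_collection: float  # years
    whisker_length: float  # mm
    baseline_d13C: float  # ‰, value at age 0 before oscillation/noise
    baseline_d15N: float  # ‰
    oscillation_amplitude_d13C: float = 1.0  # ‰
    ontogenetic_slope_d13C: float = -0.30  # ‰/year
    ontogenetic_slope_d15N: float = 0.15  # ‰/year
    noise_sd: float = 0.3  # ‰, δ13C segment noise
    has_tip_peak: bool = False
    oscillation_phase: float = 0.0  # radians
    noise_sd_d15N: float | None = None  # ‰; defaults to noise_sd
    tip_peak_height: float = 3.0  # ‰, δ15N bump at ages < tip_peak_max_age
    tip_peak_max_age: float = 0.35  # years

    def __post_init__(self) -> None:
        if self.true_growth_rate <= 0:
            raise ValueError("true_growth_rate must be positive")
        if self.whisker_length <= 0:
            raise ValueError("whisker_length must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.oscillation_amplitude_d13C < 0:
            raise ValueError("oscillation amplitude must be non-negative")
        if self.group in ("female_g1", "female_g2") and self.sex != "female":
            raise ValueError("female group labels require sex == 'female'")
        if self.sex == "male" and self.group != "male":
            raise ValueError("males carry group 'male'")


@dataclass
class SimConfig:
    """Population-level simulation settings."""

    n_males: int = 20
    n_females: int = 20
    prop_female_g2: float = 6 / 20
    segment_mm: float = 5.0
    group_means: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_MEANS))
    group_sds: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SDS))
    between_sd: tuple = DEFAULT_BETWEEN_SD
    oscillation_amplitude_d13C: float = 1.0
    ontogenetic_slope_d13C: float = -0.30
    ontogenetic_slope_d15N: float = 0.15
    noise_sd: float | None = None  # ‰; None calibrates noise from group_sds
    prop_tip_peak: float = 6 / 20
    tdf_d13C: float = 2.06
    prey_mean_d13C: float = -20.98
    prey_sd: float = 1.0
    n_prey: int = 20
    n_readers: int = 3
    reader_error_sd: float = 0.7  # years
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_males < 0 or self.n_females < 0:
            raise ValueError("counts must be non-negative")
        if self.segment_mm <= 0:
            raise ValueError("segment_mm must be positive")
        if not 0.0 <= self.prop_female_g2 <= 1.0:
            raise ValueError("prop_female_g2 must lie in [0, 1]")
        if self.prey_sd < 0 or self.reader_error_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def segment_positions(whisker_length: float, segment_mm: float) -> np.ndarray:
    """Segment-start offsets 0, s, 2s, ... < whisker_length (mm, facial end)."""
    if segment_mm <= 0:
        raise ValueError("segment_mm must be positive")
    if whisker_length < segment_mm:
        raise EmptySeriesError(
            f"whisker ({whisker_length:.1f} mm) shorter than one "
            f"{segment_mm:.1f} mm segment"
        )
    n = int(np.ceil(whisker_length / segment_mm - 1e-12))
    return np.arange(n) * segment_mm


def true_ages(params: IndividualParams, positions: np.ndarray) -> np.ndarray:
    """Ground-truth age (years) of the growth at each position."""
    return params.age_at_collection - positions / (
        params.true_growth_rate * DAYS_PER_YEAR
    )


def simulate_whisker(
    params: IndividualParams, segment_mm: float = 5.0, seed: int | None = 0
) -> WhiskerSeries:
    """Simulate one whisker's per-segment δ13C/δ15N record.

    δ13C(x) = baseline + slope_C·age(x) + A·sin(2πx/(365.25·rate) + φ) + ε,
    δ15N(x) = baseline + slope_N·age(x) + tip-peak bump + ε, with independent
    Gaussian ε of sd ``noise_sd``.  The sinusoid has one cycle per year of
    growth, i.e. spatial period rate·365.25 mm.
    """
    rng = np.random.default_rng(seed)
    x = segment_positions(params.whisker_length, segment_mm)
    age = true_ages(params, x)
    period_mm = params.true_growth_rate * DAYS_PER_YEAR
    d13c = (
        params.baseline_d13C
        + params.ontogenetic_slope_d13C * age
        + params.oscillation_amplitude_d13C
        * np.sin(2 * np.pi * x / period_mm + params.oscillation_phase)
        + rng.normal(0.0, params.noise_sd, x.size)
    )
    sd_n = params.noise_sd if params.noise_sd_d15N is None else params.noise_sd_d15N
    d15n = (
        params.baseline_d15N
        + params.ontogenetic_slope_d15N * age
        + rng.normal(0.0, sd_n, x.size)
    )
    if params.has_tip_peak:
        # suckling signal: ramps up towards the tip over the nursing window
        frac = np.clip(1.0 - age / params.tip_peak_max_age, 0.0, None)
        d15n = d15n + params.tip_peak_height * frac
    return WhiskerSeries(params.seal_id, params.sex, x, d13c, d15n)


def _truncated_normal(rng, mean, sd, lower, size=None):
    """Rejection-sampled normal truncated below at ``lower``."""
    out = rng.normal(mean, sd, size)
    bad = out <= lower
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size), out)
        bad = out <= lower
    return out


def _draw_individual(
    rng: np.random.Generator, seal_id: str, sex: str, group: str, config: SimConfig
) -> IndividualParams:
    rate = float(_truncated_normal(rng, *GROWTH_RATE[sex], 0.01))
    length = float(_truncated_normal(rng, *WHISKER_LENGTH[sex], 50.0))
    has_peak = sex == "female" and rng.random() < config.prop_tip_peak
    if sex == "male":
        age = float(_truncated_normal(rng, 8.70, 0.73, 4.0))
        # whisker record cannot predate the animal; the guard also keeps the
        # record shorter than the (rounded) tooth age in most draws
        length = min(length, (age - 0.6) * rate * DAYS_PER_YEAR)
    else:
        # female true age = whisker record duration + unrecorded wear at tip;
        # a suckling tip-peak means the tip survived, so wear is negligible
        wear = 0.05 if has_peak else float(rng.uniform(0.05, 2.0))
        age = length / (rate * DAYS_PER_YEAR) + wear

    mean_c, mean_n = config.group_means[group]
    eff_c = float(rng.normal(0.0, config.between_sd[0]))
    eff_n = float(rng.normal(0.0, config.between_sd[1]))
    phase = float(rng.uniform(0.0, 2 * np.pi))

    # anchor baselines so the individual's expected whisker mean equals the
    # group mean plus its individual effect, whatever its age span
    draft = IndividualParams(
        seal_id=seal_id,
        sex=sex,
        group=group,
        true_growth_rate=rate,
        age_at_collection=age,
        whisker_length=length,
        baseline_d13C=0.0,
        baseline_d15N=0.0,
        oscillation_amplitude_d13C=config.oscillation_amplitude_d13C,
        ontogenetic_slope_d13C=config.ontogenetic_slope_d13C,
        ontogenetic_slope_d15N=config.ontogenetic_slope_d15N,
        noise_sd=0.3,
        has_tip_peak=has_peak,
        oscillation_phase=phase,
    )
    ages = true_ages(draft, segment_positions(length, config.segment_mm))
    mean_age = float(np.mean(ages))

    # calibrate segment noise so the pooled group SD lands near the target:
    # total variance = between + oscillation (A²/2, δ13C only) + ontogenetic
    # trend spread (slope²·var(age)) + noise.  Floor at 0.3 ‰ (measurement-
    # scale noise); an explicit config noise_sd overrides the calibration.
    if config.noise_sd is not None:
        noise_c = noise_n = config.noise_sd
    else:
        sd_c, sd_n = config.group_sds[group]
        var_ages = float(np.var(ages))
        resid_c = (
            sd_c**2
            - config.between_sd[0] ** 2
            - config.oscillation_amplitude_d13C**2 / 2.0
            - config.ontogenetic_slope_d13C**2 * var_ages
        )
        resid_n = (
            sd_n**2
            - config.between_sd[1] ** 2
            - config.ontogenetic_slope_d15N**2 * var_ages
        )
        noise_c = float(np.sqrt(max(resid_c, 0.09)))
        noise_n = float(np.sqrt(max(resid_n, 0.09)))
    return replace(
        draft,
        baseline_d13C=mean_c + eff_c - config.ontogenetic_slope_d13C * mean_age,
        baseline_d15N=mean_n + eff_n - config.ontogenetic_slope_d15N * mean_age,
        noise_sd=noise_c,
        noise_sd_d15N=noise_n,
    )


def simulate_population(
    config: SimConfig | None = None,
) -> tuple[list[WhiskerSeries], list[IndividualParams], pd.DataFrame]:
    """Simulate a colony: whisker series, ground-truth params, morphometrics."""
    config = config if config is not None else SimConfig()
    ss = np.random.SeedSequence(config.seed)
    pop_rng = np.random.default_rng(ss.spawn(1)[0])
    n_total = config.n_males + config.n_females
    child_seeds = ss.spawn(n_total)

    series: list[WhiskerSeries] = []
    params: list[IndividualParams] = []
    morpho_rows = []
    for i in range(n_total):
        if i < config.n_males:
            sex, group = "male", "male"
            seal_id = f"m{i + 1:02d}"
        else:
            sex = "female"
            group = (
                "female_g2"
                if pop_rng.random() < config.prop_female_g2
                else "female_g1"
            )
            seal_id = f"f{i - config.n_males + 1:02d}"
        p = _draw_individual(pop_rng, seal_id, sex, group, config)
        params.append(p)
        series.append(simulate_whisker(p, config.segment_mm, child_seeds[i]))
        offset = 1.10 if group == "female_g2" else 1.0
        vals = [
            pop_rng.normal(m * offset, s)
            for m, s in zip(MORPHO_MEANS[sex], MORPHO_SDS[sex])
        ]
        morpho_rows.append(
            {
                "seal_id": seal_id,
                "sex": sex,
                "group": group,
                "age_years": p.age_at_collection,
                **dict(zip(MORPHO_COLS, vals)),
            }
        )
    return series, params, pd.DataFrame(morpho_rows)


def simulate_tooth_readings(
    true_age: float, n_readers: int = 3, error_sd: float = 0.7, seed: int | None = 0
) -> np.ndarray:
    """Integer growth-ridge age readings from ``n_readers`` independent readers.

    Readings are round-half-up of true age + Gaussian reader error, floored
    at 1 year (a ridge count of zero is never recorded).
    """
    if n_readers < 1:
        raise ValueError("n_readers must be >= 1")
    if true_age <= 0:
        raise ValueError("true_age must be positive")
    rng = np.random.default_rng(seed)
    raw = true_age + rng.normal(0.0, error_sd, n_readers)
    return np.maximum(1, np.floor(raw + 0.5).astype(int))


def simulate_prey_samples(
    mean: float = -20.98, sd: float = 1.0, n: int = 20, seed: int | None = 0
) -> np.ndarray:
    """Gaussian prey δ13C samples (myctophids and krill at the front)."""
    if n < 1:
        raise ValueError("need at least one prey sample")
    rng = np.random.default_rng(seed)
    return rng.normal(mean, sd, n)


# ---------------------------------------------------------------------------
# CSV export

def segments_frame(series: list[WhiskerSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        rows.append(
            pd.DataFrame(
                {
                    "seal_id": s.seal_id,
                    "sex": s.sex,
                    "position_mm": s.positions,
                    "d13C": s.d13C,
                    "d15N": s.d15N,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["seal_id", "sex", "position_mm", "d13C", "d15N"]
        )
    return pd.concat(rows, ignore_index=True)


def write_population(out_dir, config: SimConfig | None = None):
    """Generate a population and write the four input CSVs to ``out_dir``.

    Files: whisker_segments.csv, seals.csv, age_readings.csv (males only,
    three readers by default), prey.csv.  Same seed ⇒ byte-identical files.
    """
    from pathlib import Path

    config = config if config is not None else SimConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series, params, morpho = simulate_population(config)

    segments_frame(series).to_csv(out / "whisker_segments.csv", index=False)
    morpho.to_csv(out / "seals.csv", index=False)

    ss = np.random.SeedSequence((config.seed, 1))
    reading_rows = []
    for p, child in zip(params, ss.spawn(max(len(params), 1))):
        if p.sex != "male":
            continue
        readings = simulate_tooth_readings(
            p.age_at_collection, config.n_readers, config.reader_error_sd, child
        )
        for r, val in enumerate(readings, start=1):
            reading_rows.append(
                {"seal_id": p.seal_id, "reader_id": f"r{r}", "age_years": int(val)}
            )
    pd.DataFrame(
        reading_rows, columns=["seal_id", "reader_id", "age_years"]
    ).to_csv(out / "age_readings.csv", index=False)

    prey = simulate_prey_samples(
        config.prey_mean_d13C,
        config.prey_sd,
        config.n_prey,
        np.random.SeedSequence((config.seed, 2)),
    )
    pd.DataFrame(
        {
            "sample_id": [f"p{i + 1:02d}" for i in range(len(prey))],
            "species": ["myctophid" if i % 2 == 0 else "krill" for i in range(len(prey))],
            "d13C": prey,
        }
    ).to_csv(out / "prey.csv", index=False)
    return series, params, morpho
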