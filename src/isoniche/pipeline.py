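"""End-to-end orchestration: ingest → ageing → chronology → front
classification → niche ellipses → mixed models → specialisation indices.

Every stage logs one structured line with record counts; the run is fully
determined by the config (including its seed), and the summary JSON embeds a
hash of the config for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ageing, chronology, front, io, niche, stats
from .core import DAYS_PER_YEAR, IsonicheError

log = logging.getLogger("isoniche")


@dataclass
class RunConfig:
    """All pipeline settings; round-trips losslessly through YAML."""

    input_dir: str = "."
    output_dir: str = "results"
    segment_mm: float = 5.0
    root_exclusion_mm: float = 5.0
    tdf_d13C: float = 2.06
    # wavelet settings
    omega0: float = 6.0
    period_range: tuple = (10.0, 100.0)
    n_periods: int = 60
    n_null: int = 100
    sig_level: float = 0.95
    # chronology
    tip_anchor_age: float = 0.3  # yr, weaning anchor for tip-peak females
    tip_peak_threshold: float = 1.5  # ‰
    # niche
    n_posterior_draws: int = 100_000
    n_overlap_draws: int = 1000
    age_window_years: float = 1.0
    proportion_def: str = "union"
    # stats
    selection_alpha: float = 0.05
    ar_order: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.segment_mm <= 0 or self.age_window_years <= 0:
            raise ValueError("segment_mm and age_window_years must be positive")
        if not 0 < self.selection_alpha < 1 or not 0 < self.sig_level < 1:
            raise ValueError("alpha levels must lie in (0, 1)")
        if self.n_posterior_draws < 1000:
            raise ValueError("n_posterior_draws must be >= 1000")
        self.period_range = tuple(float(v) for v in self.period_range)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    @property
    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _build_chronologies(series_list, tooth_ages, config):
    """Wavelet growth rates (cohort fallback) and per-segment ages."""
    rates: dict[str, float | None] = {}
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 17)))
    for s in series_list:
        seed = int(rng.integers(2**31))
        try:
            rate, _ = chronology.estimate_growth_rate(
                s,
                period_range=config.period_range,
                n_periods=config.n_periods,
                omega0=config.omega0,
                n_null=config.n_null,
                sig_level=config.sig_level,
                seed=seed,
            )
        except IsonicheError:
            rate = None
        rates[s.seal_id] = rate

    by_sex = {"male": [], "female": []}
    for s in series_list:
        if rates[s.seal_id] is not None:
            by_sex[s.sex].append(rates[s.seal_id])

    chronologies = []
    for s in series_list:
        rate = rates[s.seal_id]
        source = "wavelet"
        if rate is None:
            rate = chronology.cohort_fallback_rate(by_sex, s.sex)
            source = "cohort_mean"
            log.warning("seal %s: no clear periodicity, cohort mean rate %.4f",
                        s.seal_id, rate)
        if s.sex == "male" and s.seal_id in tooth_ages:
            try:
                c = chronology.assign_ages(
                    s, rate, age_at_collection=float(tooth_ages[s.seal_id]),
                    rate_source=source,
                )
            except IsonicheError:
                log.warning(
                    "seal %s: tooth age %.1f yr shorter than whisker record; "
                    "using span-based minimum ages", s.seal_id,
                    tooth_ages[s.seal_id],
                )
                c = chronology.assign_ages(s, rate, rate_source=source)
        elif s.sex == "female" and chronology.detect_tip_peak(
            s, threshold=config.tip_peak_threshold
        ) is not None:
            c = chronology.assign_ages(
                s, rate, tip_anchor_age=config.tip_anchor_age, rate_source=source
            )
        else:
            c = chronology.assign_ages(s, rate, rate_source=source)
        chronologies.append(c)
    return chronologies


def _segment_table(series_list, chronologies, groups):
    chron = {c.seal_id: c for c in chronologies}
    rows = []
    for s in series_list:
        c = chron[s.seal_id]
        rows.append(pd.DataFrame({
            "seal_id": s.seal_id,
            "sex": s.sex,
            "group": groups[s.seal_id],
            "position_mm": s.positions,
            "age": c.ages,
            "d13C": s.d13C,
            "d15N": s.d15N,
        }))
    df = pd.concat(rows, ignore_index=True)
    df["group"] = pd.Categorical(df["group"],
                                 categories=["male", "female_g1", "female_g2"])
    return df


def _points(df: pd.DataFrame, mask) -> np.ndarray:
    return df.loc[mask, ["d13C", "d15N"]].to_numpy(float)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all output tables plus a summary JSON.

    Returns the summary dict.  Identical config (same seed) gives identical
    outputs byte for byte.
    """
    in_dir = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_digest": config.digest, "seed": config.seed}

    def stage(name):
        log.info("stage %s", name)

    try:
        stage("ingest")
        series_list = io.read_segments(
            in_dir / "whisker_segments.csv", config.root_exclusion_mm
        )
        if not series_list:
            raise IsonicheError("no whisker series in input")
        prey = io.read_prey(in_dir / "prey.csv")
        readings = io.read_age_readings(in_dir / "age_readings.csv")
        seals = io.read_seals(in_dir / "seals.csv")
        log.info("ingest: %d seals, %d segments, %d prey samples",
                 len(series_list), sum(len(s) for s in series_list), len(prey))
    except (OSError, IsonicheError) as exc:
        raise IsonicheError(f"stage ingest failed: {exc}") from exc

    # ---- ageing -----------------------------------------------------------
    stage("ageing")
    tooth_ages = {}
    reading_rows = []
    for seal_id, sub in readings.groupby("seal_id"):
        vals = sub["age_years"].to_numpy()
        tooth_ages[str(seal_id)] = ageing.modal_age(vals)
        reading_rows.append(vals)
    ages_df = pd.DataFrame(
        {"seal_id": sorted(tooth_ages),
         "modal_age": [tooth_ages[k] for k in sorted(tooth_ages)],
         "n_readings": [len(readings[readings["seal_id"] == k])
                        for k in sorted(tooth_ages)]}
    )
    ages_df.to_csv(out / "ages.csv", index=False)
    summary["iape_percent"] = ageing.iape(reading_rows) if reading_rows else None
    summary["reader_agreement_pm1"] = (
        ageing.pairwise_agreement(reading_rows) if reading_rows else None
    )

    # ---- chronology -------------------------------------------------------
    stage("chronology")
    chronologies = _build_chronologies(series_list, tooth_ages, config)
    chron_rows = []
    for s, c in zip(series_list, chronologies):
        for p, a in zip(c.positions, c.ages):
            chron_rows.append({
                "seal_id": c.seal_id, "position_mm": p, "age_years": a,
                "growth_rate_mm_day": c.growth_rate, "rate_source": c.rate_source,
                "is_minimum_age": c.is_minimum_age,
            })
    pd.DataFrame(chron_rows).to_csv(out / "chronology.csv", index=False)
    rates_by_sex = {
        sex: [c.growth_rate for s, c in zip(series_list, chronologies)
              if s.sex == sex]
        for sex in ("male", "female")
    }
    summary["growth_rate_mm_day"] = {
        sex: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0}
        for sex, v in rates_by_sex.items() if v
    }

    # ---- front classification --------------------------------------------
    stage("front")
    model = front.front_threshold(prey["d13C"], config.tdf_d13C)
    summary["front_threshold_d13C"] = model.threshold
    classifications = [front.classify_segments(s, model) for s in series_list]
    groups = {c.seal_id: c.group for c in classifications}
    pd.DataFrame([
        {"seal_id": c.seal_id, "group": c.group, "prop_north": c.prop_north,
         "n_segments": len(c.segment_north),
         "mean_d13C": float(s.d13C.mean()), "max_d13C": float(s.d13C.max())}
        for s, c in zip(series_list, classifications)
    ]).to_csv(out / "classification.csv", index=False)
    summary["n_female_g1"] = sum(g == "female_g1" for g in groups.values())
    summary["n_female_g2"] = sum(g == "female_g2" for g in groups.values())
    summary["ever_north"] = {
        "females": int(sum(front.max_exceeds_threshold(s, model)
                           for s in series_list if s.sex == "female")),
        "males": int(sum(front.max_exceeds_threshold(s, model)
                         for s in series_list if s.sex == "male")),
    }

    # ---- niche ellipses ---------------------------------------------------
    stage("niche")
    df = _segment_table(series_list, chronologies, groups)
    seed_seq = np.random.SeedSequence((config.seed, 23))
    seeds = iter(int(s.generate_state(1)[0] % 2**31) for s in seed_seq.spawn(16))
    fits = {}
    pools = {
        "male": df["sex"] == "male",
        "female": df["sex"] == "female",
        "female_g1": df["group"] == "female_g1",
        "female_g2": df["group"] == "female_g2",
    }
    for label, mask in pools.items():
        pts = _points(df, mask)
        if len(pts) >= 3:
            fits[label] = niche.sea_bayesian(
                pts, label, n_draws=config.n_posterior_draws, seed=next(seeds)
            )
    niche_rows = [
        {"group": f.group_label, "n": f.n, "sea": f.sea, "sea_c": f.sea_c,
         "sea_b_mode": f.sea_b_mode, "ci_low": f.sea_b_ci95[0],
         "ci_high": f.sea_b_ci95[1]}
        for f in fits.values()
    ]
    pd.DataFrame(niche_rows).to_csv(out / "niche_summary.csv", index=False)

    pairs = [("male", "female"), ("female_g1", "female_g2"),
             ("male", "female_g1"), ("male", "female_g2")]
    overlap_rows = []
    for a, b in pairs:
        if a not in fits or b not in fits:
            continue
        ov = niche.ellipse_overlap(
            fits[a], fits[b], config.proportion_def,
            n_bayes_draws=config.n_overlap_draws, seed=next(seeds),
        )
        overlap_rows.append({
            "group_a": a, "group_b": b, "area": ov.area_overlap,
            "proportion": ov.proportion, "bayes_mode": ov.bayes_mode,
            "ci_low": ov.bayes_ci95[0] if ov.bayes_ci95 else None,
            "ci_high": ov.bayes_ci95[1] if ov.bayes_ci95 else None,
        })
    pd.DataFrame(overlap_rows).to_csv(out / "overlap.csv", index=False)
    summary["sea"] = {k: f.sea for k, f in fits.items()}
    summary["overlap_proportion"] = {
        f"{r['group_a']}|{r['group_b']}": r["proportion"] for r in overlap_rows
    }

    stage("ontogenetic niche")
    refs = {k: fits[k] for k in ("female_g1", "female_g2") if k in fits}
    ml_refs = {k: niche.fit_ellipse(_points(df, pools[k]), k) for k in refs}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            onto = niche.ontogenetic_ellipses(
                series_list, chronologies, config.age_window_years,
                group_filter="male", groups=groups, reference_fits=ml_refs,
                proportion_def=config.proportion_def,
            )
    except IsonicheError as exc:
        log.warning("ontogenetic ellipses skipped: %s", exc)
        onto = []
    onto_rows = []
    for (lo, hi), f, ovs in onto:
        row = {"age_lo": lo, "age_hi": hi, "n": f.n, "sea": f.sea,
               "mean_d13C": f.mean[0], "mean_d15N": f.mean[1]}
        for ref, ov in ovs.items():
            row[f"overlap_{ref}"] = ov.proportion
        onto_rows.append(row)
    pd.DataFrame(onto_rows).to_csv(out / "ontogenetic_niche.csv", index=False)

    # ---- mixed models -----------------------------------------------------
    stage("models")
    model_rows, spec_rows = [], []
    summary["models"] = {}
    for response in ("d13C", "d15N"):
        spec = stats.LmmSpec(response, ar_order=config.ar_order)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit, trace = stats.backward_select(df, spec, config.selection_alpha)
        for name, (est, se, p) in fit.fixed_effects.items():
            model_rows.append({"response": response, "term": name,
                               "estimate": est, "se": se, "p": p})
        idx = stats.wic_tnw(fit)
        spec_rows.append({"response": response, "wic": idx.wic,
                          "tnw": idx.tnw, "index": idx.index})
        summary["models"][response] = {
            "terms": list(fit.fixed_terms),
            "r2_conditional": fit.r2_conditional,
            "specialisation_index": idx.index,
            "ar_coefficients": fit.residual_correlation,
            "selection_trace": trace,
        }
    pd.DataFrame(model_rows).to_csv(out / "model_summary.csv", index=False)
    pd.DataFrame(spec_rows).to_csv(out / "specialisation.csv", index=False)

    stage("proportions north")
    cls_df = pd.DataFrame([
        {"seal_id": c.seal_id, "prop_north": c.prop_north, "group": c.group}
        for c in classifications
    ])
    try:
        beta = stats.fit_beta_proportions(cls_df["prop_north"], cls_df["group"])
        summary["prop_north"] = {
            "group_means": beta.group_means, "lr_p": beta.lr_p,
        }
    except ValueError as exc:
        log.warning("beta regression skipped: %s", exc)
        summary["prop_north"] = None
    summary["prop_north_observed"] = {
        g: float(sub["prop_north"].mean())
        for g, sub in cls_df.groupby("group")
    }

    stage("morphometrics")
    try:
        if "group" not in seals.columns:
            seals = seals.assign(group=seals["seal_id"].map(groups))
        else:
            seals = seals.assign(group=seals["seal_id"].map(groups))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pca = stats.morphometric_pca(seals[seals["sex"] == "female"])
        pca.scores.to_csv(out / "pca.csv", index=False)
        summary["morphometrics_welch"] = {k: {"t": v[0], "p": v[1]}
                                          for k, v in pca.welch.items()}
    except (IsonicheError, KeyError) as exc:
        log.warning("morphometric PCA skipped: %s", exc)
        summary["morphometrics_welch"] = None

    # routine two-sample comparisons reported via standard routines
    wl = {s.seal_id: s.span_mm for s in series_list}
    male_l = [wl[s.seal_id] for s in series_list if s.sex == "male"]
    fem_l = [wl[s.seal_id] for s in series_list if s.sex == "female"]
    if male_l and fem_l:
        from scipy import stats as sps
        u, p = sps.mannwhitneyu(male_l, fem_l)
        summary["whisker_length_mannwhitney"] = {"U": float(u), "p": float(p)}
        t, p = sps.ttest_ind(rates_by_sex["male"], rates_by_sex["female"],
                             equal_var=False)
        summary["growth_rate_welch"] = {"t": float(t), "p": float(p)}

    mean_by_sex = df.groupby("sex", observed=True)[["d13C", "d15N"]].mean()
    summary["mean_isotopes"] = {
        sex: {"d13C": float(r["d13C"]), "d15N": float(r["d15N"])}
        for sex, r in mean_by_sex.iterrows()
    }

    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
    config.to_yaml(out / "config.yaml")
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
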