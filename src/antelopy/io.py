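"""CSV readers/writers, run configuration, the run manifest, and the stage
orchestration that chains simulate -> features -> train -> classify ->
budgets -> moonlight test -> GAM partitioning.

The interchange dialect is the Movebank ACC export: one row per burst with
``accelerations-raw`` holding the space-separated interleaved integer
samples ``x1 y1 z1 x2 y2 z2 ...``.  Malformed rows are never silently
dropped; they are collected into a rejects table with reasons.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

import numpy as np
import pandas as pd

from . import astro, classifier, features, gam, synthetic, timebudget

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "read_acc_csv",
    "read_env_csv",
    "run_all",
]

log = logging.getLogger("antelopy")

ACC_REQUIRED = (
    "individual-local-identifier",
    "timestamp",
    "sampling-frequency",
    "accelerations-raw",
)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All stage parameters with the study's deployed defaults.

    33 Hz / 3.3 s bursts every 5 min, 22-sample ODBA window, 0.9
    correlation threshold, k = 10 spline bases, 0.9/0.1 lunar thresholds,
    -30 deg pitch split, 10-day settling exclusion, site (-19.2, 15.2),
    local time UTC+2.
    """

    out_dir: str = "antelopy_run"
    acc_path: str | None = None
    labels_path: str | None = None
    env_path: str | None = None
    latitude: float = astro.SITE_LAT
    longitude: float = astro.SITE_LON
    tz_offset_h: int = astro.LOCAL_UTC_OFFSET_H
    seed: int = 0
    # simulate stage
    simulate: bool = True
    n_individuals: int = 3
    start: str = "2021-03-01"
    end: str = "2021-04-15"
    lunar_effect: float = 0.10
    individual_sd: float = 0.30
    n_labelled_per_class: int = 400
    # classifier stage
    correlation_threshold: float = 0.9
    train_split: float = 0.75
    # budget stage
    min_daily_coverage: int = timebudget.MIN_DAILY_COVERAGE
    actogram_year: int = 2021
    # moonlight stage
    moonlit_threshold: float = astro.MOONLIT_THRESHOLD
    dark_threshold: float = astro.DARK_THRESHOLD
    # gam stage
    gam_min_rows: int = 50

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        flat: dict = {}
        for key, value in raw.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**flat)

    def sim_config(self) -> synthetic.SimConfig:
        return synthetic.SimConfig(
            n_individuals=self.n_individuals,
            start=date.fromisoformat(self.start),
            end=date.fromisoformat(self.end),
            lunar_effect=self.lunar_effect,
            individual_sd=self.individual_sd,
            latitude=self.latitude,
            longitude=self.longitude,
            tz_offset_h=self.tz_offset_h,
            seed=self.seed,
        )


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seed, input checksums."""

    config: dict
    seed: int
    created_utc: str
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, dict] = field(default_factory=dict)

    def checksum(self) -> str:
        payload = json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "inputs": self.input_checksums,
                "counts": self.stage_counts,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def write(self, path) -> None:
        data = dataclasses.asdict(self)
        data["manifest_sha256"] = self.checksum()
        Path(path).write_text(json.dumps(data, indent=2, default=str))


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_acc_csv(path) -> tuple[list[features.Burst], pd.DataFrame]:
    """Parse a Movebank-dialect ACC CSV into bursts plus a rejects table.

    ``accelerations-raw`` must contain 3k integers (interleaved x y z);
    malformed rows land in the rejects frame with a reason, never silently
    dropped.  Returns (bursts, rejects).
    """
    df = pd.read_csv(path, dtype={"accelerations-raw": str})
    missing = [c for c in ACC_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s) in {path}: {missing}")
    bursts: list[features.Burst] = []
    rejects = []
    for i, row in df.iterrows():
        try:
            values = np.fromstring(row["accelerations-raw"], dtype=np.int64, sep=" ")
        except Exception:
            rejects.append({"row": i, "reason": "unparseable accelerations-raw"})
            continue
        if values.size == 0 or values.size % 3 != 0:
            rejects.append({"row": i, "reason": f"sample count {values.size} not a multiple of 3"})
            continue
        if values.size // 3 < 8:
            rejects.append({"row": i, "reason": "burst shorter than 8 samples"})
            continue
        if values.min() < 0 or values.max() > 4095:
            rejects.append({"row": i, "reason": "sample outside 0-4095"})
            continue
        bursts.append(
            features.Burst(
                individual_id=str(row["individual-local-identifier"]),
                start_utc=pd.Timestamp(row["timestamp"]),
                rate=float(row["sampling-frequency"]),
                x=values[0::3],
                y=values[1::3],
                z=values[2::3],
            )
        )
    rejects_df = pd.DataFrame(rejects, columns=["row", "reason"])
    if len(rejects_df):
        log.warning("read_acc_csv: rejected %d of %d rows", len(rejects_df), len(df))
    return bursts, rejects_df


def read_env_csv(path) -> pd.DataFrame:
    """Per-individual daily environmental covariates.

    Returns columns ``individual_id, date, ndvi, temp_mean_c`` with one row
    per individual-date.  Duplicate individual-dates are averaged with a
    warning; rows with NDVI outside [-1, 1] are rejected; missing
    temperature is kept as NaN (such rows are excluded from GAM fitting).
    """
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"empty environmental file {path}")
        return pd.DataFrame(columns=["individual_id", "date", "ndvi", "temp_mean_c"])
    df = df.rename(columns={"individual-local-identifier": "individual_id"})
    df["date"] = pd.to_datetime(df["date"]).dt.date
    bad = (df["ndvi"] < -1) | (df["ndvi"] > 1)
    if bad.any():
        warnings.warn(f"rejecting {int(bad.sum())} rows with NDVI outside [-1, 1]")
        df = df.loc[~bad]
    dup = df.duplicated(["individual_id", "date"], keep=False)
    if dup.any():
        warnings.warn("duplicate individual-date rows averaged")
    out = (
        df.groupby(["individual_id", "date"], as_index=False)[["ndvi", "temp_mean_c"]]
        .mean()
    )
    return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _paths(cfg: PipelineConfig) -> dict[str, Path]:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return {
        "out": out,
        "acc": Path(cfg.acc_path) if cfg.acc_path else out / "acc.csv",
        "labels": Path(cfg.labels_path) if cfg.labels_path else out / "labelled.csv",
        "env": Path(cfg.env_path) if cfg.env_path else out / "env.csv",
        "features": out / "features.csv",
        "model": out / "model.joblib",
        "confusion": out / "confusion.csv",
        "selection": out / "feature_selection.json",
        "classified": out / "classified.csv",
        "daily": out / "daily_budget.csv",
        "monthly": out / "monthly_budget.csv",
        "diel": out / "diel",
        "actogram": out / "actogram.png",
        "moonlight": out / "moonlight_test.json",
        "gamhp": out / "gam_hp.json",
        "gamhp_bars": out / "gam_hp_bars.csv",
        "manifest": out / "manifest.json",
        "rejects": out / "acc_rejects.csv",
    }


def stage_simulate(cfg: PipelineConfig, manifest: RunManifest) -> None:
    p = _paths(cfg)
    sim = cfg.sim_config()
    env = synthetic.generate_env_series(sim)
    schedule = synthetic.generate_behaviour_schedule(sim, env)
    bursts = synthetic.synthesize_schedule_bursts(schedule, sim)
    synthetic.write_dataset(schedule, bursts, env, p["acc"], p["env"], sampling_rate=sim.sampling_rate)
    labelled = synthetic.generate_labelled_bursts(sim, n_per_class=cfg.n_labelled_per_class)
    lab_sched = pd.DataFrame(
        {
            "individual_id": "TRAIN01",
            "burst_start_utc": pd.date_range(
                datetime(sim.start.year, 1, 1), periods=len(labelled), freq="5min"
            ),
            "label_raw": labelled["label_raw"],
        }
    )
    synthetic.write_dataset(
        lab_sched, list(labelled["burst"]), env, p["labels"].with_suffix(".acc.csv"),
        p["labels"].with_suffix(".env.csv"), labels_path=p["labels"],
        sampling_rate=sim.sampling_rate,
    )
    schedule.to_csv(p["out"] / "true_schedule.csv", index=False)
    manifest.stage_counts["simulate"] = {
        "bursts": len(schedule),
        "labelled_bursts": len(labelled),
        "days": len(env),
    }
    log.info("simulate: %d bursts, %d labelled", len(schedule), len(labelled))


def _labelled_features(cfg: PipelineConfig) -> pd.DataFrame:
    p = _paths(cfg)
    df = pd.read_csv(p["labels"], dtype={"accelerations-raw": str})
    bursts, rejects = read_acc_csv(p["labels"])
    table = features.feature_table(bursts)
    kept = df.drop(index=rejects["row"]) if len(rejects) else df
    table["label"] = kept["behaviour"].to_numpy()
    return table


def stage_features(cfg: PipelineConfig, manifest: RunManifest) -> pd.DataFrame:
    p = _paths(cfg)
    bursts, rejects = read_acc_csv(p["acc"])
    if len(rejects):
        rejects.to_csv(p["rejects"], index=False)
    # orientation harmonisation against the labelled training stand-in
    lab_bursts, _ = read_acc_csv(p["labels"])
    ref = _axis_means_g(lab_bursts)
    orientations = {}
    by_ind: dict[str, list] = {}
    for b in bursts:
        by_ind.setdefault(b.individual_id, []).append(b)
    for ind, blist in by_ind.items():
        means = _axis_means_g(blist)
        orientations[ind] = features.decide_orientation(ref, means)
    table = features.feature_table(bursts, orientations)
    table.to_csv(p["features"], index=False)
    manifest.stage_counts["features"] = {
        "bursts_read": len(bursts),
        "bursts_rejected": int(len(rejects)),
        "individuals": len(by_ind),
        "flipped": sum(o.flip_x or o.flip_y for o in orientations.values()),
    }
    log.info("features: %d bursts, %d rejected", len(bursts), len(rejects))
    return table


def _axis_means_g(bursts: list[features.Burst]) -> tuple[float, float]:
    if not bursts:
        raise ValueError("no bursts to summarise")
    x = np.concatenate([np.asarray(b.x, dtype=float) for b in bursts])
    y = np.concatenate([np.asarray(b.y, dtype=float) for b in bursts])
    return (
        float((x.mean() - features.RAW_OFFSET) / features.UNITS_PER_G),
        float((y.mean() - features.RAW_OFFSET) / features.UNITS_PER_G),
    )


def stage_train(cfg: PipelineConfig, manifest: RunManifest) -> classifier.ClassifierModel:
    p = _paths(cfg)
    table = _labelled_features(cfg)
    feat_cols = [c for c in features.FEATURE_NAMES]
    sel = classifier.remove_redundant(
        table[feat_cols + ["label"]], threshold=cfg.correlation_threshold, seed=cfg.seed
    )
    model, cm = classifier.train(
        table, feature_names=sel.retained, split=cfg.train_split, seed=cfg.seed
    )
    contrib = classifier.rank_contributions(
        table[feat_cols + ["label"]], sel, seed=cfg.seed
    )
    classifier.save_model(model, p["model"])
    cm.counts.to_csv(p["confusion"])
    p["selection"].write_text(
        json.dumps(
            {
                "retained": list(sel.retained),
                "dropped": sel.dropped,
                "contributions": contrib,
                "balanced_accuracy": cm.balanced_accuracy,
            },
            indent=2,
        )
    )
    manifest.stage_counts["train"] = {
        "rows": len(table),
        "retained_features": len(sel.retained),
        "balanced_accuracy": cm.balanced_accuracy,
    }
    log.info("train: balanced accuracy %.3f", cm.balanced_accuracy)
    return model


def stage_classify(cfg: PipelineConfig, manifest: RunManifest) -> pd.DataFrame:
    p = _paths(cfg)
    if not p["model"].exists():
        raise FileNotFoundError("no trained model; run the train stage first")
    model = classifier.load_model(p["model"])
    table = pd.read_csv(p["features"])
    out = classifier.classify(model, table)
    out["label_class"] = out["label"].map(synthetic.ANALYSIS_CLASS_OF)
    out.to_csv(p["classified"], index=False)
    manifest.stage_counts["classify"] = {"bursts": len(out)}
    log.info("classify: %d bursts", len(out))
    return out


def stage_budget(cfg: PipelineConfig, manifest: RunManifest) -> pd.DataFrame:
    p = _paths(cfg)
    cls = pd.read_csv(p["classified"], parse_dates=["start_utc"])
    series = cls.rename(columns={"start_utc": "burst_start_utc", "label_class": "label_keep"})
    series = series[["individual_id", "burst_start_utc", "label_keep", "static_pitch_deg"]]
    series = series.rename(columns={"label_keep": "label"})
    series = timebudget.apply_exclusions(series)
    series = timebudget.split_feeding_by_pitch(series)
    daily = timebudget.daily_proportions(series, min_coverage=cfg.min_daily_coverage)
    daily.to_csv(p["daily"], index=False)
    monthly = timebudget.monthly_budget(daily)
    monthly.to_csv(p["monthly"], index=False)
    series.to_csv(p["out"] / "classified_clean.csv", index=False)
    manifest.stage_counts["budget"] = {
        "bursts_retained": len(series),
        "individual_days": int(daily.groupby(["individual_id", "date_local"]).ngroups),
    }
    log.info("budget: %d bursts after exclusions", len(series))
    return daily


def stage_actogram(cfg: PipelineConfig, manifest: RunManifest) -> None:
    p = _paths(cfg)
    series = pd.read_csv(p["out"] / "classified_clean.csv", parse_dates=["burst_start_utc"])
    try:
        mats = timebudget.diel_matrix(series, cfg.actogram_year)
    except ValueError:
        log.warning("actogram: no bursts in year %d; skipped", cfg.actogram_year)
        return
    p["diel"].mkdir(exist_ok=True)
    for label, mat in mats.items():
        mat.to_csv(p["diel"] / f"diel_{label}.csv")
    timebudget.plot_actogram(mats, p["actogram"], lat=cfg.latitude, lon=cfg.longitude)
    manifest.stage_counts["actogram"] = {"classes": len(mats)}


def stage_moonlight(cfg: PipelineConfig, manifest: RunManifest) -> pd.DataFrame:
    p = _paths(cfg)
    series = pd.read_csv(p["out"] / "classified_clean.csv", parse_dates=["burst_start_utc"])
    budget = astro.midnight_hour_budget(series)
    contrast = astro.moonlight_contrast(
        budget, thresholds=(cfg.moonlit_threshold, cfg.dark_threshold)
    )
    report = {
        row["label"]: {
            "median_moonlit": row["median_moonlit"],
            "median_dark": row["median_dark"],
            "W": row["W"],
            "p": row["p"],
            "n_nights": int(row["n_moonlit"] + row["n_dark"]),
        }
        for _, row in contrast.iterrows()
    }
    p["moonlight"].write_text(json.dumps(report, indent=2))
    manifest.stage_counts["moonlight"] = {"behaviours_tested": len(report)}
    log.info("moonlight: %d behaviours tested", len(report))
    return contrast


def stage_gamhp(cfg: PipelineConfig, manifest: RunManifest) -> dict:
    p = _paths(cfg)
    daily = pd.read_csv(p["daily"])
    env = read_env_csv(p["env"])
    daily["date"] = pd.to_datetime(daily["date_local"]).dt.date
    merged = daily.merge(env, on=["individual_id", "date"], how="inner")
    merged["month"] = pd.to_datetime(merged["date_local"]).dt.month
    merged = merged.dropna(subset=["ndvi", "temp_mean_c"])
    results: dict = {}
    bar_rows = []
    for label, sub in merged.groupby("label", observed=True):
        if len(sub) < cfg.gam_min_rows or sub["individual_id"].nunique() < 2:
            log.warning("gam-hp: skipping %s (too few rows)", label)
            continue
        fit = gam.fit_gam(sub)
        hp = gam.hierarchical_partition(sub)
        conc = gam.concurvity(fit, sub)
        results[label] = {
            "explained_deviance": gam.explained_deviance(fit),
            "edf": fit.edf,
            "dispersion": fit.phi,
            "groups": {
                g: {
                    "independent": hp.independent[g],
                    "unique": hp.unique[g],
                    "shared": hp.shared[g],
                }
                for g in hp.groups
            },
            "concurvity": conc.to_dict(),
        }
        for g in hp.groups:
            bar_rows.append(
                {
                    "behaviour": label,
                    "group": g,
                    "unique": hp.unique[g],
                    "shared": hp.shared[g],
                    "independent": hp.independent[g],
                }
            )
    p["gamhp"].write_text(json.dumps(results, indent=2))
    pd.DataFrame(bar_rows).to_csv(p["gamhp_bars"], index=False)
    manifest.stage_counts["gam_hp"] = {"behaviours_fit": len(results)}
    log.info("gam-hp: fitted %d behaviours", len(results))
    return results


def run_all(cfg: PipelineConfig) -> RunManifest:
    """Run every stage in order; any stage error aborts with the stage
    named, partial outputs preserved on disk.  Fixed seed means
    bit-identical outputs and manifest checksum."""
    p = _paths(cfg)
    manifest = RunManifest(
        config=dataclasses.asdict(cfg),
        seed=cfg.seed,
        created_utc="(deterministic-run)",
    )
    stages = [
        ("simulate", stage_simulate) if cfg.simulate else None,
        ("features", stage_features),
        ("train", stage_train),
        ("classify", stage_classify),
        ("budget", stage_budget),
        ("actogram", stage_actogram),
        ("moonlight", stage_moonlight),
        ("gam-hp", stage_gamhp),
    ]
    if not cfg.simulate:
        for key in ("acc", "labels", "env"):
            if not p[key].exists():
                raise FileNotFoundError(f"required input missing before any compute: {p[key]}")
    for item in stages:
        if item is None:
            continue
        name, fn = item
        try:
            fn(cfg, manifest)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    for key in ("acc", "labels", "env"):
        if p[key].exists():
            manifest.input_checksums[key] = _sha256(p[key])
    manifest.write(p["manifest"])
    return manifest
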