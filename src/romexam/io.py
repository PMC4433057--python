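"""File formats and run configuration.

CSV dialects (all angles in degrees, full precision):

* IMU stream: ``t,gx,gy,gz,ax,ay,az`` (s, rad/s, m/s²), one file per site per
  repetition named ``S{subject}_R{rater}_{angle_id}_rep{k}_{site_id}.csv``;
* examiner sheet: ``subject,rater,angle_id,rep,rating_deg``;
* ground truth: ``subject,angle_id,true_rom_deg``;
* results sheet: ``subject,rater,angle_id,rep,measured_rom_deg,min_deg,max_deg``;
* Bland–Altman plot data: ``subject,mean_deg,diff_deg`` preceded by a
  ``#``-comment header block carrying MDiff and the limits of agreement.

The stats JSON produced by the analysis stage is described by
:data:`STATS_SCHEMA_KEYS`; a manifest echoing the configuration and seed
makes every run reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import Catalog, load_catalog
from .fusion import FilterConfig
from .kinesim import CohortSpec, IMUStream, NoiseModel

__all__ = [
    "RunConfig",
    "stream_filename",
    "write_stream_csv",
    "read_stream_csv",
    "write_sheet",
    "read_sheet",
    "write_manifest",
    "read_manifest",
    "write_stats_json",
    "read_stats_json",
    "validate_stats",
    "write_plot_data",
    "STATS_SCHEMA_KEYS",
]

EXAMINER_COLUMNS = ["subject", "rater", "angle_id", "rep", "rating_deg"]
RESULTS_COLUMNS = ["subject", "rater", "angle_id", "rep", "measured_rom_deg", "min_deg", "max_deg"]
GROUND_TRUTH_COLUMNS = ["subject", "angle_id", "true_rom_deg"]

STATS_SCHEMA_KEYS = {
    "angle": ("n", "n_dropped", "repeatability", "icc", "bland_altman", "validity"),
    "icc": ("icc_3k", "bms", "jms", "ems", "n", "k", "acceptable", "undefined"),
    "bland_altman": ("pair", "mdiff", "sd_diff", "loa_low", "loa_high", "mdiff_acceptable"),
}


@dataclass
class RunConfig:
    """One reproducible four-stage run (simulate → process → analyze → report)."""

    output_dir: Path
    seed: int = 0
    catalog_path: Path | None = None
    cohort: CohortSpec = field(default_factory=CohortSpec)
    noise: NoiseModel = field(default_factory=NoiseModel)
    filter: FilterConfig = field(default_factory=FilterConfig)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        run_seed = int(seed if seed is not None else raw.get("seed", 0))
        cohort_kw = dict(raw.get("cohort", {}))
        if "angle_ids" in cohort_kw and cohort_kw["angle_ids"] is not None:
            cohort_kw["angle_ids"] = tuple(cohort_kw["angle_ids"])
        for key in ("rater_bias", "rater_sd"):
            if key in cohort_kw and isinstance(cohort_kw[key], list):
                cohort_kw[key] = tuple(cohort_kw[key])
        cohort_kw["seed"] = run_seed
        noise_kw = dict(raw.get("noise", {}))
        if isinstance(noise_kw.get("gyro_bias"), list):
            noise_kw["gyro_bias"] = tuple(noise_kw["gyro_bias"])
        noise_kw["seed"] = run_seed
        cat = raw.get("catalog_path")
        out = raw.get("output_dir")
        if out is None:
            raise ValueError(f"config {path} must set output_dir")
        return cls(
            output_dir=Path(out),
            seed=run_seed,
            catalog_path=None if cat is None else Path(cat),
            cohort=CohortSpec(**cohort_kw),
            noise=NoiseModel(**noise_kw),
            filter=FilterConfig(**dict(raw.get("filter", {}))),
            log_level=str(raw.get("log_level", "INFO")),
        )

    def load_catalog(self) -> Catalog:
        return load_catalog(self.catalog_path)

    def to_dict(self) -> dict:
        d = {
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "catalog_path": None if self.catalog_path is None else str(self.catalog_path),
            "cohort": dataclasses.asdict(self.cohort),
            "noise": dataclasses.asdict(self.noise),
            "filter": dataclasses.asdict(self.filter),
            "log_level": self.log_level,
        }
        if d["cohort"]["angle_ids"] is not None:
            d["cohort"]["angle_ids"] = list(d["cohort"]["angle_ids"])
        for key in ("rater_bias", "rater_sd"):
            if isinstance(d["cohort"][key], tuple):
                d["cohort"][key] = list(d["cohort"][key])
        if d["cohort"]["true_rom_mean"] is not None:
            d["cohort"]["true_rom_mean"] = dict(d["cohort"]["true_rom_mean"])
        if isinstance(d["cohort"]["true_rom_sd"], dict):
            d["cohort"]["true_rom_sd"] = dict(d["cohort"]["true_rom_sd"])
        if isinstance(d["noise"]["gyro_bias"], tuple):
            d["noise"]["gyro_bias"] = list(d["noise"]["gyro_bias"])
        return d


def stream_filename(subject: int, rater: int, angle_id: str, rep: int, site_id: str) -> str:
    return f"S{subject}_R{rater}_{angle_id}_rep{rep}_{site_id}.csv"


def write_stream_csv(stream: IMUStream, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "t": stream.t,
            "gx": stream.omega[:, 0],
            "gy": stream.omega[:, 1],
            "gz": stream.omega[:, 2],
            "ax": stream.accel[:, 0],
            "ay": stream.accel[:, 1],
            "az": stream.accel[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_stream_csv(path: str | Path, site_id: str | None = None) -> IMUStream:
    path = Path(path)
    df = pd.read_csv(path)
    expected = ["t", "gx", "gy", "gz", "ax", "ay", "az"]
    if list(df.columns) != expected:
        raise ValueError(f"stream file {path} must have columns {expected}")
    t = df["t"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"stream file {path} holds fewer than 2 samples")
    rate = 1.0 / float(np.mean(np.diff(t)))
    if site_id is None:
        site_id = path.stem.rsplit("_", 1)[-1]
        # site ids may themselves contain underscores; recover from pattern
        parts = path.stem.split("_rep")
        if len(parts) == 2 and "_" in parts[1]:
            site_id = parts[1].split("_", 1)[1]
    return IMUStream(
        site_id=site_id,
        t=t,
        omega=df[["gx", "gy", "gz"]].to_numpy(),
        accel=df[["ax", "ay", "az"]].to_numpy(),
        sampling_rate=rate,
    )


def write_sheet(df: pd.DataFrame, path: str | Path, columns: list[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"sheet is missing columns {missing}")
    df[columns].to_csv(path, index=False, float_format="%.9g")


def read_sheet(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sheet not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"sheet {path} is missing columns {missing}")
    return df


def write_manifest(config: RunConfig, angle_ids, path: str | Path) -> None:
    payload = {
        "format": "romexam-run-manifest",
        "version": 1,
        "config": config.to_dict(),
        "angle_ids": list(angle_ids),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path} (run 'simulate' first)")
    payload = json.loads(path.read_text())
    if payload.get("format") != "romexam-run-manifest":
        raise ValueError(f"{path} is not a run manifest")
    return payload


def validate_stats(stats: dict) -> None:
    """Check the stats JSON against the published key schema."""
    if not isinstance(stats, dict) or "angles" not in stats:
        raise ValueError("stats JSON must contain an 'angles' mapping")
    if not stats["angles"]:
        raise ValueError("stats JSON holds no angles")
    for aid, entry in stats["angles"].items():
        for key in STATS_SCHEMA_KEYS["angle"]:
            if key not in entry:
                raise ValueError(f"stats for {aid} missing key {key!r}")
        for source, icc in entry["icc"].items():
            for key in STATS_SCHEMA_KEYS["icc"]:
                if key not in icc:
                    raise ValueError(f"ICC entry {aid}/{source} missing key {key!r}")
        for ba in entry["bland_altman"]:
            for key in STATS_SCHEMA_KEYS["bland_altman"]:
                if key not in ba:
                    raise ValueError(f"Bland-Altman entry of {aid} missing key {key!r}")


def write_stats_json(stats: dict, path: str | Path) -> None:
    validate_stats(stats)
    Path(path).write_text(json.dumps(stats, indent=2, sort_keys=True) + "\n")


def read_stats_json(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stats file not found: {path}")
    stats = json.loads(path.read_text())
    validate_stats(stats)
    return stats


def write_plot_data(ba, path: str | Path) -> None:
    """Bland–Altman plot data CSV with a metadata header block."""
    header = (
        f"# angle_id={ba.angle_id}\n"
        f"# pair={ba.rater_pair[0]}-{ba.rater_pair[1]}\n"
        f"# mdiff={ba.mdiff:.9g}\n"
        f"# loa_low={ba.loa_low:.9g}\n"
        f"# loa_high={ba.loa_high:.9g}\n"
    )
    body = ba.points.to_csv(index=False, float_format="%.9g")
    Path(path).write_text(header + body)
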