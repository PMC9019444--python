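"""Pipeline orchestration, Table-style reporting and STA summaries.

``run_pipeline`` chains the whole analysis — simulate (or ingest) →
filter/notch → wavelet decomposition → windowed features → channel x band
classification sweep → report — writing delimited tables and a manifest
under an output directory, deterministically for a fixed global seed.
"""

from __future__ import annotations

import hashlib
import json
import os
import sys
import time
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import io as eio
from .classify import SUBSET_NAMES, ClassifierSpec, channel_band_sweep
from .features import extract_features
from .signals import FilterSpec, dwt_band_decompose, preprocess
from .simulate import STARecord, SimulationConfig, iter_cohort_recordings, \
    simulate_sta_cohort

__all__ = [
    "CHANNEL_REGIONS",
    "STASummary",
    "PipelineConfig",
    "sta_deviation",
    "make_report",
    "run_pipeline",
]

#: Scalp regions of the 14-electrode montage.
CHANNEL_REGIONS = {
    "central": ("C3", "C4"),
    "frontal": ("F3", "F4", "F7", "F8", "FP1", "FP2"),
    "parietal": ("P3", "P4"),
    "temporal": ("T3", "T4", "T5", "T6"),
}


@dataclass(frozen=True)
class STASummary:
    """Per-group anxiety-score summary.

    ``groups`` maps group name to a dict with the pre-score range
    (sta1_min/max), post-score range (sta2_min/max), the sample SD (ddof 1)
    of the paired pre-minus-post differences, their mean, and n.
    """

    groups: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"group": g, **v} for g, v in self.groups.items()]
        )


def sta_deviation(records) -> STASummary:
    """Group-wise STA score ranges and paired-difference deviation.

    Groups with fewer than 2 records are omitted with a warning (an SD of a
    single pair is undefined).
    """
    by_group = {}
    for r in records:
        by_group.setdefault(r.group, []).append(r)
    out = {}
    for group, rs in by_group.items():
        if len(rs) < 2:
            warnings.warn(
                f"group {group!r} has {len(rs)} record(s); omitted from the "
                f"STA summary"
            )
            continue
        sta1 = np.array([r.sta1 for r in rs])
        sta2 = np.array([r.sta2 for r in rs])
        diff = sta1 - sta2
        out[group] = {
            "n": len(rs),
            "sta1_min": float(sta1.min()), "sta1_max": float(sta1.max()),
            "sta2_min": float(sta2.min()), "sta2_max": float(sta2.max()),
            "diff_mean": float(diff.mean()),
            "diff_sd": float(diff.std(ddof=1)),
        }
    return STASummary(groups=out)


def _collapse_channels(filtered: pd.DataFrame) -> pd.DataFrame:
    """Display form: channels with identical (subset, intervention, band,
    rounded accuracy) collapse into one comma-joined row."""
    if filtered.empty:
        return pd.DataFrame(
            columns=["subset", "intervention", "band", "channels",
                     "accuracy", "sensitivity", "specificity"]
        )
    grouped = (
        filtered
        .groupby(["subset", "intervention", "band", "accuracy_2dp"],
                 as_index=False)
        .agg(
            channels=("channel", lambda s: ", ".join(sorted(s))),
            sensitivity=("sensitivity", "mean"),
            specificity=("specificity", "mean"),
        )
        .rename(columns={"accuracy_2dp": "accuracy"})
    )
    return grouped[["subset", "intervention", "band", "channels",
                    "accuracy", "sensitivity", "specificity"]]


def make_report(sweep: pd.DataFrame, sta: STASummary, threshold: float = 70.0,
                out_dir=".", features: pd.DataFrame = None, plots: bool = False):
    """Write the full sweep, the threshold-filtered display table, and the
    STA summary; optionally per-region box plots of the activity feature.

    The filtered table keeps cells whose accuracy, rounded to 2 decimals,
    is >= threshold (the conventional acceptability cut of 70%).
    Returns a dict of written paths.
    """
    if sweep.empty:
        raise ValueError("sweep table is empty")
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    full_path = os.path.join(out_dir, "sweep_full.csv")
    sweep.to_csv(full_path, index=False)
    paths["full"] = full_path

    scored = sweep[sweep["accuracy"].notna()].copy()
    scored["accuracy_2dp"] = scored["accuracy"].round(2)
    filtered = scored[scored["accuracy_2dp"] >= threshold]
    display = _collapse_channels(filtered)
    filt_path = os.path.join(out_dir, "sweep_accepted.csv")
    display.to_csv(filt_path, index=False)
    paths["filtered"] = filt_path

    sta_path = os.path.join(out_dir, "sta_summary.csv")
    sta.to_frame().to_csv(sta_path, index=False)
    paths["sta"] = sta_path

    if plots and features is not None:
        paths["plots"] = _region_boxplots(features, out_dir)
    return paths


def _region_boxplots(features: pd.DataFrame, out_dir):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for region, chans in CHANNEL_REGIONS.items():
        sub = features[features["channel"].isin(chans)]
        if sub.empty:
            continue
        fig, ax = plt.subplots(figsize=(7, 4))
        data, labels = [], []
        for band in ("delta", "theta", "alpha", "beta", "gamma"):
            vals = sub.loc[sub["band"] == band, "activity"]
            if len(vals):
                data.append(np.log10(vals + 1e-12))
                labels.append(band)
        ax.boxplot(data, tick_labels=labels)
        ax.set_ylabel("log10 activity (uV^2)")
        ax.set_title(f"{region} region ({', '.join(chans)})")
        path = os.path.join(out_dir, f"activity_{region}.png")
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written


@dataclass
class PipelineConfig:
    """End-to-end settings; every stage seed derives from ``seed``."""

    out_dir: str = "results"
    sim: SimulationConfig = None
    input_dir: str = None  # ingest pre-existing recordings instead
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    wavelet: str = "db7"
    levels: int = 5
    window_s: float = 30.0
    alpha: float = 0.05
    clf: ClassifierSpec = None
    subset_names: tuple = SUBSET_NAMES
    interventions: tuple = None
    threshold: float = 70.0
    seed: int = 0
    write_recordings: bool = False
    write_band_series: bool = False
    plots: bool = False

    def __post_init__(self):
        if self.sim is None and self.input_dir is None:
            self.sim = SimulationConfig(seed=self.seed)
        if self.clf is None:
            self.clf = ClassifierSpec(seed=self.seed)
        if self.interventions is None:
            conds = self.sim.conditions if self.sim else ("baseline", "MI-1",
                                                          "MI-2", "MI-3", "MI-4")
            self.interventions = tuple(c for c in conds if c != "baseline")


def _jsonable(o):
    if isinstance(o, dict):
        return {str(k): _jsonable(v) for k, v in o.items()}
    if isinstance(o, (list, tuple, set)):
        return [_jsonable(v) for v in o]
    if isinstance(o, (str, int, float, bool)) or o is None:
        return o
    if hasattr(o, "__dict__"):
        return _jsonable(vars(o))
    return str(o)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_jsonable(asdict(config)), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_recordings(input_dir):
    manifest = pd.read_csv(os.path.join(input_dir, "manifest.csv"))
    sta_records = []
    seen = set()
    for row in manifest.itertuples():
        if row.subject_id not in seen and np.isfinite(row.sta1):
            sta_records.append(
                STARecord(row.subject_id, row.group,
                          float(row.sta1), float(row.sta2))
            )
            seen.add(row.subject_id)
    def gen():
        for row in manifest.itertuples():
            path = os.path.join(input_dir, row.file)
            if path.lower().endswith(".edf"):
                yield eio.read_recording_edf(
                    path, row.subject_id, row.group, row.condition
                )
            else:
                yield eio.read_recording_txt(path)
    return gen(), sta_records


def run_pipeline(config: PipelineConfig):
    """Simulate/ingest → preprocess → decompose → features → sweep → report.

    Writes features, sweep tables, STA summary and a manifest (config hash,
    seed, package versions, per-stage timings) under ``config.out_dir``;
    returns the dict of written paths.  A stage failure aborts with the
    stage and offending recording named.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    timings = {}
    t0 = time.time()

    if config.input_dir is not None:
        recordings, sta_records = _load_recordings(config.input_dir)
    else:
        recordings = iter_cohort_recordings(config.sim)
        sta_records = simulate_sta_cohort(config.sim)
    timings["setup"] = time.time() - t0

    tables = []
    rec_dir = os.path.join(config.out_dir, "recordings")
    t0 = time.time()
    for rec in recordings:
        tag = f"{rec.subject_id}/{rec.condition}"
        try:
            if config.write_recordings:
                os.makedirs(rec_dir, exist_ok=True)
                eio.write_recording_txt(
                    rec, os.path.join(rec_dir, eio.recording_filename(rec))
                )
            clean = preprocess(rec, config.filter_spec)
            bands = dwt_band_decompose(clean, config.wavelet, config.levels)
            if config.write_band_series:
                _write_band_series(bands, config.out_dir)
            tables.append(extract_features(bands, config.window_s))
        except Exception as e:
            raise RuntimeError(
                f"pipeline failed at recording {tag}: {e}"
            ) from e
    features = pd.concat(tables, ignore_index=True)
    feat_path = os.path.join(config.out_dir, "features.csv")
    eio.write_feature_table(features, feat_path)
    timings["features"] = time.time() - t0

    t0 = time.time()
    sweep = channel_band_sweep(
        features,
        subset_names=config.subset_names,
        interventions=config.interventions,
        clf_spec=config.clf,
        alpha=config.alpha,
    )
    timings["sweep"] = time.time() - t0

    t0 = time.time()
    sta = sta_deviation(sta_records)
    paths = make_report(sweep, sta, config.threshold, config.out_dir,
                        features=features, plots=config.plots)
    paths["features"] = feat_path
    timings["report"] = time.time() - t0

    import sklearn
    import scipy
    import pywt
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "pywavelets": pywt.__version__,
        },
        "n_feature_rows": int(len(features)),
        "n_sweep_rows": int(len(sweep)),
    }
    man_path = os.path.join(config.out_dir, "run_manifest.json")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    paths["manifest"] = man_path
    print(
        f"[eegstress] features={len(features)} rows, sweep={len(sweep)} cells "
        f"-> {config.out_dir}", file=sys.stderr,
    )
    return paths


def _write_band_series(bands, out_dir):
    bdir = os.path.join(out_dir, "bands")
    os.makedirs(bdir, exist_ok=True)
    rows = []
    for ch in bands.channel_names:
        for band in bands.bands:
            y = bands.series[ch][band]
            rows.append(pd.DataFrame({
                "channel": ch, "band": band,
                "sample_index": np.arange(len(y)), "value": y,
            }))
    path = os.path.join(
        bdir, f"{bands.subject_id}_{bands.condition}_bands.csv"
    )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    return path
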