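"""End-to-end orchestration: log -> sequences -> spectra -> variability ->
dual k-means clustering -> explained-variance tables and habit report.

Observation windows are grouped by their window label (a single ``session``
group, or morning/afternoon/night phases), and each group is clustered
separately on one or both feature sets:

* ``raw`` — the 200-frame behavioral spectra, clustered as-is;
* ``variability`` — the five-feature summaries, z-scored before clustering
  (their scales differ by orders of magnitude), with explained variance
  reported on the original features for comparability with the raw route.

All artifacts are plain CSV plus a JSON run manifest recording the
configuration, seed and package version; a rerun with the same manifest is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .activity import (
    DEFAULT_PHASE_WINDOWS,
    ActivityEvent,
    ActivityRegistry,
    HabitSequence,
    PhaseWindows,
    extract_sequences,
    load_registry,
    read_activity_log,
)
from .clustering import (
    ClusterModel,
    ElbowCurve,
    elbow_curve,
    explained_variance_from_labels,
    kmeans_cluster,
    standardize_features,
)
from .spectrum import SignalConfig, behavioral_spectrum, spectra_matrix
from .variability import variability_table

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "sequences_from_log"]


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    log_path: str
    registry_path: str
    out_dir: str
    signal: SignalConfig = SignalConfig()
    delay_k: int = 1
    entropy_mode: str = "normalized"
    ev_mode: str = "uncentered"
    k_min: int = 1
    k_max: int = 12
    restarts: int = 50
    seed: int = 0
    session_mode: bool = True
    phase_windows: PhaseWindows = DEFAULT_PHASE_WINDOWS
    feature_set: str = "both"  # raw | variability | both

    def __post_init__(self) -> None:
        if self.feature_set not in ("raw", "variability", "both"):
            raise ValueError("feature_set must be 'raw', 'variability' or 'both'")
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("need 1 <= k_min <= k_max")


@dataclass
class PipelineResult:
    """In-memory view of one run's artifacts."""

    sequences: list[HabitSequence]
    spectra: pd.DataFrame  # one row per sequence, frame columns + metadata
    variability: pd.DataFrame  # Table-style five-feature summary
    explained: dict[str, pd.DataFrame]  # window label -> EV table (rows k)
    clusters: dict[tuple[str, str], pd.DataFrame]  # (window, feature set) -> report
    suggested_k: dict[tuple[str, str], int]
    manifest: dict


def sequences_from_log(
    log_path: str,
    registry: ActivityRegistry,
    session_mode: bool = True,
    phase_windows: PhaseWindows = DEFAULT_PHASE_WINDOWS,
) -> list[HabitSequence]:
    events = read_activity_log(log_path, registry)
    return extract_sequences(
        events, windows=None if session_mode else phase_windows, session_mode=session_mode
    )


def _spectra_frame(sequences: Sequence[HabitSequence], signal: SignalConfig) -> pd.DataFrame:
    X = spectra_matrix(sequences, signal)
    cols = [f"frame_{i + 1:03d}" for i in range(signal.n_frames)]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "subject", [s.subject for s in sequences])
    df.insert(1, "date", [s.date.isoformat() if s.date else "" for s in sequences])
    df.insert(2, "window", [s.window_label for s in sequences])
    return df

def _feature_sets(config: RunConfig) -> list[str]:
    return ["raw", "variability"] if config.feature_set == "both" else [config.feature_set]


def _cluster_group(
    config: RunConfig,
    label: str,
    sequences: list[HabitSequence],
    raw: np.ndarray,
    var: np.ndarray,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], dict[str, int]]:
    """Elbow sweep and final clustering for one window group."""
    n_distinct = min(
        np.unique(raw, axis=0).shape[0], np.unique(var, axis=0).shape[0]
    )
    if config.k_min > n_distinct:
        raise PipelineError(
            f"window {label!r}: k_min={config.k_min} exceeds {n_distinct} distinct observations"
        )
    k_max = min(config.k_max, n_distinct)
    ev_table: dict[str, list[float]] = {}
    reports: dict[str, pd.DataFrame] = {}
    suggested: dict[str, int] = {}
    obs = [s.key for s in sequences]
    for feat in _feature_sets(config):
        if feat == "raw":
            X_fit = X_score = raw
        else:
            X_fit, transform = standardize_features(var)
            # score on per-feature-scaled (not centred) features: same cluster
            # geometry as the z-scored fit, but the ratio keeps the mean term,
            # so it is positive at k = 1 and comparable with the raw route
            safe = np.where(transform.scale == 0, 1.0, transform.scale)
            X_score = var / safe
        curve = elbow_curve(
            X_fit, k_max, restarts=config.restarts, seed=config.seed, keep_models=True
        )
        ev_table[feat] = [
            explained_variance_from_labels(X_score, m.assignments, mode=config.ev_mode)
            for m in curve.models
        ]
        suggested[feat] = curve.suggested_k
        final = curve.models[curve.suggested_k - 1]
        reports[feat] = pd.DataFrame(
            {"observation": obs, "window": label, "cluster": final.assignments}
        )
    table = pd.DataFrame(ev_table, index=pd.Index(range(1, k_max + 1), name="k"))
    table = table.loc[config.k_min : k_max]
    return table, reports, suggested


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full habit-assessment pipeline and write all artifacts.

    Raises :class:`PipelineError` (before writing anything) when fewer than
    two sequences can be extracted or the requested k range is infeasible.
    """
    registry = load_registry(config.registry_path)
    sequences = sequences_from_log(
        config.log_path, registry, config.session_mode, config.phase_windows
    )
    if len(sequences) < 2:
        raise PipelineError(
            f"only {len(sequences)} sequence(s) extracted; need >= 2 "
            "(check --session-mode / phase windows)"
        )
    spectra_df = _spectra_frame(sequences, config.signal)
    spectra = [behavioral_spectrum(s, config.signal) for s in sequences]
    var_df = variability_table(
        spectra, delay_k=config.delay_k, entropy_mode=config.entropy_mode
    )

    groups: dict[str, list[int]] = {}
    for i, s in enumerate(sequences):
        groups.setdefault(s.window_label, []).append(i)

    explained: dict[str, pd.DataFrame] = {}
    clusters: dict[tuple[str, str], pd.DataFrame] = {}
    suggested_k: dict[tuple[str, str], int] = {}
    raw_all = spectra_df.filter(like="frame_").to_numpy()
    var_all = var_df.to_numpy()
    for label, idx in sorted(groups.items()):
        if len(idx) < 2:
            raise PipelineError(f"window {label!r} has fewer than 2 sequences")
        seqs = [sequences[i] for i in idx]
        table, reports, sugg = _cluster_group(
            config, label, seqs, raw_all[idx], var_all[idx]
        )
        explained[label] = table
        for feat, rep in reports.items():
            clusters[(label, feat)] = rep
            suggested_k[(label, feat)] = sugg[feat]

    manifest = {
        "package": "habitspectrum",
        "version": __version__,
        "seed": config.seed,
        "config": _jsonable(config),
        "n_sequences": len(sequences),
        "windows": {label: len(idx) for label, idx in sorted(groups.items())},
        "suggested_k": {f"{w}/{f}": k for (w, f), k in sorted(suggested_k.items())},
    }

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spectra_df.to_csv(out / "spectra.csv", index=False)
    var_df.to_csv(out / "variability.csv")
    for label, table in explained.items():
        table.to_csv(out / f"explained_variance_{label}.csv")
    for (label, feat), rep in clusters.items():
        rep.to_csv(out / f"clusters_{label}_{feat}.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        sequences=sequences,
        spectra=spectra_df,
        variability=var_df,
        explained=explained,
        clusters=clusters,
        suggested_k=suggested_k,
        manifest=manifest,
    )


def _jsonable(config: RunConfig) -> dict:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (_dt.date, _dt.time)):
            return o.isoformat()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    return json.loads(json.dumps(dataclasses.asdict(config), default=default))
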