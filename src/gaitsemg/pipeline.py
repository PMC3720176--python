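"""Study-level orchestration: simulate, process, compare.

File formats
------------
signals
    Wide delimited text, first column ``time_s`` then one column per muscle
    (microvolts), plus a JSON sidecar carrying sampling rate and labels.
events
    JSON with ``heel_strikes`` and ``toe_offs`` (arrays of seconds) and
    ``source_rate_hz``.
reference curves
    Two-column delimited text (percent of phase, amplitude), one file per
    muscle x phase named ``<muscle>_<phase>.csv``.
outputs
    Delimited tables; every output directory carries a JSON run manifest
    (config hash, seed, software version) so results are traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .envelope import MUSCLES, EmgRecording, linear_envelope
from .gait import (
    GaitEventSeries,
    build_strides,
    select_middle_strides,
    summarize_phase_distribution,
)
from .stats import (
    DegenerateDataError,
    mann_whitney_u,
    compare_conditions,
    shapiro_wilk,
    spearman_similarity,
)
from .synthetic import SimulationConfig, simulate_subject
from .trajectory import (
    ensemble_average,
    group_average,
    phase_mean_amplitude,
    resample_reference,
    stride_curves,
)

logger = logging.getLogger("gaitsemg")

FLOAT_FMT = "%.6f"


# ---------------------------------------------------------------------------
# layout and manifest
# ---------------------------------------------------------------------------


@dataclass
class StudyLayout:
    """A study directory: one signal + events file per subject x condition."""

    root: Path
    metadata: pd.DataFrame

    @classmethod
    def load(cls, root) -> "StudyLayout":
        root = Path(root)
        meta_path = root / "metadata.csv"
        if not meta_path.exists():
            raise FileNotFoundError(f"no metadata.csv under {root}")
        metadata = pd.read_csv(meta_path)
        for col in ("signal_file", "events_file"):
            for rel in metadata[col]:
                if not (root / rel).exists():
                    raise FileNotFoundError(f"missing file {rel} referenced by metadata")
        return cls(root=root, metadata=metadata)


@dataclass
class RunManifest:
    """Reproducibility record attached to every output directory."""

    config_hash: str
    seed: int
    version: str = __version__
    created_utc: str = ""
    input_checksums: dict[str, str] = field(default_factory=dict)

    def write(self, path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "created_utc": self.created_utc or datetime.now(timezone.utc).isoformat(),
            "input_checksums": self.input_checksums,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def write_signal(base: Path, recordings: dict[str, EmgRecording], seed: int) -> None:
    first = next(iter(recordings.values()))
    t = first.times
    cols = [t] + [recordings[m].samples for m in MUSCLES]
    table = np.column_stack(cols)
    header = ",".join(["time_s", *MUSCLES])
    np.savetxt(base.with_suffix(".csv"), table, delimiter=",", header=header,
               comments="", fmt=["%.6f"] + ["%.4f"] * len(MUSCLES))
    sidecar = {
        "fs_hz": first.fs,
        "subject": first.subject,
        "group": first.group,
        "condition": first.condition,
        "leg": first.leg,
        "muscle_columns": {m: i + 1 for i, m in enumerate(MUSCLES)},
        "units": "uV",
        "seed": seed,
        "source": "synthetic",
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_signal(csv_path, sidecar_path) -> dict[str, EmgRecording]:
    meta = json.loads(Path(sidecar_path).read_text())
    frame = pd.read_csv(csv_path)
    fs = float(meta["fs_hz"])
    return {
        m: EmgRecording(
            samples=frame[m].to_numpy(), fs=fs, muscle=m,
            subject=meta.get("subject", ""), group=meta.get("group", ""),
            condition=meta.get("condition", ""), leg=meta.get("leg", ""),
        )
        for m in meta["muscle_columns"]
    }


def write_events(path, events: GaitEventSeries) -> None:
    Path(path).write_text(json.dumps({
        "heel_strikes": [round(float(t), 6) for t in events.heel_strikes],
        "toe_offs": [round(float(t), 6) for t in events.toe_offs],
        "source_rate_hz": events.source_rate,
    }, indent=2))


def read_events(path) -> GaitEventSeries:
    data = json.loads(Path(path).read_text())
    return GaitEventSeries(
        heel_strikes=np.asarray(data["heel_strikes"], dtype=float),
        toe_offs=np.asarray(data["toe_offs"], dtype=float),
        source_rate=data.get("source_rate_hz"),
    )


def read_reference_curve(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (percent, amplitude) delimited text file."""
    frame = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (percent, amplitude)")
    # tolerate a header row of labels
    try:
        float(frame.iloc[0, 0])
    except (TypeError, ValueError):
        frame = frame.iloc[1:]
    pct = frame.iloc[:, 0].astype(float).to_numpy()
    amp = frame.iloc[:, 1].astype(float).to_numpy()
    return pct, amp


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def write_cohort(config: SimulationConfig, out_dir) -> StudyLayout:
    """Simulate every subject x condition and write the study directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seq = np.random.SeedSequence(config.seed)
    meta_rows: list[dict] = []
    truth_rows: list[dict] = []
    jobs = [
        (group, f"{group}{i + 1:02d}", condition)
        for group, n in config.n_subjects.items()
        for i in range(n)
        for condition in config.conditions
    ]
    for child, (group, subject, condition) in zip(seq.spawn(max(len(jobs), 1)), jobs):
        rng = np.random.default_rng(child)
        recordings, events, truth = simulate_subject(
            config, group, condition, subject, rng
        )
        base = out / f"{subject}_{condition}_emg"
        write_signal(base, recordings, config.seed)
        events_file = out / f"{subject}_{condition}_events.json"
        write_events(events_file, events)
        logger.info("simulated %s/%s/%s: %d strides", group, subject, condition,
                    truth.stride_durations.size)
        meta_rows.append({
            "subject": subject, "group": group, "condition": condition,
            "signal_file": base.with_suffix(".csv").name,
            "sidecar_file": base.with_suffix(".json").name,
            "events_file": events_file.name,
            "fs_hz": config.fs_emg,
        })
        for idx in range(truth.stride_durations.size):
            truth_rows.append({
                "subject": subject, "group": group, "condition": condition,
                "stride_index": idx,
                "duration_s": truth.stride_durations[idx],
                "stance_fraction": truth.stride_stance_fractions[idx],
                "subject_stance_fraction": truth.subject_stance_fraction,
                "hs_exact_s": truth.heel_strikes_exact[idx],
                "to_exact_s": truth.toe_offs_exact[idx],
            })
    meta_cols = ["subject", "group", "condition", "signal_file", "sidecar_file",
                 "events_file", "fs_hz"]
    truth_cols = ["subject", "group", "condition", "stride_index", "duration_s",
                  "stance_fraction", "subject_stance_fraction", "hs_exact_s",
                  "to_exact_s"]
    metadata = pd.DataFrame(meta_rows, columns=meta_cols)
    metadata.to_csv(out / "metadata.csv", index=False)
    pd.DataFrame(truth_rows, columns=truth_cols).to_csv(
        out / "ground_truth.csv", index=False, float_format=FLOAT_FMT
    )
    (out / "templates.json").write_text(json.dumps(
        {cond: {m: tpl.model_dump() for m, tpl in tpls.items()}
         for cond, tpls in config.templates.items()},
        indent=2, sort_keys=True,
    ))
    checksums = {p.name: _checksum(p) for p in sorted(out.glob("*.csv"))}
    RunManifest(
        config_hash=_hash_obj(config.model_dump(mode="json")),
        seed=config.seed, input_checksums=checksums,
    ).write(out / "manifest.json")
    return StudyLayout(root=out, metadata=metadata)


def cmd_simulate(config_path, out_dir, seed: int | None = None) -> StudyLayout:
    """Load and validate a JSON config (defaults if None), then simulate."""
    if config_path is None:
        config = SimulationConfig()
    else:
        config = SimulationConfig.from_json(config_path)
    if seed is not None:
        config = config.model_copy(update={"seed": seed})
    return write_cohort(config, out_dir)


# ---------------------------------------------------------------------------
# process
# ---------------------------------------------------------------------------


def cmd_process(layout_root, out_dir, k_strides: int = 20) -> dict:
    """Run the per-subject chain over a study directory and write tables.

    For every subject x condition x muscle: linear envelope, the k
    mid-recording strides, cycle/stance/swing normalized curves, subject
    ensembles, phase-mean amplitudes, and stance/swing percentages. Failures
    are logged and skipped; the returned summary lists them.
    """
    layout = StudyLayout.load(layout_root)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stance_rows, amp_rows, curve_rows = [], [], []
    subject_ensembles: dict[tuple, list] = {}
    failures: list[str] = []
    for (subject, group, condition), rows in layout.metadata.groupby(
        ["subject", "group", "condition"], sort=True
    ):
        row = rows.iloc[0]
        key = f"{subject}/{condition}"
        try:
            recs = read_signal(layout.root / row["signal_file"],
                               layout.root / row["sidecar_file"])
            events = read_events(layout.root / row["events_file"])
            strides = build_strides(events)
            duration = next(iter(recs.values())).duration_s
            chosen = select_middle_strides(strides, k=k_strides,
                                           recording_span=(0.0, duration))
            if len(chosen) < k_strides:
                logger.warning("%s: only %d of %d strides available", key,
                               len(chosen), k_strides)
            mean_st, sd_st, mean_sw = summarize_phase_distribution(chosen)
            stance_rows.append({
                "subject": subject, "group": group, "condition": condition,
                "n_strides": len(chosen), "stance_pct_mean": mean_st,
                "stance_pct_sd": sd_st, "swing_pct_mean": mean_sw,
            })
            for muscle, rec in recs.items():
                env = linear_envelope(rec)
                per_phase = {"cycle": [], "stance": [], "swing": []}
                amps = []
                for stride in chosen:
                    cyc, sta, swi = stride_curves(env, stride)
                    per_phase["cycle"].append(cyc)
                    per_phase["stance"].append(sta)
                    per_phase["swing"].append(swi)
                    amps.append(phase_mean_amplitude(env, stride))
                amp_rows.append({
                    "subject": subject, "group": group, "condition": condition,
                    "muscle": muscle,
                    "stance_mean_uv": float(np.mean([a.stance_mean for a in amps])),
                    "swing_mean_uv": float(np.mean([a.swing_mean for a in amps])),
                })
                for phase, curves in per_phase.items():
                    ens = ensemble_average(curves, level="subject")
                    subject_ensembles.setdefault(
                        (group, condition, muscle, phase), []
                    ).append(ens)
                    for k, (m, s) in enumerate(zip(ens.mean, ens.sd)):
                        curve_rows.append({
                            "subject": subject, "group": group,
                            "condition": condition, "muscle": muscle,
                            "phase": phase, "point": k, "mean_uv": m,
                            "sd_uv": s, "n_strides": ens.n,
                        })
            logger.info("processed %s: %d strides used", key, len(chosen))
        except Exception as exc:  # per-file isolation
            logger.error("failed %s: %s", key, exc)
            failures.append(f"{key}: {exc}")
    group_rows = []
    for (group, condition, muscle, phase), ensembles in sorted(subject_ensembles.items()):
        grp = group_average(ensembles)
        for k, (m, s) in enumerate(zip(grp.mean, grp.sd)):
            group_rows.append({
                "group": group, "condition": condition, "muscle": muscle,
                "phase": phase, "point": k, "mean_uv": m, "sd_uv": s,
                "n_subjects": grp.n,
            })
    pd.DataFrame(stance_rows).to_csv(out / "stance_summary.csv", index=False,
                                     float_format=FLOAT_FMT)
    pd.DataFrame(amp_rows).to_csv(out / "phase_amplitudes.csv", index=False,
                                  float_format=FLOAT_FMT)
    pd.DataFrame(curve_rows).to_csv(out / "subject_curves.csv", index=False,
                                    float_format=FLOAT_FMT)
    pd.DataFrame(group_rows).to_csv(out / "group_curves.csv", index=False,
                                    float_format=FLOAT_FMT)
    checksums = {p.name: _checksum(p) for p in sorted(Path(layout_root).glob("*.csv"))}
    RunManifest(config_hash=_hash_obj({"layout": str(layout_root),
                                       "k_strides": k_strides}),
                seed=-1, input_checksums=checksums).write(out / "manifest.json")
    return {"n_processed": len(stance_rows), "failures": failures}


# ---------------------------------------------------------------------------
# compare
# ---------------------------------------------------------------------------


def _complete_pivot(frame: pd.DataFrame, value: str, conditions: list[str]
                    ) -> tuple[np.ndarray, list[str]]:
    """Subjects x conditions matrix, dropping subjects with missing cells."""
    pivot = frame.pivot_table(index="subject", columns="condition",
                              values=value, aggfunc="first")
    pivot = pivot.reindex(columns=conditions).dropna()
    return pivot.to_numpy(), list(pivot.index)


def cmd_compare(processed_dir, out_dir, reference_dir=None,
                alpha: float = 0.05) -> dict:
    """Statistical comparison tables from processed outputs.

    Emits (i) stance/swing phase-distribution comparisons within and
    between groups, (ii) amplitude comparisons and curve similarities per
    muscle, and (iii) a reference-similarity matrix when digitized
    reference trajectories are supplied.
    """
    processed = Path(processed_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stance = pd.read_csv(processed / "stance_summary.csv")
    amps = pd.read_csv(processed / "phase_amplitudes.csv")
    curves = pd.read_csv(processed / "group_curves.csv")
    conditions = sorted(stance["condition"].unique(),
                        key=["DGO", "DGO_therapist", "treadmill"].index)
    groups = sorted(stance["group"].unique())

    def _condition_rows(matrix, labels, context):
        omnibus, pairwise, pair_labels, flags = compare_conditions(
            matrix, alpha=alpha, condition_labels=tuple(labels)
        )
        rows = [{**context, "comparison": "omnibus", "method": omnibus.method,
                 "statistic": omnibus.statistic, "p_raw": omnibus.p_raw,
                 "p_adjusted": "", "significant": omnibus.p_raw < alpha,
                 "exact": omnibus.exact}]
        for res, (ca, cb), flag in zip(pairwise, pair_labels, flags):
            rows.append({**context, "comparison": f"{ca} vs {cb}",
                         "method": res.method, "statistic": res.statistic,
                         "p_raw": res.p_raw, "p_adjusted": res.p_adjusted,
                         "significant": flag, "exact": res.exact})
        return rows

    # (i) phase distribution
    stance_stat_rows, screen_rows = [], []
    for group in groups:
        sub = stance[stance["group"] == group]
        matrix, _ = _complete_pivot(sub, "stance_pct_mean", conditions)
        if matrix.shape[0] >= 2:
            stance_stat_rows += _condition_rows(matrix, conditions,
                                                {"group": group, "measure": "stance_pct"})
        for condition in conditions:
            vals = sub[sub["condition"] == condition]["stance_pct_mean"].to_numpy()
            try:
                sw = shapiro_wilk(vals)
                screen_rows.append({"group": group, "condition": condition,
                                    "measure": "stance_pct", "W": sw.statistic,
                                    "p": sw.p_raw, "n": sw.n})
            except (ValueError, DegenerateDataError) as exc:
                logger.warning("normality screen skipped for %s/%s: %s",
                               group, condition, exc)
    if len(groups) == 2:
        for condition in conditions:
            a = stance[(stance["group"] == groups[0])
                       & (stance["condition"] == condition)]["stance_pct_mean"]
            b = stance[(stance["group"] == groups[1])
                       & (stance["condition"] == condition)]["stance_pct_mean"]
            if len(a) and len(b):
                res = mann_whitney_u(a.to_numpy(), b.to_numpy())
                stance_stat_rows.append({
                    "group": f"{groups[0]} vs {groups[1]}", "measure": "stance_pct",
                    "comparison": condition, "method": res.method,
                    "statistic": res.statistic, "p_raw": res.p_raw,
                    "p_adjusted": "", "significant": res.p_raw < alpha,
                    "exact": res.exact,
                })
    pd.DataFrame(stance_stat_rows).to_csv(out / "stance_stats.csv", index=False,
                                          float_format=FLOAT_FMT)
    pd.DataFrame(screen_rows).to_csv(out / "normality_screen.csv", index=False,
                                     float_format=FLOAT_FMT)

    # (ii) amplitudes within group, between groups, and curve similarity
    amp_rows, amp_group_rows, sim_rows = [], [], []
    for group in groups:
        for muscle in sorted(amps["muscle"].unique()):
            for phase, col in (("stance", "stance_mean_uv"), ("swing", "swing_mean_uv")):
                sub = amps[(amps["group"] == group) & (amps["muscle"] == muscle)]
                matrix, _ = _complete_pivot(sub, col, conditions)
                if matrix.shape[0] >= 2:
                    amp_rows += _condition_rows(
                        matrix, conditions,
                        {"group": group, "muscle": muscle, "phase": phase},
                    )
    if len(groups) == 2:
        for condition in conditions:
            for muscle in sorted(amps["muscle"].unique()):
                for phase, col in (("stance", "stance_mean_uv"),
                                   ("swing", "swing_mean_uv")):
                    a = amps[(amps["group"] == groups[0]) & (amps["muscle"] == muscle)
                             & (amps["condition"] == condition)][col]
                    b = amps[(amps["group"] == groups[1]) & (amps["muscle"] == muscle)
                             & (amps["condition"] == condition)][col]
                    if len(a) and len(b):
                        res = mann_whitney_u(a.to_numpy(), b.to_numpy())
                        amp_group_rows.append({
                            "condition": condition, "muscle": muscle,
                            "phase": phase, "method": res.method,
                            "statistic": res.statistic, "p_raw": res.p_raw,
                            "significant": res.p_raw < alpha, "exact": res.exact,
                        })

    def _group_curve(group, condition, muscle, phase) -> np.ndarray | None:
        sel = curves[(curves["group"] == group) & (curves["condition"] == condition)
                     & (curves["muscle"] == muscle) & (curves["phase"] == phase)]
        if sel.empty:
            return None
        return sel.sort_values("point")["mean_uv"].to_numpy()

    for group in groups:
        for muscle in sorted(curves["muscle"].unique()):
            for phase in ("cycle", "stance", "swing"):
                for i, ca in enumerate(conditions):
                    for cb in conditions[i + 1:]:
                        va = _group_curve(group, ca, muscle, phase)
                        vb = _group_curve(group, cb, muscle, phase)
                        if va is None or vb is None:
                            continue
                        try:
                            sim = spearman_similarity(va, vb)
                        except DegenerateDataError:
                            continue
                        sim_rows.append({
                            "scope": "between_conditions", "group": group,
                            "comparison": f"{ca} vs {cb}", "muscle": muscle,
                            "phase": phase, "rho": sim.rho, "p": sim.p_value,
                            "label": sim.magnitude_label, "sign": sim.sign,
                        })
    if len(groups) == 2:
        for condition in conditions:
            for muscle in sorted(curves["muscle"].unique()):
                for phase in ("cycle", "stance", "swing"):
                    va = _group_curve(groups[0], condition, muscle, phase)
                    vb = _group_curve(groups[1], condition, muscle, phase)
                    if va is None or vb is None:
                        continue
                    try:
                        sim = spearman_similarity(va, vb)
                    except DegenerateDataError:
                        continue
                    sim_rows.append({
                        "scope": "between_groups",
                        "group": f"{groups[0]} vs {groups[1]}",
                        "comparison": condition, "muscle": muscle,
                        "phase": phase, "rho": sim.rho, "p": sim.p_value,
                        "label": sim.magnitude_label, "sign": sim.sign,
                    })
    pd.DataFrame(amp_rows).to_csv(out / "amplitude_condition_stats.csv",
                                  index=False, float_format=FLOAT_FMT)
    pd.DataFrame(amp_group_rows).to_csv(out / "amplitude_group_stats.csv",
                                        index=False, float_format=FLOAT_FMT)
    pd.DataFrame(sim_rows).to_csv(out / "curve_similarity.csv", index=False,
                                  float_format=FLOAT_FMT)

    # (iii) reference similarity matrix
    n_reference = 0
    if reference_dir is not None:
        ref_rows = []
        for path in sorted(Path(reference_dir).glob("*_*.csv")):
            muscle, phase = path.stem.rsplit("_", 1)
            if phase not in ("cycle", "stance", "swing"):
                logger.warning("skipping reference file %s: unknown phase", path.name)
                continue
            pct, amp = read_reference_curve(path)
            ref = resample_reference(pct, amp, phase=phase)
            for group in groups:
                for condition in conditions:
                    vals = _group_curve(group, condition, muscle, phase)
                    if vals is None:
                        continue
                    try:
                        sim = spearman_similarity(vals, ref.values)
                    except DegenerateDataError:
                        continue
                    ref_rows.append({
                        "group": group, "condition": condition,
                        "muscle": muscle, "phase": phase, "rho": sim.rho,
                        "p": sim.p_value, "label": sim.magnitude_label,
                        "sign": sim.sign,
                    })
        pd.DataFrame(ref_rows).to_csv(out / "reference_similarity.csv",
                                      index=False, float_format=FLOAT_FMT)
        n_reference = len(ref_rows)
    RunManifest(config_hash=_hash_obj({"processed": str(processed_dir),
                                       "alpha": alpha}),
                seed=-1).write(out / "manifest.json")
    return {"n_similarity_rows": len(sim_rows), "n_reference_rows": n_reference}
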