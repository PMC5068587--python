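"""End-to-end pipeline: simulate -> preprocess -> extract -> stats.

A run is fully described by a :class:`RunConfig` (serializable to YAML); all
randomness flows from its master seed through named substreams, so re-running
an identical config reproduces identical outputs.  Each stage writes plain
tabular artifacts (CSV/TSV; EEG as EDF) plus a manifest with SHA-256
checksums of everything it produced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .edf import read_edf, write_edf
from .extraction import participant_gcsr
from .preprocessing import (
    build_blink_template,
    detect_blinks,
    reject_artifacts,
    remove_blinks,
    running_mean_filter,
    CleanedEEG,
)
from .stats import (
    channel_gradient,
    contrast_score,
    group_contrast_anova,
    one_sample_contrast_test,
    stepwise_forward,
    trait_correlations,
)
from .synthetic_data import (
    CohortConfig,
    ConflictInjection,
    EEGParams,
    ParticipantRecord,
    ResponderModel,
    generate_cohort,
)

__all__ = ["RunConfig", "cmd_simulate", "cmd_preprocess", "cmd_extract", "cmd_stats", "cmd_run_all"]

ANALYSIS_CHANNELS = ("F7", "F3", "Fz", "F4", "F8")


@dataclass
class RunConfig:
    """Declarative description of one full pipeline run."""

    seed: int = 0
    groups: dict[str, int] = field(
        default_factory=lambda: {"placebo": 8, "buspirone": 9, "triazolam": 9, "pregabalin": 8}
    )
    drug_multipliers: dict[str, float] = field(
        default_factory=lambda: {
            "placebo": 1.0,
            "buspirone": 0.3,
            "triazolam": 0.3,
            "pregabalin": 0.3,
        }
    )
    trait_coupling: float = 0.0
    injection_amplitude: float = 8.0
    injection_band: tuple[float, float] = (4.0, 12.0)
    block_profile: tuple[float, ...] = (1.0, 0.0, 1.0)
    n_blocks: int = 3
    trials_per_block: int = 128
    channels: tuple[str, ...] = ANALYSIS_CHANNELS
    artifact_threshold_uv: float = 150.0
    artifact_pad_s: float = 0.1
    blink_threshold_uv: float = 50.0
    freq_orders: tuple[str, ...] = ("linear", "quadratic", "cubic")
    p_enter: float = 0.05

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            groups=dict(self.groups),
            drug_multipliers=dict(self.drug_multipliers),
            trait_coupling=self.trait_coupling,
            responder=ResponderModel(),
            eeg=EEGParams(),
            injection=ConflictInjection(
                amplitude=self.injection_amplitude,
                band=tuple(self.injection_band),
                block_profile=tuple(self.block_profile),
            ),
            n_blocks=self.n_blocks,
            trials_per_block=self.trials_per_block,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("injection_band", "block_profile", "channels", "freq_orders"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for key in ("injection_band", "block_profile", "channels", "freq_orders"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, config: RunConfig, stage: str, files: list[Path],
                    notes: dict | None = None) -> Path:
    manifest = {
        "stage": stage,
        "version": __version__,
        "config": dataclasses.asdict(config),
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
        "notes": notes or {},
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


# -- stage 1: simulate -------------------------------------------------------

def cmd_simulate(config: RunConfig, outdir: str | Path) -> list[Path]:
    """Generate the cohort and write per-participant EDF + events + behaviour."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config.cohort_config())
    files: list[Path] = []
    meta_rows = []
    for rec in cohort:
        base = outdir / rec.id
        files.append(
            write_edf(base.with_suffix(".edf"), rec.eeg.data, rec.eeg.channels, rec.eeg.fs,
                      patient_id=rec.id)
        )
        rec.eeg.events.to_csv(base.with_name(base.name + "_events.tsv"), sep="\t", index=False)
        files.append(base.with_name(base.name + "_events.tsv"))
        rec.behavior.trials.to_csv(base.with_name(base.name + "_behavior.csv"), index=False)
        files.append(base.with_name(base.name + "_behavior.csv"))
        meta_rows.append(
            dict(
                participant=rec.id,
                group=rec.group,
                pretest_go_rt_ms=rec.behavior.pretest_go_rt_ms,
                median_go_rt_ms=rec.behavior.median_go_rt_ms,
                ssrt_ms=rec.behavior.ssrt_ms,
                p_inhibit_short=rec.behavior.p_inhibit["short"],
                p_inhibit_medium=rec.behavior.p_inhibit["medium"],
                p_inhibit_long=rec.behavior.p_inhibit["long"],
                **rec.traits,
            )
        )
    meta = pd.DataFrame(meta_rows)
    meta_path = outdir / "participants.csv"
    meta.to_csv(meta_path, index=False)
    files.append(meta_path)
    config.to_yaml(outdir / "config.yaml")
    files.append(outdir / "config.yaml")
    _write_manifest(outdir, config, "simulate", files, {"n_participants": len(cohort)})
    return files


# -- stage 2: preprocess -----------------------------------------------------

def preprocess_record(
    data: np.ndarray,
    channels: tuple[str, ...],
    fs: float,
    config: RunConfig,
) -> CleanedEEG:
    """Mains smoothing, blink-template subtraction, artifact rejection."""
    data = running_mean_filter(data)
    fp1 = data[channels.index("Fp1")]
    windows = detect_blinks(fp1, fs, threshold_uv=config.blink_threshold_uv)
    if windows:
        template = build_blink_template(fp1, windows)
        cleaned = remove_blinks(data, channels, fs, template, windows)
    else:
        cleaned = CleanedEEG(
            signal=data, channels=tuple(channels), fs=fs,
            rejection_mask=np.zeros(data.shape, dtype=bool),
            provenance=["remove_blinks: no blinks detected"],
        )
    return reject_artifacts(cleaned, config.artifact_threshold_uv, config.artifact_pad_s)


def _mask_to_intervals(mask: np.ndarray, fs: float) -> pd.DataFrame:
    rows = []
    for c in range(mask.shape[0]):
        m = mask[c]
        edges = np.flatnonzero(np.diff(np.concatenate([[0], m.astype(int), [0]])))
        for start, stop in zip(edges[::2], edges[1::2]):
            rows.append(dict(channel=c, onset_s=start / fs, offset_s=stop / fs))
    return pd.DataFrame(rows, columns=["channel", "onset_s", "offset_s"])


def cmd_preprocess(config: RunConfig, simdir: str | Path, outdir: str | Path) -> list[Path]:
    """Clean every simulated EDF; write cleaned EDFs plus rejection intervals."""
    simdir, outdir = Path(simdir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    for edf_path in sorted(simdir.glob("*.edf")):
        data, channels, fs = read_edf(edf_path)
        cleaned = preprocess_record(data, channels, fs, config)
        out = outdir / edf_path.name.replace(".edf", "_clean.edf")
        files.append(write_edf(out, cleaned.signal, cleaned.channels, fs,
                               patient_id=edf_path.stem))
        intervals = _mask_to_intervals(cleaned.rejection_mask, fs)
        ipath = outdir / edf_path.name.replace(".edf", "_rejections.tsv")
        intervals.to_csv(ipath, sep="\t", index=False)
        files.append(ipath)
    _write_manifest(outdir, config, "preprocess", files)
    return files


# -- stage 3: extract --------------------------------------------------------

def _apply_rejections(data: np.ndarray, intervals: pd.DataFrame, fs: float) -> np.ndarray:
    data = np.array(data)
    for _, r in intervals.iterrows():
        data[int(r["channel"]), int(r["onset_s"] * fs) : int(r["offset_s"] * fs)] = np.nan
    return data


def cmd_extract(config: RunConfig, simdir: str | Path, cleandir: str | Path,
                outdir: str | Path) -> list[Path]:
    """Epoch, transform and contrast the cleaned records into GCSR tables."""
    simdir, cleandir, outdir = Path(simdir), Path(cleandir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gcsr_tables, cell_tables, logs = [], [], []
    for clean_path in sorted(cleandir.glob("*_clean.edf")):
        pid = clean_path.name.replace("_clean.edf", "")
        data, channels, fs = read_edf(clean_path)
        intervals = pd.read_csv(cleandir / f"{pid}_rejections.tsv", sep="\t")
        data = _apply_rejections(data, intervals, fs)
        trials = pd.read_csv(simdir / f"{pid}_behavior.csv")
        g, cells, log = participant_gcsr(
            data, channels, fs, trials, analysis_channels=tuple(config.channels)
        )
        g.insert(0, "participant", pid)
        cells.insert(0, "participant", pid)
        gcsr_tables.append(g)
        cell_tables.append(cells)
        logs.extend(f"{pid}\t{line}" for line in log)
    gcsr_all = pd.concat(gcsr_tables, ignore_index=True)
    cells_all = pd.concat(cell_tables, ignore_index=True)
    files = [outdir / "gcsr.csv", outdir / "power_cells.csv", outdir / "exclusions.tsv"]
    gcsr_all.to_csv(files[0], index=False)
    cells_all.to_csv(files[1], index=False)
    files[2].write_text("participant\treason\n" + "".join(line + "\n" for line in logs))
    _write_manifest(outdir, config, "extract", files)
    return files


# -- stage 4: stats ----------------------------------------------------------

def compute_contrast_scores(cells: pd.DataFrame, config: RunConfig,
                            channel: str = "F8") -> pd.DataFrame:
    """Per-participant x block composite contrast scores at one channel."""
    rows = []
    sub = cells[cells["channel"] == channel]
    for (pid, block), chunk in sub.groupby(["participant", "block"]):
        for order in config.freq_orders:
            rows.append(
                dict(participant=pid, block=block, channel=channel, freq_order=order,
                     score=contrast_score(chunk, freq_order=order))
            )
    return pd.DataFrame(rows)


def cmd_stats(config: RunConfig, simdir: str | Path, extractdir: str | Path,
              outdir: str | Path) -> dict:
    """Contrast tests, group ANOVAs, trait correlations, stepwise selection."""
    simdir, extractdir, outdir = Path(simdir), Path(extractdir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells = pd.read_csv(extractdir / "power_cells.csv")
    gcsr_all = pd.read_csv(extractdir / "gcsr.csv")
    meta = pd.read_csv(simdir / "participants.csv").set_index("participant")

    scores = compute_contrast_scores(cells, config)
    test_rows = []
    for (block, order), chunk in scores.groupby(["block", "freq_order"]):
        merged = chunk.set_index("participant").join(meta[["group"]])
        s = merged["score"].to_numpy()
        label = f"StopGo x SSDquad x freq-{order}, block {block}, F8"
        finite = s[np.isfinite(s)]
        if finite.size >= 2 and np.std(finite, ddof=1) > 0:
            res = one_sample_contrast_test(s, effect=label)
            test_rows.append(dict(effect=res.effect, test="one_sample", f=res.f_value,
                                  df1=res.df[0], df2=res.df[1], p=res.p_value))
        groups = merged["group"]
        if groups.nunique() >= 2 and (merged.groupby("group")["score"].count() >= 2).all():
            res = group_contrast_anova(s, groups.to_numpy(), effect=label + " x group")
            test_rows.append(dict(effect=res.effect, test="group_anova", f=res.f_value,
                                  df1=res.df[0], df2=res.df[1], p=res.p_value))
    tests = pd.DataFrame(test_rows)

    f8 = gcsr_all[gcsr_all["channel"] == "F8"]
    corr_frames = [
        trait_correlations(f8, meta[trait], trait_name=trait)
        for trait in ("neuroticism", "trait_anxiety", "bis")
        if trait in meta.columns
    ]
    corrs = pd.concat(corr_frames, ignore_index=True) if corr_frames else pd.DataFrame()

    stepwise_rows = []
    if "neuroticism" in meta.columns:
        for block, chunk in f8.groupby("block"):
            wide = chunk.pivot_table(index="participant", columns="frequency_hz",
                                     values="gcsr")
            wide.columns = [f"gcsr_{f}Hz" for f in wide.columns]
            joined = wide.join(meta["neuroticism"]).dropna()
            if len(joined) >= 12:
                steps = stepwise_forward(joined[wide.columns], joined["neuroticism"],
                                         p_enter=config.p_enter)
                for i, st in enumerate(steps, 1):
                    stepwise_rows.append(dict(block=block, step=i, predictor=st.predictor,
                                              r=st.r, f_change=st.f_change,
                                              df1=st.df[0], df2=st.df[1], p=st.p_value))
    stepwise = pd.DataFrame(stepwise_rows,
                            columns=["block", "step", "predictor", "r", "f_change",
                                     "df1", "df2", "p"])

    gradient = channel_gradient(gcsr_all)

    files = []
    for name, frame in [("contrast_scores", scores), ("tests", tests),
                        ("trait_correlations", corrs), ("stepwise", stepwise),
                        ("channel_gradient", gradient)]:
        p = outdir / f"{name}.csv"
        frame.to_csv(p, index=False)
        files.append(p)

    report = outdir / "report.txt"
    with open(report, "w") as fh:
        fh.write("GCSR pipeline report\n====================\n\n")
        fh.write(f"participants: {len(meta)}  groups: {meta['group'].value_counts().to_dict()}\n")
        fh.write(f"GCSR rows: {len(gcsr_all)}  cells: {len(cells)}\n\n")
        fh.write("Contrast tests (uncorrected p):\n")
        fh.write(tests.to_string(index=False) + "\n\n")
        if len(stepwise):
            fh.write("Stepwise (neuroticism ~ GCSR by frequency):\n")
            fh.write(stepwise.to_string(index=False) + "\n\n")
        fh.write("Channel gradient (F8 - mean others):\n")
        fh.write(gradient.to_string(index=False) + "\n")
    files.append(report)
    _write_manifest(outdir, config, "stats", files)
    return dict(tests=tests, correlations=corrs, stepwise=stepwise, gradient=gradient,
                scores=scores)


def cmd_run_all(config: RunConfig, outdir: str | Path) -> dict:
    """simulate -> preprocess -> extract -> stats, all under one output root."""
    outdir = Path(outdir)
    stages = {name: outdir / name for name in ("simulate", "preprocess", "extract", "stats")}
    cmd_simulate(config, stages["simulate"])
    cmd_preprocess(config, stages["simulate"], stages["preprocess"])
    cmd_extract(config, stages["simulate"], stages["preprocess"], stages["extract"])
    return cmd_stats(config, stages["simulate"], stages["extract"], stages["stats"])


# -- in-memory path (no files), used by tests and the acceptance script ------

def analyze_cohort_in_memory(records: list[ParticipantRecord], config: RunConfig | None = None,
                             preprocess: bool = True) -> dict:
    """Run preprocess + extract on an in-memory cohort; return tidy tables."""
    config = config or RunConfig()
    gcsr_tables, cell_tables = [], []
    for rec in records:
        if preprocess:
            cleaned = preprocess_record(rec.eeg.data, rec.eeg.channels, rec.eeg.fs, config)
            data = cleaned.signal
        else:
            data = rec.eeg.data
        g, cells, _ = participant_gcsr(
            data, rec.eeg.channels, rec.eeg.fs, rec.behavior.trials,
            analysis_channels=tuple(config.channels),
        )
        g.insert(0, "participant", rec.id)
        cells.insert(0, "participant", rec.id)
        gcsr_tables.append(g)
        cell_tables.append(cells)
    return dict(
        gcsr=pd.concat(gcsr_tables, ignore_index=True),
        cells=pd.concat(cell_tables, ignore_index=True),
    )
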