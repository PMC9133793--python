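"""End-to-end synthetic study orchestration.

Runs the full analysis structure of the roving-oddball study on simulated
cohorts: one Control-profile group (repetition-attenuation deepening with
position) and one Dyslexia-profile group (immediate but flat attenuation),
each passed through design generation, per-participant epoch simulation,
preprocessing, time-resolved decoding of every contrast, and group-level
permutation inference - including the ordered repetition contrasts
(1v3 > 1v2, 1v4 > 1v2, 1v4 > 1v3), the trial-count-matched subset control,
temporal generalization, latency comparisons, and the stimulus-specific
5 x 5 decoding grid whose tiny per-cell trial counts reproduce the
unreliable / below-chance regime.

Everything is derived from one master seed via ``numpy.random.SeedSequence``
fan-out, so two runs with the same config produce identical reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import EpochsData, default_layout
from .decode import DecodeConfig, decode_timecourse, subset_trials, temporal_generalization
from .design import DesignSpec, TrainDesign, generate_design
from .inference import (
    ClusterTestConfig,
    ClusterTestResult,
    LatencyEstimate,
    LatencyResult,
    bootstrap_latency_test,
    onset_and_peak_latency,
    paired_difference_cluster_test,
    sign_permutation_cluster_test,
    two_sample_cluster_test,
)
from .preprocess import PreprocConfig, RejectionCriteria, run_preprocessing
from .simulate import default_ground_truth, default_times, inject_artifacts, simulate_epochs

__all__ = [
    "StudyConfig",
    "StudyReport",
    "contrast_mask_and_labels",
    "simulate_participant",
    "decode_contrast",
    "compare_repetition_levels",
    "run_full_study",
]

REPETITION_PAIRS = (("1v3", "1v2"), ("1v4", "1v2"), ("1v4", "1v3"))


@dataclass(frozen=True)
class StudyConfig:
    n_per_group: int = 24
    group_profiles: Mapping[str, str] = field(
        default_factory=lambda: {"control": "control", "dyslexia": "dyslexia"}
    )
    design: DesignSpec = field(default_factory=DesignSpec)
    n_sensors: int = 306
    sfreq: float = 1000.0
    contrasts: tuple[str, ...] = ("deviant_vs_standards", "1v2", "1v3", "1v4", "1v5", "1v6")
    artifact_fraction: float = 0.02
    simulator: Mapping[str, float] = field(default_factory=dict)  # default_ground_truth overrides
    decode: DecodeConfig = field(default_factory=DecodeConfig)
    cluster: ClusterTestConfig = field(default_factory=ClusterTestConfig)
    n_boot: int = 1000
    run_subset_control: bool = True
    run_temporal_generalization: bool = True
    run_stimulus_specific: bool = True
    run_latency: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 participants per group")
        if not self.contrasts:
            raise ValueError("need at least one contrast")

    @classmethod
    def smoke(cls, seed: int = 0, **overrides) -> "StudyConfig":
        """Reduced-scale configuration for fast end-to-end runs."""
        base = dict(
            n_per_group=4,
            design=DesignSpec(n_trains=60, length_counts={4: 20, 5: 20, 6: 20}),
            n_sensors=32,
            sfreq=50.0,
            decode=DecodeConfig(n_repetitions=10),
            cluster=ClusterTestConfig(n_permutations=500),
            n_boot=100,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)


def contrast_mask_and_labels(trials: pd.DataFrame, contrast: str) -> tuple[np.ndarray, np.ndarray]:
    """Trial mask and binary condition labels for a named contrast.

    ``deviant_vs_standards`` pits position-1 trials against every other
    position; ``1v2`` .. ``1v6`` pit them against a single standard position.
    """
    pos = trials["position_in_train"].to_numpy()
    if contrast == "deviant_vs_standards":
        mask = np.ones(len(trials), dtype=bool)
        labels = np.where(pos == 1, "deviant", "standard")
        return mask, labels[mask]
    if len(contrast) == 3 and contrast[0] == "1" and contrast[1] == "v":
        k = int(contrast[2])
        if not 2 <= k <= 6:
            raise ValueError(f"unknown contrast {contrast!r}")
        mask = (pos == 1) | (pos == k)
        labels = np.where(pos == 1, "deviant", f"standard{k}")
        return mask, labels[mask]
    raise ValueError(f"unknown contrast {contrast!r}")


def _stimulus_specific_cells(trials: pd.DataFrame, design: TrainDesign):
    """The 25 (standard stimulus, successor) cells of the stimulus-specific grid.

    The standard of each cell is the 4th token of its stimulus.  The
    same-stimulus cell pairs those 4ths with 5ths of the same stimulus; the
    deviant cells pair them with deviants of the successor stimulus that
    immediately follow a length-4 train of the standard stimulus (so the 4th
    token is the final standard directly preceding the deviant).
    """
    stim_of_train = {i: s for i, (s, _) in enumerate(design.trains)}
    len_of_train = {i: ln for i, (_, ln) in enumerate(design.trains)}
    pos = trials["position_in_train"].to_numpy()
    stim = trials["stimulus"].to_numpy()
    tr = trials["train_index"].to_numpy()
    prev_stim = np.array([stim_of_train.get(t - 1, "") for t in tr], dtype=object)
    prev_len = np.array([len_of_train.get(t - 1, 0) for t in tr])
    stimuli = sorted(set(stim_of_train.values()))
    cells = {}
    for s in stimuli:
        std_mask = (pos == 4) & (stim == s)
        for succ in stimuli:
            if succ == s:
                other = (pos == 5) & (stim == s)
            else:
                other = (pos == 1) & (stim == succ) & (prev_stim == s) & (prev_len == 4)
            cells[(s, succ)] = (std_mask, other)
    return cells


def simulate_participant(
    design: TrainDesign,
    profile: str,
    config: StudyConfig,
    seed_seq: np.random.SeedSequence,
) -> tuple[EpochsData, pd.DataFrame]:
    """Simulate and preprocess one participant's epochs (seeded fan-out)."""
    truth_seed, sim_seed, art_seed = (int(s) for s in seed_seq.generate_state(3) % (2**31))
    layout = default_layout(config.n_sensors)
    times = default_times(config.sfreq)
    truth = default_ground_truth(
        layout, times, profile=profile, seed=truth_seed, **dict(config.simulator)
    )
    epochs = simulate_epochs(design, truth, layout, seed=sim_seed)
    if config.artifact_fraction > 0:
        epochs, _ = inject_artifacts(epochs, config.artifact_fraction, seed=art_seed)
    clean, log = run_preprocessing(epochs, RejectionCriteria(), PreprocConfig())
    return clean, log


def decode_contrast(
    epochs: EpochsData, contrast: str, decode_config: DecodeConfig
) -> np.ndarray:
    """Accuracy time series for one contrast on preprocessed epochs."""
    mask, labels = contrast_mask_and_labels(epochs.trials, contrast)
    sub = epochs.select_trials(np.flatnonzero(mask))
    return decode_timecourse(sub, labels, decode_config).accuracy


def compare_repetition_levels(
    series_by_level: Mapping[str, np.ndarray],
    times: np.ndarray,
    config: ClusterTestConfig,
) -> dict[tuple[str, str], ClusterTestResult]:
    """One-sided ordered repetition contrasts on per-subject difference series.

    For each ordered pair (e.g. 1v4 > 1v2) a one-sample sign-permutation
    cluster test is run on the per-subject accuracy differences (null 0).
    """
    shapes = {np.asarray(v).shape for v in series_by_level.values()}
    if len(shapes) != 1:
        raise ValueError("repetition-level series must share subjects and time grid")
    out = {}
    for hi, lo in REPETITION_PAIRS:
        if hi in series_by_level and lo in series_by_level:
            out[(hi, lo)] = paired_difference_cluster_test(
                series_by_level[hi], series_by_level[lo], times,
                replace(config, null_value=0.0, alternative="greater"),
            )
    return out


@dataclass
class StudyReport:
    config: StudyConfig
    design: TrainDesign
    times: np.ndarray
    subject_series: dict  # group -> contrast -> (n_subjects, n_times)
    subject_series_subset: dict  # group -> contrast -> (n_subjects, n_times)
    n_rejected: dict  # group -> list per subject
    within_group: dict  # group -> contrast -> ClusterTestResult
    between_group: dict  # contrast -> ClusterTestResult
    repetition_contrasts: dict  # group -> (hi, lo) -> ClusterTestResult
    repetition_contrasts_subset: dict
    subset_vs_full: dict  # group -> contrast -> ClusterTestResult (full > subset)
    tg_group_mean: dict  # group -> matrix
    tg_times: np.ndarray | None
    stimulus_specific: dict  # group -> (std, succ) -> (n_subjects, n_times) or None
    latencies: dict  # group -> contrast -> LatencyEstimate
    latency_tests: dict  # description -> LatencyResult

    def group_mean(self, group: str, contrast: str) -> np.ndarray:
        return self.subject_series[group][contrast].mean(axis=0)

    def report_hash(self) -> str:
        """Digest of every numeric result; equal configs+seed => equal hash."""
        h = hashlib.sha256()

        def feed(obj):
            if isinstance(obj, dict):
                for key in sorted(obj, key=repr):
                    h.update(repr(key).encode())
                    feed(obj[key])
            elif isinstance(obj, np.ndarray):
                h.update(np.ascontiguousarray(obj).tobytes())
            elif isinstance(obj, ClusterTestResult):
                feed({"map": obj.statistic_map, "mask": obj.significant_mask.astype(np.uint8),
                      "p": np.array([c.corrected_p for c in obj.clusters])})
            elif isinstance(obj, (LatencyEstimate, LatencyResult)):
                h.update(repr(obj).encode())
            elif obj is None:
                h.update(b"none")
            else:
                h.update(repr(obj).encode())

        feed(self.subject_series)
        feed(self.subject_series_subset)
        feed(self.within_group)
        feed(self.between_group)
        feed(self.repetition_contrasts)
        feed(self.subset_vs_full)
        feed(self.tg_group_mean)
        feed(self.stimulus_specific)
        feed(self.latencies)
        feed(self.latency_tests)
        return h.hexdigest()

    def save(self, out_dir: str | Path) -> None:
        """Machine-readable tables plus a JSON manifest, one file per analysis."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.design.save(out / "design.tsv")
        manifest: dict = {"seed": self.config.seed, "n_per_group": self.config.n_per_group,
                          "groups": {}, "between_group": {}, "latency_tests": {}}
        for group, by_contrast in self.subject_series.items():
            gdir = out / group
            gdir.mkdir(exist_ok=True)
            ginfo: dict = {"contrasts": {}}
            for contrast, series in by_contrast.items():
                frame = pd.DataFrame(series.T)
                frame.insert(0, "time_ms", self.times)
                frame.to_csv(gdir / f"accuracy_{contrast}.tsv", sep="\t", index=False)
                info = {}
                res = self.within_group.get(group, {}).get(contrast)
                if res is not None:
                    info["clusters"] = [
                        {"start_ms": c.start_ms, "end_ms": c.end_ms, "mass": c.mass,
                         "corrected_p": c.corrected_p}
                        for c in res.clusters
                    ]
                ginfo["contrasts"][contrast] = info
            for (hi, lo), res in self.repetition_contrasts.get(group, {}).items():
                ginfo[f"{hi}_gt_{lo}_p"] = res.min_corrected_p
            manifest["groups"][group] = ginfo
        for contrast, res in self.between_group.items():
            manifest["between_group"][contrast] = res.min_corrected_p
        for name, res in self.latency_tests.items():
            manifest["latency_tests"][name] = {
                "kind": res.latency_kind, "latency_a": res.latency_a,
                "latency_b": res.latency_b, "p": res.p_two_sided, "reliable": res.reliable,
            }
        manifest["report_hash"] = self.report_hash()
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_full_study(config: StudyConfig | None = None) -> StudyReport:
    """Execute the complete synthetic study; see the module docstring."""
    config = config if config is not None else StudyConfig()
    root = np.random.SeedSequence(config.seed)
    design_seed = int(root.generate_state(1)[0] % (2**31))
    design = generate_design(replace(config.design, seed=design_seed))
    times = default_times(config.sfreq)

    groups = list(config.group_profiles)
    subject_seeds = {g: root.spawn(config.n_per_group) for g in groups}
    decode_seed_pool = root.generate_state(10_000) % (2**31)
    seed_cursor = 0

    def next_seed() -> int:
        nonlocal seed_cursor
        seed_cursor += 1
        return int(decode_seed_pool[seed_cursor - 1])

    subject_series: dict = {g: {c: [] for c in config.contrasts} for g in groups}
    subset_contrasts = [c for c in config.contrasts if c in ("1v2", "1v3", "1v4", "1v5")]
    subject_series_subset: dict = {g: {c: [] for c in subset_contrasts} for g in groups}
    n_rejected: dict = {g: [] for g in groups}
    tg_accum: dict = {}
    stim_cells_series: dict = {g: {} for g in groups}

    for group in groups:
        profile = config.group_profiles[group]
        for s_idx in range(config.n_per_group):
            epochs, rej_log = simulate_participant(
                design, profile, config, subject_seeds[group][s_idx]
            )
            n_rejected[group].append(len(rej_log))
            pos = epochs.trials["position_in_train"].to_numpy()
            for contrast in config.contrasts:
                if contrast != "deviant_vs_standards":
                    k = int(contrast[2])
                    if (pos == k).sum() < config.decode.n_folds:
                        raise ValueError(f"too few position-{k} trials for {contrast}")
                cfg = replace(config.decode, seed=next_seed())
                subject_series[group][contrast].append(
                    decode_contrast(epochs, contrast, cfg)
                )
            if config.run_subset_control and subset_contrasts:
                n6 = int((pos == 6).sum())
                for contrast in subset_contrasts:
                    k = int(contrast[2])
                    std_idx = np.flatnonzero(pos == k)
                    dev_idx = np.flatnonzero(pos == 1)
                    sub = subset_trials({"std": std_idx}, min(n6, std_idx.size),
                                        seed=next_seed())["std"]
                    keep = np.sort(np.concatenate([dev_idx, sub]))
                    cfg = replace(config.decode, seed=next_seed())
                    reduced = epochs.select_trials(keep)
                    mask, labels = contrast_mask_and_labels(reduced.trials, contrast)
                    subject_series_subset[group][contrast].append(
                        decode_timecourse(reduced.select_trials(np.flatnonzero(mask)),
                                          labels, cfg).accuracy
                    )
            if config.run_temporal_generalization:
                mask, labels = contrast_mask_and_labels(epochs.trials, "deviant_vs_standards")
                cfg = replace(config.decode, seed=next_seed())
                tg = temporal_generalization(
                    epochs.select_trials(np.flatnonzero(mask)), labels, cfg
                )
                if group not in tg_accum:
                    tg_accum[group] = [np.zeros_like(tg.matrix), 0, tg.times]
                tg_accum[group][0] += tg.matrix
                tg_accum[group][1] += 1
            if config.run_stimulus_specific:
                for cell, (m_std, m_other) in _stimulus_specific_cells(
                    epochs.trials, design
                ).items():
                    if m_std.sum() < config.decode.n_folds or m_other.sum() < config.decode.n_folds:
                        stim_cells_series[group].setdefault(cell, None)
                        continue
                    keep = np.flatnonzero(m_std | m_other)
                    labels = np.where(m_std[keep], "standard4", "other")
                    cfg = replace(config.decode, seed=next_seed())
                    acc = decode_timecourse(epochs.select_trials(keep), labels, cfg).accuracy
                    stim_cells_series[group].setdefault(cell, []).append(acc)

    for g in groups:
        for c in list(subject_series[g]):
            subject_series[g][c] = np.asarray(subject_series[g][c])
        for c in list(subject_series_subset[g]):
            subject_series_subset[g][c] = np.asarray(subject_series_subset[g][c])
        for cell in list(stim_cells_series[g]):
            if stim_cells_series[g][cell] is not None:
                stim_cells_series[g][cell] = np.asarray(stim_cells_series[g][cell])

    # ---------------- group inference ----------------
    within_group: dict = {g: {} for g in groups}
    between_group: dict = {}
    for contrast in config.contrasts:
        for g in groups:
            within_group[g][contrast] = sign_permutation_cluster_test(
                subject_series[g][contrast], times,
                replace(config.cluster, null_value=0.5, alternative="greater",
                        seed=next_seed()),
            )
        if len(groups) == 2:
            a, b = groups
            between_group[contrast] = two_sample_cluster_test(
                subject_series[a][contrast], subject_series[b][contrast], times,
                replace(config.cluster, null_value=0.0, alternative="two-sided",
                        seed=next_seed()),
            )

    repetition_contrasts = {
        g: compare_repetition_levels(
            subject_series[g], times, replace(config.cluster, seed=next_seed())
        )
        for g in groups
    }
    repetition_contrasts_subset = {
        g: compare_repetition_levels(
            subject_series_subset[g], times, replace(config.cluster, seed=next_seed())
        )
        for g in groups
        if subject_series_subset[g]
    }

    subset_vs_full: dict = {g: {} for g in groups}
    if config.run_subset_control:
        for g in groups:
            for contrast in subset_contrasts:
                subset_vs_full[g][contrast] = paired_difference_cluster_test(
                    subject_series[g][contrast], subject_series_subset[g][contrast],
                    times,
                    replace(config.cluster, null_value=0.0, alternative="greater",
                            seed=next_seed()),
                )

    latencies: dict = {g: {} for g in groups}
    latency_tests: dict = {}
    if config.run_latency:
        window_mask = (times >= config.cluster.analysis_window[0]) & (
            times <= config.cluster.analysis_window[1]
        )
        for g in groups:
            for contrast in ("1v2", "1v3", "1v4"):
                if contrast not in subject_series[g]:
                    continue
                latencies[g][contrast] = onset_and_peak_latency(
                    subject_series[g][contrast][:, window_mask],
                    within_group[g][contrast],
                )
        if len(groups) == 2:
            a, b = groups
            for contrast in ("1v2", "1v3", "1v4"):
                if contrast not in subject_series[a]:
                    continue
                for kind in ("onset", "peak"):
                    latency_tests[f"{a}_vs_{b}_{contrast}_{kind}"] = bootstrap_latency_test(
                        subject_series[a][contrast], subject_series[b][contrast], times,
                        latency_kind=kind, n_boot=config.n_boot,
                        cluster_config=config.cluster, seed=next_seed(),
                    )
        # within-group repetition-level latency comparisons (paired: the same
        # participants contribute both condition series)
        for g in groups:
            for hi, lo in REPETITION_PAIRS:
                if hi not in subject_series[g] or lo not in subject_series[g]:
                    continue
                for kind in ("onset", "peak"):
                    latency_tests[f"{g}_{hi}_vs_{lo}_{kind}"] = bootstrap_latency_test(
                        subject_series[g][hi], subject_series[g][lo], times,
                        latency_kind=kind, n_boot=config.n_boot, paired=True,
                        cluster_config=config.cluster, seed=next_seed(),
                    )

    tg_group_mean = {g: acc / cnt for g, (acc, cnt, _) in tg_accum.items()}
    tg_times = next(iter(tg_accum.values()))[2] if tg_accum else None

    return StudyReport(
        config=config,
        design=design,
        times=times,
        subject_series=subject_series,
        subject_series_subset=subject_series_subset,
        n_rejected=n_rejected,
        within_group=within_group,
        between_group=between_group,
        repetition_contrasts=repetition_contrasts,
        repetition_contrasts_subset=repetition_contrasts_subset,
        subset_vs_full=subset_vs_full,
        tg_group_mean=tg_group_mean,
        tg_times=tg_times,
        stimulus_specific=stim_cells_series,
        latencies=latencies,
        latency_tests=latency_tests,
    )
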