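"""Batch orchestration of a two-rater, two-occasion reliability study.

A study is a manifest of (subject, rater, occasion) -> recording file.
Each cell is preprocessed (ectopic detection, 10% discard rule), a
256-beat stationary segment is selected, and the 13 HRV indices are
computed. Rater/occasion variation on a shared recording is emulated by
re-selecting the segment within a jitter neighbourhood of the canonical
best window, with a seeded subjective score perturbation split into a
rater-persistent component and an occasion component; intrarater pairs
share the rater component, so interrater differences are structurally at
least as variable.

Outputs mirror the conventional reporting layout: a descriptives table
(mean +/- SD per index per rater/occasion) and three reliability tables
(intrarater for each rater: test vs retest; interrater: the two raters'
test analyses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .indices import INDEX_NAMES, compute_indices
from .io import read_rri_txt, write_rri_txt
from .preprocessing import (
    DEFAULT_SEGMENT_LENGTH,
    DEFAULT_STRIDE,
    DEFAULT_WEIGHTS,
    apply_discard_rule,
    detect_ectopic,
    score_window,
    select_best_segment,
)
from .reliability import RatingsMatrix, reliability_report
from .series import RRiSeries
from .synthetic import jittered_selection, generate_rri, sample_subject_params

OCCASIONS = ("test", "retest")

REPORT_COLUMNS = [
    "index", "comparison", "n", "ICC", "CI95_low", "CI95_high", "ICC_class",
    "SEM", "SEM_pct", "MDC", "MDC_pct", "bias", "SD_diff", "CV_pct",
    "LoA_low", "LoA_high",
]


@dataclass
class StudyConfig:
    segment_length: int = DEFAULT_SEGMENT_LENGTH
    stride: int = DEFAULT_STRIDE
    weights: tuple = DEFAULT_WEIGHTS
    ectopic_threshold: float = 0.20
    ectopic_local_window: int = 11
    max_ectopic_frac: float = 0.10
    jitter_beats: int = 0
    seed: int = 0
    #: SD of the rater-persistent subjective score perturbation.
    rater_noise_sd: float = 0.03
    #: SD of the per-occasion score perturbation.
    occasion_noise_sd: float = 0.015


@dataclass
class StudyLayout:
    """Manifest of recordings: one row per (subject, rater, occasion)."""

    manifest: pd.DataFrame
    config: StudyConfig = field(default_factory=StudyConfig)

    def __post_init__(self) -> None:
        required = {"subject_id", "rater", "occasion", "path"}
        missing = required - set(self.manifest.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        dup = self.manifest.duplicated(["subject_id", "rater", "occasion"])
        if dup.any():
            raise ValueError("duplicate (subject, rater, occasion) cells in manifest")


@dataclass
class StudyResult:
    descriptives: pd.DataFrame
    intrarater: dict  # rater -> reliability table (DataFrame)
    interrater: pd.DataFrame
    bland_altman_points: pd.DataFrame
    excluded: list
    log: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return int(self.log["subject_id"].nunique())


def _cell_noise(cfg: StudyConfig, subj_idx: int, rater_idx: int,
                occ_idx: int, size: int) -> np.ndarray:
    """Seeded subjective score perturbation for one manifest cell.

    The rater stream depends only on (seed, subject, rater); the
    occasion stream also on the occasion, so two occasions of one rater
    share the larger component.
    """
    rater_rng = np.random.default_rng([cfg.seed, subj_idx, rater_idx, 1009])
    occ_rng = np.random.default_rng([cfg.seed, subj_idx, rater_idx, occ_idx, 2003])
    return rater_rng.normal(0.0, cfg.rater_noise_sd, size) + occ_rng.normal(
        0.0, cfg.occasion_noise_sd, size
    )


def _analyze_subject(
    series: RRiSeries,
    subj_idx: int,
    raters: list,
    cfg: StudyConfig,
) -> tuple[dict | None, list, str | None]:
    """All four cells of one subject; returns (cells, log rows, discard reason)."""
    labeled = detect_ectopic(series, cfg.ectopic_threshold, cfg.ectopic_local_window)
    decision = apply_discard_rule(labeled, cfg.max_ectopic_frac)
    if not decision.accept:
        return None, [], decision.reason
    anchor = select_best_segment(
        labeled, cfg.segment_length, cfg.stride, cfg.weights
    )
    n_candidates = 2 * cfg.jitter_beats + 1
    cells, log_rows = {}, []
    index_cache: dict[int, dict] = {}
    for rater_idx, rater in enumerate(raters):
        for occ_idx, occasion in enumerate(OCCASIONS):
            if cfg.jitter_beats == 0:
                sel = anchor
            else:
                noise = _cell_noise(cfg, subj_idx, rater_idx, occ_idx, n_candidates)
                sel = jittered_selection(
                    labeled, anchor.start_index, cfg.jitter_beats,
                    noise=noise, length=cfg.segment_length, weights=cfg.weights,
                )
            if sel.start_index not in index_cache:
                index_cache[sel.start_index] = compute_indices(sel.window).as_dict()
            cells[(rater, occasion)] = index_cache[sel.start_index]
            log_rows.append(
                {
                    "rater": rater,
                    "occasion": occasion,
                    "start_index": sel.start_index,
                    "composite": sel.quality["composite"],
                    "ectopic_fraction": decision.fraction,
                }
            )
    return cells, log_rows, None


def _assemble(
    subject_cells: dict,
    raters: list,
    excluded: list,
    log_rows: list,
) -> StudyResult:
    if len(subject_cells) < 2:
        raise ValueError("fewer than 2 subjects with complete cells")
    subjects = sorted(subject_cells)
    r1, r2 = raters[0], raters[1]

    desc_rows = []
    for rater in raters:
        for occasion in OCCASIONS:
            vals = pd.DataFrame(
                [subject_cells[s][(rater, occasion)] for s in subjects]
            )
            for name in INDEX_NAMES:
                desc_rows.append(
                    {
                        "index": name, "rater": rater, "occasion": occasion,
                        "mean": vals[name].mean(), "sd": vals[name].std(ddof=1),
                    }
                )
    descriptives = pd.DataFrame(desc_rows)

    def table(cell_a, cell_b, comparison):
        rows, points = [], []
        for name in INDEX_NAMES:
            values = np.array(
                [
                    [subject_cells[s][cell_a][name], subject_cells[s][cell_b][name]]
                    for s in subjects
                ]
            )
            ratings = RatingsMatrix(values, index_name=name, comparison=comparison)
            rows.append(reliability_report(ratings).as_row())
            for s, (x1, x2) in zip(subjects, values):
                points.append(
                    {
                        "comparison": comparison, "index": name, "subject_id": s,
                        "mean": (x1 + x2) / 2, "difference": x1 - x2,
                    }
                )
        return pd.DataFrame(rows, columns=REPORT_COLUMNS), points

    all_points = []
    intra = {}
    for rater in (r1, r2):
        tab, pts = table((rater, "test"), (rater, "retest"), f"intrarater-{rater}")
        intra[rater] = tab
        all_points.extend(pts)
    inter, pts = table((r1, "test"), (r2, "test"), "interrater")
    all_points.extend(pts)

    return StudyResult(
        descriptives=descriptives,
        intrarater=intra,
        interrater=inter,
        bland_altman_points=pd.DataFrame(all_points),
        excluded=excluded,
        log=pd.DataFrame(log_rows),
    )


def run_study(layout: StudyLayout) -> StudyResult:
    """Run the full reliability study from a file manifest.

    Subjects with incomplete cells or recordings failing the ectopic
    discard rule are excluded listwise.
    """
    cfg = layout.config
    m = layout.manifest
    raters = sorted(m["rater"].unique())
    if len(raters) != 2:
        raise ValueError("study requires exactly 2 raters")
    subject_cells, excluded, log_rows = {}, [], []
    for subj_idx, (subject, grp) in enumerate(sorted(m.groupby("subject_id"))):
        cells_present = set(zip(grp["rater"], grp["occasion"]))
        needed = {(r, o) for r in raters for o in OCCASIONS}
        if cells_present != needed:
            excluded.append((subject, "incomplete manifest cells"))
            continue
        paths = set(grp["path"])
        if len(paths) == 1:
            # one shared recording re-analyzed per cell (re-analysis layout)
            series = read_rri_txt(paths.pop())
            cells, rows, reason = _analyze_subject(series, subj_idx, raters, cfg)
        else:
            # distinct recordings per cell (re-recording layout): each file
            # is analyzed deterministically, variation lives in the data
            cells, rows, reason = {}, [], None
            for _, row in grp.iterrows():
                series = read_rri_txt(row["path"])
                labeled = detect_ectopic(
                    series, cfg.ectopic_threshold, cfg.ectopic_local_window
                )
                decision = apply_discard_rule(labeled, cfg.max_ectopic_frac)
                if not decision.accept:
                    cells, reason = None, decision.reason
                    break
                sel = select_best_segment(
                    labeled, cfg.segment_length, cfg.stride, cfg.weights
                )
                cells[(row["rater"], row["occasion"])] = compute_indices(
                    sel.window
                ).as_dict()
                rows.append(
                    {
                        "rater": row["rater"], "occasion": row["occasion"],
                        "start_index": sel.start_index,
                        "composite": sel.quality["composite"],
                        "ectopic_fraction": decision.fraction,
                    }
                )
        if cells is None:
            excluded.append((subject, reason))
            continue
        subject_cells[subject] = cells
        for r in rows:
            log_rows.append({"subject_id": subject, **r})
    return _assemble(subject_cells, raters, excluded, log_rows)


def run_synthetic_study(
    n_subjects: int = 40,
    seed: int = 7,
    jitter_beats: int = 16,
    config: StudyConfig | None = None,
    ectopic_rate: float = 0.0,
) -> StudyResult:
    """Generate and analyze a fully synthetic two-rater study in memory."""
    cfg = config or StudyConfig()
    cfg.jitter_beats = jitter_beats
    cfg.seed = seed
    pop_rng = np.random.default_rng(seed)
    subject_cells, excluded, log_rows = {}, [], []
    for subj_idx in range(n_subjects):
        params = sample_subject_params(pop_rng, ectopic_rate=ectopic_rate)
        series = generate_rri(params)
        cells, rows, reason = _analyze_subject(
            series, subj_idx, ["R1", "R2"], cfg
        )
        subject = f"S{subj_idx:03d}"
        if cells is None:
            excluded.append((subject, reason))
            continue
        subject_cells[subject] = cells
        for r in rows:
            log_rows.append({"subject_id": subject, **r})
    return _assemble(subject_cells, ["R1", "R2"], excluded, log_rows)


def write_synthetic_study(
    outdir, n_subjects: int = 40, seed: int = 7, ectopic_rate: float = 0.0
) -> pd.DataFrame:
    """Write per-subject Polar-style .txt recordings plus a manifest.

    All four cells of a subject reference the same recording (the
    re-analysis layout); returns the manifest DataFrame, also saved as
    ``manifest.csv`` next to the recordings.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pop_rng = np.random.default_rng(seed)
    rows = []
    for subj_idx in range(n_subjects):
        params = sample_subject_params(pop_rng, ectopic_rate=ectopic_rate)
        series = generate_rri(params)
        path = outdir / f"S{subj_idx:03d}.txt"
        write_rri_txt(series, path)
        for rater in ("R1", "R2"):
            for occasion in OCCASIONS:
                rows.append(
                    {
                        "subject_id": f"S{subj_idx:03d}", "rater": rater,
                        "occasion": occasion, "path": str(path),
                    }
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
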