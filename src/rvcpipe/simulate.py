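"""Synthetic longitudinal athlete cohort with linked telemetry.

Emulates the study design the analysis assumes: a collision-sport cohort
(CSA; football and soccer) imaged at Pre/In1/In2/Post1/Post2 with a
Post3 subset, a non-collision control cohort (NCA) imaged Test/Retest,
and per-athlete head-acceleration telemetry across the season.

Generative model
----------------
Observed ROI volume for athlete j, ROI i, session k:

    Vol = scale_j * atlas_i * effect(i, j, k) * session_noise * roi_noise

* ``scale_j`` — per-athlete global head-size factor, lognormal.
* ``atlas_i`` — parcellation voxel count times voxel volume.
* ``effect`` — 1 plus the injected fractional change: a concave-up
  per-session gray-matter trajectory (zero at Pre, most negative at
  Post1, zero again at Post3) and a ventricular-CSF increase linear in
  the athlete's cumulative count of events above a latent PTA threshold
  (reverting to baseline at Post2/Post3).  WM and CSF carry no effect.
* ``session_noise`` — lognormal scan-to-scan global scale jitter shared
  by all ROIs of one scan (positioning/registration-like error).
* ``roi_noise`` — independent lognormal measurement noise per ROI.

Both noise terms are mean-one, and follow-up sessions carry a
deterministic correction factor cancelling the lognormal ratio bias so
that the *expected* relative volume change of a follow-up equals the
injected fractional effect exactly.

Telemetry is Poisson events per activity window with lognormal PTA
magnitudes, pooled HITS (football) and xPatch (soccer) sensors, a small
fraction of spurious out-of-window events, and optional athletes with
incomplete records (encoder failure mid-season), always drawn from the
football subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exposure import (
    DEFAULT_THRESHOLDS,
    EXPOSURE_SESSIONS,
    ExposureMatrix,
    count_nhae,
    prune_events,
)
from .parcellation import ParcellationSpec, Roi
from .volumes import CSA_SESSIONS, NCA_SESSIONS, VOLUME_COLUMNS, validate_volume_table

#: Concave-up per-session fractional GM trajectory (zero at Pre and
#: Post3, most negative shortly after the season at Post1).
DEFAULT_GM_TRAJECTORY: Mapping[str, float] = {
    "Pre": 0.0,
    "In1": -0.0089,
    "In2": -0.0180,
    "Post1": -0.0244,
    "Post2": -0.0001,
    "Post3": 0.0,
}

SEASON_START = pd.Timestamp("2023-08-01")
INTERVAL_DAYS = 30  # days between consecutive imaging sessions


@dataclass(frozen=True)
class CohortDesign:
    """Roster and schedule of the simulated study."""

    n_csa_football: int = 38
    n_csa_soccer: int = 19
    n_nca: int = 29
    sessions_csa: tuple[str, ...] = CSA_SESSIONS
    sessions_nca: tuple[str, ...] = NCA_SESSIONS
    post3_subset_size: int = 21
    n_incomplete_hae: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        n_csa = self.n_csa_football + self.n_csa_soccer
        if self.post3_subset_size > n_csa:
            raise ValueError("post3_subset_size exceeds CSA cohort size")
        if self.n_incomplete_hae > self.n_csa_football:
            raise ValueError("incomplete-telemetry athletes are drawn from football only")

    @property
    def n_csa(self) -> int:
        return self.n_csa_football + self.n_csa_soccer

    def roster(self) -> pd.DataFrame:
        """Athlete table: id, group, sex, sport (football male, soccer
        female; controls split ~half and half)."""
        rows = []
        for i in range(self.n_csa_football):
            rows.append((f"CSA-F{i + 1:02d}", "CSA", "M", "football"))
        for i in range(self.n_csa_soccer):
            rows.append((f"CSA-S{i + 1:02d}", "CSA", "F", "soccer"))
        n_m = self.n_nca // 2 + self.n_nca % 2
        for i in range(self.n_nca):
            sex = "M" if i < n_m else "F"
            rows.append((f"NCA-{i + 1:02d}", "NCA", sex, "non-collision"))
        return pd.DataFrame(rows, columns=["athlete_id", "group", "sex", "sport"])


@dataclass(frozen=True)
class EffectModel:
    """Injected effects and noise levels (all fractional)."""

    gm_session_effect: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GM_TRAJECTORY)
    )
    dcsf_slope_per_event: float = 0.0025
    latent_threshold: float = 50.0
    noise_sd: float = 0.008
    session_scale_sd: float = 0.008
    subject_scale_sd: float = 0.10

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.session_scale_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.gm_session_effect.get("Pre", 0.0) != 0.0:
            raise ValueError("GM effect must be zero at the Pre baseline")


@dataclass(frozen=True)
class HaeGeneratorConfig:
    """Telemetry stream shape (placeholders, not study estimates)."""

    events_per_window_mean: float = 4.0
    pta_log_median: float = 25.0  # G; lognormal median of event PTA
    pta_log_sigma: float = 0.5  # lognormal shape
    windows_per_session_interval: int = 15
    out_of_window_rate: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.out_of_window_rate < 1.0):
            raise ValueError("out_of_window_rate must lie in [0, 1)")
        if self.pta_log_median <= 0 or self.pta_log_sigma <= 0:
            raise ValueError("PTA distribution parameters must be positive")

    def tail_mass(self, threshold_g: float) -> float:
        """P(PTA >= threshold) under the configured lognormal."""
        from scipy.stats import norm

        z = np.log(threshold_g / self.pta_log_median) / self.pta_log_sigma
        return float(norm.sf(z))


def default_parcellation(
    n_gm: int = 150, n_wm: int = 100, n_csf: int = 35, n_dcsf: int = 15, seed: int = 12345
) -> ParcellationSpec:
    """A 300-ROI synthetic standard-space parcellation.

    ROI voxel counts are drawn once from broad lognormals sized so tissue
    totals roughly match an adult template brain at 1 mm isotropic
    (GM ~600 cm3, WM ~500 cm3, CSF ~100 cm3, ventricles ~25 cm3).
    """
    rng = np.random.default_rng(seed)
    rois: list[Roi] = []
    next_id = 1
    for tissue, n, mean_vox in (("GM", n_gm, 4000), ("WM", n_wm, 5000),
                                ("CSF", n_csf, 3000), ("dCSF", n_dcsf, 1600)):
        sizes = np.maximum(rng.lognormal(np.log(mean_vox), 0.4, size=n), 50).astype(int)
        for s in sizes:
            rois.append(Roi(next_id, tissue, int(s)))
            next_id += 1
    return ParcellationSpec(rois=rois)


def session_schedule(design: CohortDesign) -> dict[str, pd.Timestamp]:
    """Scan times: Pre at season start, later sessions 30 days apart."""
    return {
        s: SEASON_START + pd.Timedelta(days=INTERVAL_DAYS * i)
        for i, s in enumerate(design.sessions_csa)
    }


def activity_windows(config: HaeGeneratorConfig) -> pd.DataFrame:
    """Practice/game windows, evenly spread over the three in-season
    intervals (Pre->In1, In1->In2, In2->Post1); each lasts 2 hours."""
    if config.windows_per_session_interval <= 0:
        raise ValueError("at least one activity window per interval is required")
    rows = []
    wid = 0
    for interval in range(3):
        t0 = interval * INTERVAL_DAYS
        step = INTERVAL_DAYS / config.windows_per_session_interval
        for w in range(config.windows_per_session_interval):
            start = SEASON_START + pd.Timedelta(days=t0 + w * step, hours=16)
            rows.append((f"W{wid:03d}", start, start + pd.Timedelta(hours=2)))
            wid += 1
    return pd.DataFrame(rows, columns=["window_id", "start", "end"])


@dataclass
class SimulatedTelemetry:
    """Raw telemetry bundle: observed events (with gaps for incomplete
    athletes), the complete underlying stream, windows, and flags."""

    events: pd.DataFrame
    events_complete: pd.DataFrame
    windows: pd.DataFrame
    session_cutoffs: dict[str, pd.Timestamp]
    incomplete: list[str]


def simulate_hae(
    design: CohortDesign,
    config: HaeGeneratorConfig = HaeGeneratorConfig(),
    rng: np.random.Generator | None = None,
) -> SimulatedTelemetry:
    """Generate the per-athlete HAE event stream.

    Event counts per (athlete, window) are Poisson; PTA magnitudes are
    lognormal; a configurable fraction of events is spurious
    (out-of-window timestamps).  Incomplete-telemetry athletes (football
    only) lose all events from a mid-season window onward in the
    *observed* stream; the complete stream is retained for generating
    volumes, since the athlete experienced the events regardless of
    whether the sensor recorded them.
    """
    if design.n_csa < 1:
        raise ValueError("telemetry simulation needs at least one CSA athlete")
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    roster = design.roster()
    csa = roster[roster["group"] == "CSA"]
    windows = activity_windows(config)
    schedule = session_schedule(design)
    cutoffs = {s: schedule[s] for s in EXPOSURE_SESSIONS if s in schedule}

    starts = windows["start"].to_numpy()
    n_win = len(windows)
    rows: list[pd.DataFrame] = []
    for _, athlete in csa.iterrows():
        counts = rng.poisson(config.events_per_window_mean, size=n_win)
        total = int(counts.sum())
        if total == 0:
            continue
        win_idx = np.repeat(np.arange(n_win), counts)
        offsets_h = rng.uniform(0.0, 2.0, size=total)
        spurious = rng.random(total) < config.out_of_window_rate
        # spurious events drift outside the window (earlier the same day)
        offsets_h[spurious] = -rng.uniform(1.0, 8.0, size=int(spurious.sum()))
        times = starts[win_idx] + (offsets_h * 3.6e12).astype("timedelta64[ns]")
        pta = rng.lognormal(np.log(config.pta_log_median), config.pta_log_sigma, size=total)
        sensor = "HITS" if athlete["sport"] == "football" else "xPatch"
        rows.append(
            pd.DataFrame(
                {
                    "athlete_id": athlete["athlete_id"],
                    "timestamp": times,
                    "pta_g": pta,
                    "window_id": np.where(spurious, "", windows["window_id"].to_numpy()[win_idx]),
                    "sensor": sensor,
                }
            )
        )
    complete_events = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["athlete_id", "timestamp", "pta_g", "window_id", "sensor"])
    )

    football_ids = csa.loc[csa["sport"] == "football", "athlete_id"].to_numpy()
    incomplete = list(
        rng.choice(football_ids, size=design.n_incomplete_hae, replace=False)
    ) if design.n_incomplete_hae else []
    observed = complete_events
    if incomplete:
        drop = pd.Series(False, index=complete_events.index)
        for athlete in incomplete:
            fail_from = windows["start"].iloc[int(rng.integers(n_win // 3, n_win))]
            drop |= (complete_events["athlete_id"] == athlete) & (
                complete_events["timestamp"] >= fail_from
            )
        observed = complete_events[~drop].reset_index(drop=True)
    return SimulatedTelemetry(
        events=observed,
        events_complete=complete_events,
        windows=windows,
        session_cutoffs=cutoffs,
        incomplete=incomplete,
    )


def true_exposure(
    telemetry: SimulatedTelemetry,
    design: CohortDesign,
    thresholds=DEFAULT_THRESHOLDS,
) -> ExposureMatrix:
    """Exposure matrix from the complete (ground-truth) event stream."""
    pruned, _ = prune_events(telemetry.events_complete, telemetry.windows)
    roster = design.roster()
    csa_ids = roster.loc[roster["group"] == "CSA", "athlete_id"]
    return count_nhae(
        pruned,
        telemetry.session_cutoffs,
        thresholds=thresholds,
        athletes=csa_ids,
        complete={a: a not in set(telemetry.incomplete) for a in csa_ids},
    )


def simulate_volumes(
    design: CohortDesign,
    parcellation: ParcellationSpec,
    effects: EffectModel,
    exposure: ExposureMatrix,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate the longitudinal ROI volume table.

    ``exposure`` must cover every CSA athlete at every exposure session
    (use :func:`true_exposure`; the latent dCSF effect follows the
    athlete's actual events, not the possibly gappy observed record).
    The latent threshold must be on the exposure grid.
    """
    rng = rng if rng is not None else np.random.default_rng(design.seed + 1)
    if effects.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if effects.latent_threshold not in exposure.thresholds:
        raise ValueError(
            f"latent threshold {effects.latent_threshold} G not on the exposure grid"
        )
    roster = design.roster()
    parc = parcellation.frame
    atlas_mm3 = (parc["voxel_count"] * parcellation.voxel_volume).to_numpy(dtype=float)
    roi_ids = parc["roi_id"].to_numpy()
    tissue = parc["tissue"].to_numpy()
    n_roi = len(roi_ids)

    # latent cumulative counts above the latent threshold, per CSA athlete
    latent: dict[str, dict[str, float]] = {}
    for s in EXPOSURE_SESSIONS:
        col = exposure.wide(s, effects.latent_threshold)
        for a, c in col.items():
            latent.setdefault(a, {})[s] = float(c)
    csa_ids = roster.loc[roster["group"] == "CSA", "athlete_id"]
    for a in csa_ids:
        missing = [s for s in EXPOSURE_SESSIONS if s not in latent.get(a, {})]
        if missing:
            raise ValueError(f"exposure matrix lacks sessions {missing} for CSA athlete {a}")

    post3_ids = set(
        rng.choice(csa_ids.to_numpy(), size=design.post3_subset_size, replace=False)
    ) if design.post3_subset_size else set()

    sd_r, sd_g = effects.noise_sd, effects.session_scale_sd
    bias_correction = np.exp(-(sd_r**2 + sd_g**2))  # cancels lognormal ratio bias

    is_gm = tissue == "GM"
    is_dcsf = tissue == "dCSF"
    cols: dict[str, list] = {c: [] for c in VOLUME_COLUMNS}
    vols: list[np.ndarray] = []
    for athlete in roster.itertuples(index=False):
        aid, group = athlete.athlete_id, athlete.group
        scale = np.exp(rng.normal(0.0, effects.subject_scale_sd))
        sessions = design.sessions_csa if group == "CSA" else design.sessions_nca
        sessions = tuple(
            s for s in sessions if not (s == "Post3" and aid not in post3_ids)
        )
        baseline = sessions[0]
        for s in sessions:
            effect = np.ones(n_roi)
            if group == "CSA":
                effect[is_gm] = 1.0 + effects.gm_session_effect.get(s, 0.0)
                if s in EXPOSURE_SESSIONS:
                    effect[is_dcsf] = 1.0 + effects.dcsf_slope_per_event * latent[aid][s]
            g = np.exp(rng.normal(0.0, sd_g) - sd_g**2 / 2.0) if sd_g > 0 else 1.0
            e = (
                np.exp(rng.normal(0.0, sd_r, size=n_roi) - sd_r**2 / 2.0)
                if sd_r > 0
                else 1.0
            )
            vol = scale * atlas_mm3 * effect * g * e
            if s != baseline and (sd_r > 0 or sd_g > 0):
                vol = vol * bias_correction
            cols["athlete_id"].append(aid)
            cols["group"].append(group)
            cols["sex"].append(athlete.sex)
            cols["sport"].append(athlete.sport)
            cols["session"].append(s)
            vols.append(np.asarray(vol, dtype=float).reshape(-1))
    n_blocks = len(vols)
    table = pd.DataFrame(
        {
            "athlete_id": np.repeat(cols["athlete_id"], n_roi),
            "group": np.repeat(cols["group"], n_roi),
            "sex": np.repeat(cols["sex"], n_roi),
            "sport": np.repeat(cols["sport"], n_roi),
            "session": np.repeat(cols["session"], n_roi),
            "roi_id": np.tile(roi_ids, n_blocks),
            "volume_mm3": np.concatenate(vols),
        }
    )
    return validate_volume_table(table)


@dataclass
class SimulatedCohort:
    """Everything one study replicate produces."""

    design: CohortDesign
    parcellation: ParcellationSpec
    effects: EffectModel
    volumes: pd.DataFrame
    telemetry: SimulatedTelemetry
    exposure_true: ExposureMatrix


def simulate_cohort(
    design: CohortDesign = CohortDesign(),
    parcellation: ParcellationSpec | None = None,
    effects: EffectModel = EffectModel(),
    hae_config: HaeGeneratorConfig = HaeGeneratorConfig(),
    seed: int | None = None,
) -> SimulatedCohort:
    """One full study replicate: telemetry, exposure, and volumes.

    ``seed`` overrides the design's seed; one generator drives every
    random draw, so identical seeds give bit-identical tables.
    """
    if seed is not None:
        design = CohortDesign(**{**design.__dict__, "seed": int(seed)})
    rng = np.random.default_rng(design.seed)
    parcellation = parcellation if parcellation is not None else default_parcellation()
    telemetry = simulate_hae(design, hae_config, rng=rng)
    exposure = true_exposure(telemetry, design)
    volumes = simulate_volumes(design, parcellation, effects, exposure, rng=rng)
    return SimulatedCohort(
        design=design,
        parcellation=parcellation,
        effects=effects,
        volumes=volumes,
        telemetry=telemetry,
        exposure_true=exposure,
    )
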