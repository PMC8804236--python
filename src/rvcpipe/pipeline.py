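"""End-to-end orchestration with validated config and deterministic outputs.

Stage order mirrors the analysis plan: volumes -> relative changes ->
exposure counting -> sex check -> sphericity/normality -> rANOVA ->
post-hoc matrices -> threshold screen -> linear fits -> deviation maps.
Every run writes tidy CSVs, a plain-text report, and a run-info record
carrying the seed and a hash of the resolved configuration; reruns with
the same config and seed are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import change, deviation, exposure, simulate, stats
from .parcellation import load_parcellation
from .volumes import read_volume_table


class AnalysisConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    simulate: bool = True
    seed: int = 0
    # input paths (required when simulate is off)
    volumes: str | None = None
    events: str | None = None
    windows: str | None = None
    parcellation: str | None = None
    session_cutoffs: dict[str, str] | None = None
    # analysis settings
    baselines: dict[str, str] = {"CSA": "Pre", "NCA": "Test"}
    thresholds: list[float] = list(exposure.DEFAULT_THRESHOLDS)
    screen_tissues: list[str] | None = None
    family_within: int | None = None
    family_across: int | None = None
    family_screen: int | None = None
    reference_method: str = "population"
    welch: bool = False
    greenhouse_geisser: bool = False

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> AnalysisConfig:
    payload = yaml.safe_load(Path(path).read_text()) or {}
    return AnalysisConfig(**payload)


def run_all(config: AnalysisConfig, outdir: str | Path) -> Path:
    """Run the full pipeline; returns the results directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)

    if config.simulate:
        cohort = simulate.simulate_cohort(seed=config.seed)
        parc = cohort.parcellation
        volumes = cohort.volumes
        events = cohort.telemetry.events
        windows = cohort.telemetry.windows
        cutoffs = cohort.telemetry.session_cutoffs
        incomplete = list(cohort.telemetry.incomplete)
        volumes.to_csv(outdir / "volumes.csv", index=False)
        events.to_csv(outdir / "events.csv", index=False)
        note(f"simulated cohort: {volumes['athlete_id'].nunique()} athletes, "
             f"{len(events)} raw telemetry events, seed {config.seed}")
    else:
        for name in ("volumes", "events", "windows", "parcellation", "session_cutoffs"):
            if getattr(config, name) is None:
                raise ValueError(f"config must set {name!r} when simulate is off")
        parc = load_parcellation(config.parcellation)
        volumes = read_volume_table(config.volumes)
        events = exposure.read_events(config.events)
        windows = pd.read_csv(config.windows)
        cutoffs = {k: pd.Timestamp(v) for k, v in config.session_cutoffs.items()}
        incomplete = []
        note(f"loaded {len(volumes)} volume records, {len(events)} events")

    # relative change levels
    rrvc = change.compute_rrvc(volumes, config.baselines)
    rtvc = change.compute_rtvc(rrvc, parc)
    rbvc = change.compute_rbvc(rtvc, parc)
    rrvc.to_csv(outdir / "rrvc.csv", index=False)
    rtvc.to_csv(outdir / "rtvc.csv", index=False)
    rbvc.to_csv(outdir / "rbvc.csv", index=False)
    note(f"relative change: {len(rrvc)} rRVC, {len(rtvc)} rTVC, {len(rbvc)} rBVC rows")

    # exposure
    pruned, prune_log = exposure.prune_events(events, windows)
    complete_flags = {a: a not in set(incomplete) for a in pd.unique(pruned["athlete_id"])}
    matrix = exposure.count_nhae(
        pruned, cutoffs, thresholds=config.thresholds, complete=complete_flags
    )
    matrix_used, excluded = exposure.exclude_incomplete(matrix)
    exposure.write_exposure(matrix_used, outdir / "nhae.csv")
    note(f"pruning: {prune_log.n_raw} raw, {prune_log.n_out_of_window} out-of-window, "
         f"{prune_log.n_below_threshold} below 20 G, {prune_log.n_retained} retained")
    note(f"exposure: {matrix.n_athletes} athletes, {len(excluded)} excluded as incomplete "
         f"({excluded}), {matrix_used.n_athletes} analyzed")

    csa_rtvc = rtvc[rtvc["group"] == "CSA"]
    nca_rtvc = rtvc[rtvc["group"] == "NCA"]

    # sex-effect check on the controls
    sex_rows = []
    for tissue, res in stats.sex_effect_check(nca_rtvc, welch=config.welch).items():
        sex_rows.append({"tissue": tissue, "t": res.statistic, "df": res.df[0],
                         "p_raw": res.p_raw, "significant": res.significant})
    pd.DataFrame(sex_rows).to_csv(outdir / "sex_check.csv", index=False)

    # preliminary checks + rANOVA per tissue over the four follow-ups
    prelim_rows, ranova_rows = [], []
    for tissue in parc.tissues:
        sub = csa_rtvc[csa_rtvc["tissue"] == tissue]
        comp = stats.complete_cases(sub, stats.RANOVA_SESSIONS)
        n_complete = comp["athlete_id"].nunique()
        mau = stats.mauchly_test(comp)
        ks = stats.ks_normality(
            comp.loc[comp["session"] == "Post1", "rtvc"].to_numpy(),
            name=f"ks {tissue} Post1",
        )
        prelim_rows.append({"tissue": tissue, "mauchly_w": mau.statistic,
                            "mauchly_p": mau.p_raw, "ks_d": ks.statistic,
                            "ks_p": ks.p_raw, "n": n_complete})
        rres = stats.rm_anova(comp, greenhouse_geisser=config.greenhouse_geisser)
        ranova_rows.append({"tissue": tissue, "F": rres.statistic,
                            "df1": rres.df[0], "df2": rres.df[1],
                            "p_raw": rres.p_raw, "n": n_complete,
                            "note": rres.note})
    pd.DataFrame(prelim_rows).to_csv(outdir / "preliminary.csv", index=False)
    pd.DataFrame(ranova_rows).to_csv(outdir / "ranova.csv", index=False)

    # post-hoc pairwise matrices
    posthoc = pd.concat(
        [
            stats.posthoc_matrix(
                csa_rtvc, nca_rtvc, tissue,
                m_within=config.family_within, m_across=config.family_across,
                welch=config.welch,
            ).to_frame()
            for tissue in parc.tissues
        ],
        ignore_index=True,
    )
    posthoc.to_csv(outdir / "posthoc.csv", index=False)

    # exposure screen + linear predictors for significant cells
    screen = stats.screen_correlation(
        csa_rtvc, matrix_used,
        tissues=config.screen_tissues, family_size=config.family_screen,
    )
    screen_df = stats.screen_to_frame(screen)
    screen_df.to_csv(outdir / "screen.csv", index=False)
    fit_rows = []
    for cell in screen:
        if not cell.significant:
            continue
        counts = matrix_used.wide(cell.session, cell.threshold_g)
        vals = csa_rtvc[
            (csa_rtvc["tissue"] == cell.tissue) & (csa_rtvc["session"] == cell.session)
        ].set_index("athlete_id")["rtvc"]
        common = vals.index.intersection(counts.index)
        fit = stats.fit_linear_predictor(
            counts.loc[common].to_numpy(), vals.loc[common].to_numpy()
        )
        lo, hi = fit.slope_ci()
        fit_rows.append({"tissue": cell.tissue, "session": cell.session,
                         "threshold_g": cell.threshold_g, "n": fit.n,
                         "slope": fit.slope, "intercept": fit.intercept,
                         "slope_ci_low": lo, "slope_ci_high": hi})
    pd.DataFrame(fit_rows, columns=["tissue", "session", "threshold_g", "n", "slope",
                                    "intercept", "slope_ci_low", "slope_ci_high"]
                 ).to_csv(outdir / "fits.csv", index=False)
    note(f"screen: {sum(s.significant for s in screen)} significant cells, "
         f"{len(fit_rows)} linear fits")

    # deviation maps (Post3 included when present)
    csa_rrvc = rrvc[rrvc["group"] == "CSA"]
    maps = deviation.build_deviation_maps(
        csa_rrvc, nca_rtvc, parc, method=config.reference_method
    )
    maps.to_frame().to_csv(outdir / "deviation_flags.csv", index=False)
    maps.flag_counts().to_csv(outdir / "deviation_counts.csv", index=False)
    refs = pd.DataFrame(
        [
            {"tissue": t, "lower": e.reference.lower, "upper": e.reference.upper,
             "n": e.reference.n, "method": e.reference.method}
            for (t, s), e in maps.entries.items() if s == "In1"
        ]
    )
    refs.to_csv(outdir / "reference_intervals.csv", index=False)

    run_info = {"config_hash": config.content_hash(), "seed": config.seed,
                "config": config.model_dump()}
    (outdir / "run_info.json").write_text(json.dumps(run_info, indent=2, default=str))
    (outdir / "report.txt").write_text("\n".join(log) + "\n")
    return outdir
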