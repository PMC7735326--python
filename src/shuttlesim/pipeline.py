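"""Top-level pipeline: simulate -> metrics -> analyze, reproducibly.

One master seed spawns named substreams (cohort simulation, surfacing assay,
bootstrap/permutation) so each stage is independently re-runnable.  All
artifacts are CSV/JSON text; the manifest records the config snapshot, seeds
and SHA-256 checksums sufficient for exact reproduction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, config_to_dict
from .inference import (
    asr_glm,
    compare_treatments,
    ramping_test_model,
    repeatability,
    smooth_difference,
    zip_compare,
)
from .metrics import body_temperature, detect_shuttles, summaries_to_frame, summarize
from .params import PHASES, TrackSeries, asr_trials_to_frame
from .sim import generate_asr, generate_cohort

__all__ = ["RunManifest", "run_pipeline", "shuttle_counts_per_bin",
           "binned_body_temperature"]

logger = logging.getLogger("shuttlesim")


@dataclass
class RunManifest:
    """Everything needed to reproduce a pipeline run byte-for-byte."""

    config: dict
    master_seed: int
    stage_seeds: dict
    artifacts: dict  # filename -> sha256
    version: str
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def shuttle_counts_per_bin(
    track: TrackSeries, phase: str = "test", bin_s: float = 60.0,
    deadband: float = 0.0,
) -> np.ndarray:
    """Shuttle counts per time bin (default 1 min) within a phase."""
    tr = track.truncated()
    events, _ = detect_shuttles(tr, deadband=deadband)
    mask = tr.phase == phase
    if not mask.any():
        return np.zeros(0, dtype=int)
    t_ph = tr.t[mask]
    t0, t1 = float(t_ph[0]), float(t_ph[-1])
    n_bins = max(int((t1 - t0 + (tr.t[1] - tr.t[0])) // bin_s), 1)
    edges = t0 + bin_s * np.arange(n_bins + 1)
    ev_t = [e.t for e in events if tr.phase[e.index] == phase]
    counts, _ = np.histogram(ev_t, bins=edges)
    return counts.astype(int)


def binned_body_temperature(
    track: TrackSeries, bin_s: float = 60.0
) -> tuple[np.ndarray, np.ndarray]:
    """(bin centers, mean body temperature per bin) over the whole trial."""
    bt = body_temperature(track)
    dt = float(track.t[1] - track.t[0]) if len(track) > 1 else 1.0
    per_bin = max(int(round(bin_s / dt)), 1)
    n_bins = len(track) // per_bin
    if n_bins < 1:
        raise ValueError("track shorter than one bin")
    tb = bt.T_B[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)
    tc = track.t[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)
    return tc, tb


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fmt_ci(lo: float, hi: float) -> str:
    return f"[{lo:.3f}, {hi:.3f}]"


def run_pipeline(config: RunConfig, seed: int, out_dir=None) -> RunManifest:
    """Execute simulate -> metrics -> analyze and write all artifacts.

    Writes ``tracks.csv``, ``truth.csv``, ``summaries.csv``, ``asr.csv``,
    ``results.csv``, ``report.txt`` and ``manifest.json`` under the output
    directory.  Identical (config, seed) runs produce identical CSV bytes.
    """
    out = Path(out_dir if out_dir is not None else config.output.directory)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    sim_ss, asr_ss, boot_ss = ss.spawn(3)
    stage_seeds = {
        "simulate": "master.spawn[0]",
        "asr": "master.spawn[1]",
        "repeatability": "master.spawn[2]",
    }
    logger.info("pipeline start: seed=%d out=%s", seed, out)

    # ---- simulate -------------------------------------------------------
    try:
        tracks, truth = generate_cohort(config.population, config.trial, sim_ss)
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError("simulate", str(e)) from e
    n_ctl = config.population.n_control
    n_trt = config.population.n_treated
    logger.info("simulated cohort: n_control=%d n_treated=%d", n_ctl, n_trt)
    n_quiet = int(truth["quiescent_from_s"].notna().sum())
    if n_quiet:
        logger.info("%d fish entered quiescence", n_quiet)
    tracks_df = pd.concat([t.to_frame() for t in tracks], ignore_index=True)
    tracks_path = out / "tracks.csv"
    tracks_df.to_csv(tracks_path, index=False)
    truth_path = out / "truth.csv"
    truth.to_csv(truth_path, index=False)

    # ---- metrics --------------------------------------------------------
    try:
        mo = config.metrics
        summaries = []
        for t in tracks:
            summaries.extend(
                summarize(
                    t,
                    deadband=mo.deadband_cm,
                    surface_threshold=mo.surface_threshold,
                    velocity_floor=mo.velocity_floor,
                    box_height=config.trial.box_height_cm,
                )
            )
    except Exception as e:  # noqa: BLE001
        raise StageError("metrics", str(e)) from e
    sdf = summaries_to_frame(summaries)
    n_undef = int(sdf[["LET_C", "UET_C"]].isna().sum().sum())
    if n_undef:
        logger.info("%d undefined escape-temperature entries flagged", n_undef)
    summaries_path = out / "summaries.csv"
    sdf.to_csv(summaries_path, index=False)

    # ---- analyze --------------------------------------------------------
    results_rows: list[dict] = []
    report: list[str] = []
    io = config.inference

    def add_row(analysis, term, estimate, lo, hi, p, n):
        results_rows.append(
            {
                "analysis": analysis,
                "term": term,
                "estimate": estimate,
                "ci_low": lo,
                "ci_high": hi,
                "p": p,
                "n": n,
            }
        )

    try:
        report.append("== Treatment comparisons (test phase) ==")
        comparison_plan = [
            ("mean_T_B", "identity"),
            ("LET", "identity"),
            ("UET", "identity"),
            ("side_preference", "identity"),
            ("shuttle_rate", "log"),
            ("mean_log_velocity", "identity"),
        ]
        for metric, transform in comparison_plan:
            try:
                try:
                    res = compare_treatments(
                        sdf, metric, "test", transform=transform
                    )
                except ValueError as err:
                    if transform == "log" and "positive values" in str(err):
                        # zero rates (quiescent fish) cannot be logged
                        res = compare_treatments(sdf, metric, "test")
                        logger.warning(
                            "%s: log transform unavailable (%s); identity "
                            "used", metric, err,
                        )
                    else:
                        raise
            except ValueError as err:
                if "fewer than 2 defined values" in str(err):
                    # a metric can be legitimately undefined (e.g. no
                    # shuttles in a direction); flag it, do not abort
                    logger.warning("%s: skipped (%s)", metric, err)
                    report.append(f"{metric}: skipped ({err})")
                    continue
                raise
            add_row(
                "compare", f"{metric}[{res.transform}]", res.estimate,
                res.ci_low, res.ci_high, res.p_value,
                res.n_reference + res.n_treated,
            )
            report.append(
                f"{metric} ({res.transform}): effect {res.estimate:.3f} "
                f"CI {_fmt_ci(res.ci_low, res.ci_high)} p={res.p_value:.4g} "
                f"(n={res.n_reference}+{res.n_treated})"
            )
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("analyze:compare", str(e)) from e

    try:
        report.append("")
        report.append("== Ramping vs test set-point regression ==")
        reg = ramping_test_model(sdf)
        add_row("ramping_test", "slope", reg.slope, *reg.slope_ci,
                reg.slope_p, reg.n)
        add_row("ramping_test", "treatment_shift", reg.treatment_shift,
                *reg.shift_ci, reg.shift_p, reg.n)
        add_row("ramping_test", "interaction", reg.interaction,
                *reg.interaction_ci, reg.interaction_p, reg.n)
        report.append(
            f"slope {reg.slope:.3f} CI {_fmt_ci(*reg.slope_ci)} "
            f"p={reg.slope_p:.4g}"
        )
        report.append(
            f"treatment intercept shift {reg.treatment_shift:.3f} "
            f"CI {_fmt_ci(*reg.shift_ci)} p={reg.shift_p:.4g}"
        )
        report.append(
            f"interaction {reg.interaction:.3f} "
            f"CI {_fmt_ci(*reg.interaction_ci)} p={reg.interaction_p:.4g}"
        )
        report.append(f"set-point-shift verdict: {reg.set_point_shift_verdict}")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("analyze:ramping_test", str(e)) from e

    try:
        report.append("")
        report.append("== Repeatability (control, ramping vs test mean T_B) ==")
        ctl = sdf[sdf["treatment"] == ("control" if "control" in
                                       set(sdf["treatment"]) else
                                       sorted(set(sdf["treatment"]))[0])]
        wide = ctl.pivot_table(index="fish_id", columns="phase",
                               values="mean_TB_C", aggfunc="first")
        pairs = wide[["ramping", "test"]].dropna().to_numpy()
        rpt = repeatability(pairs, n_boot=io.n_boot, n_perm=io.n_perm,
                            seed=boot_ss)
        add_row("repeatability", "R", rpt.R, rpt.ci_low, rpt.ci_high,
                rpt.p_value, rpt.n_individuals)
        report.append(
            f"R = {rpt.R:.3f} CI {_fmt_ci(rpt.ci_low, rpt.ci_high)} "
            f"p={rpt.p_value:.4g} (n={rpt.n_individuals} fish)"
        )
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("analyze:repeatability", str(e)) from e

    try:
        report.append("")
        report.append("== Body-temperature time-course difference smooth ==")
        grids = [binned_body_temperature(t, bin_s=io.smooth_bin_s)
                 for t in tracks]
        times = grids[0][0]
        tb = np.vstack([g[1] for g in grids])
        labels = [t.treatment for t in tracks]
        basis = min(io.basis_dim, max(4, len(times) - 2))
        fit = smooth_difference(tb, labels, times, rho=io.rho,
                                basis_dim=basis)
        inside = np.mean((fit.band_low <= 0) & (0 <= fit.band_high))
        add_row("smooth_difference", "mean_abs_difference",
                float(np.mean(np.abs(fit.difference))), math.nan, math.nan,
                math.nan, tb.shape[0])
        report.append(
            f"rho={fit.rho} lambda={fit.lam:.3g} edf={fit.edf:.1f}; "
            f"mean |difference| {np.mean(np.abs(fit.difference)):.3f} degC; "
            f"band covers 0 at {inside:.0%} of grid points"
        )
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("analyze:smooth_difference", str(e)) from e

    try:
        report.append("")
        report.append("== Zero-inflated Poisson shuttle-count model ==")
        counts = {
            lab: np.concatenate(
                [shuttle_counts_per_bin(t, bin_s=io.zip_bin_s,
                                        deadband=config.metrics.deadband_cm)
                 for t in tracks if t.treatment == lab]
            )
            for lab in sorted({t.treatment for t in tracks})
        }
        zc = zip_compare(counts)
        for lab, f in zc.fits.items():
            add_row("zip", f"lambda[{lab}]", f.lam, *f.lam_ci, math.nan, f.n)
            add_row("zip", f"pi[{lab}]", f.pi, *f.pi_ci, math.nan, f.n)
            report.append(
                f"{lab}: lambda={f.lam:.3f} CI {_fmt_ci(*f.lam_ci)}, "
                f"pi={f.pi:.3f} CI {_fmt_ci(*f.pi_ci)} "
                f"({f.n} bins{'; ' + ','.join(f.flags) if f.flags else ''})"
            )
        add_row("zip", "LR_stat", zc.lr_stat, math.nan, math.nan,
                zc.p_value, sum(f.n for f in zc.fits.values()))
        report.append(
            f"shared vs separate LRT: stat={zc.lr_stat:.2f} df={zc.df} "
            f"p={zc.p_value:.4g}"
        )
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("analyze:zip", str(e)) from e

    try:
        report.append("")
        report.append("== Aquatic surface respiration binomial GLM ==")
        trials = generate_asr(list(config.asr.design),
                              tuple(config.asr.coefficients), asr_ss)
        asr_path = out / "asr.csv"
        asr_trials_to_frame(trials).to_csv(asr_path, index=False)
        glm = asr_glm(trials)
        tab = glm.table()
        for _, r in tab.iterrows():
            add_row("asr_glm", r["term"], r["coef"], r["ci_low"],
                    r["ci_high"], r["p"], len(trials))
            report.append(
                f"{r['term']}: {r['coef']:.3f} log-odds "
                f"CI {_fmt_ci(r['ci_low'], r['ci_high'])} "
                f"OR {r['odds_ratio']:.2f} p={r['p']:.4g}"
            )
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("analyze:asr", str(e)) from e

    results_path = out / "results.csv"
    pd.DataFrame(results_rows).to_csv(results_path, index=False)
    report_path = out / "report.txt"
    report_path.write_text("\n".join(report) + "\n")

    from . import __version__

    artifacts = {
        p.name: _checksum(p)
        for p in (tracks_path, truth_path, summaries_path, asr_path,
                  results_path, report_path)
    }
    manifest = RunManifest(
        config=config_to_dict(config),
        master_seed=int(seed),
        stage_seeds=stage_seeds,
        artifacts=artifacts,
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    (out / "manifest.json").write_text(manifest.to_json())
    logger.info("pipeline complete: %d artifacts", len(artifacts))
    return manifest
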