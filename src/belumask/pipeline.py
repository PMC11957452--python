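"""End-to-end orchestration of the before/during/after experiment.

``run_full_pipeline`` simulates the configured noise events, runs the
noise-analysis chain (quiet snippets -> SSDL -> 1/3-octave -> signal excess
-> masking frequency -> summary) and the call-analysis chain (classify truth
selections -> count table -> NB GLMM -> Holm contrasts -> variance shares),
writes every intermediate product, and returns one machine-readable report.
Events in which no calls were produced are dropped from the rate analysis
and reported.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .calibration import pressure_to_digital
from .calls import ClassifierConfig, classify_selection
from .config import PipelineConfig
from .audio import write_wav
from .masking import masking_frequency, signal_excess, summarize_masking
from .rates import (
    fit_nb_glmm,
    pairwise_contrasts,
    pseudo_r2,
    records_to_frame,
    tabulate_rates,
)
from .selections import SelectionRecord, write_selection_table
from .spectral import concatenate_snippets, extract_noise_snippets, third_octave_levels, welch_ssdl

__all__ = ["run_full_pipeline", "scene_specs", "masking_for_scene"]

TREATMENTS = ("before", "during", "after")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _write_csv(frame: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    """Write a CSV with provenance comment lines (config hash and seed)."""
    with open(path, "w") as f:
        f.write(f"# config_hash={config.config_hash()}\n# seed={config.seed}\n")
        frame.to_csv(f, index=False)


def scene_specs(config: PipelineConfig) -> list[tuple[synth.EventSpec, float]]:
    """Event specs (and their vessel rolloffs) derived from the config seed."""
    children = np.random.SeedSequence(config.seed).spawn(config.n_events)
    dur = config.treatment_duration_s
    expected = {
        (tr, ct): config.rates_per_min.get(ct, {}).get(tr, 0.0) * dur / 60.0
        for tr in TREATMENTS
        for ct in ("CC", "HFBP", "OTHER")
    }
    # HFBP split between monophonic and biphonal; buzzes and whistles are
    # rendered too so the classifier's exclusion rules are exercised
    counts = {}
    for (tr, ct), mu in expected.items():
        if ct == "HFBP":
            counts[(tr, "HFBP_M")] = 0.6 * mu
            counts[(tr, "HFBP_B")] = 0.4 * mu
        elif ct == "OTHER":
            counts[(tr, "WHISTLE")] = mu
        else:
            counts[(tr, ct)] = mu
    specs = []
    for i, child in enumerate(children):
        specs.append(
            (
                synth.EventSpec(
                    event_id=f"event{i + 1:02d}",
                    seed=int(child.generate_state(1)[0] % 2**31),
                    sampling_rate_hz=config.sampling_rate_hz,
                    treatment_durations_s={t: dur for t in TREATMENTS},
                    expected_counts=counts,
                    nb_dispersion=config.nb_dispersion,
                    event_random_intercept_sd=config.event_sd,
                ),
                float(config.vessel_rolloffs_hz[i % len(config.vessel_rolloffs_hz)]),
            )
        )
    return specs


def masking_for_scene(scene: synth.SyntheticScene, uncertainty_db: float = 3.0):
    """Quiet snippets -> mean SSDL -> 1/3-octave -> excess -> f_down."""
    bands = {}
    ssdl = {}
    for tr in TREATMENTS:
        clip = scene.clips[tr]
        occupied = [(t["begin_s"], t["end_s"]) for t in scene.truth_for(tr)]
        windows = extract_noise_snippets(clip.duration_s, occupied)
        noise = concatenate_snippets(clip, windows)
        ssdl[tr] = welch_ssdl(noise)
        bands[tr] = third_octave_levels(ssdl[tr])
    excess = signal_excess(bands["during"], bands["before"], bands["after"])
    result = masking_frequency(excess, uncertainty_db=uncertainty_db, event_id=scene.event_id)
    return result, excess, bands, ssdl


def _classify_scene(scene: synth.SyntheticScene, config: ClassifierConfig):
    """Classify every truth selection; returns rows for rates + measurements."""
    rows = []
    for tr in TREATMENTS:
        clip = scene.clips[tr]
        entries = scene.truth_for(tr)
        for t in entries:
            sel = SelectionRecord(
                begin_s=t["begin_s"], end_s=t["end_s"],
                low_hz=t["low_hz"], high_hz=t["high_hz"],
            )
            # echolocation-adjacency context: another pulsed selection whose
            # span comes within the click-context window
            near = any(
                o is not t
                and o["call_class"] == "BUZZ"
                and o["begin_s"] < t["end_s"] + config.click_context_window_s
                and o["end_s"] > t["begin_s"] - config.click_context_window_s
                for o in entries
            )
            label, m, _ = classify_selection(clip, sel, near_click_train=near, config=config)
            rows.append(
                {
                    "event_id": scene.event_id,
                    "treatment": tr,
                    "true_class": t["call_class"],
                    "label": label,
                    "begin_s": t["begin_s"],
                    "end_s": t["end_s"],
                    **{f"{k}": getattr(m, k) for k in (
                        "low_freq_khz", "high_freq_khz", "delta_time_s", "peak_freq_khz",
                        "center_freq_khz", "q1_freq_khz", "q3_freq_khz",
                    )},
                    "delta_freq_khz": m.delta_freq_khz,
                }
            )
    return rows


def run_full_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the whole experiment; write intermediates; return the report."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    classifier = ClassifierConfig(**config.classifier)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_events": config.n_events,
        "stage_rows": {},  # per-stage input/output row counts
    }

    # ---- stage 1: simulate ------------------------------------------------
    try:
        scenes = []
        for spec, rolloff in scene_specs(config):
            scene = synth.render_event(
                spec,
                cal=config.calibration,
                ambient=synth.AmbientSpec(
                    config.ambient_level_db_at_1khz, config.ambient_slope_db_per_decade
                ),
                vessel_rolloff_hz=rolloff,
            )
            scenes.append(scene)
            if config.write_audio:
                ev_dir = out / "audio" / scene.event_id
                ev_dir.mkdir(parents=True, exist_ok=True)
                for tr, clip in scene.clips.items():
                    write_wav(
                        ev_dir / f"{tr}.wav",
                        pressure_to_digital(clip, config.calibration),
                        clip.fs,
                        config.calibration.bit_depth,
                    )
            write_selection_table(
                [
                    SelectionRecord(
                        begin_s=t["begin_s"], end_s=t["end_s"], low_hz=t["low_hz"],
                        high_hz=t["high_hz"], label=t["call_class"],
                        extras={"Treatment": t["treatment"]},
                    )
                    for t in scene.truth
                ],
                out / f"{scene.event_id}_truth.txt",
            )
        report["stage_rows"]["simulate"] = {
            "events": len(scenes),
            "truth_selections": sum(len(s.truth) for s in scenes),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(f"simulate: {e}") from e

    # ---- stage 2: noise analysis -----------------------------------------
    try:
        masking_rows = []
        excess_frames = []
        results = []
        for scene in scenes:
            result, excess, bands, _ = masking_for_scene(scene, config.uncertainty_db)
            results.append(result)
            masking_rows.append(
                {
                    "event_id": scene.event_id,
                    "rolloff_truth_hz": scene.vessel_rolloff_hz,
                    "f_down_hz": result.f_down,
                    "f_down_lower_hz": result.f_down_lower,
                    "full_band": result.full_band,
                }
            )
            excess_frames.append(
                pd.DataFrame(
                    {
                        "event_id": scene.event_id,
                        "center_hz": excess.centers,
                        "delta_db": excess.delta_db,
                        **{f"{tr}_level_db": bands[tr].levels for tr in TREATMENTS},
                    }
                )
            )
        _write_csv(pd.concat(excess_frames), out / "signal_excess.csv", config)
        _write_csv(pd.DataFrame(masking_rows), out / "masking.csv", config)
        defined = [r for r in results if not r.full_band]
        if defined:
            summary = summarize_masking(results)
            report["masking"] = {
                "mean_khz": summary.mean_hz / 1e3,
                "sd_khz": summary.sd_hz / 1e3,
                "percentiles_khz": {str(k): v / 1e3 for k, v in summary.percentiles_hz.items()},
                "n": summary.n,
                "n_full_band": summary.n_full_band,
            }
        else:
            report["masking"] = {"n": 0, "n_full_band": len(results)}
        report["stage_rows"]["noise_analysis"] = {
            "events_in": len(scenes),
            "excess_rows_out": int(sum(len(f) for f in excess_frames)),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(f"noise-analysis: {e}") from e

    # ---- stage 3: classification ------------------------------------------
    try:
        rows = []
        for scene in scenes:
            rows.extend(_classify_scene(scene, classifier))
        measurements = pd.DataFrame(rows)
        _write_csv(measurements, out / "call_measurements.csv", config)
        report["classification"] = {"n_selections": len(rows)}
        if rows:
            pooled = {"HFBP_M": "HFBP", "HFBP_B": "HFBP", "CC": "CC", "WHISTLE": "OTHER", "BUZZ": "BUZZ_EXCLUDED"}
            truth_pooled = measurements["true_class"].map(pooled)
            label_pooled = measurements["label"].map(lambda s: {"HFBP_M": "HFBP", "HFBP_B": "HFBP"}.get(s, s))
            report["classification"]["accuracy_pooled"] = float((truth_pooled == label_pooled).mean())
        report["stage_rows"]["classification"] = {
            "selections_in": sum(len(s.truth) for s in scenes),
            "measurements_out": len(rows),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(f"classification: {e}") from e

    # ---- stage 4: rate analysis -------------------------------------------
    try:
        durations = {
            (scene.event_id, tr): scene.clips[tr].duration_s
            for scene in scenes
            for tr in TREATMENTS
        }
        classified = [
            (r["event_id"], r["treatment"], r["label"])
            for r in rows
        ]
        records = tabulate_rates(classified, durations)
        frame = records_to_frame(records)
        totals = frame.groupby("event_id")["count"].sum()
        zero_events = sorted(totals[totals == 0].index)
        report["rates"] = {"dropped_zero_call_events": zero_events}
        keep = [r for r in records if r.event_id not in zero_events]
        frame = records_to_frame(keep)
        _write_csv(frame, out / "call_counts.csv", config)
        fit = fit_nb_glmm(keep)
        _write_csv(
            pd.DataFrame({"name": fit.names, "estimate": fit.beta, "se": fit.se, "z": fit.z}),
            out / "glmm_coefficients.csv", config,
        )
        contrasts = pairwise_contrasts(fit)
        _write_csv(pd.DataFrame([asdict(c) for c in contrasts]), out / "contrasts.csv", config)
        marg, rand, resid = pseudo_r2(fit)
        _write_csv(
            pd.DataFrame({"component": ["fixed", "random_event", "residual"], "percent": [marg, rand, resid]}),
            out / "pseudo_r2.csv", config,
        )
        report["rates"].update(
            {
                "n_events_modeled": int(frame["event_id"].nunique()),
                "converged": fit.converged,
                "theta": fit.theta,
                "sigma2_event": fit.sigma2_event,
                "coefficients": {n: float(b) for n, b in zip(fit.names, fit.beta)},
                "contrasts": [asdict(c) for c in contrasts],
                "pseudo_r2_percent": {"fixed": marg, "random_event": rand, "residual": resid},
            }
        )
        report["stage_rows"]["rate_analysis"] = {
            "selections_in": len(classified),
            "count_records_out": len(keep),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(f"rate-analysis: {e}") from e

    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=2, sort_keys=True)
    return report
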