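"""End-to-end pipeline: simulate -> preprocess -> decode -> rsa -> stats -> fuse.

A pipeline run is driven by one config mapping (YAML or JSON). Every source
of randomness derives from the mandatory master ``seed``, so rerunning the
same config reproduces all outputs bit-identically. Each stage writes its
outputs plus a JSON provenance sidecar (parameters, seeds, input digests)
into the output directory, and ``run_pipeline`` returns a report dict that
is also written as ``report.json``.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .decoding import (
    DecodingParams,
    DecodingResult,
    decode_static,
    decode_timecourse,
    ecog_feature_vector,
    patternsets_to_trials,
    stack_accuracies,
)
from .design import ROIS, make_design
from .fusion import fuse_rdm_timecourse, snr_vs_correspondence
from .generator import GeneratorParams, simulate_ecog, simulate_eeg, simulate_fmri
from .inference import fdr_correct, onset_latency, peak_latency, wilcoxon_above_chance
from .preprocessing import rereference
from .rsa import condition_means, compute_rdm, mean_rdm, rdm_timecourse

logger = logging.getLogger("neurofuse")

STAGES = ("simulate", "preprocess", "decode", "rsa", "stats", "fuse")


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def validate_config(cfg: dict) -> dict:
    if "seed" not in cfg:
        raise ValueError("config must set a master 'seed'")
    cfg = dict(cfg)
    cfg.setdefault("output_dir", "neurofuse-output")
    cfg.setdefault("stages", list(STAGES))
    unknown = [s for s in cfg["stages"] if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")
    return cfg


def demo_config(seed: int = 7, output_dir: str = "neurofuse-demo") -> dict:
    """A small configuration that exercises every stage in minutes."""
    return {
        "seed": seed,
        "output_dir": output_dir,
        "stages": list(STAGES),
        "design": {"n_identities": 2, "n_repetitions": 8},
        "generator": {
            "n_participants": 3,
            "n_channels": 16,
            "sfreq": 200.0,
            "epoch_window": (-100.0, 400.0),
            "noise_sd": 0.8,
            "category_amplitudes": {
                "animal": 1.0, "chair": 0.9, "face": 1.5, "fruit": 0.8, "vehicle": 1.1,
            },
            "n_voxels": 30,
            "n_runs": 4,
            "n_electrodes_per_region": 6,
        },
        "decoding": {
            "schemes": ["category_selectivity", "rotation_invariance"],
            "n_pseudotrials": 8,
            "n_repeats": 2,
        },
        "inference": {"q": 0.05, "min_run": 5},
        "fusion": {"n_perm": 200},
    }


def _generator_params(cfg: dict) -> GeneratorParams:
    g = dict(cfg.get("generator", {}))
    if "epoch_window" in g:
        g["epoch_window"] = tuple(g["epoch_window"])
    g.setdefault("seed", cfg["seed"])
    return GeneratorParams(**g)


def run_pipeline(cfg: dict, stages: list[str] | None = None) -> dict:
    """Execute the configured stages in order; returns the report dict."""
    cfg = validate_config(cfg)
    stages = list(stages or cfg["stages"])
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    ctx: dict = {"report": {"seed": cfg["seed"], "stages": stages}}
    for stage in STAGES:
        if stage not in stages:
            continue
        fn = _STAGE_FNS[stage]
        t0 = time.time()
        logger.info("stage=%s seed=%s starting", stage, cfg["seed"])
        try:
            fn(cfg, ctx, out)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage=%s done in %.1fs", stage, time.time() - t0)
    report = ctx["report"]
    nio.write_provenance(out / "report.json", **report)
    (out / "report.txt").write_text(_format_report(report))
    return report


def _stage_simulate(cfg, ctx, out):
    params = _generator_params(cfg)
    design = make_design(**cfg.get("design", {}))
    fmri_design = make_design(
        **{**cfg.get("design", {}), "n_repetitions": params.n_runs, "n_runs": params.n_runs}
    )
    eeg = simulate_eeg(params, design)
    ecog = simulate_ecog(params, design)
    fmri = simulate_fmri(params, fmri_design)
    design.to_csv(out / "design.tsv", sep="\t", index=False)
    for rec in eeg:
        nio.write_epochs(out / f"eeg_{rec.participant_id}.h5", rec)
    nio.write_epochs(out / "ecog_super-subject.h5", ecog)
    nio.write_provenance(
        out / "simulate_provenance.json",
        params=params,
        seed=cfg["seed"],
        digests={"eeg_sub01": nio.digest(eeg[0].data), "ecog": nio.digest(ecog.data)},
    )
    ctx.update(eeg=eeg, ecog=ecog, fmri=fmri, params=params, design=design)
    ctx["report"]["n_participants"] = len(eeg)
    ctx["report"]["n_conditions"] = int(design["condition_id"].nunique())


def _stage_preprocess(cfg, ctx, out):
    ref = cfg.get("preprocess", {}).get("reference_channel")
    if ref:
        ctx["eeg"] = [rereference(r, ref) for r in ctx["eeg"]]
    ctx["report"]["preprocess"] = {"reference_channel": ref, "baseline_correction": None}


def _decoding_params(cfg, seed) -> DecodingParams:
    d = dict(cfg.get("decoding", {}))
    d.pop("schemes", None)
    return DecodingParams(seed=seed, **d)


def _stage_decode(cfg, ctx, out):
    schemes = cfg.get("decoding", {}).get("schemes", ["category_selectivity"])
    rng = np.random.default_rng(cfg["seed"] + 1)
    results: dict[str, list[DecodingResult]] = {}
    frames = []
    for scheme in schemes:
        per_part = []
        for rec in ctx["eeg"]:
            params = _decoding_params(cfg, seed=int(rng.integers(2**31 - 1)))
            res = decode_timecourse(rec, scheme, params)
            per_part.append(res)
            frames.append(res.to_frame())
        results[scheme] = per_part
    df = pd.concat(frames, ignore_index=True)
    nio.write_table(out / "decoding_eeg.tsv", df)
    nio.write_provenance(
        out / "decoding_provenance.json",
        schemes=schemes,
        params=_decoding_params(cfg, seed=0),
        seed=cfg["seed"],
    )
    ctx["decoding"] = results
    peak = {
        s: float(np.max(stack_accuracies(r).mean(axis=(0, 1)))) for s, r in results.items()
    }
    ctx["report"]["eeg_peak_accuracy"] = peak


def _stage_rsa(cfg, ctx, out):
    eeg_stacks = [rdm_timecourse(rec) for rec in ctx["eeg"]]
    group = [mean_rdm([s[t] for s in eeg_stacks]) for t in range(len(eeg_stacks[0]))]
    ctx["eeg_rdms"] = group
    ctx["ecog_rdms"] = rdm_timecourse(ctx["ecog"])
    fmri_rdms: dict[str, list] = {}
    participants = sorted({ps.participant_id for ps in ctx["fmri"]})
    for roi in ROIS:
        per_part = []
        for pid in participants:
            x, labels = patternsets_to_trials(ctx["fmri"], roi, pid)
            means, order = condition_means(x, labels)
            per_part.append(compute_rdm(means, order, meta={"roi": roi, "participant": pid}))
        fmri_rdms[roi] = per_part
    ctx["fmri_rdms"] = fmri_rdms
    nio.write_rdm(out / "eeg_rdm_last.csv", group[-1])
    nio.write_rdm(out / "ecog_rdm_last.csv", ctx["ecog_rdms"][-1])
    ctx["report"]["rdm_dimension"] = group[0].n_conditions


def _stage_stats(cfg, ctx, out):
    q = cfg.get("inference", {}).get("q", 0.05)
    min_run = cfg.get("inference", {}).get("min_run", 15)
    summary = {}
    rows = []
    for scheme, results in ctx.get("decoding", {}).items():
        acc = stack_accuracies(results).mean(axis=1)  # participants x time
        time_ms = results[0].time_ms
        p = wilcoxon_above_chance(acc) if acc.shape[0] >= 5 else np.full(acc.shape[1], np.nan)
        sig = fdr_correct(np.where(np.isfinite(p), p, 1.0), q)
        curve = acc.mean(axis=0)
        onset = onset_latency(sig, time_ms, min_run=min_run)
        peak = peak_latency(curve, time_ms)
        summary[scheme] = {"onset_ms": onset, "peak_ms": peak}
        for t in range(time_ms.size):
            rows.append((scheme, float(time_ms[t]), float(sig.p_values[t]),
                         float(sig.p_adjusted[t]), bool(sig.mask[t])))
    nio.write_table(
        out / "stats_eeg.tsv",
        pd.DataFrame(rows, columns=["scheme", "time_ms", "p", "p_adj", "significant"]),
    )
    nio.write_provenance(out / "stats_provenance.json", q=q, min_run=min_run, summary=summary)
    ctx["report"]["latencies"] = summary


def _stage_fuse(cfg, ctx, out):
    n_perm = cfg.get("fusion", {}).get("n_perm", 1000)
    time_ms = ctx["eeg"][0].time_ms
    fus = fuse_rdm_timecourse(
        ctx["eeg_rdms"], ctx["ecog_rdms"], time_ms, n_perm=n_perm, seed=cfg["seed"] + 2,
        pair=("EEG", "ECoG", "all"),
    )
    nio.write_table(out / "fusion_eeg_ecog.tsv", fus.to_frame())
    rho = fus.rho[np.isfinite(fus.rho)]
    ctx["report"]["eeg_ecog_fusion_max_rho"] = float(rho.max()) if rho.size else None

    # per-ROI fMRI decoding + ECoG regional decoding -> SNR correspondence
    rng = np.random.default_rng(cfg["seed"] + 3)
    participants = sorted({ps.participant_id for ps in ctx["fmri"]})
    fmri_acc, ecog_acc = {}, {}
    feats_all = None
    for roi in ROIS:
        accs = []
        for pid in participants:
            x, labels = patternsets_to_trials(ctx["fmri"], roi, pid)
            params = DecodingParams(whitening=False, n_repeats=1,
                                    seed=int(rng.integers(2**31 - 1)))
            res = decode_static(x, labels, "category_selectivity", params,
                                cv="leave_one_run_out", participant_id=pid)
            accs.append(res.accuracy)
        fmri_acc[roi] = np.mean(accs, axis=0)
        mask = (ctx["ecog"].channels["region"] == roi).to_numpy()
        window = cfg.get("fusion", {}).get("ecog_window")
        if window is None:
            t0 = max(50.0, float(time_ms[0]))
            window = (t0, t0 + 25.0 * int((float(time_ms[-1]) - t0) // 25.0))
        feats = ecog_feature_vector(ctx["ecog"], window=tuple(window), electrodes=mask)
        params = DecodingParams(whitening=False, n_repeats=1,
                                seed=int(rng.integers(2**31 - 1)))
        res = decode_static(feats, ctx["ecog"].labels, "category_selectivity", params,
                            cv="leave_one_trial_out", participant_id="super-subject")
        ecog_acc[roi] = res.accuracy
    corr = snr_vs_correspondence(fmri_acc, ecog_acc, ctx["fmri_rdms"])
    nio.write_table(out / "region_correspondence.tsv", corr.table)
    nio.write_provenance(
        out / "fusion_provenance.json", n_perm=n_perm, seed=cfg["seed"],
        summary_rho=corr.summary_rho,
    )
    ctx["report"]["snr_correspondence_rho"] = corr.summary_rho


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "decode": _stage_decode,
    "rsa": _stage_rsa,
    "stats": _stage_stats,
    "fuse": _stage_fuse,
}


def _format_report(report: dict) -> str:
    lines = ["neurofuse pipeline report", "=" * 25]
    for key, val in report.items():
        lines.append(f"{key}: {val}")
    return "\n".join(lines) + "\n"
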