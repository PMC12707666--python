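"""End-to-end pipeline: simulate -> features -> fit -> partition -> group.

Each stage writes its outputs into ``<out>/<stage>/`` (atomically: work
happens in a ``.tmp`` directory that is renamed on success and quarantined
on failure) and a manifest records configuration, seeds and content hashes
so reruns can be verified to be bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .encoding import build_design, cross_validate, make_cv_scheme
from .features import (
    GaborBankConfig,
    build_filter_bank,
    categorical_features,
    extract_kp3d,
    moten_features,
    simdist_features,
)
from .group_stats import fdr_bh, paired_contrast, signflip_permutation
from .io import write_events, write_features, write_json, read_events, read_features
from .partition import accuracy, hsv_composite, partial_contribution
from .synthetic import (
    JointTrajectory,
    default_skeleton,
    default_stimulus_pool,
    generate_stimulus_set,
    make_event_schedule,
    make_ground_truth,
    n_trs_per_run,
    simulate_bold,
)

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("simulate", "features", "fit", "partition", "group")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _run_stage(out: Path, name: str, fn) -> dict:
    """Run one stage in a temp dir, renaming on success; quarantine partial
    outputs on failure."""
    final = out / name
    tmp = out / f"{name}.tmp"
    if tmp.exists():
        shutil.rmtree(tmp)
    tmp.mkdir(parents=True)
    try:
        fn(tmp)
    except Exception:
        quarantine = out / "quarantine"
        quarantine.mkdir(exist_ok=True)
        dest = quarantine / name
        if dest.exists():
            shutil.rmtree(dest)
        tmp.rename(dest)
        raise
    if final.exists():
        shutil.rmtree(final)
    tmp.rename(final)
    files = sorted(p for p in final.rglob("*") if p.is_file())
    return {p.name: _sha256(p) for p in files}


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, d: Path) -> None:
    skel = default_skeleton()
    clips = generate_stimulus_set(
        n_pairs=cfg.n_stimulus_pairs, n_actors=cfg.n_actors,
        seed=cfg.stage_seed("simulate"), skeleton=skel, render=True,
        image_h=cfg.image_h, image_w=cfg.image_w,
    )
    events = make_event_schedule(
        pool=default_stimulus_pool(cfg.n_stimulus_pairs),
        n_runs=cfg.n_runs, n_sessions=cfg.n_sessions,
        stimuli_per_run=cfg.stimuli_per_run, reps=cfg.reps,
        n_targets=cfg.n_targets, n_blanks=cfg.n_blanks,
        tr_s=cfg.tr_s, isi_trs=cfg.isi_trs, seed=cfg.stage_seed("simulate") + 1,
    )
    write_events(events, d / "events.tsv")
    traj = {c.id: c.trajectory.euler.astype(np.float32) for c in clips}
    np.savez_compressed(d / "trajectories.npz", **traj)
    np.savez_compressed(
        d / "videos.npz", **{c.id: c.frames.astype(np.float32) for c in clips}
    )
    meta = {c.id: {"actor": c.actor, "action": c.action, "plausibility": c.plausibility,
                   "fps": c.trajectory.fps} for c in clips}
    write_json(meta, d / "clips.json")


def _load_clips(out: Path):
    skel = default_skeleton()
    meta = json.loads((out / "simulate" / "clips.json").read_text())
    trajs, labels = {}, {}
    with np.load(out / "simulate" / "trajectories.npz") as z:
        for sid in z.files:
            trajs[sid] = JointTrajectory(
                skeleton=skel, euler=z[sid].astype(float),
                fps=meta[sid]["fps"], label=meta[sid]["plausibility"],
            )
            labels[sid] = meta[sid]["plausibility"]
    return skel, trajs, labels, meta


def stage_features(cfg: PipelineConfig, d: Path, out: Path) -> None:
    skel, trajs, labels, _ = _load_clips(out)
    write_features(extract_kp3d(trajs, skeleton=skel), d / "kp3d.tsv")
    write_features(categorical_features(labels), d / "categorical.tsv")

    sd = simdist_features(trajs, labels, frame_step=cfg.simdist_frame_step)
    from .features.posture import FeatureSpace

    write_features(
        FeatureSpace(name="simdist", X=sd.X, feature_names=sd.retained_joints,
                     stimulus_ids=sd.stimulus_ids),
        d / "simdist.tsv",
    )

    bank = build_filter_bank(GaborBankConfig(
        image_h=cfg.image_h, image_w=cfg.image_w,
        pixels_per_degree=cfg.pixels_per_degree, fps=cfg.fps,
        spatial_frequencies=cfg.spatial_frequencies,
        temporal_frequencies=cfg.temporal_frequencies,
        max_positions_per_axis=cfg.max_positions_per_axis,
    ))
    with np.load(out / "simulate" / "videos.npz") as z:
        vids = {sid: z[sid].astype(float) for sid in z.files}
    write_features(moten_features(vids, bank), d / "moten.tsv")


def _load_design(cfg: PipelineConfig, out: Path):
    events = read_events(out / "simulate" / "events.tsv")
    spaces = {
        name: read_features(out / "features" / f"{name}.tsv", name=name)
        for name in ("kp3d", "categorical", "simdist", "moten")
    }
    n_tr = n_trs_per_run(events, cfg.tr_s)
    return events, spaces, build_design(events, spaces, n_tr, cfg.tr_s, cfg.n_delays)


def stage_fit(cfg: PipelineConfig, d: Path, out: Path) -> None:
    events, spaces, design = _load_design(cfg, out)
    per_run = {b: design.bands[b] for b in design.bands}
    delayed = {b: [None] * design.n_runs for b in design.bands}
    from .encoding import delay_design

    for b in per_run:
        for r in range(design.n_runs):
            delayed[b][r] = delay_design(per_run[b][r], cfg.n_delays)
    gt = make_ground_truth(
        delayed, cfg.band_fractions, n_voxels=cfg.n_voxels,
        noise_sd=cfg.noise_sd, seed=cfg.stage_seed("bold"),
    )
    runs = simulate_bold(delayed, gt, tr_s=cfg.tr_s)
    Y_runs = [r.Y for r in runs]
    np.savez_compressed(d / "bold.npz", **{f"run{r:03d}": Y for r, Y in enumerate(Y_runs)})
    write_json({"band_fractions": cfg.band_fractions, "noise_sd": cfg.noise_sd},
               d / "ground_truth.json")

    cv = make_cv_scheme(cfg.n_runs, cfg.n_outer_folds, cfg.n_inner_folds)
    res = cross_validate(
        design, Y_runs, cv,
        lambda_range=(cfg.lambda_min, cfg.lambda_max),
        n_random=cfg.n_random_search, refine_steps=cfg.refine_steps,
        seed=cfg.stage_seed("fit"), standardize_mode=cfg.standardize_mode,
    )
    fid, Yt, Yp, bp = res.concatenated()
    np.savez_compressed(
        d / "cv.npz", fold_ids=fid, Y_true=Yt, Y_pred=Yp,
        **{f"pred_{b}": bp[b] for b in bp},
    )
    r = accuracy(Yt, Yp, fid)
    write_json(
        {
            "lambdas": [f.fit.lambda_b for f in res.folds],
            "mean_r_joint": float(np.mean(r)),
            "fold_of_run": {str(k): v for k, v in res.fold_of_run.items()},
        },
        d / "fit_summary.json",
    )


def stage_partition(cfg: PipelineConfig, d: Path, out: Path) -> None:
    with np.load(out / "fit" / "cv.npz") as z:
        fid, Yt, Yp = z["fold_ids"], z["Y_true"], z["Y_pred"]
        bp = {k[5:]: z[k] for k in z.files if k.startswith("pred_")}
    r = accuracy(Yt, Yp, fid)
    amap = partial_contribution(Yt, bp)
    df = pd.DataFrame({"voxel": np.arange(r.size), "r_joint": r, "R2_joint": amap.R2_joint})
    for b in bp:
        df[f"fraction_{b}"] = amap.fraction_b[b]
        df[f"partial_r_{b}"] = amap.partial_r[b]
    df.to_csv(d / "maps.tsv", sep="\t", index=False, float_format="%.8g")
    comp = hsv_composite(amap.fraction_b, r)
    pd.DataFrame({"voxel": np.arange(r.size), "H": comp.H, "S": comp.S, "V": comp.V}).to_csv(
        d / "hsv.tsv", sep="\t", index=False, float_format="%.8g"
    )


def stage_group(cfg: PipelineConfig, d: Path, out: Path) -> None:
    events, spaces, design = _load_design(cfg, out)
    from .encoding import delay_design

    delayed = {
        b: [delay_design(X, cfg.n_delays) for X in design.bands[b]]
        for b in design.bands
    }
    gt = make_ground_truth(
        delayed, cfg.band_fractions, n_voxels=cfg.n_voxels,
        noise_sd=cfg.noise_sd, seed=cfg.stage_seed("bold"),
    )
    summary = json.loads((out / "fit" / "fit_summary.json").read_text())
    lambdas = summary["lambdas"][0]
    cv = make_cv_scheme(cfg.n_runs, cfg.n_outer_folds, cfg.n_inner_folds)

    subj_r, subj_frac = [], []
    base = cfg.stage_seed("group")
    for s in range(cfg.n_subjects):
        gt_s = make_ground_truth(
            delayed, cfg.band_fractions, n_voxels=cfg.n_voxels,
            noise_sd=cfg.noise_sd, seed=base + 17 * s,
        )
        Y_runs = [r.Y for r in simulate_bold(delayed, gt_s, tr_s=cfg.tr_s)]
        res = cross_validate(
            design, Y_runs, cv, fixed_lambdas=lambdas,
            standardize_mode=cfg.standardize_mode,
        )
        fid, Yt, Yp, bp = res.concatenated()
        subj_r.append(accuracy(Yt, Yp, fid))
        amap = partial_contribution(Yt, bp)
        subj_frac.append({b: np.nanmean(amap.fraction_b[b]) for b in bp})

    maps = np.vstack(subj_r)
    perm = signflip_permutation(maps, seed=base, q_level=cfg.q_level)
    pd.DataFrame(
        {"voxel": np.arange(maps.shape[1]), "observed": perm.observed,
         "p": perm.p, "q": perm.q}
    ).to_csv(d / "group_map.tsv", sep="\t", index=False, float_format="%.8g")

    bands = list(subj_frac[0])
    rows = []
    for i in range(len(bands)):
        for j in range(i + 1, len(bands)):
            a = np.array([f[bands[i]] for f in subj_frac])
            b = np.array([f[bands[j]] for f in subj_frac])
            t = paired_contrast(a, b)
            rows.append({"contrast": f"{bands[i]} vs {bands[j]}", "t": t.t, "df": t.df,
                         "p": t.p, "dz": t.dz, "power": t.power})
    con = pd.DataFrame(rows)
    if con["p"].notna().all():
        con["q"], _ = fdr_bh(con["p"].to_numpy(), cfg.q_level)
    con.to_csv(d / "contrasts.tsv", sep="\t", index=False, float_format="%.6g")
    write_json({"n_permutations": perm.n_permutations, "exhaustive": perm.exhaustive},
               d / "group_summary.json")


# ---------------------------------------------------------------------------


def run_pipeline(
    cfg: PipelineConfig, out: str | Path, stages: tuple[str, ...] = STAGES
) -> dict:
    """Run the requested stages and write a manifest; returns the manifest."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    fns = {
        "simulate": lambda d: stage_simulate(cfg, d),
        "features": lambda d: stage_features(cfg, d, out),
        "fit": lambda d: stage_fit(cfg, d, out),
        "partition": lambda d: stage_partition(cfg, d, out),
        "group": lambda d: stage_group(cfg, d, out),
    }
    manifest_path = out / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {
        "version": __version__, "config": cfg.to_dict(), "stages": {},
    }
    for name in stages:
        if name not in fns:
            raise ValueError(f"unknown stage {name!r}")
        manifest["stages"][name] = _run_stage(out, name, fns[name])
    if (out / "fit" / "fit_summary.json").exists():
        manifest["summary"] = json.loads((out / "fit" / "fit_summary.json").read_text())
    write_json(manifest, manifest_path)
    return manifest
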