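"""End-to-end runner: simulate → preprocess → connectivity → task GLM → group stats.

Each stage writes standard-format artifacts (NIfTI volumes, tab-separated
confounds/events, CSV tables, JSON logs) into a stage-named subfolder of
one run directory and records row counts in a manifest.  Outputs are a
pure function of (config, seed): re-running with the same config yields
byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .connectivity import NETWORKS, connectivity_profile, extract_network_timeseries
from .group_inference import (
    apply_qc_filters,
    dispersion_test,
    factorial_glm,
    linear_check_regression,
    negbin_regression,
    partial_correlation,
)
from .preprocess import (
    NuisanceSet,
    build_censor_mask,
    check_temporal_dof,
    compute_framewise_displacement,
    project_clean,
)
from .synthetic import (
    LogisticInhibitionModel,
    MaskGeometry,
    MotionSpec,
    NuisanceSpec,
    SimulationConfig,
    render_voxel_data,
    simulate_cohort,
    simulate_eat_session,
)
from .task_response import (
    build_design_matrix,
    extract_network_beta,
    fit_subject_glm,
    scale_to_percent_bold,
)

__all__ = ["run_pipeline", "validate_inputs"]

_MOTION_COLS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def _sim_config(cfg: RunConfig) -> SimulationConfig:
    return SimulationConfig(
        n_per_group=cfg.n_per_group,
        T=cfg.T,
        TR=cfg.TR,
        ar1_phi=cfg.ar1_phi,
        group_delta_sn_dmn=cfg.group_delta_sn_dmn,
        voxel_noise_sd=cfg.voxel_noise_sd,
        spike_rate=cfg.spike_rate,
        nb_intercept=cfg.nb_intercept,
        nb_slope=cfg.nb_slope,
        nb_dispersion=cfg.nb_dispersion,
        seed=cfg.seed,
        n_task_runs=cfg.task_runs,
    )


def stage_simulate(cfg: RunConfig, run_dir: Path) -> dict:
    """Draw the cohort and render per-subject resting runs to NIfTI + TSV."""
    import nibabel as nib

    out = run_dir / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    sim = _sim_config(cfg)
    cohort, truth = simulate_cohort(sim)
    geometry = MaskGeometry.default()
    rng = np.random.default_rng(sim.seed + 1_000_003)

    nib.save(
        nib.Nifti1Image(geometry.labels.astype(np.int16), geometry.affine),
        out / "network_labels.nii",
    )
    nib.save(nib.Nifti1Image(geometry.wm.astype(np.uint8), geometry.affine), out / "wm_mask.nii")
    nib.save(nib.Nifti1Image(geometry.csf.astype(np.uint8), geometry.affine), out / "csf_mask.nii")

    gt_json: dict = {}
    for _, row in cohort.iterrows():
        sub = row["subject"]
        entry = truth[sub]
        rendered = render_voxel_data(
            entry.latent,
            geometry,
            voxel_noise_sd=cfg.voxel_noise_sd,
            nuisance_spec=NuisanceSpec(),
            motion_spec=MotionSpec(spike_volumes=tuple(int(s) for s in entry.spike_volumes)),
            seed=rng,
        )
        img, *_ = rendered.to_nifti()
        nib.save(img, out / f"{sub}_rest_bold.nii")
        rendered.confounds_frame().to_csv(out / f"{sub}_confounds.tsv", sep="\t", index=False)
        pd.DataFrame(entry.latent, columns=list(NETWORKS)).to_csv(
            out / f"{sub}_latent.tsv", sep="\t", index=False
        )
        gt_json[sub] = {
            "true_corr": entry.true_corr,
            "spike_volumes": [int(s) for s in entry.spike_volumes],
            "censored_volumes": [int(s) for s in entry.censored_volumes],
            "nb_linpred": entry.nb_linpred,
        }
    cohort.to_csv(out / "cohort.csv", index=False)
    (out / "ground_truth.json").write_text(json.dumps(gt_json, indent=1, sort_keys=True))
    return {"n_subjects": len(cohort)}


def stage_preprocess(cfg: RunConfig, run_dir: Path) -> dict:
    """FD, censoring, aCompCor, and simultaneous regression + bandpass."""
    import nibabel as nib

    sim_dir = run_dir / "simulate"
    out = run_dir / "preprocess"
    out.mkdir(parents=True, exist_ok=True)
    cohort = pd.read_csv(sim_dir / "cohort.csv")
    labels = np.asanyarray(nib.load(sim_dir / "network_labels.nii").dataobj)
    wm = np.asanyarray(nib.load(sim_dir / "wm_mask.nii").dataobj).astype(bool)
    csf = np.asanyarray(nib.load(sim_dir / "csf_mask.nii").dataobj).astype(bool)

    logs = {}
    mean_fds = []
    dof_ok = []
    for sub in cohort["subject"]:
        bold = np.asanyarray(nib.load(sim_dir / f"{sub}_rest_bold.nii").dataobj).astype(float)
        motion = pd.read_csv(sim_dir / f"{sub}_confounds.tsv", sep="\t")[_MOTION_COLS].to_numpy()
        fd = compute_framewise_displacement(motion, cfg.head_radius_mm)
        plan = build_censor_mask(fd, cfg.fd_threshold_mm, cfg.n_nonsteady)
        flat = bold.reshape(-1, bold.shape[3]).T
        nuis = NuisanceSet.build(
            motion,
            csf_series=flat[:, csf.reshape(-1)],
            wm_series=flat[:, wm.reshape(-1)],
            k=cfg.acompcor_k,
            n_nonsteady=cfg.n_nonsteady,
        )
        from .preprocess import spectral_stopband_regressors

        n_reg = nuis.n_regressors + spectral_stopband_regressors(
            bold.shape[3], cfg.TR, cfg.band_hz
        ).shape[1]
        passed = check_temporal_dof(plan.n_retained, n_reg)
        dof_ok.append(passed)
        mean_fds.append(fd.mean_fd)
        logs[sub] = {
            "mean_fd": fd.mean_fd,
            "n_censored": int(len(plan.censored)),
            "n_retained": plan.n_retained,
            "n_regressors": int(n_reg),
            "dof_check": "pass" if passed else "violation",
        }
        pd.DataFrame(
            {
                "fd": fd.fd,
                "keep": plan.keep.astype(int),
                "reason": [
                    ";".join(plan.reasons.get(t, ())) for t in range(len(plan.keep))
                ],
            }
        ).to_csv(out / f"{sub}_censor.tsv", sep="\t", index=False)
        if not passed:
            continue
        mask = labels > 0
        cleaned = project_clean(
            flat[:, mask.reshape(-1)], nuis, cfg.band_hz, cfg.TR, plan
        )
        series = extract_network_timeseries(cleaned, labels[mask].reshape(-1), plan=None)
        pd.DataFrame(series, columns=list(NETWORKS)).to_csv(
            out / f"{sub}_network_timeseries.tsv", sep="\t", index=False
        )
    cohort["mean_fd"] = mean_fds  # measured, replaces the generative stand-in
    cohort["dof_pass"] = dof_ok
    cohort.to_csv(out / "cohort.csv", index=False)
    (out / "processing_log.json").write_text(json.dumps(logs, indent=1, sort_keys=True))
    return {
        "n_subjects": len(cohort),
        "n_dof_violations": int(len(cohort) - sum(dof_ok)),
    }


def stage_connectivity(cfg: RunConfig, run_dir: Path) -> dict:
    """Per-subject correlation matrices, Fisher-z couplings and RAIs."""
    pre = run_dir / "preprocess"
    out = run_dir / "connectivity"
    out.mkdir(parents=True, exist_ok=True)
    cohort = pd.read_csv(pre / "cohort.csv")
    rows = []
    for _, rec in cohort.iterrows():
        if not rec["dof_pass"]:
            continue
        ts = pd.read_csv(pre / f"{rec['subject']}_network_timeseries.tsv", sep="\t")
        profile = connectivity_profile(ts.to_numpy())
        rows.append(profile.as_row(subject=rec["subject"]))
    conn = pd.DataFrame(rows)
    merged = cohort.merge(conn, on="subject", how="inner")
    merged.to_csv(out / "connectivity.csv", index=False)
    return {"n_subjects": len(merged)}


def _render_task_subject(rec, events, cfg: RunConfig, geometry, rng) -> np.ndarray:
    """Voxel task data: baseline 100·(1 + Σ (β/100)·HRF-regressor) + noise."""
    from .connectivity import NETWORK_LABELS

    with warnings.catch_warnings():
        # sessions without Go-errors are normal here
        warnings.simplefilter("ignore")
        design = build_design_matrix(
            events,
            n_volumes=cfg.task_volumes_per_run,
            tr=cfg.TR,
            poly_order=0,
            hrf_p=cfg.hrf_p,
            hrf_q=cfg.hrf_q,
        )
    total = cfg.task_runs * cfg.task_volumes_per_run
    betas = {
        "SN": rec["beta_sn"],
        "DMN": rec["beta_dmn"],
        "L.CEN": rec["beta_lcen"],
        "R.CEN": rec["beta_rcen"],
    }
    lab = geometry.labels.reshape(-1)
    n_vox = lab.size
    data = np.zeros((total, n_vox))
    baseline = 100.0
    for name in NETWORKS:
        sel = lab == NETWORK_LABELS[name]
        sig = np.zeros(total)
        if "NoGo-error" in design.columns:
            sig = baseline * (betas[name] / 100.0) * design["NoGo-error"].to_numpy()
        if "NoGo-correct" in design.columns:
            sig = sig + baseline * 0.001 * design["NoGo-correct"].to_numpy()
        data[:, sel] = baseline + sig[:, None]
    data[:, lab == 0] = baseline
    data[:, geometry.wm.reshape(-1) | geometry.csf.reshape(-1)] = baseline
    data += rng.normal(0.0, 0.2, size=data.shape)
    return data


def stage_taskglm(cfg: RunConfig, run_dir: Path) -> dict:
    """Simulate EAT sessions, render task runs, fit subject GLMs, extract βs."""
    sim_dir = run_dir / "simulate"
    out = run_dir / "taskglm"
    out.mkdir(parents=True, exist_ok=True)
    cohort = pd.read_csv(sim_dir / "cohort.csv")
    geometry = MaskGeometry.default()
    sim = _sim_config(cfg)
    rng = np.random.default_rng(cfg.seed + 7_000_003)

    rows = []
    for idx, rec in cohort.iterrows():
        subject_model = LogisticInhibitionModel(midpoint=float(rng.uniform(0.2, 0.8)))
        session = simulate_eat_session(
            subject_model,
            n_runs=cfg.task_runs,
            trials_per_run=sim.trials_per_run,
            nogo_prop=sim.nogo_prop,
            seed=rng,
        )
        events = session.events()
        # keep events inside the run: trials beyond the scan are dropped
        events = events[events["onset"] / cfg.TR < cfg.task_volumes_per_run - 1]
        events.to_csv(out / f"{rec['subject']}_events.tsv", sep="\t", index=False)
        data = _render_task_subject(rec, events, cfg, geometry, rng)
        scaled, good = scale_to_percent_bold(data)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            design = build_design_matrix(
                events,
                n_volumes=cfg.task_volumes_per_run,
                tr=cfg.TR,
                poly_order=cfg.poly_order,
                hrf_p=cfg.hrf_p,
                hrf_q=cfg.hrf_q,
            )
        fit = fit_subject_glm(scaled, design)
        netbeta = extract_network_beta(fit, geometry.labels)
        rows.append(
            {
                "subject": rec["subject"],
                "nogo_error_rate": session.nogo_error_rate,
                "n_aware": session.n_aware,
                "n_unaware": session.n_unaware,
                **{f"beta_hat_{n.lower().replace('.', '')}": b for n, b in netbeta.items()},
            }
        )
    pd.DataFrame(rows).to_csv(out / "network_betas.csv", index=False)
    return {"n_subjects": len(rows)}


def stage_groupstats(cfg: RunConfig, run_dir: Path) -> dict:
    """QC, factorial models, count models and partial correlations."""
    conn_path = run_dir / "connectivity" / "connectivity.csv"
    out = run_dir / "groupstats"
    out.mkdir(parents=True, exist_ok=True)
    cohort = pd.read_csv(conn_path)
    task_path = run_dir / "taskglm" / "network_betas.csv"
    if task_path.exists():
        cohort = cohort.merge(pd.read_csv(task_path), on="subject", how="left")

    filtered, exclusions = apply_qc_filters(
        cohort, go_error_cap=cfg.go_error_cap, outlier_z=cfg.outlier_z
    )
    exclusions.to_csv(out / "exclusions.csv", index=False)

    lines = []
    glm_rows = []
    for outcome in ("r_rai", "l_rai", "fcc_sn_dmn", "fcc_sn_lcen", "fcc_sn_rcen"):
        res = factorial_glm(filtered, outcome, covariates=cfg.rsfc_covariates)
        for term in ("HIV", "CB", "HIV:CB"):
            t = res.term(term)
            glm_rows.append({"outcome": outcome, "term": term, **t.to_dict()})
            lines.append(
                f"{outcome} ~ {term}: F[{t.df_num:.0f}, {t.df_den:.0f}] = {t.F:.2f}, "
                f"p = {t.p:.4f}, eta_p2 = {t.eta_p2:.3f}"
            )
    pd.DataFrame(glm_rows).to_csv(out / "group_models.csv", index=False)

    nb_pred = {"fcc_sn_dmn": filtered["fcc_sn_dmn"]}
    for cov in cfg.nb_covariates:
        nb_pred[cov] = filtered[cov]
    if len(filtered) > len(nb_pred) + 4:
        disp = dispersion_test(filtered["unaware_errors"], nb_pred)
        nb = negbin_regression(
            filtered["unaware_errors"], nb_pred, run_dispersion_test=False
        )
        ols = linear_check_regression(filtered["unaware_errors"], nb_pred)
        nb.table.to_csv(out / "negbin_unaware.csv")
        ols.to_csv(out / "ols_unaware_log10.csv")
        c = nb.coef("fcc_sn_dmn")
        lines.append(
            f"unaware ~ fcc_sn_dmn (NB): b = {c['coef']:.2f} [{c['se']:.2f}], "
            f"z = {c['z']:.2f}, p = {c['p']:.4f}; dispersion test p = {disp.pvalue:.2g}; "
            f"alpha = {nb.alpha:.2f}"
        )
    else:
        lines.append("unaware-error count models skipped: too few subjects")

    pc_rows = []
    if "beta_hat_dmn" in filtered.columns and filtered["beta_hat_dmn"].notna().all():
        for net in ("dmn", "sn", "lcen", "rcen"):
            pc = partial_correlation(
                filtered["fcc_sn_dmn"], filtered[f"beta_hat_{net}"],
                controls=filtered[["mean_fd"]].to_numpy(),
            )
            pc_rows.append({"pair": f"fcc_sn_dmn~beta_{net}", "r": pc.r, "df": pc.df, "p": pc.p})
            lines.append(f"partial r(fcc_sn_dmn, beta_{net} | mean_fd) = {pc.r:.3f}, p = {pc.p:.3f}")
        pd.DataFrame(pc_rows).to_csv(out / "partial_correlations.csv", index=False)

    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return {"n_analyzed": len(filtered), "n_excluded": len(exclusions)}


_STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "connectivity": stage_connectivity,
    "taskglm": stage_taskglm,
    "groupstats": stage_groupstats,
}


def run_pipeline(cfg: RunConfig, run_dir, stages=None) -> dict:
    """Execute the requested stages in order and write a manifest.

    Stage failure halts the run; the manifest records the failed stage and
    partial outputs are retained.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    stages = list(stages or _STAGES)
    unknown = set(stages) - set(_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    cfg_yaml = run_dir / "config.yaml"
    cfg.to_yaml(cfg_yaml)
    manifest = {
        "netrai_version": __version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(cfg_yaml.read_bytes()).hexdigest(),
        "stages": {},
    }
    try:
        for name in stages:
            manifest["stages"][name] = _STAGES[name](cfg, run_dir)
    except Exception as err:
        manifest["failed_stage"] = name
        manifest["error"] = f"{type(err).__name__}: {err}"
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def validate_inputs(
    bold_path=None, labels_path=None, confounds_path=None, events_path=None
) -> pd.DataFrame:
    """Machine-readable consistency checks on pipeline inputs.

    Verifies NIfTI grid agreement between data and masks, confounds row
    counts against volume counts, and event-table schema.  Returns one row
    per check with columns (check, passed, detail); never raises.
    """
    import nibabel as nib

    checks = []

    def record(name: str, passed: bool, detail: str = "") -> None:
        checks.append({"check": name, "passed": bool(passed), "detail": detail})

    bold = None
    if bold_path is not None:
        try:
            bold = nib.load(bold_path)
            record("bold_readable", True, str(bold.shape))
        except Exception as err:
            record("bold_readable", False, str(err))
    if labels_path is not None:
        try:
            lab = nib.load(labels_path)
            if bold is not None:
                same = lab.shape == bold.shape[:3]
                record(
                    "grid_match",
                    same,
                    f"labels {lab.shape} vs data {bold.shape[:3]}",
                )
            present = set(np.unique(np.asanyarray(lab.dataobj))) >= {1, 2, 3, 4}
            record("labels_complete", present, "need labels 1-4")
        except Exception as err:
            record("labels_readable", False, str(err))
    if confounds_path is not None:
        try:
            conf = pd.read_csv(confounds_path, sep="\t")
            missing = [c for c in _MOTION_COLS if c not in conf.columns]
            record("confounds_columns", not missing, f"missing {missing}" if missing else "")
            if bold is not None:
                ok = len(conf) == bold.shape[3]
                record(
                    "confounds_rows",
                    ok,
                    f"{confounds_path}: {len(conf)} rows vs {bold.shape[3]} volumes",
                )
        except Exception as err:
            record("confounds_readable", False, str(err))
    if events_path is not None:
        try:
            ev = pd.read_csv(events_path, sep="\t")
            missing = [c for c in ("onset", "duration", "trial_type") if c not in ev.columns]
            record("events_schema", not missing, f"missing {missing}" if missing else "")
        except Exception as err:
            record("events_readable", False, str(err))
    return pd.DataFrame(checks, columns=["check", "passed", "detail"])
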