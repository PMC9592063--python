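"""Stage-oriented experiment runner.

Stages (``simulate, align, targets, features, prep, train, evaluate,
predict``) communicate only through files under the experiment output
directory, and each stage writes a manifest (config hash, derived seed,
realized dimensions) so any stage can be re-run reproducibly from its
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import io as eio
from .acoustics import (
    CalibrationInfo,
    PitchParams,
    calibrate_spl,
    extract_f0,
    extract_intensity,
    frame_targets,
)
from .align import align_emg_to_audio
from .emgfeat import FrameSpec, extract_all
from .evalmetrics import EvalReport, compute_metrics, select_final_fold, summarize_folds
from .mlprep import (
    apply_pca,
    augment_gaussian,
    fit_pca,
    make_folds,
    stratified_split,
)
from .regressor import ModelConfig, TargetTransform, predict, train_model
from .signals import Contour, SignalTrack
from .synthgen import generate_session, make_task_config

__all__ = ["ExperimentConfig", "run_stage", "report", "STAGES"]

STAGES = (
    "simulate",
    "align",
    "targets",
    "features",
    "prep",
    "train",
    "evaluate",
    "predict",
)

STREAMS = ("f0", "intensity")

_DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "run",
    "dtw_hop": 0.010,
    "pitch": {"f_min": 65.0, "f_max": 475.0},
    "frames": {
        "f0": {"frame_len": 0.040, "step": 0.020},
        "intensity": {"frame_len": 0.150, "step": 0.030},
    },
    "min_coverage": 0.5,
    "pca_variance": 0.90,
    "augment_scale": 0.1,
    "k_folds": 5,
    "folds_to_train": None,  # None -> all k folds
    "schemes": {"f0": "single_f0", "intensity": "single_intensity"},
    "sessions": {
        "speaker_seed": 1,
        "tasks": {
            "tone": 2,
            "legato": 1,
            "vcv": 1,
            "phrase": 2,
            "passage": 1,
            "question": 1,
            "monologue": 1,
        },
        "duration_scale": 1.0,
    },
    "model": {},  # ModelConfig overrides (max_epochs, hidden_layers, ...)
}


class ExperimentConfig(dict):
    """Plain dict config with defaults filled in and a stable hash."""

    def __init__(self, data: dict | None = None):
        merged = json.loads(json.dumps(_DEFAULTS))
        for key, val in (data or {}).items():
            if isinstance(val, dict) and isinstance(merged.get(key), dict):
                merged[key].update(val)
            else:
                merged[key] = val
        super().__init__(merged)
        if self["seed"] is None:
            raise ValueError("seed is mandatory")

    @staticmethod
    def from_yaml(path: str | Path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            return ExperimentConfig(yaml.safe_load(fh) or {})

    @property
    def out_dir(self) -> Path:
        return Path(self["out_dir"])

    def config_hash(self) -> str:
        blob = json.dumps(self, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        blob = f"{self['seed']}:{stage}".encode()
        return int.from_bytes(hashlib.sha256(blob).digest()[:4], "big")

    def frame_spec(self, stream: str) -> FrameSpec:
        f = self["frames"][stream]
        return FrameSpec(frame_len=f["frame_len"], step=f["step"])

    def pitch_params(self) -> PitchParams:
        return PitchParams(**self["pitch"])


def _write_manifest(config: ExperimentConfig, stage: str, extra: dict) -> None:
    mdir = config.out_dir / "manifests"
    mdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config["seed"],
        "stage_seed": config.stage_seed(stage),
        "config": dict(config),
    }
    manifest.update(extra)
    with open(mdir / f"{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the '{producer}' stage first"
        )
    return path


def _session_names(config: ExperimentConfig) -> list[str]:
    names = []
    for task, count in sorted(config["sessions"]["tasks"].items()):
        for i in range(count):
            names.append(f"{task}_{i:03d}")
    return names


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: ExperimentConfig) -> dict:
    seed0 = config.stage_seed("simulate")
    sess_cfg = config["sessions"]
    scale = float(sess_cfg.get("duration_scale", 1.0))
    sdir = config.out_dir / "sessions"
    total = 0.0
    # coupling gains and SPL calibration are speaker-level: shared across
    # every session of the suite, otherwise the EMG->prosody mapping would
    # change per recording and nothing could be learned across sessions
    from .synthgen import default_coupling_gains

    speaker_seed = int(sess_cfg["speaker_seed"])
    gains = default_coupling_gains(8, speaker_seed)
    cal_offset = float(
        np.random.default_rng(np.random.SeedSequence([speaker_seed, 0xCA])).uniform(
            5.0, 20.0
        )
    )
    for si, name in enumerate(_session_names(config)):
        task = name.rsplit("_", 1)[0]
        tcfg = make_task_config(
            task,
            seed=seed0 + si,
            duration_s=None,
        )
        if scale != 1.0:
            tcfg = make_task_config(
                task,
                seed=seed0 + si,
                duration_s=scale * tcfg.duration_s,
            )
        tcfg.coupling_gains = gains
        tcfg.calibration_offset_db = cal_offset
        session = generate_session(tcfg)
        d = sdir / name
        d.mkdir(parents=True, exist_ok=True)
        eio.write_wav(d / "audio.wav", session.audio)
        eio.write_emg(
            d / "emg.csv",
            session.emg,
            meta={
                "task": session.task_label,
                "calibration_offset_db": session.calibration_offset_db,
                "coupling_gains": session.coupling_gains.tolist(),
                "speaker_seed": sess_cfg["speaker_seed"],
            },
        )
        eio.write_contour(d / "truth_f0.tsv", session.truth_f0)
        eio.write_contour(d / "truth_intensity.tsv", session.truth_intensity)
        total += session.audio.duration
    return {"n_sessions": si + 1, "total_audio_s": round(total, 3)}


def _downsample(track: SignalTrack, fs_out: float) -> SignalTrack:
    n_out = int(round(track.duration * fs_out))
    y = sps.resample(track.samples, n_out)
    return SignalTrack(samples=y, rate=fs_out, units=track.units)


def _stage_align(config: ExperimentConfig) -> dict:
    sdir = config.out_dir / "sessions"
    adir = config.out_dir / "aligned"
    hop = float(config["dtw_hop"])
    stats = []
    for name in _session_names(config):
        d = _require(sdir / name, "simulate")
        audio = eio.read_wav(d / "audio.wav")
        tracks, meta = eio.read_emg(d / "emg.csv")
        from .synthgen import SynthSession  # light reuse of the carrier type

        session = SynthSession(
            audio=audio,
            emg=tracks,
            truth_f0=None,  # type: ignore[arg-type]
            truth_intensity=None,  # type: ignore[arg-type]
            task_label=meta["task"],
            calibration_offset_db=meta["calibration_offset_db"],
            coupling_gains=np.asarray(meta["coupling_gains"]),
        )
        paths, warped = align_emg_to_audio(session, hop=hop)
        od = adir / name
        od.mkdir(parents=True, exist_ok=True)
        down = [_downsample(w, tracks[0].rate) for w in warped]
        eio.write_emg(od / "aligned_emg.csv", down, meta=meta)
        for ci, p in enumerate(paths, start=1):
            np.savetxt(
                od / f"path_ch{ci}.tsv",
                p.pairs,
                fmt="%d",
                delimiter="\t",
                header="emg_hop\taudio_hop",
            )
        diag = np.mean(
            [
                np.mean(np.abs(p.pairs[:, 0] - p.pairs[:, 1]) <= 1)
                for p in paths
            ]
        )
        stats.append(diag)
    return {"mean_near_diagonal_fraction": float(np.mean(stats))}


def _stage_targets(config: ExperimentConfig) -> dict:
    sdir = config.out_dir / "sessions"
    tdir = config.out_dir / "targets"
    params = config.pitch_params()
    cov = float(config["min_coverage"])
    counts = {"f0": 0, "intensity": 0}
    for name in _session_names(config):
        d = _require(sdir / name, "simulate")
        audio = eio.read_wav(d / "audio.wav")
        _, meta = eio.read_emg(d / "emg.csv")
        od = tdir / name
        od.mkdir(parents=True, exist_ok=True)

        f0 = extract_f0(audio, params)
        eio.write_contour(od / "f0_contour.tsv", f0)
        spec_f0 = config.frame_spec("f0")
        f0_frames = frame_targets(f0, spec_f0.frame_len, spec_f0.step, cov)
        eio.write_contour(od / "f0_frames.tsv", f0_frames)
        counts["f0"] += f0_frames.n_defined

        inten = extract_intensity(audio, f_min=params.f_min)
        cal = CalibrationInfo(
            meter_reading=float(meta["calibration_offset_db"]),
            measured_level=0.0,
        )
        spl = calibrate_spl(inten, cal)
        eio.write_contour(od / "intensity_contour.tsv", spl)
        spec_int = config.frame_spec("intensity")
        int_frames = frame_targets(spl, spec_int.frame_len, spec_int.step, cov)
        eio.write_contour(od / "intensity_frames.tsv", int_frames)
        counts["intensity"] += int_frames.n_defined
    return {"defined_target_frames": counts}


def _stage_features(config: ExperimentConfig) -> dict:
    adir = config.out_dir / "aligned"
    fdir = config.out_dir / "features"
    dims: dict[str, int] = {}
    for name in _session_names(config):
        d = _require(adir / name, "align")
        tracks, _ = eio.read_emg(d / "aligned_emg.csv")
        rate = tracks[0].rate
        channels = [t.samples for t in tracks]
        od = fdir / name
        od.mkdir(parents=True, exist_ok=True)
        for stream in STREAMS:
            fm = extract_all(channels, rate, config.frame_spec(stream))
            np.save(od / f"{stream}.npy", fm.values.astype(np.float32))
            np.save(od / f"{stream}_times.npy", fm.frame_times)
            with open(od / f"{stream}_names.json", "w") as fh:
                json.dump(fm.feature_names, fh)
                fh.write("\n")
            dims[stream] = fm.n_features
    return {"feature_dimension": dims}


def _load_stream_dataset(config: ExperimentConfig, stream: str):
    """Concatenate per-session features and frame targets for one stream."""
    fdir = config.out_dir / "features"
    tdir = config.out_dir / "targets"
    X_parts, y_parts, labels, sess_ids, times = [], [], [], [], []
    for name in _session_names(config):
        feats = np.load(_require(fdir / name / f"{stream}.npy", "features"))
        ft = np.load(fdir / name / f"{stream}_times.npy")
        targ = eio.read_contour(
            _require(tdir / name / f"{stream}_frames.tsv", "targets")
        )
        n = min(feats.shape[0], len(targ))
        if n and not np.allclose(ft[:n], targ.times[:n], atol=1e-9):
            raise ValueError(f"frame-grid mismatch in session {name}")
        keep = targ.defined[:n]
        X_parts.append(feats[:n][keep])
        y_parts.append(targ.values[:n][keep])
        task = name.rsplit("_", 1)[0]
        labels.extend([task] * int(keep.sum()))
        sess_ids.extend([name] * int(keep.sum()))
        times.append(targ.times[:n][keep])
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    return X, y, np.asarray(labels), np.asarray(sess_ids), np.concatenate(times)


def _stage_prep(config: ExperimentConfig) -> dict:
    pdir = config.out_dir / "prep"
    pdir.mkdir(parents=True, exist_ok=True)
    seed = config.stage_seed("prep")
    info = {}
    for stream in STREAMS:
        X, y, labels, sess_ids, times = _load_stream_dataset(config, stream)
        split = stratified_split(labels, seed=seed, k=int(config["k_folds"]))
        np.savez(
            pdir / f"dataset_{stream}.npz",
            X=X.astype(np.float32),
            y=y,
            labels=labels,
            sessions=sess_ids,
            times=times,
            test_idx=split.test_idx,
            train_idx=split.train_idx,
            fold=split.fold,
            k=split.k,
        )
        info[stream] = {
            "n_frames": int(X.shape[0]),
            "n_test": int(split.test_idx.size),
            "n_features": int(X.shape[1]),
        }
    return {"datasets": info}


def _reload_split(pdir: Path, stream: str):
    from .mlprep import DatasetSplit

    z = np.load(_require(pdir / f"dataset_{stream}.npz", "prep"), allow_pickle=True)
    split = DatasetSplit(
        test_idx=z["test_idx"],
        train_idx=z["train_idx"],
        labels=z["labels"],
        fold=z["fold"],
        k=int(z["k"]),
    )
    return z, split


def evaluate_predictions(
    y_raw: np.ndarray,
    pred_out: np.ndarray,
    tt: TargetTransform,
    dataset_tag: str,
) -> EvalReport:
    """Metrics in the output unit, with MAPE on the raw unit (Hz / dB SPL).

    MAPE on speaker-relative semitones is ill-defined near 0 ST, so percent
    error is always computed on the raw scale.
    """
    obs_out = np.asarray(tt.forward(y_raw))
    rep = compute_metrics(obs_out, pred_out, unit=tt.output_unit, dataset_tag=dataset_tag)
    raw_pred = tt.inverse(pred_out)
    raw_rep = compute_metrics(np.asarray(y_raw), raw_pred, unit="raw", dataset_tag=dataset_tag)
    rep.mape = raw_rep.mape
    rep.n_mape_excluded = raw_rep.n_mape_excluded
    return rep


def _save_model(path: Path, model, pca) -> None:
    net = model.net
    arrays = {}
    for i, (W, b) in enumerate(zip(net.W, net.b)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    if net.bn:
        arrays.update(
            gamma=net.gamma,
            beta=net.beta,
            run_mean=net.run_mean,
            run_var=net.run_var,
        )
    arrays.update(
        feat_mean=model.feat_mean,
        feat_std=model.feat_std,
        pca_mean=pca.mean,
        pca_scale=pca.scale,
        pca_components=pca.components,
        pca_evr=pca.explained_variance_ratio,
    )
    tt = model.target_transform
    meta = {
        "config": {
            "scheme": model.config.scheme,
            "input_dim": model.config.input_dim,
            "hidden_layers": list(model.config.hidden_layers),
            "learning_rate": model.config.learning_rate,
            "batch_size": model.config.batch_size,
            "batch_norm_first": model.config.batch_norm_first,
            "target_transform": model.config.target_transform,
            "max_epochs": model.config.max_epochs,
            "patience": model.config.patience,
            "seed": model.config.seed,
            "dtype": model.config.dtype,
        },
        "target_transform": {
            "kind": tt.kind,
            "ref": tt.ref,
            "vmin": tt.vmin,
            "vmax": tt.vmax,
        },
        "best_epoch": model.best_epoch,
        "pca_components": int(pca.n_components),
    }
    np.savez(path.with_suffix(".npz"), **arrays)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _load_model(path: Path):
    from .mlprep import PCAModel
    from .regressor import TrainedModel, _Net

    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    z = np.load(path.with_suffix(".npz"))
    cfg = meta["config"]
    cfg["hidden_layers"] = tuple(cfg["hidden_layers"])
    config = ModelConfig(**cfg)
    net = _Net(config)
    for i in range(len(net.W)):
        net.W[i] = z[f"W{i}"]
        net.b[i] = z[f"b{i}"]
    if net.bn:
        net.gamma = z["gamma"]
        net.beta = z["beta"]
        net.run_mean = z["run_mean"]
        net.run_var = z["run_var"]
    ttm = meta["target_transform"]
    tt = TargetTransform(
        kind=ttm["kind"], ref=ttm["ref"], vmin=ttm["vmin"], vmax=ttm["vmax"]
    )
    model = TrainedModel(
        config=config,
        net=net,
        target_transform=tt,
        feat_mean=z["feat_mean"],
        feat_std=z["feat_std"],
        best_epoch=meta["best_epoch"],
    )
    pca = PCAModel(
        mean=z["pca_mean"],
        scale=z["pca_scale"],
        components=z["pca_components"],
        explained_variance_ratio=z["pca_evr"],
        n_components=z["pca_components"].shape[0],
    )
    return model, pca


def _stage_train(config: ExperimentConfig) -> dict:
    pdir = config.out_dir / "prep"
    mdir = config.out_dir / "train"
    mdir.mkdir(parents=True, exist_ok=True)
    seed = config.stage_seed("train")
    overrides = dict(config["model"])
    if "hidden_layers" in overrides:
        overrides["hidden_layers"] = tuple(overrides["hidden_layers"])
    info: dict = {}
    for stream in STREAMS:
        z, split = _reload_split(pdir, stream)
        X, y = z["X"].astype(np.float64), z["y"]
        folds = make_folds(split)
        n_train = int(config["folds_to_train"] or split.k)
        fold_models = []
        fold_reports_val: list[EvalReport] = []
        fold_reports_train: list[EvalReport] = []
        fold_meta = []
        for fi, (tr, va) in enumerate(folds[:n_train]):
            pca = fit_pca(X[tr], variance_target=float(config["pca_variance"]))
            Xtr = apply_pca(pca, X[tr])
            Xva = apply_pca(pca, X[va])
            Xtr_aug, ytr_aug = augment_gaussian(
                Xtr, scale=float(config["augment_scale"]), seed=seed + 97 * fi,
                targets=y[tr],
            )
            mcfg = ModelConfig.for_scheme(
                config["schemes"][stream],
                input_dim=Xtr.shape[1],
                seed=seed + fi,
                **overrides,
            )
            model = train_model(mcfg, Xtr_aug, ytr_aug, Xva, y[va])
            pred_va = predict(model, Xva)
            pred_tr = predict(model, Xtr)
            rep_va = evaluate_predictions(
                y[va], pred_va, model.target_transform, "validation"
            )
            rep_tr = evaluate_predictions(
                y[tr], pred_tr, model.target_transform, "train"
            )
            fold_models.append((model, pca))
            fold_reports_val.append(rep_va)
            fold_reports_train.append(rep_tr)
            fold_meta.append(
                {
                    "fold": fi + 1,
                    "pca_components": pca.n_components,
                    "epochs": len(model.history),
                    "train": rep_tr.as_dict(),
                    "validation": rep_va.as_dict(),
                }
            )
            pd.DataFrame(
                model.history, columns=["train_loss", "val_loss"]
            ).to_csv(mdir / f"history_{stream}_fold{fi + 1}.csv", index=False)
        final = select_final_fold(fold_reports_val)
        _save_model(mdir / f"model_{stream}", *fold_models[final])
        summary = {
            "folds": fold_meta,
            "final_fold": final + 1,
        }
        if len(fold_reports_val) >= 2:
            summary["validation_mean_sd"] = {
                k: list(v) for k, v in summarize_folds(fold_reports_val).items()
            }
            summary["train_mean_sd"] = {
                k: list(v) for k, v in summarize_folds(fold_reports_train).items()
            }
        with open(mdir / f"folds_{stream}.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        info[stream] = {
            "final_fold": final + 1,
            "pca_components": fold_meta[final]["pca_components"],
        }
    return {"training": info}


def _stage_evaluate(config: ExperimentConfig) -> dict:
    pdir = config.out_dir / "prep"
    mdir = config.out_dir / "train"
    edir = config.out_dir / "eval"
    edir.mkdir(parents=True, exist_ok=True)
    results = {}
    for stream in STREAMS:
        z, split = _reload_split(pdir, stream)
        _require(mdir / f"model_{stream}.npz", "train")
        model, pca = _load_model(mdir / f"model_{stream}")
        X = z["X"].astype(np.float64)
        y = z["y"]
        te = split.test_idx
        pred = predict(model, apply_pca(pca, X[te]))
        rep = evaluate_predictions(y[te], pred, model.target_transform, "test")
        with open(edir / f"report_{stream}.json", "w") as fh:
            json.dump(rep.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        obs_out = np.asarray(model.target_transform.forward(y[te]))
        overlay = pd.DataFrame(
            {
                "time_s": z["times"][te],
                "observed": obs_out,
                "predicted": pred,
            }
        )
        overlay.insert(0, "session", z["sessions"][te])
        overlay.to_csv(edir / f"overlay_{stream}.tsv", sep="\t", index=False)
        results[stream] = rep.as_dict()
    return {"test": results}


def _stage_predict(config: ExperimentConfig) -> dict:
    mdir = config.out_dir / "train"
    fdir = config.out_dir / "features"
    odir = config.out_dir / "predictions"
    odir.mkdir(parents=True, exist_ok=True)
    n_rows = {}
    for stream in STREAMS:
        _require(mdir / f"model_{stream}.npz", "train")
        model, pca = _load_model(mdir / f"model_{stream}")
        for name in _session_names(config):
            feats = np.load(
                _require(fdir / name / f"{stream}.npy", "features")
            ).astype(np.float64)
            times = np.load(fdir / name / f"{stream}_times.npy")
            pred = predict(model, apply_pca(pca, feats))
            df = pd.DataFrame({"time_s": times, "predicted": pred})
            (odir / name).mkdir(parents=True, exist_ok=True)
            df.to_csv(odir / name / f"{stream}.tsv", sep="\t", index=False)
            n_rows[stream] = n_rows.get(stream, 0) + len(df)
    return {"predicted_rows": n_rows}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "align": _stage_align,
    "targets": _stage_targets,
    "features": _stage_features,
    "prep": _stage_prep,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
    "predict": _stage_predict,
}


def run_stage(stage: str, config: ExperimentConfig) -> dict:
    """Run one pipeline stage; returns the manifest extras it recorded."""
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    extra = _STAGE_FUNCS[stage](config)
    _write_manifest(config, stage, extra)
    return extra


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run (per-fold table + test)."""
    run_dir = Path(run_dir)
    lines = []
    for stream in STREAMS:
        fpath = run_dir / "train" / f"folds_{stream}.json"
        epath = run_dir / "eval" / f"report_{stream}.json"
        _require(epath, "evaluate")
        with open(fpath) as fh:
            folds = json.load(fh)
        with open(epath) as fh:
            test = json.load(fh)
        lines.append(f"== {stream} ==")
        lines.append("fold  dataset      MAPE%      r     CCC    RMSE     MBE")
        for fm in folds["folds"]:
            for tag in ("train", "validation"):
                rep = fm[tag]
                lines.append(
                    f"{fm['fold']:>4}  {tag:<11}"
                    f"{rep['mape']:>8.2f}{rep['pearson_r']:>7.3f}"
                    f"{rep['ccc']:>8.3f}{rep['rmse']:>8.3f}{rep['mbe']:>8.3f}"
                )
        if "validation_mean_sd" in folds:
            ms = folds["validation_mean_sd"]
            lines.append(
                "validation mean±SD: "
                + ", ".join(
                    f"{k}={v[0]:.3f}±{v[1]:.3f}" for k, v in sorted(ms.items())
                )
            )
        lines.append(f"final fold: {folds['final_fold']}")
        lines.append(
            f"test ({test['unit']}, n={test['n_frames']}): "
            f"MAPE={test['mape']:.2f}% r={test['pearson_r']:.3f} "
            f"CCC={test['ccc']:.3f} RMSE={test['rmse']:.3f} MBE={test['mbe']:.3f}"
        )
        lines.append("")
    return "\n".join(lines)
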