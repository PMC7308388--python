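"""End-to-end orchestration: staged disk pipeline and in-memory experiments.

Stage seeds are derived deterministically from the global seed and the
stage name, so re-running any stage with the same config reproduces its
artifacts bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import dbn as dbn_mod
from . import psychophysics as psy
from . import rsa as rsa_mod
from .config import ExperimentConfig
from .errors import DependencyError, InvalidArgumentError
from .renderer import downscale_image, measure_empirical_features, render_dot_array
from .stimulus_space import (
    StimulusPoint,
    build_full_grid,
    derive_features,
    grid_to_frame,
    log_grid_levels,
    numerosity_levels,
)
from .trials import (
    ChoiceDataset,
    TrialPair,
    dataset_to_frame,
    sample_comparison_pairs,
    sample_uniform_pairs,
    simulate_observer,
)

logger = logging.getLogger(__name__)

__all__ = [
    "STAGES",
    "stage_seed",
    "run_stage",
    "report",
    "run_developmental_experiment",
    "DevelopmentalResult",
]

STAGES = (
    "generate",
    "render",
    "pairs",
    "observer",
    "fit",
    "train",
    "task",
    "rsa",
    "report",
)

#: Candidate features used for projection/angle analysis and categorical RDMs.
CANDIDATE_FEATURES = (
    "numerosity",
    "size",
    "spacing",
    "isa",
    "tsa",
    "fa",
    "sparsity",
    "coverage",
    "total_perimeter",
    "convex_hull",
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic 32-bit sub-seed for a named stage."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


# ---------------------------------------------------------------------------
# stimulus construction shared by the disk pipeline and in-memory experiments
# ---------------------------------------------------------------------------


def _level_grids(cfg: ExperimentConfig):
    s = cfg.stimulus
    nums = numerosity_levels(*s.num_range, s.levels)
    sizes = log_grid_levels(*s.size_range, s.levels)
    spacings = log_grid_levels(*s.spacing_range, s.levels)
    return nums, sizes, spacings


def _with_instance_offset(points: list[StimulusPoint], offset: int) -> list[StimulusPoint]:
    return [dataclasses.replace(p, instance_id=p.instance_id + offset) for p in points]


def build_stimulus_points(cfg: ExperimentConfig):
    """Stimulus sets: unsupervised-learning grid, task grid, held-out test
    grid (disjoint instance ids) and RSA probe set.

    Mirroring the experimental design, the unsupervised image set spans a
    wider numerosity range than the task space; size/spacing grids are
    shared.  When no separate range is configured the task grid doubles
    as the unsupervised set.
    """
    nums, sizes, spacings = _level_grids(cfg)
    s = cfg.stimulus
    train = build_full_grid(nums, sizes, spacings, instances=s.instances)
    test = _with_instance_offset(
        build_full_grid(nums, sizes, spacings, instances=s.test_instances),
        s.instances,
    )
    idx = cfg.analysis.rsa_level_indices
    probe = rsa_mod.build_probe_set(
        nums, sizes, spacings, level_indices=(idx, idx, idx),
        instances=cfg.analysis.rsa_instances,
    )
    probe = _with_instance_offset(probe, s.instances + s.test_instances)
    if s.unsup_num_range is None:
        unsup = train
    else:
        unsup_nums = numerosity_levels(*s.unsup_num_range, s.unsup_num_levels)
        unsup = build_full_grid(
            unsup_nums, sizes, spacings, instances=s.unsup_instances
        )
        unsup = _with_instance_offset(
            unsup, s.instances + s.test_instances + cfg.analysis.rsa_instances
        )
    return unsup, train, test, probe


def _dbn_hyper(cfg: ExperimentConfig) -> tuple:
    d = cfg.dbn
    return (
        dbn_mod.RbmHyper(
            learning_rate=d.lr_layer1,
            batch_size=d.batch_size,
            init_sigma=d.init_sigma,
            init_visible_bias_from_data=d.init_visible_bias_from_data,
        ),
        dbn_mod.RbmHyper(
            learning_rate=d.lr_layer2,
            batch_size=d.batch_size,
            init_sigma=d.init_sigma,
            init_visible_bias_from_data=d.init_visible_bias_from_data,
        ),
    )


def render_points(
    points: Sequence[StimulusPoint],
    cfg: ExperimentConfig,
    rng: np.random.Generator,
    measure_hull: bool = False,
):
    """Render points to a flattened image matrix (optionally measuring hulls)."""
    s = cfg.stimulus
    imgs, hulls = [], []
    for p in points:
        img = render_dot_array(p, canvas=s.canvas, rng=rng)
        if measure_hull:
            hulls.append(measure_empirical_features(img).convex_hull_area)
        pix = img.pixels.astype(float)
        if s.downscale is not None:
            pix = downscale_image(pix, s.downscale)
        imgs.append(pix.ravel())
    mat = np.stack(imgs)
    return (mat, np.array(hulls)) if measure_hull else mat


# ---------------------------------------------------------------------------
# in-memory developmental experiment (Young vs Mature across seeds)
# ---------------------------------------------------------------------------


@dataclass
class StageOutcome:
    """Per-(seed, developmental stage) behavioral and representational results."""

    fit: psy.GlmFit
    accuracy: float
    rdm: rsa_mod.Rdm
    taus: dict[str, float]


@dataclass
class DevelopmentalResult:
    seeds: list[int]
    young: list[StageOutcome]
    mature: list[StageOutcome]
    relatedness: dict[str, dict]
    noise_ceiling: dict[str, tuple[float, float]]
    config: ExperimentConfig = field(repr=False)

    def betas(self, stage: str, name: str) -> np.ndarray:
        outcomes = getattr(self, stage)
        return np.array([getattr(o.fit, name) for o in outcomes])


def _categorical_rdms(
    probe_points: Sequence[StimulusPoint], probe_hulls: np.ndarray
) -> tuple[dict[str, rsa_mod.Rdm], tuple]:
    """Candidate RDMs from nominal features; convex hull from measured means."""
    by_cond: dict[tuple, list[int]] = {}
    for i, p in enumerate(probe_points):
        by_cond.setdefault(rsa_mod.condition_key(p), []).append(i)
    conditions = tuple(sorted(by_cond))
    values: dict[str, list[float]] = {f: [] for f in CANDIDATE_FEATURES}
    for c in conditions:
        n, size, spacing = c
        fb = derive_features(StimulusPoint(n=int(n), size=size, spacing=spacing))
        values["numerosity"].append(n)
        values["size"].append(size)
        values["spacing"].append(spacing)
        values["isa"].append(fb.isa)
        values["tsa"].append(fb.tsa)
        values["fa"].append(fb.fa)
        values["sparsity"].append(fb.sparsity)
        values["coverage"].append(fb.coverage)
        values["total_perimeter"].append(fb.total_perimeter)
        values["convex_hull"].append(float(np.mean(probe_hulls[by_cond[c]])))
    rdms = {
        name: rsa_mod.categorical_rdm(vals, conditions, name=name)
        for name, vals in values.items()
    }
    return rdms, conditions


def _probe_rdm(model, probe_images, probe_points, conditions) -> rsa_mod.Rdm:
    codes = dbn_mod.encode(model, probe_images)
    by_cond: dict[tuple, list[np.ndarray]] = {}
    for p, code in zip(probe_points, codes):
        by_cond.setdefault(rsa_mod.condition_key(p), []).append(code)
    patterns, conds = rsa_mod.mean_activation_patterns(by_cond)
    assert conds == conditions
    return rsa_mod.model_rdm(patterns, conds)


def run_developmental_experiment(
    cfg: ExperimentConfig,
    n_seeds: int | None = None,
    progress: bool = False,
) -> DevelopmentalResult:
    """Train ``n_seeds`` networks; compare Young vs Mature behavior and RSA.

    One shared stimulus set (rendered once) feeds every seed: the DBN is
    trained unsupervised on the training images, an identical-protocol
    readout is trained per checkpoint on training-image pairs, choices are
    collected on held-out test pairs and fitted with the choice GLM, and
    probe-set RDMs are related to the categorical feature RDMs.
    """
    cfg.validate()
    n_seeds = cfg.dbn.n_seeds if n_seeds is None else n_seeds
    unsup_pts, train_pts, test_pts, probe_pts = build_stimulus_points(cfg)

    rng_render = np.random.default_rng(stage_seed(cfg.seed, "render"))
    unsup_imgs = render_points(unsup_pts, cfg, rng_render)
    train_imgs = (
        unsup_imgs if unsup_pts is train_pts else render_points(train_pts, cfg, rng_render)
    )
    test_imgs = render_points(test_pts, cfg, rng_render)
    probe_imgs, probe_hulls = render_points(probe_pts, cfg, rng_render, measure_hull=True)

    cat_rdms, conditions = _categorical_rdms(probe_pts, probe_hulls)

    rng_pairs = np.random.default_rng(stage_seed(cfg.seed, "pairs"))
    train_index = {p: i for i, p in enumerate(train_pts)}
    test_index = {p: i for i, p in enumerate(test_pts)}
    readout_pairs = sample_uniform_pairs(train_pts, cfg.trials.n_readout_pairs, rng_pairs)
    test_pairs = sample_uniform_pairs(test_pts, cfg.trials.n_uniform_pairs, rng_pairs)
    ro_left = np.array([train_index[p.left] for p in readout_pairs])
    ro_right = np.array([train_index[p.right] for p in readout_pairs])
    te_left = np.array([test_index[p.left] for p in test_pairs])
    te_right = np.array([test_index[p.right] for p in test_pairs])
    readout_labels = [p.correct_side for p in readout_pairs]

    protocol = dbn_mod.ReadoutProtocol()
    hyper = _dbn_hyper(cfg)

    seeds = list(range(n_seeds))
    young_out, mature_out = [], []
    for s in seeds:
        if progress:
            logger.info("training network seed %d/%d", s + 1, n_seeds)
        checkpoints = dbn_mod.train_dbn(
            unsup_imgs,
            arch=cfg.dbn.arch,
            epochs=cfg.dbn.epochs,
            hyper=hyper,
            rng=stage_seed(cfg.seed, f"dbn-{s}"),
            checkpoint_epochs=(cfg.dbn.young_epoch, cfg.dbn.epochs),
            dtype=np.float32,
        )
        for epoch, bucket in (
            (cfg.dbn.young_epoch, young_out),
            (cfg.dbn.epochs, mature_out),
        ):
            model = checkpoints[epoch]
            # encode each unique image once; pairs index into the codes
            train_codes = dbn_mod.encode(model, train_imgs)
            test_codes = dbn_mod.encode(model, test_imgs)
            readout = dbn_mod.train_readout_codes(
                np.hstack([train_codes[ro_left], train_codes[ro_right]]),
                readout_labels,
                protocol,
            )
            choices = dbn_mod.run_comparison_task_codes(
                readout,
                test_pairs,
                np.hstack([test_codes[te_left], test_codes[te_right]]),
                rng=np.random.default_rng(stage_seed(cfg.seed, f"task-{s}-{epoch}")),
                observer_id=f"net-seed{s}-epoch{epoch}",
            )
            fit = psy.fit_choice_glm(choices, gamma_mode=cfg.analysis.gamma_mode)
            rdm = _probe_rdm(model, probe_imgs, probe_pts, conditions)
            taus = {name: rsa_mod.kendall_tau_a(rdm, cat) for name, cat in cat_rdms.items()}
            bucket.append(
                StageOutcome(fit=fit, accuracy=choices.accuracy(), rdm=rdm, taus=taus)
            )

    relatedness, ceilings = {}, {}
    for stage, bucket in (("young", young_out), ("mature", mature_out)):
        rdms = [o.rdm for o in bucket]
        if len(rdms) >= 5:
            relatedness[stage] = rsa_mod.relatedness_test(
                rdms, cat_rdms, q=cfg.analysis.fdr_q
            )
        if len(rdms) >= 2:
            ceilings[stage] = rsa_mod.noise_ceiling(rdms)

    return DevelopmentalResult(
        seeds=seeds,
        young=young_out,
        mature=mature_out,
        relatedness=relatedness,
        noise_ceiling=ceilings,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# staged disk pipeline
# ---------------------------------------------------------------------------


def _manifest_path(run_dir: Path) -> Path:
    return run_dir / "manifest.json"


def _load_manifest(run_dir: Path) -> dict:
    path = _manifest_path(run_dir)
    return json.loads(path.read_text()) if path.exists() else {"stages": {}}


def _save_manifest(run_dir: Path, manifest: dict) -> None:
    _manifest_path(run_dir).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _require(run_dir: Path, *relpaths: str) -> None:
    for rel in relpaths:
        if not (run_dir / rel).exists():
            raise DependencyError(f"missing artifact {rel!r}; run its stage first")


def _points_from_frame(df: pd.DataFrame) -> list[StimulusPoint]:
    return [
        StimulusPoint(
            n=int(r.n), size=float(r.size), spacing=float(r.spacing),
            instance_id=int(r.instance_id),
        )
        for r in df.itertuples()
    ]


def _frame_for_points(points: Sequence[StimulusPoint], role: str) -> pd.DataFrame:
    df = grid_to_frame(points)
    df.insert(0, "role", role)
    return df


def _fit_payload(fit: psy.GlmFit) -> dict:
    v = psy.discrimination_vector(fit)
    angles, ranking = psy.angles_to_axes(v) if v.magnitude > 0 else ({}, [])
    return {
        "beta_side": fit.beta_side,
        "beta_num": fit.beta_num,
        "beta_size": fit.beta_size,
        "beta_spacing": fit.beta_spacing,
        "gamma": fit.gamma,
        "deviance": fit.deviance,
        "adj_r2": fit.adj_r2,
        "se": fit.se,
        "n_trials": fit.n_trials,
        "magnitude": v.magnitude,
        "projections": psy.project_onto_axes(v),
        "angles": angles,
        "angle_ranking": ranking,
        "weber_fraction": (
            psy.weber_fraction(fit) if fit.beta_num > 0 else None
        ),
    }


def run_stage(name: str, cfg: ExperimentConfig, run_dir: str | Path) -> dict:
    """Execute one pipeline stage; outputs land under ``run_dir``.

    Stages are idempotent: completed stages (per the run manifest) are
    skipped.  Configuration is validated before any computation.
    """
    if name not in STAGES:
        raise InvalidArgumentError(f"unknown stage {name!r}; stages: {STAGES}")
    cfg.validate()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(run_dir)
    cfg_hash = hashlib.sha256(cfg.to_json().encode()).hexdigest()[:16]
    manifest.setdefault("config_hash", cfg_hash)
    manifest.setdefault("config", json.loads(cfg.to_json()))
    if manifest["config_hash"] != cfg_hash:
        raise InvalidArgumentError("run directory was created with a different config")

    if name in manifest["stages"]:
        logger.info("stage %s already complete; skipping", name)
        return manifest["stages"][name]

    handler = _STAGE_HANDLERS[name]
    outputs = handler(cfg, run_dir)
    manifest["stages"][name] = {
        "outputs": outputs,
        "seed": stage_seed(cfg.seed, name),
    }
    _save_manifest(run_dir, manifest)
    return manifest["stages"][name]


def _stage_generate(cfg: ExperimentConfig, run_dir: Path) -> list[str]:
    unsup, train, test, probe = build_stimulus_points(cfg)
    frames = [
        _frame_for_points(train, "train"),
        _frame_for_points(test, "test"),
        _frame_for_points(probe, "probe"),
    ]
    if unsup is not train:
        frames.insert(0, _frame_for_points(unsup, "unsup"))
    df = pd.concat(frames, ignore_index=True)
    out = run_dir / "stimuli.csv"
    df.to_csv(out, index=False)
    return ["stimuli.csv"]


def _stage_render(cfg: ExperimentConfig, run_dir: Path) -> list[str]:
    _require(run_dir, "stimuli.csv")
    df = pd.read_csv(run_dir / "stimuli.csv")
    rng = np.random.default_rng(stage_seed(cfg.seed, "render"))
    outputs = []
    roles = list(dict.fromkeys(df.role))
    for role in roles:
        pts = _points_from_frame(df[df.role == role])
        if role == "probe":
            imgs, hulls = render_points(pts, cfg, rng, measure_hull=True)
        else:
            imgs = render_points(pts, cfg, rng)
        path = run_dir / f"images_{role}.npz"
        payload = {"images": imgs.astype(np.float32)}
        if role == "probe":
            payload["hulls"] = hulls
        np.savez_compressed(path, **payload)
        outputs.append(path.name)
    return outputs


def _stage_pairs(cfg: ExperimentConfig, run_dir: Path) -> list[str]:
    _require(run_dir, "stimuli.csv")
    df = pd.read_csv(run_dir / "stimuli.csv")
    train_pts = _points_from_frame(df[df.role == "train"])
    test_pts = _points_from_frame(df[df.role == "test"])
    rng = np.random.default_rng(stage_seed(cfg.seed, "pairs"))
    protocol_pairs = sample_comparison_pairs(
        train_pts, cfg.trials.n_comparison_pairs, cfg.trials.quota_bins(), rng
    )
    readout_pairs = sample_uniform_pairs(train_pts, cfg.trials.n_readout_pairs, rng)
    test_pairs = sample_uniform_pairs(test_pts, cfg.trials.n_uniform_pairs, rng)
    index = {"train": {p: i for i, p in enumerate(train_pts)},
             "test": {p: i for i, p in enumerate(test_pts)}}

    def frame(pairs, role):
        rows = []
        for p in pairs:
            rows.append(
                {
                    "pair_id": p.pair_id,
                    "left_idx": index[role][p.left],
                    "right_idx": index[role][p.right],
                    "n_left": p.left.n,
                    "n_right": p.right.n,
                    "size_left": p.left.size,
                    "size_right": p.right.size,
                    "spacing_left": p.left.spacing,
                    "spacing_right": p.right.spacing,
                    "instance_left": p.left.instance_id,
                    "instance_right": p.right.instance_id,
                }
            )
        return pd.DataFrame(rows)

    outputs = []
    for pairs, role, fname in (
        (protocol_pairs, "train", "pairs_protocol.csv"),
        (readout_pairs, "train", "pairs_readout.csv"),
        (test_pairs, "test", "pairs_test.csv"),
    ):
        frame(pairs, role).to_csv(run_dir / fname, index=False)
        outputs.append(fname)
    return outputs


def _pairs_from_frame(df: pd.DataFrame) -> list[TrialPair]:
    pairs = []
    for r in df.itertuples():
        pairs.append(
            TrialPair(
                left=StimulusPoint(int(r.n_left), float(r.size_left),
                                   float(r.spacing_left), int(r.instance_left)),
                right=StimulusPoint(int(r.n_right), float(r.size_right),
                                    float(r.spacing_right), int(r.instance_right)),
                pair_id=int(r.pair_id),
            )
        )
    return pairs


def _stage_observer(cfg: ExperimentConfig, run_dir: Path) -> list[str]:
    _require(run_dir, "pairs_protocol.csv")
    pairs = _pairs_from_frame(pd.read_csv(run_dir / "pairs_protocol.csv"))
    rng = np.random.default_rng(stage_seed(cfg.seed, "observer"))
    data = simulate_observer(
        pairs,
        betas=cfg.observer.betas,
        gamma=cfg.observer.gamma,
        rt_model=(cfg.observer.rt_median_ms, cfg.observer.rt_sigma),
        rng=rng,
    )
    dataset_to_frame(data).to_csv(run_dir / "observer_choices.csv", index=False)
    return ["observer_choices.csv"]


def _choices_from_csv(path: Path, pairs: list[TrialPair]) -> ChoiceDataset:
    df = pd.read_csv(path)
    by_id = {p.pair_id: p for p in pairs}
    trials = [by_id[int(i)] for i in df.pair_id]
    rts = None
    if "response_time" in df and df.response_time.notna().all():
        rts = df.response_time.tolist()
    return ChoiceDataset(
        trials=trials,
        chosen_side=df.chosen_side.tolist(),
        response_time=rts,
        observer_id=str(df.observer_id.iloc[0]),
    )


def _stage_fit(cfg: ExperimentConfig, run_dir: Path) -> list[str]:
    _require(run_dir, "observer_choices.csv", "pairs_protocol.csv")
    pairs = _pairs_from_frame(pd.read_csv(run_dir / "pairs_protocol.csv"))
    data = _choices_from_csv(run_dir / "observer_choices.csv", pairs)
    filtered, removal = psy.filter_outlier_trials(data)
    fit = psy.fit_choice_glm(filtered, gamma_mode=cfg.analysis.gamma_mode)
    payload = {"observer": _fit_payload(fit), "outlier_filter": removal}
    (run_dir / "fits_observer.json").write_text(json.dumps(payload, indent=2))
    return ["fits_observer.json"]


def _stage_train(cfg: ExperimentConfig, run_dir: Path) -> list[str]:
    _require(run_dir, "images_train.npz")
    unsup_path = run_dir / "images_unsup.npz"
    src = unsup_path if unsup_path.exists() else run_dir / "images_train.npz"
    imgs = np.load(src)["images"].astype(float)
    models_dir = run_dir / "models"
    models_dir.mkdir(exist_ok=True)
    hyper = _dbn_hyper(cfg)
    outputs = []
    for s in range(cfg.dbn.n_seeds):
        checkpoints = dbn_mod.train_dbn(
            imgs,
            arch=cfg.dbn.arch,
            epochs=cfg.dbn.epochs,
            hyper=hyper,
            rng=stage_seed(cfg.seed, f"dbn-{s}"),
            checkpoint_epochs=(cfg.dbn.young_epoch, cfg.dbn.epochs),
        )
        for epoch, model in checkpoints.items():
            path = models_dir / f"seed{s}_epoch{epoch}.npz"
            np.savez_compressed(
                path,
                w1=model.layers[0].weights,
                vb1=model.layers[0].visible_bias,
                hb1=model.layers[0].hidden_bias,
                w2=model.layers[1].weights,
                vb2=model.layers[1].visible_bias,
                hb2=model.layers[1].hidden_bias,
                meta=json.dumps(
                    {"epochs": epoch, "seed": s, "arch": list(cfg.dbn.arch)}
                ),
            )
            outputs.append(str(path.relative_to(run_dir)))
    return outputs


def load_model(path: Path) -> dbn_mod.DbnModel:
    z = np.load(path)
    meta = json.loads(str(z["meta"]))
    return dbn_mod.DbnModel(
        layers=[
            dbn_mod.RbmParams(z["w1"], z["vb1"], z["hb1"]),
            dbn_mod.RbmParams(z["w2"], z["vb2"], z["hb2"]),
        ],
        epochs_trained=meta["epochs"],
        seed=meta["seed"],
        arch_id="x".join(str(a) for a in meta["arch"]),
    )


def _stage_task(cfg: ExperimentConfig, run_dir: Path) -> list[str]:
    _require(run_dir, "images_train.npz", "images_test.npz",
             "pairs_readout.csv", "pairs_test.csv", "models")
    train_imgs = np.load(run_dir / "images_train.npz")["images"].astype(float)
    test_imgs = np.load(run_dir / "images_test.npz")["images"].astype(float)
    readout_df = pd.read_csv(run_dir / "pairs_readout.csv")
    test_df = pd.read_csv(run_dir / "pairs_test.csv")
    readout_pairs = _pairs_from_frame(readout_df)
    test_pairs = _pairs_from_frame(test_df)
    readout_imgs = [
        (train_imgs[int(r.left_idx)], train_imgs[int(r.right_idx)])
        for r in readout_df.itertuples()
    ]
    test_pair_imgs = [
        (test_imgs[int(r.left_idx)], test_imgs[int(r.right_idx)])
        for r in test_df.itertuples()
    ]
    labels = [p.correct_side for p in readout_pairs]
    protocol = dbn_mod.ReadoutProtocol()
    outputs = []
    fits = {}
    for path in sorted((run_dir / "models").glob("seed*_epoch*.npz")):
        model = load_model(path)
        readout = dbn_mod.train_readout(model, readout_imgs, labels, protocol)
        choices = dbn_mod.run_comparison_task(
            model,
            readout,
            test_pairs,
            test_pair_imgs,
            rng=np.random.default_rng(stage_seed(cfg.seed, f"task-{path.stem}")),
            observer_id=path.stem,
        )
        fname = f"choices_{path.stem}.csv"
        dataset_to_frame(choices).to_csv(run_dir / fname, index=False)
        outputs.append(fname)
        fit = psy.fit_choice_glm(choices, gamma_mode=cfg.analysis.gamma_mode)
        fits[path.stem] = _fit_payload(fit)
        fits[path.stem]["accuracy"] = choices.accuracy()
    (run_dir / "fits_networks.json").write_text(json.dumps(fits, indent=2))
    outputs.append("fits_networks.json")
    return outputs


def _stage_rsa(cfg: ExperimentConfig, run_dir: Path) -> list[str]:
    _require(run_dir, "stimuli.csv", "images_probe.npz", "models")
    df = pd.read_csv(run_dir / "stimuli.csv")
    probe_pts = _points_from_frame(df[df.role == "probe"])
    z = np.load(run_dir / "images_probe.npz")
    probe_imgs, hulls = z["images"].astype(float), z["hulls"]
    cat_rdms, conditions = _categorical_rdms(probe_pts, hulls)

    by_epoch: dict[int, list[rsa_mod.Rdm]] = {}
    taus: dict[str, dict[str, float]] = {}
    for path in sorted((run_dir / "models").glob("seed*_epoch*.npz")):
        model = load_model(path)
        rdm = _probe_rdm(model, probe_imgs, probe_pts, conditions)
        by_epoch.setdefault(model.epochs_trained, []).append(rdm)
        taus[path.stem] = {
            name: rsa_mod.kendall_tau_a(rdm, cat) for name, cat in cat_rdms.items()
        }
    payload: dict = {"per_model_tau": taus, "relatedness": {}, "noise_ceiling": {}}
    for epoch, rdms in by_epoch.items():
        key = f"epoch{epoch}"
        if len(rdms) >= 5:
            payload["relatedness"][key] = rsa_mod.relatedness_test(
                rdms, cat_rdms, q=cfg.analysis.fdr_q
            )
        if len(rdms) >= 2:
            payload["noise_ceiling"][key] = rsa_mod.noise_ceiling(rdms)
    (run_dir / "rsa.json").write_text(json.dumps(payload, indent=2))
    return ["rsa.json"]


def report(run_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Summarize fits and RSA artifacts into tidy tables (also saved as CSV)."""
    run_dir = Path(run_dir)
    _require(run_dir, "fits_networks.json", "rsa.json")
    fits = json.loads((run_dir / "fits_networks.json").read_text())
    rsa_data = json.loads((run_dir / "rsa.json").read_text())
    coef_rows, angle_rows = [], []
    for stem, f in sorted(fits.items()):
        seed, epoch = stem.replace("seed", "").split("_epoch")
        base = {"model": stem, "seed": int(seed), "epoch": int(epoch)}
        coef_rows.append(
            {**base, **{k: f[k] for k in
                        ("beta_side", "beta_num", "beta_size", "beta_spacing",
                         "gamma", "adj_r2", "accuracy")}}
        )
        for axis, ang in f["angles"].items():
            angle_rows.append({**base, "axis": axis, "angle_deg": ang,
                               "projection": f["projections"][axis]})
    tau_rows = [
        {"model": stem, "feature": feat, "tau_a": val}
        for stem, taus in sorted(rsa_data["per_model_tau"].items())
        for feat, val in taus.items()
    ]
    tables = {
        "coefficients": pd.DataFrame(coef_rows),
        "angles": pd.DataFrame(angle_rows),
        "rsa_tau": pd.DataFrame(tau_rows),
    }
    for name, df in tables.items():
        df.to_csv(run_dir / f"report_{name}.csv", index=False)
    return tables


def _stage_report(cfg: ExperimentConfig, run_dir: Path) -> list[str]:
    report(run_dir)
    return ["report_coefficients.csv", "report_angles.csv", "report_rsa_tau.csv"]


_STAGE_HANDLERS = {
    "generate": _stage_generate,
    "render": _stage_render,
    "pairs": _stage_pairs,
    "observer": _stage_observer,
    "fit": _stage_fit,
    "train": _stage_train,
    "task": _stage_task,
    "rsa": _stage_rsa,
    "report": _stage_report,
}
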