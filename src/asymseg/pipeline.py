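"""End-to-end segmentation pipeline.

Order of stages: intensity histogram → asymmetric-Gaussian mixture fit →
membership probabilities → initial labels + overlap mask → 3-D GLCM
texture features over the target area → stepwise discriminant feature
selection → one-vs-rest RBF-SVM relabeling of the overlap voxels →
(optional) agreement evaluation against ground truth.

A single master seed is expanded into independent per-stage seeds, making
whole-pipeline runs reproducible.  When an output directory is given,
every intermediate artifact (initial labels, overlap mask, feature table,
selection report, final labels, run manifest) is persisted.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import asymem, glcm, metrics, sda, svm
from .volume_io import LabelMap, Volume3D, compute_histogram, write_labelmap, write_volume

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "features_for_voxels"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, with desk-scale defaults.

    ``train_samples`` caps the SVM training sample drawn from one volume
    (the per-volume budget of :class:`~asymseg.svm.SVMConfig` applies to
    full-resolution brains; phantom-scale grids need fewer).
    """

    n_bins: int = 256
    smoothing: int = asymem.SMOOTH_WINDOW
    r_step: float = asymem.R_STEP
    r_bounds: tuple[float, float] = asymem.R_BOUNDS
    rms_factor: float = asymem.RMS_FACTOR
    tau: float = asymem.OVERLAP_TAU
    region_grow: bool = False
    seed_threshold: float = asymem.SEED_THRESHOLD
    admit_threshold: float = asymem.ADMIT_THRESHOLD
    n_levels: int = glcm.N_LEVELS_DEFAULT
    window_size: int = glcm.WINDOW_DEFAULT
    distances: tuple[int, ...] = glcm.DISTANCES_DEFAULT
    f_enter: float = sda.F_ENTER_DEFAULT
    f_remove: float = sda.F_REMOVE_DEFAULT
    max_features: int = sda.MAX_FEATURES_DEFAULT
    svm: svm.SVMConfig = field(default_factory=svm.SVMConfig)
    train_samples: int = 2000
    refine: bool = True          # False: stop after the EM labeling + overlap mask
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if self.n_bins < 8:
            raise ValueError("n_bins must be >= 8")
        if not 0 < self.tau <= 1:
            raise ValueError("tau must lie in (0, 1]")
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")
        if self.train_samples < 30:
            raise ValueError("train_samples must be >= 30")

    def stage_seeds(self) -> dict[str, int]:
        """Independent per-stage seeds derived from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        kids = ss.spawn(3)
        names = ("sampling", "svm", "misc")
        return {n: int(k.generate_state(1)[0] % (2 ** 31)) for n, k in zip(names, kids)}


@dataclass
class PipelineResult:
    """Artifacts of one pipeline run."""

    initial_labels: LabelMap
    final_labels: LabelMap
    mixture_params: list[asymem.AsymGaussianParams]
    r_traces: list[asymem.RSearchTrace]
    overlap_count: int
    changed_count: int
    report: metrics.AgreementReport | None = None
    selection: sda.SDAResult | None = None
    manifest: dict = field(default_factory=dict)


def features_for_voxels(vol: Volume3D, indices: np.ndarray, cfg: PipelineConfig,
                        quantized: np.ndarray | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix for a list of VOI centers.

    Returns (X, missing): rows of the 130-feature vector and a boolean
    flag for voxels whose VOI was entirely background (their row is zero).
    """
    Q = quantized if quantized is not None else glcm.quantize(vol, n_levels=cfg.n_levels)
    dirs = glcm.enumerate_directions_3d()
    n_feat = 26 * len(cfg.distances)
    X = np.zeros((len(indices), n_feat))
    missing = np.zeros(len(indices), dtype=bool)
    for row, idx in enumerate(indices):
        try:
            fv = glcm.feature_vector_for_voi(
                vol, tuple(int(i) for i in idx), window_size=cfg.window_size,
                distances=cfg.distances, n_levels=cfg.n_levels, quantized=Q,
                directions=dirs)
            X[row] = fv.values
        except ValueError:
            missing[row] = True
    return X, missing


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(vol: Volume3D, cfg: PipelineConfig | None = None,
                 truth: LabelMap | None = None) -> PipelineResult:
    """Run the full segmentation on one (skull-stripped) volume."""
    cfg = cfg or PipelineConfig()
    cfg.validate()
    seeds = cfg.stage_seeds()
    out = Path(cfg.output_dir) if cfg.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    # --- stage 1: histogram + asymmetric mixture fit -----------------------
    hist = compute_histogram(vol, mask=None, n_bins=cfg.n_bins)
    params, split, traces = asymem.fit_asymmetric_mixture(
        hist, smoothing=cfg.smoothing, step=cfg.r_step, r_bounds=cfg.r_bounds)
    log.info("mixture fit: %s", [(round(p.mean, 1), round(p.sigma_first, 2),
                                  round(p.ratio, 2)) for p in params])

    # --- stage 2: membership, initial labels, overlap mask ------------------
    posteriors = asymem.membership_probability(vol, params)
    initial = asymem.initial_labeling(posteriors, region_grow=cfg.region_grow,
                                      seed_threshold=cfg.seed_threshold,
                                      admit_threshold=cfg.admit_threshold)
    overlap_mask, pair_counts = asymem.detect_overlap_voxels(posteriors, tau=cfg.tau)
    overlap_mask &= initial.foreground()
    initial = LabelMap(labels=initial.labels, overlap_mask=overlap_mask)
    n_overlap = int(overlap_mask.sum())
    log.info("initial labeling done: %d overlap voxels %s", n_overlap, pair_counts)
    if out:
        write_labelmap(initial, out / "initial_labels.nii.gz")
        write_volume(Volume3D(overlap_mask.astype(np.int16)), out / "overlap_mask.nii.gz")

    selection = None
    changed = 0
    if n_overlap == 0 or not cfg.refine:
        # no ambiguity (or EM-only run): the refinement stage has nothing to do
        final = LabelMap(labels=initial.labels.copy())
    else:
        # --- stage 3: texture features over the target area -----------------
        Q = glcm.quantize(vol, n_levels=cfg.n_levels)
        rng_n = min(cfg.train_samples, int(initial.foreground().sum()))
        train_idx, train_lab = svm.sample_training_voxels(
            initial, n=rng_n, seed=seeds["sampling"])
        overlap_idx = np.argwhere(overlap_mask)
        X_train, miss_train = features_for_voxels(vol, train_idx, cfg, quantized=Q)
        keep = ~miss_train
        X_train, train_lab = X_train[keep], train_lab[keep]

        # --- stage 4: stepwise discriminant feature selection ----------------
        selection = sda.sda_select(X_train, train_lab, f_enter=cfg.f_enter,
                                   f_remove=cfg.f_remove, max_features=cfg.max_features)
        sel = np.array(selection.selected, dtype=int) if selection.selected else None
        log.info("SDA selected %s features", len(selection.selected))
        if out:
            names = glcm.feature_names(cfg.distances)
            pd.DataFrame({"index": selection.selected,
                          "name": [names[i] for i in selection.selected],
                          }).to_csv(out / "sda_selection.csv", index=False)
            pd.DataFrame(X_train, columns=names).assign(label=train_lab).to_csv(
                out / "training_features.csv", index=False)

        # --- stage 5: SVM refinement of overlap voxels -----------------------
        svm_cfg = svm.SVMConfig(C=cfg.svm.C, kernel=cfg.svm.kernel, gamma=cfg.svm.gamma,
                                samples_per_brain=cfg.svm.samples_per_brain,
                                seed=seeds["svm"])
        refiner = svm.train_refiner(X_train, train_lab, cfg=svm_cfg, selected_indices=sel)
        X_ov, miss_ov = features_for_voxels(vol, overlap_idx, cfg, quantized=Q)
        final = svm.relabel_overlap(initial, X_ov, overlap_idx, refiner, missing=miss_ov)
        changed = int((final.labels != initial.labels).sum())
        log.info("SVM refinement relabeled %d / %d overlap voxels", changed, n_overlap)

    if out:
        write_labelmap(final, out / "final_labels.nii.gz")

    report = metrics.evaluate_segmentation(final, truth) if truth is not None else None
    manifest = {"config_hash": _config_hash(cfg), "seeds": seeds,
                "master_seed": cfg.seed, "n_overlap": n_overlap,
                "n_changed": changed, "runtime_s": round(time.time() - t0, 2)}
    if out:
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump({**manifest, "config": asdict(cfg)}, fh, default_flow_style=False)
        if report is not None:
            pd.DataFrame(report.as_rows()).to_csv(out / "agreement.csv", index=False)

    return PipelineResult(initial_labels=initial, final_labels=final,
                          mixture_params=params, r_traces=traces,
                          overlap_count=n_overlap, changed_count=changed,
                          report=report, selection=selection, manifest=manifest)
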