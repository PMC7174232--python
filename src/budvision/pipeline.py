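"""End-to-end orchestration: synthetic benchmark -> segmentation ->
features/crops -> PCA and classifier reports.

Both pipelines are deterministic per seed: every random draw funnels
through generators derived from ``RunConfig.seed``.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    GridSpec,
    LabeledDataset,
    SplitSpec,
    classify_task,
    pca_explore,
    split_dataset,
    zscore,
)
from .morphology import FEATURE_NAMES, centroid, compute_morphology
from .nn import (
    DEFAULT_ARCHITECTURE,
    DEFAULT_CANDIDATES,
    TrainConfig,
    architecture_search,
    evaluate_cnn,
    preprocess_crop,
    train_cnn,
)
from .plates import (
    PlateImage,
    correct_perspective,
    crop_instances,
    detect_finder_patterns,
    extract_contour,
    otsu_threshold,
    segment_components,
    segment_plate,
)
from .synthetic import (
    DEFAULT_CLASS_PROFILES,
    BenchmarkDataset,
    GroundTruthInstance,
    color_only_profiles,
    make_benchmark_dataset,
    sample_area_geometry,
    stage_contrast_profiles,
)

PROFILE_SETS = {
    "default": lambda: list(DEFAULT_CLASS_PROFILES),
    "stage": stage_contrast_profiles,
    "color": color_only_profiles,
}


@dataclass
class RunConfig:
    """Configuration of one reproducible benchmark run."""

    seed: int = 0
    n_per_class: int = 30
    profiles: str = "default"
    outdir: str | None = None
    min_area: int = 64
    tasks: tuple[str, ...] = ("stage", "type")
    families: tuple[str, ...] = ("knn", "mlp", "svm")
    epochs: int = 30
    batch_size: int = 128
    learning_rate: float = 1e-4
    search: bool = False
    paper_mode: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        for key in ("tasks", "families"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def match_instances(instances, gts: list[GroundTruthInstance], tol_px: float = 10.0):
    """Pair segmented instances with ground truth by nearest centroid.

    Returns ``pairs`` as a list of ``(instance, gt)``.  Raises if counts
    differ or any match exceeds ``tol_px``.
    """
    if len(instances) != len(gts):
        raise ValueError(
            f"segmentation found {len(instances)} instances, "
            f"ground truth has {len(gts)}"
        )
    inst_cents = np.array([centroid(i) for i in instances])
    pairs = []
    used = set()
    for gt in gts:
        d = np.hypot(*(inst_cents - np.array(gt.centroid)).T)
        j = int(np.argmin(d))
        if d[j] > tol_px or j in used:
            raise ValueError("instance/ground-truth centroid matching failed")
        used.add(j)
        pairs.append((instances[j], gt))
    return pairs


def gel_feature_table(
    plates: list[tuple[PlateImage, list[GroundTruthInstance]]],
    min_area: int = 64,
) -> pd.DataFrame:
    """Segment every gel plate and compute the 14 descriptors per bud.

    One row per instance: id, plate index, class, stage, then the feature
    columns in canonical order.
    """
    rows = []
    iid = 0
    for pi, (plate, gts) in enumerate(plates):
        instances = segment_plate(plate, min_area=min_area)
        for inst, gt in match_instances(instances, gts):
            vec = compute_morphology(inst, extract_contour(inst))
            rows.append(
                {"instance_id": iid, "plate": pi, "class": gt.class_name,
                 "stage": gt.stage, **vec.to_dict()}
            )
            iid += 1
    return pd.DataFrame(rows, columns=["instance_id", "plate", "class", "stage",
                                       *FEATURE_NAMES])


def rectify_phone_plate(plate: PlateImage, out_px: int | None = None) -> PlateImage:
    """Detect the corner fiducials and rectify the square sample area.

    When ``out_px`` is omitted it is inferred from the mean detected corner
    spacing, giving a near-1:1 resampling."""
    corners = detect_finder_patterns(plate)
    if out_px is None:
        edges = np.hypot(*np.diff(np.vstack([corners, corners[:1]]), axis=0).T)
        out_px = int(round(edges.mean())) + 1
    return correct_perspective(plate, corners, out_px)


def segment_rectified_interior(
    rect: PlateImage, min_area: int = 64, finder_size_px: int = 41
) -> list:
    """Segment the interior of a rectified sample area.

    Three robustness choices over plain grayscale Otsu:

    * the quartered corner fiducials are excluded *before* thresholding
      (they are nearly black, so including them makes the histogram
      trimodal and can pull the split below the buds);
    * the grayscale projection is the per-pixel *minimum* RGB channel —
      white paper is neutral even in shadow, while colored petals depress
      at least one channel strongly;
    * low-frequency illumination (gradient, cast shadow) is flattened by
      dividing by a large-scale Gaussian background estimate, and the
      thresholded mask is closed with a 3x3 element to reconnect thin
      petal tips.

    Instance offsets are reported in full rectified-plate coordinates.
    """
    from scipy import ndimage as ndi

    band = finder_size_px // 2 + 4
    interior = rect.pixels[band:-band, band:-band]
    gray = interior.min(axis=2).astype(float)
    bg = ndi.gaussian_filter(gray, sigma=gray.shape[0] / 6)
    flat = gray / np.maximum(bg, 1e-6)
    _, mask = otsu_threshold(flat)
    mask = ndi.binary_closing(mask, structure=np.ones((3, 3), bool))
    mask = ndi.binary_fill_holes(mask)
    out = []
    for inst in segment_components(mask, min_area=min_area):
        x0, y0 = inst.offset
        out.append(
            type(inst)(inst.mask, (x0 + band, y0 + band), index=inst.index)
        )
    return out


def phone_crop_stack(
    plates: list[tuple[PlateImage, list[GroundTruthInstance]]],
    min_area: int = 64,
    margin_px: int = 2,
    sample_px: int | None = None,
    finder_size_px: int = 41,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full phone branch up to the CNN input.

    Rectifies each plate from its fiducials, segments the rectified
    interior, crops each bud with margin, resizes bicubically to 50x50 and
    stacks.  Returns ``(X, type_labels, stage_labels)``.
    """
    crops, types, stages = [], [], []
    for plate, gts in plates:
        rect = rectify_phone_plate(plate, out_px=sample_px)
        instances = segment_rectified_interior(
            rect, min_area=min_area, finder_size_px=finder_size_px
        )
        pairs = match_instances(instances, gts)
        imgs = crop_instances(rect, [i for i, _ in pairs], margin_px=margin_px)
        for img, (_, gt) in zip(imgs, pairs):
            crops.append(preprocess_crop(img))
            types.append(gt.class_name)
            stages.append(gt.stage)
    return np.stack(crops), np.array(types), np.array(stages)


def features_to_dataset(df: pd.DataFrame) -> LabeledDataset:
    return LabeledDataset(
        X=df[list(FEATURE_NAMES)].to_numpy(float),
        type_labels=df["class"].to_numpy(),
        stage_labels=df["stage"].to_numpy(),
        ids=df["instance_id"].to_numpy(),
    )


def _report_header(cfg: RunConfig) -> dict:
    return {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "seed": cfg.seed,
    }


def run_shape_pipeline(cfg: RunConfig, grid: GridSpec = GridSpec()) -> dict:
    """Gel branch: plates -> features.csv -> PCA -> three classifiers per
    task.  Writes features.csv, pca.png and report.json when ``cfg.outdir``
    is set; returns the report dict."""
    report = _report_header(cfg)
    times = {}
    t0 = time.perf_counter()
    profiles = PROFILE_SETS[cfg.profiles]()
    bench = make_benchmark_dataset(
        profiles, cfg.n_per_class, cfg.seed, modes=("gel16",)
    )
    times["render_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    df = gel_feature_table(bench.gel, min_area=cfg.min_area)
    times["features_s"] = time.perf_counter() - t0
    ds = features_to_dataset(df)

    t0 = time.perf_counter()
    Xz, _ = zscore(ds.X, ds.X, list(FEATURE_NAMES))
    scores, loadings, evr = pca_explore(Xz, n_components=2)
    report["pca"] = {
        "explained_variance_pct": [100 * float(v) for v in evr],
        "explained_pc1_pc2_pct": 100 * float(evr[:2].sum()),
    }
    times["pca_s"] = time.perf_counter() - t0

    report["classifiers"] = []
    for task in cfg.tasks:
        for family in cfg.families:
            t0 = time.perf_counter()
            res = classify_task(ds, task, family, grid=grid,
                                split=SplitSpec(seed=cfg.seed), seed=cfg.seed)
            d = res.to_dict()
            d["wall_s"] = time.perf_counter() - t0
            report["classifiers"].append(d)
    report["wall_times_s"] = times
    report["n_instances"] = int(ds.n)

    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "features.csv", index=False)
        _plot_pca(scores, ds, out / "pca.png")
        (out / "shape_report.json").write_text(json.dumps(report, indent=1))
    return report


def _plot_pca(scores: np.ndarray, ds: LabeledDataset, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5), sharex=True, sharey=True)
    for ax, labels, title in (
        (axes[0], ds.stage_labels, "by flowering stage"),
        (axes[1], ds.type_labels, "by product type"),
    ):
        for lab in np.unique(labels):
            sel = labels == lab
            ax.scatter(scores[sel, 0], scores[sel, 1], s=12, label=str(lab))
        ax.set_xlabel("PC 1")
        ax.set_title(title)
        ax.legend(fontsize=7)
    axes[0].set_ylabel("PC 2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_cnn_pipeline(cfg: RunConfig) -> dict:
    """Phone branch: rectify -> crop -> resize -> train -> evaluate, for
    both tasks; optional architecture search."""
    report = _report_header(cfg)
    times = {}
    t0 = time.perf_counter()
    profiles = PROFILE_SETS[cfg.profiles]()
    bench = make_benchmark_dataset(
        profiles, cfg.n_per_class, cfg.seed, modes=("phone8",)
    )
    X, types, stages = phone_crop_stack(
        bench.phone, min_area=cfg.min_area,
        sample_px=bench.phone_sample_px + 1,
    )
    times["render_and_crop_s"] = time.perf_counter() - t0

    ds = LabeledDataset(X=X, type_labels=types, stage_labels=stages)
    tr, te = split_dataset(ds, SplitSpec(seed=cfg.seed))
    tcfg = TrainConfig(
        learning_rate=cfg.learning_rate,
        max_epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        seed=cfg.seed,
    )
    report["tasks"] = {}
    for task in cfg.tasks:
        y = ds.labels_for(task)
        n_classes = len(np.unique(y))
        t0 = time.perf_counter()
        if cfg.search:
            cands = [
                type(a)(a.conv_kernel, a.stages, n_classes=n_classes)
                for a in DEFAULT_CANDIDATES
            ]
            rows, best = architecture_search(
                cands, X[tr], y[tr], tcfg, X_test=X[te], y_test=y[te],
                paper_mode=cfg.paper_mode,
            )
            model = rows[best]["model"]
            table = [
                {k: v for k, v in r.items() if k != "model"} for r in rows
            ]
        else:
            arch = type(DEFAULT_ARCHITECTURE)(
                DEFAULT_ARCHITECTURE.conv_kernel,
                DEFAULT_ARCHITECTURE.stages,
                n_classes=n_classes,
            )
            model = train_cnn(arch, X[tr], y[tr], tcfg)
            table = None
        train_acc, _, _ = evaluate_cnn(model, X[tr], y[tr])
        test_acc, cm, classes = evaluate_cnn(model, X[te], y[te])
        report["tasks"][task] = {
            "arch": model.arch.name,
            "n_params": model.network.n_params,
            "train_accuracy": train_acc,
            "test_accuracy": test_acc,
            "train_accuracy_pct": int(round(train_acc)),
            "test_accuracy_pct": int(round(test_acc)),
            "confusion": cm.tolist(),
            "class_names": classes,
            "final_loss": model.loss_curve[-1],
            "wall_s": time.perf_counter() - t0,
        }
        if table is not None:
            report["tasks"][task]["candidates"] = table
    report["wall_times_s"] = times
    report["n_instances"] = int(ds.n)
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "cnn_report.json").write_text(json.dumps(report, indent=1))
    return report
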