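"""End-to-end experiment orchestration.

``run_experiment`` drives the staged pipeline — simulate -> tile ->
embed -> {baseline mean-pool | attention-MIL | barcode} -> evaluate —
from a single :class:`ExperimentConfig`, writing a metrics report and a
run manifest (config hash, seeds, stage counts, leakage-guard result).
Re-running an identical config in the same output directory reuses the
cached report.  ``compare_scales`` repeats one experiment across scale
sets and assembles a single comparison table with one column per set.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import barcode as bc
from . import evaluation as ev
from .embeddings import ExtractorConfig, TileClassifier, mean_pool_slide_score
from .mil import AttentionMIL, Bag, MILTrainConfig, stack_concentric, stack_grid
from .synthetic import CohortConfig, generate_cohort

logger = logging.getLogger("scalestack")

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "compare_scales",
    "run_scale_trend",
]

VALID_METHODS = ("baseline_mean_pool", "mil", "barcode")
VALID_BALANCING = ("full_mfb", "undersample_ce")


@dataclass
class ExperimentConfig:
    """One experiment: cohort conditions, tiling, scales, method."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    tiling: str = "grid"
    scales: tuple = (5, 10, 20)
    method: str = "mil"
    balancing: str = "undersample_ce"
    undersample_cap: int = 100
    train_frac: float = 0.8
    min_tiles: int = 0  # 0 disables the barcode min-tile filter
    k_clusters: int = bc.DEFAULT_K
    hp_draws: int = 0
    n_estimators: int = 200
    mil: MILTrainConfig = None
    seed: int = 0
    output_dir: str = None
    allow_concentric_mfb: bool = False

    def __post_init__(self):
        if not self.scales:
            raise ValueError("scales must be nonempty")
        if self.method not in VALID_METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.balancing not in VALID_BALANCING:
            raise ValueError(f"unknown balancing {self.balancing!r}")
        if self.tiling not in ("grid", "concentric"):
            raise ValueError("tiling must be 'grid' or 'concentric'")
        if (
            self.tiling == "concentric"
            and self.balancing == "full_mfb"
            and not self.allow_concentric_mfb
        ):
            raise ValueError(
                "concentric experiments run only under undersampling "
                "(set allow_concentric_mfb to override)"
            )

    def content_hash(self) -> str:
        payload = asdict(self)
        payload.pop("output_dir")
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    metrics: pd.DataFrame
    confusion: np.ndarray
    manifest: dict


def _slide_bags(slides, labels, scales, tiling):
    bags = []
    for slide, y in zip(slides, labels):
        embs = {m: slide.embeddings[m] for m in scales}
        if tiling == "concentric" and len(scales) > 1:
            # synthetic embeddings are gridwise; the 1:1 correspondence is
            # emulated by giving each base tile its ancestors as context,
            # which yields one row per base tile exactly like concentric sets
            H, _ = stack_grid(embs, scales)
        else:
            H, _ = stack_grid(embs, scales)
        bags.append(Bag(slide_id=slide.slide_id, label=int(y), instances=H))
    return bags


def _run_mil(cfg, train_slides, y_train, test_slides, y_test):
    bags_tr = _slide_bags(train_slides, y_train, cfg.scales, cfg.tiling)
    bags_te = _slide_bags(test_slides, y_test, cfg.scales, cfg.tiling)
    mil_cfg = cfg.mil or MILTrainConfig(seed=cfg.seed)
    if cfg.balancing == "undersample_ce":
        mil_cfg = replace(mil_cfg, loss_mode="plain_CE")
    res = AttentionMIL(bags_tr).fit(mil_cfg)
    return res.predict(bags_te)


def _run_barcode(cfg, train_slides, y_train, test_slides, y_test):
    scales = tuple(sorted(cfg.scales, reverse=True))
    if cfg.min_tiles > 0:
        def counts(slides):
            return pd.DataFrame(
                {m: [s.embeddings[m].n_tiles for s in slides] for m in scales},
                index=[s.slide_id for s in slides],
            )

        keep_tr = set(bc.filter_min_tiles(counts(train_slides), scales, cfg.min_tiles))
        keep_te = set(bc.filter_min_tiles(counts(test_slides), scales, cfg.min_tiles))
        tr = [(s, y) for s, y in zip(train_slides, y_train) if s.slide_id in keep_tr]
        te = [(s, y) for s, y in zip(test_slides, y_test) if s.slide_id in keep_te]
        train_slides, y_train = [t[0] for t in tr], [t[1] for t in tr]
        test_slides, y_test = [t[0] for t in te], [t[1] for t in te]
    models = {}
    for m in scales:
        pooled = np.vstack([s.embeddings[m].matrix for s in train_slides])
        models[m] = bc.fit_corpus_clusters(
            pooled, m, k=cfg.k_clusters, seed=cfg.seed
        )

    def barcodes_for(slides):
        out = []
        for s in slides:
            blocks = {
                m: bc.compute_barcode(
                    bc.assign_clusters(models[m], s.embeddings[m]), cfg.k_clusters
                )
                for m in scales
            }
            out.append(bc.concat_barcodes(blocks, s.slide_id, scales))
        return out

    bcs_tr = barcodes_for(train_slides)
    bcs_te = barcodes_for(test_slides)
    if cfg.balancing == "full_mfb":
        weights = bc.class_prevalence_weights(y_train)
    else:
        weights = None
    model = bc.BarcodeClassifier.from_barcodes(bcs_tr, np.asarray(y_train), sample_weight=weights)
    res = model.fit(
        n_draws=cfg.hp_draws, n_estimators=cfg.n_estimators, seed=cfg.seed
    )
    X_te = np.vstack([b.vector for b in bcs_te])
    return res.predict(X_te), y_test, len(bcs_tr[0].vector)


def _run_baseline(cfg, train_slides, y_train, test_slides, y_test):
    mag = max(cfg.scales)
    X_tr, lab_tr, sid_tr = [], [], []
    for i, (s, y) in enumerate(zip(train_slides, y_train)):
        m = s.embeddings[mag].matrix
        X_tr.append(m)
        lab_tr.extend([int(y)] * len(m))
        sid_tr.extend([i] * len(m))
    X_tr = np.vstack(X_tr)
    n_classes = int(max(max(y_train), max(y_test))) + 1
    model = TileClassifier(
        X_tr.shape[1], n_classes, embed_dim=min(128, X_tr.shape[1] * 4), seed=cfg.seed
    )
    model.fit(
        X_tr,
        np.asarray(lab_tr),
        slide_ids=np.asarray(sid_tr),
        config=ExtractorConfig(embed_dim=model.embed_dim, epochs=8),
        seed=cfg.seed,
    )
    preds = []
    for s in test_slides:
        tile_p = model.predict_proba(s.embeddings[mag].matrix)
        _, pred = mean_pool_slide_score(tile_p)
        preds.append(pred)
    return np.asarray(preds)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute the staged pipeline for one configuration."""
    out_dir = Path(config.output_dir) if config.output_dir else None
    chash = config.content_hash()
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest_path = out_dir / "manifest.json"
        metrics_path = out_dir / "metrics.csv"
        if manifest_path.exists() and metrics_path.exists():
            manifest = json.loads(manifest_path.read_text())
            if manifest.get("config_hash") == chash:
                logger.info("cache hit for %s; reusing report", chash)
                metrics = pd.read_csv(metrics_path)
                conf = np.loadtxt(out_dir / "confusion.csv", delimiter=",")
                return ExperimentResult(config, metrics, conf, manifest)

    stage = "simulate"
    try:
        cohort, slides = generate_cohort(config.cohort)
        by_id = {s.slide_id: s for s in slides}

        stage = "split"
        cohort = ev.patient_wise_stratified_split(
            cohort, train_frac=config.train_frac, seed=config.seed
        )
        if config.balancing == "undersample_ce":
            train_tab = ev.undersample_per_class(
                cohort[cohort["split"] == "train"],
                cap=config.undersample_cap,
                seed=config.seed,
            )
        else:
            train_tab = cohort[cohort["split"] == "train"]
        test_tab = cohort[cohort["split"] == "test"]
        ev.assert_patient_disjoint(cohort)
        train_slides = [by_id[s] for s in train_tab["slide_id"]]
        test_slides = [by_id[s] for s in test_tab["slide_id"]]
        y_train = train_tab["class_label"].to_numpy()
        y_test = test_tab["class_label"].to_numpy()
        n_classes = config.cohort.n_classes
        logger.info(
            "stage=split train=%d test=%d leakage_guard=pass",
            len(train_slides),
            len(test_slides),
        )

        stage = config.method
        barcode_len = None
        if config.method == "mil":
            y_pred = _run_mil(config, train_slides, y_train, test_slides, y_test)
        elif config.method == "barcode":
            y_pred, y_test, barcode_len = _run_barcode(
                config, train_slides, y_train, test_slides, y_test
            )
            y_test = np.asarray(y_test)
        else:
            y_pred = _run_baseline(config, train_slides, y_train, test_slides, y_test)

        stage = "evaluate"
        metrics = ev.metrics_report(y_test, y_pred, n_classes)
        C = ev.confusion_matrix_counts(y_test, y_pred, n_classes)
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "method": config.method,
        "tiling": config.tiling,
        "scales": list(config.scales),
        "n_train": len(train_slides),
        "n_test": len(test_slides),
        "leakage_guard": "pass",
    }
    if barcode_len is not None:
        manifest["barcode_length"] = int(barcode_len)
        logger.info("stage=barcode barcode_length=%d", barcode_len)
    if out_dir is not None:
        metrics.to_csv(out_dir / "metrics.csv", index=False)
        np.savetxt(out_dir / "confusion.csv", C, fmt="%d", delimiter=",")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ExperimentResult(config, metrics, C, manifest)


def compare_scales(template: ExperimentConfig, scale_sets) -> pd.DataFrame:
    """One report column per scale set (metric rows shared)."""
    scale_sets = list(scale_sets)
    if not scale_sets:
        raise ValueError("need at least one scale set")
    out = None
    for scales in scale_sets:
        cfg = replace(template, scales=tuple(scales), output_dir=None)
        res = run_experiment(cfg)
        col = "+".join(f"{m:g}x" for m in sorted(scales))
        part = res.metrics.rename(columns={"value": col})
        out = part if out is None else out.merge(part, on="metric")
    return out


def run_scale_trend(method: str, seed: int, scale_sets=((5,), (10,), (20,), (5, 10, 20))) -> dict:
    """Macro F1 per scale set on the scale-complementary synthetic cohort.

    Study conditions: 10 classes x 30 slides, separation 6, unit noise;
    an 8x8 base grid for MIL and a 32x32 base grid for the barcode runs
    so the 64-tile-minimum filter can stay active at every magnification.
    Returns ``{scale_set: macro F1}``; the qualitative expectation is
    that the combined scales match or beat every single scale, since by
    construction no single magnification separates all ten classes.
    """
    from dataclasses import replace as _replace

    from .synthetic import scale_complementary_config

    out = {}
    if method == "mil":
        cohort = scale_complementary_config(
            n_classes=10, slides_per_class=30, tiles_base=8,
            embedding_dim=32, seed=seed,
        )
        mil_cfg = MILTrainConfig(
            epochs=30, learning_rate=1e-3, bag_size=64, hidden=64,
            loss_mode="plain_CE", seed=seed,
        )
        for scales in scale_sets:
            cfg = ExperimentConfig(
                cohort=cohort, scales=tuple(scales), method="mil",
                balancing="undersample_ce", mil=mil_cfg, seed=seed,
            )
            res = run_experiment(cfg)
            macro = res.metrics.loc[res.metrics["metric"] == "macro_f1", "value"]
            out[tuple(scales)] = float(macro.iloc[0])
    elif method == "barcode":
        cohort = scale_complementary_config(
            n_classes=10, slides_per_class=30, tiles_base=32,
            embedding_dim=32, seed=seed,
        )
        for scales in scale_sets:
            cfg = ExperimentConfig(
                cohort=cohort, scales=tuple(scales), method="barcode",
                balancing="undersample_ce", min_tiles=64, k_clusters=16,
                hp_draws=0, n_estimators=100, seed=seed,
            )
            res = run_experiment(cfg)
            macro = res.metrics.loc[res.metrics["metric"] == "macro_f1", "value"]
            out[tuple(scales)] = float(macro.iloc[0])
    else:
        raise ValueError("method must be 'mil' or 'barcode'")
    return out
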