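"""End-to-end orchestration: simulate -> process -> analyze -> train ->
evaluate -> interpret, driven by one YAML-serializable config.

Every stochastic stage consumes a child seed spawned from the top-level
seed, so a full run is reproducible from the config alone.  Stages write
their artifacts under ``<out_dir>/<stage>/`` with a completion marker
carrying the config hash; re-running with the same config skips completed
stages unless forced.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from .analysis import (
    DoseResponseSeries,
    build_reference_ranges,
    classify_by_ed,
    cluster_success_rate,
    estimate_lod,
    hca_ward,
    series_from_pairs,
)
from .imaging import delta_signature, extract_spot_rgb, fit_calibration
from .nn import (
    ModelConfig,
    TrainConfig,
    build_model,
    evaluate,
    grad_cam,
    overlay,
    preprocess_images,
    train,
)
from .synth import (
    ALL_VOCS,
    CLASSES,
    blank_spot_colors,
    generate_dose_response_images,
    generate_ripeness_dataset,
    make_dye_library,
)

STAGES = ("simulate", "process", "lod", "hca", "train", "eval", "gradcam", "compare")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/demo"
    # generator
    dose_concentrations: tuple[float, ...] = (3.0, 10.0, 20.0, 50.0, 100.0, 250.0)
    dose_replicates: int = 3
    hca_concentrations: tuple[float, ...] = (20.0, 50.0, 100.0)
    n_images_per_class: int = 20
    scene_preset: str = "hard"
    image_side: int = 96
    # processing / analysis
    calibrate: bool = True
    blank_mean: float = 47.75
    blank_sd: float = 2.0
    # model / training
    input_side: int = 32
    epochs: int = 4
    batch_size: int = 32
    lr_steps: tuple[float, float, float] = (0.01, 0.005, 0.001)
    split_ratio: tuple[int, int] = (17, 3)
    full_scale: bool = False
    # comparison
    n_calibration_per_class: int = 10
    n_eval_per_class: int = 20

    def child_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([self.seed, STAGES.index(stage) if stage in STAGES else 97])
        return int(ss.generate_state(1)[0] % (2**31 - 1))

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str)
                              .encode()).hexdigest()[:16]

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        kwargs = {k: v for k, v in raw.items() if k in known}
        for key in ("dose_concentrations", "hca_concentrations", "lr_steps", "split_ratio"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def model_config(self) -> ModelConfig:
        side = 255 if self.full_scale else self.input_side
        return ModelConfig(input_side=side)

    def train_config(self) -> TrainConfig:
        if self.full_scale:
            return TrainConfig(epochs=500, batch_size=256, lr_steps=self.lr_steps,
                               seed=self.child_seed("train"))
        return TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                           lr_steps=self.lr_steps, seed=self.child_seed("train"))


class Pipeline:
    """Stage runner with on-disk artifacts and in-memory caching."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.cache: dict = {}
        os.makedirs(config.out_dir, exist_ok=True)

    # -- plumbing ---------------------------------------------------------
    def _stage_dir(self, stage: str) -> str:
        d = os.path.join(self.config.out_dir, stage)
        os.makedirs(d, exist_ok=True)
        return d

    def _marker(self, stage: str) -> str:
        return os.path.join(self.config.out_dir, stage, ".done")

    def is_done(self, stage: str) -> bool:
        marker = self._marker(stage)
        if not os.path.exists(marker):
            return False
        with open(marker) as fh:
            return fh.read().strip() == self.config.config_hash()

    def _mark_done(self, stage: str) -> None:
        with open(self._marker(stage), "w") as fh:
            fh.write(self.config.config_hash())

    def run_stage(self, name: str, force: bool = False) -> dict:
        """Run one stage; returns its report fragment (timings + metrics).

        Raises a MissingUpstreamError-style ValueError naming the stage to
        run first when upstream artifacts are absent.
        """
        if name == "full":
            report = {}
            for stage in STAGES:
                report[stage] = self.run_stage(stage, force=force)
            with open(os.path.join(self.config.out_dir, "run_report.json"), "w") as fh:
                json.dump(report, fh, indent=2, default=float)
            return report
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}; expected one of {STAGES} or 'full'")
        runner = getattr(self, f"_stage_{name}")
        if self.is_done(name) and not force and self._load_fragment(name) is not None:
            return self._load_fragment(name)
        t0 = time.time()
        metrics = runner()
        fragment = {"stage": name, "seconds": round(time.time() - t0, 2),
                    "artifacts": sorted(os.listdir(self._stage_dir(name))), **metrics}
        with open(os.path.join(self._stage_dir(name), "fragment.json"), "w") as fh:
            json.dump(fragment, fh, indent=2, default=float)
        self._mark_done(name)
        return fragment

    def _load_fragment(self, stage: str) -> dict | None:
        path = os.path.join(self.config.out_dir, stage, "fragment.json")
        if os.path.exists(path):
            with open(path) as fh:
                return json.load(fh)
        return None

    def _require(self, key: str, stage: str):
        if key not in self.cache:
            raise ValueError(
                f"missing upstream artifact {key!r}: run the '{stage}' stage first"
            )
        return self.cache[key]

    # -- stages -----------------------------------------------------------
    def library(self):
        if "library" not in self.cache:
            self.cache["library"] = make_dye_library(self.config.child_seed("simulate"))
        return self.cache["library"]

    def _stage_simulate(self) -> dict:
        cfg = self.config
        out = self._stage_dir("simulate")
        lib = self.library()
        pairs = {}
        seed = cfg.child_seed("simulate")
        for i, voc in enumerate(ALL_VOCS):
            pairs[voc] = generate_dose_response_images(
                lib, voc, list(cfg.dose_concentrations), cfg.dose_replicates,
                seed=seed + i + 1, blank_total_mean=cfg.blank_mean,
                blank_total_sd=cfg.blank_sd, side=cfg.image_side,
            )
        self.cache["pairs"] = pairs
        ds = generate_ripeness_dataset(
            lib, cfg.n_images_per_class, seed=seed + 100,
            split_ratio=cfg.split_ratio,
            scene_preset=cfg.scene_preset, side=cfg.image_side,
        )
        ds_test = generate_ripeness_dataset(
            lib, max(cfg.n_images_per_class // 4, 2), seed=seed + 200,
            scene_preset=cfg.scene_preset, side=cfg.image_side, batch="test",
        )
        self.cache["dataset"], self.cache["dataset_test"] = ds, ds_test
        ds.save(os.path.join(out, "dataset"))
        ds_test.save(os.path.join(out, "dataset_test"))
        pd.DataFrame(
            [(d.dye_id, d.name, d.dye_class, *d.baseline_rgb) for d in lib],
            columns=["dye_id", "name", "dye_class", "base_r", "base_g", "base_b"],
        ).to_csv(os.path.join(out, "dye_library.csv"), index=False)
        return {"n_dose_pairs": sum(len(v) for v in pairs.values()),
                "n_dataset_images": len(ds), "n_test_images": len(ds_test)}

    def _stage_process(self) -> dict:
        from .imaging import signature_from_pair

        cfg = self.config
        out = self._stage_dir("process")
        sig_dir = os.path.join(out, "signatures")
        os.makedirs(sig_dir, exist_ok=True)
        pairs = self._require("pairs", "simulate")
        series: dict[str, DoseResponseSeries] = {}
        n_signatures = 0
        for voc, ps in pairs.items():
            slug = voc.replace(" ", "_").replace("/", "-")
            by_conc: dict[float, list] = {}
            for p in ps:
                sig = signature_from_pair(p.pre, p.post, calibrate=cfg.calibrate)
                sig.to_frame().to_csv(
                    os.path.join(sig_dir, f"sig_{slug}_{p.concentration:g}ppm_r{p.replicate}.csv"),
                    index=False)
                n_signatures += 1
                by_conc.setdefault(p.concentration, []).append(sig)
            concs = sorted(by_conc)
            s = DoseResponseSeries(
                voc_name=voc,
                concentrations=np.array(concs),
                total_ed=np.array([np.mean([g.total_ed for g in by_conc[c]]) for c in concs]),
                per_spot_ed=np.array([np.mean([g.ed_per_spot for g in by_conc[c]], axis=0)
                                      for c in concs]),
                blank_mean=cfg.blank_mean, blank_sd=cfg.blank_sd,
            )
            series[voc] = s
            s.to_frame().to_csv(os.path.join(out, f"series_{slug}.csv"), index=False)
        self.cache["series"] = series
        return {"n_series": len(series), "n_signatures": n_signatures}

    def _stage_lod(self) -> dict:
        out = self._stage_dir("lod")
        series = self._require("series", "process")
        rows = [(voc, s.blank_mean, s.blank_sd, estimate_lod(s)) for voc, s in series.items()]
        table = pd.DataFrame(rows, columns=["voc", "blank_mean", "blank_sd", "lod_ppm"])
        table.to_csv(os.path.join(out, "lod_table.csv"), index=False)
        self.cache["lod_table"] = table
        return {"lod_ppm": dict(zip(table["voc"], table["lod_ppm"]))}

    def _stage_hca(self) -> dict:
        cfg = self.config
        out = self._stage_dir("hca")
        series = self._require("series", "process")
        rows, cond_labels, voc_labels = [], [], []
        for voc, s in series.items():
            for conc in cfg.hca_concentrations:
                idx = int(np.argmin(np.abs(s.concentrations - conc)))
                rows.append(s.per_spot_ed[idx])
                cond_labels.append(f"{voc}@{s.concentrations[idx]:g}ppm")
                voc_labels.append(voc)
        matrix = np.array(rows)
        link = hca_ward(matrix, labels=cond_labels)
        success = cluster_success_rate(link, cond_labels, k=len(cond_labels))
        success_voc = cluster_success_rate(link, voc_labels, k=len(series))
        pd.DataFrame(matrix, index=cond_labels).to_csv(os.path.join(out, "ed_matrix.csv"))
        link.to_frame().to_csv(os.path.join(out, "linkage.csv"), index=False)
        self._plot_dendrogram(link, os.path.join(out, "dendrogram.png"))
        self.cache["hca"] = link
        return {"matrix_shape": list(matrix.shape),
                "success_rate_conditions": 100.0 * success,
                "success_rate_vocs": 100.0 * success_voc}

    @staticmethod
    def _plot_dendrogram(link, path: str) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from scipy.cluster import hierarchy

        fig, ax = plt.subplots(figsize=(10, 4))
        hierarchy.dendrogram(link.merges, labels=list(link.labels), ax=ax,
                             leaf_rotation=90, leaf_font_size=6)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)

    def _prepare_arrays(self, ds):
        cfg = self.config
        X = preprocess_images(ds.images, side=cfg.input_side, full_scale=cfg.full_scale)
        return X, ds.labels()

    def _stage_train(self) -> dict:
        out = self._stage_dir("train")
        ds = self._require("dataset", "simulate")
        X, y = self._prepare_arrays(ds)
        tr = (ds.manifest["split"] == "train").to_numpy()
        model = build_model(self.config.model_config(), seed=self.config.child_seed("train"))
        state = train(model, X[tr], y[tr], self.config.train_config())
        state.history.to_csv(os.path.join(out, "history.csv"), index=False)
        np.savez(os.path.join(out, "checkpoint.npz"), **model.get_state())
        with open(os.path.join(out, "architecture.json"), "w") as fh:
            json.dump({"config": asdict(self.config.model_config()),
                       "n_parameters": model.n_parameters(),
                       "channel_trace": model.channel_trace()}, fh, indent=2)
        self.cache["model"] = model
        self.cache["arrays"] = (X, y, tr)
        final = state.history.iloc[-1]
        return {"final_train_loss": float(final["loss"]),
                "final_train_accuracy": float(final["accuracy"])}

    def _stage_eval(self) -> dict:
        out = self._stage_dir("eval")
        model = self._require("model", "train")
        X, y, tr = self._require("arrays", "train")
        rep_val = evaluate(model, X[~tr], y[~tr], CLASSES)
        ds_test = self._require("dataset_test", "simulate")
        Xt, yt = self._prepare_arrays(ds_test)
        rep_test = evaluate(model, Xt, yt, CLASSES)
        for tag, rep in (("val", rep_val), ("test", rep_test)):
            with open(os.path.join(out, f"report_{tag}.json"), "w") as fh:
                json.dump(rep.to_dict(), fh, indent=2)
            pd.DataFrame(rep.confusion, index=CLASSES, columns=CLASSES).to_csv(
                os.path.join(out, f"confusion_{tag}.csv"))
        self.cache["reports"] = {"val": rep_val, "test": rep_test}
        return {"val_accuracy": rep_val.accuracy, "val_macro_f1": rep_val.macro_f1,
                "test_accuracy": rep_test.accuracy}

    def _stage_gradcam(self) -> dict:
        from PIL import Image

        out = self._stage_dir("gradcam")
        model = self._require("model", "train")
        ds = self._require("dataset", "simulate")
        X, y, _ = self._require("arrays", "train")
        n_maps = 0
        for cls_idx, cls in enumerate(CLASSES):
            hits = np.flatnonzero(y == cls_idx)
            if hits.size == 0:
                continue
            i = int(hits[0])
            cam = grad_cam(model, X[i], cls_idx)
            Image.fromarray(overlay(cam, ds.images[i].pixels)).save(
                os.path.join(out, f"gradcam_{cls}.png"))
            n_maps += 1
        return {"n_maps": n_maps}

    def image_total_ed(self, image) -> float:
        """Total ED of one dataset image against the unreacted baseline."""
        lib = self.library()
        if self.config.calibrate:
            image = fit_calibration(image).apply(image)
        rgb = extract_spot_rgb(image)
        baseline = blank_spot_colors(lib).astype(float)
        return delta_signature(baseline, rgb).total_ed

    def _stage_compare(self) -> dict:
        cfg = self.config
        out = self._stage_dir("compare")
        model = self._require("model", "train")
        lib = self.library()
        seed = cfg.child_seed("compare")
        cal = generate_ripeness_dataset(lib, cfg.n_calibration_per_class, seed=seed,
                                        scene_preset=cfg.scene_preset, side=cfg.image_side)
        eds: dict[str, list[float]] = {}
        for img, label in zip(cal.images, cal.manifest["class_label"]):
            eds.setdefault(label, []).append(self.image_total_ed(img))
        ranges = build_reference_ranges(eds)
        ranges.to_frame().to_csv(os.path.join(out, "reference_ranges.csv"), index=False)
        ev = generate_ripeness_dataset(lib, cfg.n_eval_per_class, seed=seed + 1,
                                       scene_preset=cfg.scene_preset, side=cfg.image_side)
        ed_hits = sum(
            classify_by_ed(self.image_total_ed(img), ranges).label == label
            for img, label in zip(ev.images, ev.manifest["class_label"])
        )
        ed_acc = 100.0 * ed_hits / len(ev.images)
        Xe, ye = self._prepare_arrays(ev)
        dcnn_acc = evaluate(model, Xe, ye, CLASSES).accuracy
        table = pd.DataFrame({"method": ["ED reference range", "dense-block CNN"],
                              "accuracy_pct": [ed_acc, dcnn_acc]})
        table.to_csv(os.path.join(out, "ed_vs_dcnn.csv"), index=False)
        return {"ed_accuracy": ed_acc, "dcnn_accuracy": dcnn_acc,
                "n_eval_images": len(ev.images)}


def compare_ed_vs_dcnn(config: RunConfig) -> pd.DataFrame:
    """Convenience wrapper: run the pipeline through the comparison stage
    and return the two-method accuracy table."""
    pipe = Pipeline(config)
    for stage in ("simulate", "process", "train"):
        pipe.run_stage(stage)
    frag = pipe.run_stage("compare", force=True)
    return pd.DataFrame({"method": ["ED reference range", "dense-block CNN"],
                         "accuracy_pct": [frag["ed_accuracy"], frag["dcnn_accuracy"]]})
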