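"""Experiment orchestration: configuration, staged execution, manifests.

An experiment is the composed workflow simulate → label → preprocess →
train → evaluate → interpret, described by one YAML-serializable,
schema-validated configuration whose every random draw flows from named
per-stage seeds derived from a single global seed. Each stage writes its
artifact into the output directory and records it (with a SHA-256 checksum)
in the run manifest; re-running with ``resume=True`` skips stages whose
artifacts already exist.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError

from tracenet import labeling, models, polymer_sim, trace_data, interpret

log = logging.getLogger("tracenet")


class ConfigError(ValueError):
    pass


class SimulationSection(BaseModel):
    n_monomers: int = 52
    n_chains: int = 100
    frames_per_chain: int = 100
    steps_per_frame: int = 100
    bond_stiffness: float = 40.0
    bend_stiffness: float = 8.0
    repulsion_radius: float = 0.8
    repulsion_strength: float = 20.0
    confinement_radius: float = 4.0
    confinement_stiffness: float = 10.0
    step_size: float = 0.005
    thermal_scale: float = 1.0
    burn_in_steps: Optional[int] = None
    nm_per_unit: float = 60.0


class RuleSection(BaseModel):
    kind: Literal["binary_contact", "compaction", "hierarchical"] = "binary_contact"
    enhancer_index: int = 20
    promoter_index: int = 40
    on_fraction: float = 0.30
    noise_fraction: float = 0.50
    # hierarchical-only
    enhancers: tuple[int, int] = (5, 35)
    silencer: int = 45
    cooperative: bool = False
    p_silence: float = 0.8
    p_activate_single: float = 0.8
    p_activate_both: float = 0.8
    target_on_fraction: float = 0.30
    shuffle: bool = False


class PreprocessSection(BaseModel):
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    norm_mode: Literal["zscore", "mean_ratio"] = "zscore"
    epsilon: float = 1e-6
    jitter_sigma_nm: float = 0.0


class ModelSection(BaseModel):
    kind: Literal["cnn", "dnn", "rf"] = "cnn"
    conv_blocks: list[tuple[int, int]] = [(8, 3), (16, 3)]
    use_batchnorm: bool = True
    dense_units: list[int] = [16]
    learning_rate: float = 2e-3
    weight_decay: float = 2e-3
    batch_size: int = 128
    epochs: int = 14
    class_weight: bool = False
    occlusion_min_window: int = 3
    occlusion_max_window: int = 7
    occlusion_prob: float = 1.0
    occlusion_windows: int = 3


class InterpretSection(BaseModel):
    window_sizes: list[int] = [5, 20]
    blank_trials: int = 10
    shap_samples: int = 32
    shap_background: int = 100
    shap_examples: int = 500
    decile: float = 0.1
    coop_percentile: float = 99.0
    run_blanking: bool = True
    run_shap: bool = True
    run_cooperativity: bool = False


class ExperimentConfig(BaseModel):
    seed: int = 0
    output_dir: str = "runs/experiment"
    log_level: str = "INFO"
    simulation: SimulationSection = Field(default_factory=SimulationSection)
    rule: RuleSection = Field(default_factory=RuleSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    model: ModelSection = Field(default_factory=ModelSection)
    interpret: InterpretSection = Field(default_factory=InterpretSection)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls.model_validate(raw)
        except ValidationError as exc:
            raise ConfigError(f"invalid experiment config {path}: {exc}") from exc

    def stage_seed(self, stage: str) -> int:
        """Named, reproducible per-stage substream of the global seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class ExperimentArtifacts:
    output_dir: Path
    manifest: dict

    def path(self, name: str) -> Path:
        return self.output_dir / name


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def simulate_stage(cfg: ExperimentConfig) -> polymer_sim.ConformationEnsemble:
    sim = polymer_sim.SimulationConfig(
        seed=cfg.stage_seed("simulate"), **cfg.simulation.model_dump()
    )
    log.info(
        "simulating %d chains x %d frames", sim.n_chains, sim.frames_per_chain
    )
    return polymer_sim.simulate_ensemble(sim)


def label_stage(cfg: ExperimentConfig, ensemble) -> np.ndarray:
    r = cfg.rule
    seed = cfg.stage_seed("label")
    if r.kind == "binary_contact":
        labels = labeling.label_binary_contact(
            ensemble,
            labeling.ContactRule(r.enhancer_index, r.promoter_index, r.on_fraction),
            labeling.NoiseSpec(r.noise_fraction),
            seed=seed,
        )
    elif r.kind == "compaction":
        labels = labeling.label_compaction(
            ensemble,
            labeling.CompactionRule(r.on_fraction),
            labeling.NoiseSpec(r.noise_fraction),
            seed=seed,
        )
    else:
        rule = labeling.HierarchicalRule(
            promoter=r.promoter_index,
            enhancers=tuple(r.enhancers),
            silencer=r.silencer,
            p_silence=r.p_silence,
            p_activate_single=r.p_activate_single,
            p_activate_both=r.p_activate_both,
            cooperative=r.cooperative,
        )
        rule.contact_threshold = labeling.calibrate_contact_threshold(
            ensemble, r.target_on_fraction, rule
        )
        labels = labeling.label_hierarchical(ensemble, rule, seed=seed)
    if r.shuffle:
        labels = labeling.shuffle_labels(labels, seed=cfg.stage_seed("shuffle"))
    log.info("labeled %d examples, ON fraction %.3f", len(labels), labels.mean())
    return labels


def preprocess_stage(cfg: ExperimentConfig, ensemble, labels) -> trace_data.LabeledDataset:
    coords = ensemble.coords()
    if cfg.preprocess.jitter_sigma_nm > 0:
        coords = models.add_coordinate_jitter(
            coords, cfg.preprocess.jitter_sigma_nm, seed=cfg.stage_seed("jitter")
        )
    d = np.linalg.norm(coords[:, :, None, :] - coords[:, None, :, :], axis=-1)
    ds = trace_data.build_dataset(
        d,
        labels,
        fractions=tuple(cfg.preprocess.fractions),
        seed=cfg.stage_seed("split"),
        epsilon=cfg.preprocess.epsilon,
        norm_mode=cfg.preprocess.norm_mode,
        meta={"rule": cfg.rule.model_dump()},
    )
    return ds


def train_stage(cfg: ExperimentConfig, dataset) -> models.TrainedClassifier:
    m = cfg.model
    mc = models.ClassifierConfig(
        kind=m.kind,
        conv_blocks=tuple(tuple(b) for b in m.conv_blocks),
        use_batchnorm=m.use_batchnorm,
        dense_units=tuple(m.dense_units),
        learning_rate=m.learning_rate,
        weight_decay=m.weight_decay,
        batch_size=m.batch_size,
        epochs=m.epochs,
        class_weight=m.class_weight,
        occlusion_min_window=m.occlusion_min_window,
        occlusion_max_window=m.occlusion_max_window,
        occlusion_prob=m.occlusion_prob,
        occlusion_windows=m.occlusion_windows,
        seed=cfg.stage_seed("train"),
    )
    return models.TRAINERS[m.kind](dataset, mc)


def evaluate_stage(cfg: ExperimentConfig, model, dataset) -> dict:
    report = models.evaluate_classifier(
        model, dataset, split="test", seed=cfg.stage_seed("evaluate")
    )
    out = report.to_dict()
    # comparison baselines on the raw test matrices
    test_idx = dataset.indices("test")
    train_idx = dataset.indices("train")
    raw_test = dataset.matrices[test_idx]
    y_test = dataset.labels[test_idx]
    try:
        ep = models.ep_contact_predictor(raw_test)
        out["ep_contact_odds_ratio"] = models.odds_ratio(
            ep, y_test == 1, n_bootstrap=500, seed=cfg.stage_seed("evaluate")
        )[0]
    except models.ModelError:
        pass
    avg = models.average_similarity_classifier(
        dataset.matrices[train_idx], dataset.labels[train_idx], raw_test
    )
    out["avg_similarity_odds_ratio"] = models.odds_ratio(
        avg, y_test == 1, n_bootstrap=500, seed=cfg.stage_seed("evaluate")
    )[0]
    train_auc = models.compute_auc(
        dataset.split_labels("train"),
        model.predict_proba(dataset.standardized_matrices("train")),
    )
    out["train_auc"] = train_auc
    return out


def interpret_stage(cfg: ExperimentConfig, model, dataset) -> dict:
    ic = cfg.interpret
    out: dict = {}
    Xte = dataset.standardized_matrices("test")
    yte = dataset.split_labels("test")
    if ic.run_blanking:
        out["blanking"] = {}
        for w in ic.window_sizes:
            prof = interpret.blanking_scan(
                model, Xte, yte, w, n_trials=ic.blank_trials,
                seed=cfg.stage_seed(f"blank{w}"),
            )
            out["blanking"][w] = prof
    if ic.run_shap and model.kind in ("cnn", "dnn"):
        rng = np.random.default_rng(cfg.stage_seed("shap"))
        Xtr = dataset.standardized_matrices("train")
        bg = Xtr[rng.choice(len(Xtr), min(ic.shap_background, len(Xtr)), replace=False)]
        n_ex = min(ic.shap_examples, len(Xte))
        sel = rng.choice(len(Xte), n_ex, replace=False)
        attr = interpret.compute_attributions(
            model, Xte[sel], bg, n_samples=ic.shap_samples,
            seed=cfg.stage_seed("shap"),
        )
        labels_sel = yte[sel]
        raw_sel = dataset.matrices[dataset.indices("test")][sel]
        agg = interpret.aggregate_extreme_decile(attr, labels_sel, ic.decile)
        med = interpret.median_distance_of_extreme_decile(
            attr, raw_sel, labels_sel, ic.decile
        )
        out["shap"] = {
            "attributions": attr,
            "labels": labels_sel,
            "aggregate": agg,
            "median_distance": med,
        }
        if ic.run_cooperativity:
            out["cooperativity"] = {
                side: interpret.cooperativity_map(
                    attr, labels_sel, side=side, percentile=ic.coop_percentile,
                    raw_matrices=raw_sel, seed=cfg.stage_seed("coop"),
                )
                for side in ("on", "off")
            }
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_experiment(
    config: ExperimentConfig, resume: bool = False
) -> ExperimentArtifacts:
    """Execute every stage, persisting artifacts and a checksummed manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    (out / "config.yaml").write_text(yaml.safe_dump(config.model_dump()))
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    t0 = time.time()

    def record(name: str, path: Path):
        manifest["files"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _checksum(path),
        }

    try:
        ds_path = out / "dataset.h5"
        if resume and ds_path.exists():
            dataset = trace_data.LabeledDataset.from_hdf5(ds_path)
        else:
            ensemble = simulate_stage(config)
            labels = label_stage(config, ensemble)
            dataset = preprocess_stage(config, ensemble, labels)
            dataset.to_hdf5(ds_path)
        record("dataset", ds_path)

        model = train_stage(config, dataset)
        hist_path = out / "training_history.json"
        hist_path.write_text(json.dumps(model.history))
        record("training_history", hist_path)
        if model.kind in ("cnn", "dnn"):
            ckpt = out / "model.npz"
            model.save(ckpt)
            record("model_checkpoint", ckpt)

        evaluation = evaluate_stage(config, model, dataset)
        eval_path = out / "evaluation.json"
        eval_path.write_text(json.dumps(evaluation, indent=2))
        record("evaluation", eval_path)

        interp = interpret_stage(config, model, dataset)
        for w, prof in interp.get("blanking", {}).items():
            p = out / f"blanking_w{w}.tsv"
            prof.to_frame().to_csv(p, sep="\t", index=False)
            record(f"blanking_w{w}", p)
        if "shap" in interp:
            agg = interp["shap"]["aggregate"]
            for name, arr in (
                ("shap_on_top_decile", agg.on_top_decile_mean),
                ("shap_off_bottom_decile", agg.off_bottom_decile_mean),
                ("shap_on_median_distance", interp["shap"]["median_distance"]["on_median_distance"]),
                ("shap_off_median_distance", interp["shap"]["median_distance"]["off_median_distance"]),
            ):
                p = out / f"{name}.tsv"
                np.savetxt(p, arr, delimiter="\t")
                record(name, p)
                interpret.save_heatmap(
                    arr, p.with_suffix(".png"), title=name.replace("_", " "),
                    symmetric="decile" in name,
                )
                record(f"{name}_png", p.with_suffix(".png"))
        for side, cmap in interp.get("cooperativity", {}).items():
            p = out / f"cooperativity_{side}.tsv"
            np.savetxt(p, cmap.avg_cooccurrence, delimiter="\t")
            record(f"cooperativity_{side}", p)
            interpret.save_heatmap(
                cmap.avg_cooccurrence, p.with_suffix(".png"),
                title=f"cooperativity ({side})", symmetric=False,
            )
            record(f"cooperativity_{side}_png", p.with_suffix(".png"))
    except Exception as exc:
        raise RuntimeError(
            f"experiment failed (seed {config.seed}, output {out}): {exc}"
        ) from exc

    manifest["wall_seconds"] = time.time() - t0
    manifest["config_file"] = "config.yaml"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ExperimentArtifacts(output_dir=out, manifest=manifest)


def generate_fixture(seed: int = 0, n_examples: int = 500) -> trace_data.LabeledDataset:
    """A tiny deterministic binary-contact dataset (noise 0) for tests/demos.

    500 examples at ON fraction 0.30 give exactly 150 ON labels; a checksum
    of the matrix bytes is stored in ``meta`` so fixture drift is visible.
    """
    cfg = polymer_sim.fast_config(
        n_examples=n_examples, frames_per_chain=min(100, n_examples),
        steps_per_frame=10, seed=seed,
    )
    cfg = dataclasses.replace(cfg, burn_in_steps=50)
    ens = polymer_sim.simulate_ensemble(cfg)
    ens.traces = ens.traces[:n_examples]
    ens.provenance = ens.provenance[:n_examples]
    labels = labeling.label_binary_contact(
        ens, labeling.ContactRule(), labeling.NO_NOISE, seed=seed
    )
    coords = ens.coords()
    d = np.linalg.norm(coords[:, :, None, :] - coords[:, None, :, :], axis=-1)
    ds = trace_data.build_dataset(d, labels, seed=seed)
    ds.meta["checksum"] = hashlib.sha256(
        np.ascontiguousarray(np.round(d, 6)).tobytes()
    ).hexdigest()
    return ds


def report(artifacts: ExperimentArtifacts | Path | str) -> str:
    """One-page human-readable summary assembled from the run manifest."""
    out = (
        artifacts.output_dir
        if isinstance(artifacts, ExperimentArtifacts)
        else Path(artifacts)
    )
    manifest_path = out / "manifest.json"
    lines = ["# Experiment report", ""]
    if not manifest_path.exists():
        return "\n".join(lines + ["manifest.json: ABSENT — cannot summarize run"])
    manifest = json.loads(manifest_path.read_text())
    lines.append(f"seed: {manifest.get('seed')}")
    lines.append("")

    lines.append("## Evaluation")
    eval_path = out / "evaluation.json"
    if eval_path.exists():
        ev = json.loads(eval_path.read_text())
        lines.append(f"- test AUC: {ev['auc']:.4f} (train AUC {ev.get('train_auc', float('nan')):.4f})")
        lines.append(
            f"- precision {ev['precision']:.3f} / recall {ev['recall']:.3f} / f1 {ev['f1']:.3f}"
        )
        ci = ev.get("odds_ratio_ci", [float("nan")] * 2)
        lines.append(
            f"- model odds ratio: {ev['odds_ratio']:.2f} (CI {ci[0]:.2f}-{ci[1]:.2f})"
        )
        if "ep_contact_odds_ratio" in ev:
            lines.append(
                f"- enhancer-promoter contact odds ratio: {ev['ep_contact_odds_ratio']:.2f}"
            )
        if "avg_similarity_odds_ratio" in ev:
            lines.append(
                f"- average-similarity odds ratio: {ev['avg_similarity_odds_ratio']:.2f}"
            )
    else:
        lines.append("- evaluation.json: ABSENT")

    lines.append("")
    lines.append("## Blanking profiles")
    found = False
    for name, entry in manifest.get("files", {}).items():
        if name.startswith("blanking_"):
            found = True
            p = out / entry["path"]
            if p.exists():
                import pandas as pd

                df = pd.read_csv(p, sep="\t")
                prof = df.groupby("center")["predictability"].mean()
                lines.append(
                    f"- {name}: min {prof.min():.1f} at center {int(prof.idxmin())}, "
                    f"median {prof.median():.1f}"
                )
            else:
                lines.append(f"- {name}: ABSENT")
    if not found:
        lines.append("- (no blanking artifacts)")

    lines.append("")
    lines.append("## Attribution maps")
    for name in (
        "shap_on_top_decile",
        "shap_off_bottom_decile",
        "cooperativity_on",
        "cooperativity_off",
    ):
        entry = manifest.get("files", {}).get(name)
        if entry is None:
            continue
        p = out / entry["path"]
        if p.exists():
            arr = np.loadtxt(p, delimiter="\t")
            i, j = np.unravel_index(np.argmax(np.abs(np.nan_to_num(arr))), arr.shape)
            lines.append(
                f"- {name}: extreme value {arr[i, j]:.4g} at barcodes ({i + 1}, {j + 1})"
            )
        else:
            lines.append(f"- {name}: ABSENT")
    return "\n".join(lines)
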