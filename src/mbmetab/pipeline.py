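"""End-to-end pipeline: blocks in, model + report + marker tables out.

One :func:`run_pipeline` call reproduces the whole workflow — load or
simulate the four blocks, preprocess, fit the multiblock model, validate it
by leave-one-out cross-validation, select and direction-assign discriminant
variables, export biplot coordinates — and writes a manifest with a content
hash of every artifact so reruns can be verified byte for byte.  All
randomness funnels through the single seed in the config.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

from . import __version__
from .blocks import BlockMatrix, StudyDesign
from .discriminant import (biplot_coordinates, discriminant_table,
                           select_discriminant)
from .mbpls import fit_mbpls
from .preprocessing import PreprocessParams, StudyPreprocessor
from .synthetic import SyntheticConfig, generate_study, save_study
from .validation import evaluate


@dataclass
class PipelineConfig:
    """Everything one run needs.

    Either ``block_paths`` + ``design_path`` (CSV inputs as written by the
    synthetic generator) or ``synthetic`` must be given.  ``seed`` overrides
    the synthetic config's seed so one flag controls all randomness.
    """

    block_paths: dict | None = None         # block id -> csv path
    design_path: str | None = None
    synthetic: SyntheticConfig | None = None
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    n_components: int = 4
    selection_rule: str = "range-quarter"
    selection_axes: tuple = (0, 1, 2)
    out_dir: str = "mbmetab_out"
    seed: int | None = None
    run_validation: bool = True

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if (self.block_paths is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of block_paths/design_path or synthetic required")
        if self.block_paths is not None:
            missing = [p for p in list(self.block_paths.values())
                       + [self.design_path] if not p or not os.path.exists(p)]
            if missing:
                raise FileNotFoundError(f"missing input files: {missing}")
        if self.seed is not None and self.synthetic is not None:
            self.synthetic.seed = self.seed

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Load from YAML or JSON."""
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.update(overrides)
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = raw["synthetic"]
            if isinstance(syn.get("block_dims"), dict):
                syn["block_dims"] = {k: int(v) for k, v in syn["block_dims"].items()}
            raw["synthetic"] = SyntheticConfig(**syn)
        if "preprocess" in raw and isinstance(raw["preprocess"], dict):
            raw["preprocess"] = PreprocessParams(**raw["preprocess"])
        if "selection_axes" in raw:
            raw["selection_axes"] = tuple(raw["selection_axes"])
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_fingerprint(cfg: PipelineConfig) -> str:
    def default(o):
        try:
            return asdict(o)
        except TypeError:
            return str(o)
    blob = json.dumps(asdict(cfg), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()


def load_blocks(cfg: PipelineConfig):
    if cfg.synthetic is not None:
        blocks, design, truth = generate_study(cfg.synthetic)
        return blocks, design, truth
    blocks = [BlockMatrix.from_csv(path, bid)
              for bid, path in sorted(cfg.block_paths.items())]
    design = StudyDesign.from_csv(cfg.design_path)
    return blocks, design, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write all artifacts under ``cfg.out_dir``.

    Returns a result bundle with the fitted model, validation report,
    discriminant variables and the manifest.  Identical config + seed give
    byte-identical model JSON.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    outputs: dict[str, str] = {}

    def out(name: str) -> str:
        path = os.path.join(cfg.out_dir, name)
        outputs[name] = path
        return path

    try:
        blocks_raw, design, truth = load_blocks(cfg)
    except Exception as e:
        raise RuntimeError(f"stage 'load': {e}") from e
    if cfg.synthetic is not None:
        save_study(cfg.out_dir, blocks_raw, design, truth)
        for b in blocks_raw:
            outputs[f"{b.block_id}.csv"] = os.path.join(cfg.out_dir,
                                                        f"{b.block_id}.csv")
        outputs["design.csv"] = os.path.join(cfg.out_dir, "design.csv")
        outputs["ground_truth.json"] = os.path.join(cfg.out_dir,
                                                    "ground_truth.json")

    try:
        pre, blocks = StudyPreprocessor.fit(blocks_raw, cfg.preprocess)
        pre.to_json(out("preprocessing.json"))
        for b in blocks:
            b.to_csv(out(f"{b.block_id}_preprocessed.csv"))
    except Exception as e:
        raise RuntimeError(f"stage 'preprocess': {e}") from e

    try:
        model = fit_mbpls(blocks, design.response_matrix(), cfg.n_components)
        model.to_json(out("model.json"))
    except Exception as e:
        raise RuntimeError(f"stage 'fit': {e}") from e

    report = None
    if cfg.run_validation:
        try:
            report = evaluate(blocks_raw, design, cfg.preprocess,
                              cfg.n_components)
            report.to_json(out("validation.json"))
        except Exception as e:
            raise RuntimeError(f"stage 'validate': {e}") from e

    try:
        axes = tuple(a for a in cfg.selection_axes if a < cfg.n_components)
        selected = select_discriminant(model, design, axes=axes,
                                       rule=cfg.selection_rule)
        coords = biplot_coordinates(
            model, selected,
            panels=tuple(p for p in ((0, 1), (1, 2))
                         if max(p) < cfg.n_components))
        discriminant_table(selected).to_csv(out("discriminant_variables.csv"),
                                            index=False)
        for panel, df in coords.items():
            fname = f"biplot_{panel.replace('/', '_')}.csv"
            df.to_csv(out(fname), index=False)
    except Exception as e:
        raise RuntimeError(f"stage 'select': {e}") from e

    manifest = {
        "package": "mbmetab",
        "version": __version__,
        "seed": cfg.seed if cfg.seed is not None
        else (cfg.synthetic.seed if cfg.synthetic else None),
        "config_sha256": _config_fingerprint(cfg),
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)

    return {"blocks_raw": blocks_raw, "blocks": blocks, "design": design,
            "ground_truth": truth, "preprocessor": pre, "model": model,
            "report": report, "selected": selected, "biplot": coords,
            "manifest": manifest}


def verify_manifest(out_dir) -> bool:
    """Re-hash every artifact listed in the manifest; False on any change."""
    with open(os.path.join(out_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    for name, digest in manifest["outputs"].items():
        path = os.path.join(out_dir, name)
        if not os.path.exists(path) or _sha256(path) != digest:
            return False
    return True
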