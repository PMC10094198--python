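"""Run configuration: one YAML document drives a whole experiment.

A ``RunConfig`` bundles the architecture and protocol parameters with the
data location, split scheme and hierarchy source; saving it alongside every
artifact directory makes a run re-executable, and all randomness flows from
its single seed (the training config's).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model import ModelConfig, MultiTaskECGNet
from .taxonomy import LabelHierarchy, cpsc_hierarchy, ptbxl_hierarchy
from .training import TrainingConfig

__all__ = ["RunConfig", "resolve_hierarchy", "save_checkpoint", "load_checkpoint"]


def resolve_hierarchy(source: str) -> LabelHierarchy:
    """'cpsc', 'ptbxl', or a path to a two-column (fine, coarse) CSV."""
    if source == "cpsc":
        return cpsc_hierarchy()
    if source == "ptbxl":
        return ptbxl_hierarchy()
    return LabelHierarchy.from_csv(source)


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    data_dir: str = "."
    layout: str = "wfdb"          # 'wfdb' or 'mat'
    scheme: str = "ptbxl_recommended"
    hierarchy: str = "cpsc"
    output_dir: str = "runs/run0"

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "model": self.model.to_dict(),
            "training": self.training.to_dict(),
            "data_dir": self.data_dir, "layout": self.layout,
            "scheme": self.scheme, "hierarchy": self.hierarchy,
            "output_dir": self.output_dir,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            model=ModelConfig.from_dict(doc.get("model", {})),
            training=TrainingConfig(**doc.get("training", {})),
            data_dir=doc.get("data_dir", "."), layout=doc.get("layout", "wfdb"),
            scheme=doc.get("scheme", "ptbxl_recommended"),
            hierarchy=doc.get("hierarchy", "cpsc"),
            output_dir=doc.get("output_dir", "runs/run0"),
        )


def save_checkpoint(model: MultiTaskECGNet, path: str | Path,
                    seed: int = 0) -> None:
    """Persist all parameters and running stats with the full ModelConfig."""
    arrays = {f"arr_{i:04d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, _config=yaml.safe_dump(model.cfg.to_dict()),
             _seed=np.asarray(seed), **arrays)


def load_checkpoint(path: str | Path) -> MultiTaskECGNet:
    with np.load(path, allow_pickle=False) as data:
        cfg = ModelConfig.from_dict(yaml.safe_load(str(data["_config"])))
        seed = int(data["_seed"])
        arrays = [data[k] for k in sorted(data.files) if k.startswith("arr_")]
    model = MultiTaskECGNet(cfg, seed=seed)
    model.load_state_arrays(arrays)
    model.eval()
    return model
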