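"""Checkpointing of trained ensembles with a reproducibility manifest."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import yaml

from .ensemble import (
    BiRNNPredictor,
    LogisticPredictor,
    PredictorConfig,
    PredictorEnsemble,
)

_CLASSES = {"logistic": LogisticPredictor, "birnn": BiRNNPredictor}


def split_hash(sequences: list[str]) -> str:
    digest = hashlib.sha256("\n".join(sequences).encode())
    return digest.hexdigest()[:16]


def save_ensemble(ensemble: PredictorEnsemble, out_dir: str | Path,
                  extra: dict | None = None) -> Path:
    """Write member weights plus a manifest (configs, alphabet, version)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": 1,
        "alphabet": ensemble.alphabet,
        "sequence_length": ensemble.sequence_length,
        "k": ensemble.k,
        "members": [],
    }
    if extra:
        manifest.update(extra)
    for i, member in enumerate(ensemble.members):
        np.savez(out / f"member_{i}.npz", **member.state())
        manifest["members"].append({
            "file": f"member_{i}.npz",
            "config": dict(member.config.__dict__),
        })
    with open(out / "manifest.yaml", "w") as handle:
        yaml.safe_dump(manifest, handle, sort_keys=False)
    return out


def load_ensemble(model_dir: str | Path) -> PredictorEnsemble:
    model_dir = Path(model_dir)
    with open(model_dir / "manifest.yaml") as handle:
        manifest = yaml.safe_load(handle)
    members = []
    for entry in manifest["members"]:
        config = PredictorConfig(**entry["config"])
        model = _CLASSES[config.architecture](config, manifest["sequence_length"])
        with np.load(model_dir / entry["file"]) as data:
            model.load_state({k: data[k] for k in data.files})
        members.append(model)
    return PredictorEnsemble(
        members=members,
        alphabet=manifest["alphabet"],
        sequence_length=manifest["sequence_length"],
    )
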