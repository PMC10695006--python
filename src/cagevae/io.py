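"""Readers and writers binding the modules into reproducible runs.

Formats: cage CSV (header ``bb1_id,bb2_smiles,reaction,label``, quoted
SMILES, one cage per row), catalog and fragment-library JSON sidecars,
YAML run configuration, an ``.npz`` checkpoint with a versioned JSON header,
and a JSON run manifest capturing config, seeds and input digests so equal
manifests reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import CageVAENetwork, ModelConfig
from .representation import (
    BB1Catalog,
    CageRecord,
    ReactionCatalog,
    TokenVocabulary,
    relabel,
)

__all__ = [
    "read_cage_csv",
    "write_cage_csv",
    "read_catalogs",
    "write_catalogs",
    "read_config",
    "save_checkpoint",
    "load_checkpoint",
    "write_manifest",
    "file_digest",
]

CHECKPOINT_FORMAT_VERSION = 1


def read_cage_csv(path, reactions: ReactionCatalog) -> list[CageRecord]:
    """Load cage records; raw label text is normalised through `relabel`."""
    df = pd.read_csv(path, dtype={"bb1_id": int, "bb2_smiles": str, "reaction": str},
                     keep_default_na=False)
    required = {"bb1_id", "bb2_smiles", "reaction", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cage CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(CageRecord(
            bb1_id=int(row.bb1_id),
            bb2=row.bb2_smiles,
            reaction_id=reactions.id_of(row.reaction),
            label=relabel(str(row.label)),
        ))
    return records


def write_cage_csv(path, records: list[CageRecord], reactions: ReactionCatalog) -> None:
    df = pd.DataFrame({
        "bb1_id": [r.bb1_id for r in records],
        "bb2_smiles": [r.bb2 for r in records],
        "reaction": [reactions.names[r.reaction_id] for r in records],
        "label": ["" if r.label == "unlabeled" else r.label for r in records],
    })
    df.to_csv(path, index=False, quoting=2)  # QUOTE_NONNUMERIC keeps SMILES intact


def write_catalogs(path, bb1: BB1Catalog, reactions: ReactionCatalog) -> None:
    Path(path).write_text(json.dumps({
        "bb1_skeletons": list(bb1.skeletons),
        "reactions": list(reactions.names),
    }, indent=2))


def read_catalogs(path) -> tuple[BB1Catalog, ReactionCatalog]:
    data = json.loads(Path(path).read_text())
    return (BB1Catalog(tuple(data["bb1_skeletons"])),
            ReactionCatalog(tuple(data["reactions"])))


def read_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def save_checkpoint(path, network: CageVAENetwork, vocab: TokenVocabulary,
                    bb1: BB1Catalog, reactions: ReactionCatalog) -> None:
    """Write a checkpoint: JSON header (format version, model config,
    vocabulary, catalogs) plus the parameter arrays."""
    header = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "model_config": asdict(network.config),
        "vocabulary": {"tokens": list(vocab.tokens), "max_len": vocab.max_len},
        "bb1_skeletons": list(bb1.skeletons),
        "reactions": list(reactions.names),
    }
    arrays = {f"param_{i}": a for i, a in enumerate(network.state_arrays())}
    np.savez(path, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path):
    """Returns ``(network, vocab, bb1_catalog, reaction_catalog)``."""
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        if header["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format {header['format_version']}")
        config = ModelConfig(**header["model_config"])
        network = CageVAENetwork(config)
        n_params = len(network.parameters())
        network.load_state_arrays([data[f"param_{i}"] for i in range(n_params)])
    vocab = TokenVocabulary(tuple(header["vocabulary"]["tokens"]),
                            header["vocabulary"]["max_len"])
    bb1 = BB1Catalog(tuple(header["bb1_skeletons"]))
    reactions = ReactionCatalog(tuple(header["reactions"]))
    return network, vocab, bb1, reactions


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, command: str, seed: int, config: dict,
                   inputs: list[str]) -> None:
    """One manifest per CLI run: command, seed, config snapshot, input
    digests, package version, timestamp."""
    from . import __version__

    manifest = {
        "command": command,
        "seed": seed,
        "config": config,
        "inputs": {str(p): file_digest(p) for p in inputs if Path(p).exists()},
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
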