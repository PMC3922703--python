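"""Readers and writers for the pipeline's TSV/JSON/YAML artifacts.

TSV dialect: tab-separated, UTF-8, header row; gene (or sample) ids in the
first column.  All writers go through pandas, whose shortest-repr float
formatting makes the matrix round trips lossless.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .dataset import DetectionProfile, SignalDataset
from .simulate import GroundTruth

__all__ = [
    "read_matrix",
    "read_dataset",
    "read_ground_truth",
    "write_profile",
    "read_yaml_config",
    "file_checksum",
    "write_manifest",
]


def read_matrix(path) -> pd.DataFrame:
    """Read a gene-by-sample TSV matrix (gene ids in column 1)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_dataset(directory) -> SignalDataset:
    """Load intensity/snr/annotation/metadata TSVs from a directory."""
    directory = Path(directory)
    return SignalDataset(
        intensity=read_matrix(directory / "intensity.tsv"),
        snr=read_matrix(directory / "snr.tsv"),
        annotation=pd.read_csv(directory / "annotation.tsv", sep="\t", index_col=0),
        metadata=pd.read_csv(directory / "metadata.tsv", sep="\t", index_col=0),
    )


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    prob = pd.DataFrame(payload["per_gene_presence_prob"])
    prob.index.name = "gene"
    return GroundTruth(
        core_gene_ids=payload["core_gene_ids"],
        exclusive_gene_ids_by_group={
            k: list(v) for k, v in payload["exclusive_gene_ids_by_group"].items()
        },
        planted_triplets_by_group={
            k: [tuple(t) for t in v]
            for k, v in payload["planted_triplets_by_group"].items()
        },
        per_gene_presence_prob=prob,
    )


def write_profile(profile: DetectionProfile, directory) -> dict:
    """Write detection calls, normalized abundances, the non-core binary
    matrix and a JSON core/non-core partition manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (
        ("detected", profile.detected.astype(int)),
        ("normalized", profile.normalized),
        ("noncore_binary", profile.noncore_binary),
    ):
        path = directory / f"{name}.tsv"
        out = frame.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")
        paths[name] = path
    partition = directory / "partition.json"
    partition.write_text(
        json.dumps(
            {
                "n_genes_detected": int(len(profile.genes)),
                "core_genes": list(map(str, profile.core_genes)),
                "noncore_genes": list(map(str, profile.noncore_genes)),
            },
            indent=1,
        )
    )
    paths["partition"] = partition
    return paths


def read_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(paths: dict, out_path, extra: dict | None = None) -> Path:
    """Write a JSON manifest listing every artifact with its checksum."""
    out_path = Path(out_path)
    manifest = {
        "artifacts": {
            name: {"path": str(p), "sha256": file_checksum(p)}
            for name, p in sorted(paths.items(), key=lambda kv: str(kv[0]))
        }
    }
    if extra:
        manifest.update(extra)
    out_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out_path
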