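"""Detection calling, normalization and the core/non-core partition.

A gene is called *present* ("positive calling") in a sample when its
hybridization intensity and its signal-to-noise ratio both clear their
cutoffs (defaults 1000 and 2, the standard practice for this chip family).
Detected intensities are then rescaled per sample to relative abundances,
and genes are partitioned into *core* (detected in every sample) and
*non-core* (detected somewhere, but missing in at least one sample).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import DetectionProfile, SignalDataset

__all__ = [
    "DEFAULT_MIN_INTENSITY",
    "DEFAULT_MIN_SNR",
    "call_positives",
    "normalize",
    "partition_core_noncore",
    "build_profile",
    "aggregate_by_category",
]

DEFAULT_MIN_INTENSITY = 1000.0
DEFAULT_MIN_SNR = 2.0


def call_positives(
    dataset: SignalDataset,
    min_intensity: float = DEFAULT_MIN_INTENSITY,
    min_snr: float = DEFAULT_MIN_SNR,
) -> pd.DataFrame:
    """Boolean gene-by-sample detection matrix.

    An entry is True iff ``intensity >= min_intensity`` **and**
    ``snr >= min_snr`` (both filters applied conjunctively).
    """
    return (dataset.intensity >= min_intensity) & (dataset.snr >= min_snr)


def normalize(dataset: SignalDataset, detected: pd.DataFrame) -> pd.DataFrame:
    """Per-sample total-sum scaling of detected intensities.

    Detected intensities are divided by the sample's detected-intensity sum;
    undetected entries are set to 0, so every column sums to exactly 1.

    Raises
    ------
    ValueError
        If any sample has zero detections (the offending samples are named).
    """
    if not detected.index.equals(dataset.intensity.index) or not detected.columns.equals(
        dataset.intensity.columns
    ):
        raise ValueError("detection matrix is not aligned with the dataset")
    masked = dataset.intensity.where(detected, 0.0)
    totals = masked.sum(axis=0)
    empty = totals.index[totals <= 0]
    if len(empty):
        raise ValueError(
            f"no detected genes in sample(s): {', '.join(map(str, empty))}"
        )
    return masked / totals


def partition_core_noncore(detected: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
    """Split genes into core (present everywhere) and non-core.

    Core genes are detected in every sample; non-core genes are detected in
    at least one but not all samples.  Genes never detected belong to
    neither set.
    """
    if detected.shape[1] == 0:
        raise ValueError("detection matrix has no samples")
    n_hits = detected.sum(axis=1)
    core = detected.index[n_hits == detected.shape[1]]
    noncore = detected.index[(n_hits > 0) & (n_hits < detected.shape[1])]
    return core, noncore


def build_profile(
    dataset: SignalDataset,
    min_intensity: float = DEFAULT_MIN_INTENSITY,
    min_snr: float = DEFAULT_MIN_SNR,
) -> DetectionProfile:
    """Run positive calling, normalization and partitioning in one step.

    Genes detected in zero samples are dropped before any downstream
    analysis, so the profile covers exactly the genes detected at least
    once.
    """
    detected = call_positives(dataset, min_intensity, min_snr)
    keep = detected.index[detected.any(axis=1)]
    detected = detected.loc[keep]
    sub = SignalDataset(
        intensity=dataset.intensity.loc[keep],
        snr=dataset.snr.loc[keep],
        annotation=dataset.annotation,
        metadata=dataset.metadata,
    )
    normalized = normalize(sub, detected)
    core, noncore = partition_core_noncore(detected)
    return DetectionProfile(
        detected=detected,
        normalized=normalized,
        core_genes=core,
        noncore_genes=noncore,
        annotation=dataset.annotation.loc[keep],
        metadata=dataset.metadata,
    )


def aggregate_by_category(
    profile: DetectionProfile, annotation: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Category-by-sample relative abundance and relative diversity tables.

    Per sample, a category's *relative abundance* is the summed normalized
    intensity of its detected genes, and its *relative diversity* is the
    fraction of the sample's detected genes that fall in the category.
    Both tables therefore sum to 1 down each sample column.

    Raises
    ------
    ValueError
        If any detected gene is missing from the annotation (the gene ids
        are listed).
    """
    if annotation is None:
        annotation = profile.annotation
    if annotation is None:
        raise ValueError("no annotation available")
    missing = profile.genes.difference(annotation.index)
    if len(missing):
        raise ValueError(f"unannotated detected genes: {list(missing)}")
    categories = annotation.loc[profile.genes, "category"]
    abundance = profile.normalized.groupby(categories).sum()
    abundance.index.name = "category"
    richness = profile.detected.sum(axis=0)
    diversity = profile.detected.astype(float).groupby(categories).sum() / richness
    diversity.index.name = "category"
    return abundance, diversity
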