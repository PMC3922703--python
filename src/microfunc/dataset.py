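"""Core data containers for functional-gene microarray experiments.

A chip experiment yields two gene-by-sample matrices — hybridization signal
intensity and signal-to-noise ratio (SNR) — together with a per-gene
annotation (gene family, functional category, metabolic pathway group) and
per-sample host metadata (health group ``H``/``C``, DMFT caries index,
gender, age).  :class:`SignalDataset` bundles the four tables and enforces
their alignment; :class:`DetectionProfile` holds everything derived from
positive calling (see :mod:`microfunc.preprocessing`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SignalDataset", "DetectionProfile", "PATHWAY_GROUPS"]

#: Metabolic pathway groups used for non-core sub-networks, mapping the
#: pathway-group label to the functional categories it comprises.
PATHWAY_GROUPS: dict[str, tuple[str, ...]] = {
    "Carbon": (
        "Complex Carbohydrates",
        "Feeder Pathways to Glycolysis",
        "Respiration",
    ),
    "AA": (
        "Amino acid transport and metabolism",
        "Amino acid synthesis",
    ),
    "Nitrogen": ("Nitrogen Metabolism",),
}


@dataclass
class SignalDataset:
    """Paired intensity/SNR matrices with gene annotation and sample metadata.

    Parameters
    ----------
    intensity, snr
        Gene-by-sample DataFrames (genes as rows, samples as columns) holding
        fluorescence intensity (arbitrary units, >= 0) and signal-to-noise
        ratio.  Both must share identical gene and sample indexes.
    annotation
        Per-gene table indexed by gene id with columns ``family``,
        ``category`` and ``pathway_group``.
    metadata
        Per-sample table indexed by sample id with columns ``group`` (``H``
        or ``C``), ``dmft``, ``gender`` and ``age``.
    """

    intensity: pd.DataFrame
    snr: pd.DataFrame
    annotation: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.intensity.index.equals(self.snr.index):
            raise ValueError("intensity and snr gene indexes differ")
        if not self.intensity.columns.equals(self.snr.columns):
            raise ValueError("intensity and snr sample columns differ")
        if len(self.intensity.columns) == 0:
            raise ValueError("dataset has no samples")
        missing = self.intensity.index.difference(self.annotation.index)
        if len(missing):
            raise ValueError(
                f"{len(missing)} genes lack annotation (e.g. {list(missing[:3])})"
            )
        missing_s = self.intensity.columns.difference(self.metadata.index)
        if len(missing_s):
            raise ValueError(f"samples missing from metadata: {list(missing_s)}")
        if (np.asarray(self.intensity) < 0).any():
            raise ValueError("negative intensities")

    @property
    def genes(self) -> pd.Index:
        return self.intensity.index

    @property
    def samples(self) -> pd.Index:
        return self.intensity.columns

    def samples_in_group(self, group: str) -> list[str]:
        """Sample ids belonging to host group ``group`` (e.g. ``"H"``)."""
        meta = self.metadata.loc[list(self.samples)]
        return list(meta.index[meta["group"] == group])

    @property
    def groups(self) -> list[str]:
        """Distinct host groups in metadata order of first appearance."""
        meta = self.metadata.loc[list(self.samples)]
        return list(dict.fromkeys(meta["group"]))


@dataclass
class DetectionProfile:
    """Positive-calling products: detection calls and derived encodings.

    Attributes
    ----------
    detected
        Boolean gene-by-sample matrix restricted to genes detected in at
        least one sample (never-detected genes are dropped up front).
    normalized
        Relative-abundance matrix: per sample, detected intensities divided
        by the sample's total detected intensity; undetected entries 0.
        Every column sums to 1.
    core_genes, noncore_genes
        The complete-presence ("core": detected in every sample) vs
        partial-presence ("non-core": missing in >= 1 sample) partition.
    noncore_binary
        0/1 matrix ``detected`` restricted to the non-core genes.
    """

    detected: pd.DataFrame
    normalized: pd.DataFrame
    core_genes: pd.Index
    noncore_genes: pd.Index
    annotation: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    @property
    def noncore_binary(self) -> pd.DataFrame:
        return self.detected.loc[self.noncore_genes].astype(int)

    @property
    def genes(self) -> pd.Index:
        return self.detected.index

    @property
    def samples(self) -> pd.Index:
        return self.detected.columns

    def samples_in_group(self, group: str) -> list[str]:
        if self.metadata is None:
            raise ValueError("profile carries no sample metadata")
        meta = self.metadata.loc[list(self.samples)]
        return list(meta.index[meta["group"] == group])
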