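"""Shared data containers for the functional-gene-array pipeline.

The pipeline's tabular objects are thin wrappers around pandas DataFrames:
probe-by-sample signal/SNR tables, the study design (sample -> lake ->
elevation group), and the processed signal matrices.  Wrappers carry
provenance flags so stage ordering can be enforced (e.g. relative
intensities can only be computed from a normalized matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

LOW = "low"
HIGH = "high"


class PipelineError(Exception):
    """Base class for pipeline-contract violations."""


class DesignMismatchError(PipelineError):
    """Samples in a table do not match the study design."""


class NormalizationError(PipelineError):
    """A sample lacks usable positive-control probes."""


@dataclass(frozen=True)
class StudyDesign:
    """Sample -> lake -> elevation-group mapping.

    Parameters
    ----------
    sample_to_lake
        Mapping of sample id to lake id.
    lake_to_group
        Mapping of lake id to elevation group, ``"low"`` or ``"high"``.
    lake_to_elevation
        Mapping of lake id to elevation in metres.
    """

    sample_to_lake: Mapping[str, str]
    lake_to_group: Mapping[str, str]
    lake_to_elevation: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lake in set(self.sample_to_lake.values()):
            if lake not in self.lake_to_group:
                raise DesignMismatchError(f"lake {lake!r} has no elevation group")
        groups = set(self.lake_to_group.values())
        bad = groups - {LOW, HIGH}
        if bad:
            raise PipelineError(f"unknown elevation groups: {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.sample_to_lake)

    @property
    def lakes(self) -> list[str]:
        return sorted(set(self.sample_to_lake.values()))

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.lake_to_group.values()))

    def group_of_sample(self, sample: str) -> str:
        return self.lake_to_group[self.sample_to_lake[sample]]

    def samples_in_lake(self, lake: str) -> list[str]:
        return [s for s, l in self.sample_to_lake.items() if l == lake]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_to_lake if self.group_of_sample(s) == group]

    def group_labels(self, samples: list[str] | None = None) -> pd.Series:
        samples = list(self.sample_to_lake) if samples is None else samples
        return pd.Series({s: self.group_of_sample(s) for s in samples}, name="group")

    def validate_samples(self, samples) -> None:
        missing = [s for s in samples if s not in self.sample_to_lake]
        if missing:
            raise DesignMismatchError(f"samples absent from design: {missing}")


@dataclass
class RawProbeTable:
    """Probe-by-sample raw signal intensities and signal-to-noise ratios.

    ``signal`` and ``snr`` share index (probe ids) and columns (sample ids);
    an undetected (probe, sample) cell is NaN in both.  ``is_positive``
    flags positive-control probes.
    """

    signal: pd.DataFrame
    snr: pd.DataFrame
    is_positive: pd.Series

    def __post_init__(self) -> None:
        if not self.signal.index.equals(self.snr.index) or not self.signal.columns.equals(
            self.snr.columns
        ):
            raise PipelineError("signal and SNR tables must share probes and samples")
        self.is_positive = self.is_positive.reindex(self.signal.index).fillna(False).astype(bool)
        # a cell is either fully observed or fully missing
        mismatch = self.signal.isna() ^ self.snr.isna()
        if mismatch.to_numpy().any():
            raise PipelineError("cells must carry both signal and SNR, or neither")

    @property
    def detected(self) -> pd.DataFrame:
        """Boolean probe-by-sample detection mask."""
        return self.signal.notna()

    @property
    def probes(self) -> pd.Index:
        return self.signal.index

    @property
    def samples(self) -> pd.Index:
        return self.signal.columns

    def subset_probes(self, probes) -> "RawProbeTable":
        return RawProbeTable(
            self.signal.loc[probes], self.snr.loc[probes], self.is_positive.loc[probes]
        )


@dataclass
class SignalMatrix:
    """Probe-by-sample normalized signal intensities.

    ``transformed`` / ``normalized`` are provenance flags set by the
    preprocessing steps; downstream stages check them.
    """

    values: pd.DataFrame
    transformed: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise PipelineError("signal matrix has negative entries")

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class RelativeMatrix:
    """Probe-by-sample relative signal intensities; columns sum to 1."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.values.sum(axis=0).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise PipelineError("relative-intensity columns must sum to 1")

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


ANNOTATION_COLUMNS = ["gene_family", "subcategory", "category", "lineage"]


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check a probe annotation table (index = probe_id) for required columns."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise PipelineError(f"annotation table missing columns: {missing}")
    if annotation.index.duplicated().any():
        dup = annotation.index[annotation.index.duplicated()].tolist()
        raise PipelineError(f"duplicate probe ids in annotation: {dup[:5]}")
    if annotation["category"].isna().any() or (annotation["category"] == "").any():
        raise PipelineError("every probe needs a non-empty category")
    return annotation
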