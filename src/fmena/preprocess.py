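"""Signal preprocessing: quality and prevalence filters, normalization,
relative intensities, and the between-group difference metric.

The pipeline follows the conventional functional-gene-array sequence:

(i)   keep only (probe, sample) cells with signal-to-noise ratio
      strictly greater than a cutoff (default 2);
(ii)  keep probes detected in at least a minimum number of samples of at
      least one lake (default 2 of 6, i.e. >~30% of a lake's samples);
(iii) ln(x+1)-transform each cell and divide by the per-sample mean of
      the transformed positive-control probes;
(iv)  convert to relative intensities by dividing each sample column by
      its total, and
(v)   summarize a gene family / subcategory / category as
      (S_high / S_low) - 1, the fractional change of the group-summed
      intensity from the low- to the high-elevation group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    NormalizationError,
    PipelineError,
    RawProbeTable,
    RelativeMatrix,
    SignalMatrix,
    StudyDesign,
)

logger = logging.getLogger(__name__)

LEVELS = ("gene_family", "subcategory", "category")


def filter_by_snr(table: RawProbeTable, snr_min: float = 2.0) -> RawProbeTable:
    """Mask cells with SNR <= ``snr_min`` as undetected; drop empty probes.

    The inequality is strict: a cell with SNR exactly equal to the cutoff
    is removed.  Retained signal values are unchanged.
    """
    if table.signal.empty:
        raise PipelineError("empty probe table")
    keep = table.snr > snr_min
    signal = table.signal.where(keep)
    snr = table.snr.where(keep)
    nonempty = signal.notna().any(axis=1)
    if not nonempty.any():
        logger.warning("SNR filter removed every cell (snr_min=%s)", snr_min)
    return RawProbeTable(signal[nonempty], snr[nonempty], table.is_positive[nonempty])


def prevalence_threshold(n_lake_samples: int, min_detected_per_lake: int | None) -> int:
    """Per-lake detection threshold: explicit count, or ceil(0.3 * n)."""
    if min_detected_per_lake is not None:
        return min_detected_per_lake
    return math.ceil(0.3 * n_lake_samples)


def filter_by_prevalence(
    table: RawProbeTable,
    design: StudyDesign,
    min_detected_per_lake: int | None = 2,
) -> RawProbeTable:
    """Keep probes detected in >= threshold samples of at least one lake.

    With ``min_detected_per_lake=None`` the threshold is ceil(30% of the
    lake's sample count), the generalization of "2 of 6" to unequal lakes.
    """
    design.validate_samples(table.samples)
    detected = table.detected
    keep = pd.Series(False, index=table.probes)
    for lake in design.lakes:
        lake_samples = [s for s in design.samples_in_lake(lake) if s in detected.columns]
        if not lake_samples:
            continue
        thr = prevalence_threshold(len(lake_samples), min_detected_per_lake)
        keep |= detected[lake_samples].sum(axis=1) >= thr
    logger.info("prevalence filter: %d of %d probes kept", int(keep.sum()), len(keep))
    return table.subset_probes(table.probes[keep])


def normalize(
    table: RawProbeTable,
    keep_controls: bool = False,
    divide_before_log: bool = False,
) -> SignalMatrix:
    """ln(x+1)-transform and scale by the positive-control mean per sample.

    Default order: each detected cell becomes ``ln(raw + 1)`` and is then
    divided by the mean of the *transformed* positive-control values of
    its sample, keeping both operands on the same scale.  Setting
    ``divide_before_log=True`` instead divides the raw intensity by the
    mean *raw* positive-control intensity first and then applies
    ``ln(x+1)``.  Undetected cells become 0.  Positive-control probes are
    dropped from the output unless ``keep_controls``.
    """
    pos = table.is_positive
    if not pos.any():
        raise NormalizationError("no positive-control probes in table")
    pos_signal = table.signal[pos]
    for sample in table.samples:
        if pos_signal[sample].notna().sum() == 0:
            raise NormalizationError(f"sample {sample!r} has no detected positive controls")

    if divide_before_log:
        scale = pos_signal.mean(axis=0)
        values = np.log1p(table.signal.div(scale, axis=1))
    else:
        transformed = np.log1p(table.signal)
        scale = np.log1p(pos_signal).mean(axis=0)
        values = transformed.div(scale, axis=1)
    if (scale <= 0).any():
        bad = scale.index[scale <= 0].tolist()
        raise NormalizationError(f"non-positive control mean in samples {bad}")
    values = values.fillna(0.0)
    if not keep_controls:
        values = values[~pos]
    return SignalMatrix(values, transformed=True, normalized=True)


def relative_intensity(matrix: SignalMatrix) -> RelativeMatrix:
    """Divide each sample column by its total so columns sum to 1."""
    if not matrix.normalized:
        raise PipelineError("relative intensities require a normalized matrix")
    totals = matrix.values.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise PipelineError(f"all-zero sample columns: {zero}")
    return RelativeMatrix(matrix.values.div(totals, axis=1))


@dataclass
class GroupDifference:
    """Fractional change of a unit's group-summed intensity, high vs low."""

    unit: str
    level: str
    s_high: float
    s_low: float
    delta: float | None  # (s_high / s_low) - 1; None when s_low == 0

    @property
    def flagged(self) -> bool:
        return self.delta is None


def group_difference(
    matrix: SignalMatrix | RelativeMatrix,
    design: StudyDesign,
    annotation: pd.DataFrame,
    level: str = "gene_family",
) -> list[GroupDifference]:
    """Per-unit (S_high / S_low) - 1 over group-summed intensities.

    ``S_high`` / ``S_low`` total the chosen intensity over all probes of
    the unit and all samples of the elevation group.  Units with zero
    low-group total are flagged (``delta=None``) rather than divided.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    values = matrix.values
    design.validate_samples(values.columns)
    high = [s for s in values.columns if design.group_of_sample(s) == "high"]
    low = [s for s in values.columns if design.group_of_sample(s) == "low"]
    if not high or not low:
        raise PipelineError("both elevation groups must be present")
    units = annotation.loc[values.index, level]
    s_high = values[high].sum(axis=1).groupby(units).sum()
    s_low = values[low].sum(axis=1).groupby(units).sum()
    out = []
    for unit in s_high.index:
        sh, sl = float(s_high[unit]), float(s_low[unit])
        delta = (sh / sl) - 1.0 if sl > 0 else None
        out.append(GroupDifference(str(unit), level, sh, sl, delta))
    return out


@dataclass
class PreprocessResult:
    matrix: SignalMatrix
    relative: RelativeMatrix
    filtered: RawProbeTable
    report: dict


def run_preprocessing(
    table: RawProbeTable,
    design: StudyDesign,
    snr_min: float = 2.0,
    min_detected_per_lake: int | None = 2,
    divide_before_log: bool = False,
) -> PreprocessResult:
    """Run filters (i)-(ii), normalization (iii) and relative step (iv).

    Returns the matrices plus a JSON-serializable report with probe
    counts at each stage.
    """
    n0 = len(table.probes)
    snr_filtered = filter_by_snr(table, snr_min)
    prev_filtered = filter_by_prevalence(snr_filtered, design, min_detected_per_lake)
    matrix = normalize(prev_filtered, divide_before_log=divide_before_log)
    relative = relative_intensity(matrix)
    report = {
        "probes_input": n0,
        "probes_after_snr": len(snr_filtered.probes),
        "probes_after_prevalence": len(prev_filtered.probes),
        "probes_in_matrix": len(matrix.probes),
        "snr_min": snr_min,
        "min_detected_per_lake": min_detected_per_lake,
        "divide_before_log": divide_before_log,
        "n_samples": len(table.samples),
    }
    return PreprocessResult(matrix, relative, prev_filtered, report)
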