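"""Read-count and cell-count community abundance.

RPM normalization divides mapped reads by feature length and rescales the
length-corrected weights to one million per sample; MAG relative abundance
re-expresses MAG-level RPM as percentages. FISH-derived population
fractions convert to absolute abundances and fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FEATURE_TSV_COLUMNS = ["sample_id", "feature_id", "length_bp", "mapped_reads"]


@dataclass(frozen=True)
class FeatureCount:
    """Mapped-read count for one gene or MAG in one sample."""

    feature_id: str
    length: int
    mapped_reads: int
    sample_id: str = "S1"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("feature length must be > 0")
        if self.mapped_reads < 0:
            raise ValueError("mapped_reads must be >= 0")


@dataclass(frozen=True)
class PopulationCount:
    """A taxon's fraction of total (DAPI) cells plus the total abundance."""

    name: str
    fraction_of_total: float
    total_cells: float  # cells mL^-1

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_of_total <= 1.0:
            raise ValueError("fraction_of_total must lie in [0, 1]")
        if self.total_cells < 0:
            raise ValueError("total_cells must be >= 0")


def rpm(features: list[FeatureCount]) -> dict[str, float]:
    """Mapped reads per million, length-normalized, for one sample.

    RPM_i = 1e6 * (reads_i / length_i) / sum_j (reads_j / length_j).
    Zero-read features keep RPM 0 and stay in the table. The values sum to
    1e6 exactly (up to float rounding).
    """
    if not features:
        raise ValueError("empty feature set")
    samples = {f.sample_id for f in features}
    if len(samples) != 1:
        raise ValueError(f"rpm() is per-sample; got samples {sorted(samples)}")
    ids = [f.feature_id for f in features]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate feature_id in sample")
    weights = np.array([f.mapped_reads / f.length for f in features], float)
    total = weights.sum()
    if total == 0:
        raise ValueError("all features have zero mapped reads")
    return {f.feature_id: 1e6 * w / total for f, w in zip(features, weights)}


def rpm_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-sample RPM over a (sample_id, feature_id, length_bp,
    mapped_reads) frame."""
    missing = [c for c in FEATURE_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    out = []
    for sample, sub in df.groupby("sample_id"):
        feats = [
            FeatureCount(
                feature_id=str(r.feature_id),
                length=int(r.length_bp),
                mapped_reads=int(r.mapped_reads),
                sample_id=str(sample),
            )
            for r in sub.itertuples()
        ]
        for fid, value in rpm(feats).items():
            out.append({"sample_id": sample, "feature_id": fid, "rpm": value})
    return pd.DataFrame(out)


def mag_relative_abundance(mag_rpm: dict[str, float]) -> dict[str, float]:
    """Each MAG's RPM as a percentage of the summed RPM of all MAGs."""
    if not mag_rpm:
        raise ValueError("empty MAG set")
    total = sum(mag_rpm.values())
    if total <= 0:
        raise ValueError("summed RPM must be > 0")
    return {mag: 100.0 * v / total for mag, v in mag_rpm.items()}


def population_absolute(pop: PopulationCount) -> float:
    """Absolute abundance (cells mL^-1) of a FISH-identified population."""
    return pop.fraction_of_total * pop.total_cells


def fold_change(
    initial: PopulationCount, final: PopulationCount, dilution_factor: float = 10.0
) -> float:
    """Fold increase of a population relative to its diluted starting stock.

    The inoculum enters the incubation diluted by ``dilution_factor``
    (default 10, the 9:1 aged-seawater:inoculum setup), so the reference
    abundance is ``initial / dilution_factor``.
    """
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be > 0")
    start = population_absolute(initial)
    if start <= 0:
        raise ValueError("initial population must be > 0 for a fold change")
    return population_absolute(final) / (start / dilution_factor)
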