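"""Clonotype diversity, trajectory classification, and V-gene usage.

"Clonal diversity" here means the number of cells with distinct
immunoreceptor sequences in a sample. A clonotype is keyed by
(locus, V gene, CDR3 nucleotide junction) at the cell level after a
dominant-chain filter; induced diversity is a strictly greater unique
clonotype count in the post-treatment sample of the same patient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .config import InputError, ParseError, UndefinedStatisticError

ALLOWED_LOCI = ("TRA", "TRB", "IGH", "IGK", "IGL")
RECEPTOR_CLASSES = {"TCR": ("TRA", "TRB"), "BCR": ("IGH", "IGK", "IGL")}

REQUIRED_COLUMNS = ("cell_id", "sample_id", "locus", "v_call", "junction")


@dataclass(frozen=True)
class SampleRepertoire:
    """Per-sample unique clonotype counts by receptor class."""

    sample_id: str
    patient_id: str
    timepoint: str
    unique_counts: dict
    cell_total: int


@dataclass(frozen=True)
class DiversityTrajectory:
    """Pre/post unique-count pair and the induced-diversity call.

    ``increased`` requires a strictly greater post-treatment count."""

    patient_id: str
    receptor_class: str
    pre_count: int
    post_count: int
    delta: int
    increased: bool


@dataclass(frozen=True)
class VGeneUsage:
    """V-gene frequency vector of one sample and locus over a fixed
    universe (an ``other`` bucket collects out-of-universe calls; it is
    excluded from correlation support)."""

    sample_id: str
    patient_id: str
    timepoint: str
    locus: str
    frequencies: pd.Series
    empty: bool


@dataclass(frozen=True)
class UsageCorrelation:
    correlation: float
    matched: bool
    n_support: int


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check the AIRR-style table; raise :class:`ParseError` naming the
    first offending row."""
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise ParseError(f"missing required column {col!r}")
    bad = ~records["locus"].isin(ALLOWED_LOCI)
    if bad.any():
        row = records.index[bad][0]
        raise ParseError(
            f"row {row}: unknown locus {records.loc[row, 'locus']!r} "
            f"(allowed: {ALLOWED_LOCI})"
        )
    if "duplicate_count" in records.columns:
        neg = records["duplicate_count"] < 1
        if neg.any():
            row = records.index[neg][0]
            raise ParseError(f"row {row}: duplicate_count must be >= 1")
    asserted = records["junction"].astype(str).str.len() == 0
    if asserted.any():
        row = records.index[asserted][0]
        raise ParseError(f"row {row}: empty junction for an asserted clonotype")
    return records


def dominant_chain_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one chain per (sample, cell, locus): the highest
    ``duplicate_count``, ties broken by lexicographic junction. Prevents
    doublet/ambient inflation of cell-level clonotype counts."""
    if records.empty:
        return records
    df = records.copy()
    if "duplicate_count" not in df.columns:
        df["duplicate_count"] = 1
    df = df.sort_values(
        ["sample_id", "cell_id", "locus", "duplicate_count", "junction"],
        ascending=[True, True, True, False, True],
        kind="mergesort",
    )
    return df.drop_duplicates(["sample_id", "cell_id", "locus"], keep="first")


def clonotype_key(records: pd.DataFrame) -> pd.Series:
    """The clonotype identity: locus + V call + CDR3 nucleotide."""
    return (
        records["locus"].astype(str)
        + "|" + records["v_call"].astype(str)
        + "|" + records["junction"].astype(str)
    )


def count_unique_clonotypes(
    records: pd.DataFrame,
    receptor_class: str,
    samples: list[str] | None = None,
) -> pd.Series:
    """Unique clonotype count per sample for one receptor class.

    Samples listed in ``samples`` but absent from the records report 0.
    """
    if receptor_class not in RECEPTOR_CLASSES:
        raise InputError(f"unknown receptor class {receptor_class!r}")
    if len(records) == 0:
        counts = pd.Series(dtype=int, name=f"{receptor_class}_unique")
    else:
        validate_records(records)
        df = dominant_chain_filter(records)
        df = df[df["locus"].isin(RECEPTOR_CLASSES[receptor_class])]
        counts = (
            clonotype_key(df)
            .groupby(df["sample_id"].to_numpy())
            .nunique()
            .rename(f"{receptor_class}_unique")
        )
    if samples is not None:
        counts = counts.reindex(samples, fill_value=0).astype(int)
    return counts


def build_repertoire(records: pd.DataFrame, sample_id: str) -> SampleRepertoire:
    """Summarize one sample's records into a :class:`SampleRepertoire`."""
    sub = records[records["sample_id"] == sample_id]
    if len(sub) == 0:
        raise InputError(f"sample {sample_id!r} has no records")
    validate_records(sub)
    patient = str(sub["patient_id"].iloc[0]) if "patient_id" in sub else ""
    timepoint = str(sub["timepoint"].iloc[0]) if "timepoint" in sub else ""
    filtered = dominant_chain_filter(sub)
    counts = {
        cls: int(clonotype_key(filtered[filtered["locus"].isin(loci)]).nunique())
        for cls, loci in RECEPTOR_CLASSES.items()
    }
    return SampleRepertoire(
        sample_id=sample_id,
        patient_id=patient,
        timepoint=timepoint,
        unique_counts=counts,
        cell_total=int(filtered["cell_id"].nunique()),
    )


def classify_trajectory(
    pre: SampleRepertoire, post: SampleRepertoire, receptor_class: str
) -> DiversityTrajectory:
    """Induced-diversity call: increased iff post count strictly exceeds
    the pre count of the same patient."""
    if receptor_class not in RECEPTOR_CLASSES:
        raise InputError(f"unknown receptor class {receptor_class!r}")
    if pre.patient_id != post.patient_id:
        raise InputError(
            f"patient mismatch: {pre.patient_id!r} vs {post.patient_id!r}"
        )
    if pre.timepoint != "pre" or post.timepoint != "post":
        raise InputError(
            f"timepoint mismatch: got ({pre.timepoint!r}, {post.timepoint!r})"
        )
    pre_n = int(pre.unique_counts[receptor_class])
    post_n = int(post.unique_counts[receptor_class])
    delta = post_n - pre_n
    return DiversityTrajectory(
        patient_id=pre.patient_id,
        receptor_class=receptor_class,
        pre_count=pre_n,
        post_count=post_n,
        delta=delta,
        increased=delta > 0,
    )


def classify_static_diversity(counts: pd.Series) -> pd.Series:
    """Above-median split: high iff strictly greater than the cohort
    median of the supplied counts."""
    if len(counts) < 2:
        raise InputError("static diversity split needs at least 2 samples")
    med = float(np.median(counts.to_numpy(dtype=float)))
    return pd.Series(
        np.where(counts.to_numpy(dtype=float) > med, "high", "low"),
        index=counts.index,
        name="static_diversity",
    )


def vgene_usage(
    records: pd.DataFrame,
    sample_id: str,
    locus: str,
    universe: tuple[str, ...],
) -> VGeneUsage:
    """Cell-level V-gene frequencies of one sample and locus over a fixed
    universe (one vote per cell after the dominant-chain filter)."""
    if locus not in ALLOWED_LOCI:
        raise InputError(f"unknown locus {locus!r}")
    sub = records[(records["sample_id"] == sample_id) & (records["locus"] == locus)]
    patient = str(sub["patient_id"].iloc[0]) if len(sub) and "patient_id" in sub else ""
    timepoint = str(sub["timepoint"].iloc[0]) if len(sub) and "timepoint" in sub else ""
    index = list(universe) + ["other"]
    if len(sub) == 0:
        return VGeneUsage(sample_id, patient, timepoint, locus,
                          pd.Series(0.0, index=index), empty=True)
    sub = dominant_chain_filter(sub)
    calls = sub["v_call"].astype(str)
    outside = ~calls.isin(universe)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} record(s) with V calls outside the universe "
            f"bucketed as 'other' in sample {sample_id}",
            stacklevel=2,
        )
    bucketed = calls.where(~outside, "other")
    freq = bucketed.value_counts(normalize=True).reindex(index, fill_value=0.0)
    return VGeneUsage(sample_id, patient, timepoint, locus, freq, empty=False)


def usage_from_vector(
    sample_id: str, locus: str, counts: pd.Series,
    patient_id: str = "", timepoint: str = "",
) -> VGeneUsage:
    """Usage from an already-aggregated count vector (e.g. summed spatial
    V-gene probe counts)."""
    total = float(counts.sum())
    freq = counts.astype(float) / total if total > 0 else counts.astype(float)
    return VGeneUsage(sample_id, patient_id, timepoint, locus,
                      freq, empty=total == 0)


def usage_correlation(a: VGeneUsage, b: VGeneUsage) -> UsageCorrelation:
    """Spearman correlation of two usage vectors over their union support
    (genes with nonzero frequency in either sample; the ``other`` bucket is
    excluded). Tagged matched iff patient and timepoint coincide."""
    if a.locus != b.locus:
        raise InputError(f"locus mismatch: {a.locus!r} vs {b.locus!r}")
    common = a.frequencies.index.intersection(b.frequencies.index)
    common = common[common != "other"]
    fa = a.frequencies.reindex(common, fill_value=0.0)
    fb = b.frequencies.reindex(common, fill_value=0.0)
    support = (fa > 0) | (fb > 0)
    if int(support.sum()) < 3:
        raise UndefinedStatisticError(
            f"usage correlation undefined: support {int(support.sum())} < 3"
        )
    rho = spearmanr(fa[support], fb[support]).statistic
    matched = (a.patient_id == b.patient_id) and (a.timepoint == b.timepoint)
    return UsageCorrelation(float(rho), matched, int(support.sum()))
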