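"""Read-level QC: conversion filtering, spike-in metrics, fragment lengths.

The C-to-T conversion introduced by the 5hmC labelling chemistry is the
direct readout of a hydroxymethylated site; a sequenced read with no
converted cytosine carries no 5hmC evidence and is dropped before peak
work.  Spike-in controls with known 5hmC sites measure the chemistry's
detection rate and the pulldown's enrichment specificity.  Fragment
lengths are reported descriptively (histogram + mode); cfDNA shows the
mono-nucleosomal ~167 bp mode.

Conversion tables are pandas DataFrames with columns
``read_id, n_cytosines, n_converted, is_spikein, spikein_true_sites``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import IntervalSet

__all__ = [
    "QcReport",
    "filter_converted_reads",
    "spikein_detection_rate",
    "spikein_enrichment",
    "fragment_length_profile",
    "qc_report",
    "read_conversion_tsv",
]


@dataclass
class QcReport:
    n_reads_in: int
    n_reads_kept: int
    kept_fraction: float
    spikein_detection_rate: float | None = None
    spikein_detection_rate_read_level: float | None = None
    spikein_enrichment: float | None = None
    fragment_length_histogram: dict[int, int] = field(default_factory=dict)
    modal_length: int | None = None

    def to_json(self, path: str | Path) -> None:
        obj = {
            "n_reads_in": self.n_reads_in,
            "n_reads_kept": self.n_reads_kept,
            "kept_fraction": self.kept_fraction,
            "spikein_detection_rate": self.spikein_detection_rate,
            "spikein_detection_rate_read_level": self.spikein_detection_rate_read_level,
            "spikein_enrichment": self.spikein_enrichment,
            "modal_length": self.modal_length,
            "fragment_length_histogram": {
                str(k): v for k, v in sorted(self.fragment_length_histogram.items())
            },
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)
            fh.write("\n")


def read_conversion_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_spikein"] = df["is_spikein"].astype(bool)
    return df


def filter_converted_reads(
    records: pd.DataFrame, min_converted: int = 1
) -> tuple[pd.DataFrame, dict]:
    """Keep reads with >= ``min_converted`` converted cytosines.

    The minimal faithful reading of "contains a C-to-T conversion signal" is
    one converted cytosine; the threshold is exposed for stricter filtering.
    Row order is preserved and the operation is idempotent.
    """
    if min_converted < 1:
        raise ValueError("min_converted must be >= 1")
    if ((records["n_converted"] < 0) | (records["n_converted"] > records["n_cytosines"])).any():
        raise ValueError("invalid conversion record: n_converted outside [0, n_cytosines]")
    kept = records.loc[records["n_converted"] >= min_converted].copy()
    n_in, n_kept = len(records), len(kept)
    stats = {
        "n_reads_in": n_in,
        "n_reads_kept": n_kept,
        "kept_fraction": (n_kept / n_in) if n_in else 0.0,
    }
    return kept, stats


def spikein_detection_rate(records: pd.DataFrame, level: str = "site") -> float:
    """Detection rate over spike-in reads with known 5hmC sites.

    ``site`` level (default): converted true sites / total true sites.
    ``read`` level: fraction of modified spike-in reads with >= 1 conversion.
    Conversions on modified spike-in reads are attributed to their known
    sites (spike-in reads carry no other cytosines in this representation).
    """
    spk = records.loc[records["is_spikein"] & (records["spikein_true_sites"] > 0)]
    if len(spk) == 0:
        raise ValueError("no spike-in sites: need >= 1 spike-in read with true sites")
    conv = np.minimum(spk["n_converted"], spk["spikein_true_sites"])
    if level == "site":
        return float(conv.sum() / spk["spikein_true_sites"].sum())
    if level == "read":
        return float((conv >= 1).mean())
    raise ValueError("level must be 'site' or 'read'")


def spikein_enrichment(records: pd.DataFrame, input_modified_fraction: float) -> float:
    """Fold enrichment of modified spike-ins, as an odds ratio vs the input.

    ``(observed modified odds) / (input modified odds)``; 1.0 means the
    library composition matches the input, i.e. no enrichment.  When no
    unmodified spike-in read survives, +inf is returned with a warning.
    """
    if not (0.0 < input_modified_fraction < 1.0):
        raise ValueError("input_modified_fraction must be in (0, 1)")
    spk = records.loc[records["is_spikein"]]
    if len(spk) == 0:
        raise ValueError("no spike-in reads")
    n_mod = int((spk["spikein_true_sites"] > 0).sum())
    n_unmod = len(spk) - n_mod
    input_odds = input_modified_fraction / (1.0 - input_modified_fraction)
    if n_unmod == 0:
        warnings.warn("no unmodified spike-in reads observed; enrichment is infinite")
        return math.inf
    return (n_mod / n_unmod) / input_odds


def fragment_length_profile(fragments: IntervalSet) -> tuple[dict[int, int], int]:
    """Histogram of fragment lengths and the modal length.

    Ties at the maximum count resolve to the smallest length.
    """
    if len(fragments) == 0:
        raise ValueError("fragment_length_profile requires >= 1 fragment")
    lengths = fragments.lengths()
    values, counts = np.unique(lengths, return_counts=True)
    histogram = {int(v): int(c) for v, c in zip(values, counts)}
    modal = int(values[np.argmax(counts)])  # first argmax = smallest length
    return histogram, modal


def qc_report(
    conversions: pd.DataFrame,
    fragments: IntervalSet | None = None,
    spikeins: pd.DataFrame | None = None,
    input_modified_fraction: float | None = None,
    min_converted: int = 1,
) -> QcReport:
    """Assemble the per-sample QC summary."""
    _, stats = filter_converted_reads(conversions, min_converted=min_converted)
    report = QcReport(**stats)
    if spikeins is not None and len(spikeins):
        report.spikein_detection_rate = spikein_detection_rate(spikeins, level="site")
        report.spikein_detection_rate_read_level = spikein_detection_rate(
            spikeins, level="read"
        )
        if input_modified_fraction is not None:
            report.spikein_enrichment = spikein_enrichment(
                spikeins, input_modified_fraction
            )
    if fragments is not None and len(fragments):
        hist, modal = fragment_length_profile(fragments)
        report.fragment_length_histogram = hist
        report.modal_length = modal
    return report
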