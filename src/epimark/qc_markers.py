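"""Marker-modification QC: S/N filter, rRNA markers, degradation index.

Certain modifications are (near-)exclusive to one RNA class and therefore
act as tracers for that class inside a gel-excised size fraction:

* ``m6,6A`` occurs almost exclusively in 18S (small-subunit) rRNA, and
  ``Am`` is a ribose methylation absent from tRNA — together they are the
  co-varying small-subunit rRNA markers.
* ``m3U`` is characteristic of 28S (large-subunit) rRNA but follows a
  degradation path of its own, so it is tracked but kept out of the index.
* ``ms2i6A`` marks mitochondrial tRNA.

When rRNA degrades, its fragments drift into the tRNA-size gel window
(60-75 nt) and the rRNA markers accumulate there.  The **degradation
index** of a tRNA-fraction sample is the geometric mean of the fold
changes of m6,6A and Am over a pristine baseline; samples whose index
exceeds a configurable threshold (default 2-fold) are classified as
degraded and excluded from downstream profiling.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .iodata import NormalizedMatrix, PeakTable

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerPanel",
    "DegradationReport",
    "sn_filter",
    "marker_covariation",
    "degradation_index",
    "classify_sample",
    "qc_cohort",
    "write_qc_report",
]

DEFAULT_INDEX_THRESHOLD = 2.0


@dataclass(frozen=True)
class MarkerPanel:
    """Marker modifications per RNA class.

    ``trna_core`` never contains the rRNA markers: Am and m6,6A do not occur
    in tRNA, which is precisely what makes them degradation tracers there.
    """

    ssu_rrna: frozenset[str] = frozenset({"m6,6A", "Am"})
    lsu_rrna: frozenset[str] = frozenset({"m3U"})
    mito: frozenset[str] = frozenset({"ms2i6A"})
    trna_core: frozenset[str] = frozenset({
        "m5U", "D", "Tm", "m1A", "m2,2G", "m1G", "m2G", "t6A", "m3C", "I",
        "i6A", "Q",
    })

    def __post_init__(self):
        if self.ssu_rrna & self.trna_core:
            raise ValueError("rRNA markers must be disjoint from the tRNA core set")

    @property
    def rrna_markers(self) -> frozenset[str]:
        return self.ssu_rrna


@dataclass(frozen=True)
class DegradationReport:
    sample_id: str
    marker_values: Mapping[str, float]
    index: float | None
    verdict: str  # pristine | degraded | indeterminate
    rationale: str
    threshold: float = DEFAULT_INDEX_THRESHOLD

    def __post_init__(self):
        if self.verdict == "degraded" and not (self.index is not None and self.index > self.threshold):
            raise ValueError("verdict 'degraded' requires index > threshold")


def sn_filter(
    peaks: PeakTable,
    samples: Sequence[str],
    threshold: float = 5.0,
) -> tuple[set[str], set[str]]:
    """Partition modifications into kept/dropped by the group S/N rule.

    A modification is kept iff its light-channel S/N reaches ``threshold``
    (inclusive) in at least one sample of the compared group; the dropped
    set is reported for grey-bar annotation in heatmaps.
    """
    if not samples:
        raise ValueError("sn_filter needs a non-empty sample group")
    best: dict[str, float] = {}
    for rec in peaks.records:
        if rec.channel != "C12" or rec.sample_id not in samples:
            continue
        best[rec.compound] = max(best.get(rec.compound, 0.0), rec.snr)
    kept = {m for m, s in best.items() if s >= threshold}
    dropped = set(best) - kept
    return kept, dropped


def marker_covariation(
    matrix: NormalizedMatrix,
    a: str = "m6,6A",
    b: str = "Am",
) -> float | None:
    """Pearson correlation of two marker rows across samples.

    Returns None (indeterminate) when either row is constant; requires both
    rows in at least 3 samples.
    """
    for mod in (a, b):
        if mod not in matrix.values.index:
            raise KeyError(f"modification {mod!r} not in matrix")
    xa = matrix.row(a).to_numpy(float)
    xb = matrix.row(b).to_numpy(float)
    if xa.size < 3:
        raise ValueError("marker covariation needs >= 3 samples")
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        logger.warning("marker_covariation: constant row for %s/%s, indeterminate", a, b)
        return None
    return float(np.corrcoef(xa, xb)[0, 1])


def degradation_index(
    sample_values: Mapping[str, float],
    baseline: Mapping[str, float],
    markers: Iterable[str] = ("m6,6A", "Am"),
) -> float | None:
    """Geometric-mean fold change of the rRNA markers over a pristine baseline.

    Only the marker rows enter, so the index inherits any global scaling of
    the sample relative to the baseline; with both on the same normalization
    stage a sample identical to baseline scores exactly 1.  Returns None when
    no marker has a positive baseline and a present sample value.
    """
    folds = []
    for m in markers:
        base = baseline.get(m, 0.0)
        if base <= 0:
            logger.warning("degradation_index: baseline for %s not positive, skipped", m)
            continue
        if m not in sample_values:
            continue
        folds.append(sample_values[m] / base)
    if not folds:
        return None
    return float(np.exp(np.mean(np.log(np.maximum(folds, 1e-300)))))


def classify_sample(
    sample_id: str,
    sample_values: Mapping[str, float],
    baseline: Mapping[str, float],
    threshold: float = DEFAULT_INDEX_THRESHOLD,
    markers: Iterable[str] = ("m6,6A", "Am"),
) -> DegradationReport:
    """Keep/exclude verdict for one tRNA-fraction sample.

    degraded iff index > threshold; indeterminate when the index cannot be
    computed (missing markers or non-positive baseline).
    """
    markers = tuple(markers)
    idx = degradation_index(sample_values, baseline, markers)
    marker_values = {m: sample_values.get(m, 0.0) for m in markers}
    if idx is None:
        return DegradationReport(
            sample_id, marker_values, None, "indeterminate",
            "degradation index not computable (missing markers or baseline)",
            threshold,
        )
    if idx > threshold:
        verdict, why = "degraded", (
            f"rRNA-marker index {idx:.3g} exceeds {threshold:g}-fold over baseline"
        )
    else:
        verdict, why = "pristine", (
            f"rRNA-marker index {idx:.3g} within {threshold:g}-fold of baseline"
        )
    return DegradationReport(sample_id, marker_values, idx, verdict, why, threshold)


def qc_cohort(
    matrix: NormalizedMatrix,
    baseline_samples: Sequence[str],
    threshold: float = DEFAULT_INDEX_THRESHOLD,
    markers: Iterable[str] = ("m6,6A", "Am"),
) -> list[DegradationReport]:
    """Classify every column of a tRNA-fraction matrix against a baseline.

    The baseline is the mean profile of the samples declared pristine (the
    paper's role is played by the 0 h unfrozen preparations).
    """
    missing = [s for s in baseline_samples if s not in matrix.samples]
    if missing:
        raise KeyError(f"baseline samples not in matrix: {missing}")
    baseline = matrix.values[list(baseline_samples)].mean(axis=1).to_dict()
    reports = []
    for sample in matrix.samples:
        rep = classify_sample(sample, matrix.values[sample].to_dict(), baseline,
                              threshold, markers)
        if rep.verdict == "degraded":
            logger.info("QC: sample %s excluded (%s)", sample, rep.rationale)
        reports.append(rep)
    return reports


def write_qc_report(
    reports: Sequence[DegradationReport],
    tsv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    """Emit the QC verdicts as TSV plus an optional JSON summary."""
    rows = []
    for r in reports:
        row = {"sample": r.sample_id,
               "index": "" if r.index is None else f"{r.index:.6g}",
               "verdict": r.verdict, "rationale": r.rationale}
        for m, v in r.marker_values.items():
            row[m] = f"{v:.6g}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        summary = {
            "threshold": reports[0].threshold if reports else DEFAULT_INDEX_THRESHOLD,
            "n_samples": len(reports),
            "n_degraded": sum(r.verdict == "degraded" for r in reports),
            "n_indeterminate": sum(r.verdict == "indeterminate" for r in reports),
            "verdicts": {r.sample_id: r.verdict for r in reports},
            "provenance": "fold-change rule over pristine-baseline mean; the "
                          "underlying published exclusion was qualitative",
        }
        Path(json_path).write_text(json.dumps(summary, indent=2, sort_keys=True))
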