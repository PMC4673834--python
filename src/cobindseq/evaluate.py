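"""Recovery metrics against planted simulation truth.

Used by the test-bench and the reproduction script to measure how well
the pipeline recovers what the generator planted: binding-site recovery
and false-discovery fraction per factor, and co-binding class agreement
(adjusted Rand index, class-fraction estimates) for the K-means
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cobinding import (
    CoBindingClassifier,
    merge_factor_sites,
    profile_matrix,
    subtract_control,
)
from .consensus import BindingSiteSet, ConsensusPeakCaller
from .genome import coverage_from_intervals
from .simulate import SimulatedDataset, SyntheticTruth


def fit_factor(ds: SimulatedDataset, factor: str, **params) -> ConsensusPeakCaller:
    """Run the consensus caller for one factor of a simulated dataset."""
    return ConsensusPeakCaller(factor=factor, **params).fit(
        ds.caller_peaks[factor],
        sample_reads=ds.reads[factor],
        control_reads=ds.reads["IgG"],
        genome=ds.genome,
    )


def site_recovery(
    sites: BindingSiteSet,
    truth: SyntheticTruth,
    factor: str,
    tolerance: int = 300,
) -> tuple[float, float]:
    """(recovery, false-discovery fraction) for one factor's site set.

    A planted bound site is recovered when some filtered site overlaps
    center +/- tolerance; a filtered site is a false discovery when it
    overlaps no planted bound site's window.
    """
    bound = truth.sites_bound_by(factor)
    windows: dict[str, list[tuple[int, int]]] = {}
    for s in bound:
        windows.setdefault(s.chrom, []).append(
            (s.center - tolerance, s.center + tolerance)
        )
    intervals = sites.intervals()
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    def overlaps_any(chrom, lo, hi, table):
        return any(lo < e and s < hi for s, e in table.get(chrom, ()))

    n_rec = sum(
        overlaps_any(s.chrom, s.center - tolerance, s.center + tolerance, by_chrom)
        for s in bound
    )
    n_fp = sum(
        not overlaps_any(iv.chrom, iv.start, iv.end, windows) for iv in intervals
    )
    recovery = n_rec / len(bound) if bound else float("nan")
    fdr = n_fp / len(intervals) if intervals else 0.0
    return recovery, fdr


@dataclass
class CoBindingEvaluation:
    ari: float
    fractions: dict[str, float]
    truth_classes: list[str]
    predicted_classes: list[str]
    combined: list
    classifier: CoBindingClassifier


def evaluate_cobinding(
    ds: SimulatedDataset,
    caller_a: ConsensusPeakCaller,
    caller_b: ConsensusPeakCaller,
    pairing_distance: int = 250,
    seed: int = 0,
) -> CoBindingEvaluation:
    """Merge, profile, classify, and compare with the planted classes.

    Each combined site is matched to the nearest planted site (site
    centers are >= 2 kb apart, so the match is unambiguous).
    """
    from sklearn.metrics import adjusted_rand_score

    combined = merge_factor_sites(caller_a.sites_, caller_b.sites_, pairing_distance)
    cov = {k: coverage_from_intervals(ds.reads[k], ds.genome) for k in ("A", "B", "IgG")}
    sub = {
        "A": subtract_control(cov["A"], cov["IgG"], caller_a.background_),
        "B": subtract_control(cov["B"], cov["IgG"], caller_b.background_),
    }
    profiles = profile_matrix(combined, sub["A"], sub["B"])
    clf = CoBindingClassifier(random_state=seed).fit(profiles)

    truth_centers: dict[str, list[tuple[int, str]]] = {}
    for s in ds.truth.sites:
        truth_centers.setdefault(s.chrom, []).append((s.center, s.klass))
    truth_classes = []
    for site in combined:
        arr = truth_centers.get(site.chrom, [])
        truth_classes.append(
            min(arr, key=lambda x: abs(x[0] - site.center))[1] if arr else "none"
        )
    predicted = [str(c) for c in clf.site_classes_]
    ari = float(adjusted_rand_score(truth_classes, predicted))
    n = len(predicted)
    fractions = {
        k: predicted.count(k) / n for k in ("shared", "A_only", "B_only")
    }
    return CoBindingEvaluation(
        ari=ari, fractions=fractions, truth_classes=truth_classes,
        predicted_classes=predicted, combined=combined, classifier=clf,
    )
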