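"""Accuracy and precision statistics for model-derived metrics.

Accuracy scores a model-derived value against a ground truth as a
percentage of the truth's usable range:

* linear metrics (distances, R, 1/k):   100·(1 − |m − t| / t)
* fractal dimension:                    100·(1 − |m − t| / (t − 1))

The fractal variant subtracts one from the denominator because D of a
surface only varies between 2 and 3, so errors should be scored against
that one-unit range rather than against the full value of D.

Precision over replicate renderings of the same quadrat is the coefficient
of variation: the average of the per-quadrat sample standard deviations
divided by the average of all measurements, as a percentage.

``REFERENCE_VALIDATION_PAIRS`` bundles a published validation dataset:
fractal dimension (four resolution bands) and vector dispersion of three
reference structures — concrete casts of 3D-printed geometries — measured
both on the true geometry and on an underwater photogrammetric model of the
structures placed on a reef.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "accuracy_linear",
    "accuracy_fractal",
    "mean_sd",
    "coefficient_of_variation",
    "table1_report",
    "REFERENCE_VALIDATION_PAIRS",
]

#: (metric, kind, [(ground truth, model value) x 3 structures])
REFERENCE_VALIDATION_PAIRS = {
    "D_0.60-0.30": ("fractal", [(2.0032, 2.0056), (2.0026, 2.0071),
                                (2.0003, 2.0033)]),
    "D_0.30-0.15": ("fractal", [(2.3257, 2.2606), (2.0131, 2.0138),
                                (2.4096, 2.54)]),
    "D_0.15-0.05": ("fractal", [(2.4148, 2.3516), (2.0952, 2.0138),
                                (2.5085, 2.383)]),
    "D_0.05-0.01": ("fractal", [(2.1975, 2.1044), (2.131, 2.086),
                                (2.264, 2.1687)]),
    "1/k": ("linear", [(0.249, 0.226), (0.194, 0.171), (0.304, 0.359)]),
}


def accuracy_linear(measured: float, truth: float) -> float:
    """Accuracy (%) of a linear-scale measurement against its ground truth.

    100·(1 − |measured − truth| / truth). Not clamped: a relative error
    above 100% yields a negative accuracy.
    """
    if truth == 0:
        raise ValueError("ground truth must be nonzero")
    return 100.0 * (1.0 - abs(measured - truth) / truth)


def accuracy_fractal(measured: float, truth: float) -> float:
    """Accuracy (%) of a fractal-dimension measurement.

    100·(1 − |measured − truth| / (truth − 1)); the denominator shift
    reflects D's [2, 3] range for surfaces. Values outside (2, 3) are
    accepted with a warning — they indicate a degenerate band fit.
    """
    if truth <= 1:
        raise ValueError("fractal ground truth must exceed 1")
    for name, v in (("measured", measured), ("truth", truth)):
        if not 2.0 < v < 3.0:
            warnings.warn(f"{name} D = {v} outside the surface range (2, 3)",
                          stacklevel=2)
    return 100.0 * (1.0 - abs(measured - truth) / (truth - 1.0))


def mean_sd(values) -> tuple[float, float]:
    """Arithmetic mean and sample (n−1) standard deviation.

    The sample denominator is what reproduces published ±SD figures from
    per-structure accuracy triples. SD is NaN for a single value.
    """
    v = np.asarray(list(values), dtype=float)
    if len(v) == 0:
        raise ValueError("empty value list")
    sd = float(np.std(v, ddof=1)) if len(v) >= 2 else float("nan")
    return float(v.mean()), sd


def coefficient_of_variation(replicate_sets) -> float:
    """Replicate precision as a percentage.

    CV = 100 · mean(per-set sample SD) / mean(all measurements). Each set
    holds repeated measurements of one quadrat; identical replicates give
    CV = 0 regardless of between-set differences.
    """
    sets = [np.asarray(list(s), dtype=float) for s in replicate_sets]
    if not sets:
        raise ValueError("no replicate sets")
    for s in sets:
        if len(s) < 2:
            raise ValueError("each replicate set needs >= 2 measurements")
    mean_sd_ = float(np.mean([np.std(s, ddof=1) for s in sets]))
    grand_mean = float(np.mean(np.concatenate(sets)))
    if grand_mean == 0:
        raise ValueError("overall mean of measurements is zero")
    return 100.0 * mean_sd_ / grand_mean


def table1_report(pairs=None) -> pd.DataFrame:
    """Per-metric accuracy summary from (ground truth, model) value pairs.

    ``pairs`` maps a metric name to ``(kind, [(truth, measured), ...])``
    with kind ``"fractal"`` or ``"linear"``; defaults to the bundled
    reference dataset. Returns a DataFrame with per-pair accuracies and the
    metric's mean ± sample SD, rounded to 2 decimals (half-even) in the
    ``mean_2dp``/``sd_2dp`` columns for comparison against printed values.
    """
    if pairs is None:
        pairs = REFERENCE_VALIDATION_PAIRS
    rows = []
    for metric, (kind, pair_list) in pairs.items():
        if kind == "fractal":
            acc_fn = accuracy_fractal
        elif kind == "linear":
            acc_fn = accuracy_linear
        else:
            raise ValueError(f"unknown metric kind {kind!r}")
        accs = [acc_fn(measured, truth) for truth, measured in pair_list]
        mean, sd = mean_sd(accs)
        rows.append({
            "metric": metric,
            "kind": kind,
            "n_pairs": len(accs),
            "accuracies_pct": accs,
            "mean_pct": mean,
            "sd_pct": sd,
            "mean_2dp": _round2(mean),
            "sd_2dp": _round2(sd),
        })
    return pd.DataFrame(rows).set_index("metric")


def _round2(x: float) -> float:
    # numpy.round is round-half-even, the deterministic convention used for
    # comparisons against printed 2-decimal values
    return float(np.round(x, 2))
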