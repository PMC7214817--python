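"""Reporter-based quantification from tabular inputs.

Two estimators mirror the experimental readouts of the dual-reporter
assay for non-canonical initiation:

* the **initiation rate** from densitometry of paired constructs — a
  wild-type reporter (canonical start intact, signal dominated by
  AUG initiation) and an M1A reporter (canonical start mutated, so
  only upstream non-AUG initiation yields protein) — each lane
  normalized to its tubulin loading control;
* the **co-localization fraction** of marker-positive organellar foci
  (mCherry-SKL) that also contain reporter (GFP) signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "InitiationRateEstimate",
    "ColocalizationEstimate",
    "estimate_initiation_rate",
    "colocalization_fraction",
    "boxplot_stats",
    "read_densitometry",
    "read_foci",
]

DENSITOMETRY_COLUMNS = ["lane_id", "construct", "gfp_intensity", "loading_intensity"]
FOCI_COLUMNS = ["focus_id", "marker_positive", "signal_positive"]

WT_LABEL = "WT"
MUT_LABEL = "M1A"


@dataclass(frozen=True)
class InitiationRateEstimate:
    """Non-canonical initiation rate as a percentage of canonical expression.

    ``rate_percent = 100 * mean(normalized M1A) / mean(normalized WT)``
    where each lane is normalized as gfp/loading.  ``per_replicate_rates``
    are the per-M1A-lane rates against the mean WT signal; their standard
    deviation is ``dispersion``.
    """

    rate_percent: float
    per_replicate_rates: tuple
    n_wt: int
    n_mut: int
    dispersion: float


@dataclass(frozen=True)
class ColocalizationEstimate:
    fraction: float
    n_marker_positive: int
    n_double_positive: int


def read_densitometry(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DENSITOMETRY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"densitometry table missing columns: {sorted(missing)}")
    return df


def read_foci(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(FOCI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"foci table missing columns: {sorted(missing)}")
    return df


def _validate_densitometry(table: pd.DataFrame) -> None:
    if (table["loading_intensity"] <= 0).any():
        raise ValueError("loading_intensity must be positive in every lane")
    if (table["gfp_intensity"] < 0).any():
        raise ValueError("gfp_intensity must be nonnegative")
    for label in (WT_LABEL, MUT_LABEL):
        if not (table["construct"] == label).any():
            raise ValueError(f"no lanes labelled {label!r}")


def estimate_initiation_rate(table: pd.DataFrame) -> InitiationRateEstimate:
    """Estimate the non-canonical initiation rate from a densitometry table.

    The estimate is invariant to uniform rescaling of all intensities, to
    per-lane loading differences (they cancel in gfp/loading), and to lane
    order.
    """
    _validate_densitometry(table)
    norm = table["gfp_intensity"] / table["loading_intensity"]
    wt = norm[table["construct"] == WT_LABEL].to_numpy(float)
    mut = norm[table["construct"] == MUT_LABEL].to_numpy(float)
    wt_mean = wt.mean()
    if wt_mean == 0:
        raise ZeroDivisionError("mean normalized WT signal is zero; rate undefined")
    per_rep = 100.0 * mut / wt_mean
    return InitiationRateEstimate(
        rate_percent=float(per_rep.mean()),
        per_replicate_rates=tuple(float(r) for r in per_rep),
        n_wt=wt.size,
        n_mut=mut.size,
        dispersion=float(np.std(per_rep, ddof=1)) if per_rep.size > 1 else 0.0,
    )


def colocalization_fraction(table: pd.DataFrame) -> ColocalizationEstimate:
    """Fraction of marker-positive foci that also carry reporter signal.

    Signal-only foci (marker-negative) are excluded from the denominator;
    they are reported separately by callers that need them.
    """
    marker = table[table["marker_positive"].astype(bool)]
    if marker.empty:
        raise ValueError("no marker-positive foci; fraction undefined")
    double = int(marker["signal_positive"].astype(bool).sum())
    return ColocalizationEstimate(
        fraction=double / len(marker),
        n_marker_positive=len(marker),
        n_double_positive=double,
    )


def boxplot_stats(values) -> dict:
    """Box-plot summary: median, quartiles, and 1.5*IQR whisker bounds.

    Whiskers extend to the most extreme data point within 1.5 interquartile
    ranges of the box.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_limit, hi_limit = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_limit) & (v <= hi_limit)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "n": int(v.size),
    }
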