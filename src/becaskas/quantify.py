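"""Absolute off-target editing quantification.

Pulldown sequencing measures editing conditional on an R-loop being present;
amplicon sequencing measures absolute editing in the population.  Their
ratio — the through-origin slope of amplicon frequency on in-R-loop
frequency — estimates base-editor occupancy, and scaling every in-R-loop
edit frequency by it yields expected edited bases per genome
(``edits_per_genome``) and the peaks-per-edit efficiency of each editor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class OccupancyFit:
    scaling: float  # slope of amplicon on R-loop frequency, through origin
    residual_sd: float
    n_points: int


@dataclass
class AbsoluteQuant:
    edits_per_genome: float
    n_differential_peaks: int | None = None

    @property
    def peaks_per_edit(self) -> float:
        if self.n_differential_peaks is None:
            raise ValueError("differential peak count not supplied")
        if self.edits_per_genome <= 0:
            raise ValueError("peaks_per_edit undefined at zero edits_per_genome")
        return self.n_differential_peaks / self.edits_per_genome


def fit_occupancy(table: pd.DataFrame) -> OccupancyFit:
    """Through-origin least squares of ``amplicon_freq`` on ``rloop_freq``."""
    x = table["rloop_freq"].to_numpy(dtype=float)
    y = table["amplicon_freq"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 site-matched frequency pairs")
    denom = float(np.dot(x, x))
    if denom == 0:
        raise ValueError("all R-loop frequencies are zero")
    slope = float(np.dot(x, y) / denom)
    resid = y - slope * x
    sd = float(np.std(resid, ddof=1)) if len(x) > 1 else 0.0
    return OccupancyFit(scaling=slope, residual_sd=sd, n_points=len(x))


def edits_per_genome(
    site_frequencies: pd.DataFrame | float,
    scaling: float,
    ploidy: int = 2,
    n_differential_peaks: int | None = None,
) -> AbsoluteQuant:
    """Expected edited bases per genome over gRNA-dependent sites.

    ``site_frequencies`` is either a frame with a ``freq`` column (one row
    per called edited position per differential-peak site) or a precomputed
    total of in-R-loop frequencies.  Each in-R-loop frequency is converted
    to an absolute per-allele frequency by ``scaling`` and summed over
    ``ploidy`` alleles.
    """
    if scaling <= 0:
        raise ValueError("scaling must be positive")
    if isinstance(site_frequencies, pd.DataFrame):
        total = float(site_frequencies["freq"].sum())
    else:
        total = float(site_frequencies)
    return AbsoluteQuant(
        edits_per_genome=total * scaling * ploidy,
        n_differential_peaks=n_differential_peaks,
    )


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + sig - 1)


def fold_comparisons(
    value_a: float, value_b: float, label_a: str = "A", label_b: str = "B"
) -> dict:
    """Labelled A/B ratio, rounded to 3 significant figures."""
    if value_b == 0:
        raise ZeroDivisionError("denominator is zero")
    return dict(
        numerator=label_a,
        denominator=label_b,
        value_a=value_a,
        value_b=value_b,
        fold=_round_sig(value_a / value_b, 3),
    )


def dose_response(series: pd.DataFrame, flat_threshold: float = 1.2) -> dict:
    """Fold changes across an editor-mRNA dose series.

    ``series`` has a ``dose`` column plus one column per metric (e.g.
    on-target edit frequency, off-target R-loop signal, mean off-target edit
    frequency).  Fold change = value at the highest dose / value at the
    lowest dose; a metric with fold <= ``flat_threshold`` is flagged flat.
    """
    if len(series) < 2:
        raise ValueError("need at least two doses")
    doses = series["dose"].to_numpy(dtype=float)
    if not (np.all(np.diff(doses) > 0) or np.all(np.diff(doses) < 0)):
        raise ValueError("doses must be strictly monotone")
    top = series.loc[series["dose"].idxmax()]
    bottom = series.loc[series["dose"].idxmin()]
    out = {}
    for col in series.columns:
        if col == "dose":
            continue
        hi, lo = float(top[col]), float(bottom[col])
        fold = hi / lo if lo != 0 else float("inf")
        out[col] = dict(fold=_round_sig(fold, 3), flat=fold <= flat_threshold)
    return out
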