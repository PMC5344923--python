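"""Goodness-of-fit between structure-derived and experimental exchange data.

Two comparison currencies:

* residue-resolved protection factors (HDX-NMR): per-residue absolute error
  |ln P_der - ln P_obs|, its mean over compared residues, and the squared
  Pearson correlation between the two ln P series;
* peptide-resolved uptake curves (HDX-MS): per-peptide summed absolute
  deviation over the experimental time grid, and its mean over peptides.

:func:`select_best` runs the full forward pipeline for every member of an
ensemble and returns the conformation minimizing the aggregate error.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .exchange import ModelParams, ProtectionFactorSet, protection_factors
from .kinetics import (
    IntrinsicRates,
    Peptide,
    UptakeCurve,
    peptide_uptake,
    residue_uptake,
)
from .structures import Ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "NMRFitReport",
    "MSFitReport",
    "SelectionResult",
    "nmr_fit",
    "ms_fit",
    "derive_uptake",
    "select_best",
    "load_observed_pf_csv",
    "load_observed_ms_csv",
]


@dataclass
class NMRFitReport:
    per_residue_error: dict[int, float]
    mean_abs_error: float
    r_squared: Optional[float]
    r_sign: Optional[int]
    n: int


@dataclass
class MSFitReport:
    per_peptide_error: dict[str, float]
    mean_error: float
    n_peptides: int
    times: np.ndarray
    peptide_spans: Optional[dict[str, tuple[int, int]]] = None


@dataclass
class SelectionResult:
    best_index: int
    best_score: float
    scores: list[float]


def nmr_fit(derived: ProtectionFactorSet,
            observed: ProtectionFactorSet) -> NMRFitReport:
    """Compare two ln P sets over their common residues.

    R^2 is the squared Pearson correlation; its sign is reported alongside so
    that perfect anti-correlation (which also squares to 1) stays visible.
    With fewer than 2 common residues or a zero-variance series, R^2 is
    undefined and reported as None.
    """
    common = sorted(set(derived.values) & set(observed.values))
    if not common:
        raise ValueError("no residues in common between derived and observed data")
    dropped = (len(derived.values) - len(common), len(observed.values) - len(common))
    if any(dropped):
        logger.info("nmr_fit: dropped %d derived-only and %d observed-only residues",
                    *dropped)
    a = np.array([derived.values[i] for i in common])
    b = np.array([observed.values[i] for i in common])
    errors = {i: float(abs(x - y)) for i, x, y in zip(common, a, b)}
    mean_abs_error = float(np.mean(np.abs(a - b)))
    r_squared: Optional[float] = None
    r_sign: Optional[int] = None
    if len(common) >= 2 and np.ptp(a) > 0 and np.ptp(b) > 0:
        r = stats.pearsonr(a, b).statistic
        r_squared = float(r * r)
        r_sign = int(math.copysign(1, r)) if r != 0 else 0
    else:
        logger.warning("nmr_fit: R^2 undefined (n < 2 or zero variance)")
    return NMRFitReport(
        per_residue_error=errors,
        mean_abs_error=mean_abs_error,
        r_squared=r_squared,
        r_sign=r_sign,
        n=len(common),
    )


def ms_fit(derived: Mapping[str, UptakeCurve],
           observed: Mapping[str, UptakeCurve],
           peptides: Optional[Sequence[Peptide]] = None) -> MSFitReport:
    """Compare uptake-curve sets: per-peptide sum over the time grid of
    |D_der(t) - D_obs(t)|, averaged over the common peptides."""
    common = sorted(set(derived) & set(observed))
    if not common:
        raise ValueError("no peptides in common between derived and observed data")
    errors: dict[str, float] = {}
    times = None
    for pid in common:
        d, o = derived[pid], observed[pid]
        if d.times.shape != o.times.shape or not np.allclose(d.times, o.times):
            raise ValueError(f"peptide {pid}: derived and observed time grids differ")
        errors[pid] = float(np.sum(np.abs(d.values - o.values)))
        times = d.times
    spans = None
    if peptides is not None:
        spans = {p.id: (p.start, p.end) for p in peptides if p.id in errors}
    return MSFitReport(
        per_peptide_error=errors,
        mean_error=float(np.mean(list(errors.values()))),
        n_peptides=len(errors),
        times=times,
        peptide_spans=spans,
    )


def derive_uptake(pf: ProtectionFactorSet, rates: IntrinsicRates,
                  peptides: Sequence[Peptide],
                  times: Sequence[float]) -> dict[str, UptakeCurve]:
    """Forward pipeline from ln P to peptide uptake curves."""
    residue_curves = {
        i: residue_uptake(pf.values[i], rates.values[i], times)
        for i in pf.values
        if i in rates.values
    }
    out: dict[str, UptakeCurve] = {}
    for pep in peptides:
        out[pep.id] = peptide_uptake(pep, residue_curves)
    return out


ExperimentalData = Union[ProtectionFactorSet, Mapping[str, UptakeCurve]]


def score_conformation(conf, experimental: ExperimentalData,
                       params: ModelParams = ModelParams(),
                       rates: Optional[IntrinsicRates] = None,
                       peptides: Optional[Sequence[Peptide]] = None,
                       times: Optional[Sequence[float]] = None) -> float:
    """Aggregate fit error of one conformation against experimental data.

    Protection-factor data scores by mean absolute ln P error; uptake-curve
    data by the mean per-peptide summed deviation (the forward pipeline then
    needs ``rates``, ``peptides`` and ``times``).
    """
    pf = protection_factors(conf, params)
    if isinstance(experimental, ProtectionFactorSet):
        return nmr_fit(pf, experimental).mean_abs_error
    if rates is None or peptides is None:
        raise ValueError("uptake-curve scoring needs intrinsic rates and peptides")
    if times is None:
        times = next(iter(experimental.values())).times
    derived = derive_uptake(pf, rates, peptides, times)
    return ms_fit(derived, experimental, peptides).mean_error


def select_best(ens: Ensemble, experimental: ExperimentalData,
                params: ModelParams = ModelParams(),
                rates: Optional[IntrinsicRates] = None,
                peptides: Optional[Sequence[Peptide]] = None,
                times: Optional[Sequence[float]] = None) -> SelectionResult:
    """Score every ensemble member and return the best-fitting conformation.

    Ties break to the lowest index for determinism.
    """
    scores = [
        score_conformation(c, experimental, params, rates, peptides, times)
        for c in ens
    ]
    best_index = int(np.argmin(scores))  # argmin returns the first minimum
    return SelectionResult(best_index=best_index,
                           best_score=scores[best_index],
                           scores=scores)


# ---------------------------------------------------------------------------
# tabular I/O


def load_observed_pf_csv(path: str | Path,
                         author_to_internal: Optional[Mapping[str, int]] = None
                         ) -> ProtectionFactorSet:
    """Read observed protection factors.

    CSV columns: ``residue`` (author numbering), ``value``, and ``log_base``
    (``ln`` or ``log10``; log10 values are converted to natural log).
    ``author_to_internal`` maps author labels onto internal indices; without
    it the residue column is taken as already internal.
    """
    values: dict[int, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            label = row["residue"].strip()
            if author_to_internal is not None:
                if label not in author_to_internal:
                    logger.info("observed residue %s not in structure; dropped", label)
                    continue
                idx = author_to_internal[label]
            else:
                idx = int(label)
            v = float(row["value"])
            if row.get("log_base", "ln").strip() == "log10":
                v *= math.log(10.0)
            values[idx] = v
    if not values:
        raise ValueError(f"{path}: no observed protection factors loaded")
    return ProtectionFactorSet(values=values)


def load_observed_ms_csv(path: str | Path
                         ) -> tuple[list[Peptide], dict[str, UptakeCurve]]:
    """Read observed peptide uptake (long format).

    CSV columns: peptide_id, start, end, sequence, time_min, uptake_frac.
    """
    rows_by_pep: dict[str, list[tuple[float, float]]] = {}
    meta: dict[str, tuple[int, int, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            pid = row["peptide_id"].strip()
            meta[pid] = (int(row["start"]), int(row["end"]), row["sequence"].strip())
            rows_by_pep.setdefault(pid, []).append(
                (float(row["time_min"]), float(row["uptake_frac"]))
            )
    if not rows_by_pep:
        raise ValueError(f"{path}: no peptide uptake data loaded")
    peptides = [Peptide(pid, *meta[pid]) for pid in sorted(meta)]
    curves: dict[str, UptakeCurve] = {}
    for pid, rows in rows_by_pep.items():
        rows.sort()
        t, v = zip(*rows)
        curves[pid] = UptakeCurve(times=np.array(t), values=np.array(v))
    return peptides, curves
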