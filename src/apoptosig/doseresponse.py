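"""Four-parameter logistic dose-response fitting and MEKi sensitivity calls.

The model is r = bottom + (top - bottom) / (1 + 10**(hill*(log10 d - log10 IC50)))
fit by bounded least squares with jittered restarts.  Flat curves
(amplitude below a fraction of the vehicle response, or a hill slope
whose confidence interval spans zero) yield an undefined IC50 — the
behaviour of extremely MEKi-resistant lines.  Two classification rules
are provided and never mixed implicitly: an absolute IC50 threshold
(2000 pM) and a top-n/bottom-n ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

#: vehicle (dose 0) anchor on the log10 micromolar scale
VEHICLE_LOG10_UM = -5.0
FLAT_FRACTION = 0.2
SENSITIVITY_THRESHOLD_MOLAR = 2e-9  # 2000 pM


@dataclass
class DoseResponseFit:
    cell_line: str
    top: float | None
    bottom: float | None
    hill: float | None
    log10_ic50_um: float | None
    ic50_molar: float | None
    rss: float | None
    flat_flag: bool
    converged: bool
    label: str = "unclassified"

    @property
    def ic50_defined(self) -> bool:
        return self.ic50_molar is not None and np.isfinite(self.ic50_molar)


def _model(theta: np.ndarray, logd: np.ndarray) -> np.ndarray:
    top, bottom, hill, logi = theta
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logd - logi)))


def fit_4pl(
    doses_molar,
    responses,
    cell_line: str = "",
    vehicle_log10_um: float = VEHICLE_LOG10_UM,
    flat_fraction: float = FLAT_FRACTION,
    n_restarts: int = 5,
    seed: int = 0,
) -> DoseResponseFit:
    """Least-squares 4PL fit with flat-curve detection.

    Vehicle rows (dose 0) are anchored at ``vehicle_log10_um`` on the
    log10 micromolar scale.  The IC50 search range is the dose range
    extended one decade each side.
    """
    d = np.asarray(doses_molar, dtype=float)
    r = np.asarray(responses, dtype=float)
    if d.shape != r.shape:
        raise ValueError("doses and responses must align")
    n_distinct = np.unique(d[d > 0]).size
    if n_distinct < 4:
        raise ValueError("need >=4 distinct positive doses (4 free parameters)")
    logd = np.where(d > 0, np.log10(np.maximum(d, 1e-300) * 1e6), vehicle_log10_um)
    vehicle = r[d == 0]
    baseline = float(np.mean(vehicle)) if vehicle.size else float(np.max(r))

    rmin, rmax = float(r.min()), float(r.max())
    span = max(rmax - rmin, 1e-12)
    pos = logd[d > 0]
    lo_logi, hi_logi = pos.min() - 1.0, pos.max() + 1.0
    # initial log IC50: dose nearest the half-range crossing
    half = (rmin + rmax) / 2.0
    order = np.argsort(logd)
    cross = logd[order][np.argmin(np.abs(r[order] - half))]
    x0 = np.array([rmax, rmin, 1.0, float(np.clip(cross, lo_logi, hi_logi))])
    lb = np.array([rmin - span, rmin - span, 1e-6, lo_logi])
    ub = np.array([rmax + span, rmax + span, 20.0, hi_logi])

    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_restarts):
        start = x0.copy()
        if k > 0:
            start[:2] += rng.normal(0.0, 0.05 * span, size=2)
            start[2] = np.clip(10.0 ** rng.normal(0.0, 0.3), lb[2], ub[2])
            start[3] = float(rng.uniform(lo_logi, hi_logi))
            start = np.clip(start, lb, ub)
        try:
            sol = least_squares(
                lambda t: _model(t, logd) - r, start, bounds=(lb, ub), method="trf"
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        return DoseResponseFit(
            cell_line, None, None, None, None, None, None, flat_flag=False, converged=False
        )
    top, bottom, hill, logi = (float(v) for v in best.x)
    rss = float(2.0 * best.cost)

    # hill standard error from the Gauss-Newton covariance
    hill_ci_spans_zero = False
    dof = max(r.size - 4, 1)
    J = best.jac
    try:
        cov = np.linalg.inv(J.T @ J) * (rss / dof)
        se_hill = float(np.sqrt(max(cov[2, 2], 0.0)))
        hill_ci_spans_zero = hill - 1.96 * se_hill <= 0.0
    except np.linalg.LinAlgError:
        hill_ci_spans_zero = True

    flat = abs(top - bottom) < flat_fraction * abs(baseline) or hill_ci_spans_zero
    if flat:
        return DoseResponseFit(
            cell_line, top, bottom, hill, None, None, rss, flat_flag=True, converged=True
        )
    ic50_molar = 10.0**logi * 1e-6
    return DoseResponseFit(
        cell_line, top, bottom, hill, logi, ic50_molar, rss, flat_flag=False, converged=True
    )


def fit_dose_response_table(
    table: pd.DataFrame, seed: int = 0, **kwargs
) -> dict[str, DoseResponseFit]:
    """Fit every cell line of a cell_line,dose_molar,replicate,response table."""
    fits = {}
    for line, sub in table.groupby("cell_line", sort=True):
        fits[line] = fit_4pl(
            sub["dose_molar"].to_numpy(),
            sub["response"].to_numpy(),
            cell_line=line,
            seed=seed,
            **kwargs,
        )
    return fits


def classify_threshold(
    fit: DoseResponseFit, threshold_molar: float = SENSITIVITY_THRESHOLD_MOLAR
) -> str:
    """Sensitive iff IC50 is defined and strictly below the threshold."""
    label = (
        "sensitive"
        if fit.ic50_defined and fit.ic50_molar < threshold_molar
        else "resistant"
    )
    fit.label = label
    return label


def rank_extremes(
    fits: dict[str, DoseResponseFit], n_per_group: int = 20
) -> pd.DataFrame:
    """Rank lines by IC50; the resistant pool is the top n plus every
    undefined-IC50 line, the sensitive pool the bottom n, the middle
    unclassified.  Ties and the undefined group are ordered by name.
    """
    if len(fits) < 2 * n_per_group:
        raise ValueError("too few cell lines for the requested group size")
    rows = []
    for name in sorted(fits):
        f = fits[name]
        rows.append((name, f.ic50_molar if f.ic50_defined else np.nan))
    df = pd.DataFrame(rows, columns=["cell_line", "ic50_molar"])
    # undefined IC50 sorts above every finite value (most resistant)
    df["sort_key"] = df["ic50_molar"].fillna(np.inf)
    df = df.sort_values(["sort_key", "cell_line"], ascending=[False, True]).reset_index(
        drop=True
    )
    labels = np.array(["unclassified"] * len(df), dtype=object)
    undefined = df["ic50_molar"].isna().to_numpy()
    finite_rank = np.cumsum(~undefined)  # 1-based rank among finite, high->low
    labels[undefined] = "resistant"
    labels[(~undefined) & (finite_rank <= n_per_group)] = "resistant"
    sens_order = df.sort_values(["sort_key", "cell_line"], ascending=[True, True]).index
    sens_idx = [i for i in sens_order if not undefined[i]][:n_per_group]
    labels[sens_idx] = "sensitive"
    df["label"] = labels
    for name, lab in zip(df["cell_line"], df["label"]):
        fits[name].label = lab
    return df.drop(columns="sort_key")
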