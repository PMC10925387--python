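"""Monte-Carlo bias/variance characterization of estimators against the CRB.

Each evaluated test point yields sample bias and *uncorrected* sample
variance (divide-by-n, matching the training loss convention) per parameter,
alongside the CRB at the realized noise level, the normalized bias/std, the
CRB-weighted squared bias ``bias^2 / b`` and the variance ratio ``var / b``.
An exactly efficient estimator has bias -> 0 and variance ratio -> 1.

Seed ladder: every test point derives its noise stream from
``(master_seed, point_index)``, so adding test points never perturbs the
noise seen by existing ones.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "monte_carlo_eval",
    "sweep_parameter_axis",
    "snr_sweep",
    "population_histograms",
    "compare_estimators",
]

Estimator = Callable[[np.ndarray], np.ndarray]  # (n, r) complex -> (n, Np)

_PARAM_NAMES = ("t1", "t2")


def monte_carlo_eval(
    estimator: Estimator,
    theta_true: np.ndarray,
    y0: np.ndarray,
    crb: np.ndarray,
    snr: float,
    n_real: int,
    seed: int = 0,
    point_index: int = 0,
    m0_scale: float = 1.0,
) -> pd.DataFrame:
    """Bias/variance of one estimator at one test point.

    ``y0`` is the noiseless compressed measurement at unit m0, ``crb`` the
    per-parameter bounds at sigma = m0_scale/snr.  Draws ``n_real``
    independent complex Gaussian corruptions, estimates, and reports one row
    per parameter.  Estimator failures (non-finite rows) are excluded and
    counted.
    """
    if n_real < 2:
        raise ValueError("n_real must be >= 2")
    theta_true = np.asarray(theta_true, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(point_index)]))
    sigma = m0_scale / snr
    y = y0[None, :] + sigma * (
        rng.normal(size=(n_real, y0.size)) + 1j * rng.normal(size=(n_real, y0.size))
    )
    est = np.asarray(estimator(y), dtype=float)
    ok = np.isfinite(est).all(axis=1)
    n_failed = int((~ok).sum())
    est = est[ok]
    mu = est.mean(axis=0)
    var = ((est - mu) ** 2).mean(axis=0)  # uncorrected
    bias = mu - theta_true
    rows = []
    for k, name in enumerate(_PARAM_NAMES[: theta_true.size]):
        rows.append({
            "parameter": name,
            "theta_true": theta_true[k],
            "bias": bias[k],
            "variance": var[k],
            "crb": crb[k],
            "normalized_bias": bias[k] / theta_true[k],
            "normalized_std": np.sqrt(var[k]) / theta_true[k],
            "crb_weighted_sq_bias": bias[k] ** 2 / crb[k],
            "variance_ratio": var[k] / crb[k],
            "snr": snr,
            "n_realizations": int(ok.sum()),
            "n_failed": n_failed,
            "point_index": point_index,
            "seed": seed,
        })
    return pd.DataFrame(rows)


def sweep_parameter_axis(
    estimator: Estimator,
    simulate_point: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]],
    base_theta: np.ndarray,
    axis: int,
    values: np.ndarray,
    snr: float,
    n_real: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Vary one parameter, holding the rest fixed (one MC eval per value).

    ``simulate_point(theta)`` must return ``(y0, crb_at_sigma)`` for the
    requested tissue at sigma = 1/snr.  Rows share the seed ladder keyed by
    the position along the sweep.
    """
    tables = []
    for i, v in enumerate(np.asarray(values, dtype=float)):
        theta = np.array(base_theta, dtype=float)
        theta[axis] = v
        y0, crb = simulate_point(theta)
        tab = monte_carlo_eval(estimator, theta, y0, crb, snr, n_real, seed=seed, point_index=i)
        tab["swept_value"] = v
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)


def snr_sweep(
    estimator: Estimator,
    theta: np.ndarray,
    y0: np.ndarray,
    crb_ref: np.ndarray,
    snr_values: np.ndarray,
    n_real: int,
    seed: int = 0,
    m0_scale: float = 1.0,
) -> pd.DataFrame:
    """Bias/std versus SNR at a fixed tissue, with the efficient reference.

    ``crb_ref`` holds the bounds at sigma = 1; per SNR they rescale as
    sigma^2.  The returned table includes ``crb_reference_std`` =
    sqrt(b)/theta, the normalized std of a hypothetical efficient estimator
    (zero bias, variance equal to the CRB), which falls off exactly as 1/SNR.
    """
    theta = np.asarray(theta, dtype=float)
    tables = []
    for i, snr in enumerate(np.asarray(snr_values, dtype=float)):
        sigma = m0_scale / snr
        crb = np.asarray(crb_ref) * sigma**2
        tab = monte_carlo_eval(
            estimator, theta, y0, crb, snr, n_real, seed=seed, point_index=i, m0_scale=m0_scale
        )
        tab["crb_reference_std"] = np.sqrt(crb[: theta.size]) / theta
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)


def population_histograms(
    report: pd.DataFrame,
    delta: float = 1.0,
    n_bins: int = 30,
    log_range: tuple[float, float] = (-8.0, 2.0),
) -> dict:
    """Histogram tables and summary statistics over a test-set report.

    Bins are log-spaced (edges recorded in the output).  Summaries per
    parameter: median CRB-weighted squared bias, median variance ratio, and
    the fraction of test points with variance <= delta * CRB.
    """
    edges = np.logspace(*log_range, n_bins + 1)
    out: dict = {"bin_edges": edges, "histograms": {}, "summary": {}}
    for name, grp in report.groupby("parameter"):
        hb, _ = np.histogram(grp["crb_weighted_sq_bias"], bins=edges)
        hv, _ = np.histogram(grp["variance_ratio"], bins=edges)
        out["histograms"][name] = {"crb_weighted_sq_bias": hb, "variance_ratio": hv}
        out["summary"][name] = {
            "median_crb_weighted_sq_bias": float(grp["crb_weighted_sq_bias"].median()),
            "median_variance_ratio": float(grp["variance_ratio"].median()),
            "fraction_var_at_most_delta_crb": float((grp["variance_ratio"] <= delta).mean()),
            "n_points": int(len(grp)),
        }
    return out


def compare_estimators(report_a: pd.DataFrame, report_b: pd.DataFrame) -> dict:
    """Paired statistical comparison of two estimators on the same test set.

    Wilcoxon signed-rank on the paired CRB-weighted squared-bias vectors per
    parameter (does estimator A have systematically different bias than B?),
    plus Welch's t-test on the raw bias values per shared sweep point when a
    ``swept_value`` column is present.
    """
    out: dict = {"wilcoxon": {}, "welch": {}}
    for name in sorted(set(report_a["parameter"]) & set(report_b["parameter"])):
        a = report_a[report_a["parameter"] == name].sort_values("point_index")
        b = report_b[report_b["parameter"] == name].sort_values("point_index")
        if len(a) < 2 or len(a) != len(b):
            raise ValueError("need >= 2 paired points per parameter")
        xa = a["crb_weighted_sq_bias"].to_numpy()
        xb = b["crb_weighted_sq_bias"].to_numpy()
        if np.allclose(xa, xb):
            stat, p = np.nan, 1.0  # identical estimators: no detectable difference
        else:
            stat, p = scipy.stats.wilcoxon(xa, xb)
        out["wilcoxon"][name] = {"statistic": float(stat), "p_value": float(p)}
        if "swept_value" in a.columns and "swept_value" in b.columns:
            welch = scipy.stats.ttest_ind(
                a["bias"].to_numpy(), b["bias"].to_numpy(), equal_var=False
            )
            out["welch"][name] = {"statistic": float(welch.statistic), "p_value": float(welch.pvalue)}
    return out
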