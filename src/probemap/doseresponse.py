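"""Concentration–response statistics for receptor-activity validation.

Four-parameter logistic (4PL) fits of ΔEbBRET-style readouts,

    y = basal + (emax - basal) / (1 + 10^((log_ec50 - x) * hill)),

with x = log10 molar concentration, the basal fixed to zero by default, and
unweighted least squares.  Condition comparisons (e.g. with/without an
allosteric modulator, wild-type vs mutant) use the extra-sum-of-squares F
test between independent fits and a global fit sharing one parameter.
Responses can be normalized to percent of the vehicle-condition maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["DoseResponseFit", "fit_4pl", "fit_4pl_shared", "ess_f_test",
           "normalize_percent_vehicle_max", "logistic4"]


def logistic4(x: np.ndarray, emax: float, log_ec50: float, hill: float,
              basal: float = 0.0) -> np.ndarray:
    """4PL response at log10 concentration x."""
    return basal + (emax - basal) / (1.0 + 10.0 ** ((log_ec50 - x) * hill))


@dataclass
class DoseResponseFit:
    """Result of a 4PL least-squares fit."""

    emax: float
    log_ec50: float
    hill: float
    basal: float
    se: dict = field(default_factory=dict)
    ss: float = 0.0
    df: int = 0
    n_points: int = 0
    converged: bool = True
    ill_conditioned: bool = False

    @property
    def parameters(self) -> dict:
        return {"emax": self.emax, "log_ec50": self.log_ec50,
                "hill": self.hill, "basal": self.basal}

    def predict(self, x: np.ndarray) -> np.ndarray:
        return logistic4(np.asarray(x, float), self.emax, self.log_ec50,
                         self.hill, self.basal)


def _check_dataset(x: np.ndarray, y: np.ndarray) -> None:
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("concentrations and responses must be finite")
    if len(np.unique(x)) < 4:
        raise ValueError("at least 4 distinct concentrations are required")


def _grid_start(x: np.ndarray, y: np.ndarray, fix_basal: bool):
    """Multistart grid: log_ec50 over the observed range, hill in
    {±0.5, ±1, ±2}; emax solved linearly at each grid point (basal = 0)."""
    best = None
    for lec in np.linspace(x.min(), x.max(), 7):
        for hill in (0.5, 1.0, 2.0, -0.5, -1.0, -2.0):
            g = 1.0 / (1.0 + 10.0 ** ((lec - x) * hill))
            denom = float(g @ g)
            emax = float(g @ y) / denom if denom > 1e-12 else 0.0
            ss = float(((y - emax * g) ** 2).sum())
            if best is None or ss < best[0] - 1e-15:
                best = (ss, emax, lec, hill)
    _, emax, lec, hill = best
    return (emax, lec, hill) if fix_basal else (emax, lec, hill, 0.0)


def fit_4pl(dataset: pd.DataFrame | None = None,
            *,
            x: np.ndarray | None = None,
            y: np.ndarray | None = None,
            fix_basal: bool = True,
            max_starts: int = 5) -> DoseResponseFit:
    """Fit the 4PL model by unweighted least squares.

    ``dataset`` is a long-format DataFrame with columns ``log10_conc`` and
    ``response`` (replicates as repeated rows), or pass ``x``/``y`` arrays
    directly.  The basal is fixed at zero unless ``fix_basal=False``.
    Initialization is a deterministic grid multistart (best residual sum of
    squares wins); standard errors come from the Jacobian at the optimum.
    A fit is flagged ``ill_conditioned`` when the parameter covariance is
    not resolvable (e.g. flat data).
    """
    if dataset is not None:
        x = dataset["log10_conc"].to_numpy(float)
        y = dataset["response"].to_numpy(float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    _check_dataset(x, y)

    p0 = np.asarray(_grid_start(x, y, fix_basal), float)
    names = ["emax", "log_ec50", "hill"] + ([] if fix_basal else ["basal"])

    def resid(p):
        basal = 0.0 if fix_basal else p[3]
        return logistic4(x, p[0], p[1], p[2], basal) - y

    sol = optimize.least_squares(resid, p0, method="lm", max_nfev=2000)
    # a couple of perturbed restarts if the first solve stalled
    tries = 1
    while not sol.success and tries < max_starts:
        jitter = p0 * (1 + 0.1 * tries) + 0.1 * tries
        alt = optimize.least_squares(resid, jitter, method="lm", max_nfev=2000)
        if alt.cost < sol.cost:
            sol = alt
        tries += 1

    p = sol.x
    ss = float(2 * sol.cost)
    n_free = len(p)
    df = len(y) - n_free
    se: dict[str, float] = {}
    ill = False
    try:
        jtj = sol.jac.T @ sol.jac
        cond = np.linalg.cond(jtj)
        if not np.isfinite(cond) or cond > 1e10:
            ill = True
        cov = np.linalg.pinv(jtj) * (ss / df if df > 0 else np.nan)
        se = {nm: float(np.sqrt(max(cov[i, i], 0.0)))
              for i, nm in enumerate(names)}
    except np.linalg.LinAlgError:
        ill = True
    return DoseResponseFit(
        emax=float(p[0]), log_ec50=float(p[1]), hill=float(p[2]),
        basal=0.0 if fix_basal else float(p[3]), se=se, ss=ss, df=df,
        n_points=len(y), converged=bool(sol.success), ill_conditioned=ill)


def fit_4pl_shared(datasets: Sequence[pd.DataFrame],
                   share: str,
                   fix_basal: bool = True) -> DoseResponseFit:
    """Global 4PL fit of several conditions sharing one parameter.

    ``share`` is ``"emax"``, ``"log_ec50"`` or ``"hill"``; the other
    parameters are fitted per condition.  Returns a fit whose ``ss``/``df``
    cover the pooled data (parameter attributes hold condition-0 values plus
    the shared one).
    """
    if share not in ("emax", "log_ec50", "hill"):
        raise ValueError(f"cannot share parameter {share!r}")
    xs, ys = [], []
    for ds in datasets:
        x = ds["log10_conc"].to_numpy(float)
        y = ds["response"].to_numpy(float)
        _check_dataset(x, y)
        xs.append(x)
        ys.append(y)
    k = len(datasets)
    order = ["emax", "log_ec50", "hill"]
    s_i = order.index(share)
    free = [o for o in order if o != share]

    starts = [np.asarray(_grid_start(x, y, True), float) for x, y in zip(xs, ys)]
    shared0 = float(np.mean([s[s_i] for s in starts]))
    p0 = np.concatenate([[shared0]]
                        + [[s[j] for j in range(3) if j != s_i] for s in starts])

    def unpack(p, c):
        vals = {share: p[0]}
        vals[free[0]] = p[1 + 2 * c]
        vals[free[1]] = p[2 + 2 * c]
        return vals["emax"], vals["log_ec50"], vals["hill"]

    def resid(p):
        return np.concatenate([
            logistic4(xs[c], *unpack(p, c)) - ys[c] for c in range(k)])

    sol = optimize.least_squares(resid, p0, method="lm", max_nfev=5000)
    ss = float(2 * sol.cost)
    n = sum(len(y) for y in ys)
    df = n - len(p0)
    emax, lec, hill = unpack(sol.x, 0)
    fit = DoseResponseFit(emax=emax, log_ec50=lec, hill=hill, basal=0.0,
                          ss=ss, df=df, n_points=n,
                          converged=bool(sol.success))
    fit.se["shared_" + share] = float("nan")
    return fit


def ess_f_test(fits_independent: Sequence[DoseResponseFit],
               fit_shared: DoseResponseFit,
               tol: float = 1e-8) -> tuple[float, float, tuple[int, int]]:
    """Extra-sum-of-squares F test of shared vs independent fits.

    F = ((SS_shared − SS_indep) / (df_shared − df_indep)) / (SS_indep / df_indep),
    with p from the F distribution on (df_shared − df_indep, df_indep)
    degrees of freedom.  Returns ``(F, p, (df_num, df_den))``.
    """
    ss_indep = float(sum(f.ss for f in fits_independent))
    df_indep = int(sum(f.df for f in fits_independent))
    ss_shared = float(fit_shared.ss)
    df_shared = int(fit_shared.df)
    df_num = df_shared - df_indep
    if df_num <= 0:
        raise ValueError(
            f"shared model must have more residual df than the independent "
            f"fits (got {df_shared} vs {df_indep}); models are not nested")
    if df_indep <= 0:
        raise ValueError("independent fits have no residual degrees of freedom")
    if ss_shared < ss_indep - tol * max(1.0, ss_indep):
        raise ValueError(
            f"shared-model SS ({ss_shared:.6g}) is below the independent SS "
            f"({ss_indep:.6g}); an optimizer failed to converge")
    f_stat = max(0.0, (ss_shared - ss_indep) / df_num) / (ss_indep / df_indep)
    p = float(stats.f.sf(f_stat, df_num, df_indep))
    return float(f_stat), p, (df_num, df_indep)


def normalize_percent_vehicle_max(dataset: pd.DataFrame,
                                  reference_condition: str,
                                  condition_col: str = "condition") -> pd.DataFrame:
    """Express responses as % of the reference (vehicle/no-modulator)
    condition's maximum observed response.

    The maximum of ``reference_condition`` maps to 100%.  Raises if the
    reference condition is absent or its maximum is not positive.
    """
    if condition_col not in dataset.columns:
        raise ValueError(f"dataset has no {condition_col!r} column")
    ref = dataset[dataset[condition_col] == reference_condition]
    if ref.empty:
        raise ValueError(
            f"reference condition {reference_condition!r} not in dataset")
    ref_max = float(ref["response"].max())
    if ref_max <= 0:
        raise ValueError(
            f"reference-condition maximum is {ref_max}; cannot normalize")
    out = dataset.copy()
    out["response"] = out["response"] / ref_max * 100.0
    return out
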