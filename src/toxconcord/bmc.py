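"""Simplified benchmark-concentration (BMC) modeling of dose-response data.

Stages mirror a standard transcriptomic BMC workflow: (1) a Williams-type
monotone trend prefilter (permutation p-values, both directions, unadjusted
p < 0.05); (2) a nine-model least-squares suite (linear, power, hill, 2nd-
and 3rd-degree polynomial, exponential 2-5) under constant variance with a
benchmark response of 1 residual SD; (3) range and confidence-interval
filters on the winning model's BMC; (4) pathway functional classification by
two-tailed Fisher's exact test with per-set median BMCs.

The Williams statistic uses the isotonic (pool-adjacent-violators)
amalgamated mean of the top dose group, which for the last ordered group
equals the extremal weighted suffix mean of the dose-group means — computed
directly, and vectorized over label permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InvalidInputError

TREND_ALPHA = 0.05
FIT_P_MIN = 0.1
FISHER_TWO_TAIL = 0.1
MODEL_ORDER = (
    "linear", "power", "hill", "poly2", "poly3", "exp2", "exp3", "exp4", "exp5",
)


# --------------------------------------------------------------------------
# Williams trend prefilter
# --------------------------------------------------------------------------

def _williams_stats(values: np.ndarray, member: np.ndarray, n_per_group: np.ndarray) -> np.ndarray:
    """Williams-type statistic for each row of ``values``.

    ``member`` is (n_samples, n_groups) 0/1 with group 0 = control and dose
    groups in ascending concentration order. Returns max of the increasing-
    and decreasing-direction statistics per row.
    """
    means = (values @ member) / n_per_group  # (rows, G)
    ss = (values**2) @ member
    within = ss - n_per_group * means**2
    n = values.shape[1]
    G = member.shape[1]
    s2 = within.sum(axis=1) / max(n - G, 1)
    s2 = np.maximum(s2, 1e-300)
    se = np.sqrt(s2 * (1.0 / n_per_group[-1] + 1.0 / n_per_group[0]))

    dose_means = means[:, 1:]
    dose_n = n_per_group[1:]
    # weighted suffix means: A_u = sum_{j>=u} n_j m_j / sum_{j>=u} n_j
    wsum = np.cumsum((dose_means * dose_n)[:, ::-1], axis=1)
    wn = np.cumsum(dose_n[::-1])
    suffix = wsum / wn  # [:, u] = mean of last (u+1) dose groups
    m_inc = suffix.max(axis=1)  # isotonic fit at top dose, increasing order
    m_dec = suffix.min(axis=1)
    t_inc = (m_inc - means[:, 0]) / se
    t_dec = (means[:, 0] - m_dec) / se
    return np.maximum(t_inc, t_dec)


def williams_trend_filter(
    expression: pd.DataFrame,
    concentrations: pd.Series,
    alpha: float = TREND_ALPHA,
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[list[str], pd.Series]:
    """Permutation Williams trend test per gene; returns (kept genes, p-values).

    ``expression`` is genes x samples, ``concentrations`` per-sample doses
    (control = smallest, usually 0). Requires >=3 dose groups plus control
    with >=2 replicates each. All-constant genes get p = 1 by convention.
    """
    conc = concentrations.reindex(expression.columns).to_numpy(dtype=float)
    levels = np.unique(conc)
    if len(levels) < 4:
        raise InvalidInputError(">=3 concentration groups plus control required")
    member = (conc[:, None] == levels[None, :]).astype(float)
    n_per_group = member.sum(axis=0)
    if (n_per_group < 2).any():
        raise InvalidInputError(">=2 replicates per group required")

    rng = np.random.default_rng(seed)
    X = expression.to_numpy(dtype=float)
    t_obs = _williams_stats(X, member, n_per_group)

    pvals = np.ones(len(X))
    n = X.shape[1]
    for i in range(len(X)):
        y = X[i]
        if np.ptp(y) == 0.0:
            pvals[i] = 1.0
            continue
        perms = rng.permuted(np.broadcast_to(np.arange(n), (n_perm, n)), axis=1)
        t_perm = _williams_stats(y[perms], member, n_per_group)
        pvals[i] = (1.0 + np.sum(t_perm >= t_obs[i] - 1e-12)) / (1.0 + n_perm)

    pser = pd.Series(pvals, index=expression.index, name="trend_p")
    kept = pser.index[pser < alpha].tolist()
    return kept, pser


# --------------------------------------------------------------------------
# Dose-response model suite
# --------------------------------------------------------------------------

def _m_linear(x, a, b):
    return a + b * x


def _m_power(x, a, b, g):
    return a + b * np.power(x, g)


def _m_hill(x, a, b, g, k):
    xg = np.power(x, g)
    return a + b * xg / (np.power(k, g) + xg)


def _m_poly2(x, a, b1, b2):
    return a + b1 * x + b2 * x**2


def _m_poly3(x, a, b1, b2, b3):
    return a + b1 * x + b2 * x**2 + b3 * x**3


def _m_exp2(x, a, b):
    return a * np.exp(b * x)


def _m_exp3(x, a, b, d):
    return a * np.exp(np.sign(b) * np.power(np.abs(b) * x, d))


def _m_exp4(x, a, b, c):
    return a * (c - (c - 1.0) * np.exp(-b * x))


def _m_exp5(x, a, b, c, d):
    return a * (c - (c - 1.0) * np.exp(-np.power(b * x, d)))


def _p0(name: str, x: np.ndarray, y: np.ndarray) -> tuple[list[float], tuple]:
    """Initial parameters and bounds per model, from crude data features."""
    y0 = float(np.mean(y[x == x.min()]))
    yspan = float(y.max() - y.min()) or 1.0
    xmid = float(np.median(np.unique(x[x > 0]))) if (x > 0).any() else 1.0
    xmax = float(x.max()) or 1.0
    slope = (float(np.mean(y[x == x.max()])) - y0) / xmax
    inf = np.inf
    a0 = y0 if abs(y0) > 1e-8 else (1e-8 if y0 >= 0 else -1e-8)
    if name == "linear":
        return [y0, slope], ([-inf, -inf], [inf, inf])
    if name == "power":
        return [y0, slope, 1.0], ([-inf, -inf, 0.1], [inf, inf, 8.0])
    if name == "hill":
        sgn = 1.0 if slope >= 0 else -1.0
        return [y0, sgn * yspan, 2.0, xmid], (
            [-inf, -inf, 0.5, 1e-9 * xmax], [inf, inf, 18.0, 100.0 * xmax]
        )
    if name == "poly2":
        return [y0, slope, 0.0], ([-inf] * 3, [inf] * 3)
    if name == "poly3":
        return [y0, slope, 0.0, 0.0], ([-inf] * 4, [inf] * 4)
    if name == "exp2":
        b = slope / a0
        return [a0, b], ([-inf, -inf], [inf, inf])
    if name == "exp3":
        b = slope / a0 if a0 != 0 else 0.0
        return [a0, b, 1.0], ([-inf, -inf, 0.1], [inf, inf, 8.0])
    if name == "exp4":
        c = 1.0 + slope * xmax / a0
        return [a0, 1.0 / xmid, c], ([-inf, 1e-12 / xmax, -inf], [inf, inf, inf])
    if name == "exp5":
        c = 1.0 + slope * xmax / a0
        return [a0, 1.0 / xmid, c, 1.0], (
            [-inf, 1e-12 / xmax, -inf, 0.1], [inf, inf, inf, 8.0]
        )
    raise InvalidInputError(f"unknown model {name}")


MODELS = {
    "linear": _m_linear,
    "power": _m_power,
    "hill": _m_hill,
    "poly2": _m_poly2,
    "poly3": _m_poly3,
    "exp2": _m_exp2,
    "exp3": _m_exp3,
    "exp4": _m_exp4,
    "exp5": _m_exp5,
}


@dataclass
class BmcFit:
    """One model's fit for one gene."""

    gene: str
    model: str
    params: tuple[float, ...] = ()
    converged: bool = False
    rss: float = float("inf")
    aic: float = float("inf")
    fit_p: float = float("nan")
    bmc: float = float("nan")
    bmcl: float = float("nan")
    bmcu: float = float("nan")
    winning: bool = False
    filter_status: str = ""
    extras: dict = field(default_factory=dict)


def _lack_of_fit_p(x, y, yhat, n_params) -> float:
    """Chi-square lack-of-fit p versus the saturated group-means model."""
    levels, inv = np.unique(x, return_inverse=True)
    gm = np.bincount(inv, weights=y) / np.bincount(inv)
    rss_sat = float(np.sum((y - gm[inv]) ** 2))
    rss_mod = float(np.sum((y - yhat) ** 2))
    df = len(levels) - n_params
    if df <= 0:
        return 1.0
    if rss_sat <= 1e-300:
        return 1.0 if rss_mod <= 1e-12 else 0.0
    sigma2 = rss_sat / max(len(y) - len(levels), 1)
    x2 = max(rss_mod - rss_sat, 0.0) / sigma2
    return float(stats.chi2.sf(x2, df))


def _solve_bmc(f, theta, xmax: float, delta: float) -> float:
    """Smallest x > 0 with |f(x) - f(0)| = delta, searched up to 100*xmax."""
    if delta <= 0:
        return float("nan")
    grid = np.concatenate([
        [0.0],
        np.linspace(0.0, xmax, 1001)[1:],
        np.geomspace(xmax, 100.0 * xmax, 200)[1:],
    ])
    with np.errstate(all="ignore"):
        gv = np.abs(f(grid, *theta) - f(np.asarray([0.0]), *theta)[0]) - delta
    if not np.all(np.isfinite(gv)):
        return float("nan")
    hits = np.nonzero(gv >= 0.0)[0]
    if len(hits) == 0 or hits[0] == 0:
        return float("nan")
    i = hits[0]
    if gv[i] == 0.0:
        return float(grid[i])

    def g(xv):
        return abs(f(np.asarray([xv]), *theta)[0] - f(np.asarray([0.0]), *theta)[0]) - delta

    return float(optimize.brentq(g, grid[i - 1], grid[i], xtol=1e-14, rtol=1e-14))


def _profile_bounds(
    f, x, y, theta, bmc_hat, delta, level: float = 0.95, n_grid: int = 17
) -> tuple[float, float]:
    """Profile-likelihood BMC bounds by penalized refits on a log grid.

    Accepts candidate b while n*ln(RSS_b / RSS_min) <= chi2_1(level), walking
    outward from the point estimate; sigma is profiled out analytically.
    """
    n = len(y)
    rss0 = float(np.sum((y - f(x, *theta)) ** 2))
    if rss0 <= 1e-300 or not np.isfinite(bmc_hat):
        return bmc_hat, bmc_hat
    thresh = stats.chi2.ppf(level, 1)
    xmax = float(np.max(x))

    def rss_at(b: float) -> float:
        logb = np.log(b)

        def obj(th):
            r = float(np.sum((y - f(x, *th)) ** 2))
            bm = _solve_bmc(f, th, xmax, delta)
            if not np.isfinite(bm) or bm <= 0:
                return r + 1e6 * rss0
            return r + 1e4 * rss0 * (np.log(bm) - logb) ** 2

        res = optimize.minimize(obj, theta, method="Nelder-Mead",
                                options=dict(maxiter=400, fatol=1e-12))
        bm = _solve_bmc(f, res.x, xmax, delta)
        if not np.isfinite(bm):
            return float("inf")
        return float(np.sum((y - f(x, *res.x)) ** 2))

    lo = hi = bmc_hat
    for b in bmc_hat * 10.0 ** (-np.linspace(0.25, 2.0, n_grid // 2)):
        if n * np.log(max(rss_at(b), rss0) / rss0) > thresh:
            break
        lo = b
    for b in bmc_hat * 10.0 ** (np.linspace(0.25, 2.0, n_grid // 2)):
        if n * np.log(max(rss_at(b), rss0) / rss0) > thresh:
            break
        hi = b
    return float(lo), float(hi)


def fit_models(
    y: np.ndarray | pd.Series,
    x: np.ndarray | pd.Series,
    gene: str = "",
    bmr: float = 1.0,
    sd: float | None = None,
    models: tuple[str, ...] = MODEL_ORDER,
    compute_ci: bool = True,
) -> list[BmcFit]:
    """Fit the model suite to one gene and locate each model's BMC.

    ``sd`` overrides the residual SD used for the benchmark response
    (delta = bmr * sd); by default each model's own residual SD
    sqrt(RSS/(n-p)) is used (constant-variance assumption). The winning
    model (lowest AIC among converged fits) gets profile-likelihood BMCL/
    BMCU bounds when ``compute_ci``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    fits: list[BmcFit] = []
    for name in models:
        f = MODELS[name]
        p0, bounds = _p0(name, x, y)
        fit = BmcFit(gene=gene, model=name)
        try:
            with np.errstate(all="ignore"):
                theta, _ = optimize.curve_fit(
                    f, x, y, p0=p0, bounds=bounds, maxfev=5000
                )
            yhat = f(x, *theta)
            if not np.all(np.isfinite(yhat)):
                raise RuntimeError("non-finite prediction")
            fit.params = tuple(float(t) for t in theta)
            fit.converged = True
            fit.rss = float(np.sum((y - yhat) ** 2))
            k = len(theta)
            fit.aic = n * np.log(max(fit.rss, 1e-300) / n) + 2 * (k + 1)
            fit.fit_p = _lack_of_fit_p(x, y, yhat, k)
            sigma = sd if sd is not None else np.sqrt(fit.rss / max(n - k, 1))
            fit.extras["sigma"] = float(sigma)
            fit.bmc = _solve_bmc(f, theta, float(x.max()), bmr * sigma)
        except (RuntimeError, ValueError):
            fit.converged = False
        fits.append(fit)

    converged = [ft for ft in fits if ft.converged]
    if converged:
        winner = min(converged, key=lambda ft: (ft.aic, MODEL_ORDER.index(ft.model)))
        winner.winning = True
        if compute_ci and np.isfinite(winner.bmc):
            sigma = winner.extras["sigma"]
            winner.bmcl, winner.bmcu = _profile_bounds(
                MODELS[winner.model], x, y, np.asarray(winner.params),
                winner.bmc, bmr * sigma,
            )
    else:
        for ft in fits:
            ft.filter_status = "poor_fit"
    return fits


def filter_bmc(
    fits: list[BmcFit],
    concentrations: np.ndarray | list[float],
    fit_p_min: float = FIT_P_MIN,
    apply_ci_rules: bool = True,
) -> list[BmcFit]:
    """Assign filter status to winning fits per the range/CI/fit rules.

    Status precedence: poor_fit (fit p < 0.1) > below_range (BMC more than
    10-fold below the lowest tested concentration) > above_range (BMC above
    the highest, or no finite BMC) > wide_ci (BMC/BMCL > 20, BMCU/BMC > 20
    or BMCU/BMCL > 40; only when ``apply_ci_rules``) > pass.
    """
    conc = np.asarray(concentrations, dtype=float)
    lowest = conc[conc > 0].min()
    highest = conc.max()
    winners = [ft for ft in fits if ft.winning]
    for ft in winners:
        if np.isfinite(ft.fit_p) and ft.fit_p < fit_p_min:
            ft.filter_status = "poor_fit"
        elif np.isfinite(ft.bmc) and ft.bmc < lowest / 10.0:
            ft.filter_status = "below_range"
        elif not np.isfinite(ft.bmc) or ft.bmc > highest:
            ft.filter_status = "above_range"
        elif apply_ci_rules and _wide_ci(ft):
            ft.filter_status = "wide_ci"
        else:
            ft.filter_status = "pass"
    return winners


def _wide_ci(ft: BmcFit) -> bool:
    if not (np.isfinite(ft.bmcl) and np.isfinite(ft.bmcu)):
        return True
    if ft.bmcl <= 0:
        return True
    return (
        ft.bmc / ft.bmcl > 20.0
        or ft.bmcu / ft.bmc > 20.0
        or ft.bmcu / ft.bmcl > 40.0
    )


def pathway_classification(
    passing: list[BmcFit],
    gene_sets: dict[str, list[str]],
    universe: list[str],
    p_max: float = FISHER_TWO_TAIL,
) -> pd.DataFrame:
    """Two-tailed Fisher's exact per set over passing genes; median BMCs.

    Sets with p < ``p_max`` and >=1 passing gene are reported with the
    median BMC over their passing genes.
    """
    uni = set(universe)
    pass_genes = {ft.gene for ft in passing if ft.filter_status == "pass"} & uni
    bmc_of = {ft.gene: ft.bmc for ft in passing}
    N = len(uni)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & uni
        in_pass = members & pass_genes
        if not in_pass:
            continue
        a = len(in_pass)
        b = len(pass_genes) - a
        c = len(members) - a
        d = N - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if p < p_max:
            rows.append(
                dict(
                    set_name=name,
                    n_genes_passing=a,
                    fisher_two_tail_p=float(p),
                    median_bmc=float(np.median([bmc_of[g] for g in sorted(in_pass)])),
                )
            )
    return pd.DataFrame(rows, columns=["set_name", "n_genes_passing", "fisher_two_tail_p", "median_bmc"])


def accumulation_table(pathway_bmcs: pd.DataFrame) -> pd.DataFrame:
    """Sorted median BMCs with cumulative rank (accumulation-plot data)."""
    out = pathway_bmcs.sort_values("median_bmc").reset_index(drop=True)
    out["cumulative_rank"] = np.arange(1, len(out) + 1)
    return out
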