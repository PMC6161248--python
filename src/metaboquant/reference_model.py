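"""Hierarchical log-normal estimation of population reference medians.

Pooled-serum QC concentrations accumulated across years come from a handful
of serum *lots*; lot-to-lot differences inflate the spread of the raw values
and must not leak into a population reference interval.  The model is a
one-way random-effects model on the log scale, per metabolite:

    log(y_ij) = mu + b_j + e_ij,   b_j ~ N(0, s_lot^2),   e_ij ~ N(0, s^2)

with a flat prior on mu and inverse-gamma(0.001, 0.001) priors on both
variances.  The posterior is sampled by a blocked Gibbs scheme: mu is drawn
from its marginal conditional given only the variances (the lot effects are
integrated out analytically — lot means are then independent
N(mu, s_lot^2 + s^2/n_j)), after which the lot effects and the two
variances are drawn from their standard conditionals.  This collocated
blocking mixes fast where the naive mu | b alternation crawls.

The population median is exp(mu); it is summarised by the median of the
exp(mu) posterior draws and a central 95% credibility interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import Panel
from .qc_monitor import QCHistory

DEFAULT_DRAWS = 20_000
DEFAULT_BURN_IN = 5_000
PRIOR_SHAPE = 0.001
PRIOR_SCALE = 0.001


@dataclass
class MetaboliteFit:
    """Posterior summary for one metabolite."""

    hmdb_id: str
    posterior_median: float
    cri_lower: float
    cri_upper: float
    lot_effects: dict[str, float]  # multiplicative deviations exp(E[b_j])
    sigma_lot: float  # posterior mean, log scale
    sigma_resid: float
    n_obs: int
    n_rejected: int
    mu_draws: np.ndarray
    lot_sum_mean: float  # posterior mean of sum(b_j); ~0 for balanced designs
    single_lot: bool = False


class ReferenceMedianResults:
    """Results container for :class:`ReferenceMedianModel`."""

    def __init__(self, fits: dict[str, MetaboliteFit], n_draws: int,
                 burn_in: int, seed: int) -> None:
        self.fits = fits
        self.n_draws = n_draws
        self.burn_in = burn_in
        self.seed = seed

    def __getitem__(self, hmdb_id: str) -> MetaboliteFit:
        return self.fits[hmdb_id]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "hmdb_id": f.hmdb_id,
                "median_umol_l": f.posterior_median,
                "ci_lower": f.cri_lower,
                "ci_upper": f.cri_upper,
                "sigma_lot": f.sigma_lot,
                "sigma_resid": f.sigma_resid,
                "n_obs": f.n_obs,
            }
            for f in self.fits.values()
        ]
        return pd.DataFrame(rows).set_index("hmdb_id")

    def summary(self) -> str:
        lines = [
            f"Hierarchical log-normal reference medians "
            f"({self.n_draws} draws after {self.burn_in} burn-in, seed {self.seed})",
            f"{'hmdb_id':<14}{'median':>12}{'2.5%':>12}{'97.5%':>12}"
            f"{'s_lot':>9}{'s_res':>9}{'n':>6}",
        ]
        for f in self.fits.values():
            lines.append(
                f"{f.hmdb_id:<14}{f.posterior_median:>12.4g}"
                f"{f.cri_lower:>12.4g}{f.cri_upper:>12.4g}"
                f"{f.sigma_lot:>9.3f}{f.sigma_resid:>9.3f}{f.n_obs:>6d}"
            )
        return "\n".join(lines)


class ReferenceMedianModel:
    """One-way random-effects model on log concentrations, per metabolite.

    Parameters
    ----------
    history : QCHistory
        Lot/batch-stamped QC concentrations.  Non-positive concentrations
        cannot be log-transformed; such rows are rejected and counted.
    """

    def __init__(self, history: QCHistory) -> None:
        self.history = history

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "ReferenceMedianModel":
        return cls(QCHistory(frame))

    def fit(
        self,
        n_draws: int = DEFAULT_DRAWS,
        burn_in: int = DEFAULT_BURN_IN,
        seed: int = 0,
        min_obs: int = 3,
        prior_shape: float = PRIOR_SHAPE,
        prior_scale: float = PRIOR_SCALE,
    ) -> ReferenceMedianResults:
        rng = np.random.default_rng(seed)
        fits: dict[str, MetaboliteFit] = {}
        for hmdb_id, sub in self.history.frame.groupby("hmdb_id", sort=True):
            conc = sub["conc_umol_l"].to_numpy(dtype=float)
            lots = sub["qc_lot"].to_numpy()
            keep = conc > 0
            n_rejected = int((~keep).sum())
            conc, lots = conc[keep], lots[keep]
            if len(conc) < min_obs:
                continue
            fit = _gibbs_one_metabolite(
                hmdb_id, np.log(conc), lots, n_draws, burn_in, rng,
                prior_shape, prior_scale,
            )
            fit.n_rejected = n_rejected
            fits[hmdb_id] = fit
        return ReferenceMedianResults(fits, n_draws, burn_in, seed)


def _gibbs_one_metabolite(
    hmdb_id: str,
    logy: np.ndarray,
    lots: np.ndarray,
    n_draws: int,
    burn_in: int,
    rng: np.random.Generator,
    prior_shape: float = PRIOR_SHAPE,
    prior_scale: float = PRIOR_SCALE,
) -> MetaboliteFit:
    lot_names, lot_idx = np.unique(lots, return_inverse=True)
    J = len(lot_names)
    N = len(logy)
    single_lot = J < 2
    if single_lot:
        import warnings

        warnings.warn(
            f"{hmdb_id}: single QC lot; falling back to a no-lot model",
            stacklevel=3,
        )

    # per-lot sufficient statistics
    n_j = np.bincount(lot_idx, minlength=J).astype(float)
    sum_j = np.bincount(lot_idx, weights=logy, minlength=J)
    ybar_j = sum_j / n_j
    ss_within = float(np.sum((logy - ybar_j[lot_idx]) ** 2))

    mu = float(np.mean(logy))
    b = np.zeros(J)
    var_resid = max(float(np.var(logy)), 1e-8)
    var_lot = max(float(np.var(ybar_j)), 1e-8) if not single_lot else 0.0

    total = burn_in + n_draws
    mu_draws = np.empty(n_draws)
    b_sums = np.empty(n_draws)
    b_means = np.zeros(J)
    var_lot_draws = np.empty(n_draws)
    var_resid_draws = np.empty(n_draws)

    for it in range(total):
        if single_lot:
            # plain normal model: mu | var from all observations
            post_var = var_resid / N
            mu = rng.normal(np.mean(logy), np.sqrt(post_var))
            resid_ss = float(np.sum((logy - mu) ** 2))
            var_resid = _draw_inv_gamma(rng, N, resid_ss, prior_shape, prior_scale)
            b[:] = 0.0
            var_lot = 0.0
        else:
            # mu | variances, y  (lot effects integrated out)
            v_j = var_lot + var_resid / n_j
            w = 1.0 / v_j
            mu_mean = float(np.sum(w * ybar_j) / np.sum(w))
            mu = rng.normal(mu_mean, np.sqrt(1.0 / np.sum(w)))
            # b_j | mu, variances, y
            prec = n_j / var_resid + 1.0 / var_lot
            b_mean = (n_j * (ybar_j - mu) / var_resid) / prec
            b = rng.normal(b_mean, np.sqrt(1.0 / prec))
            # variances
            var_lot = _draw_inv_gamma(
                rng, J, float(np.sum(b**2)), prior_shape, prior_scale
            )
            resid_ss = ss_within + float(
                np.sum(n_j * (ybar_j - mu - b) ** 2)
            )
            var_resid = _draw_inv_gamma(rng, N, resid_ss, prior_shape, prior_scale)

        if it >= burn_in:
            k = it - burn_in
            mu_draws[k] = mu
            b_sums[k] = float(np.sum(b))
            b_means += b
            var_lot_draws[k] = var_lot
            var_resid_draws[k] = var_resid

    b_means /= n_draws
    median_draws = np.exp(mu_draws)
    lo, med, hi = np.percentile(median_draws, [2.5, 50.0, 97.5])
    return MetaboliteFit(
        hmdb_id=hmdb_id,
        posterior_median=float(med),
        cri_lower=float(lo),
        cri_upper=float(hi),
        lot_effects={
            name: float(np.exp(b_means[j])) for j, name in enumerate(lot_names)
        },
        sigma_lot=float(np.sqrt(np.mean(var_lot_draws))),
        sigma_resid=float(np.sqrt(np.mean(var_resid_draws))),
        n_obs=N,
        n_rejected=0,
        mu_draws=mu_draws,
        lot_sum_mean=float(np.mean(b_sums)),
        single_lot=single_lot,
    )


def _draw_inv_gamma(
    rng: np.random.Generator,
    n: int,
    ss: float,
    prior_shape: float = PRIOR_SHAPE,
    prior_scale: float = PRIOR_SCALE,
) -> float:
    shape = prior_shape + n / 2.0
    scale = prior_scale + ss / 2.0
    return scale / rng.gamma(shape)


def fit_reference(
    history: QCHistory,
    n_draws: int = DEFAULT_DRAWS,
    burn_in: int = DEFAULT_BURN_IN,
    seed: int = 0,
) -> ReferenceMedianResults:
    """Functional shorthand for ``ReferenceMedianModel(history).fit(...)``."""
    return ReferenceMedianModel(history).fit(n_draws, burn_in, seed)


def reference_table(
    results: ReferenceMedianResults | pd.DataFrame, panel: Panel
) -> pd.DataFrame:
    """Class-grouped reference table: name, HMDB id, estimate, lower, upper.

    Accepts either fitted results or a pre-built frame (e.g. the packaged
    reference database) indexed by hmdb_id with columns
    ``median_umol_l, ci_lower, ci_upper``.  Row order follows the panel.
    """
    frame = results.to_frame() if isinstance(results, ReferenceMedianResults) else results
    rows = []
    for entry in panel.entries:
        if entry.hmdb_id not in frame.index:
            continue
        r = frame.loc[entry.hmdb_id]
        rows.append({
            "class": entry.class_name,
            "name": entry.name,
            "hmdb_id": entry.hmdb_id,
            "median_umol_l": float(r["median_umol_l"]),
            "ci_lower": float(r["ci_lower"]),
            "ci_upper": float(r["ci_upper"]),
        })
    return pd.DataFrame(
        rows,
        columns=["class", "name", "hmdb_id", "median_umol_l", "ci_lower", "ci_upper"],
    )


@dataclass
class PlatformComparison:
    r_squared: float
    slope: float
    intercept: float
    residuals: pd.Series
    n: int


def cross_platform_compare(
    values_a: pd.Series | dict[str, float],
    values_b: pd.Series | dict[str, float],
) -> PlatformComparison:
    """OLS agreement between two platforms' concentration tables.

    Matches on the intersection of metabolite ids, regresses platform B on
    platform A and reports R², slope, intercept and per-point residuals.
    Needs at least 3 matched metabolites.
    """
    import statsmodels.api as sm

    a = pd.Series(values_a, dtype=float)
    b = pd.Series(values_b, dtype=float)
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 matched metabolites, got {len(common)}"
        )
    x, y = a.loc[common], b.loc[common]
    model = sm.OLS(y.to_numpy(), sm.add_constant(x.to_numpy())).fit()
    intercept, slope = model.params
    return PlatformComparison(
        r_squared=float(model.rsquared),
        slope=float(slope),
        intercept=float(intercept),
        residuals=pd.Series(model.resid, index=common),
        n=len(common),
    )
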