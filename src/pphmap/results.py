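"""Posterior summaries: DIC model comparison, variance decomposition,
exceedance-probability surfaces, and convergence diagnostics."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .areal import AreaConditionData
from .sampler import PosteriorDraws, SCMParams, poisson_log_lik

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelFit:
    """Deviance information criterion pieces.

    ``pd`` (effective number of parameters) is mean posterior deviance
    minus the deviance at the posterior mean; ``dic = dbar + pd`` holds
    by construction. A negative ``pd`` is reported as-is but flagged.
    """

    dbar: float
    d_at_mean: float

    @property
    def pd(self) -> float:
        return self.dbar - self.d_at_mean

    @property
    def dic(self) -> float:
        return self.dbar + self.pd

    def __post_init__(self):
        if self.pd < 0:
            logger.warning("negative effective parameter count pD = %.2f", self.pd)


def dic(draws: PosteriorDraws, data: AreaConditionData) -> ModelFit:
    """DIC from retained draws: Dbar is the mean of the per-draw
    deviances; the plug-in deviance is evaluated at the posterior means
    of alpha, log(delta), phi and eps on their sampled (log) scales."""
    dev = draws.pooled("deviance")
    if dev.size < 1:
        raise ValueError("no retained draws")
    dbar = float(dev.mean())
    mean_params = SCMParams(
        alpha=draws.pooled("alpha").mean(axis=0),
        log_delta=draws.pooled("log_delta").mean(axis=0),
        phi=draws.pooled("phi").mean(axis=0),
        epsilon=draws.pooled("epsilon").mean(axis=0),
        prec_phi=float(draws.pooled("prec_phi").mean()),
        prec_eps=draws.pooled("prec_eps").mean(axis=0),
    )
    d_at_mean = -2.0 * poisson_log_lik(data, mean_params)
    return ModelFit(dbar=dbar, d_at_mean=d_at_mean)


@dataclass(frozen=True)
class DecompositionSummary:
    """Per-condition variance decomposition of log relative risk into the
    scaled shared pattern and the specific pattern (the Table-2 surface)."""

    table: pd.DataFrame           # rows per condition
    sigma_shared: tuple[float, float, float]   # median, lo95, hi95

    def __str__(self) -> str:
        lines = ["Shared-component decomposition",
                 f"sigma_shared: {self.sigma_shared[0]:.3f} "
                 f"({self.sigma_shared[1]:.3f} - {self.sigma_shared[2]:.3f})",
                 self.table.to_string(float_format=lambda v: f"{v:.3f}")]
        return "\n".join(lines)


def variance_explained(draws: PosteriorDraws,
                       conditions: list[str] | None = None) -> DecompositionSummary:
    """Per-draw decomposition of each condition's log-risk variance.

    For retained draw t and condition j the shared fraction is

        f_jt = Var_i(delta_j phi_i) / [Var_i(delta_j phi_i) + Var_i(eps_ij)]

    with empirical variances across areas. The summary reports
    100 * posterior mean with a central 95% credible interval, together
    with posterior medians/intervals for sigma_specific,j, delta_j and
    the global sigma_shared.
    """
    phi = draws.pooled("phi")                    # (T, N)
    delta = np.exp(draws.pooled("log_delta"))    # (T, J)
    eps = draws.pooled("epsilon")                # (T, N, J)
    var_phi = phi.var(axis=1)                    # (T,)
    var_shared = (delta ** 2) * var_phi[:, None]          # (T, J)
    var_spec = eps.var(axis=1)                            # (T, J)
    total = var_shared + var_spec
    zero = total <= 0
    if zero.any():
        logger.warning("%d draw/condition cells with zero total variance",
                       int(zero.sum()))
    frac = np.where(zero, 0.0, var_shared / np.where(zero, 1.0, total)) * 100.0

    sig_spec = 1.0 / np.sqrt(draws.pooled("prec_eps"))
    sig_shared = 1.0 / np.sqrt(draws.pooled("prec_phi"))
    q = lambda a, qs: np.quantile(a, qs, axis=0)
    if conditions is None:
        conditions = draws.meta.get(
            "conditions", [f"c{k}" for k in range(delta.shape[1])])
    table = pd.DataFrame({
        "sigma_specific": np.median(sig_spec, axis=0),
        "sigma_specific_lo": q(sig_spec, 0.025),
        "sigma_specific_hi": q(sig_spec, 0.975),
        "delta": np.median(delta, axis=0),
        "delta_lo": q(delta, 0.025),
        "delta_hi": q(delta, 0.975),
        "pct_shared": frac.mean(axis=0),
        "pct_shared_lo": q(frac, 0.025),
        "pct_shared_hi": q(frac, 0.975),
    }, index=pd.Index(conditions, name="condition"))
    return DecompositionSummary(
        table=table,
        sigma_shared=(float(np.median(sig_shared)),
                      float(np.quantile(sig_shared, 0.025)),
                      float(np.quantile(sig_shared, 0.975))),
    )


@dataclass(frozen=True)
class ExceedanceSurface:
    """Posterior exceedance probabilities per area (columns per
    condition, or a single column for the shared pattern), with the
    0.8/0.2 high/low/indeterminate categorisation used for mapping."""

    prob: pd.DataFrame
    threshold: float = 1.0
    high_cut: float = 0.8
    low_cut: float = 0.2

    @property
    def category(self) -> pd.DataFrame:
        cat = pd.DataFrame("indeterminate", index=self.prob.index,
                           columns=self.prob.columns)
        cat = cat.mask(self.prob > self.high_cut, "high")
        cat = cat.mask(self.prob < self.low_cut, "low")
        return cat


def exceedance(draws: PosteriorDraws, term: str = "shared",
               threshold: float = 1.0,
               area_ids: list[str] | None = None) -> ExceedanceSurface:
    """Fraction of retained draws in which a relative-risk term exceeds
    ``threshold``.

    ``term``: ``shared`` maps exp(phi_i); ``condition_rr`` the smoothed
    standardized ratio exp(alpha_j + delta_j phi_i + eps_ij) per
    condition; ``specific`` the discrepant component exp(eps_ij).
    """
    conditions = draws.meta.get("conditions")
    log_thr = np.log(threshold)
    if term == "shared":
        x = draws.pooled("phi")                              # (T, N)
        prob = (x > log_thr).mean(axis=0)
        frame = pd.DataFrame({"shared": prob})
    elif term in ("condition_rr", "specific"):
        eps = draws.pooled("epsilon")                        # (T, N, J)
        if term == "condition_rr":
            phi = draws.pooled("phi")
            delta = np.exp(draws.pooled("log_delta"))
            alpha = draws.pooled("alpha")
            x = (alpha[:, None, :] + delta[:, None, :] * phi[:, :, None] + eps)
        else:
            x = eps
        prob = (x > log_thr).mean(axis=0)                    # (N, J)
        cols = conditions or [f"c{k}" for k in range(prob.shape[1])]
        frame = pd.DataFrame(prob, columns=cols)
    else:
        raise ValueError(f"unknown exceedance term {term!r}")
    if area_ids is not None:
        frame.index = pd.Index(area_ids, name="area_id")
    return ExceedanceSurface(prob=frame, threshold=threshold)


# ---------------------------------------------------------------------------
# convergence diagnostics


def _extract(draws: PosteriorDraws, parameter: str, index=None) -> np.ndarray:
    """(n_chains, n_draws) series for one scalar component."""
    x = draws.stacked(parameter)
    if x.ndim > 2:
        if index is None:
            raise ValueError(f"parameter {parameter!r} needs an index")
        if np.isscalar(index):
            index = (index,)
        x = x[(slice(None), slice(None)) + tuple(index)]
    return x


def rhat(draws: PosteriorDraws, parameter: str, index=None) -> float:
    """Split-chain potential scale reduction factor (Gelman-Rubin /
    Brooks-Gelman). Each chain is split in half; R-hat compares between-
    to within-half variance. Returns 1.0 (with a warning) for a
    parameter constant across all chains."""
    x = _extract(draws, parameter, index)
    c, t = x.shape
    if c < 2:
        raise ValueError("need >= 2 chains for R-hat")
    if t < 4:
        raise ValueError("need >= 4 retained draws per chain")
    half = t // 2
    splits = np.concatenate([x[:, :half], x[:, half: 2 * half]], axis=0)
    m, nn = splits.shape
    w = splits.var(axis=1, ddof=1).mean()
    if w == 0:
        logger.warning("zero within-chain variance for %s; R-hat set to 1",
                       parameter)
        return 1.0
    b = nn * splits.mean(axis=1).var(ddof=1)
    var_plus = (nn - 1) / nn * w + b / nn
    return float(np.sqrt(var_plus / w))


def rhat_table(draws: PosteriorDraws) -> pd.DataFrame:
    """R-hat for every hyperparameter and intercept (the quantities the
    strict convergence gate checks), plus the deviance."""
    rows = []
    jn = draws.chains[0]["alpha"].shape[1]
    for j in range(jn):
        rows.append((f"alpha[{j}]", rhat(draws, "alpha", j)))
        rows.append((f"log_delta[{j}]", rhat(draws, "log_delta", j)))
        rows.append((f"prec_eps[{j}]", rhat(draws, "prec_eps", j)))
    rows.append(("prec_phi", rhat(draws, "prec_phi")))
    rows.append(("deviance", rhat(draws, "deviance")))
    return pd.DataFrame(rows, columns=["parameter", "rhat"]).set_index("parameter")


def autocorrelation(draws: PosteriorDraws, parameter: str, index=None,
                    max_lag: int = 50) -> np.ndarray:
    """Sample autocorrelation at lags 0..max_lag, averaged over chains."""
    x = _extract(draws, parameter, index)
    c, t = x.shape
    if t < max_lag + 2:
        raise ValueError("need at least max_lag + 2 draws")
    acfs = []
    for chain in x:
        z = chain - chain.mean()
        denom = float(z @ z)
        if denom == 0:
            raise ValueError("zero-variance chain")
        full = np.correlate(z, z, mode="full")[t - 1:]
        acfs.append(full[: max_lag + 1] / denom)
    return np.mean(acfs, axis=0)
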