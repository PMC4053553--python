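"""Model classes for joint spatial analysis of areal admission counts.

The central object is :class:`SharedComponentModel`: a joint Poisson
model for several conditions over the same small areas,

    O_ij ~ Poisson(e_ij * rho_ij),
    log(rho_ij) = alpha_j + delta_j * phi_i + eps_ij,

where phi_i is a latent risk surface shared by all conditions,
delta_j > 0 its per-condition factor loading, and eps_ij exchangeable
condition-specific residual spatial effects. :class:`BYMModel` is the
classical single-condition comparator with a structured (intrinsic CAR)
plus unstructured pair of random effects, and
:class:`IndependentModel` the non-spatial per-condition baseline.

`fit()` runs the Metropolis-within-Gibbs sampler and returns a results
object carrying the retained draws with DIC, the shared/specific
variance decomposition, exceedance surfaces, convergence diagnostics
and a text `summary()`.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .areal import AreaConditionData, AreaGraph, StratumTable, assemble, \
    read_adjacency_gal, read_stratum_table
from .sampler import BYMSpec, GibbsSampler, PosteriorDraws, SCMSpec
from . import results as _post


class _BaseModel:
    """Shared constructor plumbing for the Poisson areal models."""

    def __init__(self, data: AreaConditionData, spec: SCMSpec):
        self.data = data
        self.spec = spec
        self._sampler = GibbsSampler(data, spec)

    @classmethod
    def from_files(cls, counts_csv, gal_path, **kwargs):
        """Build from a stratum-table CSV and a GAL adjacency file."""
        table = read_stratum_table(counts_csv)
        graph = read_adjacency_gal(gal_path)
        return cls.from_stratum_table(table, graph, **kwargs)

    @classmethod
    def from_stratum_table(cls, table: StratumTable, graph: AreaGraph, **kwargs):
        return cls(assemble(table, graph), **kwargs)

    def _fit(self, n_chains, iterations, burn_in, thin, seed) -> PosteriorDraws:
        return self._sampler.sample(n_chains=n_chains, iterations=iterations,
                                    burn_in=burn_in, thin=thin, seed=seed)


class SharedComponentModel(_BaseModel):
    """Joint shared-component model over all conditions in ``data``."""

    def __init__(self, data: AreaConditionData, spec: SCMSpec | None = None):
        super().__init__(data, spec or SCMSpec())

    def fit(self, n_chains: int = 3, iterations: int = 49_500,
            burn_in: int = 12_000, thin: int = 75,
            seed: int | None = None) -> "SCMResults":
        draws = self._fit(n_chains, iterations, burn_in, thin, seed)
        return SCMResults(self, draws)


class BYMModel(_BaseModel):
    """Besag-York-Mollie model for a single condition."""

    def __init__(self, data: AreaConditionData, spec: BYMSpec | None = None):
        if data.n_conditions != 1:
            raise ValueError("BYMModel takes a single-condition slice; "
                             "use data.condition_slice(condition)")
        self.bym_spec = spec or BYMSpec()
        super().__init__(data, self.bym_spec.to_scm_spec())

    def fit(self, n_chains: int = 3, iterations: int = 49_500,
            burn_in: int = 12_000, thin: int = 75,
            seed: int | None = None) -> "BYMResults":
        draws = self._fit(n_chains, iterations, burn_in, thin, seed)
        draws.meta["model"] = "bym"
        return BYMResults(self, draws)


class IndependentModel(_BaseModel):
    """Non-spatial per-condition baseline: intercept plus exchangeable
    area effect, no sharing across conditions (fit one per condition)."""

    def __init__(self, data: AreaConditionData,
                 variance_hyperprior: tuple[float, float] = (0.5, 0.0005)):
        if data.n_conditions != 1:
            raise ValueError("IndependentModel takes a single-condition slice")
        super().__init__(data, SCMSpec(shared_prior="exchangeable",
                                       sample_delta=False,
                                       include_epsilon=False,
                                       variance_hyperprior=variance_hyperprior))

    def fit(self, n_chains: int = 3, iterations: int = 49_500,
            burn_in: int = 12_000, thin: int = 75,
            seed: int | None = None) -> "BYMResults":
        draws = self._fit(n_chains, iterations, burn_in, thin, seed)
        draws.meta["model"] = "independent"
        return BYMResults(self, draws)


class _BaseResults:
    """Posterior-draw container shared by all model families."""

    def __init__(self, model: _BaseModel, draws: PosteriorDraws):
        self.model = model
        self.draws = draws

    @property
    def data(self) -> AreaConditionData:
        return self.model.data

    def dic(self) -> _post.ModelFit:
        return _post.dic(self.draws, self.data)

    def rhat(self, parameter: str, index=None) -> float:
        return _post.rhat(self.draws, parameter, index)

    def rhat_table(self) -> pd.DataFrame:
        return _post.rhat_table(self.draws)

    def autocorrelation(self, parameter: str, index=None, max_lag: int = 50):
        return _post.autocorrelation(self.draws, parameter, index, max_lag)

    def exceedance(self, term: str = "shared", threshold: float = 1.0):
        return _post.exceedance(self.draws, term, threshold,
                                area_ids=list(self.data.graph.area_ids))

    def acceptance_rates(self) -> list[dict]:
        return self.draws.meta["acceptance_rates"]

    def to_csv(self, draws_path, meta_path=None) -> None:
        """Serialize retained draws to long CSV (chain, draw, parameter,
        value) with a JSON meta sidecar."""
        rows = []
        for c, chain in enumerate(self.draws.chains):
            for name, arr in chain.items():
                flat = arr.reshape(arr.shape[0], -1)
                idx_labels = [
                    name if flat.shape[1] == 1 else
                    f"{name}[{','.join(map(str, np.unravel_index(k, arr.shape[1:])))}]"
                    for k in range(flat.shape[1])
                ]
                for k, label in enumerate(idx_labels):
                    rows.append(pd.DataFrame({
                        "chain": c, "draw": np.arange(flat.shape[0]),
                        "parameter": label, "value": flat[:, k]}))
        pd.concat(rows, ignore_index=True).to_csv(draws_path, index=False)
        if meta_path is not None:
            with open(meta_path, "w", encoding="utf-8") as fh:
                json.dump(self.draws.meta, fh, indent=1, default=str)


class SCMResults(_BaseResults):
    """Results of a shared-component fit."""

    def variance_explained(self) -> _post.DecompositionSummary:
        return _post.variance_explained(self.draws, list(self.data.conditions))

    def shared_field_mean(self) -> np.ndarray:
        """Posterior mean of the shared field phi (log scale)."""
        return self.draws.pooled("phi").mean(axis=0)

    def summary(self) -> str:
        fit = self.dic()
        dec = self.variance_explained()
        rt = self.rhat_table()
        lines = [
            "Shared Component Model results",
            "==============================",
            f"model: {self.draws.meta['model']}   areas: {self.data.n_areas}   "
            f"conditions: {self.data.n_conditions}",
            f"chains: {self.draws.n_chains}   retained draws/chain: "
            f"{self.draws.n_retained}",
            f"DIC: {fit.dic:.1f}   pD: {fit.pd:.1f}   Dbar: {fit.dbar:.1f}",
            f"max R-hat (monitored): {rt['rhat'].max():.3f}",
            "",
            str(dec),
        ]
        return "\n".join(lines)


class BYMResults(_BaseResults):
    """Results of a single-condition (BYM or independent) fit."""

    def variance_summary(self) -> pd.DataFrame:
        """Posterior medians and 95% intervals of the random-effect
        standard deviations (structured sigma_u, unstructured sigma_v)."""
        rows = {}
        sig_u = 1.0 / np.sqrt(self.draws.pooled("prec_phi"))
        rows["sigma_u"] = [np.median(sig_u), *np.quantile(sig_u, [0.025, 0.975])]
        if self.model.spec.include_epsilon:
            sig_v = 1.0 / np.sqrt(self.draws.pooled("prec_eps")[:, 0])
            rows["sigma_v"] = [np.median(sig_v), *np.quantile(sig_v, [0.025, 0.975])]
        return pd.DataFrame(rows, index=["median", "lo95", "hi95"]).T

    def summary(self) -> str:
        fit = self.dic()
        lines = [
            f"{self.draws.meta['model']} fit: condition "
            f"{self.data.conditions[0]!r}, {self.data.n_areas} areas",
            f"DIC: {fit.dic:.1f}   pD: {fit.pd:.1f}   Dbar: {fit.dbar:.1f}",
            self.variance_summary().to_string(float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional front-ends


def fit_scm(data: AreaConditionData, spec: SCMSpec | None = None,
            n_chains: int = 3, iterations: int = 49_500, burn_in: int = 12_000,
            thin: int = 75, seed: int | None = None) -> SCMResults:
    """Fit the shared component model; see :class:`SharedComponentModel`."""
    return SharedComponentModel(data, spec).fit(
        n_chains=n_chains, iterations=iterations, burn_in=burn_in,
        thin=thin, seed=seed)


def fit_bym(data: AreaConditionData, spec: BYMSpec | None = None,
            n_chains: int = 3, iterations: int = 49_500, burn_in: int = 12_000,
            thin: int = 75, seed: int | None = None) -> BYMResults:
    """Fit the BYM model to a single-condition slice."""
    return BYMModel(data, spec).fit(
        n_chains=n_chains, iterations=iterations, burn_in=burn_in,
        thin=thin, seed=seed)
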