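"""Metropolis-within-Gibbs engine for joint Poisson disease-mapping models.

All model families in this package share one second level,

    log(mu_ij) = log(e_ij) + alpha_j + delta_j * phi_i + eps_ij,

and differ only in which pieces are present and which prior the latent
field phi carries:

* shared component model (SCM): J conditions, delta sampled, phi
  exchangeable or intrinsic CAR, eps exchangeable per condition;
* BYM: one condition, delta fixed at 1, phi intrinsic CAR (the
  structured effect u), eps exchangeable (the unstructured effect v);
* independent non-spatial model: one condition, delta fixed at 1, phi
  exchangeable, no eps.

Updates: conjugate Gibbs draws for the precisions (Gamma hyperpriors);
adaptive random-walk Metropolis for alpha_j, log delta_j, each phi_i and
each eps_ij, with Robbins-Monro scale adaptation during burn-in only.
Site updates are vectorized: exchangeable sites are conditionally
independent and accepted element-wise; under the ICAR prior, areas are
partitioned by graph coloring and each color class (no two members
adjacent) is updated simultaneously.

After every sweep the standard identifiability transforms are applied:
phi is centered (the shift absorbed into alpha through delta), each eps
column is centered into alpha_j, and the delta/phi scale is fixed by the
geometric-mean-one rescaling. These transforms act only on directions
the likelihood cannot see.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .areal import AreaConditionData, AreaGraph

logger = logging.getLogger(__name__)

_ADAPT_TARGET = 0.44  # canonical univariate RW acceptance target


@dataclass
class SCMSpec:
    """Prior and structural choices for the shared component model.

    ``logdelta_prior_precision`` follows the WinBUGS convention: the
    normal prior on log(delta_j) is parameterized by its precision
    (default 5.9, i.e. variance ~0.17); set
    ``logdelta_prior_is_variance`` for the variance reading.
    """

    shared_prior: str = "exchangeable"            # exchangeable | icar
    logdelta_prior_precision: float = 5.9
    logdelta_prior_is_variance: bool = False
    variance_hyperprior: tuple[float, float] = (0.5, 0.0005)   # Gamma(shape, rate)
    delta_identifiability: str = "geometric-mean-one"          # or "none"
    sample_delta: bool = True
    include_epsilon: bool = True
    fixed_prec_phi: float | None = None
    fixed_prec_eps: float | None = None

    def __post_init__(self):
        if self.shared_prior not in ("exchangeable", "icar"):
            raise ValueError(f"unknown shared_prior {self.shared_prior!r}")
        if self.delta_identifiability not in ("geometric-mean-one", "none"):
            raise ValueError("delta_identifiability must be "
                             "'geometric-mean-one' or 'none'")
        if self.logdelta_prior_precision <= 0:
            raise ValueError("logdelta prior scale must be positive")
        a, b = self.variance_hyperprior
        if a <= 0 or b <= 0:
            raise ValueError("variance hyperprior parameters must be positive")

    @property
    def logdelta_precision(self) -> float:
        p = self.logdelta_prior_precision
        return 1.0 / p if self.logdelta_prior_is_variance else p


@dataclass
class BYMSpec:
    """Besag-York-Mollie model for a single condition: intrinsic CAR
    structured effect plus exchangeable unstructured effect."""

    variance_hyperprior: tuple[float, float] = (0.5, 0.0005)

    def to_scm_spec(self) -> SCMSpec:
        return SCMSpec(shared_prior="icar", sample_delta=False,
                       include_epsilon=True,
                       variance_hyperprior=self.variance_hyperprior)


@dataclass
class SCMParams:
    """One MCMC state."""

    alpha: np.ndarray          # (J,)
    log_delta: np.ndarray      # (J,)
    phi: np.ndarray            # (N,)
    epsilon: np.ndarray        # (N, J)
    prec_phi: float
    prec_eps: np.ndarray       # (J,)

    @property
    def delta(self) -> np.ndarray:
        return np.exp(self.log_delta)


@dataclass
class PosteriorDraws:
    """Retained draws across chains.

    Each chain is a dict of arrays keyed by parameter name with leading
    dimension = number of retained draws: ``alpha`` (T, J), ``log_delta``
    (T, J), ``phi`` (T, N), ``epsilon`` (T, N, J), ``prec_phi`` (T,),
    ``prec_eps`` (T, J), ``deviance`` (T,).
    """

    chains: list[dict[str, np.ndarray]]
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_retained(self) -> int:
        return self.chains[0]["deviance"].shape[0]

    def stacked(self, param: str) -> np.ndarray:
        """(n_chains, n_retained, ...) array for one parameter."""
        return np.stack([c[param] for c in self.chains])

    def pooled(self, param: str) -> np.ndarray:
        """All chains concatenated along the draw axis."""
        return np.concatenate([c[param] for c in self.chains])


def poisson_log_lik(data: AreaConditionData, params: SCMParams) -> float:
    """Full Poisson log-likelihood of the collapsed counts at one state."""
    log_mu = (np.log(data.expected) + params.alpha[None, :]
              + params.delta[None, :] * params.phi[:, None] + params.epsilon)
    if not np.isfinite(log_mu).all():
        i, j = np.argwhere(~np.isfinite(log_mu))[0]
        raise FloatingPointError(f"non-finite log mu at cell ({i}, {j})")
    o = data.observed
    return float(np.sum(o * log_mu - np.exp(log_mu) - gammaln(o + 1.0)))


def icar_quadratic(phi: np.ndarray, graph: AreaGraph) -> float:
    """Pairwise-difference quadratic form of the intrinsic CAR prior:
    sum over undirected edges of (phi_i - phi_k)^2."""
    edges = np.asarray(graph.edges(), dtype=int)
    if edges.size == 0:
        return 0.0
    d = phi[edges[:, 0]] - phi[edges[:, 1]]
    return float(np.sum(d * d))


class _GraphStructure:
    """Precomputed adjacency machinery for ICAR updates."""

    def __init__(self, graph: AreaGraph):
        import networkx as nx

        self.edges = np.asarray(graph.edges(), dtype=int).reshape(-1, 2)
        n = graph.n_areas
        self.deg = np.zeros(n)
        for i, k in self.edges:
            self.deg[i] += 1
            self.deg[k] += 1
        self.adjacency = graph.adjacency_matrix()
        self.isolated = self.deg == 0
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(self.edges)
        coloring = nx.greedy_color(g, strategy="largest_first")
        n_colors = 1 + max(coloring.values()) if coloring else 1
        self.color_classes = [
            np.array([v for v, c in coloring.items() if c == col], dtype=int)
            for col in range(n_colors)
        ]
        n_comp = sum(1 for _ in nx.connected_components(g))
        # degrees of freedom of the intrinsic quadratic, counting each
        # isolated area (handled with an exchangeable conditional) fully
        self.icar_df = (n - n_comp) + int(self.isolated.sum())

    def quad(self, phi: np.ndarray) -> float:
        d = phi[self.edges[:, 0]] - phi[self.edges[:, 1]]
        return float(np.sum(d * d) + np.sum(phi[self.isolated] ** 2))


class GibbsSampler:
    """One-model sampler instance bound to a dataset and spec."""

    def __init__(self, data: AreaConditionData, spec: SCMSpec):
        self.data = data
        self.spec = spec
        self.O = data.observed.astype(float)
        self.E = data.expected
        self.log_E = np.log(self.E)
        self.T_j = self.O.sum(axis=0)
        if (self.T_j < 1).any():
            raise ValueError("each condition needs >= 1 admission for a "
                             "proper intercept posterior")
        self.gammaln_O = gammaln(self.O + 1.0)
        self.n, self.j = self.O.shape
        self.gs = _GraphStructure(data.graph)
        if spec.shared_prior == "icar" and self.gs.isolated.any():
            logger.warning("%d isolated area(s): ICAR conditional replaced by "
                           "an exchangeable one with the shared precision",
                           int(self.gs.isolated.sum()))

    # -- state -------------------------------------------------------------

    def initial_state(self, rng: np.random.Generator) -> SCMParams:
        alpha = np.log(self.T_j / self.E.sum(axis=0))
        phi = rng.normal(0.0, 0.1, size=self.n)
        eps = (rng.normal(0.0, 0.1, size=(self.n, self.j))
               if self.spec.include_epsilon else np.zeros((self.n, self.j)))
        prec_phi = (self.spec.fixed_prec_phi
                    if self.spec.fixed_prec_phi is not None else 10.0)
        prec_eps = np.full(self.j, self.spec.fixed_prec_eps
                           if self.spec.fixed_prec_eps is not None else 10.0)
        return SCMParams(alpha=alpha, log_delta=np.zeros(self.j), phi=phi,
                         epsilon=eps, prec_phi=float(prec_phi), prec_eps=prec_eps)

    def deviance(self, params: SCMParams) -> float:
        return -2.0 * poisson_log_lik(self.data, params)

    # -- one chain ---------------------------------------------------------

    def run_chain(self, iterations: int, burn_in: int, thin: int,
                  rng: np.random.Generator) -> tuple[dict, dict]:
        spec = self.spec
        n, jn = self.n, self.j
        st = self.initial_state(rng)
        alpha, ld, phi, eps = st.alpha, st.log_delta, st.phi, st.epsilon
        prec_phi, prec_eps = st.prec_phi, st.prec_eps
        a_hp, b_hp = spec.variance_hyperprior
        prec_ld = spec.logdelta_precision
        icar = spec.shared_prior == "icar"
        eff_deg = np.maximum(self.gs.deg, 1.0)  # isolated -> exchangeable
        adj_by_class = ([self.gs.adjacency[idx] for idx in self.gs.color_classes]
                        if icar else None)

        # proposal scales, roughly matched to Poisson information
        s_alpha = 2.4 / np.sqrt(self.T_j + 1.0)
        s_ld = np.full(jn, 0.1)
        s_phi = 2.4 / np.sqrt(self.O.sum(axis=1) + 10.0)
        s_eps = 2.4 / np.sqrt(self.O + 10.0)
        s_tr = np.full(jn, 0.1)       # delta/eps transfer move
        s_amp_phi = 0.1               # shared-field amplitude move
        s_amp_eps = np.full(jn, 0.1)  # specific-field amplitude move

        n_keep = (iterations - burn_in) // thin
        out = {
            "alpha": np.empty((n_keep, jn)),
            "log_delta": np.empty((n_keep, jn)),
            "phi": np.empty((n_keep, n)),
            "epsilon": np.empty((n_keep, n, jn)),
            "prec_phi": np.empty(n_keep),
            "prec_eps": np.empty((n_keep, jn)),
            "deviance": np.empty(n_keep),
        }
        acc_counts = {"alpha": 0.0, "log_delta": 0.0, "phi": 0.0, "epsilon": 0.0}
        post_sweeps = 0
        kept = 0

        for t in range(iterations):
            adapting = t < burn_in
            gamma = min(0.5, (t + 1.0) ** -0.6) if adapting else 0.0
            delta = np.exp(ld)
            mu = self.E * np.exp(alpha[None, :] + delta[None, :] * phi[:, None] + eps)

            # alpha_j | rest (flat prior); mu scales by exp(da_j) per column
            da = rng.normal(size=jn) * s_alpha
            col_mu = mu.sum(axis=0)
            dll = self.T_j * da - col_mu * np.expm1(da)
            acc = np.log(rng.uniform(size=jn)) < dll
            if acc.any():
                alpha = alpha + da * acc
                mu[:, acc] *= np.exp(da[acc])
            if adapting:
                s_alpha *= np.exp(gamma * (acc - _ADAPT_TARGET))
            elif post_sweeps >= 0:
                acc_counts["alpha"] += acc.mean()

            # log delta_j | rest
            if spec.sample_delta:
                dld = rng.normal(size=jn) * s_ld
                dnew = np.exp(ld + dld)
                dlin = (dnew - delta)[None, :] * phi[:, None]
                ex = np.expm1(dlin)
                dll = (self.O * dlin - mu * ex).sum(axis=0)
                dlp = -0.5 * prec_ld * ((ld + dld) ** 2 - ld ** 2)
                acc = np.log(rng.uniform(size=jn)) < dll + dlp
                if acc.any():
                    ld = ld + dld * acc
                    mu[:, acc] *= (1.0 + ex)[:, acc]
                    delta = np.exp(ld)
                if adapting:
                    s_ld *= np.exp(gamma * (acc - _ADAPT_TARGET))
                else:
                    acc_counts["log_delta"] += acc.mean()

            # phi_i | rest
            if icar:
                acc_frac = 0.0
                for idx, adj_c in zip(self.gs.color_classes, adj_by_class):
                    if idx.size == 0:
                        continue
                    dphi = rng.normal(size=idx.size) * s_phi[idx]
                    dlin = delta[None, :] * dphi[:, None]
                    ex = np.expm1(dlin)
                    dll = (self.O[idx] * dlin - mu[idx] * ex).sum(axis=1)
                    nb_sum = adj_c @ phi
                    dlp = -0.5 * prec_phi * (
                        eff_deg[idx] * (2.0 * phi[idx] * dphi + dphi ** 2)
                        - 2.0 * dphi * nb_sum)
                    acc = np.log(rng.uniform(size=idx.size)) < dll + dlp
                    if acc.any():
                        sel = idx[acc]
                        phi[sel] += dphi[acc]
                        mu[sel] *= 1.0 + ex[acc]
                    if adapting:
                        s_phi[idx] *= np.exp(gamma * (acc - _ADAPT_TARGET))
                    acc_frac += acc.sum()
                if not adapting:
                    acc_counts["phi"] += acc_frac / n
            else:
                dphi = rng.normal(size=n) * s_phi
                dlin = delta[None, :] * dphi[:, None]
                ex = np.expm1(dlin)
                dll = (self.O * dlin - mu * ex).sum(axis=1)
                dlp = -0.5 * prec_phi * (2.0 * phi * dphi + dphi ** 2)
                acc = np.log(rng.uniform(size=n)) < dll + dlp
                if acc.any():
                    phi = phi + dphi * acc
                    mu[acc] *= 1.0 + ex[acc]
                if adapting:
                    s_phi *= np.exp(gamma * (acc - _ADAPT_TARGET))
                else:
                    acc_counts["phi"] += acc.mean()

            # eps_ij | rest
            if spec.include_epsilon:
                deps = rng.normal(size=(n, jn)) * s_eps
                ex = np.expm1(deps)
                dll = self.O * deps - mu * ex
                dlp = -0.5 * prec_eps[None, :] * (2.0 * eps * deps + deps ** 2)
                acc = np.log(rng.uniform(size=(n, jn))) < dll + dlp
                eps = eps + deps * acc
                mu *= 1.0 + ex * acc
                if adapting:
                    s_eps *= np.exp(gamma * (acc - _ADAPT_TARGET))
                else:
                    acc_counts["epsilon"] += acc.mean()

            # coherent scale moves: single-site updates mix the variance
            # partition slowly (the classical hierarchical funnel), so a
            # few joint proposals move whole fields with their precision.

            # (a) transfer between the scaled shared field and the
            # specific effects: delta_j -> delta_j e^c with
            # eps_ij -> eps_ij + (delta_j - delta_j e^c) phi_i keeps the
            # likelihood fixed; only the priors decide.
            if spec.sample_delta and spec.include_epsilon:
                c = rng.normal(size=jn) * s_tr
                dnew = delta * np.exp(c)
                shift = (delta - dnew)[None, :] * phi[:, None]
                eps_new = eps + shift
                dlp = (-0.5 * prec_eps * ((eps_new ** 2).sum(axis=0)
                                          - (eps ** 2).sum(axis=0))
                       - 0.5 * prec_ld * ((ld + c) ** 2 - ld ** 2))
                acc = np.log(rng.uniform(size=jn)) < dlp
                if acc.any():
                    eps[:, acc] = eps_new[:, acc]
                    ld = ld + c * acc
                    delta = np.exp(ld)
                if adapting:
                    s_tr *= np.exp(gamma * (acc - _ADAPT_TARGET))

            # (b) shared-field amplitude with compensating precision:
            # phi -> e^c phi, prec_phi -> e^{-2c} prec_phi
            if spec.fixed_prec_phi is None:
                c = float(rng.normal()) * s_amp_phi
                dlin = delta[None, :] * (np.expm1(c) * phi)[:, None]
                ex = np.expm1(dlin)
                dll = float((self.O * dlin - mu * ex).sum())
                df = self.gs.icar_df if icar else n
                prec_new = prec_phi * np.exp(-2.0 * c)
                dlp = (-df * c                       # (df/2) log prec term
                       + (a_hp - 1.0) * (-2.0 * c)   # hyperprior
                       - b_hp * (prec_new - prec_phi)
                       + (n - 2.0) * c)              # Jacobian
                if np.log(rng.uniform()) < dll + dlp:
                    phi = phi * np.exp(c)
                    prec_phi = prec_new
                    mu *= 1.0 + ex
                    acc_a = 1.0
                else:
                    acc_a = 0.0
                if adapting:
                    s_amp_phi *= np.exp(gamma * (acc_a - _ADAPT_TARGET))

            # (c) specific-effect amplitude per condition:
            # eps_j -> e^{c_j} eps_j, prec_eps_j -> e^{-2c_j} prec_eps_j
            if spec.include_epsilon and spec.fixed_prec_eps is None:
                c = rng.normal(size=jn) * s_amp_eps
                dlin = np.expm1(c)[None, :] * eps
                ex = np.expm1(dlin)
                dll = (self.O * dlin - mu * ex).sum(axis=0)
                prec_new = prec_eps * np.exp(-2.0 * c)
                dlp = (-n * c + (a_hp - 1.0) * (-2.0 * c)
                       - b_hp * (prec_new - prec_eps) + (n - 2.0) * c)
                acc = np.log(rng.uniform(size=jn)) < dll + dlp
                if acc.any():
                    eps[:, acc] *= np.exp(c[acc])[None, :]
                    prec_eps = np.where(acc, prec_new, prec_eps)
                    mu[:, acc] *= (1.0 + ex)[:, acc]
                if adapting:
                    s_amp_eps *= np.exp(gamma * (acc - _ADAPT_TARGET))

            # precisions | rest (conjugate Gamma)
            if spec.fixed_prec_phi is None:
                if icar:
                    quad = self.gs.quad(phi)
                    shape = a_hp + 0.5 * self.gs.icar_df
                else:
                    quad = float(phi @ phi)
                    shape = a_hp + 0.5 * n
                prec_phi = float(rng.gamma(shape, 1.0 / (b_hp + 0.5 * quad)))
            if spec.include_epsilon and spec.fixed_prec_eps is None:
                rate = b_hp + 0.5 * (eps * eps).sum(axis=0)
                prec_eps = rng.gamma(a_hp + 0.5 * n, 1.0 / rate)

            # identifiability transforms (likelihood-invariant)
            m = phi.mean()
            if m != 0.0:
                phi = phi - m
                alpha = alpha + delta * m
            if spec.include_epsilon:
                me = eps.mean(axis=0)
                eps = eps - me[None, :]
                alpha = alpha + me
            if spec.sample_delta and spec.delta_identifiability == "geometric-mean-one":
                c = ld.mean()
                if c != 0.0:
                    ld = ld - c
                    phi = phi * np.exp(c)
                    delta = np.exp(ld)

            if not adapting:
                post_sweeps += 1
                if (t - burn_in + 1) % thin == 0 and kept < n_keep:
                    params = SCMParams(alpha=alpha.copy(), log_delta=ld.copy(),
                                       phi=phi.copy(), epsilon=eps.copy(),
                                       prec_phi=prec_phi, prec_eps=prec_eps.copy())
                    dev = self.deviance(params)
                    if not np.isfinite(dev):
                        raise FloatingPointError(
                            f"non-finite deviance at iteration {t}")
                    out["alpha"][kept] = alpha
                    out["log_delta"][kept] = ld
                    out["phi"][kept] = phi
                    out["epsilon"][kept] = eps
                    out["prec_phi"][kept] = prec_phi
                    out["prec_eps"][kept] = prec_eps
                    out["deviance"][kept] = dev
                    kept += 1

        for k in out:
            out[k] = out[k][:kept]
        rates = {k: (v / max(post_sweeps, 1)) for k, v in acc_counts.items()}
        return out, rates

    def sample(self, n_chains: int = 3, iterations: int = 49_500,
               burn_in: int = 12_000, thin: int = 75,
               seed: int | None = None) -> PosteriorDraws:
        """Run ``n_chains`` independent chains and collect retained draws.

        One master seed derives independent per-chain streams; the same
        seed reproduces the draws bit for bit.
        """
        if iterations <= burn_in:
            raise ValueError("iterations must exceed burn_in")
        if thin < 1:
            raise ValueError("thin must be >= 1")
        ss = np.random.SeedSequence(seed)
        chains, rates = [], []
        for child in ss.spawn(n_chains):
            rng = np.random.Generator(np.random.PCG64(child))
            out, r = self.run_chain(iterations, burn_in, thin, rng)
            chains.append(out)
            rates.append(r)
        meta = {
            "iterations": iterations, "burn_in": burn_in, "thin": thin,
            "n_chains": n_chains, "seed": seed,
            "model": ("scm-" + ("car" if self.spec.shared_prior == "icar"
                                else "exch")),
            "acceptance_rates": rates,
            "n_areas": self.n, "conditions": list(self.data.conditions),
        }
        logger.info("sampling done: %d chains x %d retained draws",
                    n_chains, chains[0]["deviance"].shape[0])
        return PosteriorDraws(chains=chains, meta=meta)
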