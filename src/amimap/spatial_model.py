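"""Bayesian spatial smoothing of township incidence (BYM convolution model).

Raw township rates y_i / E_i are unstable when event counts are small.
The Besag-York-Mollie convolution model stabilizes them by borrowing
strength from neighbouring townships:

    y_i   ~ Poisson(E_i * exp(alpha + u_i + v_i))
    u     ~ ICAR(tau_u)      (intrinsic CAR over the adjacency graph)
    v_i   ~ Normal(0, 1/tau_v)   iid
    tau_u, tau_v ~ Gamma(a, b),  alpha ~ Normal(0, sd^2) (vague)

where E_i are person-years and the ICAR prior puts each u_i conditionally
normal around the mean of its neighbours. The improper ICAR is identified
by recentring u to sum to zero (per connected component) after every
sweep; islands (degree-0 townships) have u_i fixed at 0 and rely on v_i.

Inference is Metropolis-within-Gibbs: adaptive random-walk Metropolis
updates for alpha and each u_i, v_i (proposal scales tuned toward 0.44
acceptance during burn-in only, then frozen, preserving detailed
balance), and conjugate Gibbs draws for the two precisions. Spatial sites
are updated simultaneously within graph-colouring classes, which is valid
because same-colour townships are never neighbours.

Each sex x age-group x period stratum is fitted independently. Reported
small-area estimates are posterior means of exp(alpha + u_i + v_i) x
100,000, i.e. incidence per 100,000 person-years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._common import ConfigError


@dataclass
class MCMCConfig:
    n_chains: int = 2
    n_iter: int = 4000
    n_burnin: int = 2000
    thin: int = 1
    target_accept: float = 0.44
    adapt_interval: int = 50
    hyper_a: float = 0.5
    hyper_b: float = 0.0005
    alpha_prior_sd: float = 10.0
    seed: int = 0
    #: pin a precision instead of sampling it (e.g. a huge fix_tau_u turns
    #: the spatial term off, reducing the model to a Poisson-lognormal
    #: exchangeable hierarchy)
    fix_tau_u: float | None = None
    fix_tau_v: float | None = None

    def validate(self) -> None:
        if not self.n_iter > self.n_burnin >= 0:
            raise ConfigError("need n_iter > n_burnin >= 0")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")
        if self.n_chains < 1:
            raise ConfigError("need at least one chain")
        if self.hyper_a <= 0 or self.hyper_b <= 0:
            raise ConfigError("gamma hyperparameters must be positive")


@dataclass
class Adjacency:
    """Neighbour structure consumed by the sampler."""

    townships: list[str]
    matrix: sp.csr_matrix  # symmetric 0/1
    degrees: np.ndarray
    islands: list[str]
    color_classes: list[np.ndarray]  # index arrays; no within-class edges
    component_labels: np.ndarray  # per non-island township
    n_components: int  # connected components among non-islands

    @property
    def n(self) -> int:
        return len(self.townships)


def build_adjacency(map_) -> Adjacency:
    """Validate a TownshipMap's adjacency and prepare sampler structures.

    Raises on asymmetric adjacency; reports islands, which get u_i = 0.
    Colour classes come from a greedy graph colouring.
    """
    import networkx as nx

    map_.validate()
    a = map_.matrix if hasattr(map_, "matrix") else map_.adjacency_matrix()
    if (abs(a - a.T)).nnz:
        raise ConfigError("adjacency matrix is not symmetric")
    deg = np.asarray(a.sum(axis=1)).ravel()
    islands = [t for t, d in zip(map_.townships, deg) if d == 0]
    g = nx.from_scipy_sparse_array(a)
    coloring = nx.greedy_color(g, strategy="largest_first")
    n_colors = max(coloring.values()) + 1 if coloring else 0
    classes = [
        np.array([i for i, c in coloring.items() if c == k and deg[i] > 0], dtype=int)
        for k in range(n_colors)
    ]
    classes = [c for c in classes if len(c)]
    labels = np.full(len(map_.townships), -1, dtype=int)
    comp_id = 0
    for comp in nx.connected_components(g):
        comp = [i for i in comp if deg[i] > 0]
        if comp:
            labels[comp] = comp_id
            comp_id += 1
    return Adjacency(
        townships=list(map_.townships),
        matrix=a.tocsr(),
        degrees=deg,
        islands=islands,
        color_classes=classes,
        component_labels=labels,
        n_components=comp_id,
    )


@dataclass
class BYMPosterior:
    """Retained MCMC draws and posterior summaries for one stratum."""

    townships: list[str]
    y: np.ndarray
    exposure: np.ndarray
    alpha: np.ndarray  # (chains, draws)
    u: np.ndarray  # (chains, draws, n)
    v: np.ndarray  # (chains, draws, n)
    tau_u: np.ndarray  # (chains, draws)
    tau_v: np.ndarray  # (chains, draws)
    config: MCMCConfig
    acceptance: dict = field(default_factory=dict)

    def rate_draws(self) -> np.ndarray:
        """Incidence per 100,000 person-years, shape (chains, draws, n)."""
        return np.exp(self.alpha[..., None] + self.u + self.v) * 1e5

    def log_rate_draws(self) -> np.ndarray:
        return self.alpha[..., None] + self.u + self.v

    def posterior_mean_rate(self) -> np.ndarray:
        return self.rate_draws().mean(axis=(0, 1))

    def posterior_mean_log_rate(self) -> np.ndarray:
        return self.log_rate_draws().mean(axis=(0, 1))

    def rate_interval(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        q = (1 - level) / 2
        r = self.rate_draws().reshape(-1, len(self.townships))
        return np.quantile(r, q, axis=0), np.quantile(r, 1 - q, axis=0)

    def summary(self) -> pd.DataFrame:
        lo, hi = self.rate_interval()
        return pd.DataFrame(
            {
                "township_id": self.townships,
                "rate": self.posterior_mean_rate(),
                "rate_lower": lo,
                "rate_upper": hi,
                "raw_rate": np.divide(
                    self.y, self.exposure, out=np.zeros_like(self.exposure),
                    where=self.exposure > 0,
                )
                * 1e5,
            }
        )


def _run_chain(
    y: np.ndarray,
    e: np.ndarray,
    adj: Adjacency,
    cfg: MCMCConfig,
    rng: np.random.Generator,
):
    n = adj.n
    a_mat, deg = adj.matrix, adj.degrees
    non_island = deg > 0
    labels = adj.component_labels
    rank_u = int(non_island.sum()) - adj.n_components  # ICAR rank
    sum_y = float(y.sum())
    a_hyp, b_hyp = cfg.hyper_a, cfg.hyper_b
    alpha_var = cfg.alpha_prior_sd**2

    alpha = float(np.log((sum_y + 0.5) / e.sum()))
    u = np.zeros(n)
    v = np.zeros(n)
    tau_u, tau_v = 10.0, 10.0
    sig_u = np.full(n, 0.3)
    sig_v = np.full(n, 0.3)
    sig_a = 0.1
    sig_tu, sig_tv = 1.0, 1.0
    acc_u = np.zeros(n)
    acc_v = np.zeros(n)
    acc_a = acc_tu = acc_tv = 0.0
    n_updates = 0

    n_keep = (cfg.n_iter - cfg.n_burnin) // cfg.thin
    out_alpha = np.empty(n_keep)
    out_u = np.empty((n_keep, n))
    out_v = np.empty((n_keep, n))
    out_tu = np.empty(n_keep)
    out_tv = np.empty(n_keep)
    kept = 0
    exp_u = np.exp(u)
    exp_v = np.exp(v)

    for it in range(cfg.n_iter):
        # --- u: per colour class, conditional prior N(nbr mean, 1/(tau_u d)) ---
        e_av = e * np.exp(alpha) * exp_v
        for cls in adj.color_classes:
            nbr = a_mat @ u
            m = nbr[cls] / deg[cls]
            cur = u[cls]
            prop = cur + sig_u[cls] * rng.standard_normal(len(cls))
            logr = (
                y[cls] * (prop - cur)
                - e_av[cls] * (np.exp(prop) - exp_u[cls])
                - 0.5 * tau_u * deg[cls] * ((prop - m) ** 2 - (cur - m) ** 2)
            )
            acc = np.log(rng.random(len(cls))) < logr
            u[cls] = np.where(acc, prop, cur)
            exp_u[cls] = np.where(acc, np.exp(prop), exp_u[cls])
            acc_u[cls] += acc

        # recentre u (ICAR identifiability); the mean moves into alpha so the
        # likelihood is untouched — for a connected map this is exact
        if adj.n_components == 1:
            m_all = u[non_island].mean()
            u[non_island] -= m_all
            alpha += m_all
        elif adj.n_components > 1:
            means = []
            for k in range(adj.n_components):
                m_k = labels == k
                mu_k = u[m_k].mean()
                u[m_k] -= mu_k
                means.append(mu_k)
            alpha += float(np.mean(means))
        exp_u = np.exp(u)

        # --- v: all sites at once (iid prior, conditionally independent) ---
        e_au = e * np.exp(alpha) * exp_u
        prop = v + sig_v * rng.standard_normal(n)
        logr = (
            y * (prop - v)
            - e_au * (np.exp(prop) - exp_v)
            - 0.5 * tau_v * (prop**2 - v**2)
        )
        acc = np.log(rng.random(n)) < logr
        v = np.where(acc, prop, v)
        exp_v = np.where(acc, np.exp(prop), exp_v)
        acc_v += acc

        # --- alpha: scalar random walk ---
        s = float(e @ (exp_u * exp_v))
        prop_a = alpha + sig_a * rng.standard_normal()
        logr_a = (
            sum_y * (prop_a - alpha)
            - s * (np.exp(prop_a) - np.exp(alpha))
            - (prop_a**2 - alpha**2) / (2 * alpha_var)
        )
        if np.log(rng.random()) < logr_a:
            alpha = prop_a
            acc_a += 1

        # --- precisions: conjugate Gibbs ---
        if cfg.fix_tau_u is not None:
            tau_u = cfg.fix_tau_u
        elif rank_u > 0:
            ss_u = float(u @ (deg * u) - u @ (a_mat @ u))
            tau_u = rng.gamma(a_hyp + 0.5 * rank_u, 1.0 / (b_hyp + 0.5 * ss_u))
        else:
            tau_u = rng.gamma(a_hyp, 1.0 / b_hyp)
        if cfg.fix_tau_v is not None:
            tau_v = cfg.fix_tau_v
        else:
            tau_v = rng.gamma(a_hyp + 0.5 * n, 1.0 / (b_hyp + 0.5 * float(v @ v)))

        # --- interweaving (ASIS): Metropolis on log tau in the non-centered
        # parameterization, rescaling the whole field; breaks the strong
        # coupling between each field and its precision ---
        ea = np.exp(alpha)
        if rank_u > 0 and cfg.fix_tau_u is None:
            lt = np.log(tau_u)
            lt_p = lt + sig_tu * rng.standard_normal()
            scale = np.exp(0.5 * (lt - lt_p))  # u' = u*sqrt(tau/tau')
            u_p = u * scale
            logr_t = (
                float(y @ (u_p - u))
                - float((ea * e * exp_v) @ (np.exp(u_p) - exp_u))
                + a_hyp * (lt_p - lt)
                - b_hyp * (np.exp(lt_p) - np.exp(lt))
            )
            if np.log(rng.random()) < logr_t:
                tau_u = float(np.exp(lt_p))
                u = u_p
                exp_u = np.exp(u)
                acc_tu += 1
        if cfg.fix_tau_v is None:
            lt = np.log(tau_v)
            lt_p = lt + sig_tv * rng.standard_normal()
            v_p = v * np.exp(0.5 * (lt - lt_p))
            logr_t = (
                float(y @ (v_p - v))
                - float((ea * e * exp_u) @ (np.exp(v_p) - exp_v))
                + a_hyp * (lt_p - lt)
                - b_hyp * (np.exp(lt_p) - np.exp(lt))
            )
            if np.log(rng.random()) < logr_t:
                tau_v = float(np.exp(lt_p))
                v = v_p
                exp_v = np.exp(v)
                acc_tv += 1

        # --- proposal adaptation, burn-in only ---
        n_updates += 1
        if it < cfg.n_burnin and n_updates == cfg.adapt_interval:
            sig_u *= np.exp(acc_u / n_updates - cfg.target_accept)
            sig_v *= np.exp(acc_v / n_updates - cfg.target_accept)
            sig_a *= float(np.exp(acc_a / n_updates - cfg.target_accept))
            sig_tu *= float(np.exp(acc_tu / n_updates - cfg.target_accept))
            sig_tv *= float(np.exp(acc_tv / n_updates - cfg.target_accept))
            acc_u[:] = 0.0
            acc_v[:] = 0.0
            acc_a = acc_tu = acc_tv = 0.0
            n_updates = 0
        elif it == cfg.n_burnin:
            acc_u[:] = 0.0
            acc_v[:] = 0.0
            acc_a = acc_tu = acc_tv = 0.0
            n_updates = 0

        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
            out_alpha[kept] = alpha
            out_u[kept] = u
            out_v[kept] = v
            out_tu[kept] = tau_u
            out_tv[kept] = tau_v
            kept += 1

    post_sweeps = max(cfg.n_iter - cfg.n_burnin, 1)
    acc_rates = {
        "u": float(acc_u[non_island].mean() / post_sweeps) if non_island.any() else 0.0,
        "v": float(acc_v.mean() / post_sweeps),
        "alpha": float(acc_a / post_sweeps),
    }
    return out_alpha[:kept], out_u[:kept], out_v[:kept], out_tu[:kept], out_tv[:kept], acc_rates


def fit_bym(
    y: np.ndarray,
    exposure: np.ndarray,
    adjacency: Adjacency,
    config: MCMCConfig | None = None,
) -> BYMPosterior:
    """Fit the BYM model to one stratum's counts and person-years.

    Parameters
    ----------
    y
        Event counts per township (non-negative integers, adjacency order).
    exposure
        Person-years per township, strictly positive.
    adjacency
        From :func:`build_adjacency`.
    config
        Sampler settings; chains differ only by their spawned RNG streams.
    """
    cfg = config or MCMCConfig()
    cfg.validate()
    y = np.asarray(y, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    if y.shape != (adjacency.n,) or exposure.shape != (adjacency.n,):
        raise ConfigError("y and exposure must have one entry per township")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ConfigError("counts must be non-negative integers")
    if np.any(exposure <= 0):
        raise ConfigError("exposures must be strictly positive")
    if y.sum() == 0:
        warnings.warn(
            "all counts are zero; posterior will be dominated by the priors",
            stacklevel=2,
        )
    ss = np.random.SeedSequence(cfg.seed)
    chains = [
        _run_chain(y, exposure, adjacency, cfg, np.random.default_rng(child))
        for child in ss.spawn(cfg.n_chains)
    ]
    alpha = np.stack([c[0] for c in chains])
    u = np.stack([c[1] for c in chains])
    v = np.stack([c[2] for c in chains])
    tau_u = np.stack([c[3] for c in chains])
    tau_v = np.stack([c[4] for c in chains])
    acc = {k: float(np.mean([c[5][k] for c in chains])) for k in chains[0][5]}
    return BYMPosterior(
        townships=list(adjacency.townships),
        y=y.astype(int),
        exposure=exposure,
        alpha=alpha,
        u=u,
        v=v,
        tau_u=tau_u,
        tau_v=tau_v,
        config=cfg,
        acceptance=acc,
    )


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------


@dataclass
class ConvergenceReport:
    rhat: dict[str, float]
    ess: dict[str, float]
    flagged: list[str]
    ok: bool


def check_convergence(
    posterior: BYMPosterior, threshold: float = 1.05, n_spatial: int = 10, seed: int = 0
) -> ConvergenceReport:
    """Split-R-hat and effective sample size for the scalar parameters and a
    random subset of spatial effects; flags any parameter with R-hat above
    `threshold`."""
    import arviz as az

    if posterior.alpha.shape[0] < 2:
        raise ConfigError("convergence diagnostics need at least 2 chains")
    rng = np.random.default_rng(seed)
    n = len(posterior.townships)
    pick = rng.choice(n, size=min(n_spatial, n), replace=False)
    params: dict[str, np.ndarray] = {
        "alpha": posterior.alpha,
        "tau_u": posterior.tau_u,
        "tau_v": posterior.tau_v,
    }
    for i in sorted(pick):
        params[f"u[{posterior.townships[i]}]"] = posterior.u[:, :, i]
    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, draws in params.items():
            data = az.convert_to_dataset(draws[..., None])
            r = float(az.rhat(data)["x"].values[0])
            e = float(az.ess(data)["x"].values[0])
            rhat[name] = r
            ess[name] = e
    flagged = [k for k, r in rhat.items() if not np.isfinite(r) or r > threshold]
    degenerate = [k for k, r in rhat.items() if not np.isfinite(r)]
    identical = any(
        np.array_equal(posterior.alpha[0], posterior.alpha[c])
        for c in range(1, posterior.alpha.shape[0])
    )
    if degenerate or identical:
        warnings.warn(
            "degenerate R-hat: identical or constant chains "
            f"({degenerate or 'duplicate chain draws'})",
            stacklevel=2,
        )
    return ConvergenceReport(rhat=rhat, ess=ess, flagged=flagged, ok=not flagged)


# ---------------------------------------------------------------------------
# Multi-stratum fitting
# ---------------------------------------------------------------------------


def fit_all_strata(
    counts: pd.DataFrame,
    person_years: pd.DataFrame,
    adjacency: Adjacency,
    config: MCMCConfig | None = None,
    progress: bool = False,
) -> dict[tuple[str, str, str], BYMPosterior]:
    """Fit one BYM model per (sex, age_group, period) stratum.

    `counts` needs columns township_id, sex, age_group, period, count;
    `person_years` the same keys with person_years. Every stratum present
    in counts must have exposures for every township; missing entries
    raise. Each stratum gets its own seed spawned from config.seed.
    """
    cfg = config or MCMCConfig()
    cfg.validate()
    merged = counts.merge(
        person_years, on=["township_id", "sex", "age_group", "period"], how="left"
    )
    if merged["person_years"].isna().any():
        bad = merged.loc[merged["person_years"].isna()].head(5)
        raise ConfigError(f"missing person-years for strata:\n{bad}")
    strata = sorted(
        merged[["sex", "age_group", "period"]].drop_duplicates().itertuples(index=False)
    )
    order = {t: i for i, t in enumerate(adjacency.townships)}
    posteriors: dict[tuple[str, str, str], BYMPosterior] = {}
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.generate_state(len(strata)) % (2**31)
    for k, (sex, age, period) in enumerate(strata):
        sub = merged[
            (merged["sex"] == sex)
            & (merged["age_group"] == age)
            & (merged["period"] == period)
        ]
        if set(sub["township_id"]) != set(adjacency.townships):
            missing = sorted(set(adjacency.townships) - set(sub["township_id"]))
            raise ConfigError(
                f"stratum ({sex}, {age}, {period}) missing townships {missing[:5]}"
            )
        sub = sub.iloc[np.argsort(sub["township_id"].map(order).to_numpy())]
        scfg = MCMCConfig(**{**cfg.__dict__, "seed": int(seeds[k])})
        posteriors[(sex, age, period)] = fit_bym(
            sub["count"].to_numpy(),
            sub["person_years"].to_numpy(),
            adjacency,
            scfg,
        )
        if progress:
            print(f"fitted stratum {sex}/{age}/{period}", flush=True)
    return posteriors


def posterior_rate_table(
    posteriors: dict[tuple[str, str, str], BYMPosterior],
) -> pd.DataFrame:
    """Long table of posterior-mean rates per township stratum.

    Columns: township_id, sex, age_group, period, rate (posterior mean per
    100,000 person-years), rate_lower, rate_upper, raw_rate.
    """
    if not posteriors:
        raise ConfigError("no fitted strata supplied")
    frames = []
    for (sex, age, period), post in posteriors.items():
        s = post.summary()
        s.insert(1, "sex", sex)
        s.insert(2, "age_group", age)
        s.insert(3, "period", period)
        frames.append(s)
    out = pd.concat(frames, ignore_index=True)
    if (out["rate"] <= 0).any():
        raise ConfigError("non-positive posterior rate produced")
    return out
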