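"""Hierarchical Bayesian estimation of shape-to-shape coupling.

For one waveform feature, the neural feature value of each matched cycle is
regressed on the respiration feature value with a within-between
decomposition: the respiration predictor is split into a subject-mean-
centered *within* component (scaled by the pooled within-subject SD) and a
grand-mean-centered *between* component of subject means (scaled by the
between-subject SD); the neural outcome is standardized by its pooled SD.
The within-subject slope ``beta_within`` then measures cycle-by-cycle
coupling in SD units, comparable across features.

Model (Student-t likelihood to accommodate skewed/heavy-tailed features)::

    y_i ~ StudentT(nu, mu_i, sigma)
    mu_i = alpha + beta_within * xw_i + beta_between * xb_i
           + u_subject[s_i] + u_channel[c_i] + w_subject[s_i] * xw_i

with weakly informative priors: beta ~ Normal(0, 1) on all fixed effects,
alpha ~ Normal(0, 2), all variance components ~ Exponential(1), and
nu ~ Gamma(2, 0.1). Random effects are intercepts for subject and
channel-within-subject plus a by-subject random within-slope (droppable for
small designs, where it is weakly identified).

Posteriors are sampled with an affine-invariant/differential-evolution
ensemble sampler (:mod:`emcee`) on a non-centered parameterization, with
positive parameters sampled on the log scale. The ``chains``/``iterations``/
``warmup`` interface is kept: ``iterations`` is the number of ensemble steps,
``warmup`` steps are discarded, and the walkers serve as (many) chains for
the split-Rhat diagnostic.

Matched null models permute the within-subject predictor across cycles
within each subject -- destroying cycle-by-cycle pairing while preserving
the predictor distribution and the multilevel structure -- and are fit with
identical priors and sampler settings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import t as student_t
from scipy.stats import wilcoxon

from .cycles import SHAPE_FEATURES
from .exceptions import InsufficientDataError, InvalidArgumentError

__all__ = [
    "WithinBetweenDesign", "build_design", "ShapeCouplingModel",
    "CouplingResults", "fit_coupling_model", "fit_null_model",
    "compare_modalities",
]


# --------------------------------------------------------------------------
# design


@dataclass
class WithinBetweenDesign:
    """Standardized within/between design for one waveform feature."""

    y: np.ndarray             # standardized neural feature
    xw: np.ndarray            # within-subject respiration component
    xb: np.ndarray            # between-subject respiration component
    subject_idx: np.ndarray   # 0..S-1 per row
    channel_idx: np.ndarray   # 0..C-1 per row (channels nested in subjects)
    subject_ids: list
    channel_ids: list
    feature: str = ""
    is_null: bool = False

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def permuted_within(self, seed: int) -> "WithinBetweenDesign":
        """Copy with xw randomly permuted across cycles within each subject."""
        rng = np.random.default_rng(seed)
        xw = self.xw.copy()
        for s in range(self.n_subjects):
            idx = np.nonzero(self.subject_idx == s)[0]
            xw[idx] = xw[rng.permutation(idx)]
        return replace(self, xw=xw, is_null=True)


def build_design(rows: pd.DataFrame, feature: str,
                 resp_prefix: str = "resp_",
                 neural_prefix: str = "neural_") -> WithinBetweenDesign:
    """Build the standardized within-between design from a cycle table.

    ``rows`` is a tidy matched-cycle table with ``resp_<feature>`` /
    ``neural_<feature>`` columns plus subject and channel ids. Needs at
    least 20 cycles; with a single subject the between component is zero
    (with a warning) and only the within slope is estimable.
    """
    ycol, xcol = neural_prefix + feature, resp_prefix + feature
    for col in (ycol, xcol, "subject_id", "channel_id"):
        if col not in rows.columns:
            raise InvalidArgumentError(f"missing column {col!r}")
    df = rows[[ycol, xcol, "subject_id", "channel_id"]].dropna()
    if len(df) < 20:
        raise InsufficientDataError(
            f"need >= 20 cycles, got {len(df)} for {feature!r}")

    subject_ids = sorted(df["subject_id"].unique().tolist())
    s_map = {s: i for i, s in enumerate(subject_ids)}
    subject_idx = df["subject_id"].map(s_map).to_numpy()
    chan_keys = sorted(set(zip(df["subject_id"], df["channel_id"])))
    c_map = {k: i for i, k in enumerate(chan_keys)}
    channel_idx = np.array([c_map[k] for k in
                            zip(df["subject_id"], df["channel_id"])])

    x = df[xcol].to_numpy(dtype=float)
    y = df[ycol].to_numpy(dtype=float)
    subj_means = np.array([x[subject_idx == i].mean()
                           for i in range(len(subject_ids))])
    xw = x - subj_means[subject_idx]
    sd_w = xw.std()
    if sd_w == 0:
        raise InvalidArgumentError(f"{xcol} has no within-subject variance")
    xw = xw / sd_w
    if len(subject_ids) >= 2:
        xb_vals = subj_means - subj_means.mean()
        sd_b = xb_vals.std()
        xb = (xb_vals[subject_idx] / sd_b if sd_b > 0
              else np.zeros_like(xw))
    else:
        warnings.warn("single subject: between component set to zero",
                      stacklevel=2)
        xb = np.zeros_like(xw)
    sd_y = y.std()
    if sd_y == 0:
        raise InvalidArgumentError(f"{ycol} has no variance")
    y = (y - y.mean()) / sd_y
    return WithinBetweenDesign(
        y=y, xw=xw, xb=xb, subject_idx=subject_idx, channel_idx=channel_idx,
        subject_ids=subject_ids, channel_ids=chan_keys, feature=feature)


# --------------------------------------------------------------------------
# model


class ShapeCouplingModel:
    """Hierarchical Student-t within-between regression for one feature.

    Statsmodels-style: construct from a design (or a matched-cycle table via
    :meth:`from_cycles`), then :meth:`fit` returns a
    :class:`CouplingResults`.

    Parameters
    ----------
    design : WithinBetweenDesign
    include_random_slope : bool, optional
        Random by-subject within-slope. Defaults to True when the design has
        at least 5 subjects (below that the slope SD is weakly identified).
    """

    def __init__(self, design: WithinBetweenDesign,
                 include_random_slope: bool | None = None):
        if design.n_obs == 0:
            raise InvalidArgumentError("empty design")
        self.design = design
        if include_random_slope is None:
            include_random_slope = design.n_subjects >= 5
        self.include_random_slope = bool(include_random_slope)
        S, C = design.n_subjects, design.n_channels
        names = ["alpha", "beta_within", "beta_between",
                 "log_sigma", "log_nu", "log_sd_subject", "log_sd_channel"]
        if self.include_random_slope:
            names.append("log_sd_slope")
        names += [f"z_subject[{i}]" for i in range(S)]
        names += [f"z_channel[{i}]" for i in range(C)]
        if self.include_random_slope:
            names += [f"z_slope[{i}]" for i in range(S)]
        self.param_names = names
        self.ndim = len(names)
        self._n_fixed = 8 if self.include_random_slope else 7

    @classmethod
    def from_cycles(cls, rows: pd.DataFrame, feature: str,
                    include_random_slope: bool | None = None,
                    ) -> "ShapeCouplingModel":
        return cls(build_design(rows, feature),
                   include_random_slope=include_random_slope)

    # -------------------------------------------------------- log posterior

    def _unpack(self, theta: np.ndarray):
        d = self.design
        S, C = d.n_subjects, d.n_channels
        k = self._n_fixed
        alpha, bw, bb = theta[:, 0], theta[:, 1], theta[:, 2]
        log_scales = np.clip(theta[:, 3:k], -15.0, 15.0)
        sigma = np.exp(log_scales[:, 0])
        nu = np.exp(log_scales[:, 1])
        sd_s = np.exp(log_scales[:, 2])
        sd_c = np.exp(log_scales[:, 3])
        sd_w = np.exp(log_scales[:, 4]) if self.include_random_slope else None
        z_s = theta[:, k:k + S]
        z_c = theta[:, k + S:k + S + C]
        z_w = (theta[:, k + S + C:k + S + C + S]
               if self.include_random_slope else None)
        return alpha, bw, bb, sigma, nu, sd_s, sd_c, sd_w, z_s, z_c, z_w, log_scales

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        """Vectorized log posterior for a (walkers, ndim) parameter block."""
        theta = np.atleast_2d(theta)
        d = self.design
        (alpha, bw, bb, sigma, nu, sd_s, sd_c, sd_w,
         z_s, z_c, z_w, log_scales) = self._unpack(theta)

        mu = (alpha[:, None]
              + bw[:, None] * d.xw[None, :]
              + bb[:, None] * d.xb[None, :]
              + (sd_s[:, None] * z_s)[:, d.subject_idx]
              + (sd_c[:, None] * z_c)[:, d.channel_idx])
        if self.include_random_slope:
            mu = mu + (sd_w[:, None] * z_w)[:, d.subject_idx] * d.xw[None, :]

        r2 = ((d.y[None, :] - mu) / sigma[:, None]) ** 2
        nu_col = nu[:, None]
        ll = (gammaln((nu + 1.0) / 2.0) - gammaln(nu / 2.0)
              - 0.5 * np.log(np.pi * nu) - np.log(sigma)) * d.n_obs
        ll = ll - 0.5 * np.sum((nu_col + 1.0) * np.log1p(r2 / nu_col), axis=1)

        lp = -alpha ** 2 / 8.0 - bw ** 2 / 2.0 - bb ** 2 / 2.0
        # Exponential(1) scales, sampled on the log scale (Jacobian included)
        for j in (0, 2, 3) + ((4,) if self.include_random_slope else ()):
            lp += log_scales[:, j] - np.exp(log_scales[:, j])
        # nu ~ Gamma(2, 0.1), log-scale: 2*log(nu) - 0.1*nu
        lp += 2.0 * log_scales[:, 1] - 0.1 * nu
        lp -= 0.5 * np.sum(z_s ** 2, axis=1)
        lp -= 0.5 * np.sum(z_c ** 2, axis=1)
        if self.include_random_slope:
            lp -= 0.5 * np.sum(z_w ** 2, axis=1)
        out = ll + lp
        out[~np.isfinite(out)] = -np.inf
        return out

    # ------------------------------------------------------------- fitting

    def _initial_state(self, n_walkers: int,
                       rng: np.random.Generator) -> np.ndarray:
        d = self.design
        bw0 = float(np.clip(np.cov(d.y, d.xw)[0, 1] / max(d.xw.var(), 1e-12),
                            -2.0, 2.0))
        resid_sd = float(max(np.std(d.y - bw0 * d.xw), 0.05))
        center = np.zeros(self.ndim)
        center[1] = bw0
        center[3] = np.log(resid_sd)
        center[4] = np.log(10.0)       # nu
        center[5] = center[6] = np.log(0.2)
        if self.include_random_slope:
            center[7] = np.log(0.1)
        p0 = center + 0.05 * rng.standard_normal((n_walkers, self.ndim))
        return p0

    def fit(self, chains: int = 4, iterations: int = 3000,
            warmup: int = 1500, seed: int | None = None,
            n_walkers: int | None = None, thin: int = 1,
            progress: bool = False) -> "CouplingResults":
        """Sample the posterior.

        ``chains`` independent walker ensembles are each run for
        ``iterations`` steps, discarding the first ``warmup``; every ensemble
        yields ``n_walkers`` draws per retained step, so the total draw count
        far exceeds a one-draw-per-iteration sampler at the same settings.
        The Rhat diagnostic compares the independent ensembles.
        """
        import emcee

        if warmup >= iterations:
            raise InvalidArgumentError("warmup must be < iterations")
        if chains < 1:
            raise InvalidArgumentError("need >= 1 chain")
        if n_walkers is None:
            n_walkers = 2 * self.ndim + 2
        n_walkers += n_walkers % 2
        seed_seq = np.random.SeedSequence(
            seed if seed is not None else np.random.randint(2 ** 31))
        ensembles = []
        acc = []
        for child in seed_seq.spawn(chains):
            rng = np.random.default_rng(child)
            p0 = self._initial_state(n_walkers, rng)
            sampler = emcee.EnsembleSampler(
                n_walkers, self.ndim, self.log_prob, vectorize=True,
                moves=[(emcee.moves.DEMove(), 0.8),
                       (emcee.moves.DESnookerMove(), 0.2)])
            # the setter expects a RandomState *state tuple* (anything else
            # is silently ignored, leaving the sampler unseeded)
            sampler.random_state = np.random.RandomState(
                int(rng.integers(2 ** 31))).get_state()
            sampler.run_mcmc(p0, iterations, progress=progress)
            ensembles.append(sampler.get_chain(discard=warmup, thin=thin))
            acc.append(sampler.acceptance_fraction.mean())
        # (chains, T, W, D)
        chain = np.stack(ensembles)
        return CouplingResults(model=self, chain=chain,
                               is_null_model=self.design.is_null,
                               sampler_info=dict(
                                   chains=chains, iterations=iterations,
                                   warmup=warmup, n_walkers=n_walkers,
                                   acceptance=float(np.mean(acc))))


# --------------------------------------------------------------------------
# results


class CouplingResults:
    """Posterior draws and summaries for one fitted coupling model."""

    def __init__(self, model: ShapeCouplingModel, chain: np.ndarray,
                 is_null_model: bool = False, sampler_info: dict | None = None):
        self.model = model
        self.chain = chain                      # (chains, draws, walkers, ndim)
        self.is_null_model = bool(is_null_model)
        self.sampler_info = sampler_info or {}
        self._rhat = None
        if self.rhat_max >= 1.01:
            self.converged = False
            warnings.warn(
                f"MCMC may not have converged (max Rhat = {self.rhat_max:.3f})",
                stacklevel=2)
        else:
            self.converged = True

    # ------------------------------------------------------------- helpers

    def _draws(self, name: str) -> np.ndarray:
        j = self.model.param_names.index(name)
        return self.chain[..., j].ravel()

    def posterior_draws(self, name: str) -> np.ndarray:
        """Flattened posterior draws on the natural scale."""
        if name.startswith("log_"):
            raise KeyError("ask for the natural-scale name")
        if name in self.model.param_names:
            return self._draws(name)
        if "log_" + name in self.model.param_names:
            return np.exp(self._draws("log_" + name))
        raise KeyError(name)

    @property
    def beta_within_draws(self) -> np.ndarray:
        return self._draws("beta_within")

    @property
    def beta_within_median(self) -> float:
        return float(np.median(self.beta_within_draws))

    @property
    def cri95(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.beta_within_draws, [2.5, 97.5])
        return float(lo), float(hi)

    @property
    def p_positive(self) -> float:
        return float(np.mean(self.beta_within_draws > 0))

    @property
    def rhat_max(self) -> float:
        if self._rhat is None:
            self._rhat = {
                name: _ensemble_rhat(self.chain[..., j])
                for j, name in enumerate(self.model.param_names)
            }
        return float(max(self._rhat.values()))

    @property
    def rhat(self) -> dict:
        _ = self.rhat_max
        return dict(self._rhat)

    # ------------------------------------------------------------ summary

    def summary(self) -> pd.DataFrame:
        """Posterior summary table for the main parameters."""
        rows = []
        display = ["alpha", "beta_within", "beta_between",
                   "sigma", "nu", "sd_subject", "sd_channel"]
        if self.model.include_random_slope:
            display.append("sd_slope")
        _ = self.rhat_max
        for name in display:
            d = self.posterior_draws(name)
            lo, hi = np.percentile(d, [2.5, 97.5])
            key = name if name in self.model.param_names else "log_" + name
            rows.append(dict(param=name, median=float(np.median(d)),
                             cri_2_5=float(lo), cri_97_5=float(hi),
                             p_positive=float(np.mean(d > 0)),
                             rhat=self._rhat[key]))
        return pd.DataFrame(rows).set_index("param")

    def __repr__(self) -> str:
        lo, hi = self.cri95
        kind = "null" if self.is_null_model else "real"
        return (f"<CouplingResults [{kind}] feature={self.model.design.feature!r} "
                f"beta_within={self.beta_within_median:.3f} "
                f"95% CrI [{lo:.3f}, {hi:.3f}] "
                f"P(beta>0)={self.p_positive:.3f} "
                f"max Rhat={self.rhat_max:.3f}>")

    # ---------------------------------------------------------- diagnostics

    def ppc_coverage(self, levels: tuple[float, ...] = (0.5, 0.9),
                     n_draws: int = 200, seed: int = 0) -> dict[float, float]:
        """Posterior-predictive central-interval coverage of the data.

        For each retained draw the predictive distribution of every
        observation is Student-t(nu, mu_i, sigma); coverage is the fraction
        of observations falling inside the central ``level`` interval,
        averaged over draws. Well-calibrated models give coverage near the
        nominal level.
        """
        d = self.model.design
        flat = self.chain.reshape(-1, self.model.ndim)
        rng = np.random.default_rng(seed)
        take = rng.choice(flat.shape[0], size=min(n_draws, flat.shape[0]),
                          replace=False)
        theta = flat[take]
        (alpha, bw, bb, sigma, nu, sd_s, sd_c, sd_w,
         z_s, z_c, z_w, _) = self.model._unpack(theta)
        mu = (alpha[:, None] + bw[:, None] * d.xw[None, :]
              + bb[:, None] * d.xb[None, :]
              + (sd_s[:, None] * z_s)[:, d.subject_idx]
              + (sd_c[:, None] * z_c)[:, d.channel_idx])
        if self.model.include_random_slope:
            mu = mu + (sd_w[:, None] * z_w)[:, d.subject_idx] * d.xw[None, :]
        z = np.abs(d.y[None, :] - mu) / sigma[:, None]
        out = {}
        for level in levels:
            q = student_t.ppf(0.5 + level / 2.0, nu)[:, None]
            out[level] = float(np.mean(z < q))
        return out

    def plot_posterior(self, ax=None, **hist_kw):
        """Histogram of the beta_within posterior (null models in gray)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        color = "0.6" if self.is_null_model else "C0"
        hist_kw.setdefault("bins", 60)
        hist_kw.setdefault("density", True)
        ax.hist(self.beta_within_draws, color=color, alpha=0.7, **hist_kw)
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel(r"$\beta_\mathrm{within}$")
        ax.set_ylabel("posterior density")
        return ax


def _ensemble_rhat(chain_3d: np.ndarray) -> float:
    """Rhat across independent ensembles for one parameter.

    ``chain_3d`` is (chains, draws, walkers). Each ensemble's pooled draws
    form one chain in step-major order; a single ensemble is split into its
    first and second halves. Within-walker trajectories are too correlated
    to serve as chains themselves, so convergence is judged between
    independently initialized ensembles, matching the between/within-chain
    variance comparison the diagnostic is built on.
    """
    import arviz as az

    n_chains, draws, walkers = chain_3d.shape
    if n_chains == 1:
        half = draws // 2
        if half < 2:
            return np.nan
        seqs = np.stack([chain_3d[0, :half].reshape(-1),
                         chain_3d[0, half:2 * half].reshape(-1)])
    else:
        seqs = chain_3d.reshape(n_chains, draws * walkers)
    return float(az.rhat(seqs))


# --------------------------------------------------------------------------
# convenience wrappers


def fit_coupling_model(design: WithinBetweenDesign, chains: int = 4,
                       iterations: int = 3000, warmup: int = 1500,
                       seed: int | None = None, **kw) -> CouplingResults:
    """Fit the real coupling model for one design."""
    return ShapeCouplingModel(design).fit(chains=chains, iterations=iterations,
                                          warmup=warmup, seed=seed, **kw)


def fit_null_model(design: WithinBetweenDesign, seed: int, chains: int = 4,
                   iterations: int = 3000, warmup: int = 1500,
                   **kw) -> CouplingResults:
    """Fit the cycle-shuffled null model with identical settings."""
    null_design = design.permuted_within(seed)
    return ShapeCouplingModel(null_design).fit(
        chains=chains, iterations=iterations, warmup=warmup, seed=seed, **kw)


# --------------------------------------------------------------------------
# modality comparison


def compare_modalities(airflow_rows: pd.DataFrame, belt_rows: pd.DataFrame,
                       features: tuple[str, ...] = SHAPE_FEATURES,
                       prefix: str = "resp_") -> pd.DataFrame:
    """Paired Wilcoxon comparison of airflow vs belt waveform features.

    Per feature, the median across cycles is computed per participant in each
    modality and paired differences are tested with the two-sided Wilcoxon
    signed-rank test (exact null for n <= 25). All-zero differences are
    reported with a degenerate flag and p = 1.
    """
    a_med = airflow_rows.groupby("subject_id").median(numeric_only=True)
    b_med = belt_rows.groupby("subject_id").median(numeric_only=True)
    common = sorted(set(a_med.index) & set(b_med.index))
    if len(common) < 5:
        raise InsufficientDataError(
            f"need >= 5 participants with both modalities, got {len(common)}")
    rows = []
    for feat in features:
        col = prefix + feat
        d = (a_med.loc[common, col] - b_med.loc[common, col]).to_numpy()
        degenerate = bool(np.allclose(d, 0.0))
        if degenerate:
            stat, p = np.nan, 1.0
        else:
            method = "exact" if len(d) <= 25 else "approx"
            stat, p = wilcoxon(d, alternative="two-sided", method=method,
                               correction=(method == "approx"))
        rows.append(dict(feature=feat, n_pairs=len(common),
                         median_difference=float(np.median(d)),
                         statistic=float(stat), p_value=float(p),
                         degenerate=degenerate))
    return pd.DataFrame(rows).set_index("feature")
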