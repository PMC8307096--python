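"""Hierarchical Bayesian two-group GLMs with data-scaled priors.

Two models share one sampler:

* score model — ``y_i = beta0 + beta_g(i) + eps_i``
* metabolite model — ``y_i = beta0 + beta_g(i) + beta_cov * x_i + eps_i``

with ``eps_i ~ N(0, sigma_i^2)``. Priors are scaled from the data:

* ``beta0 ~ N(mean(y), (5 SD(y))^2)`` — wide, anchored at the data mean;
* ``beta_g ~ N(0, sigma_beta^2)`` for each group deflection, with the
  shared hyperprior ``sigma_beta ~ Gamma(shape = SD(y)/2, rate = 2 SD(y))``
  so the groups act as priors on each other (shrinkage);
* ``sigma_i ~ Uniform(SD(y)/1000, 1000 SD(y))`` — wide data-scaled bounds;
* ``beta_cov ~ N(0, (2 SD(y)/SD(x))^2)`` when a covariate is present; the
  covariate is mean-centered before fitting.

Sampling is Metropolis-within-Gibbs: conjugate normal updates for the
regression coefficients, adaptive random-walk updates on ``log sigma_i`` and
``log sigma_beta``. Retained draws are recentered per draw to the
sum-to-zero parameterization (baseline absorbs the deflection mean; the two
deflections become exact negatives), which identifies the group effect. The
reported between-group difference is the per-draw deflection difference and
the effect size is that difference divided by the per-draw ``sigma_i``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .posterior import PosteriorSamples, PosteriorSummary, effective_sample_size

__all__ = [
    "GlmPriorSpec",
    "GlmPosterior",
    "build_priors",
    "fit_group_model",
    "fit_group_covariate_model",
    "group_difference",
]


@dataclass(frozen=True)
class GlmPriorSpec:
    """Data-scaled hyperparameters of the hierarchical group GLM."""

    beta0_mean: float
    beta0_sd: float
    sigma_i_low: float
    sigma_i_high: float
    sigma_beta_shape: float
    sigma_beta_rate: float
    beta_cov_sd: float | None = None

    def __post_init__(self):
        if self.beta0_sd <= 0 or self.sigma_beta_shape <= 0 or self.sigma_beta_rate <= 0:
            raise ValueError("prior scales must be positive")
        if not 0 < self.sigma_i_low < self.sigma_i_high:
            raise ValueError("sigma_i bounds must satisfy 0 < low < high")
        if self.beta_cov_sd is not None and self.beta_cov_sd <= 0:
            raise ValueError("beta_cov_sd must be positive")


def build_priors(y, covariate=None) -> GlmPriorSpec:
    """Derive the prior hyperparameters from the response (and covariate) SDs.

    ``beta0``: normal, mean = mean(y), SD = 5 SD(y). ``sigma_i``: uniform on
    (SD(y)/1000, 1000 SD(y)). ``sigma_beta``: gamma with shape SD(y)/2 and
    rate 2 SD(y). With a covariate, ``beta_cov`` gets prior SD
    2 SD(y) / SD(covariate).
    """
    yv = np.asarray(y, dtype=float).ravel()
    yv = yv[np.isfinite(yv)]
    if yv.size < 3:
        raise DegenerateInputError(f"need >= 3 observations to scale priors, got {yv.size}")
    sd = float(yv.std(ddof=1))
    if sd == 0:
        raise DegenerateInputError("zero-variance response")
    beta_cov_sd = None
    if covariate is not None:
        cv = np.asarray(covariate, dtype=float).ravel()
        cv = cv[np.isfinite(cv)]
        sd_cov = float(cv.std(ddof=1)) if cv.size > 1 else 0.0
        if sd_cov == 0:
            raise DegenerateInputError("zero-variance covariate")
        beta_cov_sd = 2.0 * sd / sd_cov
    return GlmPriorSpec(
        beta0_mean=float(yv.mean()),
        beta0_sd=5.0 * sd,
        sigma_i_low=sd / 1000.0,
        sigma_i_high=sd * 1000.0,
        sigma_beta_shape=sd / 2.0,
        sigma_beta_rate=2.0 * sd,
        beta_cov_sd=beta_cov_sd,
    )


@dataclass
class GlmPosterior:
    """Posterior of a fitted group GLM: draws, per-parameter summaries, contrasts."""

    samples: PosteriorSamples
    summaries: dict
    difference: PosteriorSummary
    effect_size: PosteriorSummary
    labels: tuple[str, str]
    spec: GlmPriorSpec = field(repr=False, default=None)

    def deflection(self, label: str) -> np.ndarray:
        name = f"beta_{label}"
        if name not in self.samples.draws.columns:
            raise KeyError(f"unknown group label {label!r}")
        return self.samples.column(name)


class _AdaptiveLogScale:
    """Random-walk scale on a log-transformed positive parameter."""

    def __init__(self, scale: float = 0.3):
        self.scale = scale
        self.acc = 0
        self.n = 0
        self.window = 0

    def adapt(self):
        if self.n >= 50:
            self.window += 1
            rate = self.acc / self.n
            self.scale *= math.exp((rate - 0.4) / math.sqrt(self.window))
            self.scale = float(np.clip(self.scale, 1e-3, 5.0))
            self.acc = self.n = 0


def _fit(
    y: np.ndarray,
    groups: np.ndarray,
    cov: np.ndarray | None,
    spec: GlmPriorSpec,
    n_kept: int,
    thin: int,
    burn_in: int,
    seed: int,
) -> GlmPosterior:
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise DegenerateInputError(f"exactly two groups required, got {labels}")
    masks = [groups == lab for lab in labels]
    counts = [int(m.sum()) for m in masks]
    for lab, c in zip(labels, counts):
        if c == 0:
            raise DegenerateInputError(f"group {lab!r} is empty")
        if c < 2:
            warnings.warn(
                f"group {lab!r} has a single member; its deflection posterior will be wide",
                stacklevel=3,
            )
    if n_kept < 1000:
        raise ValueError("n_kept must be at least 1000")
    n = y.size
    has_cov = cov is not None
    if has_cov:
        cov = cov - cov.mean()  # center so beta0 keeps its data-mean anchoring
        sxx_cov = float(cov @ cov)
        if sxx_cov == 0:
            # inert covariate: keep the column but it never moves the fit
            pass

    # independent streams per parameter block so an inert block cannot
    # perturb the other blocks' draws
    ss = np.random.SeedSequence(seed)
    rng_b0, rng_bg, rng_bc, rng_si, rng_sb = [np.random.default_rng(s) for s in ss.spawn(5)]

    # initialization at data-driven values
    beta0 = float(y.mean())
    betas = np.array([float(y[m].mean()) - beta0 for m in masks])
    beta_c = 0.0
    resid = y - beta0 - betas[0] * masks[0] - betas[1] * masks[1]
    if has_cov:
        resid = resid - beta_c * cov
    sigma_i = float(np.clip(resid.std(ddof=1) or spec.sigma_i_low * 10,
                            spec.sigma_i_low, spec.sigma_i_high))
    sigma_b = float(max(abs(betas).max(), 0.1 * spec.beta0_sd / 5.0))

    si_walk = _AdaptiveLogScale()
    sb_walk = _AdaptiveLogScale()

    total_burn = burn_in * thin
    total = total_burn + n_kept * thin
    cols = ["beta0", f"beta_{labels[0]}", f"beta_{labels[1]}", "sigma_beta", "sigma_i"]
    if has_cov:
        cols.append("beta_cov")
    out = np.empty((n_kept, len(cols)))

    gmask0, gmask1 = masks
    n0, n1 = counts
    prior_prec0 = 1.0 / spec.beta0_sd**2
    prec_cov = 1.0 / spec.beta_cov_sd**2 if has_cov else None

    for t in range(total):
        inv_s2 = 1.0 / sigma_i**2
        # beta0 | rest — conjugate normal
        r = y - betas[0] * gmask0 - betas[1] * gmask1
        if has_cov:
            r = r - beta_c * cov
        prec = n * inv_s2 + prior_prec0
        mu = (r.sum() * inv_s2 + spec.beta0_mean * prior_prec0) / prec
        beta0 = mu + rng_b0.standard_normal() / math.sqrt(prec)

        # group deflections | rest — conjugate normal, shared sigma_beta prior
        prec_b = 1.0 / sigma_b**2
        for k, (m, nk) in enumerate(zip(masks, counts)):
            rk = y[m] - beta0
            if has_cov:
                rk = rk - beta_c * cov[m]
            prec = nk * inv_s2 + prec_b
            mu = (rk.sum() * inv_s2) / prec
            betas[k] = mu + rng_bg.standard_normal() / math.sqrt(prec)

        # covariate slope | rest — conjugate normal
        if has_cov:
            rc = y - beta0 - betas[0] * gmask0 - betas[1] * gmask1
            prec = sxx_cov * inv_s2 + prec_cov
            mu = (float(cov @ rc) * inv_s2) / prec
            beta_c = mu + rng_bc.standard_normal() / math.sqrt(prec)

        # sigma_i | rest — random walk on log scale inside the uniform bounds
        resid = y - beta0 - betas[0] * gmask0 - betas[1] * gmask1
        if has_cov:
            resid = resid - beta_c * cov
        ssr = float(resid @ resid)

        def logp_si(s):
            # uniform prior on s; Jacobian of the log transform adds +log s
            return -n * math.log(s) - ssr / (2.0 * s * s) + math.log(s)

        prop = sigma_i * math.exp(si_walk.scale * rng_si.standard_normal())
        si_walk.n += 1
        if spec.sigma_i_low < prop < spec.sigma_i_high:
            if math.log(rng_si.random()) < logp_si(prop) - logp_si(sigma_i):
                sigma_i = prop
                si_walk.acc += 1
        if t < total_burn:
            si_walk.adapt()

        # sigma_beta | rest — random walk on log scale, gamma prior on the SD
        sb_sq = float(betas @ betas)

        def logp_sb(s):
            return (
                (spec.sigma_beta_shape - 1.0) * math.log(s)
                - spec.sigma_beta_rate * s
                - 2.0 * math.log(s)
                - sb_sq / (2.0 * s * s)
                + math.log(s)
            )

        prop = sigma_b * math.exp(sb_walk.scale * rng_sb.standard_normal())
        sb_walk.n += 1
        if prop > 0 and math.log(rng_sb.random()) < logp_sb(prop) - logp_sb(sigma_b):
            sigma_b = prop
            sb_walk.acc += 1
        if t < total_burn:
            sb_walk.adapt()

        if t >= total_burn and (t - total_burn) % thin == thin - 1:
            i = (t - total_burn) // thin
            # sum-to-zero recentering: store +-d so the deflections are
            # exact floating-point negatives of each other
            d = (betas[0] - betas[1]) / 2.0
            mean_b = (betas[0] + betas[1]) / 2.0
            row = [beta0 + mean_b, d, -d, sigma_b, sigma_i]
            if has_cov:
                row.append(beta_c)
            out[i] = row

    draws = pd.DataFrame(out, columns=cols)
    diagnostics = {
        "sigma_i_scale": si_walk.scale,
        "sigma_i_acceptance": si_walk.acc / max(si_walk.n, 1),
        "sigma_beta_scale": sb_walk.scale,
        "sigma_beta_acceptance": sb_walk.acc / max(sb_walk.n, 1),
        "ess": {c: effective_sample_size(draws[c].to_numpy()) for c in cols},
        "n_per_group": dict(zip(labels, counts)),
    }
    samples = PosteriorSamples(draws=draws, thin=thin, burn_in=burn_in, seed=seed, diagnostics=diagnostics)
    support = {
        "sigma_beta": (0.0, None),
        "sigma_i": (spec.sigma_i_low, spec.sigma_i_high),
    }
    summaries = samples.summarize(support_map=support)
    diff_draws = draws[f"beta_{labels[1]}"].to_numpy() - draws[f"beta_{labels[0]}"].to_numpy()
    es_draws = diff_draws / draws["sigma_i"].to_numpy()
    difference = PosteriorSummary.from_draws(diff_draws) if np.ptp(diff_draws) else _constant_summary(diff_draws[0])
    effect_size = PosteriorSummary.from_draws(es_draws) if np.ptp(es_draws) else _constant_summary(es_draws[0])
    return GlmPosterior(
        samples=samples,
        summaries=summaries,
        difference=difference,
        effect_size=effect_size,
        labels=(labels[0], labels[1]),
        spec=spec,
    )


def _constant_summary(c: float) -> PosteriorSummary:
    return PosteriorSummary(mean=c, median=c, mode=c, hdi_low=c, hdi_high=c, pp=0.5 if c == 0 else 1.0)


def _prepare(y, groups, cov=None):
    y = np.asarray(y, dtype=float).ravel()
    groups = np.asarray(groups).astype(str).ravel()
    if y.size != groups.size:
        raise ValueError("y and groups must have equal length")
    keep = np.isfinite(y)
    if cov is not None:
        cov = np.asarray(cov, dtype=float).ravel()
        if cov.size != y.size:
            raise ValueError("covariate must match y in length")
        keep &= np.isfinite(cov)
        return y[keep], groups[keep], cov[keep]
    return y[keep], groups[keep], None


def fit_group_model(
    y, groups, spec: GlmPriorSpec, n_kept: int = 11000, thin: int = 10, burn_in: int = 1000, seed: int = 0
) -> GlmPosterior:
    """Fit the group-deflection model ``y = beta0 + beta_group + eps``."""
    yv, gv, _ = _prepare(y, groups)
    return _fit(yv, gv, None, spec, n_kept, thin, burn_in, seed)


def fit_group_covariate_model(
    y, groups, covariate, spec: GlmPriorSpec,
    n_kept: int = 11000, thin: int = 10, burn_in: int = 1000, seed: int = 0,
) -> GlmPosterior:
    """Fit ``y = beta0 + beta_group + beta_cov * covariate + eps``.

    The covariate is mean-centered before fitting; ``spec.beta_cov_sd`` must
    be set (use :func:`build_priors` with the covariate).
    """
    if spec.beta_cov_sd is None:
        raise ValueError("spec.beta_cov_sd is required for the covariate model")
    yv, gv, cv = _prepare(y, groups, covariate)
    if np.ptp(cv) == 0 and cv[0] != 0.0:
        raise DegenerateInputError("zero-variance covariate")
    return _fit(yv, gv, cv, spec, n_kept, thin, burn_in, seed)


def group_difference(post: GlmPosterior, a: str, b: str) -> tuple[PosteriorSummary, PosteriorSummary]:
    """Posterior of ``beta_a - beta_b`` and of the standardized effect size.

    The effect size divides the per-draw difference by the per-draw residual
    SD ``sigma_i``.
    """
    da = post.deflection(a)
    db = post.deflection(b)
    diff = da - db
    es = diff / post.samples.column("sigma_i")
    diff_s = PosteriorSummary.from_draws(diff) if np.ptp(diff) else _constant_summary(float(diff[0]))
    es_s = PosteriorSummary.from_draws(es) if np.ptp(es) else _constant_summary(float(es[0]))
    return diff_s, es_s
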