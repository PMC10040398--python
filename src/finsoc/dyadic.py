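"""Zero-inflated binomial GLMM of dyadic bond strength.

The response for dyad (i, j) is y = number of surveys together out of
n = surveys in which either was seen; excess never-associating dyads are
absorbed by a zero-inflation component. Fixed effects are biparental
relatedness, haplotype identity, foraging identity (three classes, MIX
reference) and absolute mean-depth difference; both members' identities
enter as a multi-membership random intercept (u_i + u_j). Priors follow
a weakly-regularising scheme: Normal(0, 10) intercepts, Normal(0, 5)
slopes, half-Cauchy(0, 2) on the random-effect SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, xlogy

from . import _zib_sampler
from .association import AssociationMatrix, MaskState

logger = logging.getLogger(__name__)

__all__ = [
    "ZIBModelSpec",
    "ZIBFit",
    "build_dyad_table",
    "zib_logpmf",
    "fit_zib_glmm",
    "bayes_r2",
    "vif_check",
    "foraging_contrasts",
]

FIXED_EFFECTS = [
    "intercept",
    "relatedness",
    "same_haplotype",
    "foraging_NN",
    "foraging_SS",
    "depth_diff",
]


@dataclass(frozen=True)
class ZIBModelSpec:
    """Sampler and prior configuration.

    ``target_accept`` and ``max_treedepth`` are honoured by HMC backends;
    the Metropolis-within-Gibbs backend used here adapts its proposal
    scales instead and ignores them.
    """

    chains: int = 4
    iterations: int = 4000  # first half warmup
    prior_sd_intercept: float = 10.0
    prior_sd_slope: float = 5.0
    cauchy_scale: float = 2.0
    target_accept: float = 0.99
    max_treedepth: int = 15
    standardize: bool = False
    rhat_limit: float = 1.01


def build_dyad_table(
    assoc: AssociationMatrix,
    attributes: pd.DataFrame,
    relatedness: pd.DataFrame,
) -> pd.DataFrame:
    """One row per unmasked dyad with response counts and covariates.

    ``attributes`` must carry individual_id, haplotype, sponger and
    mean_depth. Foraging identity is NN (both non-spongers), SS (both
    spongers) or MIX. Missing relatedness/haplotype leaves NaN and
    ``complete=False`` (the "not applicable" coding for ungenotyped
    individuals).
    """
    if assoc.together is None or assoc.n_either is None:
        raise ValueError("association matrix lacks dyadic counts")
    attrs = attributes.set_index("individual_id")
    unknown = [i for i in assoc.ids if i not in attrs.index]
    if unknown:
        raise ValueError(f"individuals missing from attribute table: {unknown[:5]}")

    rows = []
    for a_pos, a in enumerate(assoc.ids):
        for b_pos in range(a_pos + 1, assoc.n):
            b = assoc.ids[b_pos]
            if assoc.mask[a_pos, b_pos] != MaskState.VALUE:
                continue
            sp_a, sp_b = bool(attrs.at[a, "sponger"]), bool(attrs.at[b, "sponger"])
            foraging = "SS" if sp_a and sp_b else ("NN" if not sp_a and not sp_b else "MIX")
            hap_a, hap_b = attrs.at[a, "haplotype"], attrs.at[b, "haplotype"]
            same_hap = (
                float(hap_a == hap_b)
                if pd.notna(hap_a) and pd.notna(hap_b)
                else np.nan
            )
            try:
                r = float(relatedness.at[a, b])
            except KeyError:
                r = np.nan
            rows.append(
                {
                    "id_a": a,
                    "id_b": b,
                    "y": int(assoc.together[a_pos, b_pos]),
                    "n": int(assoc.n_either[a_pos, b_pos]),
                    "relatedness": r,
                    "same_haplotype": same_hap,
                    "foraging": foraging,
                    "depth_diff": abs(
                        float(attrs.at[a, "mean_depth"]) - float(attrs.at[b, "mean_depth"])
                    ),
                }
            )
    df = pd.DataFrame(rows)
    df["complete"] = df["relatedness"].notna() & df["same_haplotype"].notna()
    return df


def zib_logpmf(y, n, p, pi):
    """Log-pmf of the zero-inflated binomial, numerically stable.

    P(0) = pi + (1 - pi) (1 - p)^n; P(y > 0) = (1 - pi) Binom(y | n, p).
    """
    y = np.asarray(y)
    n = np.asarray(n)
    p = np.asarray(p, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("y must satisfy 0 <= y <= n")
    if np.any((p < 0) | (p > 1)) or np.any((pi < 0) | (pi > 1)):
        raise ValueError("p and pi must lie in [0, 1]")
    y, n, p, pi = np.broadcast_arrays(y, n, p, pi)
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log1m_pi = np.log1p(-pi)
        lchoose = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    # xlogy handles the 0*log(0) corners (p = 0 or 1 at the boundary counts)
    binom_ll = lchoose + xlogy(y, p) + xlogy(n - y, 1.0 - p)
    zero_branch = np.logaddexp(log_pi, log1m_pi + xlogy(n, 1.0 - p))
    out = np.where(y == 0, zero_branch, log1m_pi + binom_ll)
    return out


def _design(dyads: pd.DataFrame, standardize: bool) -> tuple[np.ndarray, dict]:
    X = np.column_stack(
        [
            np.ones(len(dyads)),
            dyads["relatedness"].to_numpy(dtype=float),
            dyads["same_haplotype"].to_numpy(dtype=float),
            (dyads["foraging"] == "NN").to_numpy(dtype=float),
            (dyads["foraging"] == "SS").to_numpy(dtype=float),
            dyads["depth_diff"].to_numpy(dtype=float),
        ]
    )
    scales = {"relatedness": 1.0, "depth_diff": 1.0}
    if standardize:
        for col, name in ((1, "relatedness"), (5, "depth_diff")):
            sd = X[:, col].std()
            if sd > 0:
                X[:, col] = (X[:, col] - X[:, col].mean()) / sd
                scales[name] = sd
    return X, scales


@dataclass
class ZIBFit:
    idata: az.InferenceData
    summary: pd.DataFrame
    odds_ratios: pd.DataFrame
    bayes_r2_mean: float
    bayes_r2_ci: tuple[float, float]
    zero_inflation_mean: float
    zero_inflation_ci: tuple[float, float]
    converged: bool
    max_rhat: float
    n_dyads: int
    n_dropped: int
    scales: dict = field(default_factory=dict)

    def beta_draws(self) -> np.ndarray:
        """Flattened posterior draws of the fixed effects (draws x 6)."""
        return (
            self.idata.posterior["beta"]
            .stack(sample=("chain", "draw"))
            .transpose("sample", "beta_dim")
            .to_numpy()
        )


def fit_zib_glmm(
    dyads: pd.DataFrame,
    spec: ZIBModelSpec | None = None,
    seed: int = 0,
    max_retries: int = 2,
) -> ZIBFit:
    """Fit the ZIB multi-membership GLMM by adaptive MCMC.

    Rows with missing genetic covariates are dropped (complete-case,
    logged). Convergence requires R-hat <= ``spec.rhat_limit`` for every
    parameter; on failure the fit is retried with doubled chain length
    (up to ``max_retries`` times) before returning with ``converged``
    False and a logged diagnostic.
    """
    spec = spec or ZIBModelSpec()
    complete = dyads[dyads["complete"]].reset_index(drop=True)
    n_dropped = len(dyads) - len(complete)
    if n_dropped:
        logger.info("dropped %d dyads with missing genetic covariates", n_dropped)
    if len(complete) < 30:
        raise ValueError(f"need >= 30 complete dyads, got {len(complete)}")

    ids = sorted(set(complete["id_a"]) | set(complete["id_b"]))
    idx = {ind: k for k, ind in enumerate(ids)}
    dyad_i = complete["id_a"].map(idx).to_numpy(dtype=np.int64)
    dyad_j = complete["id_b"].map(idx).to_numpy(dtype=np.int64)
    y = complete["y"].to_numpy(dtype=np.int64)
    n = complete["n"].to_numpy(dtype=np.int64)
    X, scales = _design(complete, spec.standardize)
    lchoose = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    ptr, ind_dyads = _zib_sampler.build_individual_index(dyad_i, dyad_j, len(ids))

    for attempt in range(max_retries + 1):
        iterations = spec.iterations * 2**attempt
        warmup = iterations // 2
        betas, us, sigmas, pis = [], [], [], []
        ss = np.random.SeedSequence((seed, attempt))
        chain_seeds = [int(s) % (2**31 - 1) for s in ss.generate_state(spec.chains)]
        for c in range(spec.chains):
            b, u, s, pi = _zib_sampler.run_chain(
                X,
                y,
                n,
                lchoose,
                dyad_i,
                dyad_j,
                ptr,
                ind_dyads,
                len(ids),
                iterations,
                warmup,
                chain_seeds[c],
                spec.prior_sd_intercept,
                spec.prior_sd_slope,
                spec.cauchy_scale,
            )
            betas.append(b)
            us.append(u)
            sigmas.append(s)
            pis.append(pi)

        idata = az.from_dict(
            posterior={
                "beta": np.stack(betas),
                "u": np.stack(us),
                "sigma_u": np.stack(sigmas),
                "zi": np.stack(pis),
            },
            coords={"beta_dim": FIXED_EFFECTS, "u_dim": ids},
            dims={"beta": ["beta_dim"], "u": ["u_dim"]},
        )

        rhat = az.rhat(idata)
        max_rhat = float(
            max(float(rhat[v].max()) for v in ("beta", "u", "sigma_u", "zi"))
        )
        converged = max_rhat <= spec.rhat_limit
        if converged:
            break
        if attempt < max_retries:
            logger.info(
                "max R-hat %.4f > %.2f; retrying with %d iterations",
                max_rhat,
                spec.rhat_limit,
                spec.iterations * 2 ** (attempt + 1),
            )
    if not converged:
        logger.warning(
            "max R-hat %.4f exceeds %.2f after %d retries",
            max_rhat,
            spec.rhat_limit,
            max_retries,
        )

    summary = az.summary(idata, var_names=["beta", "sigma_u", "zi"], hdi_prob=0.95)

    beta_all = np.concatenate(betas, axis=0)
    or_rows = []
    for k, name in enumerate(FIXED_EFFECTS):
        draws = beta_all[:, k]
        scale = scales.get(name, 1.0)  # report per raw unit
        ors = np.exp(draws / scale) if name in scales else np.exp(draws)
        lo, hi = np.quantile(ors, [0.025, 0.975])
        or_rows.append(
            {"effect": name, "odds_ratio": float(ors.mean()), "ci_low": float(lo), "ci_high": float(hi)}
        )
    odds_ratios = pd.DataFrame(or_rows)

    pi_all = np.concatenate(pis)
    r2 = bayes_r2(
        beta_all, np.concatenate(us, axis=0), pi_all, X, n, dyad_i, dyad_j
    )
    r2_lo, r2_hi = np.quantile(r2, [0.025, 0.975])
    zi_lo, zi_hi = np.quantile(pi_all, [0.025, 0.975])

    return ZIBFit(
        idata=idata,
        summary=summary,
        odds_ratios=odds_ratios,
        bayes_r2_mean=float(r2.mean()),
        bayes_r2_ci=(float(r2_lo), float(r2_hi)),
        zero_inflation_mean=float(pi_all.mean()),
        zero_inflation_ci=(float(zi_lo), float(zi_hi)),
        converged=converged,
        max_rhat=max_rhat,
        n_dyads=len(complete),
        n_dropped=n_dropped,
        scales=scales,
    )


def bayes_r2(
    beta_draws: np.ndarray,
    u_draws: np.ndarray,
    pi_draws: np.ndarray,
    X: np.ndarray,
    n: np.ndarray,
    dyad_i: np.ndarray,
    dyad_j: np.ndarray,
    max_draws: int = 2000,
) -> np.ndarray:
    """Per-draw Bayesian R-squared on the proportion scale.

    R2 = Var(y-hat) / (Var(y-hat) + Var(residual)), with y-hat the ZIB
    mean proportion (1 - pi) p per dyad and the residual variance the
    mean ZIB sampling variance of y / n across dyads.
    """
    n_draws = beta_draws.shape[0]
    if n_draws > max_draws:
        sel = np.linspace(0, n_draws - 1, max_draws).astype(int)
        beta_draws, u_draws, pi_draws = beta_draws[sel], u_draws[sel], pi_draws[sel]
    out = np.empty(beta_draws.shape[0])
    for t in range(beta_draws.shape[0]):
        eta = X @ beta_draws[t] + u_draws[t][dyad_i] + u_draws[t][dyad_j]
        p = expit(eta)
        pi = pi_draws[t]
        yhat = (1 - pi) * p
        var_fit = yhat.var()
        ey2 = (1 - pi) * (n * p * (1 - p) + (n * p) ** 2)
        var_y = ey2 - (n * yhat) ** 2
        var_res = float(np.mean(var_y / n**2))
        out[t] = var_fit / (var_fit + var_res)
    return out


def vif_check(dyads: pd.DataFrame) -> pd.Series:
    """Variance inflation factors of the fixed-effect covariates.

    Each covariate column (foraging as dummies) is regressed on the
    others plus an intercept; VIF = 1 / (1 - R^2). Singular designs give
    infinity.
    """
    complete = dyads[dyads["complete"]]
    X, _ = _design(complete.reset_index(drop=True), standardize=False)
    cols = FIXED_EFFECTS[1:]
    M = X[:, 1:]
    out = {}
    for k, name in enumerate(cols):
        target = M[:, k]
        others = np.column_stack(
            [np.ones(len(M))] + [M[:, j] for j in range(M.shape[1]) if j != k]
        )
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        sst = ((target - target.mean()) ** 2).sum()
        if sst == 0:
            out[name] = np.inf
            continue
        r2 = 1 - (resid**2).sum() / sst
        out[name] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def foraging_contrasts(
    fit: ZIBFit, family_alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise foraging-class odds ratios, multiplicity-adjusted.

    Contrasts NN-MIX, SS-MIX and NN-SS as posterior odds-ratio
    distributions; credible intervals widened for the three-contrast
    family (level 1 - alpha / 3). A level contrasted with itself gives
    OR exactly 1.
    """
    beta = fit.beta_draws()
    b_nn = beta[:, FIXED_EFFECTS.index("foraging_NN")]
    b_ss = beta[:, FIXED_EFFECTS.index("foraging_SS")]
    contrasts = {
        "NN_vs_MIX": b_nn,
        "SS_vs_MIX": b_ss,
        "NN_vs_SS": b_nn - b_ss,
    }
    level = 1 - family_alpha / len(contrasts)
    q = [(1 - level) / 2, 1 - (1 - level) / 2]
    rows = []
    for name, d in contrasts.items():
        ors = np.exp(d)
        lo, hi = np.quantile(ors, q)
        rows.append(
            {
                "contrast": name,
                "odds_ratio": float(ors.mean()),
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)
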