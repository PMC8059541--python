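"""Whisker time-stamping, diet-trend tests and Bayesian stable-isotope mixing.

The mixing model estimates diet proportions p over prey source groups from
consumer isotope values (d13C, d15N per consumer replicate).  For replicate
j and isotope k,

    x_jk ~ Normal( sum_s p_s (mu_sk + lam_sk),
                   sum_s p_s^2 (omega_sk^2 + tau_sk^2) + sigma_k^2 ),

where mu/omega are the source mean/SD, lam/tau the trophic enrichment
factor mean/SD, p has a Dirichlet(alpha) prior (alpha = 1, uniform on the
simplex, by default) and sigma_k a half-normal residual scale.  The
posterior is sampled on an additive-log-ratio transform of the simplex with
an affine-invariant ensemble sampler (emcee), and split-chain R-hat < 1.05
is the convergence contract; a non-converged result is returned flagged,
never silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

ISOTOPES = ("d13C", "d15N")


# ---------------------------------------------------------------------------
# whisker time-stamping

def assign_segment_dates(segments: pd.DataFrame, deploy_date, recover_date
                         ) -> pd.DataFrame:
    """Assign a date to each whisker segment under linear growth.

    Segment index 0 is the base at recovery (grown last); the highest index
    is the tip (grown first).  With n segments per seal, segment s maps to
    the midpoint of the (n - s)-th of n equal sub-intervals of
    [deploy, recover].  The linear-growth rule is isolated here so a
    nonlinear growth curve can be swapped in.
    """
    deploy = pd.Timestamp(deploy_date)
    recover = pd.Timestamp(recover_date)
    if deploy >= recover:
        raise ValueError("deploy_date must precede recover_date")
    if segments.empty:
        raise ValueError("need at least 1 segment")
    span = (recover - deploy).total_seconds()
    out = segments.copy()
    dates = []
    for seal, grp in out.groupby("seal_id"):
        n = len(grp)
        frac = (n - grp["segment"].to_numpy(float) - 0.5) / n
        dates.append(pd.Series(
            deploy + pd.to_timedelta(frac * span, unit="s"), index=grp.index))
    out["date"] = pd.concat(dates).sort_index()
    return out


def isotope_trend(samples: pd.DataFrame) -> dict:
    """Random-intercept linear trend of each isotope on date.

    Tests the seasonal diet-switch hypothesis: a slope CI covering zero for
    both isotopes means no consistent temporal trend in whisker values.
    """
    df = samples.copy()
    if df["seal_id"].nunique() < 2:
        raise ValueError("need >= 2 seals")
    df["date"] = pd.to_datetime(df["date"])
    if df["date"].nunique() < 3:
        raise ValueError("need >= 3 distinct dates")
    t0 = df["date"].min()
    df["day"] = (df["date"] - t0).dt.total_seconds() / 86400.0
    out = {}
    for iso in ISOTOPES:
        if iso not in df.columns:
            continue
        model = smf.mixedlm(f"{iso} ~ day", df, groups=df["seal_id"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=True)
        slope, se = float(fit.params["day"]), float(fit.bse["day"])
        lo, hi = slope - 1.96 * se, slope + 1.96 * se
        out[iso] = {"slope": slope, "se": se, "ci": (lo, hi),
                    "covers_zero": lo <= 0 <= hi}
    return out


# ---------------------------------------------------------------------------
# mixing model

@dataclass
class MixingResult:
    source_names: list[str]
    p_draws: np.ndarray          # (n_draws, n_sources), every row on the simplex
    sigma_draws: np.ndarray      # (n_draws, n_isotopes)
    isotopes: list[str]
    rhat: float
    converged: bool
    summary: pd.DataFrame = field(repr=False)

    def proportion(self, name: str) -> dict:
        row = self.summary.loc[self.summary["source"] == name].iloc[0]
        return {"median": row["median"], "ci": (row["q025"], row["q975"])}


def _alr_to_simplex(z: np.ndarray) -> np.ndarray:
    """Additive log-ratio inverse: z in R^(S-1) -> p on the S-simplex."""
    z = np.atleast_2d(z)
    full = np.hstack([z, np.zeros((z.shape[0], 1))])
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)


def fit_mixing_model(
    consumers: pd.DataFrame,
    sources: pd.DataFrame,
    alpha: float | Sequence[float] = 1.0,
    walkers: int = 24,
    steps: int = 3000,
    burn: int = 1000,
    seed: int = 0,
    sigma_prior_scale: float = 2.0,
    rhat_max: float = 1.05,
) -> MixingResult:
    """Sample the diet-proportion posterior.

    ``consumers`` holds one row per consumer replicate with isotope columns;
    ``sources`` one row per prey group with mean/sd and TEF mean/sd per
    isotope (columns ``mean_d13C``, ``sd_d13C``, ``tef_mean_d13C``, ...).
    Isotopes present in both tables are used, so a one-isotope model is
    valid.  Convergence (split-chain R-hat over walker groups) is reported;
    a run exceeding ``rhat_max`` comes back with ``converged=False``.
    """
    import emcee

    if len(sources) < 2:
        raise ValueError("need >= 2 sources")
    isotopes = [i for i in ISOTOPES
                if i in consumers.columns and f"mean_{i}" in sources.columns]
    if not isotopes:
        raise ValueError("no isotope columns shared by consumers and sources")
    X = consumers[isotopes].to_numpy(float)          # (n, K)
    if np.isnan(X).any():
        raise ValueError("missing consumer isotope values")
    n, K = X.shape
    S = len(sources)
    mu = np.column_stack([(sources[f"mean_{i}"] + sources[f"tef_mean_{i}"]).to_numpy(float)
                          for i in isotopes])        # (S, K)
    var = np.column_stack([(sources[f"sd_{i}"] ** 2 + sources[f"tef_sd_{i}"] ** 2)
                           .to_numpy(float) for i in isotopes])
    alpha = np.broadcast_to(np.asarray(alpha, float), (S,))

    def log_prob(theta: np.ndarray) -> float:
        z, logsig = theta[:S - 1], theta[S - 1:]
        if np.any(np.abs(z) > 30) or np.any(np.abs(logsig) > 10):
            return -np.inf
        p = _alr_to_simplex(z)[0]
        sig2 = np.exp(2 * logsig)
        mean = p @ mu                                 # (K,)
        v = (p ** 2) @ var + sig2                     # (K,)
        ll = -0.5 * np.sum((X - mean) ** 2 / v) - 0.5 * n * np.sum(np.log(2 * np.pi * v))
        # Dirichlet prior + ALR Jacobian (sum over all S components)
        lp = np.sum((alpha - 1) * np.log(p)) + np.sum(np.log(p))
        # half-normal on sigma, plus log-Jacobian of the log transform
        lp += np.sum(-0.5 * np.exp(2 * logsig) / sigma_prior_scale ** 2 + logsig)
        return float(ll + lp)

    ndim = (S - 1) + K
    rng = np.random.default_rng(seed)
    p0 = np.hstack([rng.normal(0, 0.5, (walkers, S - 1)),
                    np.log(0.5 * X.std(axis=0).clip(1e-3, None))
                    + rng.normal(0, 0.2, (walkers, K))])
    # differential-evolution moves mix far better than the default stretch
    # move on this correlated simplex posterior
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(walkers, ndim, log_prob, moves=moves)
    state = emcee.State(p0, random_state=np.random.RandomState(seed).get_state())
    sampler.run_mcmc(state, steps, progress=False)
    chain = sampler.get_chain(discard=burn)           # (steps-burn, walkers, ndim)

    rhat = _split_rhat(chain)
    converged = bool(rhat < rhat_max)
    if not converged:
        warnings.warn(f"mixing model not converged: max split R-hat {rhat:.3f}")

    flat = chain.reshape(-1, ndim)
    p_draws = _alr_to_simplex(flat[:, :S - 1])
    sigma_draws = np.exp(flat[:, S - 1:])
    names = sources["name"].tolist()
    qs = np.quantile(p_draws, [0.025, 0.5, 0.975], axis=0)
    summary = pd.DataFrame({"source": names, "median": qs[1],
                            "mean": p_draws.mean(axis=0),
                            "q025": qs[0], "q975": qs[2]})
    return MixingResult(source_names=names, p_draws=p_draws,
                        sigma_draws=sigma_draws, isotopes=isotopes,
                        rhat=rhat, converged=converged, summary=summary)


def _split_rhat(chain: np.ndarray) -> float:
    """Max split-chain R-hat across parameters; walkers act as chains."""
    nsteps, nwalk, ndim = chain.shape
    half = nsteps // 2
    # split each walker chain in half -> 2*nwalk chains
    parts = np.concatenate([chain[:half], chain[half:2 * half]], axis=1)
    m, nd = parts.shape[1], parts.shape[0]
    means = parts.mean(axis=0)                        # (m, ndim)
    var_b = nd * means.var(axis=0, ddof=1)
    var_w = parts.var(axis=0, ddof=1).mean(axis=0)
    var_post = (nd - 1) / nd * var_w + var_b / nd
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_post / var_w)
    return float(np.nanmax(rhat))


def two_source_mass_balance(consumer_mean: float, a: float, b: float) -> float:
    """Closed-form two-source, one-isotope mixing proportion of source A."""
    return (consumer_mean - b) / (a - b)
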