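"""Repeated-imputation moderated regression with stability selection.

The quantitative path of the pipeline: missing entries are imputed
group-wise from a normal distribution matching the observed mean and
standard deviation of each protein within each disease group, an ordinary
least-squares model with disease (DM/NDM) and preparation-batch predictors
is fitted per protein, residual variances are shrunk toward an
empirical-Bayes prior (moderated t), and per-protein q-values control the
false discovery rate.  The imputation is repeated M times (default 50) and
a protein is called differentially abundant when it reaches q below the
threshold in at least ``min_pass`` rounds (default 30 of 50, i.e. 60%).

The empirical-Bayes prior (d0, s0^2) is estimated by moment matching on
log residual variances under the scaled-F sampling model
s^2 ~ s0^2 * F(df_residual, d0), and re-estimated in every imputation
round, since each round is a complete data set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import (AggregationError, DesignError, EstimationError,
                     ImputationError, ValidationError)
from .preprocess import _check_design, _check_matrix

__all__ = [
    "EBPrior",
    "ImputationSpec",
    "ModeratedStabilitySelector",
    "impute_once",
    "fit_linear_models",
    "estimate_eb_prior",
    "moderate",
    "compute_qvalues",
    "stability_aggregate",
]


@dataclass
class ImputationSpec:
    n_imputations: int = 50
    seed: int = 0
    min_observed_per_group: int = 4

    def validate(self):
        if self.n_imputations < 1:
            raise ValidationError("n_imputations must be >= 1")
        return self


@dataclass
class EBPrior:
    """Variance-moderation hyperparameters: prior df and prior variance."""

    d0: float
    s0_sq: float

    def validate(self):
        if not (self.d0 >= 0):
            raise ValidationError("d0 must be >= 0")
        if not (self.s0_sq > 0) and not math.isinf(self.d0):
            raise ValidationError("s0_sq must be > 0")
        return self


def impute_once(matrix: pd.DataFrame, design: pd.DataFrame, seed) -> pd.DataFrame:
    """Complete the matrix with one group-wise normal imputation.

    Each missing entry of protein g in group G is replaced by an
    independent draw from Normal(mean, sd) of the observed (g, G) values
    (sd with one delta degree of freedom).  Observed entries are untouched.

    ``seed`` may be an int, a SeedSequence, or a Generator.
    """
    _check_matrix(matrix)
    _check_design(design, matrix)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    by_group = design.set_index("sample")["group"]
    values = matrix.to_numpy(dtype=float, copy=True)
    for g in ("DM", "NDM"):
        cols = np.array([i for i, s in enumerate(matrix.columns) if by_group[s] == g])
        sub = values[:, cols]
        obs = ~np.isnan(sub)
        n_obs = obs.sum(axis=1)
        if np.any(n_obs < 2):
            bad = matrix.index[np.flatnonzero(n_obs < 2)[0]]
            raise ImputationError(
                f"protein {bad!r} has fewer than 2 observed values in group {g}; "
                "route it to the heuristic path first")
        if not obs.all():
            with np.errstate(invalid="ignore"):
                mean = np.nanmean(sub, axis=1)
                sd = np.nanstd(sub, axis=1, ddof=1)
            draws = rng.normal(mean[:, None], sd[:, None], size=sub.shape)
            sub[~obs] = draws[~obs]
            values[:, cols] = sub
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)


def build_design_matrix(design: pd.DataFrame, sample_order) -> tuple[np.ndarray, list]:
    """Intercept + DM indicator + reference-coded batch dummies.

    The reference batch is the lexicographically first label, which leaves
    the disease coefficient (DM minus NDM) invariant to the coding choice.
    """
    d = design.set_index("sample").loc[list(sample_order)]
    batches = sorted(d["batch"].unique())
    cols = [np.ones(len(d)), (d["group"] == "DM").to_numpy(float)]
    names = ["intercept", "disease_DM"]
    for b in batches[1:]:
        cols.append((d["batch"] == b).to_numpy(float))
        names.append(f"batch_{b}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is rank deficient "
                          "(batch confounded with disease?)")
    return X, names


def fit_linear_models(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-protein OLS of log2 intensity on disease + batch.

    Requires a completed (no missing values) matrix.  Returns one row per
    protein with the disease coefficient (DM - NDM), its unmoderated
    standard error, the residual variance ``s_sq``, the residual df, and
    the design factor ``c_dd`` = [ (X'X)^-1 ]_{disease,disease} reused by
    the moderation step.
    """
    _check_matrix(matrix)
    if matrix.isna().any().any():
        raise ValidationError("fit_linear_models requires a completed matrix; "
                              "impute first")
    X, _ = build_design_matrix(design, matrix.columns)
    Y = matrix.to_numpy(dtype=float)
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    coefs = Y @ (xtx_inv @ X.T).T          # proteins x p
    resid = Y - coefs @ X.T
    df_resid = n - p
    s_sq = (resid ** 2).sum(axis=1) / df_resid
    c_dd = xtx_inv[1, 1]
    se = np.sqrt(s_sq * c_dd)
    return pd.DataFrame({
        "protein_id": matrix.index,
        "coef": coefs[:, 1],
        "se": se,
        "s_sq": s_sq,
        "df_residual": df_resid,
        "c_dd": c_dd,
    }).set_index("protein_id")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration on a log-convex scale."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def estimate_eb_prior(s_sq, df_residual: int) -> EBPrior:
    """Moment-match (d0, s0^2) from observed residual variances.

    Under s^2 ~ s0^2 * F(df, d0), e = log(s^2) - digamma(df/2) + log(df/2)
    has mean log(s0^2) + digamma(d0/2) - log(d0/2) and variance
    trigamma(df/2) + trigamma(d0/2).  Solving the second moment for d0 and
    back-substituting gives the prior; when the log-variance dispersion
    does not exceed trigamma(df/2) there is no positive solution and the
    prior degenerates to d0 = infinity (complete pooling at s0^2).

    Zero or non-finite variances are excluded (they carry no information
    about the variance distribution and log would diverge).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    ok = np.isfinite(s_sq) & (s_sq > 0)
    s_sq = s_sq[ok]
    if s_sq.size < 2:
        raise EstimationError("need at least 2 positive residual variances")
    df = float(df_residual)
    e = np.log(s_sq) - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    rhs = evar - float(special.polygamma(1, df / 2.0))
    if rhs > 0:
        d0 = 2.0 * _trigamma_inverse(rhs)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = float(s_sq.mean())  # complete pooling: the common variance
    return EBPrior(d0=d0, s0_sq=s0_sq).validate()


def moderate(fits: pd.DataFrame, prior: EBPrior) -> pd.DataFrame:
    """Shrink residual variances toward the prior and form moderated t.

    Posterior variance s~^2 = (d0*s0^2 + df*s^2) / (d0 + df); the moderated
    t is the disease coefficient over its posterior-variance standard
    error, referred to a Student t with d0 + df degrees of freedom
    (df when d0 is infinite, where s~^2 = s0^2 for every protein; the
    plain OLS t is recovered at d0 = 0).
    """
    prior.validate()
    df = fits["df_residual"].to_numpy(dtype=float)
    s_sq = fits["s_sq"].to_numpy(dtype=float)
    coef = fits["coef"].to_numpy(dtype=float)
    c_dd = fits["c_dd"].to_numpy(dtype=float)
    if math.isinf(prior.d0):
        s_tilde_sq = np.full_like(s_sq, prior.s0_sq)
        df_total = df
    else:
        s_tilde_sq = (prior.d0 * prior.s0_sq + df * s_sq) / (prior.d0 + df)
        df_total = df + prior.d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = coef / np.sqrt(s_tilde_sq * c_dd)
    t_mod = np.where(np.isnan(t_mod), 0.0, t_mod)  # 0/0: no effect, no evidence
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    out = fits.copy()
    out["s_tilde_sq"] = s_tilde_sq
    out["t_mod"] = t_mod
    out["p"] = p
    return out


def compute_qvalues(p, method: str = "bh") -> np.ndarray:
    """FDR-adjusted q-values.

    ``bh``: step-up Benjamini-Hochberg adjusted p-values (monotone, <= 1,
    never smaller than p).  ``storey``: Storey q-values with the pi0
    estimate #{p > lambda} / ((1 - lambda) m) at lambda = 0.5, capped at 1;
    these equal pi0-scaled BH values and may drop below p when pi0 < 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    bh = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return bh
    if method == "storey":
        pi0 = min(1.0, float(np.mean(p > 0.5)) / 0.5) if p.size else 1.0
        if pi0 == 0.0:
            pi0 = 1.0 / p.size  # all p tiny; keep q positive
        return np.minimum(pi0 * bh, 1.0)
    raise ValidationError(f"unknown q-value method {method!r}")


def stability_aggregate(per_imputation, spec: ImputationSpec,
                        q_threshold: float = 0.1,
                        min_pass: int | None = None) -> pd.DataFrame:
    """Aggregate per-round model fits into stability-selection calls.

    ``n_pass`` counts rounds with q below ``q_threshold``; a protein is
    called differentially abundant when n_pass >= ``min_pass`` (default
    ceil(0.6 * M), i.e. 30 of 50).  Effect size, q and t are summarized by
    their medians across rounds; ``fold_change`` is 2**median_log2fc and
    the direction of a called protein follows its fold change.
    """
    spec.validate()
    if len(per_imputation) != spec.n_imputations:
        raise AggregationError(
            f"expected {spec.n_imputations} rounds, got {len(per_imputation)}")
    if min_pass is None:
        min_pass = math.ceil(0.6 * spec.n_imputations)

    ref_ids = list(per_imputation[0].index)
    for r, fits in enumerate(per_imputation):
        if list(fits.index) != ref_ids:
            raise AggregationError(f"round {r} covers a different protein set")

    q = np.column_stack([f["q"].to_numpy() for f in per_imputation])
    fc = np.column_stack([f["coef"].to_numpy() for f in per_imputation])
    t = np.column_stack([f["t_mod"].to_numpy() for f in per_imputation])

    n_pass = (q < q_threshold).sum(axis=1)
    median_log2fc = np.median(fc, axis=1)
    called = n_pass >= min_pass
    fold_change = 2.0 ** median_log2fc
    direction = np.where(called, np.where(fold_change >= 1.0, "up", "down"), "none")
    return pd.DataFrame({
        "protein_id": ref_ids,
        "median_log2fc": median_log2fc,
        "fold_change": fold_change,
        "median_q": np.median(q, axis=1),
        "median_t": np.median(t, axis=1),
        "pass_rate": n_pass / spec.n_imputations,
        "n_pass": n_pass,
        "called": called,
        "direction": direction,
    }).set_index("protein_id")


class ModeratedStabilitySelector(BaseEstimator):
    """Differential abundance by repeated imputation + moderated regression.

    Parameters
    ----------
    n_imputations : int, default 50
        Number of imputation rounds M.
    q_threshold : float, default 0.1
        Per-round FDR threshold (q < 0.1).
    min_pass : int or None
        Rounds a protein must pass to be called; ``None`` means
        ceil(0.6 * M) -- 30 of 50 at the default M.
    q_method : {"bh", "storey"}, default "bh"
    random_state : int or None
        Master seed; round r draws from an independent substream so rounds
        are exchangeable and the full run is bit-reproducible.

    Attributes (after :meth:`fit`)
    ------------------------------
    results_ : pandas.DataFrame
        One row per protein (aggregated over rounds).
    per_round_ : pandas.DataFrame
        Long-format per-round fits (round, protein, coef, t, p, q).
    priors_ : list of EBPrior
        The empirical-Bayes prior re-estimated in each round.
    """

    def __init__(self, n_imputations: int = 50, q_threshold: float = 0.1,
                 min_pass: int | None = None, q_method: str = "bh",
                 random_state: int | None = None):
        self.n_imputations = n_imputations
        self.q_threshold = q_threshold
        self.min_pass = min_pass
        self.q_method = q_method
        self.random_state = random_state

    def fit(self, X, design):
        spec = ImputationSpec(n_imputations=self.n_imputations,
                              seed=self.random_state or 0).validate()
        if self.min_pass is not None and self.min_pass > self.n_imputations:
            raise ValidationError("min_pass cannot exceed n_imputations")
        streams = np.random.SeedSequence(self.random_state).spawn(self.n_imputations)
        rounds, priors, long_rows = [], [], []
        for r, stream in enumerate(streams):
            completed = impute_once(X, design, np.random.default_rng(stream))
            fits = fit_linear_models(completed, design)
            prior = estimate_eb_prior(fits["s_sq"], int(fits["df_residual"].iloc[0]))
            fits = moderate(fits, prior)
            fits["q"] = compute_qvalues(fits["p"].to_numpy(), self.q_method)
            rounds.append(fits)
            priors.append(prior)
            lr = fits[["coef", "t_mod", "p", "q"]].reset_index()
            lr.insert(0, "round", r)
            long_rows.append(lr)
        self.priors_ = priors
        self.per_round_ = pd.concat(long_rows, ignore_index=True)
        self.results_ = stability_aggregate(rounds, spec, self.q_threshold,
                                            self.min_pass)
        self.n_proteins_ = len(self.results_)
        return self
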