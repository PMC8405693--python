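"""Synthetic data generators with known ground truth.

The generators emulate the statistical structure a label-free proteomics
differential-abundance analysis assumes: log2-scale intensities with
per-protein variance heterogeneity (scaled inverse-chi-square), a disease
effect (DM vs NDM) in a minority of proteins, additive sample-preparation
batch offsets, left-censored (intensity-dependent) missingness, and
"group-unique" proteins that sit below the limit of detection in one group.

Every generator is deterministic given its seed; a single integer seed is
expanded into independent substreams per stage so the stages do not couple.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .sets import GeneSet, GeneSetCollection

__all__ = [
    "SimulationParams",
    "simulate_proteome",
    "simulate_gene_table",
    "make_category_collection",
]


@dataclass
class SimulationParams:
    """Parameters of the proteome generator.

    Intensities are on the log2 scale throughout.  ``prior_df_true`` and
    ``prior_var_true`` are the hyperparameters of the scaled
    inverse-chi-square distribution the per-protein residual variances are
    drawn from -- the same family the downstream empirical-Bayes moderation
    fits, which is what makes parameter-recovery tests possible.

    ``censor_mid`` is the log2 intensity at which an entry is missing with
    probability one half; ``censor_width`` is the probit slope of the
    left-censoring curve.  At the defaults (~baseline 25 +/- 2, censor
    midpoint 23.2, width 1.0) roughly a quarter of all entries are censored.
    """

    n_proteins: int = 2000
    n_per_group: int = 10
    n_batches: int = 2
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    prior_df_true: float = 4.0
    prior_var_true: float = 0.1
    frac_da: float = 0.1
    effect_size: float = 1.0
    batch_sd: float = 0.5
    censor_mid: float = 23.2
    censor_width: float = 1.0
    frac_unique: float = 0.05
    seed: int = 0

    def validate(self) -> "SimulationParams":
        for name in ("n_proteins", "n_per_group", "n_batches"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ParameterError(f"{name} must be an integer >= 1, got {v!r}")
        for name in ("frac_da", "frac_unique"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v!r}")
        if self.frac_da + self.frac_unique > 1.0 + 1e-12:
            raise ParameterError("frac_da + frac_unique must not exceed 1")
        for name in ("baseline_sd", "prior_df_true", "prior_var_true",
                     "censor_width"):
            v = getattr(self, name)
            if not v > 0:
                raise ParameterError(f"{name} must be > 0, got {v!r}")
        if self.batch_sd < 0:
            raise ParameterError("batch_sd must be >= 0")
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown simulation parameters: {sorted(unknown)}")
        return cls(**d).validate()


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_proteome(params: SimulationParams):
    """Draw an intensity matrix, its study design, and the ground truth.

    Returns
    -------
    matrix : pandas.DataFrame
        proteins x samples log2 intensities, ``NaN`` where censored.
    design : pandas.DataFrame
        columns ``sample``, ``group`` (DM/NDM), ``batch``.  Batches are
        assigned round-robin within each group so disease and batch are
        never confounded.
    truth : pandas.DataFrame
        per-protein ``true_log2fc`` (DM - NDM), ``true_var``, ``is_da``,
        ``unique_group`` in {none, DM, NDM}.
    """
    params.validate()
    rng_assign, rng_effect, rng_var, rng_batch, rng_noise, rng_censor = \
        _substreams(params.seed, 6)

    n = params.n_proteins
    npg = params.n_per_group
    protein_ids = [f"P{i:05d}" for i in range(1, n + 1)]
    sample_ids = [f"NDM_{j:02d}" for j in range(1, npg + 1)] + \
                 [f"DM_{j:02d}" for j in range(1, npg + 1)]
    groups = np.array(["NDM"] * npg + ["DM"] * npg)
    batch_idx = np.concatenate([np.arange(npg) % params.n_batches,
                                np.arange(npg) % params.n_batches])
    batches = np.array([f"B{b + 1}" for b in batch_idx])

    n_unique = int(round(params.frac_unique * n))
    n_da = int(round(params.frac_da * n))
    order = rng_assign.permutation(n)
    unique_rows = order[:n_unique]
    da_rows = order[n_unique:n_unique + n_da]

    delta = np.zeros(n)
    delta[da_rows] = params.effect_size * rng_effect.choice([-1.0, 1.0], size=n_da)
    unique_group = np.array(["none"] * n, dtype=object)
    unique_group[unique_rows] = rng_effect.choice(["DM", "NDM"], size=n_unique)

    baseline = rng_var.normal(params.baseline_mean, params.baseline_sd, size=n)
    sigma_sq = params.prior_var_true * params.prior_df_true / \
        rng_var.chisquare(params.prior_df_true, size=n)
    batch_offsets = rng_batch.normal(0.0, params.batch_sd, size=params.n_batches)

    is_dm = (groups == "DM").astype(float)
    y = (baseline[:, None]
         + delta[:, None] * is_dm[None, :]
         + batch_offsets[batch_idx][None, :]
         + rng_noise.normal(0.0, np.sqrt(sigma_sq)[:, None], size=(n, 2 * npg)))

    # left-censoring: P(missing) = Phi((censor_mid - y) / censor_width)
    with np.errstate(invalid="ignore"):
        p_missing = stats.norm.cdf((params.censor_mid - y) / params.censor_width)
    observed = rng_censor.random(size=y.shape) >= p_missing
    for row in unique_rows:
        absent = "NDM" if unique_group[row] == "DM" else "DM"
        observed[row, groups == absent] = False

    values = np.where(observed, y, np.nan)
    matrix = pd.DataFrame(values, index=pd.Index(protein_ids, name="protein_id"),
                          columns=sample_ids)
    design = pd.DataFrame({"sample": sample_ids, "group": groups, "batch": batches})
    truth = pd.DataFrame({
        "protein_id": protein_ids,
        "true_log2fc": delta,
        "true_var": sigma_sq,
        "is_da": delta != 0.0,
        "unique_group": unique_group,
    })
    return matrix, design, truth


def simulate_gene_table(n_genes: int, frac_deg: float = 0.1,
                        effect_size: float = 1.0, seed: int = 0):
    """Draw a gene-level differential-expression table plus its ground truth.

    Non-DEG genes get logFC ~ Normal(0, sd=0.1) and p ~ Uniform(0, 1); DEG
    genes get |logFC| >= ``effect_size`` (an exponential excess above the
    floor) and p ~ Uniform(0, 0.01).
    """
    if not isinstance(n_genes, (int, np.integer)) or n_genes < 1:
        raise ParameterError(f"n_genes must be an integer >= 1, got {n_genes!r}")
    if not 0.0 <= frac_deg <= 1.0:
        raise ParameterError("frac_deg must lie in [0, 1]")
    rng_assign, rng_draw = _substreams(seed, 2)

    gene_ids = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    n_deg = int(round(frac_deg * n_genes))
    deg_rows = rng_assign.permutation(n_genes)[:n_deg]
    is_deg = np.zeros(n_genes, dtype=bool)
    is_deg[deg_rows] = True

    logfc = rng_draw.normal(0.0, 0.1, size=n_genes)
    p = rng_draw.uniform(0.0, 1.0, size=n_genes)
    signs = rng_draw.choice([-1.0, 1.0], size=n_genes)
    magnitudes = effect_size + rng_draw.exponential(0.5, size=n_genes)
    logfc[is_deg] = (signs * magnitudes)[is_deg]
    p[is_deg] = rng_draw.uniform(0.0, 0.01, size=n_genes)[is_deg]

    table = pd.DataFrame({"gene": gene_ids, "logfc": logfc, "p": p})
    truth = pd.DataFrame({"gene": gene_ids, "true_logfc": np.where(is_deg, logfc, 0.0),
                          "is_deg": is_deg})
    return table, truth


def make_category_collection(protein_ids, n_categories: int = 50,
                             size_range=(10, 40), n_planted: int = 0,
                             planted_bias: float = 0.9, seed: int = 0,
                             truth: pd.DataFrame | None = None) -> GeneSetCollection:
    """Build a random category collection over ``protein_ids``.

    The first ``n_planted`` categories preferentially sample proteins whose
    true effect has one sign (alternating up/down across planted
    categories); ``planted_bias`` is the probability each planted member is
    drawn from the matching-sign pool rather than uniformly.  Requires
    ``truth`` (a table with ``protein_id`` and ``true_log2fc``) when
    ``n_planted > 0``.

    When the collection has at least two categories the last one is a
    near-duplicate of the first (>= 90% shared members), so redundancy
    clustering always has something to collapse.
    """
    protein_ids = list(protein_ids)
    lo, hi = int(size_range[0]), int(size_range[1])
    if lo < 2 or hi > len(protein_ids) or lo > hi:
        raise ParameterError(
            f"size_range {size_range} infeasible for a universe of "
            f"{len(protein_ids)} proteins")
    if n_planted > n_categories:
        raise ParameterError("n_planted cannot exceed n_categories")
    if n_planted > 0 and truth is None:
        raise ParameterError("truth table required when n_planted > 0")
    if not 0.0 <= planted_bias <= 1.0:
        raise ParameterError("planted_bias must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    pos_pool = neg_pool = None
    if n_planted > 0:
        t = truth.set_index("protein_id")["true_log2fc"].reindex(protein_ids)
        pos_pool = [p for p, v in t.items() if v > 0]
        neg_pool = [p for p, v in t.items() if v < 0]

    categories = []
    ids = np.asarray(protein_ids, dtype=object)
    for c in range(n_categories):
        size = int(rng.integers(lo, hi + 1))
        if c < n_planted:
            pool = pos_pool if c % 2 == 0 else neg_pool
            sign = "up" if c % 2 == 0 else "down"
            if len(pool) == 0:
                raise ParameterError(
                    f"no proteins with {sign}-signed true effect to plant from")
            members: list[str] = []
            taken = set()
            while len(members) < size:
                src = pool if rng.random() < planted_bias else protein_ids
                cand = src[int(rng.integers(len(src)))]
                if cand not in taken:
                    taken.add(cand)
                    members.append(cand)
            desc = f"planted {sign}-regulated category"
        else:
            members = list(rng.choice(ids, size=size, replace=False))
            desc = "random category"
        categories.append(GeneSet(f"C{c + 1:04d}", desc, tuple(members)))

    if n_categories >= 2:
        base = list(categories[0].members)
        k = math.floor(len(base) * 0.1)
        keep = base[:len(base) - k] if k else base
        outside = [p for p in protein_ids if p not in set(base)]
        extra = list(rng.choice(np.asarray(outside, dtype=object), size=k,
                                replace=False)) if k else []
        categories[-1] = GeneSet(categories[-1].category_id,
                                 "near-duplicate of " + categories[0].category_id,
                                 tuple(keep + extra))
    return GeneSetCollection(categories=categories, universe=protein_ids)
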