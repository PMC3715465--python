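"""Reference-assay stability: geNorm pairwise variation and NormFinder.

Both methods operate on log2-scale expression (-dCt at efficiency 2) and are
invariant to per-sample global shifts: geNorm because it only sees pairwise
differences between assays, NormFinder because a per-sample effect is
absorbed by the model's sample term (implemented by centering each sample
across assays).

geNorm (pairwise variation): for assay j, ``M_j`` is the mean over the other
assays k of the standard deviation across samples of ``v_j - v_k`` (the
log2 expression ratio).  Lower M = more stable.  The stepwise ranking
repeatedly removes the highest-M assay until two remain.

NormFinder (model based): within each sample the assay values are centered;
for group g the centered value of assay j has variance
``sigma2_gj * (1 - 2/k) + mean-of-sigma2 / k`` under the random-error model,
which is solved for the intra-group variances ``sigma2_gj`` (clamped at
zero).  The inter-group bias ``d_gj`` (group mean of centered values minus
their across-group mean) is shrunk toward zero by the empirical-Bayes
factor ``gamma2 / (gamma2 + sigma2_gj / n_g)`` where ``gamma2`` is the
between-group bias variance net of sampling noise.  The stability value is
the mean over groups of ``|d_shrunk| + posterior SD``; with a single group
it reduces to the intra-group standard deviation alone.  Lower = more
stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .qpcr_io import CtMatrix


@dataclass
class NormalizerReport:
    """Stability summary for one candidate reference assay."""

    assay_id: str
    mean_ct: float
    sd_ct: float
    m_value: float
    stability_value: float
    rank_genorm: int
    rank_normfinder: int
    prefilter_pass: bool


def prefilter_normalizer_candidates(
    ct: CtMatrix, max_ct: float = 33.0, min_valid_fraction: float = 0.8
) -> list[str]:
    """Assays valid with Ct below ``max_ct`` in at least ``min_valid_fraction``
    of samples ("ubiquitously and highly expressed")."""
    ok = ct.valid.to_numpy() & (ct.ct.to_numpy() < max_ct)
    frac = ok.mean(axis=0)
    return [a for a, f in zip(ct.assay_ids, frac) if f >= min_valid_fraction]


def _check_complete(expr: pd.DataFrame) -> np.ndarray:
    values = expr.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError(
            "stability analysis requires complete data; impute or exclude "
            "assays/samples with missing cells upstream"
        )
    return values


def genorm_m_values(expr: pd.DataFrame) -> pd.Series:
    """geNorm expression-stability M per assay (columns) on log2 values."""
    values = _check_complete(expr)
    n_samples, n_assays = values.shape
    if n_assays < 2 or n_samples < 2:
        raise ValidationError("geNorm needs >=2 assays and >=2 samples")
    m = np.empty(n_assays)
    for j in range(n_assays):
        diffs = values[:, [j]] - values  # sample x assay pairwise log-ratios
        sds = diffs.std(axis=0, ddof=1)
        m[j] = np.delete(sds, j).mean()
    return pd.Series(m, index=expr.columns, name="m_value")


def genorm_stepwise_rank(
    expr: pd.DataFrame, sd_ct: pd.Series | None = None
) -> pd.Series:
    """Stepwise geNorm ranking; the two last surviving assays share rank 1.

    Ties on M are broken by excluding the assay with larger raw-Ct SD when
    ``sd_ct`` is given, then by reverse-lexicographic assay id, so outputs
    are deterministic and order-independent.
    """
    if expr.shape[1] < 3:
        raise ValidationError("stepwise ranking needs >=3 assays")
    remaining = sorted(expr.columns)
    exclusion_order: list[str] = []
    while len(remaining) > 2:
        m = genorm_m_values(expr[remaining])
        worst_m = m.max()
        ties = sorted(m.index[np.isclose(m.to_numpy(), worst_m, rtol=0, atol=1e-12)])
        if len(ties) > 1 and sd_ct is not None:
            ties.sort(key=lambda a: (-float(sd_ct.get(a, 0.0)), a))
            worst = ties[0]
        else:
            worst = ties[-1]  # lexicographically last among exact ties
        remaining.remove(worst)
        exclusion_order.append(worst)
    ranks = {a: 1 for a in remaining}
    for depth, assay in enumerate(reversed(exclusion_order), start=3):
        ranks[assay] = depth
    return pd.Series(ranks, name="rank_genorm").reindex(expr.columns)


def normfinder_stability(
    expr: pd.DataFrame, groups: pd.Series | None = None
) -> pd.Series:
    """NormFinder stability value per assay (lower = more stable)."""
    values = _check_complete(expr)
    n_samples, k = values.shape
    if k < 2:
        raise ValidationError("NormFinder needs >=2 assays")
    if groups is None:
        groups = pd.Series("all", index=expr.index)
    groups = groups.reindex(expr.index)
    if groups.isna().any():
        raise ValidationError("group label missing for some samples")
    labels = groups.to_numpy()
    unique = list(dict.fromkeys(labels))
    sizes = {g: int((labels == g).sum()) for g in unique}
    small = [g for g, n in sizes.items() if n < 2]
    if small:
        raise ValidationError(f"groups with <2 samples: {small}")

    centered = values - values.mean(axis=1, keepdims=True)  # absorb sample effect

    n_groups = len(unique)
    d_hat = np.zeros((n_groups, k))
    sigma2 = np.zeros((n_groups, k))
    for gi, g in enumerate(unique):
        z = centered[labels == g]
        n_g = z.shape[0]
        u2 = z.var(axis=0, ddof=1)
        if k > 2:
            # Var(z_j) = sigma2_j (1 - 2/k) + sum(sigma2) / k^2; solve linearly.
            total = u2.sum() / (1.0 - 1.0 / k)
            sigma2[gi] = (u2 - total / k**2) * k / (k - 2)
        else:
            # k = 2: z_1 = -z_2 = (e1 - e2)/2; only the sum is identified.
            sigma2[gi] = u2
        np.clip(sigma2[gi], 0.0, None, out=sigma2[gi])
        d_hat[gi] = z.mean(axis=0)
    d_hat = d_hat - d_hat.mean(axis=0, keepdims=True)

    if n_groups == 1:
        stability = np.sqrt(sigma2[0])
        return pd.Series(stability, index=expr.columns, name="stability_value")

    n_per_group = np.array([sizes[g] for g in unique], dtype=float)[:, None]
    samp_var = sigma2 / n_per_group
    gamma2 = max(0.0, d_hat.var(ddof=0) * (n_groups * k) / (n_groups * k - 1)
                 - samp_var.mean())
    shrink = gamma2 / (gamma2 + samp_var) if gamma2 > 0 else np.zeros_like(samp_var)
    d_tilde = d_hat * shrink
    post_var = samp_var * shrink + np.where(gamma2 > 0, 0.0, samp_var)
    stability = (np.abs(d_tilde) + np.sqrt(post_var)).mean(axis=0)
    return pd.Series(stability, index=expr.columns, name="stability_value")


def spikein_sd_report(ct: CtMatrix, assays: list[str] | None = None) -> pd.DataFrame:
    """Per-assay mean and SD of raw Ct across samples (valid cells only)."""
    assays = list(assays) if assays is not None else ct.assay_ids
    masked = ct.masked()[assays]
    report = pd.DataFrame(
        {
            "assay": assays,
            "n": masked.notna().sum().to_numpy(),
            "mean_ct": masked.mean().to_numpy(),
            "sd_ct": masked.std(ddof=1).to_numpy(),
        }
    )
    return report


def normalizer_report(
    ct: CtMatrix,
    expr: pd.DataFrame,
    groups: pd.Series | None = None,
    *,
    max_ct: float = 33.0,
    min_valid_fraction: float = 0.8,
) -> pd.DataFrame:
    """Full stability report over the assays of ``expr`` (complete columns).

    Combines raw-Ct summary, geNorm M and stepwise rank, NormFinder
    stability and rank, and the high-expression prefilter flag.
    """
    assays = list(expr.columns)
    sd_table = spikein_sd_report(ct, assays).set_index("assay")
    m = genorm_m_values(expr)
    rank_g = genorm_stepwise_rank(expr, sd_ct=sd_table["sd_ct"])
    stability = normfinder_stability(expr, groups)
    rank_n = stability.rank(method="first").astype(int)
    passed = set(
        prefilter_normalizer_candidates(
            ct.subset_assays(assays), max_ct=max_ct, min_valid_fraction=min_valid_fraction
        )
    )
    report = pd.DataFrame(
        {
            "assay": assays,
            "mean_ct": sd_table["mean_ct"].reindex(assays).to_numpy(),
            "sd_ct": sd_table["sd_ct"].reindex(assays).to_numpy(),
            "m_value": m.reindex(assays).to_numpy(),
            "stability_value": stability.reindex(assays).to_numpy(),
            "rank_genorm": rank_g.reindex(assays).to_numpy(),
            "rank_normfinder": rank_n.reindex(assays).to_numpy(),
            "prefilter_pass": [a in passed for a in assays],
        }
    )
    return report
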