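"""Small-sample moderated differential expression: the random variance model.

With only a handful of arrays per group, the per-gene variance estimate is
the weak point of the ordinary t-test.  The random variance model (RVM)
assumes the per-gene precision ``1/sigma_g^2`` is drawn from a
``Gamma(a, scale=b)`` distribution shared across genes.  Under that prior the
pooled sample variance satisfies ``s^2 * a * b ~ F(f, 2a)`` across genes
(``f = n1 + n2 - 2``), which lets ``(a, b)`` be fitted by maximum likelihood
on all genes at once.  Each gene's variance is then replaced by the shrunken

    s~^2 = (f * s^2 + 2/b) / (f + 2a)

and the moderated t statistic ``(mean_d - mean_c) / sqrt(s~^2 (1/n1 + 1/n2))``
is referred to a t distribution with ``f + 2a`` degrees of freedom — the
extra ``2a`` degrees of freedom are what the prior buys in small samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.optimize
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .io import CONTROL, DISEASE, ExpressionMatrix

logger = logging.getLogger(__name__)

UP, DOWN, NS = "up", "down", "ns"


@dataclass(frozen=True)
class RVMPrior:
    """Fitted Gamma(a, scale=b) prior on per-gene precisions."""

    a: float
    b: float
    f: int  # residual degrees of freedom the prior was fitted on

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("prior parameters must be > 0")
        if self.f < 1:
            raise ValueError("residual degrees of freedom must be >= 1")

    @property
    def df_mod(self) -> float:
        return self.f + 2.0 * self.a

    @property
    def prior_variance(self) -> float:
        """Variance value toward which s^2 is shrunk: (2/b) / (2a) = 1/(a b)."""
        return 1.0 / (self.a * self.b)


def pooled_variances(matrix: ExpressionMatrix) -> Tuple[np.ndarray, int]:
    """Per-gene pooled two-group sample variance and its degrees of freedom."""
    xd = matrix.group_values(DISEASE).to_numpy()
    xc = matrix.group_values(CONTROL).to_numpy()
    n1, n2 = xd.shape[1], xc.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples for a pooled variance")
    f = n1 + n2 - 2
    s2 = ((n1 - 1) * xd.var(axis=1, ddof=1) + (n2 - 1) * xc.var(axis=1, ddof=1)) / f
    return s2, f


def _neg_loglik(log_ab: np.ndarray, s2: np.ndarray, f: int) -> float:
    a, b = np.exp(log_ab)
    # s^2 * a * b ~ F(f, 2a); include the Jacobian of the scaling
    x = s2 * a * b
    with np.errstate(over="ignore"):
        ll = scipy.stats.f.logpdf(x, f, 2.0 * a) + np.log(a * b)
    if not np.all(np.isfinite(ll)):
        return 1e300
    return -float(ll.sum())


def fit_rvm_prior(s2: np.ndarray, f: int, min_genes_warn: int = 100) -> RVMPrior:
    """Maximum-likelihood fit of the precision prior from pooled variances.

    Genes with zero variance carry no likelihood information under the model
    (the density of s^2 at 0 is 0 for f >= 3) and are excluded with a logged
    count; they are still testable afterwards because the moderated variance
    stays positive.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size == 0:
        raise ValueError("no variances supplied")
    n_zero = int((s2 <= 0).sum())
    if n_zero:
        logger.info("excluding %d zero-variance genes from RVM prior fit", n_zero)
    s2_pos = s2[s2 > 0]
    if s2_pos.size == 0:
        raise ValueError("all variances are zero; RVM prior cannot be fitted")
    if s2_pos.size < min_genes_warn:
        warnings.warn(
            f"RVM prior fitted on only {s2_pos.size} genes; "
            "estimates may be unstable", stacklevel=2)

    # coarse grid initialization, then bounded quasi-Newton on log-parameters
    grid_a = np.log(np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0]))
    grid_b = np.log(np.array([0.05, 0.2, 1.0, 5.0]) / np.mean(s2_pos))
    best, best_val = None, np.inf
    for la in grid_a:
        for lb in grid_b:
            val = _neg_loglik(np.array([la, lb]), s2_pos, f)
            if val < best_val:
                best, best_val = np.array([la, lb]), val
    res = scipy.optimize.minimize(
        _neg_loglik, best, args=(s2_pos, f), method="L-BFGS-B",
        bounds=[(-12.0, 12.0), (-25.0, 25.0)],
        options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500})
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"RVM prior fit did not converge: {res.message}")
    a, b = np.exp(res.x)
    return RVMPrior(a=float(a), b=float(b), f=int(f))


def rvm_t_test(matrix: ExpressionMatrix, prior: RVMPrior,
               p_threshold: float = 0.05,
               fc_threshold: Optional[float] = None) -> pd.DataFrame:
    """Moderated t-test of disease vs control for every gene.

    Returns a DataFrame indexed by gene id with columns ``mean_disease``,
    ``mean_control``, ``s2``, ``s2_tilde``, ``t_mod``, ``df_mod``, ``p``,
    ``q`` (Benjamini-Hochberg), ``fc`` (linear fold change, disease over
    control) and ``direction`` (up/down/ns at the given thresholds).
    """
    s2, f = pooled_variances(matrix)
    if f != prior.f:
        raise ValueError(
            f"prior fitted at f={prior.f} but matrix has f={f}")
    xd = matrix.group_values(DISEASE).to_numpy()
    xc = matrix.group_values(CONTROL).to_numpy()
    n1, n2 = xd.shape[1], xc.shape[1]
    mean_d, mean_c = xd.mean(axis=1), xc.mean(axis=1)
    diff = mean_d - mean_c

    s2_tilde = (f * s2 + 2.0 / prior.b) / (f + 2.0 * prior.a)
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    df_mod = prior.df_mod
    p = 2.0 * scipy.stats.t.sf(np.abs(t_mod), df_mod)
    degenerate = se == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} genes with zero moderated variance; "
            "p set to 0 where means differ, 1 otherwise", stacklevel=2)
        p = np.where(degenerate, np.where(diff != 0, 0.0, 1.0), p)
    q = bh_fdr(p)
    fc = np.power(2.0, diff)

    direction = np.full(len(s2), NS, dtype=object)
    sig = p < p_threshold
    if fc_threshold is not None:
        sig_up = sig & (fc >= fc_threshold)
        sig_down = sig & (fc <= 1.0 / fc_threshold)
    else:
        sig_up = sig & (fc > 1.0)
        sig_down = sig & (fc < 1.0)
    direction[sig_up] = UP
    direction[sig_down] = DOWN

    return pd.DataFrame(
        {"mean_disease": mean_d, "mean_control": mean_c, "s2": s2,
         "s2_tilde": s2_tilde, "t_mod": t_mod, "df_mod": df_mod,
         "p": p, "q": q, "fc": fc, "direction": direction},
        index=pd.Index(matrix.gene_ids, name="gene_id"))


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def run_de(matrix: ExpressionMatrix, config: PipelineConfig) -> pd.DataFrame:
    """Fit the RVM prior on the matrix and test every gene (one call)."""
    s2, f = pooled_variances(matrix)
    prior = fit_rvm_prior(s2, f)
    return rvm_t_test(matrix, prior, config.de_p_threshold,
                      config.de_fc_threshold)


def select_de(results: pd.DataFrame,
              config: PipelineConfig) -> Tuple[List[str], List[str]]:
    """Up- and down-regulated gene lists at the configured thresholds.

    A gene is selected iff ``p < de_p_threshold`` (strict) and its fold
    change is on the right side of 1 (and beyond ``de_fc_threshold`` when
    one is set).  The two lists are disjoint by construction.
    """
    sig = results["p"] < config.de_p_threshold
    if config.de_fc_threshold is not None:
        up = sig & (results["fc"] >= config.de_fc_threshold)
        down = sig & (results["fc"] <= 1.0 / config.de_fc_threshold)
    else:
        up = sig & (results["fc"] > 1.0)
        down = sig & (results["fc"] < 1.0)
    return list(results.index[up]), list(results.index[down])


def hierarchical_cluster(matrix: ExpressionMatrix):
    """Average-linkage clustering of genes and samples, 1 - Pearson distance.

    Mirrors the classic two-way heatmap clustering of significant genes.
    Zero-variance rows have no defined correlation and are dropped with a
    warning.  Returns ``(gene_order, sample_order, gene_linkage,
    sample_linkage)`` with leaf orders as id lists.
    """
    values = matrix.values
    row_sd = values.std(axis=1, ddof=0)
    if (row_sd == 0).any():
        warnings.warn(
            f"{int((row_sd == 0).sum())} zero-variance genes excluded "
            "from clustering", stacklevel=2)
        values = values.loc[row_sd > 0]
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("clustering needs >= 2 genes and >= 2 samples")

    def corr_dist(mat: np.ndarray) -> np.ndarray:
        r = np.corrcoef(mat)
        d = 1.0 - r
        iu = np.triu_indices_from(d, k=1)
        return np.clip(d[iu], 0.0, 2.0)

    gene_linkage = sch.linkage(corr_dist(values.to_numpy()), method="average")
    sample_sd = values.std(axis=0, ddof=0)
    sample_vals = values.loc[:, sample_sd > 0] if (sample_sd == 0).any() else values
    sample_linkage = sch.linkage(corr_dist(sample_vals.to_numpy().T),
                                 method="average")
    gene_order = [values.index[i] for i in sch.leaves_list(gene_linkage)]
    sample_order = [sample_vals.columns[i] for i in sch.leaves_list(sample_linkage)]
    return gene_order, sample_order, gene_linkage, sample_linkage
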