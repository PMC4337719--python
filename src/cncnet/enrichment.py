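"""Over-representation analysis of gene lists against GMT term maps.

For every term a 2x2 table is built over the analysis universe::

                in term   not in term
    DE gene        a           b
    not DE         c           d

and tested with the two-sided Fisher exact test and the Pearson chi-square
test (1 df, no continuity correction).  Benjamini-Hochberg adjustment is
applied across all terms tested within one (mode, direction) stratum.
Significance gates follow the study protocol: GO mode requires
``p < 0.01`` and ``FDR < 0.01``; pathway mode requires ``p < 0.05`` (plain
over-representation; no topology-based impact score).
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .config import PipelineConfig
from .de import bh_fdr

GO_MODE, PATHWAY_MODE = "go", "pathway"


def contingency_table(de_set: set, term_genes: set, universe: set) -> np.ndarray:
    """2x2 table [[a, b], [c, d]] of DE membership vs term membership."""
    term = term_genes & universe
    de = de_set & universe
    a = len(de & term)
    b = len(de) - a
    c = len(term) - a
    d = len(universe) - a - b - c
    return np.array([[a, b], [c, d]], dtype=int)


def fisher_two_sided(table: np.ndarray) -> float:
    """Two-sided Fisher exact p: mass of tables no more probable than the
    observed one, under the hypergeometric null with fixed margins."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (table < 0).any():
        raise ValueError("negative counts")
    return float(scipy.stats.fisher_exact(table, alternative="two-sided")[1])


def chi2_test(table: np.ndarray) -> Dict[str, float]:
    """Pearson chi-square (1 df, no continuity correction) with expected counts.

    Warns when any expected count is below 5 (the classical validity rule).
    Raises on a zero margin, where the statistic is undefined.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (table < 0).any():
        raise ValueError("negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero row or column margin")
    stat, p, _dof, expected = scipy.stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        warnings.warn("chi-square expected count < 5; prefer the Fisher p",
                      stacklevel=2)
    return {"chi2": float(stat), "p": float(p),
            "min_expected": float(expected.min())}


def enrich(de_genes: Iterable[str], universe: Iterable[str],
           term_map: Mapping[str, Sequence[str]],
           mode: str = GO_MODE, direction: str = "all",
           config: PipelineConfig | None = None) -> pd.DataFrame:
    """Test every term for over-representation of ``de_genes``.

    Terms without any universe gene are skipped; BH adjustment runs across
    the tested terms.  Returns a DataFrame sorted by Fisher p with columns
    ``term, direction, n_de_in_term, n_de, n_term, n_universe,
    fold_enrichment, p_fisher, p_chi2, q, significant``.  The chi-square p is
    NaN where a margin is zero (e.g. an empty DE list).
    """
    config = config or PipelineConfig()
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    de_set = set(de_genes)
    stray = de_set - universe
    if stray:
        raise ValueError(f"DE genes outside the universe: {sorted(stray)[:5]}")

    rows = []
    for term, genes in term_map.items():
        table = contingency_table(de_set, set(genes), universe)
        a, b = table[0]
        c, d = table[1]
        if a + c == 0:
            continue  # no universe gene carries the term
        p_fisher = fisher_two_sided(table)
        try:
            p_chi2 = chi2_test(table)["p"]
        except ValueError:
            p_chi2 = np.nan
        n_de, n_term = a + b, a + c
        n_univ = table.sum()
        fold = (a / n_de) / (n_term / n_univ) if n_de else np.nan
        rows.append({"term": term, "direction": direction,
                     "n_de_in_term": int(a), "n_de": int(n_de),
                     "n_term": int(n_term), "n_universe": int(n_univ),
                     "fold_enrichment": fold, "p_fisher": p_fisher,
                     "p_chi2": p_chi2})
    if not rows:
        return pd.DataFrame(columns=[
            "term", "direction", "n_de_in_term", "n_de", "n_term",
            "n_universe", "fold_enrichment", "p_fisher", "p_chi2", "q",
            "significant"]).set_index("term")
    out = pd.DataFrame(rows).set_index("term")
    out["q"] = bh_fdr(out["p_fisher"].to_numpy())
    if mode == GO_MODE:
        out["significant"] = (out["p_fisher"] < config.go_p_threshold) & \
                             (out["q"] < config.go_fdr_threshold)
    elif mode == PATHWAY_MODE:
        out["significant"] = out["p_fisher"] < config.pathway_p_threshold
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = out.sort_values(["p_fisher", "term"], kind="stable")
    return out
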