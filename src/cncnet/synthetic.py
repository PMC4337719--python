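"""Ground-truth simulator for the whole pipeline.

Generates a synthetic genome annotation and a matching two-group log2
expression matrix in which every signal the downstream stages look for is
planted explicitly and recorded in a :class:`SyntheticTruth`:

* differentially expressed genes with known sign and log2 effect;
* cis lncRNA-mRNA pairs in all four relation categories (overlap, antisense,
  upstream, downstream) with a tunable direction-concordance rate, placed so
  that an exhaustive interval scan recovers exactly the intended relations;
* per-gene variances drawn from the inverse-gamma law assumed by the random
  variance model (precision ``tau ~ Gamma(a, scale=b)``);
* coexpression modules built around a hub lncRNA whose within-group sample
  correlation with each member equals ``hub_corr_disease`` in the disease
  group and ``hub_corr_control`` in the control group, so that differential
  connectivity (diffK) has a known answer.

All features not involved in a planted pair are placed more than 300 kb from
every other feature, so the only cis relations in the output are the planted
ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import DEFAULT_PAIR_WINDOW, SyntheticConfig
from .io import (BIOTYPE_LNC, BIOTYPE_MRNA, CONTROL, DISEASE,
                 ExpressionMatrix, TranscriptAnnotation,
                 write_annotation_bed6, write_expression, write_gmt,
                 write_json)

RELATIONS = ("overlap", "antisense", "upstream", "downstream")

#: minimum gap between blocks, strictly beyond the pairing window
_BLOCK_SPACER = DEFAULT_PAIR_WINDOW + 1


class PlantedPair(NamedTuple):
    lnc_id: str
    mrna_id: str
    relation: str


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for validating downstream stages."""

    de_genes: Dict[str, int]              # gene id -> +1 (up) / -1 (down)
    planted_pairs: List[PlantedPair]
    module_membership: Dict[str, int]     # gene id -> module index
    hub_ids: Dict[int, str]               # module index -> hub lncRNA id
    per_gene_variance: Dict[str, float]

    def __post_init__(self) -> None:
        if any(d not in (-1, 1) for d in self.de_genes.values()):
            raise ValueError("directions must be +1 or -1")
        if any(v <= 0 for v in self.per_gene_variance.values()):
            raise ValueError("variances must be > 0")

    def de_ids_by_direction(self) -> Tuple[List[str], List[str]]:
        up = sorted(g for g, d in self.de_genes.items() if d > 0)
        down = sorted(g for g, d in self.de_genes.items() if d < 0)
        return up, down

    def to_dict(self) -> dict:
        return {
            "de_genes": self.de_genes,
            "planted_pairs": [p._asdict() for p in self.planted_pairs],
            "module_membership": self.module_membership,
            "hub_ids": {str(k): v for k, v in self.hub_ids.items()},
            "per_gene_variance": self.per_gene_variance,
        }


class _Block(NamedTuple):
    # features: (id, rel_start, rel_end, strand, biotype)
    features: tuple
    width: int
    pair: Optional[PlantedPair]


def _rng_for(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent child streams keyed on (seed, stream); no global state
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _gene_length(rng: np.random.Generator) -> int:
    return int(rng.integers(500, 5001))


def _pair_block(rng: np.random.Generator, relation: str,
                lnc_id: str, mrna_id: str) -> _Block:
    ll, lm = _gene_length(rng), _gene_length(rng)
    strand_m = "+" if rng.integers(2) == 0 else "-"
    if relation in ("overlap", "antisense"):
        strand_l = strand_m if relation == "overlap" else ("-" if strand_m == "+" else "+")
        offset = int(rng.integers(0, lm - 100))
        feats = ((mrna_id, 0, lm, strand_m, BIOTYPE_MRNA),
                 (lnc_id, offset, offset + ll, strand_l, BIOTYPE_LNC))
        width = max(lm, offset + ll)
    else:
        strand_l = "+" if rng.integers(2) == 0 else "-"
        gap = int(rng.integers(1_000, 250_001))
        lnc_first = (strand_m == "+") == (relation == "upstream")
        if lnc_first:
            feats = ((lnc_id, 0, ll, strand_l, BIOTYPE_LNC),
                     (mrna_id, ll + gap, ll + gap + lm, strand_m, BIOTYPE_MRNA))
            width = ll + gap + lm
        else:
            feats = ((mrna_id, 0, lm, strand_m, BIOTYPE_MRNA),
                     (lnc_id, lm + gap, lm + gap + ll, strand_l, BIOTYPE_LNC))
            width = lm + gap + ll
    return _Block(feats, width, PlantedPair(lnc_id, mrna_id, relation))


def generate_annotation(
    config: SyntheticConfig,
) -> Tuple[TranscriptAnnotation, List[PlantedPair]]:
    """Lay out the synthetic genome and return the planted cis pairs.

    Each planted pair occupies one genomic block whose internal geometry
    forces exactly the intended relation; blocks (and all background
    features) are separated by more than the 300 kb pairing window so no
    accidental relation can arise.

    Raises ``ValueError`` when the requested features cannot fit on the
    configured genome with that spacing.
    """
    rng = _rng_for(config, 1)
    npp = config.n_planted_pairs_per_category
    lnc_ids = [f"lnc_{i:05d}" for i in range(config.n_lnc)]
    mrna_ids = [f"mrna_{i:05d}" for i in range(config.n_mrna)]

    blocks: List[_Block] = []
    li = mi = 0
    for relation in RELATIONS:
        for _ in range(npp):
            blocks.append(_pair_block(rng, relation, lnc_ids[li], mrna_ids[mi]))
            li += 1
            mi += 1
    for fid in lnc_ids[li:]:
        length = _gene_length(rng)
        strand = "+" if rng.integers(2) == 0 else "-"
        blocks.append(_Block(((fid, 0, length, strand, BIOTYPE_LNC),), length, None))
    for fid in mrna_ids[mi:]:
        length = _gene_length(rng)
        strand = "+" if rng.integers(2) == 0 else "-"
        blocks.append(_Block(((fid, 0, length, strand, BIOTYPE_MRNA),), length, None))

    order = rng.permutation(len(blocks))
    rows = []
    pairs: List[PlantedPair] = []
    chrom_idx, cursor = 0, int(rng.integers(0, 10_000))
    for bi in order:
        block = blocks[bi]
        if cursor + block.width > config.chrom_length:
            chrom_idx += 1
            cursor = int(rng.integers(0, 10_000))
            if chrom_idx >= config.n_chromosomes or \
                    cursor + block.width > config.chrom_length:
                raise ValueError(
                    "synthetic genome too small: features cannot be placed "
                    "more than 300 kb apart; increase chrom_length or "
                    "n_chromosomes, or reduce feature counts"
                )
        chrom = f"chr{chrom_idx + 1}"
        for fid, rs, re, strand, biotype in block.features:
            rows.append((fid, chrom, cursor + rs, cursor + re, strand, biotype))
        if block.pair is not None:
            pairs.append(block.pair)
        cursor += block.width + _BLOCK_SPACER + int(rng.integers(0, 50_000))

    df = pd.DataFrame(rows, columns=["id", "chrom", "start", "end",
                                     "strand", "biotype"])
    df = df.sort_values(["chrom", "start", "id"], kind="stable").reset_index(drop=True)
    pairs.sort()
    return TranscriptAnnotation(df), pairs


def _standardize(v: np.ndarray) -> np.ndarray:
    c = v - v.mean()
    norm = np.sqrt((c ** 2).sum())
    if norm == 0:  # degenerate draw; probability zero for continuous noise
        raise ValueError("degenerate noise vector in module construction")
    return c / norm


def generate_expression(
    annotation: TranscriptAnnotation,
    config: SyntheticConfig,
    planted_pairs: Sequence[PlantedPair] = (),
) -> Tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw the two-group log2 expression matrix over the annotation.

    Per gene: baseline mean uniform on log2 [6, 14], precision
    ``tau ~ Gamma(rvm_a, scale=rvm_b)`` hence variance ``1/tau``; planted
    differentially expressed genes get ``±effect_size_log2`` added to the
    disease group.  Module genes share a latent factor per group, scaled so
    each member's within-group sample correlation with the hub equals the
    configured hub correlation exactly (see docs/methods.md).
    """
    if config.n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 (within-group variance undefined)")
    rng = _rng_for(config, 2)
    n = config.n_per_group
    gene_ids = list(annotation.df["id"])
    n_genes = len(gene_ids)
    sample_ids = [f"{DISEASE}_{i + 1:02d}" for i in range(n)] + \
                 [f"{CONTROL}_{i + 1:02d}" for i in range(n)]
    groups = pd.Series([DISEASE] * n + [CONTROL] * n, index=sample_ids)

    mu = rng.uniform(6.0, 14.0, size=n_genes)
    tau = rng.gamma(shape=config.rvm_a, scale=config.rvm_b, size=n_genes)
    sigma = 1.0 / np.sqrt(tau)

    biotype = annotation.df.set_index("id")["biotype"]
    pair_members = {p.lnc_id for p in planted_pairs} | \
                   {p.mrna_id for p in planted_pairs}

    # --- choose module hubs (lncRNA) and members (mRNA) outside pairs
    free_lnc = [g for g in gene_ids
                if biotype[g] == BIOTYPE_LNC and g not in pair_members]
    free_mrna = [g for g in gene_ids
                 if biotype[g] == BIOTYPE_MRNA and g not in pair_members]
    hub_ids: Dict[int, str] = {}
    module_membership: Dict[str, int] = {}
    if config.n_modules > 0:
        n_members = config.module_size - 1
        if len(free_lnc) < config.n_modules or \
                len(free_mrna) < config.n_modules * n_members:
            raise ValueError("not enough free features for the requested modules")
        hubs = list(rng.choice(free_lnc, size=config.n_modules, replace=False))
        members = list(rng.choice(free_mrna,
                                  size=config.n_modules * n_members,
                                  replace=False))
        for m in range(config.n_modules):
            hub_ids[m] = hubs[m]
            module_membership[hubs[m]] = m
            for g in members[m * n_members:(m + 1) * n_members]:
                module_membership[g] = m

    # --- directions: pair members first (concordance), then modules, then
    # a frac_de draw over the remaining background genes
    de_genes: Dict[str, int] = {}
    for p in planted_pairs:
        lnc_dir = 1 if rng.integers(2) == 0 else -1
        concordant = rng.random() < config.concordance_rate
        de_genes[p.lnc_id] = lnc_dir
        de_genes[p.mrna_id] = lnc_dir if concordant else -lnc_dir
    for g in module_membership:
        de_genes[g] = 1 if rng.integers(2) == 0 else -1
    background = [g for g in gene_ids if g not in de_genes]
    n_bg_de = int(round(config.frac_de * len(background)))
    if n_bg_de > 0:
        for g in rng.choice(background, size=n_bg_de, replace=False):
            de_genes[str(g)] = 1 if rng.integers(2) == 0 else -1

    # --- base noise and planted effects
    values = mu[:, None] + sigma[:, None] * rng.standard_normal((n_genes, 2 * n))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    effect = np.zeros(n_genes)
    for g, d in de_genes.items():
        effect[gene_pos[g]] = d * config.effect_size_log2
    values[:, :n] += effect[:, None]

    # --- module structure: per group, exact sample correlation to the hub
    group_slices = {DISEASE: slice(0, n), CONTROL: slice(n, 2 * n)}
    rho_of = {DISEASE: config.hub_corr_disease, CONTROL: config.hub_corr_control}
    for m, hub in hub_ids.items():
        member_ids = [g for g, mm in module_membership.items()
                      if mm == m and g != hub]
        for grp, sl in group_slices.items():
            rho = rho_of[grp]
            h = _standardize(rng.standard_normal(n))
            hi = gene_pos[hub]
            values[hi, sl] = mu[hi] + (effect[hi] if grp == DISEASE else 0.0) \
                + sigma[hi] * h * np.sqrt(n - 1)
            for g in member_ids:
                e = rng.standard_normal(n)
                resid = e - e.mean() - (e @ h) * h
                resid = _standardize(resid)
                noise = rho * h + np.sqrt(max(0.0, 1 - rho ** 2)) * resid
                gi = gene_pos[g]
                values[gi, sl] = mu[gi] + (effect[gi] if grp == DISEASE else 0.0) \
                    + sigma[gi] * noise * np.sqrt(n - 1)

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), groups)
    truth = SyntheticTruth(
        de_genes=de_genes,
        planted_pairs=list(planted_pairs),
        module_membership=module_membership,
        hub_ids=hub_ids,
        per_gene_variance={g: float(sigma[i] ** 2)
                           for i, g in enumerate(gene_ids)},
    )
    return matrix, truth


def generate_term_map(
    annotation: TranscriptAnnotation,
    truth: SyntheticTruth,
    config: SyntheticConfig,
    n_terms: int = 40,
    n_enriched: int = 5,
    enriched_de_fraction: float = 0.5,
) -> Dict[str, List[str]]:
    """Random GMT-style gene sets over the mRNA universe.

    The first ``n_enriched`` terms draw half their members from the planted
    differentially expressed mRNAs, giving the enrichment stage a real
    signal; the rest are uniform draws (null terms).
    """
    rng = _rng_for(config, 3)
    universe = annotation.ids_of_biotype(BIOTYPE_MRNA)
    de_mrna = [g for g in universe if g in truth.de_genes]
    terms: Dict[str, List[str]] = {}
    for t in range(n_terms):
        size = int(rng.integers(15, 121))
        size = min(size, len(universe))
        if t < n_enriched and de_mrna:
            n_de = min(int(round(size * enriched_de_fraction)), len(de_mrna))
            chosen = set(rng.choice(de_mrna, size=n_de, replace=False))
            rest = [g for g in universe if g not in chosen]
            chosen |= set(rng.choice(rest, size=size - n_de, replace=False))
        else:
            chosen = set(rng.choice(universe, size=size, replace=False))
        terms[f"TERM_{t:04d}"] = sorted(chosen)
    return terms


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    annotation: TranscriptAnnotation
    expression: ExpressionMatrix
    truth: SyntheticTruth
    term_map: Dict[str, List[str]]


def simulate(config: SyntheticConfig) -> SyntheticBundle:
    """Generate a complete, self-consistent input bundle for the pipeline."""
    annotation, pairs = generate_annotation(config)
    expression, truth = generate_expression(annotation, config, pairs)
    term_map = generate_term_map(annotation, truth, config)
    return SyntheticBundle(config, annotation, expression, truth, term_map)


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> Dict[str, Path]:
    """Write the bundle to disk (BED6, TSVs, GMT, truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": outdir / "annotation.bed",
        "expression": outdir / "expression.tsv",
        "design": outdir / "design.tsv",
        "terms": outdir / "terms.gmt",
        "truth": outdir / "truth.json",
    }
    write_annotation_bed6(bundle.annotation, paths["annotation"])
    write_expression(bundle.expression, paths["expression"], paths["design"])
    write_gmt(bundle.term_map, paths["terms"])
    write_json(bundle.truth.to_dict(), paths["truth"])
    return paths
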