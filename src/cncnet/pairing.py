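"""Cis classification of differentially expressed lncRNA-mRNA pairs.

Each DE lncRNA is related to each DE mRNA on the same chromosome as one of

* ``overlap``    — intervals intersect, same strand;
* ``antisense``  — intervals intersect, opposite strands;
* ``upstream``   — no intersection, boundary gap < the window (default
  300 kb), lncRNA entirely on the 5' side of the mRNA's transcription start;
* ``downstream`` — likewise on the 3' side of the mRNA's end;

or no relation at all.  Distance is the gap between the nearest interval
boundaries (0 for overlapping pairs); the window is a strict upper bound.
Orientation is anchored on the mRNA's strand by default (the coding gene is
the reference); ``anchor='lnc'`` flips the reference for the alternative
reading.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional

import numpy as np
import pandas as pd

from .config import DEFAULT_PAIR_WINDOW
from .io import BIOTYPE_LNC, BIOTYPE_MRNA, Feature, TranscriptAnnotation

OVERLAP, ANTISENSE, UPSTREAM, DOWNSTREAM = \
    "overlap", "antisense", "upstream", "downstream"
RELATION_CATEGORIES = (OVERLAP, ANTISENSE, UPSTREAM, DOWNSTREAM)


class PairRecord(NamedTuple):
    lnc_id: str
    mrna_id: str
    relation: str
    distance: int
    lnc_direction: str   # 'up' | 'down'
    mrna_direction: str
    concordant: bool


class PairSummary(NamedTuple):
    counts: Dict[str, int]
    total: int
    n_concordant: int
    n_discordant: int
    concordance_fraction: Optional[float]

    @property
    def concordance_percent(self) -> Optional[float]:
        if self.concordance_fraction is None:
            return None
        return round(100.0 * self.concordance_fraction, 1)


def _check_feature(f: Feature) -> None:
    if f.start >= f.end:
        raise ValueError(f"malformed feature {f.id!r}: start >= end")
    if f.strand not in ("+", "-"):
        raise ValueError(f"malformed feature {f.id!r}: strand {f.strand!r}")


def classify_relation(lnc: Feature, mrna: Feature,
                      max_distance: int = DEFAULT_PAIR_WINDOW,
                      anchor: str = "mrna") -> Optional[str]:
    """Relation of one lncRNA-mRNA pair, or ``None``.

    Overlap beats proximity: intersecting intervals are ``overlap`` (same
    strand) or ``antisense`` (opposite strand) regardless of the window.
    Non-overlapping pairs farther apart than ``max_distance`` (boundary gap,
    strict ``<``) have no relation.
    """
    _check_feature(lnc)
    _check_feature(mrna)
    if lnc.chrom != mrna.chrom:
        return None
    if lnc.start < mrna.end and mrna.start < lnc.end:
        return OVERLAP if lnc.strand == mrna.strand else ANTISENSE
    gap = max(lnc.start, mrna.start) - min(lnc.end, mrna.end)
    if gap >= max_distance:
        return None
    ref = mrna if anchor == "mrna" else lnc
    other = lnc if anchor == "mrna" else mrna
    # half-open intervals: a non-overlapping neighbour is entirely on one side
    other_is_left = other.end <= ref.start
    five_prime_side = other_is_left if ref.strand == "+" else not other_is_left
    return UPSTREAM if five_prime_side else DOWNSTREAM


def pair_distance(lnc: Feature, mrna: Feature) -> int:
    """Boundary gap between the two intervals (0 when they intersect)."""
    return max(0, max(lnc.start, mrna.start) - min(lnc.end, mrna.end))


def find_pairs(annotation: TranscriptAnnotation,
               de_lnc: Mapping[str, str],
               de_mrna: Mapping[str, str],
               max_distance: int = DEFAULT_PAIR_WINDOW,
               anchor: str = "mrna") -> List[PairRecord]:
    """All related DE lncRNA x DE mRNA pairs, one record per ordered pair.

    ``de_lnc`` and ``de_mrna`` map feature ids to their direction
    ('up'/'down').  A lncRNA may pair with many mRNAs and vice versa.  Uses a
    per-chromosome sweep over start-sorted mRNAs so only candidates within
    the window are examined.  Output is sorted by (chrom, lnc start,
    mrna start, ids).
    """
    fmap = annotation.feature_map()
    missing = [g for g in list(de_lnc) + list(de_mrna) if g not in fmap]
    if missing:
        raise KeyError(f"DE ids missing from annotation: {sorted(missing)[:10]}")
    for gid in de_lnc:
        if fmap[gid].biotype != BIOTYPE_LNC:
            raise ValueError(f"{gid!r} is not annotated as lncRNA")
    for gid in de_mrna:
        if fmap[gid].biotype != BIOTYPE_MRNA:
            raise ValueError(f"{gid!r} is not annotated as mRNA")

    by_chrom: Dict[str, List[Feature]] = {}
    for gid in de_mrna:
        by_chrom.setdefault(fmap[gid].chrom, []).append(fmap[gid])
    for feats in by_chrom.values():
        feats.sort(key=lambda f: (f.start, f.end, f.id))

    records: List[PairRecord] = []
    max_mrna_len = max((f.end - f.start for feats in by_chrom.values()
                        for f in feats), default=0)
    for lnc_id in de_lnc:
        lnc = fmap[lnc_id]
        feats = by_chrom.get(lnc.chrom)
        if not feats:
            continue
        starts = np.array([f.start for f in feats])
        # any related mRNA starts within [lnc.start - window - len, lnc.end + window)
        lo = np.searchsorted(starts, lnc.start - max_distance - max_mrna_len,
                             side="left")
        hi = np.searchsorted(starts, lnc.end + max_distance, side="right")
        for mrna in feats[lo:hi]:
            relation = classify_relation(lnc, mrna, max_distance, anchor)
            if relation is None:
                continue
            ld, md = de_lnc[lnc_id], de_mrna[mrna.id]
            records.append(PairRecord(
                lnc_id=lnc_id, mrna_id=mrna.id, relation=relation,
                distance=pair_distance(lnc, mrna),
                lnc_direction=ld, mrna_direction=md, concordant=ld == md))
    records.sort(key=lambda r: (fmap[r.lnc_id].chrom, fmap[r.lnc_id].start,
                                fmap[r.mrna_id].start, r.lnc_id, r.mrna_id))
    return records


def summarize_pairs(pairs: Iterable[PairRecord] = (),
                    counts: Mapping[str, int] | None = None,
                    n_concordant: int | None = None) -> PairSummary:
    """Category counts plus the direction-concordance fraction.

    Either pass a list of :class:`PairRecord` (normal use) or pre-tabulated
    ``counts`` per relation with ``n_concordant`` (worked-example use).  An
    empty input yields a fraction of ``None`` rather than a crash.
    """
    if counts is None:
        pairs = list(pairs)
        counts = {rel: 0 for rel in RELATION_CATEGORIES}
        for p in pairs:
            counts[p.relation] += 1
        n_concordant = sum(1 for p in pairs if p.concordant)
    else:
        counts = {rel: int(counts.get(rel, 0)) for rel in RELATION_CATEGORIES}
        if n_concordant is None:
            raise ValueError("n_concordant required with pre-tabulated counts")
    total = sum(counts.values())
    frac = (n_concordant / total) if total else None
    return PairSummary(counts=counts, total=total,
                       n_concordant=int(n_concordant),
                       n_discordant=total - int(n_concordant),
                       concordance_fraction=frac)


def pairs_to_frame(pairs: List[PairRecord]) -> pd.DataFrame:
    return pd.DataFrame([p._asdict() for p in pairs],
                        columns=list(PairRecord._fields))


def write_pairs_bedpe(pairs: List[PairRecord],
                      annotation: TranscriptAnnotation, path) -> None:
    """BEDPE of paired intervals: lncRNA first block, mRNA second."""
    fmap = annotation.feature_map()
    with open(path, "w") as fh:
        for p in pairs:
            a, b = fmap[p.lnc_id], fmap[p.mrna_id]
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t"
                     f"{b.end}\t{p.lnc_id}|{p.mrna_id}\t0\t{a.strand}\t"
                     f"{b.strand}\t{p.relation}\t{p.distance}\n")
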