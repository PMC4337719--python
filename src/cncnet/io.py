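"""Core data containers and readers/writers for the standard formats.

The pipeline speaks plain-text formats throughout: expression as TSV with a
two-column design file, annotation as BED6 (or minimal GTF on input), gene
sets as GMT, networks as SIF/GraphML, ground truth and run-logs as JSON.
All genomic coordinates are 0-based half-open internally (BED convention);
1-based closed GTF coordinates are converted on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, NamedTuple

import numpy as np
import pandas as pd

DISEASE = "disease"
CONTROL = "control"

BIOTYPE_LNC = "lncRNA"
BIOTYPE_MRNA = "mRNA"


class Feature(NamedTuple):
    """One annotated transcript: 0-based half-open interval plus strand/biotype."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) with a two-group design.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns;
    ``groups`` maps every sample id to ``'disease'`` or ``'control'``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"sample not in design: {missing}")
        bad = set(self.groups.unique()) - {DISEASE, CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        self.groups = self.groups.loc[self.values.columns]
        for grp in (DISEASE, CONTROL):
            if not (self.groups == grp).any():
                raise ValueError(f"group {grp!r} has no samples")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at gene {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.columns)

    def samples_of(self, group: str) -> List[str]:
        return list(self.groups.index[self.groups == group])

    def group_values(self, group: str) -> pd.DataFrame:
        """Sub-matrix restricted to one group's samples."""
        return self.values[self.samples_of(group)]

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [g for g in gene_ids]
        missing = [g for g in ids if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[ids], self.groups.copy())


@dataclass
class TranscriptAnnotation:
    """Genomic intervals, strands and biotypes for all features."""

    df: pd.DataFrame  # columns: id, chrom, start, end, strand, biotype

    def __post_init__(self) -> None:
        required = ["id", "chrom", "start", "end", "strand", "biotype"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if self.df["id"].duplicated().any():
            dup = self.df.loc[self.df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if (self.df["start"] >= self.df["end"]).any():
            bad = self.df.loc[self.df["start"] >= self.df["end"], "id"].iloc[0]
            raise ValueError(f"start >= end for feature {bad!r}")
        bad_strand = ~self.df["strand"].isin(["+", "-"])
        if bad_strand.any():
            bad = self.df.loc[bad_strand, "id"].iloc[0]
            raise ValueError(f"unknown strand for feature {bad!r}")
        bad_bt = ~self.df["biotype"].isin([BIOTYPE_LNC, BIOTYPE_MRNA])
        if bad_bt.any():
            bad = self.df.loc[bad_bt, "id"].iloc[0]
            raise ValueError(f"unknown biotype for feature {bad!r}")
        self.df = self.df[required].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def features(self) -> List[Feature]:
        return [Feature(*row) for row in self.df.itertuples(index=False)]

    def feature_map(self) -> Dict[str, Feature]:
        return {f.id: f for f in self.features()}

    def ids_of_biotype(self, biotype: str) -> List[str]:
        return list(self.df.loc[self.df["biotype"] == biotype, "id"])


# ---------------------------------------------------------------------------
# expression TSV + design
# ---------------------------------------------------------------------------

def read_expression(path_tsv: str | Path, path_design: str | Path) -> ExpressionMatrix:
    """Read a genes x samples log2 TSV plus a (sample, group) design TSV."""
    values = pd.read_csv(path_tsv, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    for col in values.columns:
        if not pd.api.types.is_numeric_dtype(values[col]):
            bad = values[col][pd.to_numeric(values[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric cell in column {col!r}, row {bad.index[0]!r}"
            )
    design = pd.read_csv(path_design, sep="\t", dtype=str)
    if list(design.columns[:2]) != ["sample", "group"]:
        raise ValueError("design file must have columns 'sample' and 'group'")
    groups = pd.Series(design["group"].values, index=design["sample"].values)
    missing = [s for s in values.columns if s not in groups.index]
    if missing:
        raise ValueError(f"sample not in design: {missing}")
    return ExpressionMatrix(values, groups)


def write_expression(matrix: ExpressionMatrix, path_tsv: str | Path,
                     path_design: str | Path) -> None:
    matrix.values.to_csv(path_tsv, sep="\t", index_label="gene_id",
                         float_format="%.17g", lineterminator="\n")
    design = pd.DataFrame({"sample": matrix.sample_ids,
                           "group": matrix.groups.values})
    design.to_csv(path_design, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# annotation: BED6 and minimal GTF
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> TranscriptAnnotation:
    """Read BED6 (name = ``id|biotype``) or minimal GTF annotation.

    Format is chosen by extension: ``.bed`` vs ``.gtf``/``.gff``.  GTF input
    uses 1-based closed coordinates and is converted to 0-based half-open.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        return _read_gtf(path)
    return _read_bed6(path)


def _read_bed6(path: Path) -> TranscriptAnnotation:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: BED6 needs 6 columns")
            chrom, start, end, name, _score, strand = parts[:6]
            if "|" not in name:
                raise ValueError(f"{path}:{ln}: BED name must be 'id|biotype'")
            fid, biotype = name.rsplit("|", 1)
            rows.append((fid, chrom, int(start), int(end), strand, biotype))
    return _annotation_from_rows(rows)


def _read_gtf(path: Path) -> TranscriptAnnotation:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{ln}: GTF needs 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = parts
            if ftype != "transcript":
                continue
            attr = _parse_gtf_attrs(attrs)
            fid = attr.get("transcript_id") or attr.get("gene_id")
            biotype = attr.get("gene_biotype") or attr.get("transcript_biotype")
            if fid is None or biotype is None:
                raise ValueError(
                    f"{path}:{ln}: GTF attributes need transcript_id and biotype"
                )
            # GTF is 1-based closed; internal convention is 0-based half-open
            rows.append((fid, chrom, int(start) - 1, int(end), strand, biotype))
    return _annotation_from_rows(rows)


def _parse_gtf_attrs(attrs: str) -> Dict[str, str]:
    out = {}
    for chunk in attrs.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def _annotation_from_rows(rows) -> TranscriptAnnotation:
    df = pd.DataFrame(rows, columns=["id", "chrom", "start", "end",
                                     "strand", "biotype"])
    return TranscriptAnnotation(df)


def write_annotation_bed6(annotation: TranscriptAnnotation,
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in annotation.features():
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}|{f.biotype}\t0\t"
                     f"{f.strand}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> Dict[str, List[str]]:
    """Read a GMT file into an ordered term -> member-gene mapping."""
    terms: Dict[str, List[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT needs term, description, genes")
            term = parts[0]
            if term in terms:
                raise ValueError(f"{path}:{ln}: duplicate term {term!r}")
            terms[term] = [g for g in parts[2:] if g]
    return terms


def write_gmt(terms: Mapping[str, List[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for term, genes in terms.items():
            desc = (descriptions or {}).get(term, "na")
            fh.write("\t".join([term, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# JSON helpers (truth, run-log)
# ---------------------------------------------------------------------------

def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
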