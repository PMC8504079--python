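"""Expression-matrix I/O, log2 transform, gene ordering and 0-255 rescaling.

Bulk RNA-seq quantifications arrive as samples x genes tables of FPKM
(Fragments Per Kilobase of transcript per Million mapped reads).  Before a
cohort can be rendered into artificial image objects the pipeline

1. log2-transforms the FPKM values (with a pseudocount, since FPKM
   contains exact zeros),
2. fixes a genome-position gene order: the genes shared by all cohorts,
   sorted by chromosome and transcription start site (TSS), truncated to
   the pixel capacity of the target image configuration, and
3. min-max rescales each gene independently into the 1-byte intensity
   range 0-255.

The per-gene scaler fit on a training cohort can be persisted and applied
to an external cohort (values outside the training range clip to [0, 255]).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    MissingGeneError,
    SizingError,
    StateError,
    ValidationError,
)

__all__ = [
    "ExpressionMatrix",
    "ScalerParams",
    "ScaledMatrix",
    "chromosome_rank",
    "read_expression_table",
    "log2_transform",
    "shared_gene_order",
    "rescale_per_gene",
    "read_labels",
    "validate_labels",
]

KI67_PERCENT_CUTOFF = 20.0  # <=20% stained cells -> negative (class 0)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Samples x genes expression values with a scale marker.

    ``scale`` is ``"fpkm"`` for raw non-negative quantifications and
    ``"log2"`` after :func:`log2_transform`.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray  # (n_samples, n_genes) float
    scale: str = "fpkm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be 2-dimensional")
        n_s, n_g = self.values.shape
        if n_s != len(self.sample_ids) or n_g != len(self.gene_ids):
            raise ValidationError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        for name, ids in (("sample", self.sample_ids), ("gene", self.gene_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise ValidationError(f"duplicate {name} identifier(s): {dupes[:5]}")
        if self.scale not in ("fpkm", "log2"):
            raise ValidationError(f"unknown scale marker {self.scale!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )
        if self.scale == "fpkm" and np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative FPKM {self.values[i, j]} at sample "
                f"{self.sample_ids[i]!r}, gene {self.gene_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Reorder/subset columns to ``genes`` (all must be present)."""
        idx = pd.Index(self.gene_ids)
        missing = [g for g in genes if g not in idx]
        if missing:
            raise MissingGeneError(f"gene(s) absent from matrix: {missing[:5]}")
        pos = idx.get_indexer(genes)
        return ExpressionMatrix(
            sample_ids=list(self.sample_ids),
            gene_ids=list(genes),
            values=self.values[:, pos],
            scale=self.scale,
        )


@dataclass
class ScalerParams:
    """Per-gene (min, max) of log2 values fit on a training cohort."""

    genes: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if not (len(self.genes) == self.mins.size == self.maxs.size):
            raise ValidationError("scaler gene/min/max lengths differ")
        if np.any(self.maxs < self.mins):
            raise ValidationError("scaler has max < min for some gene")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "min": self.mins, "max": self.maxs})

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "ScalerParams":
        df = pd.read_csv(path, sep="\t")
        return cls(genes=df["gene"].astype(str).tolist(),
                   mins=df["min"].to_numpy(), maxs=df["max"].to_numpy())


@dataclass
class ScaledMatrix:
    """Samples x genes integer intensities in [0, 255], in gene order."""

    sample_ids: list[str]
    gene_order: list[str]
    values: np.ndarray  # (n_samples, n_genes) uint8
    scaler: ScalerParams | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.min(initial=0) < 0 or vals.max(initial=0) > 255:
            raise ValidationError("scaled values must lie in [0, 255]")
        self.values = vals.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_expression_table(
    path: str | Path | io.IOBase,
    sep: str | None = None,
    orientation: str = "samples_by_genes",
    scale: str = "fpkm",
) -> ExpressionMatrix:
    """Read a delimited expression table into an :class:`ExpressionMatrix`.

    Parameters
    ----------
    path
        Delimited text file; first column holds row identifiers, header
        holds column identifiers.
    sep
        Field delimiter; ``None`` infers ``,`` for ``.csv`` and tab
        otherwise.
    orientation
        ``"samples_by_genes"`` (rows are samples) or ``"genes_by_samples"``
        (rows are genes, as GEO series matrices are usually laid out); the
        result is always samples x genes.
    scale
        Scale marker to attach, ``"fpkm"`` (validated non-negative) or
        ``"log2"``.
    """
    if sep is None:
        name = getattr(path, "name", str(path))
        sep = "," if str(name).endswith(".csv") else "\t"
    if hasattr(path, "read"):
        buf = io.StringIO(path.read())
    else:
        buf = io.StringIO(Path(path).read_text())
    header = buf.readline().rstrip("\n").split(sep)[1:]
    dupes = pd.Index(header)[pd.Index(header).duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"duplicate identifier(s) in header: {dupes[:5]}")
    buf.seek(0)
    df = pd.read_csv(buf, sep=sep, index_col=0)
    if orientation == "genes_by_samples":
        df = df.T
    elif orientation != "samples_by_genes":
        raise ValidationError(f"unknown orientation {orientation!r}")
    return ExpressionMatrix(
        sample_ids=[str(s) for s in df.index],
        gene_ids=[str(g) for g in df.columns],
        values=df.to_numpy(dtype=float),
        scale=scale,
    )


# ---------------------------------------------------------------------------
# log2 transform
# ---------------------------------------------------------------------------

def log2_transform(mat: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return ``log2(x + pseudocount)`` of an FPKM-scale matrix.

    The default pseudocount of 1 maps FPKM 0 to intensity 0 exactly.
    Applying the transform to an already log2-scaled matrix raises
    :class:`~aiocnn.errors.StateError`.
    """
    if mat.scale != "fpkm":
        raise StateError("matrix is already log2-transformed")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    return ExpressionMatrix(
        sample_ids=list(mat.sample_ids),
        gene_ids=list(mat.gene_ids),
        values=np.log2(mat.values + pseudocount),
        scale="log2",
    )


def inverse_log2(mat: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Inverse of :func:`log2_transform` (useful for round-trip checks)."""
    if mat.scale != "log2":
        raise StateError("matrix is not log2-scaled")
    return ExpressionMatrix(
        sample_ids=list(mat.sample_ids),
        gene_ids=list(mat.gene_ids),
        values=np.exp2(mat.values) - pseudocount,
        scale="fpkm",
    )


# ---------------------------------------------------------------------------
# gene ordering
# ---------------------------------------------------------------------------

_SPECIAL_CHROMS = {"X": 23, "Y": 24, "MT": 25, "M": 25}


def chromosome_rank(chrom: str) -> tuple[int, str]:
    """Total order on contigs: 1..22 numerically, then X, Y, MT, then
    other contigs alphabetically."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.isdigit():
        return (int(c), "")
    if c.upper() in _SPECIAL_CHROMS:
        return (_SPECIAL_CHROMS[c.upper()], "")
    return (26, c)


def _normalize_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    required = {"symbol", "chromosome", "tss"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValidationError(f"annotation table missing column(s): {sorted(missing)}")
    ann = annotation.loc[:, ["symbol", "chromosome", "tss"]].copy()
    ann["symbol"] = ann["symbol"].astype(str)
    if ann["symbol"].duplicated().any():
        dupes = ann.loc[ann["symbol"].duplicated(), "symbol"].unique().tolist()
        raise ValidationError(f"duplicate annotation symbol(s): {dupes[:5]}")
    tss = pd.to_numeric(ann["tss"], errors="raise")
    if (tss < 0).any():
        raise ValidationError("annotation TSS must be non-negative")
    ann["tss"] = tss.astype(np.int64)
    return ann


def shared_gene_order(
    annotation: pd.DataFrame,
    gene_lists: Iterable[Iterable[str]],
    n_selected: int,
) -> list[str]:
    """Genome-position gene order over the genes shared by all cohorts.

    Intersects ``gene_lists`` (one set of gene symbols per cohort),
    restricts to annotated genes, sorts by (chromosome rank, TSS, symbol)
    and keeps the first ``n_selected`` genes — the list that fills the
    image pixel by pixel.
    """
    ann = _normalize_annotation(annotation)
    sets = [set(map(str, gl)) for gl in gene_lists]
    if not sets:
        raise ValidationError("at least one gene list is required")
    shared = set.intersection(*sets) & set(ann["symbol"])
    if n_selected <= 0:
        raise ValidationError("n_selected must be positive")
    if len(shared) < n_selected:
        raise SizingError(
            f"shared annotated gene set has {len(shared)} genes, "
            f"fewer than the requested {n_selected}"
        )
    sub = ann[ann["symbol"].isin(shared)]
    keys = sorted(
        zip(sub["chromosome"], sub["tss"], sub["symbol"]),
        key=lambda t: (chromosome_rank(t[0]), int(t[1]), t[2]),
    )
    return [sym for _, _, sym in keys[:n_selected]]


# ---------------------------------------------------------------------------
# rescaling
# ---------------------------------------------------------------------------

def rescale_per_gene(
    mat: ExpressionMatrix,
    order: Sequence[str],
    scaler: ScalerParams | None = None,
) -> tuple[ScaledMatrix, ScalerParams]:
    """Min-max rescale each gene of a log2 matrix into integers 0-255.

    With ``scaler=None`` the per-gene (min, max) are fit on ``mat`` itself,
    so the cohort minimum maps to 0 and the maximum to 255.  With a prefit
    scaler (external-cohort application) out-of-range values clip to the
    byte range.  Quantization is round-half-to-even.  Constant genes
    (max == min) map to 0.
    """
    if mat.scale != "log2":
        raise StateError("rescaling expects a log2-scale matrix")
    sub = mat.subset_genes(list(order))
    x = sub.values
    if scaler is None:
        scaler = ScalerParams(
            genes=list(order), mins=x.min(axis=0), maxs=x.max(axis=0)
        )
    else:
        if list(scaler.genes) != list(order):
            raise ValidationError("scaler gene list does not match the gene order")
    span = scaler.maxs - scaler.mins
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = 255.0 * (x - scaler.mins) / span
    scaled[:, span == 0] = 0.0
    scaled = np.clip(np.rint(scaled), 0, 255)  # np.rint is half-to-even
    return (
        ScaledMatrix(
            sample_ids=list(mat.sample_ids),
            gene_order=list(order),
            values=scaled,
            scaler=scaler,
        ),
        scaler,
    )


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

_NHG_STRINGS = {
    "I": 0, "II": 1, "III": 2,
    "GRADE I": 0, "GRADE II": 1, "GRADE III": 2,
    "G1": 0, "G2": 1, "G3": 2,
}


def _code_nhg(value) -> float:
    """Map a raw NHG entry to the 0/1/2 coding (NaN for missing)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    if isinstance(value, str):
        s = value.strip()
        if s == "" or s.upper() in ("NA", "NAN", "MISSING"):
            return np.nan
        if s.upper() in _NHG_STRINGS:
            return float(_NHG_STRINGS[s.upper()])
        try:
            value = float(s)
        except ValueError:
            raise ValidationError(f"unrecognized NHG value {value!r}")
    v = float(value)
    if v in (1.0, 2.0, 3.0):
        return v - 1.0  # grades I/II/III given as 1/2/3
    raise ValidationError(f"NHG value {value!r} outside the I/II/III (1/2/3) domain")


def read_labels(
    path: str | Path | io.IOBase,
    sep: str | None = None,
    sample_col: str = "sample_id",
    ki67_col: str = "ki67",
    ki67_percent_col: str = "ki67_percent",
    nhg_col: str = "nhg",
    time_col: str = "survival_days",
    event_col: str = "event",
) -> pd.DataFrame:
    """Read a sample label table.

    Returns a DataFrame indexed by sample id with nullable-integer columns
    ``ki67`` (0/1), ``nhg`` (0/1/2) and optional float ``survival_days`` /
    integer ``event``.  If a raw Ki67 staining percentage column is present
    it is dichotomized at 20%: <=20 -> 0 (Ki67-), >20 -> 1 (Ki67+);
    missing stays missing.  NHG accepts Roman grades (optionally prefixed
    "Grade"), 1/2/3, or the already-coded 0/1/2 only via 1/2/3+Roman forms.
    """
    if sep is None:
        name = getattr(path, "name", str(path))
        sep = "," if str(name).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if sample_col not in df.columns:
        raise ValidationError(f"label table lacks the {sample_col!r} column")
    out = pd.DataFrame(index=pd.Index(df[sample_col].astype(str), name="sample_id"))
    if df[sample_col].duplicated().any():
        raise ValidationError("duplicate sample id in label table")

    if ki67_percent_col in df.columns:
        pct = pd.to_numeric(df[ki67_percent_col], errors="coerce").to_numpy()
        ki67 = np.where(np.isnan(pct), np.nan,
                        (pct > KI67_PERCENT_CUTOFF).astype(float))
        out["ki67"] = pd.array(ki67, dtype="Int64")
    elif ki67_col in df.columns:
        k = pd.to_numeric(df[ki67_col], errors="coerce")
        bad = k.dropna()[~k.dropna().isin([0, 1])]
        if len(bad):
            raise ValidationError(f"Ki67 status must be 0/1, got {bad.iloc[0]!r}")
        out["ki67"] = pd.array(k.to_numpy(), dtype="Int64")
    else:
        out["ki67"] = pd.array([np.nan] * len(df), dtype="Int64")

    if nhg_col in df.columns:
        out["nhg"] = pd.array([_code_nhg(v) for v in df[nhg_col]], dtype="Int64")
    else:
        out["nhg"] = pd.array([np.nan] * len(df), dtype="Int64")

    has_time = time_col in df.columns
    has_event = event_col in df.columns
    if has_time != has_event:
        raise ValidationError("survival_days and event must be supplied together")
    if has_time:
        out["survival_days"] = pd.to_numeric(df[time_col], errors="coerce")
        ev = pd.to_numeric(df[event_col], errors="coerce")
        bad = ev.dropna()[~ev.dropna().isin([0, 1])]
        if len(bad):
            raise ValidationError(f"event must be 0/1, got {bad.iloc[0]!r}")
        out["event"] = pd.array(ev.to_numpy(), dtype="Int64")
    validate_labels(out)
    return out


def validate_labels(labels: pd.DataFrame) -> None:
    """Check the label-domain invariants of a label table."""
    if "ki67" in labels:
        vals = labels["ki67"].dropna().unique()
        if not set(map(int, vals)) <= {0, 1}:
            raise ValidationError(f"ki67 labels outside {{0,1}}: {sorted(vals)}")
    if "nhg" in labels:
        vals = labels["nhg"].dropna().unique()
        if not set(map(int, vals)) <= {0, 1, 2}:
            raise ValidationError(f"nhg labels outside {{0,1,2}}: {sorted(vals)}")
    if ("survival_days" in labels) != ("event" in labels):
        raise ValidationError("survival_days present iff event present")
    if "survival_days" in labels:
        t = labels["survival_days"].dropna()
        if (t < 0).any():
            raise ValidationError("survival_days must be >= 0")
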