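"""Reading, preprocessing and binarization of gene × sample omics matrices.

The downstream network model consumes only *binary* gene–sample relations: a
``1`` marks an abnormal state of a gene in a sample (differential expression,
copy-number gain/loss, mutation, hyper-/hypo-methylation), a ``0`` a normal
state.  This module turns continuous matrices into that representation:

* expression values are centered on the per-gene median of normal samples
  (no variance scaling, which would amplify noise for low, constant genes);
* methylation beta values are screened with a four-condition filter against
  matched expression data, then shifted from [0, 1] to [-0.5, 0.5];
* every continuous matrix is thresholded on absolute value so that a target
  fraction of entries (default 0.1) becomes 1; mutation matrices are already
  binary and pass through unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DATATYPES",
    "OmicsMatrix",
    "BinaryOmicsDataset",
    "MethylationFilterParams",
    "RELAXED_HYPER",
    "STRICT_HYPER",
    "RELAXED_HYPO",
    "STRICT_HYPO",
    "read_matrix",
    "write_matrix",
    "center_expression",
    "filter_methylation",
    "shift_methylation",
    "binarize",
    "filter_to_network",
]

log = logging.getLogger(__name__)

DATATYPES = ("expression", "cnv", "methylation", "mutation")


def _check_ids(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups = sorted({i for i in ids if i in seen or seen.add(i)})
    if dups:
        raise ValueError(f"duplicate {what} id(s): {', '.join(map(str, dups))}")


@dataclass
class OmicsMatrix:
    """A real-valued genes × samples matrix for one datatype."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    datatype: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.datatype not in DATATYPES:
            raise ValueError(f"unknown datatype {self.datatype!r}; expected one of {DATATYPES}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes × samples matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.sample_ids)} samples"
            )
        _check_ids(self.gene_ids, "gene")
        _check_ids(self.sample_ids, "sample")
        if self.datatype == "mutation" and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("mutation matrices must contain only 0/1 values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class BinaryOmicsDataset:
    """0/1 gene–sample link relation for one datatype.

    ``threshold_used`` is the absolute-value cut applied during binarization;
    it is ``None`` for mutation data, which arrive binary.
    """

    links: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    datatype: str
    threshold_used: float | None = None

    def __post_init__(self) -> None:
        self.links = np.asarray(self.links)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.datatype not in DATATYPES:
            raise ValueError(f"unknown datatype {self.datatype!r}")
        if self.links.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("links shape does not match id lists")
        if not np.isin(self.links, (0, 1)).all():
            raise ValueError("links must contain only 0/1 values")
        self.links = self.links.astype(np.int8)
        _check_ids(self.gene_ids, "gene")
        _check_ids(self.sample_ids, "sample")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def link_fraction(self) -> float:
        return float(self.links.mean()) if self.links.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.links, index=self.gene_ids, columns=self.sample_ids)


def read_matrix(path: str | Path, datatype: str) -> OmicsMatrix:
    """Read a TSV matrix (first column gene ids, header row sample ids)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data rows") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    _check_ids(list(df.index), "gene")
    _check_ids(list(df.columns), "sample")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy()
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = df.index[int(np.argmax(bad.isna().to_numpy()))]
            raise ValueError(
                f"{path}: non-numeric value at gene {row!r}, sample {col!r}"
            ) from None
    return OmicsMatrix(values, list(df.index), list(df.columns), datatype)


def write_matrix(m: OmicsMatrix | BinaryOmicsDataset, path: str | Path) -> None:
    """Write a matrix in the same TSV layout accepted by :func:`read_matrix`."""
    df = m.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def center_expression(tumor: OmicsMatrix, normal: OmicsMatrix) -> OmicsMatrix:
    """Subtract the per-gene median of normal samples from tumor expression.

    Tumor genes absent from the normal matrix are dropped (logged).  The
    result reflects differential expression relative to normal tissue; no
    variance scaling is applied.
    """
    normal_idx = {g: i for i, g in enumerate(normal.gene_ids)}
    keep = [i for i, g in enumerate(tumor.gene_ids) if g in normal_idx]
    if not keep:
        raise ValueError("no overlapping genes between tumor and normal matrices")
    dropped = tumor.n_genes - len(keep)
    if dropped:
        log.warning("center_expression: dropped %d tumor gene(s) absent from normals", dropped)
    genes = [tumor.gene_ids[i] for i in keep]
    medians = np.array(
        [np.median(normal.values[normal_idx[g], :]) for g in genes]
    )
    centered = tumor.values[keep, :] - medians[:, None]
    return OmicsMatrix(centered, genes, tumor.sample_ids, tumor.datatype)


@dataclass(frozen=True)
class MethylationFilterParams:
    """Thresholds for the four-condition methylation gene filter.

    For hyper-methylation: (1) mean normal methylation below ``normal_max``;
    (2) 90th-percentile tumor methylation exceeds the normal mean by more than
    ``tumor_p90_excess``; (3) fold-change between mean normal expression and
    the mean expression of the 10% most-extremely-methylated tumor samples is
    at least ``expression_fold`` (direction set by ``fold_direction``);
    (4) Spearman correlation of methylation with expression over tumor samples
    below ``spearman_max`` (negative).  ``direction='hypo'`` mirrors the
    methylation-side inequalities of (1)-(3); (4) is unchanged.
    """

    normal_max: float
    tumor_p90_excess: float
    expression_fold: float
    spearman_max: float
    direction: str = "hyper"
    fold_direction: str = "normal_higher"  # or "tumor_higher"

    def __post_init__(self) -> None:
        if not 0.0 < self.normal_max < 1.0:
            raise ValueError("normal_max must lie in (0, 1)")
        if self.spearman_max >= 0:
            raise ValueError("spearman_max must be negative")
        if self.direction not in ("hyper", "hypo"):
            raise ValueError("direction must be 'hyper' or 'hypo'")
        if self.fold_direction not in ("normal_higher", "tumor_higher"):
            raise ValueError("fold_direction must be 'normal_higher' or 'tumor_higher'")


RELAXED_HYPER = MethylationFilterParams(0.5, 0.1, 2.0, -0.2, "hyper")
STRICT_HYPER = MethylationFilterParams(0.4, 0.3, 3.0, -0.3, "hyper")
RELAXED_HYPO = MethylationFilterParams(0.5, 0.1, 2.0, -0.2, "hypo")
STRICT_HYPO = MethylationFilterParams(0.4, 0.3, 3.0, -0.3, "hypo")


def filter_methylation(
    met_tumor: OmicsMatrix,
    met_normal: OmicsMatrix,
    expr_tumor: OmicsMatrix,
    expr_normal: OmicsMatrix,
    params: MethylationFilterParams = RELAXED_HYPER,
) -> list[str]:
    """Return gene ids passing the four-condition methylation screen.

    Genes must be present in all four matrices to be considered.  Methylation
    beta values must lie in [0, 1].  Genes with constant tumor methylation
    (undefined Spearman correlation) are rejected with a warning.
    """
    if met_tumor.n_samples < 5:
        raise ValueError("methylation filter needs at least 5 tumor samples")
    for m in (met_tumor, met_normal):
        if m.values.size and (m.values.min() < 0 or m.values.max() > 1):
            raise ValueError("methylation values must lie in [0, 1]")

    hypo = params.direction == "hypo"

    def mt(v: np.ndarray) -> np.ndarray:
        # mirror the methylation axis for the hypo direction
        return 1.0 - v if hypo else v

    expr_t = expr_tumor.to_frame()
    expr_n = expr_normal.to_frame()
    met_n = met_normal.to_frame()
    retained: list[str] = []
    candidates = [
        g
        for g in met_tumor.gene_ids
        if g in met_n.index and g in expr_t.index and g in expr_n.index
    ]
    n_top = max(1, int(np.ceil(0.1 * met_tumor.n_samples)))
    for g in candidates:
        m_t = mt(met_tumor.values[met_tumor.gene_ids.index(g), :])
        m_n = mt(met_n.loc[g].to_numpy(dtype=float))
        e_t = expr_t.loc[g].to_numpy(dtype=float)
        e_n = expr_n.loc[g].to_numpy(dtype=float)

        if m_n.mean() >= params.normal_max:  # (1) normal tissue barely methylated
            continue
        if np.percentile(m_t, 90) - m_n.mean() <= params.tumor_p90_excess:  # (2)
            continue
        # (3) expression fold change vs the 10% most extremely methylated tumors
        top = np.argsort(m_t)[::-1][:n_top]
        e_top = e_t[top].mean()
        e_norm = e_n.mean()
        if params.fold_direction == "normal_higher":
            ok = e_top > 0 and e_norm / e_top >= params.expression_fold
        else:
            ok = e_norm > 0 and e_top / e_norm >= params.expression_fold
        if not ok:
            continue
        # (4) negative methylation-expression association across tumor samples
        m_raw = met_tumor.values[met_tumor.gene_ids.index(g), :]
        if np.ptp(m_raw) == 0 or np.ptp(e_t) == 0:
            log.warning("filter_methylation: gene %s has constant values; Spearman undefined, rejected", g)
            continue
        rho = stats.spearmanr(m_raw, e_t).statistic
        if not np.isfinite(rho) or rho >= params.spearman_max:
            continue
        retained.append(g)
    return retained


def shift_methylation(m: OmicsMatrix) -> OmicsMatrix:
    """Shift methylation beta values from [0, 1] to [-0.5, 0.5]."""
    if m.values.size and (m.values.min() < 0 or m.values.max() > 1):
        raise ValueError("methylation values must lie in [0, 1] before shifting")
    return OmicsMatrix(m.values - 0.5, m.gene_ids, m.sample_ids, m.datatype)


def find_threshold(values: np.ndarray, target_fraction: float) -> float:
    """Absolute-value threshold whose strict exceedance fraction best matches the target.

    Candidate thresholds are the distinct absolute values (plus the maximum
    itself, which yields zero links).  Among candidates the one minimizing
    |realized − target| wins; exact ties resolve toward fewer links.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must lie in (0, 1)")
    a = np.abs(np.asarray(values, dtype=float)).ravel()
    n = a.size
    # distinct values ascending; count of entries strictly above each
    uniq, counts = np.unique(a, return_counts=True)
    above = n - np.cumsum(counts)  # strictly greater than uniq[i]
    if uniq[0] > 0:  # candidate below the minimum, so all entries can become 1
        uniq = np.concatenate(([0.0], uniq))
        above = np.concatenate(([n], above))
    fracs = above / n
    err = np.abs(fracs - target_fraction)
    # ties toward fewer ones == larger threshold == later index
    best = len(err) - 1 - int(np.argmin(err[::-1]))
    return float(uniq[best])


def binarize(m: OmicsMatrix, target_fraction: float = 0.1) -> BinaryOmicsDataset:
    """Threshold absolute values so ~``target_fraction`` of entries become 1.

    A single scalar threshold ``t`` is chosen so that the fraction of entries
    with ``|value| > t`` is as close as possible to the target.  Mutation
    matrices are already binary and pass through unchanged.  An all-zero
    matrix yields no links (strict inequality) with threshold 0.
    """
    if m.datatype == "mutation":
        return BinaryOmicsDataset(m.values.astype(np.int8), m.gene_ids, m.sample_ids, m.datatype, None)
    if not np.any(m.values):
        log.warning("binarize: all-zero %s matrix yields no links", m.datatype)
        return BinaryOmicsDataset(
            np.zeros_like(m.values, dtype=np.int8), m.gene_ids, m.sample_ids, m.datatype, 0.0
        )
    t = find_threshold(m.values, target_fraction)
    links = (np.abs(m.values) > t).astype(np.int8)
    return BinaryOmicsDataset(links, m.gene_ids, m.sample_ids, m.datatype, t)


def filter_to_network(d: BinaryOmicsDataset, net) -> BinaryOmicsDataset:
    """Drop genes absent from the prior-knowledge interaction network."""
    present = set(net.genes) if hasattr(net, "genes") else set(net)
    keep = [i for i, g in enumerate(d.gene_ids) if g in present]
    if not keep:
        raise ValueError(f"no {d.datatype} genes remain after network filtering")
    removed = d.n_genes - len(keep)
    if removed:
        log.info("filter_to_network: removed %d/%d %s gene(s) absent from the network",
                 removed, d.n_genes, d.datatype)
    return BinaryOmicsDataset(
        d.links[keep, :], [d.gene_ids[i] for i in keep], d.sample_ids, d.datatype, d.threshold_used
    )
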