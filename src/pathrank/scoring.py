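"""Permutation-calibrated pathway relevance scoring.

A pathway's raw score for one datatype is the mean of the sample × gene
similarity entries over the pathway's genes measured in that datatype.  Raw
scores grow with gene-set size and with overall connectivity, so each is
converted to an empirical p-value against the scores of random gene sets of
the same size drawn from the analysis universe (the prior-network genes).
The per-datatype p-values are multiplied into a single aggregate used only
for *ranking*: the datatype scores are correlated, so the product is not a
joint probability.  For display the aggregate is mapped to
``-log10(product)``, which decomposes additively into per-datatype bars.

Also provided: a naive frequency baseline (per-gene counts of abnormal
states instead of network similarities, same permutation machinery) and the
expensive validation null that permutes dataset gene labels and rebuilds the
kernel for every permutation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .kernel import SimilaritySubmatrix, compute_similarities
from .network import PriorNetwork, build_global_network
from .omics_io import BinaryOmicsDataset

__all__ = [
    "PathwayCompendium",
    "NullDistribution",
    "PathwayScore",
    "read_gmt",
    "write_gmt",
    "pathway_raw_score",
    "build_null",
    "pathway_pvalue",
    "aggregate_score",
    "rank_pathways",
    "score_ratio",
    "frequency_baseline",
    "gene_label_permutation_pvalues",
]

log = logging.getLogger(__name__)


@dataclass
class PathwayCompendium:
    """Named gene sets to be ranked (e.g. non-disease KEGG pathways)."""

    entries: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for pid, (name, genes) in self.entries.items():
            if not genes:
                raise ValueError(f"pathway {pid!r} has an empty gene set")
            self.entries[pid] = (name, frozenset(genes))

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[str]]) -> "PathwayCompendium":
        return cls({pid: (pid, frozenset(genes)) for pid, genes in d.items()})

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def genes(self, pid: str) -> frozenset[str]:
        return self.entries[pid][1]

    def name(self, pid: str) -> str:
        return self.entries[pid][0]

    @property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.entries.values():
            out |= genes
        return frozenset(out)


def read_gmt(path: str | Path) -> PathwayCompendium:
    """Read a GMT file: name <tab> description <tab> gene ids."""
    entries: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                if line.strip():
                    raise ValueError(f"{path}:{ln}: malformed GMT line")
                continue
            pid, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if pid in entries:
                raise ValueError(f"{path}:{ln}: duplicate pathway id {pid!r}")
            entries[pid] = (desc or pid, frozenset(genes))
    return PathwayCompendium(entries)


def write_gmt(c: PathwayCompendium, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in c:
            genes = "\t".join(sorted(c.genes(pid)))
            fh.write(f"{pid}\t{c.name(pid)}\t{genes}\n")


@dataclass
class NullDistribution:
    """Sorted scores of random same-size gene sets for one datatype."""

    datatype: str
    set_size: int
    n_perm: int
    scores: np.ndarray  # ascending, undefined draws dropped
    seed: int

    def __post_init__(self) -> None:
        self.scores = np.sort(np.asarray(self.scores, dtype=float))


@dataclass
class PathwayScore:
    """Per-datatype raw scores / p-values and the aggregate ranking score."""

    pathway_id: str
    name: str
    set_size: int
    raw_scores: dict[str, float | None]
    pvalues: dict[str, float]
    aggregate: float
    display_score: float

    @property
    def components(self) -> dict[str, float]:
        """Per-datatype -log10(p) bars; they sum to the display score."""
        return {d: -np.log10(p) for d, p in self.pvalues.items()}


def pathway_raw_score(s: SimilaritySubmatrix, genes: Iterable[str]) -> float | None:
    """Mean similarity over the submatrix columns belonging to the gene set.

    Returns ``None`` (undefined) when no pathway gene is measured in the
    datatype; the downstream p-value is then 1.
    """
    gene_set = set(genes)
    cols = [i for i, g in enumerate(s.gene_ids) if g in gene_set]
    if not cols:
        return None
    return float(s.values[:, cols].mean())


def _universe_value_vector(s: SimilaritySubmatrix, universe: Sequence[str]) -> np.ndarray:
    """Per-universe-gene column means; NaN for genes the datatype does not measure.

    Because every column has the same number of samples, the mean of a gene
    set's submatrix equals the mean of its per-gene column means, so the
    whole permutation null reduces to gathers into this vector.
    """
    col = {g: i for i, g in enumerate(s.gene_ids)}
    means = s.column_means()
    v = np.full(len(universe), np.nan)
    for u, g in enumerate(universe):
        i = col.get(g)
        if i is not None:
            v[u] = means[i]
    return v


def _draw_sets(n_universe: int, set_size: int, n_perm: int, seed: int) -> np.ndarray:
    """(n_perm, set_size) index draws, uniform without replacement, keyed by (seed, set_size)."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, set_size])
    return np.stack([rng.choice(n_universe, size=set_size, replace=False) for _ in range(n_perm)])


def build_null(
    submatrices: Mapping[str, SimilaritySubmatrix],
    set_size: int,
    universe: Sequence[str],
    n_perm: int,
    seed: int,
) -> dict[str, NullDistribution]:
    """Null score distributions for random gene sets of ``set_size``.

    One shared sequence of random sets is drawn per set size and scored
    against every datatype, preserving the cross-datatype correlation of the
    null.  Draws are reproducible from (seed, set_size) alone, so caching by
    set size is bitwise-identical to recomputing per pathway.
    """
    universe = list(universe)
    if set_size > len(universe):
        raise ValueError(f"set_size {set_size} exceeds universe size {len(universe)}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    draws = _draw_sets(len(universe), set_size, n_perm, seed)
    out: dict[str, NullDistribution] = {}
    for dt, s in submatrices.items():
        v = _universe_value_vector(s, universe)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            scores = np.nanmean(v[draws], axis=1)  # NaN when no drawn gene is measured
        out[dt] = NullDistribution(dt, set_size, n_perm, scores[np.isfinite(scores)], seed)
    return out


def pathway_pvalue(observed: float | None, null: NullDistribution) -> float:
    """Empirical tail probability max(r, 1)/n_perm with r = #{null >= observed}.

    The floor 1/n_perm is the minimum attainable p (1e-4 at the default
    10,000 permutations).  An undefined observed score yields p = 1.
    """
    if observed is None or not np.isfinite(observed):
        return 1.0
    r = len(null.scores) - int(np.searchsorted(null.scores, observed, side="left"))
    return max(r, 1) / null.n_perm


def aggregate_score(pvalues: Mapping[str, float] | Sequence[float]) -> tuple[float, float]:
    """Product of per-datatype p-values and its -log10 display transform."""
    ps = list(pvalues.values()) if isinstance(pvalues, Mapping) else list(pvalues)
    for p in ps:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-value {p} outside (0, 1]")
    agg = float(np.prod(ps))
    return agg, float(-np.log10(agg)) + 0.0  # +0.0 normalizes -0.0


def rank_pathways(
    compendium: PathwayCompendium,
    submatrices: Mapping[str, SimilaritySubmatrix],
    universe: Sequence[str] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[PathwayScore]:
    """Score and rank every pathway in the compendium.

    Each pathway is scored with set size |pathway ∩ universe|; null
    distributions are cached per set size.  Output is ordered by ascending
    aggregate (descending display score), ties broken by pathway id.
    Pathways with no gene in the universe receive p = 1 everywhere.
    """
    if universe is None:
        universe = sorted({g for s in submatrices.values() for g in s.gene_ids})
    universe = sorted(universe)
    uset = set(universe)
    null_cache: dict[int, dict[str, NullDistribution]] = {}
    results: list[PathwayScore] = []
    for pid in compendium:
        genes = compendium.genes(pid) & uset
        size = len(genes)
        raw: dict[str, float | None] = {}
        pvals: dict[str, float] = {}
        if size == 0:
            log.warning("rank_pathways: pathway %s has no genes in the universe", pid)
            for dt in submatrices:
                raw[dt] = None
                pvals[dt] = 1.0
        else:
            if size not in null_cache:
                null_cache[size] = build_null(submatrices, size, universe, n_perm, seed)
            nulls = null_cache[size]
            for dt, s in submatrices.items():
                obs = pathway_raw_score(s, genes)
                raw[dt] = obs
                pvals[dt] = pathway_pvalue(obs, nulls[dt])
        agg, disp = aggregate_score(pvals)
        results.append(PathwayScore(pid, compendium.name(pid), size, raw, pvals, agg, disp))
    results.sort(key=lambda r: (r.aggregate, r.pathway_id))
    return results


def scores_to_frame(scores: Sequence[PathwayScore]) -> pd.DataFrame:
    """Tabular report: one row per pathway in rank order."""
    rows = []
    for rank, s in enumerate(scores, 1):
        row: dict[str, object] = {
            "rank": rank,
            "pathway": s.pathway_id,
            "name": s.name,
            "set_size": s.set_size,
        }
        for dt in sorted(s.pvalues):
            row[f"raw_{dt}"] = s.raw_scores.get(dt)
            row[f"p_{dt}"] = s.pvalues[dt]
            row[f"component_{dt}"] = s.components[dt]
        row["aggregate"] = s.aggregate
        row["display_score"] = s.display_score
        rows.append(row)
    return pd.DataFrame(rows)


def score_ratio(
    group_a: Sequence[PathwayScore], group_b: Sequence[PathwayScore]
) -> dict[str, float]:
    """Per-pathway ratio of display scores between two sample groups.

    Ratios above 1 mean the pathway is more relevant for group A.  The ratio
    is NaN (flagged) where group B's display score is 0.
    """
    a = {s.pathway_id: s.display_score for s in group_a}
    b = {s.pathway_id: s.display_score for s in group_b}
    if set(a) != set(b):
        raise ValueError("pathway sets of the two groups differ")
    return {
        pid: (a[pid] / b[pid]) if b[pid] != 0 else float("nan") for pid in a
    }


def frequency_submatrices(
    datasets: Sequence[BinaryOmicsDataset],
) -> dict[str, SimilaritySubmatrix]:
    """Per-gene abnormal-state counts packaged as single-row score matrices."""
    out: dict[str, SimilaritySubmatrix] = {}
    for d in datasets:
        freq = d.links.sum(axis=1).astype(float)[None, :]
        out[d.datatype] = SimilaritySubmatrix(freq, ["__frequency__"], list(d.gene_ids), d.datatype)
    return out


def frequency_baseline(
    datasets: Sequence[BinaryOmicsDataset],
    compendium: PathwayCompendium,
    universe: Sequence[str] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[PathwayScore]:
    """Naive baseline: rank pathways from abnormal-state frequencies alone.

    The per-gene score is the number of samples in which the gene is
    abnormal; permutation, p-value and aggregation machinery are identical
    to the network method, so differences in ranking isolate the effect of
    the network similarity.
    """
    return rank_pathways(compendium, frequency_submatrices(datasets), universe, n_perm, seed)


def gene_label_permutation_pvalues(
    datasets: Sequence[BinaryOmicsDataset],
    prior: PriorNetwork,
    compendium: PathwayCompendium,
    pathway_ids: Sequence[str] | None = None,
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.01,
    merge_expression: bool = True,
    method: str = "eig",
) -> pd.DataFrame:
    """Validation null: permute dataset gene labels and rebuild the kernel.

    For every permutation the gene labels of each dataset are shuffled (the
    link matrix is untouched, only the row identities move), the global
    network and diffusion kernel are recomputed, and each pathway's raw
    scores are measured.  This is far more expensive than the random-gene-set
    null — one kernel per permutation — hence the small default ``n_perm``.

    Returns a pathway × datatype DataFrame of p-values max(r, 1)/n_perm.
    """
    if pathway_ids is None:
        pathway_ids = list(compendium)
    pathway_ids = list(pathway_ids)
    datatypes = [d.datatype for d in datasets]

    def raw_scores(ds: Sequence[BinaryOmicsDataset]) -> np.ndarray:
        g = build_global_network(ds, prior, merge_expression=merge_expression)
        subs = compute_similarities(g, alpha=alpha, method=method, datatypes=datatypes)
        out = np.full((len(pathway_ids), len(datatypes)), np.nan)
        for i, pid in enumerate(pathway_ids):
            genes = compendium.genes(pid)
            for j, dt in enumerate(datatypes):
                v = pathway_raw_score(subs[dt], genes)
                out[i, j] = np.nan if v is None else v
        return out

    observed = raw_scores(datasets)
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    counts = np.zeros_like(observed)
    for _ in range(n_perm):
        shuffled = []
        for d in datasets:
            perm = rng.permutation(d.n_genes)
            shuffled.append(
                BinaryOmicsDataset(
                    d.links,
                    [d.gene_ids[i] for i in perm],
                    d.sample_ids,
                    d.datatype,
                    d.threshold_used,
                )
            )
        null = raw_scores(shuffled)
        counts += (null >= observed) & np.isfinite(null) & np.isfinite(observed)
    p = np.maximum(counts, 1.0) / n_perm
    p[~np.isfinite(observed)] = 1.0
    return pd.DataFrame(p, index=pathway_ids, columns=datatypes)
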