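"""Per-pair feature construction from heterogeneous per-gene data.

Expression compendia are imputed per source dataset with a k-nearest-gene
scheme, then turned into one feature per condition: the signed
difference ``x_i - x_j`` for directed pairs and its absolute value for
undirected pairs.  Shared-annotation sources (colocalization
compartments, protein families) become binary set-intersection
features, binding-site profiles contribute a Euclidean distance, and
precomputed pairwise similarity scores (alignment E-values) enter as
``-log10`` with a floor.  Assembly concatenates source tables, dropping
sources whose tag is excluded for the target interaction type so that
data closely related to the predicted output never leaks into training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gold_standard import GenePair

logger = logging.getLogger(__name__)

SOURCE_TAGS = ("expression", "colocalization", "family", "binding-profile", "similarity")


@dataclass
class ExpressionCompendium:
    """Gene x condition matrix, possibly with NaN entries, grouped by dataset.

    ``datasets`` assigns each condition to its dataset of origin;
    imputation operates within a dataset, mirroring how per-experiment
    imputation tools are applied before compendium assembly.
    """

    genes: list[str]
    conditions: list[str]
    values: np.ndarray
    datasets: list[str] | None = None
    dropped_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.conditions)):
            raise ValueError(
                f"matrix shape {self.values.shape} != "
                f"({len(self.genes)}, {len(self.conditions)})"
            )
        if self.datasets is None:
            self.datasets = ["d0"] * len(self.conditions)
        if len(self.datasets) != len(self.conditions):
            raise ValueError("one dataset label required per condition")

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.genes.index(gene)]


@dataclass
class FeatureVectorTable:
    """Pair x feature matrix with per-feature source tags."""

    pairs: list[GenePair]
    names: list[str]
    values: np.ndarray
    sources: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.pairs), len(self.names)):
            raise ValueError(
                f"matrix shape {self.values.shape} != ({len(self.pairs)}, {len(self.names)})"
            )
        if not self.sources:
            self.sources = ["expression"] * len(self.names)
        if len(self.sources) != len(self.names):
            raise ValueError("one source tag per feature required")
        bad = set(self.sources) - set(SOURCE_TAGS)
        if bad:
            raise ValueError(f"unknown source tags {sorted(bad)}; allowed: {SOURCE_TAGS}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if np.isnan(self.values).any():
            raise ValueError("feature table contains missing values")

    def subset_rows(self, pairs: Sequence[GenePair]) -> "FeatureVectorTable":
        index = {p: i for i, p in enumerate(self.pairs)}
        missing = [p for p in pairs if p not in index]
        if missing:
            raise KeyError(f"{len(missing)} pairs absent from feature table, e.g. {missing[0]}")
        rows = [index[p] for p in pairs]
        return FeatureVectorTable(list(pairs), list(self.names),
                                  self.values[rows], list(self.sources))


# -- imputation ------------------------------------------------------------


def knn_impute(
    c: ExpressionCompendium, k: int = 10, max_missing: float = 0.30
) -> ExpressionCompendium:
    """Impute missing expression values from the k nearest genes.

    Genes missing more than ``max_missing`` of their conditions (over
    the whole compendium) are removed and recorded.  Within each
    dataset, a missing entry is replaced by the mean of that condition's
    values over the ``k`` genes closest in Euclidean distance computed
    on mutually observed conditions of that dataset; only genes observed
    in the target condition are eligible neighbors.  Falls back to the
    column mean (with a warning) when no neighbor qualifies.  Observed
    entries are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    miss_frac = np.isnan(c.values).mean(axis=1)
    keep = miss_frac <= max_missing
    dropped = [g for g, ok in zip(c.genes, keep) if not ok]
    if dropped:
        logger.info("knn_impute: dropping %d genes over the missingness threshold", len(dropped))
    genes = [g for g, ok in zip(c.genes, keep) if ok]
    values = c.values[keep].copy()
    datasets = list(c.datasets or [])
    for ds in dict.fromkeys(datasets):
        cols = np.array([j for j, d in enumerate(datasets) if d == ds])
        values[:, cols] = _impute_block(values[:, cols], k)
    return ExpressionCompendium(genes, list(c.conditions), values,
                                datasets, dropped_genes=dropped)


def _impute_block(block: np.ndarray, k: int) -> np.ndarray:
    out = block.copy()
    missing_rows = np.where(np.isnan(block).any(axis=1))[0]
    if missing_rows.size == 0:
        return out
    obs = ~np.isnan(block)
    col_means = np.nanmean(np.where(obs, block, np.nan), axis=0)
    for i in missing_rows:
        # squared Euclidean distance on mutually observed conditions
        both = obs[i] & obs
        diff = np.where(both, block[i] - np.where(obs, block, 0.0), 0.0)
        d2 = (diff ** 2).sum(axis=1)
        d2[i] = np.inf
        d2[both.sum(axis=1) == 0] = np.inf
        order = np.argsort(d2, kind="stable")
        for j in np.where(~obs[i])[0]:
            donors = [r for r in order if np.isfinite(d2[r]) and obs[r, j]][:k]
            if not donors:
                if np.isnan(col_means[j]):
                    raise ValueError(f"condition column {j} has no observed values")
                logger.warning("knn_impute: no eligible neighbor, column-mean fallback")
                out[i, j] = col_means[j]
            else:
                if len(donors) < k:
                    logger.warning(
                        "knn_impute: only %d of %d neighbors available", len(donors), k
                    )
                out[i, j] = block[donors, j].mean()
    return out


# -- per-pair features -----------------------------------------------------


def pair_features_expression(
    c: ExpressionCompendium, pairs: Sequence[GenePair], directed: bool
) -> FeatureVectorTable:
    """One feature per condition: ``x_i - x_j`` (directed) or ``|x_i - x_j|``.

    Directed features are antisymmetric in pair orientation; undirected
    features are orientation-invariant by construction.
    """
    if np.isnan(c.values).any():
        raise ValueError("expression compendium must be imputed first")
    index = {g: i for i, g in enumerate(c.genes)}
    missing = sorted({g for p in pairs for g in (p.a, p.b) if g not in index})
    if missing:
        raise KeyError(f"genes absent from compendium: {missing}")
    ai = np.array([index[p.a] for p in pairs])
    bi = np.array([index[p.b] for p in pairs])
    diff = c.values[ai] - c.values[bi]
    if not directed:
        diff = np.abs(diff)
    names = [f"expr:{cond}" for cond in c.conditions]
    return FeatureVectorTable(list(pairs), names, diff, ["expression"] * len(names))


def pair_features_shared(
    membership: Mapping[str, set[str]],
    pairs: Sequence[GenePair],
    feature_name: str,
    source: str = "colocalization",
) -> FeatureVectorTable:
    """Binary feature: 1 when the two genes share at least one category.

    Genes absent from the membership table are treated as annotated to
    nothing (absence of evidence scores 0).
    """
    empty: set[str] = set()
    vals = np.array(
        [[1.0 if membership.get(p.a, empty) & membership.get(p.b, empty) else 0.0]
         for p in pairs]
    )
    return FeatureVectorTable(list(pairs), [feature_name], vals, [source])


def pair_features_profile_distance(
    profiles: Mapping[str, np.ndarray],
    pairs: Sequence[GenePair],
    feature_name: str = "binding-profile-distance",
) -> FeatureVectorTable:
    """Euclidean distance between two genes' binding-site profiles.

    Pairs with a missing profile receive the mean distance over fully
    profiled pairs (logged), so downstream tables stay dense.
    """
    lengths = {len(v) for v in profiles.values()}
    if len(lengths) > 1:
        raise ValueError(f"profiles have inconsistent lengths {sorted(lengths)}")
    dist = np.full(len(pairs), np.nan)
    for i, p in enumerate(pairs):
        if p.a in profiles and p.b in profiles:
            d = np.asarray(profiles[p.a], float) - np.asarray(profiles[p.b], float)
            dist[i] = float(np.sqrt((d ** 2).sum()))
    if np.isnan(dist).any():
        fill = float(np.nanmean(dist)) if np.isfinite(np.nanmean(dist)) else 0.0
        n_miss = int(np.isnan(dist).sum())
        logger.info("profile distance: %d pairs without profiles set to mean %.3g",
                    n_miss, fill)
        dist = np.where(np.isnan(dist), fill, dist)
    return FeatureVectorTable(list(pairs), [feature_name], dist[:, None],
                              ["binding-profile"])


def pair_features_similarity(
    scores: Mapping[frozenset[str] | tuple[str, str], float],
    pairs: Sequence[GenePair],
    feature_name: str = "seq-similarity",
    floor: float = 1e-200,
) -> FeatureVectorTable:
    """Precomputed similarity E-values as ``-log10(max(E, floor))``.

    Pairs without a score default to E = 1 (no detectable similarity),
    i.e. a feature value of 0.
    """
    vals = np.zeros((len(pairs), 1))
    for i, p in enumerate(pairs):
        e = scores.get(frozenset((p.a, p.b)), scores.get((p.a, p.b), 1.0))
        vals[i, 0] = -np.log10(max(float(e), floor))
    return FeatureVectorTable(list(pairs), [feature_name], vals, ["similarity"])


# -- assembly --------------------------------------------------------------


def assemble_features(
    sources: Sequence[FeatureVectorTable],
    exclusion: Mapping[str, set[str]] | None = None,
    term: str | None = None,
) -> FeatureVectorTable:
    """Column-concatenate source tables, dropping excluded source tags.

    ``exclusion`` maps a term id to the set of source tags that are too
    closely related to that interaction type to be legitimate inputs
    (e.g. binding-site profiles when predicting transcriptional
    regulation).  Column order follows the order of ``sources``.
    """
    if not sources:
        raise ValueError("no feature sources given")
    ref = sources[0].pairs
    for s in sources[1:]:
        if s.pairs != ref:
            raise ValueError("feature sources are not aligned on the same pair sequence")
    banned = set() if exclusion is None or term is None else set(exclusion.get(term, set()))
    kept = [s for s in sources if not (set(s.sources) & banned)]
    if not kept:
        raise ValueError(f"all feature sources excluded for term {term!r}")
    values = np.hstack([s.values for s in kept])
    names = [n for s in kept for n in s.names]
    tags = [t for s in kept for t in s.sources]
    return FeatureVectorTable(list(ref), names, values, tags)


def standardize(
    table: FeatureVectorTable, mean: np.ndarray | None = None,
    scale: np.ndarray | None = None,
) -> tuple[FeatureVectorTable, np.ndarray, np.ndarray]:
    """Zero-mean unit-variance columns; constant columns are left centered."""
    if mean is None:
        mean = table.values.mean(axis=0)
        scale = table.values.std(axis=0)
        scale = np.where(scale == 0, 1.0, scale)
    assert scale is not None
    out = FeatureVectorTable(
        table.pairs, table.names, (table.values - mean) / scale, table.sources
    )
    return out, mean, scale


# -- file formats ----------------------------------------------------------


def load_expression(
    path: str | Path, dataset: str | None = None, skip_annotation_cols: int = 0
) -> ExpressionCompendium:
    """Read a PCL-like tab-delimited matrix: header of condition ids, first
    column gene ids, ``NA``/empty cells missing.  ``skip_annotation_cols``
    drops the optional NAME/GWEIGHT columns."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    if skip_annotation_cols:
        df = df.iloc[:, skip_annotation_cols:]
    ds = dataset or Path(path).stem
    return ExpressionCompendium(
        [str(g) for g in df.index], [str(c) for c in df.columns],
        df.to_numpy(dtype=float), [ds] * df.shape[1],
    )


def load_membership(path: str | Path) -> dict[str, set[str]]:
    """TSV ``gene <TAB> category``, one membership per line."""
    out: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        gene, cat = line.split("\t")[:2]
        out.setdefault(gene, set()).add(cat)
    return out


def load_profiles(path: str | Path) -> dict[str, np.ndarray]:
    """TSV ``gene <TAB> v1 ... vK`` binding-site profiles."""
    out: dict[str, np.ndarray] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        out[parts[0]] = np.array([float(x) for x in parts[1:]])
    return out
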