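"""Expression table IO, normalization and rank transforms.

The central container is :class:`ExpressionMatrix`, a thin wrapper around
a genes x samples :class:`pandas.DataFrame` that tracks which abundance
layer it holds (raw counts, TPM, normalized counts, quantile-uniform or
z-score) together with the ordered stage labels and an optional
stage -> replicate-column map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: Recognised abundance layers.
LAYERS = ("counts", "tpm", "normalized_counts", "quantile_uniform", "zscore")

#: Layers that must be non-negative.
NONNEGATIVE_LAYERS = ("counts", "tpm", "normalized_counts", "quantile_uniform")

#: Recognised developmental phase tags.
PHASES = ("pre-larval", "larval", "post-larval", "adult-tissue")


@dataclass(frozen=True)
class StageSeries:
    """One developmental stage of one species."""

    stage: str
    ordinal: int
    phase: str
    species_id: str

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(
                f"unknown phase {self.phase!r} for stage {self.stage!r}; "
                f"expected one of {PHASES}"
            )


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix with an explicit layer tag.

    Parameters
    ----------
    species_id:
        Free-text species label.
    data:
        Genes as the index, sample columns. When ``replicate_map`` is
        ``None`` the columns must be exactly the ordered ``stages``;
        otherwise the columns are replicate samples grouped per stage by
        the map.
    layer:
        One of :data:`LAYERS`.
    stages:
        Ordered, unique stage labels.
    replicate_map:
        Optional ``stage -> [column, ...]``; all listed columns must be
        present in ``data``.
    phases:
        Optional ``stage -> phase`` tags (see :data:`PHASES`).
    """

    species_id: str
    data: pd.DataFrame
    layer: str
    stages: list[str]
    replicate_map: dict[str, list[str]] | None = None
    phases: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        dup = self.data.index[self.data.index.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene identifier: {dup[0]!r}")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage labels are not unique")
        if self.replicate_map is None:
            if list(self.data.columns) != list(self.stages):
                raise ValueError(
                    "without a replicate_map the data columns must equal the "
                    f"ordered stages; got columns {list(self.data.columns)} vs "
                    f"stages {list(self.stages)}"
                )
        else:
            for stage in self.stages:
                cols = self.replicate_map.get(stage, [])
                missing = [c for c in cols if c not in self.data.columns]
                if missing:
                    raise ValueError(
                        f"replicate column {missing[0]!r} of stage {stage!r} "
                        "is absent from the data"
                    )
        if self.layer in NONNEGATIVE_LAYERS:
            vals = self.data.to_numpy()
            if vals.size and np.nanmin(vals) < 0:
                raise ValueError(f"layer {self.layer!r} requires values >= 0")
        if self.phases is not None:
            for stage, phase in self.phases.items():
                if phase not in PHASES:
                    raise ValueError(f"unknown phase {phase!r} for stage {stage!r}")

    # -- convenience -------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def stage_series(self) -> list[StageSeries]:
        phases = self.phases or {}
        return [
            StageSeries(s, i, phases.get(s, "pre-larval"), self.species_id)
            for i, s in enumerate(self.stages)
        ]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Row-subset preserving the requested gene order."""
        genes = list(genes)
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"gene {missing[0]!r} not in matrix")
        return replace(self, data=self.data.loc[genes])

    def with_layer(self, data: pd.DataFrame, layer: str) -> "ExpressionMatrix":
        return replace(self, data=data, layer=layer)


@dataclass
class TissuePanel:
    """Adult-tissue TPM panel with designated anterior/posterior pairs."""

    data: pd.DataFrame  # genes x tissues
    anterior: tuple[str, str]
    posterior: tuple[str, str]

    def __post_init__(self) -> None:
        for t in (*self.anterior, *self.posterior):
            if t not in self.data.columns:
                raise ValueError(f"designated tissue {t!r} missing from panel")


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_expression_table(
    path,
    species_id: str = "species",
    layer: str = "tpm",
    stages: list[str] | None = None,
    replicate_map: dict[str, list[str]] | None = None,
    phases: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a TSV expression table (header = sample labels, column 1 = gene ID).

    Lines starting with ``#`` are treated as comments. Raises on
    duplicate gene identifiers (naming the first duplicate) and on
    non-numeric cells (naming gene and column).
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene identifier in {path}: {dup[0]!r}")
    numeric = {}
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.to_numpy()][0]
            raise ValueError(
                f"non-numeric value {raw.at[gene, col]!r} at gene {gene!r}, "
                f"column {col!r} in {path}"
            )
        numeric[col] = converted
    data = pd.DataFrame(numeric, index=raw.index)
    if stages is None:
        stages = list(replicate_map) if replicate_map is not None else list(data.columns)
    return ExpressionMatrix(
        species_id=species_id,
        data=data,
        layer=layer,
        stages=list(stages),
        replicate_map=replicate_map,
        phases=phases,
    )


def write_expression_table(m: ExpressionMatrix, path, float_format: str | None = None) -> None:
    """Write the matrix as TSV (UTF-8, '.' decimal); gene IDs in column 1."""
    m.data.to_csv(path, sep="\t", index_label="gene", float_format=float_format)


# ---------------------------------------------------------------------------
# Replicates and normalization
# ---------------------------------------------------------------------------

def average_replicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse replicate columns to their per-stage arithmetic mean."""
    if m.replicate_map is None:
        raise ValueError("matrix has no replicate_map; nothing to average")
    cols = {}
    for stage in m.stages:
        reps = m.replicate_map.get(stage, [])
        if not reps:
            raise ValueError(f"stage {stage!r} has zero replicate columns")
        cols[stage] = m.data[reps].mean(axis=1)
    data = pd.DataFrame(cols, index=m.data.index)[list(m.stages)]
    return replace(m, data=data, replicate_map=None)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference, log space).

    Only genes with strictly positive counts in every column enter the
    median.
    """
    vals = counts.to_numpy(dtype=float)
    positive = (vals > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every column; cannot build a "
            "median-of-ratios reference (pseudo-reference fallback is off)"
        )
    logv = np.log(vals[positive])
    ref = np.exp(logv.mean(axis=1))  # geometric mean per gene, in log space
    sf = np.median(vals[positive] / ref[:, None], axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def size_factor_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each column by its median-of-ratios size factor."""
    if m.layer != "counts":
        raise ValueError(f"size_factor_normalize expects layer 'counts', got {m.layer!r}")
    sf = size_factors(m.data)
    data = m.data / sf
    return replace(m, data=data, layer="normalized_counts")


def expressed_genes(m: ExpressionMatrix, threshold: float = 2.0) -> set[str]:
    """Genes with TPM strictly above ``threshold`` in at least one stage.

    Replicates are averaged to stage means first, so the rule is applied
    per stage rather than per replicate. The boundary is strict: a gene
    whose maximum equals the threshold exactly is excluded.
    """
    if m.layer != "tpm":
        raise ValueError(f"expressed_genes expects layer 'tpm', got {m.layer!r}")
    if m.replicate_map is not None:
        m = average_replicates(m)
    above = (m.data.to_numpy() > threshold).any(axis=1)
    return set(m.data.index[above])


# ---------------------------------------------------------------------------
# Rank transforms
# ---------------------------------------------------------------------------

def quantile_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Map each column to the uniform [0, 1] grid by empirical rank.

    Ties receive the mean rank; a strictly increasing column of length n
    maps to ``0, 1/(n-1), ..., 1``. A single-row matrix maps to 0.
    """
    if m.layer != "tpm":
        raise ValueError(f"quantile_transform expects layer 'tpm', got {m.layer!r}")
    vals = m.data.to_numpy(dtype=float)
    n = vals.shape[0]
    if n == 0:
        raise ValueError("cannot quantile-transform an empty column")
    if n == 1:
        out = np.zeros_like(vals)
    else:
        ranks = np.apply_along_axis(lambda c: rankdata(c, method="average"), 0, vals)
        out = (ranks - 1.0) / (n - 1.0)
    data = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return replace(m, data=data, layer="quantile_uniform")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Classic across-sample quantile normalization.

    Each column's sorted values are replaced by the row-wise mean of the
    sorted columns and restored to the original order, so every column
    ends up with an identical multiset of values. Idempotent.
    """
    vals = m.data.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValueError("quantile_normalize needs at least 2 columns")
    order = np.argsort(vals, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(vals, order, axis=0)
    row_means = sorted_vals.mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        out[order[:, j], j] = row_means
    data = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return replace(m, data=data, layer=m.layer)


def zscore_rows(
    data: pd.DataFrame, drop_constant: bool = True
) -> tuple[pd.DataFrame, int]:
    """Row-wise z-score (population SD); returns (frame, n_dropped_constant)."""
    vals = data.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    constant = (sd.ravel() == 0) | ~np.isfinite(sd.ravel())
    n_dropped = 0
    if drop_constant and constant.any():
        n_dropped = int(constant.sum())
        logger.info("dropped %d zero-variance gene profiles", n_dropped)
        vals, mu, sd = vals[~constant], mu[~constant], sd[~constant]
        index = data.index[~constant]
    else:
        index = data.index
        sd = np.where(sd == 0, 1.0, sd)
    z = (vals - mu) / sd
    return pd.DataFrame(z, index=index, columns=data.columns), n_dropped
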