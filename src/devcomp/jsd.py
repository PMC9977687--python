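"""Jensen-Shannon divergence stage matching.

Stage transcriptomes restricted to one-to-one orthologues are turned
into probability vectors; every stage pair across two species gets a raw
JSD (base-2 logs, so values live in [0, 1] bits), a bootstrap mean/SD
over orthologue resamples, an adjusted value (mean divided by the
orthologue count) and min-max normalized variants pooled either globally
(JSD_norm) or within each comparison (relative JSD). The per-orthologue
additive terms (gwJSD) rank the genes driving similarity; the driver set
is cut at 25% of the gwJSD density mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from devcomp.expression import (
    ExpressionMatrix,
    average_replicates,
    quantile_transform,
)

logger = logging.getLogger(__name__)


@dataclass
class StageDistribution:
    """Probability vector over orthologues for one stage of one species."""

    species_id: str
    stage: str
    genes: list[str]
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.min() < 0:
            raise ValueError("probabilities must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("probability vector must sum to 1")
        if len(self.genes) != self.p.size:
            raise ValueError("gene list and probability vector lengths differ")


@dataclass
class JSDMatrix:
    """Stage x stage divergence grids for one species comparison."""

    species_a: str
    species_b: str
    raw: pd.DataFrame  # stages_a x stages_b
    n_orthologues: int
    boot_mean: pd.DataFrame | None = None
    boot_sd: pd.DataFrame | None = None
    adjusted: pd.DataFrame | None = None
    normalized: pd.DataFrame | None = None
    relative: pd.DataFrame | None = None

    @property
    def label(self) -> str:
        return f"{self.species_a}__vs__{self.species_b}"


@dataclass
class GeneWiseJSD:
    """Per-orthologue JSD terms for one stage pair, plus the driver cut."""

    pair_label: str
    genes: list[str]
    values: np.ndarray
    mode: float | None = None
    threshold: float | None = None
    drivers: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------

def stage_distribution(
    m: ExpressionMatrix, orthologues: list[str], stage: str
) -> StageDistribution:
    """Simplex-normalize one stage column over the orthologue set."""
    if m.layer != "quantile_uniform":
        raise ValueError(
            f"stage_distribution expects layer 'quantile_uniform', got {m.layer!r}"
        )
    sub = m.subset_genes(orthologues)
    if stage not in sub.data.columns:
        raise KeyError(f"stage {stage!r} not in matrix")
    v = sub.data[stage].to_numpy(dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError(f"stage {stage!r} has an all-zero expression vector")
    return StageDistribution(m.species_id, stage, list(orthologues), v / total)


def prepare_for_jsd(
    m: ExpressionMatrix, orthologues: list[str]
) -> ExpressionMatrix:
    """Average replicates, restrict to the orthologue set, quantile-transform."""
    if m.replicate_map is not None:
        m = average_replicates(m)
    return quantile_transform(m.subset_genes(orthologues))


# ---------------------------------------------------------------------------
# Divergence
# ---------------------------------------------------------------------------

def _jsd_terms(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Per-component JSD terms in bits; 0 * log(0/x) contributes 0."""
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        tp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0) / m), 0.0)
        tq = np.where(q > 0, q * np.log2(np.where(q > 0, q, 1.0) / m), 0.0)
    return 0.5 * (tp + tq)


def jsd_raw(p: StageDistribution | np.ndarray, q: StageDistribution | np.ndarray) -> float:
    """Jensen-Shannon divergence in bits between two probability vectors."""
    pv = p.p if isinstance(p, StageDistribution) else np.asarray(p, dtype=float)
    qv = q.p if isinstance(q, StageDistribution) else np.asarray(q, dtype=float)
    if pv.shape != qv.shape:
        raise ValueError(f"length mismatch: {pv.shape} vs {qv.shape}")
    return float(_jsd_terms(pv, qv).sum())


def gene_wise_jsd(p: StageDistribution, q: StageDistribution) -> GeneWiseJSD:
    """Per-orthologue JSD terms; they sum exactly to :func:`jsd_raw`."""
    if p.p.shape != q.p.shape:
        raise ValueError(f"length mismatch: {p.p.shape} vs {q.p.shape}")
    if p.genes != q.genes and len(p.genes) != len(q.genes):
        raise ValueError("orthologue index lists differ")
    values = _jsd_terms(p.p, q.p)
    label = f"{p.species_id}:{p.stage}__vs__{q.species_id}:{q.stage}"
    return GeneWiseJSD(pair_label=label, genes=list(p.genes), values=values)


def _simplex_rows(values: np.ndarray) -> np.ndarray:
    totals = values.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("a stage has an all-zero expression vector")
    return values / totals


def _jsd_grid(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Grid of JSD values between rows of two simplex matrices."""
    pa = a[:, None, :]
    qb = b[None, :, :]
    m = 0.5 * (pa + qb)
    with np.errstate(divide="ignore", invalid="ignore"):
        tp = np.where(pa > 0, pa * np.log2(np.where(pa > 0, pa, 1.0) / m), 0.0)
        tq = np.where(qb > 0, qb * np.log2(np.where(qb > 0, qb, 1.0) / m), 0.0)
    return 0.5 * (tp.sum(axis=2) + tq.sum(axis=2))


def _stage_value_matrix(m: ExpressionMatrix, genes: list[str]) -> np.ndarray:
    """stages x orthologues value matrix in stage order."""
    sub = m.subset_genes(genes)
    if sub.replicate_map is not None:
        sub = average_replicates(sub)
    return sub.data[list(sub.stages)].to_numpy(dtype=float).T


def stage_pair_matrix(
    m_a: ExpressionMatrix,
    m_b: ExpressionMatrix,
    orthologues: list[tuple[str, str]],
) -> JSDMatrix:
    """Raw JSD for every stage pair over the one-to-one orthologue list.

    Both matrices must already be quantile-transformed on the shared
    orthologue set (see :func:`prepare_for_jsd`).
    """
    if not orthologues:
        raise ValueError("empty orthologue list")
    for m in (m_a, m_b):
        if m.layer != "quantile_uniform":
            raise ValueError(
                f"stage_pair_matrix expects quantile_uniform matrices, got {m.layer!r}"
            )
    genes_a = [a for a, _ in orthologues]
    genes_b = [b for _, b in orthologues]
    va = _simplex_rows(_stage_value_matrix(m_a, genes_a))
    vb = _simplex_rows(_stage_value_matrix(m_b, genes_b))
    grid = _jsd_grid(va, vb)
    raw = pd.DataFrame(grid, index=list(m_a.stages), columns=list(m_b.stages))
    return JSDMatrix(
        species_a=m_a.species_id,
        species_b=m_b.species_id,
        raw=raw,
        n_orthologues=len(orthologues),
    )


def bootstrap_jsd(
    m_a: ExpressionMatrix,
    m_b: ExpressionMatrix,
    orthologues: list[tuple[str, str]],
    n_boot: int = 250,
    seed: int = 0,
) -> JSDMatrix:
    """Bootstrap over orthologue pairs: per-cell mean and SD grids.

    Each replicate resamples the orthologue pair list with replacement
    at its original size, renormalizes the stage distributions and
    recomputes the full grid. Deterministic given ``seed``.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    base = stage_pair_matrix(m_a, m_b, orthologues)
    genes_a = [a for a, _ in orthologues]
    genes_b = [b for _, b in orthologues]
    va = _stage_value_matrix(m_a, genes_a)
    vb = _stage_value_matrix(m_b, genes_b)
    n = len(orthologues)
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(base.raw.to_numpy())
    acc2 = np.zeros_like(acc)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        grid = _jsd_grid(_simplex_rows(va[:, idx]), _simplex_rows(vb[:, idx]))
        acc += grid
        acc2 += grid**2
    mean = acc / n_boot
    var = np.maximum(acc2 / n_boot - mean**2, 0.0) * n_boot / (n_boot - 1)
    return replace(
        base,
        boot_mean=pd.DataFrame(mean, index=base.raw.index, columns=base.raw.columns),
        boot_sd=pd.DataFrame(np.sqrt(var), index=base.raw.index, columns=base.raw.columns),
    )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _adjusted_grid(m: JSDMatrix) -> pd.DataFrame:
    """Bootstrap-mean (or raw) grid divided by the orthologue count."""
    grid = m.boot_mean if m.boot_mean is not None else m.raw
    return grid / m.n_orthologues


def normalize_jsd(
    matrices: list[JSDMatrix], scope: str = "global"
) -> list[JSDMatrix]:
    """Min-max normalize adjusted grids.

    ``scope='global'`` pools the min/max over every cell of every
    comparison (JSD_norm); ``scope='per_comparison'`` rescales within
    each comparison (relative JSD). Both variants are filled in on the
    returned copies.
    """
    if scope not in ("global", "per_comparison"):
        raise ValueError(f"unknown scope {scope!r}")
    if not matrices:
        raise ValueError("empty matrix collection")
    adjusted = [_adjusted_grid(m) for m in matrices]
    pooled = np.concatenate([a.to_numpy().ravel() for a in adjusted])
    gmin, gmax = float(pooled.min()), float(pooled.max())
    out = []
    for m, adj in zip(matrices, adjusted):
        lmin, lmax = float(adj.to_numpy().min()), float(adj.to_numpy().max())
        lo, hi = (gmin, gmax) if scope == "global" else (lmin, lmax)
        if hi <= lo:
            raise ValueError("degenerate collection: max adjusted JSD equals min")
        normalized = (adj - gmin) / (gmax - gmin) if gmax > gmin else adj * np.nan
        if lmax <= lmin:
            raise ValueError("degenerate comparison: max adjusted JSD equals min")
        relative = (adj - lmin) / (lmax - lmin)
        out.append(replace(m, adjusted=adj, normalized=normalized, relative=relative))
    return out


# ---------------------------------------------------------------------------
# Similarity drivers
# ---------------------------------------------------------------------------

def similarity_drivers(
    g: GeneWiseJSD,
    bw_method: str = "silverman",
    grid_points: int = 512,
    mode_fraction: float = 0.25,
) -> GeneWiseJSD:
    """Cut the gwJSD distribution at ``mode_fraction`` x its density mode.

    A Gaussian kernel density (Silverman bandwidth by default) is
    evaluated on a fixed grid from 0 to max(gwJSD); the mode is the grid
    point of maximal density and genes strictly below
    ``mode_fraction * mode`` are the similarity drivers.
    """
    values = np.asarray(g.values, dtype=float)
    if values.size < 30:
        raise ValueError("need at least 30 gwJSD values for density estimation")
    if np.allclose(values, values[0]):
        raise ValueError("degenerate gwJSD distribution: all values equal")
    kde = gaussian_kde(values, bw_method=bw_method)
    grid = np.linspace(0.0, float(values.max()), grid_points)
    density = kde(grid)
    mode = float(grid[int(np.argmax(density))])
    threshold = mode_fraction * mode
    drivers = [gene for gene, v in zip(g.genes, values) if v < threshold]
    logger.info(
        "%s: density mode %.4g, threshold %.4g, %d drivers of %d genes",
        g.pair_label, mode, threshold, len(drivers), values.size,
    )
    return replace(g, mode=mode, threshold=threshold, drivers=drivers)
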