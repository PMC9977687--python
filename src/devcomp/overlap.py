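"""Cross-species cluster comparison via orthogroup overlap.

Cluster pairs are tested for orthogroup overlap with upper-tail
hypergeometric tests; the adjusted p-value surface is summarized per
early/late quadrant by the relative-similarity ratio, and orthologue
pairs with discordant early/late membership form the heterochronically
shifted gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from devcomp.expression import ExpressionMatrix, average_replicates, zscore_rows

logger = logging.getLogger(__name__)

P_ADJ_FLOOR = 1e-300  # cap before -log10 to avoid infinities


class OrthologyMap:
    """Orthogroup memberships across species.

    Parameters
    ----------
    groups:
        ``orthogroup ID -> {species -> [gene, ...]}``. A gene may belong
        to at most one orthogroup.
    """

    def __init__(self, groups: dict[str, dict[str, list[str]]]):
        self.groups = groups
        self._gene_to_group: dict[str, dict[str, str]] = {}
        for og, per_species in groups.items():
            for species, genes in per_species.items():
                table = self._gene_to_group.setdefault(species, {})
                for gene in genes:
                    if gene in table:
                        raise ValueError(
                            f"gene {gene!r} ({species}) appears in orthogroups "
                            f"{table[gene]!r} and {og!r}"
                        )
                    table[gene] = og

    @property
    def species(self) -> list[str]:
        return sorted(self._gene_to_group)

    def orthogroup_of(self, species: str, gene: str) -> str | None:
        return self._gene_to_group.get(species, {}).get(gene)

    def one_to_one(self, species_a: str, species_b: str) -> list[tuple[str, str]]:
        """Orthologue pairs from orthogroups with exactly one gene in each species."""
        pairs = []
        for og in sorted(self.groups):
            a = self.groups[og].get(species_a, [])
            b = self.groups[og].get(species_b, [])
            if len(a) == 1 and len(b) == 1:
                pairs.append((a[0], b[0]))
        return pairs

    def single_copy(self, species_list: list[str]) -> list[tuple[str, ...]]:
        """Orthogroup tuples with exactly one gene in every listed species."""
        out = []
        for og in sorted(self.groups):
            members = [self.groups[og].get(sp, []) for sp in species_list]
            if all(len(g) == 1 for g in members):
                out.append(tuple(g[0] for g in members))
        return out

    @classmethod
    def from_orthogroups_tsv(cls, path) -> "OrthologyMap":
        """Parse an OrthoFinder-style ``Orthogroups.tsv``.

        First column: orthogroup ID; remaining columns: per-species
        comma-separated gene lists (possibly empty).
        """
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
        groups: dict[str, dict[str, list[str]]] = {}
        for og, row in df.iterrows():
            per_species = {}
            for species, cell in row.items():
                if pd.isna(cell) or not str(cell).strip():
                    continue
                genes = [g.strip() for g in str(cell).split(",") if g.strip()]
                if genes:
                    per_species[species] = genes
            groups[str(og)] = per_species
        return cls(groups)

    def to_orthogroups_tsv(self, path) -> None:
        species = self.species
        rows = {
            og: {sp: ", ".join(self.groups[og].get(sp, [])) for sp in species}
            for og in sorted(self.groups)
        }
        pd.DataFrame.from_dict(rows, orient="index", columns=species).to_csv(
            path, sep="\t", index_label="Orthogroup"
        )


@dataclass
class QuadrantSpec:
    """Per-species early/late cluster classification (with exclusions)."""

    early: dict[str, set]
    late: dict[str, set]
    excluded: dict[str, set] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for species in self.early:
            both = set(self.early[species]) & set(self.late.get(species, set()))
            if both:
                raise ValueError(
                    f"cluster(s) {sorted(both)} of {species!r} classified both early and late"
                )

    def classify(self, species: str, cluster) -> str | None:
        """'early', 'late', None for excluded; raises for unclassified."""
        if cluster in self.excluded.get(species, set()):
            return None
        if cluster in self.early.get(species, set()):
            return "early"
        if cluster in self.late.get(species, set()):
            return "late"
        raise ValueError(
            f"cluster {cluster!r} of species {species!r} is neither classified "
            "early/late nor excluded"
        )


# ---------------------------------------------------------------------------
# Overlap tests
# ---------------------------------------------------------------------------

def to_orthogroup_sets(
    assignments: pd.Series, omap: OrthologyMap, species: str
) -> dict:
    """Translate each cluster's genes into its set of distinct orthogroups."""
    sets: dict = {}
    n_unmapped = 0
    for gene, cluster in assignments.items():
        og = omap.orthogroup_of(species, gene)
        if og is None:
            n_unmapped += 1
            continue
        sets.setdefault(cluster, set()).add(og)
    if n_unmapped:
        logger.info("dropped %d genes of %s without an orthogroup", n_unmapped, species)
    if not any(sets.values()):
        raise ValueError(f"no cluster of {species!r} translated to any orthogroup")
    return sets


def pairwise_overlap_tests(
    sets_a: dict, sets_b: dict, universe: int
) -> pd.DataFrame:
    """Upper-tail hypergeometric test for every cluster pair.

    ``p_raw = P(X >= n_overlap)`` with
    ``X ~ Hypergeometric(N=universe, K=nA, n=nB)``.
    """
    max_size = max([len(s) for s in sets_a.values()] + [len(s) for s in sets_b.values()])
    if universe < max_size:
        raise ValueError(f"universe {universe} smaller than the largest set ({max_size})")
    rows = []
    for ca in sorted(sets_a):
        a = sets_a[ca]
        for cb in sorted(sets_b):
            b = sets_b[cb]
            overlap = len(a & b)
            if overlap > min(len(a), len(b)):  # pragma: no cover - set algebra forbids
                raise ValueError("overlap exceeds the smaller set")
            p = float(hypergeom.sf(overlap - 1, universe, len(a), len(b)))
            rows.append(
                {
                    "cluster_a": ca,
                    "cluster_b": cb,
                    "n_a": len(a),
                    "n_b": len(b),
                    "n_overlap": overlap,
                    "n_universe": universe,
                    "p_raw": min(p, 1.0),
                }
            )
    table = pd.DataFrame(rows)
    table["p_adj"] = adjust_pvalues(table["p_raw"].to_numpy(), method="BH")
    return table


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up or Bonferroni adjustment, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if method == "bonferroni":
        return np.minimum(p * n, 1.0)
    if method != "BH":
        raise ValueError(f"unknown correction method {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def quadrant_relative_similarity(
    table: pd.DataFrame,
    spec: QuadrantSpec,
    species_a: str,
    species_b: str,
    p_floor: float = P_ADJ_FLOOR,
) -> pd.DataFrame:
    """Relative similarity per early/late quadrant.

    ``RS = mean(-log10 p_adj within quadrant) / mean(-log10 p_adj over
    all classified pairs)``; > 1 means stronger-than-average overlap.
    Pairs touching an excluded cluster are dropped. An empty quadrant is
    reported with RS = NaN.
    """
    neglog, quadrant = [], []
    for row in table.itertuples(index=False):
        qa = spec.classify(species_a, row.cluster_a)
        qb = spec.classify(species_b, row.cluster_b)
        if qa is None or qb is None:
            continue
        quadrant.append(f"{qa}-{qb}")
        neglog.append(-np.log10(max(row.p_adj, p_floor)))
    frame = pd.DataFrame({"quadrant": quadrant, "neglog": neglog})
    if frame.empty:
        raise ValueError("no classified cluster pairs")
    overall = frame["neglog"].mean()
    rows = []
    for q in ("early-early", "early-late", "late-early", "late-late"):
        sub = frame[frame["quadrant"] == q]
        rs = float(sub["neglog"].mean() / overall) if len(sub) and overall > 0 else np.nan
        rows.append({"quadrant": q, "n_pairs": len(sub), "rs": rs})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Heterochronic gene sets
# ---------------------------------------------------------------------------

def shifted_gene_sets(
    assignments: dict[str, pd.Series],
    omap: OrthologyMap,
    spec: QuadrantSpec,
    pattern: dict[str, str],
) -> list[tuple[str, ...]]:
    """Single-copy orthologue tuples matching an early/late pattern.

    ``pattern`` maps each participating species to the required class,
    e.g. ``{"A": "early", "B": "late"}`` for the early(A)-late(B)
    quadrant, or a three-species rule like
    ``{"A": "late", "B": "late", "C": "early"}``. Tuples with a gene in
    an excluded cluster or without a cluster assignment are dropped.
    """
    species_list = list(pattern)
    out = []
    for genes in omap.single_copy(species_list):
        ok = True
        for species, gene in zip(species_list, genes):
            assign = assignments[species]
            if gene not in assign.index:
                ok = False
                break
            klass = spec.classify(species, assign[gene])
            if klass != pattern[species]:
                ok = False
                break
        if ok:
            out.append(genes)
    return out


def direction_pattern(direction: str, species_a: str, species_b: str) -> dict[str, str]:
    """Translate a two-species direction keyword into a pattern dict."""
    if direction == "earlyA_lateB":
        return {species_a: "early", species_b: "late"}
    if direction == "lateA_earlyB":
        return {species_a: "late", species_b: "early"}
    raise ValueError(f"unknown direction {direction!r}")


def average_dynamics(
    genes, m: ExpressionMatrix, smooth: bool = False, span: float = 0.75
) -> pd.DataFrame:
    """Mean z-scored profile (+/- SEM) over a gene set, per stage.

    Constant-profile genes cannot be z-scored and are excluded with a
    logged count. With ``smooth``, a LOWESS fit over stage ordinals with
    fraction ``span`` is added.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    sub = m.subset_genes(genes)
    if sub.replicate_map is not None:
        sub = average_replicates(sub)
    z, _ = zscore_rows(sub.data, drop_constant=True)
    if z.shape[0] == 0:
        raise ValueError("all genes in the set have constant profiles")
    mean = z.mean(axis=0)
    sem = z.std(axis=0, ddof=1) / np.sqrt(z.shape[0]) if z.shape[0] > 1 else mean * 0.0
    out = pd.DataFrame(
        {"stage": list(sub.stages), "mean": mean.to_numpy(), "sem": sem.to_numpy()}
    )
    if smooth:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        fitted = lowess(
            out["mean"].to_numpy(),
            np.arange(len(out)),
            frac=span,
            return_sorted=False,
        )
        out["smoothed"] = fitted
    return out
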