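"""Gene-label analytics: TF classes, phylostrata, tissue sets, dynamics.

Representation of annotation labels within expression clusters is tested
with two-tailed Fisher's exact tests; phylostratum expression summaries
use the 75th percentile of quantile-normalized values; anterior and
posterior-trunk gene sets are cut from the adult tissue panel by strict
exclusivity; per-stage dynamics contrasts use Student's t-tests with
Bonferroni correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from devcomp.expression import (
    ExpressionMatrix,
    TissuePanel,
    average_replicates,
    zscore_rows,
)
from devcomp.overlap import adjust_pvalues

logger = logging.getLogger(__name__)

#: Number of TF classes in the shipped catalogue.
N_TF_CLASSES = 36


@dataclass
class GeneAnnotation:
    """Per-gene labels: TF classes (0..n of a fixed catalogue), phylostratum."""

    tf_classes: dict[str, frozenset]
    phylostratum: dict[str, str]
    catalogue: list[str] = field(default_factory=list)
    strata_order: list[str] = field(default_factory=list)
    premetazoan_strata: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.catalogue:
            cat = set(self.catalogue)
            for gene, classes in self.tf_classes.items():
                extra = set(classes) - cat
                if extra:
                    raise ValueError(
                        f"gene {gene!r} carries TF class {sorted(extra)[0]!r} "
                        "outside the catalogue"
                    )

    def labels(self, kind: str) -> dict[str, frozenset]:
        """Gene -> label set for a label kind ('tf' or 'phylostratum')."""
        if kind == "tf":
            return self.tf_classes
        if kind == "phylostratum":
            return {g: frozenset([s]) for g, s in self.phylostratum.items()}
        raise ValueError(f"unknown label kind {kind!r}")

    def is_premetazoan(self, gene: str) -> bool | None:
        s = self.phylostratum.get(gene)
        return None if s is None else s in self.premetazoan_strata

    @classmethod
    def from_table(cls, path, catalogue: list[str] | None = None) -> "GeneAnnotation":
        """Read a (gene, label, label_kind) TSV."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        tf: dict[str, set] = {}
        ps: dict[str, str] = {}
        for row in df.itertuples(index=False):
            if row.label_kind == "tf":
                tf.setdefault(row.gene, set()).add(row.label)
            elif row.label_kind == "phylostratum":
                ps[row.gene] = row.label
        strata = sorted(set(ps.values()))
        return cls(
            tf_classes={g: frozenset(s) for g, s in tf.items()},
            phylostratum=ps,
            catalogue=catalogue or sorted({c for s in tf.values() for c in s}),
            strata_order=strata,
        )

    def to_table(self, path) -> None:
        rows = []
        for gene in sorted(self.tf_classes):
            for label in sorted(self.tf_classes[gene]):
                rows.append({"gene": gene, "label": label, "label_kind": "tf"})
        for gene in sorted(self.phylostratum):
            rows.append(
                {"gene": gene, "label": self.phylostratum[gene], "label_kind": "phylostratum"}
            )
        pd.DataFrame(rows, columns=["gene", "label", "label_kind"]).to_csv(
            path, sep="\t", index=False
        )


def classify_tf(
    gene_identifiers: dict[str, list], catalogue: dict[str, set]
) -> dict[str, frozenset]:
    """Assign TF classes by identifier intersection.

    A gene receives every class whose identifier set intersects the
    gene's identifier list; genes with no match receive none. Malformed
    (non-string) identifiers are logged and skipped.
    """
    if not catalogue:
        raise ValueError("empty TF class catalogue")
    out: dict[str, frozenset] = {}
    for gene, idents in gene_identifiers.items():
        clean = set()
        for ident in idents:
            if not isinstance(ident, str) or not ident.strip():
                logger.warning("gene %s: malformed identifier %r skipped", gene, ident)
                continue
            clean.add(ident.strip())
        classes = frozenset(
            klass for klass, members in catalogue.items() if clean & set(members)
        )
        if classes:
            out[gene] = classes
    return out


def label_enrichment(
    assignments: pd.Series,
    ann: GeneAnnotation,
    label_kind: str = "tf",
    correction: str = "BH",
) -> pd.DataFrame:
    """Two-tailed Fisher's exact test of label x cluster membership.

    For each (cluster, label) a 2x2 table is built over the assignment
    universe: ``a`` in-cluster with label, ``b`` in-cluster without,
    ``c`` out-of-cluster with label, ``d`` the rest. The two-tailed p
    sums the probabilities of all tables with fixed margins no more
    probable than the observed one. Correction is applied across the
    full (cluster, label) family.
    """
    gene_labels = ann.labels(label_kind)
    universe = list(assignments.index)
    n = len(universe)
    labels = sorted({l for g in universe for l in gene_labels.get(g, ())})
    clusters = sorted(assignments.unique())
    rows = []
    for cluster in clusters:
        members = set(assignments.index[assignments == cluster])
        if not members:
            logger.info("cluster %r is empty; skipped", cluster)
            continue
        for label in labels:
            with_label = {g for g in universe if label in gene_labels.get(g, ())}
            a = len(members & with_label)
            b = len(members) - a
            c = len(with_label) - a
            d = n - a - b - c
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(
                {
                    "cluster": cluster,
                    "label": label,
                    "a": a, "b": b, "c": c, "d": d,
                    "odds_ratio": float(odds),
                    "p_raw": float(p),
                    "direction": "over" if odds > 1 else "under",
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["cluster", "label", "a", "b", "c", "d", "odds_ratio", "p_raw", "direction"],
    )
    if len(table):
        table["p_adj"] = adjust_pvalues(table["p_raw"].to_numpy(), method=correction)
    else:
        table["p_adj"] = []
    return table


def phylostratum_profile(m: ExpressionMatrix, ann: GeneAnnotation) -> pd.DataFrame:
    """75th percentile (linear interpolation) of expression per stratum x stage."""
    data = m.data
    strata = ann.strata_order or sorted(set(ann.phylostratum.values()))
    rows = {}
    for stratum in strata:
        genes = [g for g in data.index if ann.phylostratum.get(g) == stratum]
        if not genes:
            logger.info("phylostratum %r has no genes in the matrix; skipped", stratum)
            continue
        rows[stratum] = np.percentile(data.loc[genes].to_numpy(), 75, axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=data.columns)


def tissue_restricted_sets(
    panel: TissuePanel, threshold: float = 2.0
) -> tuple[set[str], set[str]]:
    """Strictly tissue-restricted anterior and posterior-trunk gene sets.

    Anterior: TPM > threshold in BOTH designated anterior tissues and
    <= threshold in every other tissue of the panel; the posterior-trunk
    rule is symmetric. The two sets are disjoint by construction.
    """
    data = panel.data
    vals = data.to_numpy(dtype=float)
    cols = list(data.columns)

    def restricted(pair: tuple[str, str]) -> set[str]:
        in_idx = [cols.index(t) for t in pair]
        out_idx = [i for i in range(len(cols)) if i not in in_idx]
        hit = (vals[:, in_idx] > threshold).all(axis=1)
        silent = (vals[:, out_idx] <= threshold).all(axis=1) if out_idx else True
        return set(data.index[hit & silent])

    return restricted(panel.anterior), restricted(panel.posterior)


def compare_dynamics(
    set_a,
    set_b,
    m: ExpressionMatrix,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-stage Student's t-test of set A vs set B z-scored expression.

    Profiles are z-scored per gene; at each stage a two-sample,
    two-tailed t-test (pooled variance by default) contrasts the two
    sets, with Bonferroni correction across stages.
    """
    set_a, set_b = set(set_a), set(set_b)
    if set_a & set_b:
        raise ValueError("gene sets must be disjoint")
    if len(set_a) < 2 or len(set_b) < 2:
        raise ValueError("each gene set needs at least 2 genes")
    sub = m
    if sub.replicate_map is not None:
        sub = average_replicates(sub)
    z, _ = zscore_rows(sub.data, drop_constant=True)
    za = z.loc[[g for g in z.index if g in set_a]]
    zb = z.loc[[g for g in z.index if g in set_b]]
    if len(za) < 2 or len(zb) < 2:
        raise ValueError("fewer than 2 usable genes per set after z-scoring")
    rows = []
    for stage in sub.stages:
        a, b = za[stage].to_numpy(), zb[stage].to_numpy()
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append(
            {
                "stage": stage,
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "t": float(t),
                "p_raw": float(p),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = adjust_pvalues(table["p_raw"].to_numpy(), method="bonferroni")
    return table
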