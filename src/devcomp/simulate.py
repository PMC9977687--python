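"""Synthetic multi-species developmental expression datasets.

Genes follow temporally co-regulated archetypes (Gaussian bumps over
stage ordinals). A shared single-copy orthologue core spans the species;
a planted subset of orthologues has its peak shifted by a configured
number of stages in a designated species (heterochrony truth); count
noise is negative-binomial with log-normal library sizes. The generator
returns count and TPM layers, an orthology map, gene annotations with
planted TF-class enrichment, and the full ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from devcomp.enrichment import GeneAnnotation, N_TF_CLASSES
from devcomp.expression import ExpressionMatrix, write_expression_table
from devcomp.overlap import OrthologyMap

logger = logging.getLogger(__name__)


@dataclass
class SpeciesSpec:
    name: str
    n_stages: int = 8
    n_replicates: int = 2
    n_specific: int = 0  # species-specific genes without orthogroups
    late_from: int | None = None  # ordinal where the 'late' half starts


@dataclass
class HeterochronySpec:
    fraction: float = 0.0
    shift: int = 0  # in stages of the target species, positive = later
    species: str | None = None  # species receiving the shift


@dataclass
class NoiseSpec:
    dispersion: float = 0.1  # NB: var = mu + dispersion * mu^2; 0 = noiseless
    library_sigma: float = 0.2  # log-normal spread of per-column depth


@dataclass
class AnnotationSpec:
    tf_fraction: float = 0.08
    n_tf_classes: int = N_TF_CLASSES
    n_strata: int = 6
    planted_tf_class: str | None = "TF_class_01"
    planted_archetype: int = 0  # archetype enriched for the planted class
    planted_probability: float = 0.6


@dataclass
class SimulationConfig:
    species: list[SpeciesSpec] = field(
        default_factory=lambda: [SpeciesSpec("speciesA"), SpeciesSpec("speciesB")]
    )
    n_orthologous: int = 600
    n_archetypes: int = 4
    archetype_peaks: list[float] | None = None  # fractions of the stage range
    archetype_width: float = 0.12  # fraction of the stage range
    base_expression: float = 5.0
    amplitude_log_mean: float = 4.0
    amplitude_log_sigma: float = 0.4
    heterochrony: HeterochronySpec = field(default_factory=HeterochronySpec)
    annotation: AnnotationSpec = field(default_factory=AnnotationSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if not self.species:
            problems.append("no species specified")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            problems.append("species names are not unique")
        for s in self.species:
            if s.n_stages < 2:
                problems.append(f"{s.name}: n_stages must be >= 2")
            if s.n_replicates < 1:
                problems.append(f"{s.name}: n_replicates must be >= 1")
            if s.n_specific < 0:
                problems.append(f"{s.name}: n_specific must be >= 0")
        if self.n_orthologous < 1:
            problems.append("n_orthologous must be >= 1")
        if self.n_archetypes < 1:
            problems.append("n_archetypes must be >= 1")
        if self.archetype_peaks is not None and len(self.archetype_peaks) != self.n_archetypes:
            problems.append("archetype_peaks length must equal n_archetypes")
        h = self.heterochrony
        if not 0.0 <= h.fraction <= 1.0:
            problems.append("heterochrony fraction must be in [0, 1]")
        if h.fraction > 0:
            if h.species not in names:
                problems.append(f"heterochrony species {h.species!r} unknown")
            else:
                target = next(s for s in self.species if s.name == h.species)
                if abs(h.shift) >= target.n_stages:
                    problems.append("heterochrony shift must be smaller than n_stages")
        if self.noise.dispersion < 0:
            problems.append("dispersion must be >= 0")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "species" in d:
            d["species"] = [
                s if isinstance(s, SpeciesSpec) else SpeciesSpec(**s)
                for s in d["species"]
            ]
        if "heterochrony" in d:
            d["heterochrony"] = HeterochronySpec(**d["heterochrony"])
        if "noise" in d:
            d["noise"] = NoiseSpec(**d["noise"])
        if "annotation" in d:
            d["annotation"] = AnnotationSpec(**d["annotation"])
        return cls(**d)


@dataclass
class TruthBundle:
    """Planted ground truth for recovery checks."""

    archetype: dict[str, dict[str, int]]  # species -> gene -> archetype
    shifted: list[dict]  # [{orthogroup, genes: {species: gene}, shift}]
    stage_correspondence: dict[str, dict[str, str]]  # spA -> {stageA: stageB-like map}
    planted_enrichment: dict
    archetype_peaks: dict[str, list[float]]  # species -> peak ordinal per archetype

    def shifted_pairs(self, species_a: str, species_b: str) -> set[tuple[str, str]]:
        return {
            (rec["genes"][species_a], rec["genes"][species_b])
            for rec in self.shifted
            if species_a in rec["genes"] and species_b in rec["genes"]
        }


def _gauss_curve(ordinals: np.ndarray, peak: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((ordinals - peak) / width) ** 2)


def _stage_labels(n: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


def simulate_dataset(config: SimulationConfig):
    """Generate (matrices, orthology, annotation, truth) from the config.

    Returns
    -------
    matrices:
        ``{species: {"counts": ExpressionMatrix, "tpm": ExpressionMatrix}}``
    orthology: OrthologyMap
    annotation: GeneAnnotation
    truth: TruthBundle
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_arch = config.n_archetypes
    peaks_frac = (
        np.asarray(config.archetype_peaks, dtype=float)
        if config.archetype_peaks is not None
        else np.linspace(0.08, 0.92, n_arch)
    )

    # shared orthologue core: archetype, amplitude and base shared across species
    arch_of_orth = rng.integers(0, n_arch, size=config.n_orthologous)
    amplitude = rng.lognormal(config.amplitude_log_mean, config.amplitude_log_sigma,
                              size=config.n_orthologous)

    # heterochrony plant: orthologues whose shifted peak stays on the grid
    h = config.heterochrony
    shifted_idx: np.ndarray = np.array([], dtype=int)
    if h.fraction > 0 and h.shift != 0:
        target = next(s for s in config.species if s.name == h.species)
        width_ord = config.archetype_width * (target.n_stages - 1)
        peak_ord = peaks_frac * (target.n_stages - 1)
        eligible_arch = np.flatnonzero(
            (peak_ord + h.shift >= -0.25 * width_ord)
            & (peak_ord + h.shift <= (target.n_stages - 1) + 0.25 * width_ord)
        )
        eligible = np.flatnonzero(np.isin(arch_of_orth, eligible_arch))
        n_shift = int(round(h.fraction * config.n_orthologous))
        if n_shift > len(eligible):
            raise ValueError(
                f"cannot shift {n_shift} orthologues: only {len(eligible)} have "
                "archetype peaks compatible with the requested shift"
            )
        shifted_idx = np.sort(rng.choice(eligible, size=n_shift, replace=False))

    matrices: dict[str, dict[str, ExpressionMatrix]] = {}
    archetype_truth: dict[str, dict[str, int]] = {}
    peaks_by_species: dict[str, list[float]] = {}
    gene_names: dict[str, list[str]] = {}

    for spec in config.species:
        stages = _stage_labels(spec.n_stages)
        ordinals = np.arange(spec.n_stages, dtype=float)
        peak_ord = peaks_frac * (spec.n_stages - 1)
        width_ord = max(config.archetype_width * (spec.n_stages - 1), 0.25)
        peaks_by_species[spec.name] = [float(p) for p in peak_ord]

        orth_genes = [f"{spec.name}_g{i + 1:05d}" for i in range(config.n_orthologous)]
        spec_genes = [f"{spec.name}_x{i + 1:05d}" for i in range(spec.n_specific)]
        genes = orth_genes + spec_genes
        gene_names[spec.name] = genes

        arch_specific = rng.integers(0, n_arch, size=spec.n_specific)
        amp_specific = rng.lognormal(config.amplitude_log_mean,
                                     config.amplitude_log_sigma, size=spec.n_specific)
        arch_all = np.concatenate([arch_of_orth, arch_specific])
        amp_all = np.concatenate([amplitude, amp_specific])

        gene_peaks = peak_ord[arch_all].copy()
        if spec.name == h.species and len(shifted_idx):
            gene_peaks[shifted_idx] = peak_ord[arch_of_orth[shifted_idx]] + h.shift

        curves = _gauss_curve(ordinals[None, :], gene_peaks[:, None], width_ord)
        mu = config.base_expression + amp_all[:, None] * curves  # genes x stages

        rep_cols, rep_map = [], {}
        count_cols = {}
        for stage_i, stage in enumerate(stages):
            rep_map[stage] = []
            for r in range(spec.n_replicates):
                col = f"{stage}_r{r + 1}"
                rep_map[stage].append(col)
                rep_cols.append(col)
                lib = (
                    rng.lognormal(0.0, config.noise.library_sigma)
                    if config.noise.library_sigma > 0
                    else 1.0
                )
                mean_col = mu[:, stage_i] * lib
                if config.noise.dispersion > 0:
                    size = 1.0 / config.noise.dispersion
                    p = size / (size + mean_col)
                    count_cols[col] = rng.negative_binomial(size, p).astype(float)
                else:
                    count_cols[col] = mean_col.copy()
        counts = pd.DataFrame(count_cols, index=genes, columns=rep_cols)

        phases = {
            s: ("pre-larval" if spec.late_from is None or i < spec.late_from else "post-larval")
            for i, s in enumerate(stages)
        }
        counts_m = ExpressionMatrix(
            species_id=spec.name, data=counts, layer="counts",
            stages=stages, replicate_map=rep_map, phases=phases,
        )
        colsum = counts.sum(axis=0)
        tpm = counts / colsum.replace(0, np.nan) * 1e6
        tpm_m = ExpressionMatrix(
            species_id=spec.name, data=tpm.fillna(0.0), layer="tpm",
            stages=stages, replicate_map=rep_map, phases=phases,
        )
        matrices[spec.name] = {"counts": counts_m, "tpm": tpm_m}
        archetype_truth[spec.name] = {g: int(a) for g, a in zip(genes, arch_all)}

    # orthology: one gene per species per orthogroup for the shared core
    groups = {
        f"OG{i + 1:06d}": {
            spec.name: [gene_names[spec.name][i]] for spec in config.species
        }
        for i in range(config.n_orthologous)
    }
    orthology = OrthologyMap(groups)

    # annotations: TF classes (planted enrichment in one archetype) + strata
    a = config.annotation
    catalogue = [f"TF_class_{i + 1:02d}" for i in range(a.n_tf_classes)]
    strata = [f"PS{i + 1}" for i in range(a.n_strata)]
    premetazoan = set(strata[: max(1, a.n_strata // 2)])
    tf_classes: dict[str, frozenset] = {}
    phylostratum: dict[str, str] = {}
    for spec in config.species:
        for gene in gene_names[spec.name]:
            phylostratum[gene] = strata[rng.integers(0, a.n_strata)]
            is_planted_target = (
                a.planted_tf_class is not None
                and archetype_truth[spec.name][gene] == a.planted_archetype
                and rng.random() < a.planted_probability * a.tf_fraction
            )
            if is_planted_target:
                tf_classes[gene] = frozenset([a.planted_tf_class])
            elif rng.random() < a.tf_fraction:
                tf_classes[gene] = frozenset(
                    [catalogue[rng.integers(0, a.n_tf_classes)]]
                )
    annotation = GeneAnnotation(
        tf_classes=tf_classes,
        phylostratum=phylostratum,
        catalogue=catalogue,
        strata_order=strata,
        premetazoan_strata=premetazoan,
    )

    # truth bundle
    shifted = []
    for i in shifted_idx:
        og = f"OG{i + 1:06d}"
        shifted.append(
            {
                "orthogroup": og,
                "genes": {spec.name: gene_names[spec.name][i] for spec in config.species},
                "shift": int(h.shift),
            }
        )
    correspondence: dict[str, dict[str, str]] = {}
    ref = config.species[0]
    for spec in config.species[1:]:
        mapping = {}
        for i, stage in enumerate(_stage_labels(ref.n_stages)):
            frac = i / max(ref.n_stages - 1, 1)
            j = int(round(frac * (spec.n_stages - 1)))
            mapping[stage] = _stage_labels(spec.n_stages)[j]
        correspondence[f"{ref.name}->{spec.name}"] = mapping
    truth = TruthBundle(
        archetype=archetype_truth,
        shifted=shifted,
        stage_correspondence=correspondence,
        planted_enrichment={
            "tf_class": a.planted_tf_class,
            "archetype": a.planted_archetype,
        },
        archetype_peaks=peaks_by_species,
    )
    return matrices, orthology, annotation, truth


def write_bundle(
    matrices, orthology: OrthologyMap, annotation: GeneAnnotation,
    truth: TruthBundle, config: SimulationConfig, out_dir,
) -> dict:
    """Write all tables as TSV plus a JSON manifest; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for species, layers in matrices.items():
        for layer, m in layers.items():
            path = out / f"{species}.{layer}.tsv"
            write_expression_table(m, path)
            files.append(path.name)
        meta = pd.DataFrame(
            {
                "stage": m.stages,
                "ordinal": range(len(m.stages)),
                "phase": [(m.phases or {}).get(s, "pre-larval") for s in m.stages],
                "species": species,
                "replicates": [",".join((m.replicate_map or {}).get(s, [])) for s in m.stages],
            }
        )
        meta.to_csv(out / f"{species}.stages.tsv", sep="\t", index=False)
        files.append(f"{species}.stages.tsv")
    orthology.to_orthogroups_tsv(out / "orthogroups.tsv")
    annotation.to_table(out / "annotation.tsv")
    files += ["orthogroups.tsv", "annotation.tsv"]
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(dataclasses.asdict(truth), indent=1, sort_keys=True))
    files.append("truth.json")
    manifest = {"seed": config.seed, "config": config.to_dict(), "files": sorted(files)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def default_config(seed: int = 0) -> SimulationConfig:
    """Small two-species config exercising every pipeline stage quickly."""
    return SimulationConfig(
        species=[
            SpeciesSpec("speciesA", n_stages=8, n_replicates=2, n_specific=40, late_from=4),
            SpeciesSpec("speciesB", n_stages=8, n_replicates=2, n_specific=40, late_from=4),
        ],
        n_orthologous=600,
        n_archetypes=4,
        archetype_peaks=[0.0, 0.28, 0.62, 0.95],
        archetype_width=0.12,
        heterochrony=HeterochronySpec(fraction=0.05, shift=4, species="speciesB"),
        seed=seed,
    )
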