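"""Synthetic phenotype-labelled expression data with planted structure.

The generator emulates the statistical design the analysis expects: a
log2-scale expression matrix over three treatment conditions (BSA control,
palmitate, oleate) where palmitate-treated samples carry the toxic
phenotype, with

* planted cooperative gene pairs in one of three joint configurations
  (gap, substitute, on/off) that are jointly but not marginally
  phenotype-informative,
* redundant genes that are individually phenotype-shifted,
* per-condition mean trends mirroring measured metabolite profiles,
* planted pathway memberships, optionally with a designated hub gene that
  cooperates with several pathway members, and
* i.i.d. background noise genes.

All randomness flows from a single root seed through named substreams per
gene role, so a (config, seed) pair is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import CONDITIONS, ExpressionDataset, GeneSetCollection

__all__ = [
    "PlantedPair",
    "PathwaySpec",
    "SimulationConfig",
    "simulate_dataset",
    "null_config",
    "write_fixture",
]

PATTERNS = ("gap", "substitute", "onoff")

#: per-condition mean offsets (BSA, PA, OA) realising each trend code, in
#: units of ``trend_effect`` log2 expression
TREND_OFFSETS = {
    "I": (0.0, 1.0, 0.0),   # BSA < PA and PA > OA
    "II": (1.0, 0.0, 1.0),  # BSA > PA and PA < OA
    "III": (0.0, 1.0, 2.0), # BSA < PA < OA
    "IV": (2.0, 1.0, 0.0),  # BSA > PA > OA
}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedPair:
    """A cooperative gene pair to plant.

    ``delta`` is the phenotype effect (log2 units) along the pattern's
    discriminative joint axis; ``sigma_c2`` the variance of the latent
    expression level the two genes share.  The default ``sigma_c2 =
    delta**2`` keeps each gene's marginal class shift at about one
    within-class standard deviation, i.e. marginals near-uninformative
    while the joint axis separates cleanly - the defining property of a
    cooperative pair.  Gene ids are auto-assigned unless given.
    """

    pattern: str = "gap"
    delta: float = 2.0
    sigma_c2: float = 4.0
    genes: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise SimulationError(f"unknown pattern {self.pattern!r}")
        if self.delta < 0:
            raise SimulationError("delta must be >= 0")
        if self.sigma_c2 <= 0:
            raise SimulationError("sigma_c2 must be > 0")


@dataclass(frozen=True)
class PathwaySpec:
    """A planted pathway: name, member gene ids, optional hub neighbor.

    When ``hub`` is set, the generator plants cooperative (gap) pairs
    between the hub gene and the first ``n_hub_links`` members, so the hub
    emerges as a multiply-connected neighbor of the pathway in the
    inferred network.
    """

    name: str
    members: tuple[str, ...]
    hub: str | None = None
    n_hub_links: int = 3

    def __post_init__(self) -> None:
        if not self.members:
            raise SimulationError(f"pathway {self.name!r} has no members")
        if self.hub is not None and self.hub in self.members:
            raise SimulationError(
                f"hub gene {self.hub!r} is also a member of pathway {self.name!r}"
            )
        if self.hub is not None and self.n_hub_links > len(self.members):
            raise SimulationError(
                f"pathway {self.name!r}: n_hub_links exceeds member count"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults are the package's reference study conditions: 50 genes,
    30 toxic (palmitate) plus 30 nontoxic (BSA/oleate) samples, planted
    pair effect delta = 2 log2-units with shared variance delta**2, and
    measurement noise 0.3 log2-units.
    """

    n_genes: int = 50
    n_samples_per_phenotype: int = 30
    n_conditions: int = 3
    planted_pairs: tuple[PlantedPair, ...] = ()
    n_redundant_genes: int = 0
    redundant_effect: float = 2.0
    trend_assignment: Mapping[str, str] = field(default_factory=dict)
    pathway_spec: tuple[PathwaySpec, ...] = ()
    trend_effect: float = 1.0
    noise_sd: float = 0.3
    baseline_range: tuple[float, float] = (6.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples_per_phenotype < 1:
            raise SimulationError("counts must be strictly positive")
        if self.n_conditions != 3:
            raise SimulationError("the design has exactly 3 conditions")
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be > 0")
        for gene, code in self.trend_assignment.items():
            if code not in TREND_OFFSETS:
                raise SimulationError(f"gene {gene!r}: unknown trend code {code!r}")

    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]


def null_config(
    n_genes: int = 50, n_samples_per_phenotype: int = 30, seed: int = 0
) -> SimulationConfig:
    """A configuration with no planted structure (pure background noise)."""
    return SimulationConfig(
        n_genes=n_genes, n_samples_per_phenotype=n_samples_per_phenotype, seed=seed
    )


def _resolve_roles(config: SimulationConfig) -> dict:
    """Assign genes to roles; reject conflicting assignments by name."""
    names = config.gene_names()
    known = set(names)
    claimed: dict[str, str] = {}

    def claim(gene: str, role: str) -> None:
        if gene not in known:
            raise SimulationError(f"gene {gene!r} not in the gene universe")
        if gene in claimed:
            raise SimulationError(
                f"conflicting role assignment for gene {gene!r}: "
                f"{claimed[gene]} vs {role}"
            )
        claimed[gene] = role

    free = iter(names)

    def next_free() -> str:
        for g in free:
            if g not in claimed:
                return g
        raise SimulationError("not enough genes for the requested roles")

    pairs: list[tuple[str, str, PlantedPair]] = []
    for spec in config.planted_pairs:
        if spec.genes is not None:
            a, b = spec.genes
        else:
            a, b = next_free(), next_free()
        claim(a, f"pair:{spec.pattern}")
        claim(b, f"pair:{spec.pattern}")
        pairs.append((a, b, spec))

    hubs: list[tuple[str, tuple[str, ...], PathwaySpec]] = []
    for pw in config.pathway_spec:
        for g in pw.members:
            if g not in known:
                raise SimulationError(
                    f"pathway {pw.name!r} references unknown gene {g!r}"
                )
        if pw.hub is not None:
            linked = pw.members[: pw.n_hub_links]
            claim(pw.hub, f"hub:{pw.name}")
            for g in linked:
                claim(g, f"hub-partner:{pw.name}")
            hubs.append((pw.hub, linked, pw))

    redundant = [next_free() for _ in range(config.n_redundant_genes)]
    for g in redundant:
        claim(g, "redundant")

    background = [g for g in names if g not in claimed]
    return {
        "names": names,
        "pairs": pairs,
        "hubs": hubs,
        "redundant": redundant,
        "background": background,
    }


def _sample_design(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    """Sample ids, conditions and phenotypes: palmitate samples are toxic."""
    n = config.n_samples_per_phenotype
    n_bsa = (n + 1) // 2
    conditions = ["PA"] * n + ["BSA"] * n_bsa + ["OA"] * (n - n_bsa)
    phenotypes = ["toxic"] * n + ["nontoxic"] * n
    samples = [f"S{i:03d}" for i in range(1, 2 * n + 1)]
    return samples, conditions, phenotypes


def _pair_values(
    spec: PlantedPair, s: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Centered expression of a planted pair; ``s`` is +1 toxic / -1 nontoxic."""
    n = s.size
    if spec.pattern in ("gap", "substitute"):
        c = rng.normal(0.0, np.sqrt(spec.sigma_c2), n)
        e1 = rng.normal(0.0, noise_sd, n)
        e2 = rng.normal(0.0, noise_sd, n)
        if spec.pattern == "gap":
            # positively correlated; phenotype on the difference axis
            return c + s * spec.delta / 2 + e1, c - s * spec.delta / 2 + e2
        # negatively correlated; phenotype on the sum axis
        return c + s * spec.delta / 2 + e1, -c + s * spec.delta / 2 + e2
    # on/off: nontoxic samples sit in a tight joint silent state, toxic
    # samples are dispersed on an annulus of radius 2-3
    g1 = np.empty(n)
    g2 = np.empty(n)
    off = s < 0
    n_off = int(off.sum())
    quiet = rng.normal(0.0, np.sqrt(0.1), (n_off, 2))
    g1[off], g2[off] = quiet[:, 0], quiet[:, 1]
    n_on = n - n_off
    radius = rng.uniform(2.0, 3.0, n_on)
    angle = rng.uniform(0.0, 2.0 * np.pi, n_on)
    g1[~off] = radius * np.cos(angle)
    g2[~off] = radius * np.sin(angle)
    return g1, g2


def simulate_dataset(config: SimulationConfig) -> ExpressionDataset:
    """Generate a phenotype-labelled expression dataset from the config.

    The returned dataset carries a ``truth`` dict with the resolved planted
    structure (pair gene ids and patterns, redundant genes, hub links, and
    the planted gene sets) for benchmarking.
    """
    roles = _resolve_roles(config)
    samples, conditions, phenotypes = _sample_design(config)
    n = len(samples)
    s = np.where(np.array(phenotypes) == "toxic", 1.0, -1.0)
    cond_idx = np.array([CONDITIONS.index(c) for c in conditions])

    root = np.random.SeedSequence(config.seed)
    streams = dict(
        zip(
            ("baseline", "background", "pairs", "hubs", "redundant"),
            (np.random.default_rng(child) for child in root.spawn(5)),
        )
    )

    names = roles["names"]
    values = np.zeros((len(names), n))
    gi = {g: i for i, g in enumerate(names)}

    baselines = streams["baseline"].uniform(*config.baseline_range, len(names))
    values += baselines[:, None]

    for gene, code in config.trend_assignment.items():
        offsets = np.array(TREND_OFFSETS[code]) * config.trend_effect
        values[gi[gene]] += offsets[cond_idx]

    rng_bg = streams["background"]
    for g in roles["background"]:
        values[gi[g]] += rng_bg.normal(0.0, config.noise_sd, n)

    rng_pairs = streams["pairs"]
    truth_pairs = []
    for a, b, spec in roles["pairs"]:
        v1, v2 = _pair_values(spec, s, config.noise_sd, rng_pairs)
        values[gi[a]] += v1
        values[gi[b]] += v2
        truth_pairs.append({"gene1": a, "gene2": b, "pattern": spec.pattern})

    rng_hubs = streams["hubs"]
    truth_hubs = {}
    for hub, linked, pw in roles["hubs"]:
        # the hub shares one latent level with its linked pathway members:
        # every hub-member pair is a gap-configured cooperative pair
        ref = PlantedPair(pattern="gap")
        c = rng_hubs.normal(0.0, np.sqrt(ref.sigma_c2), n)
        values[gi[hub]] += c + s * ref.delta / 2 + rng_hubs.normal(0, config.noise_sd, n)
        for g in linked:
            values[gi[g]] += (
                c - s * ref.delta / 2 + rng_hubs.normal(0, config.noise_sd, n)
            )
        truth_hubs[pw.name] = {"hub": hub, "linked": list(linked)}

    rng_red = streams["redundant"]
    for g in roles["redundant"]:
        values[gi[g]] += (
            s * config.redundant_effect / 2 + rng_red.normal(0, config.noise_sd, n)
        )

    ds = ExpressionDataset(
        pd.DataFrame(values, index=names, columns=samples),
        pd.Series(conditions, index=samples),
        pd.Series(phenotypes, index=samples),
    )
    gene_sets = None
    if config.pathway_spec:
        gene_sets = GeneSetCollection(
            {pw.name: pw.members for pw in config.pathway_spec},
            {pw.name: "planted pathway" for pw in config.pathway_spec},
        )
    ds.truth = {
        "pairs": truth_pairs,
        "redundant": list(roles["redundant"]),
        "background": list(roles["background"]),
        "hubs": truth_hubs,
        "gene_sets": gene_sets,
    }
    return ds


def write_fixture(
    dataset: ExpressionDataset,
    gene_sets: GeneSetCollection | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write expression/metadata TSVs (and a GMT) under ``out_dir``."""
    from . import io as io_mod

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "metadata": out / "samples.tsv",
    }
    io_mod.write_expression(dataset, paths["expression"], paths["metadata"])
    if gene_sets is not None:
        paths["gene_sets"] = out / "gene_sets.gmt"
        io_mod.write_gene_sets(gene_sets, paths["gene_sets"])
    return paths


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different root seed."""
    return replace(config, seed=seed)
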