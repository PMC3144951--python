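"""Seeded generators for populations, Ct tables, phenotypes and dilutions.

Every generator takes an explicit ``seed`` (or an existing
``numpy.random.Generator``) and is bit-reproducible.  Ct tables are built
by inverting the copy-number equation: at 100 % efficiency the mean target
Ct is the sample's control Ct minus log2(copies / 2); with efficiencies
different from 1 the corresponding (1 + E)-based inverse is used.  Noise is
Gaussian in cycle units: a between-sample shift of the control baseline
(which cancels in the target/control difference) and independent
per-replicate scatter.

``PY_LIKE`` and ``JH_LIKE`` are convenience population specs emulating a
wide (copies 2-12, modal classes 7-10) and a narrow (copies 2-6, modal
classes 3-4) genotype distribution; the residual probability mass is
spread uniformly over the non-modal classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

from ferricnv.assoc import TRAITS, PhenotypeRecord
from ferricnv.qpcr import CtWell, DilutionPoint
from ferricnv.seqfeat import GeneModel, NucleotideSequence


def _rng(seed: "int | np.random.Generator | None") -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PopulationSpec:
    """Categorical diploid copy-number distribution for a population."""

    population_id: str
    genotype_distribution: Mapping[int, float]
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        if not self.genotype_distribution:
            raise ValueError("empty genotype distribution")
        total = float(sum(self.genotype_distribution.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genotype probabilities sum to {total}, not 1")
        for cn, p in self.genotype_distribution.items():
            if cn < 2:
                raise ValueError(f"copy number {cn} < 2 in distribution")
            if p < 0:
                raise ValueError(f"negative probability for copy number {cn}")


def _spec_with_modes(
    population_id: str,
    modes: Mapping[int, float],
    support: Sequence[int],
    n: int,
) -> PopulationSpec:
    rest = [cn for cn in support if cn not in modes]
    residual = 1.0 - sum(modes.values())
    dist = dict(modes)
    for cn in rest:
        dist[cn] = residual / len(rest)
    return PopulationSpec(
        population_id=population_id,
        genotype_distribution=dict(sorted(dist.items())),
        n=n,
    )


#: wild-like population: copies 2-12, modal classes 7/8/9/10
PY_LIKE = _spec_with_modes(
    "PY",
    {7: 0.233, 8: 0.167, 9: 0.20, 10: 0.15},
    support=range(2, 13),
    n=60,
)

#: cultured-like population: copies 2-6, modal classes 3/4
JH_LIKE = _spec_with_modes(
    "JH",
    {3: 0.40, 4: 0.49},
    support=range(2, 7),
    n=100,
)


@dataclass(frozen=True)
class CtNoiseModel:
    """Gaussian noise structure for simulated Ct tables (cycle units)."""

    baseline_control_ct: float = 26.0
    replicate_sd: float = 0.1
    between_sample_sd: float = 0.3
    eff_target: float = 1.0
    eff_control: float = 1.0

    def __post_init__(self) -> None:
        if self.replicate_sd < 0 or self.between_sample_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not (0 < self.eff_target <= 1.1 and 0 < self.eff_control <= 1.1):
            raise ValueError("efficiencies must lie in (0, 1.1]")

    @classmethod
    def noiseless(cls, **kwargs) -> "CtNoiseModel":
        return cls(replicate_sd=0.0, between_sample_sd=0.0, **kwargs)


@dataclass(frozen=True)
class PhenotypeEffectSpec:
    """Per-copy-class trait distributions: {copy: {trait: (mean, sd)}}."""

    class_params: Mapping[int, Mapping[str, tuple[float, float]]]

    def __post_init__(self) -> None:
        for cn, traits in self.class_params.items():
            for trait, (mean, sd) in traits.items():
                if sd < 0:
                    raise ValueError(f"negative SD for copy {cn} trait {trait}")

    @staticmethod
    def sd_from_se(se: float, n: int) -> float:
        """Reconstruct a group SD from a reported standard error."""
        return se * math.sqrt(n)


#: Published growth summaries for the 3- and 4-copy classes of the cultured
#: cohort: trait -> copy class -> (n, mean, SE).  Units: mm for shell
#: dimensions, g for weight.  Used to parameterise realistic simulations.
REFERENCE_GROWTH_SUMMARIES: dict[str, dict[int, tuple[int, float, float]]] = {
    "shell_length": {3: (40, 133.37, 1.29), 4: (49, 136.57, 1.30)},
    "shell_width": {3: (40, 33.23, 1.35), 4: (49, 32.98, 0.74)},
    "body_weight": {3: (40, 256.85, 15.66), 4: (49, 267.39, 9.97)},
}


def reference_effect_spec() -> PhenotypeEffectSpec:
    """Effect spec for copy classes 3 and 4 built from the published
    summaries, with SDs reconstructed as SE * sqrt(n)."""
    params: dict[int, dict[str, tuple[float, float]]] = {}
    for trait, by_class in REFERENCE_GROWTH_SUMMARIES.items():
        for cn, (n, mean, se) in by_class.items():
            params.setdefault(cn, {})[trait] = (
                mean,
                PhenotypeEffectSpec.sd_from_se(se, n),
            )
    return PhenotypeEffectSpec(class_params=params)


def simulate_population(
    spec: PopulationSpec,
    seed: "int | np.random.Generator | None" = None,
) -> list[tuple[str, int]]:
    """Draw ``spec.n`` individuals from the categorical copy distribution."""
    rng = _rng(seed)
    classes = np.array(sorted(spec.genotype_distribution), dtype=int)
    probs = np.array([spec.genotype_distribution[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    draws = rng.choice(classes, size=spec.n, p=probs)
    width = max(4, len(str(spec.n)))
    return [
        (f"{spec.population_id}_{i + 1:0{width}d}", int(copies))
        for i, copies in enumerate(draws)
    ]


def expected_target_ct(
    copies: int,
    control_ct: float,
    eff_target: float = 1.0,
    eff_control: float = 1.0,
    control_diploid_copies: int = 2,
) -> float:
    """Invert the copy-number equation: the noiseless mean target Ct."""
    if copies < 1:
        raise ValueError("copies must be >= 1")
    return (
        control_ct * math.log(1.0 + eff_control)
        - math.log(copies / control_diploid_copies)
    ) / math.log(1.0 + eff_target)


def simulate_ct_table(
    genotypes: Iterable[tuple[str, int]],
    noise: CtNoiseModel | None = None,
    replicates: int = 3,
    seed: "int | np.random.Generator | None" = None,
) -> list[CtWell]:
    """Generate replicate Ct wells for both assays for every individual."""
    noise = noise or CtNoiseModel()
    rng = _rng(seed)
    wells: list[CtWell] = []
    for sample_id, copies in genotypes:
        control_mean = noise.baseline_control_ct + (
            rng.normal(0.0, noise.between_sample_sd)
            if noise.between_sample_sd > 0
            else 0.0
        )
        target_mean = expected_target_ct(
            copies, control_mean, noise.eff_target, noise.eff_control
        )
        for assay, mean in (("control", control_mean), ("target", target_mean)):
            for rep in range(1, replicates + 1):
                ct = mean + (
                    rng.normal(0.0, noise.replicate_sd)
                    if noise.replicate_sd > 0
                    else 0.0
                )
                wells.append(
                    CtWell(sample_id=sample_id, assay=assay, replicate=rep, ct=ct)
                )
    return wells


def simulate_phenotypes(
    genotypes: Iterable[tuple[str, int]],
    effects: PhenotypeEffectSpec,
    seed: "int | np.random.Generator | None" = None,
) -> list[PhenotypeRecord]:
    """Independent normal draws per trait with class-specific mean and SD.

    Traits are physical measurements and must stay positive, so draws are
    taken from the normal distribution truncated at zero (rejection
    sampling; negligible distortion while mean/SD stays above ~2.5).
    """
    rng = _rng(seed)
    records: list[PhenotypeRecord] = []
    for sample_id, copies in genotypes:
        if copies not in effects.class_params:
            raise ValueError(f"no phenotype parameters for copy class {copies}")
        params = effects.class_params[copies]
        values = {}
        for trait in TRAITS:
            if trait not in params:
                raise ValueError(f"trait {trait!r} missing for copy class {copies}")
            mean, sd = params[trait]
            value = mean + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            while value <= 0:
                value = mean + rng.normal(0.0, sd)
            values[trait] = value
        records.append(PhenotypeRecord(sample_id=sample_id, **values))
    return records


def simulate_dilution_series(
    true_amplification_factor: float,
    levels: "int | Sequence[float]" = 5,
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: "int | np.random.Generator | None" = None,
    intercept: float = 35.0,
    level_step: float = 1.0,
) -> list[DilutionPoint]:
    """Standard-curve wells for a given per-cycle amplification factor.

    ``levels`` is either a count (log10 quantities 0, -step, -2*step, ...)
    or an explicit sequence of log10 quantities.  The noiseless Ct at
    log10 quantity q is ``intercept + slope * q`` with
    ``slope = -ln(10) / ln(factor)``, so the fitted efficiency equals
    ``(factor - 1) * 100`` exactly in the absence of noise.
    """
    f = true_amplification_factor
    if not (1.0 < f <= 2.2):
        raise ValueError(f"amplification factor must lie in (1, 2.2], got {f}")
    if isinstance(levels, int):
        if levels < 3:
            raise ValueError("need at least 3 dilution levels")
        quantities = [-level_step * i for i in range(levels)]
    else:
        quantities = list(levels)
        if len(set(quantities)) < 3:
            raise ValueError("need at least 3 distinct dilution levels")
    rng = _rng(seed)
    slope = -math.log(10.0) / math.log(f)
    points: list[DilutionPoint] = []
    for q in quantities:
        for rep in range(1, replicates + 1):
            ct = intercept + slope * q + (
                rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            )
            points.append(DilutionPoint(log10_quantity=q, ct=ct, replicate=rep))
    return points


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def simulate_gene_model(
    n_introns: int = 3,
    exon_length: tuple[int, int] = (30, 80),
    intron_length: tuple[int, int] = (20, 60),
    flank_length: tuple[int, int] = (0, 30),
    seed: "int | np.random.Generator | None" = None,
) -> tuple[NucleotideSequence, NucleotideSequence, GeneModel]:
    """Random (cdna, genomic, model) triple with canonical GT/AG introns.

    Boundaries are made unambiguous for exact-anchoring recovery: each
    intron starts with GT while the following exon never starts with G, so
    the longest exact match stops exactly at the true splice donor.
    """
    rng = _rng(seed)
    n_exons = n_introns + 1
    exons = []
    for i in range(n_exons):
        length = int(rng.integers(exon_length[0], exon_length[1] + 1))
        seq = _random_seq(rng, length)
        if i > 0:
            # first base of a non-initial exon must not extend the GT donor
            seq = str(rng.choice(np.array(list("ACT")))) + seq[1:]
        exons.append(seq)
    introns = []
    for _ in range(n_introns):
        core = _random_seq(
            rng, int(rng.integers(intron_length[0], intron_length[1] + 1)) - 4
        )
        introns.append("GT" + core + "AG")
    left = _random_seq(rng, int(rng.integers(flank_length[0], flank_length[1] + 1)))
    right = _random_seq(rng, int(rng.integers(flank_length[0], flank_length[1] + 1)))

    pieces = [left]
    coords: list[tuple[int, int]] = []
    intron_coords: list[tuple[int, int, str, str]] = []
    pos = len(left)
    for i, exon in enumerate(exons):
        coords.append((pos + 1, pos + len(exon)))
        pieces.append(exon)
        pos += len(exon)
        if i < n_introns:
            intron = introns[i]
            intron_coords.append((pos + 1, pos + len(intron), "GT", "AG"))
            pieces.append(intron)
            pos += len(intron)
    pieces.append(right)
    genomic = "".join(pieces)
    cdna = "".join(exons)
    model = GeneModel(
        exons=tuple(coords),
        introns=tuple(intron_coords),
        total_genomic_length=len(genomic),
    )
    return (
        NucleotideSequence(id="sim_cdna", residues=cdna),
        NucleotideSequence(id="sim_genomic", residues=genomic),
        model,
    )


@dataclass(frozen=True)
class Scenario:
    """End-to-end simulation configuration loaded from YAML or JSON."""

    population: PopulationSpec
    ct_noise: CtNoiseModel = field(default_factory=CtNoiseModel)
    effects: Optional[PhenotypeEffectSpec] = None
    replicates: int = 3


def load_scenario(path: "str | Path") -> Scenario:
    """Parse a scenario file.

    Expected keys: ``population`` (population_id, n, genotype_distribution),
    optional ``ct_noise`` (CtNoiseModel fields), optional ``phenotypes``
    ({copy: {trait: {mean, sd}}}) and ``replicates``.
    """
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    pop = raw["population"]
    spec = PopulationSpec(
        population_id=str(pop["population_id"]),
        genotype_distribution={
            int(k): float(v) for k, v in pop["genotype_distribution"].items()
        },
        n=int(pop["n"]),
    )
    noise = CtNoiseModel(**{k: float(v) for k, v in raw.get("ct_noise", {}).items()})
    effects = None
    if "phenotypes" in raw:
        effects = PhenotypeEffectSpec(
            class_params={
                int(cn): {
                    str(trait): (float(p["mean"]), float(p["sd"]))
                    for trait, p in traits.items()
                }
                for cn, traits in raw["phenotypes"].items()
            }
        )
    return Scenario(
        population=spec,
        ct_noise=noise,
        effects=effects,
        replicates=int(raw.get("replicates", 3)),
    )


def simulate_scenario(
    scenario: Scenario,
    seed: "int | np.random.Generator | None" = None,
) -> dict:
    """Run a scenario end to end; returns genotypes, wells and phenotypes."""
    rng = _rng(seed)
    genotypes = simulate_population(scenario.population, rng)
    wells = simulate_ct_table(
        genotypes, scenario.ct_noise, replicates=scenario.replicates, seed=rng
    )
    out = {"genotypes": genotypes, "wells": wells}
    if scenario.effects is not None:
        out["phenotypes"] = simulate_phenotypes(genotypes, scenario.effects, rng)
    return out
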