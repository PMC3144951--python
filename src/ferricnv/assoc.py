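"""Genotype frequency summaries and copy-number / growth association tests.

Frequencies are computed over called genotypes only; no-calls are counted
separately and never enter the denominator.  Association between two
copy-number classes uses a two-sided two-sample t-test per trait, with both
the Welch (unequal variance, the default) and Student (pooled variance)
variants available.  The t statistic is oriented as group_b minus group_a.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TRAITS = ("shell_length", "shell_width", "body_weight")
ALPHA = 0.05
METHODS = ("welch", "student")


@dataclass(frozen=True)
class PhenotypeRecord:
    """Growth measurements for one individual (lengths in mm, weight in g)."""

    sample_id: str
    shell_length: float
    shell_width: float
    body_weight: float

    def __post_init__(self) -> None:
        for trait in TRAITS:
            value = getattr(self, trait)
            if not math.isnan(value) and value <= 0:
                raise ValueError(f"{trait} must be positive, got {value}")


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and standard error of one group for one trait."""

    n: int
    mean: float
    se: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group size must be >= 2, got {self.n}")
        if self.se <= 0:
            raise ValueError(f"standard error must be positive, got {self.se}")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError("need >= 2 values for a summary")
        sd = float(arr.std(ddof=1))
        if sd == 0:
            raise ValueError("zero variance group")
        return cls(n=int(arr.size), mean=float(arr.mean()), se=sd / math.sqrt(arr.size))

    @property
    def sd(self) -> float:
        """Standard deviation reconstructed as se * sqrt(n)."""
        return self.se * math.sqrt(self.n)


@dataclass(frozen=True)
class AssociationResult:
    """Outcome of one two-sample comparison."""

    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    method: str
    trait: Optional[str] = None
    group_a: Optional[int] = None
    group_b: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class GenotypeFrequencyTable:
    """Copy-number counts and relative frequencies for one population."""

    population_id: str
    counts: Mapping[int, int]
    n_no_call: int = 0

    @property
    def n_called(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[int, float]:
        total = self.n_called
        return {cn: count / total for cn, count in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        freqs = self.frequencies
        return pd.DataFrame(
            {
                "population_id": self.population_id,
                "copy_number": list(self.counts),
                "count": list(self.counts.values()),
                "frequency": [freqs[cn] for cn in self.counts],
            }
        )


def genotype_frequencies(
    calls: Iterable[tuple[str, Optional[int]]],
    population_id: str = "pop",
) -> GenotypeFrequencyTable:
    """Tabulate called genotypes; no-calls tallied separately.

    ``calls`` is an iterable of ``(sample_id, copy_number_or_None)``.
    Raises ``ValueError`` when no genotype at all was called.
    """
    counts: dict[int, int] = {}
    n_no_call = 0
    for _sample_id, call in calls:
        if call is None:
            n_no_call += 1
        else:
            counts[int(call)] = counts.get(int(call), 0) + 1
    if not counts:
        raise ValueError("no called genotypes to summarise")
    return GenotypeFrequencyTable(
        population_id=population_id,
        counts=dict(sorted(counts.items())),
        n_no_call=n_no_call,
    )


def _validate_group(values: np.ndarray, label: str) -> None:
    if values.size < 2:
        raise ValueError(f"group {label} has fewer than 2 observations")
    if values.std(ddof=1) == 0:
        raise ValueError(f"group {label} has zero variance")


def t_test_raw(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "welch",
) -> AssociationResult:
    """Two-sided two-sample t-test on raw observations (b minus a)."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    _validate_group(a, "a")
    _validate_group(b, "b")
    res = stats.ttest_ind(b, a, equal_var=(method == "student"))
    return AssociationResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        method=method,
    )


def t_from_summary(
    a: GroupSummary,
    b: GroupSummary,
    method: str = "welch",
) -> AssociationResult:
    """Two-sample t-test from (n, mean, SE) summaries (b minus a).

    For Welch the statistic is (mean_b - mean_a) / sqrt(se_a^2 + se_b^2)
    with Welch-Satterthwaite degrees of freedom.  The Student variant
    reconstructs SDs as se * sqrt(n) and pools.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    res = stats.ttest_ind_from_stats(
        mean1=b.mean,
        std1=b.sd,
        nobs1=b.n,
        mean2=a.mean,
        std2=a.sd,
        nobs2=a.n,
        equal_var=(method == "student"),
    )
    if method == "student":
        df = float(a.n + b.n - 2)
    else:
        va, vb = a.se**2, b.se**2
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return AssociationResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=df,
        p_value=float(res.pvalue),
        method=method,
    )


@dataclass(frozen=True)
class AssociationReport:
    """Summary table plus per-trait test results for one class contrast."""

    class_a: int
    class_b: int
    summaries: pd.DataFrame = field(repr=False)
    results: tuple[AssociationResult, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": [r.trait for r in self.results],
                "class_a": self.class_a,
                "class_b": self.class_b,
                "t": [r.t_statistic for r in self.results],
                "df": [r.degrees_of_freedom for r in self.results],
                "p_value": [r.p_value for r in self.results],
                "method": [r.method for r in self.results],
                "significant": [r.significant for r in self.results],
            }
        )


def associate(
    calls: Iterable[tuple[str, Optional[int]]],
    phenotypes: Iterable[PhenotypeRecord],
    class_a: int,
    class_b: int,
    method: str = "welch",
    traits: Sequence[str] = TRAITS,
) -> AssociationReport:
    """Join genotype calls to phenotypes and test class_b against class_a.

    Individuals lacking either a call or a phenotype are dropped pairwise;
    unmatched sample ids are logged.  Each trait is tested independently at
    alpha = 0.05 with no multiplicity correction.
    """
    call_map = {sid: call for sid, call in calls if call is not None}
    pheno_map = {p.sample_id: p for p in phenotypes}
    unmatched = set(call_map) ^ set(pheno_map)
    if unmatched:
        logger.warning(
            "%d sample(s) present in only one of genotypes/phenotypes", len(unmatched)
        )
    shared = set(call_map) & set(pheno_map)
    if not shared:
        raise ValueError("no samples with both a genotype call and phenotypes")

    groups: dict[int, list[PhenotypeRecord]] = {class_a: [], class_b: []}
    for sid in shared:
        call = call_map[sid]
        if call in groups:
            groups[call].append(pheno_map[sid])
    for cls, members in groups.items():
        if len(members) < 2:
            raise ValueError(
                f"copy-number class {cls} has {len(members)} phenotyped "
                "individuals; need >= 2"
            )

    summary_rows = []
    results = []
    for trait in traits:
        values = {
            cls: np.array([getattr(p, trait) for p in members], dtype=float)
            for cls, members in groups.items()
        }
        for cls in (class_a, class_b):
            summary = GroupSummary.from_values(values[cls])
            summary_rows.append(
                {
                    "trait": trait,
                    "copy_number": cls,
                    "n": summary.n,
                    "mean": summary.mean,
                    "se": summary.se,
                }
            )
        res = t_test_raw(values[class_a], values[class_b], method=method)
        results.append(
            AssociationResult(
                t_statistic=res.t_statistic,
                degrees_of_freedom=res.degrees_of_freedom,
                p_value=res.p_value,
                method=method,
                trait=trait,
                group_a=class_a,
                group_b=class_b,
            )
        )
    return AssociationReport(
        class_a=class_a,
        class_b=class_b,
        summaries=pd.DataFrame(summary_rows),
        results=tuple(results),
    )
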