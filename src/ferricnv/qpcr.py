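"""Comparative-Ct quantification of diploid gene copy number.

The quantification chain is::

    CtWell table -> aggregate_replicates -> estimate_copy_number -> call_copy_number

with amplification efficiencies calibrated separately from genomic-DNA
dilution series (``fit_standard_curve``).

The raw diploid estimate for a sample is

    copies = 2 * 2 ** (-(mean_ct_target - mean_ct_control))

assuming a single-copy (two alleles per diploid genome) control locus and
100 % amplification efficiency for both assays.  An optional efficiency
correction generalises the powers of two to powers of (1 + E):

    copies = control_diploid_copies * (1 + E_control) ** ct_control
                                    * (1 + E_target) ** (-ct_target)

which reduces to the base-2 form when both efficiencies are 1.0.

Integer genotypes are assigned with a fractional-part rule: writing the raw
estimate as n + f (n integer, 0 <= f < 1), f <= ``low_cutoff`` calls n and
f >= ``high_cutoff`` calls n + 1; estimates strictly inside the exclusion
window are no-called rather than forced to an integer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ASSAYS = ("target", "control")

#: replicate scatter (SD in cycles) above which a group is flagged for QC
DEFAULT_SD_FLAG_THRESHOLD = 0.5


class StandardCurveError(ValueError):
    """Raised when a dilution series cannot yield a valid standard curve."""


@dataclass(frozen=True)
class CtWell:
    """A single threshold-cycle observation for one well.

    Parameters
    ----------
    sample_id:
        Opaque individual identifier.
    assay:
        Either ``"target"`` (the variable-copy locus) or ``"control"``
        (the single-copy reference locus).
    replicate:
        1-based technical replicate index.
    ct:
        Threshold cycle, in PCR cycles.  Must lie in (0, 60).
    """

    sample_id: str
    assay: str
    replicate: int
    ct: float

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"assay must be one of {ASSAYS}, got {self.assay!r}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")
        if not math.isfinite(self.ct) or not (0.0 < self.ct < 60.0):
            raise ValueError(f"ct must be finite and in (0, 60), got {self.ct}")


@dataclass(frozen=True)
class DilutionPoint:
    """One well of a standard-curve dilution series.

    ``log10_quantity`` is the base-10 logarithm of the relative template
    amount (0 for the undiluted level, -1 for a 10-fold dilution, ...).
    """

    log10_quantity: float
    ct: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if not math.isfinite(self.log10_quantity):
            raise ValueError("log10_quantity must be finite")
        if not math.isfinite(self.ct) or self.ct <= 0:
            raise ValueError(f"ct must be finite and positive, got {self.ct}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Standard-curve fit: slope/intercept of Ct on log10 quantity.

    ``efficiency_percent`` is derived from the slope as
    ``(10 ** (-1 / slope) - 1) * 100``; a perfect doubling per cycle has
    slope -1/log10(2) = -3.3219 and efficiency 100 %.
    """

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency_percent(self) -> float:
        return (10.0 ** (-1.0 / self.slope) - 1.0) * 100.0

    @property
    def efficiency_fraction(self) -> float:
        """Per-cycle fractional gain E, i.e. amplification factor minus 1."""
        return self.efficiency_percent / 100.0


@dataclass(frozen=True)
class CallingPolicy:
    """Parameters governing conversion of raw estimates to integer calls.

    ``low_cutoff`` / ``high_cutoff`` bound the fractional-part no-call
    window (defaults 0.3 and 0.7).  ``control_diploid_copies`` is the copy
    number assumed for the control locus (2: one locus per haploid genome).
    With ``efficiency_correction`` enabled, ``eff_target`` / ``eff_control``
    (fractions, 1.0 = perfect doubling) replace the implicit base 2.

    ``allow_single_copy`` gates calls of exactly 1 copy; by default such
    estimates are no-called since a hemizygous deletion is outside the
    calling model.
    """

    low_cutoff: float = 0.3
    high_cutoff: float = 0.7
    control_diploid_copies: int = 2
    efficiency_correction: bool = False
    eff_target: float = 1.0
    eff_control: float = 1.0
    allow_single_copy: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.low_cutoff < self.high_cutoff <= 1.0):
            raise ValueError(
                "cutoffs must satisfy 0 <= low_cutoff < high_cutoff <= 1, got "
                f"({self.low_cutoff}, {self.high_cutoff})"
            )
        if self.control_diploid_copies < 1:
            raise ValueError("control_diploid_copies must be >= 1")
        for name in ("eff_target", "eff_control"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.1):
                raise ValueError(f"{name} must lie in [0, 1.1], got {value}")


@dataclass(frozen=True)
class CopyNumberResult:
    """Per-sample quantification outcome: raw estimate plus call or no-call."""

    sample_id: str
    mean_ct_target: float
    mean_ct_control: float
    raw_estimate: float
    call: Optional[int] = None
    no_call_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.raw_estimate <= 0:
            raise ValueError("raw_estimate must be positive")
        if self.call is not None and self.call < 1:
            raise ValueError("call must be >= 1 when present")


def aggregate_replicates(
    wells: Iterable[CtWell],
    sd_flag_threshold: float = DEFAULT_SD_FLAG_THRESHOLD,
) -> pd.DataFrame:
    """Collapse replicate wells to per-(sample, assay) mean and SD.

    Returns a frame with columns ``sample_id, assay, mean_ct, sd_ct, n,
    high_sd``.  SD is the sample standard deviation (ddof=1; NaN for a
    single replicate).  Groups whose SD exceeds ``sd_flag_threshold`` are
    flagged, never dropped.

    Raises ``ValueError`` on empty input or duplicated
    (sample, assay, replicate) keys.
    """
    wells = list(wells)
    if not wells:
        raise ValueError("no Ct wells provided")
    frame = pd.DataFrame(
        {
            "sample_id": [w.sample_id for w in wells],
            "assay": [w.assay for w in wells],
            "replicate": [w.replicate for w in wells],
            "ct": [w.ct for w in wells],
        }
    )
    dup = frame.duplicated(subset=["sample_id", "assay", "replicate"])
    if dup.any():
        offender = frame.loc[dup.idxmax()]
        raise ValueError(
            "duplicate well key (sample_id=%r, assay=%r, replicate=%r)"
            % (offender.sample_id, offender.assay, offender.replicate)
        )
    out = (
        frame.groupby(["sample_id", "assay"], sort=True)["ct"]
        .agg(mean_ct="mean", sd_ct="std", n="count")
        .reset_index()
    )
    out["high_sd"] = out["sd_ct"].gt(sd_flag_threshold).fillna(False)
    for row in out.loc[out["high_sd"]].itertuples():
        logger.warning(
            "high replicate scatter for sample %s assay %s: sd=%.3f cycles",
            row.sample_id,
            row.assay,
            row.sd_ct,
        )
    return out


def fit_standard_curve(series: Iterable[DilutionPoint]) -> EfficiencyEstimate:
    """Ordinary least-squares fit of Ct on log10 template quantity.

    Requires at least three distinct dilution levels and a negative slope
    (Ct must rise as template is diluted); otherwise raises
    ``StandardCurveError``.
    """
    points = list(series)
    x = np.array([p.log10_quantity for p in points], dtype=float)
    y = np.array([p.ct for p in points], dtype=float)
    if len(np.unique(x)) < 3:
        raise StandardCurveError(
            f"need >= 3 distinct dilution levels, got {len(np.unique(x))}"
        )
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise StandardCurveError(
            f"invalid standard curve: slope {fit.slope:.4f} is not negative"
        )
    return EfficiencyEstimate(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
    )


def estimate_copy_number(
    mean_ct_target: float,
    mean_ct_control: float,
    policy: CallingPolicy | None = None,
) -> float:
    """Raw (real-valued) diploid copy estimate from mean Ct values."""
    policy = policy or CallingPolicy()
    if not (math.isfinite(mean_ct_target) and math.isfinite(mean_ct_control)):
        raise ValueError("Ct values must be finite")
    if mean_ct_target <= 0 or mean_ct_control <= 0:
        raise ValueError("Ct values must be positive")
    if policy.efficiency_correction:
        return (
            policy.control_diploid_copies
            * (1.0 + policy.eff_control) ** mean_ct_control
            * (1.0 + policy.eff_target) ** (-mean_ct_target)
        )
    return policy.control_diploid_copies * 2.0 ** (-(mean_ct_target - mean_ct_control))


def call_copy_number(
    raw_estimate: float,
    policy: CallingPolicy | None = None,
) -> tuple[Optional[int], Optional[str]]:
    """Assign an integer genotype or a no-call reason to a raw estimate.

    Returns ``(call, None)`` or ``(None, reason)``.
    """
    policy = policy or CallingPolicy()
    if raw_estimate <= 0 or not math.isfinite(raw_estimate):
        raise ValueError(f"raw_estimate must be finite and positive, got {raw_estimate}")
    if raw_estimate < policy.high_cutoff:
        return None, "below one copy"
    n = math.floor(raw_estimate)
    frac = raw_estimate - n
    if frac <= policy.low_cutoff:
        call = n
    elif frac >= policy.high_cutoff:
        call = n + 1
    else:
        return None, "ambiguous fractional estimate"
    if call == 1 and not policy.allow_single_copy:
        return None, "below one copy"
    return call, None


def genotype_population(
    wells: Iterable[CtWell],
    policy: CallingPolicy | None = None,
    sd_flag_threshold: float = DEFAULT_SD_FLAG_THRESHOLD,
) -> list[CopyNumberResult]:
    """Full quantification of a well table into per-sample genotype calls.

    Samples missing either assay are skipped with a logged warning.  The
    output order follows sorted sample id; an empty input yields an empty
    list.
    """
    policy = policy or CallingPolicy()
    wells = list(wells)
    if not wells:
        return []
    agg = aggregate_replicates(wells, sd_flag_threshold=sd_flag_threshold)
    means = agg.pivot(index="sample_id", columns="assay", values="mean_ct")
    results: list[CopyNumberResult] = []
    for sample_id, row in means.iterrows():
        ct_target = row.get("target", np.nan)
        ct_control = row.get("control", np.nan)
        if pd.isna(ct_target) or pd.isna(ct_control):
            missing = "target" if pd.isna(ct_target) else "control"
            logger.warning(
                "sample %s is missing the %s assay; excluded from genotyping",
                sample_id,
                missing,
            )
            continue
        raw = estimate_copy_number(float(ct_target), float(ct_control), policy)
        call, reason = call_copy_number(raw, policy)
        results.append(
            CopyNumberResult(
                sample_id=str(sample_id),
                mean_ct_target=float(ct_target),
                mean_ct_control=float(ct_control),
                raw_estimate=raw,
                call=call,
                no_call_reason=reason,
            )
        )
    return results


def per_replicate_estimates(
    wells: Iterable[CtWell],
    policy: CallingPolicy | None = None,
) -> pd.DataFrame:
    """QC diagnostic: copy estimates per replicate pairing instead of means.

    Pairs target and control wells by replicate index within each sample and
    applies the copy-number equation to each pair.  Intended to expose
    replicate-level dispersion, not for genotype calling.
    """
    policy = policy or CallingPolicy()
    frame = pd.DataFrame(
        {
            "sample_id": [w.sample_id for w in wells],
            "assay": [w.assay for w in wells],
            "replicate": [w.replicate for w in wells],
            "ct": [w.ct for w in wells],
        }
    )
    wide = frame.pivot(index=["sample_id", "replicate"], columns="assay", values="ct")
    wide = wide.dropna(subset=[a for a in ASSAYS if a in wide.columns])
    estimates = [
        estimate_copy_number(row.target, row.control, policy)
        for row in wide.itertuples()
    ]
    out = wide.reset_index()[["sample_id", "replicate"]]
    out["raw_estimate"] = estimates
    return out


def results_to_frame(results: Sequence[CopyNumberResult]) -> pd.DataFrame:
    """Tabulate quantification results (one row per sample)."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "mean_ct_target": [r.mean_ct_target for r in results],
            "mean_ct_control": [r.mean_ct_control for r in results],
            "raw_estimate": [r.raw_estimate for r in results],
            "call": pd.array([r.call for r in results], dtype="Int64"),
            "no_call_reason": [r.no_call_reason for r in results],
        }
    )
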