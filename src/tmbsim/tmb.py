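"""TMB arithmetic: FOCR-style filtering, psTMB/wesTMB, detection-error model,
RMSLE and discrete accuracy.

The central quantities
----------------------

psTMB
    apparent mutation count within a panel divided by the panel's exonic
    size in Mb.  wesTMB is the same quantity with the whole exome as the
    panel.

rgbrp
    the *reciprocal gap between recall and precision*,
    ``1/precision - 1/recall``.  Under the detection-error model the count
    a panel reports is ``true_count * (1 + rgbrp)``: false positives add
    ``TP/precision - TP`` calls and false negatives remove
    ``TP/recall - TP`` true ones, and both scale with the true count.
    A perfectly balanced caller (recall == precision) has rgbrp 0 however
    poor the absolute values are.

RMSLE
    ``sqrt(mean((ln(e+1) - ln(r+1))^2))`` — the continuous-accuracy metric
    of choice for right-skewed TMB distributions, since it damps the
    influence of hypermutators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import (
    FOCR_CLASSES,
    TMB_HIGH,
    TMB_NON_HIGH,
    VARIANT_CLASSES,
    MutationRecord,
    ValidationError,
)

__all__ = [
    "ComputationRule",
    "DetectionProfile",
    "apply_rule",
    "filter_frame",
    "ps_tmb",
    "rgbrp",
    "apparent_count",
    "sample_apparent_count",
    "rmsle",
    "classify_tmb",
    "discrete_accuracy",
]


#: Variant classes whose inclusion is a free parameter of the computation
#: rule grid, with the rule flag each maps to.
OPTIONAL_CLASS_FLAGS = {
    "synonymous": "Silent",
    "nonsense": "Nonsense_Mutation",
    "nonstop": "Nonstop_Mutation",
    "splice_site": "Splice_Site",
    "tss": "Translation_Start_Site",
}

#: Classes included by every rule (the FOCR indel + missense core, minus the
#: optional nonsense flag which the grid toggles).
ALWAYS_INCLUDED_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
    }
)


@dataclass(frozen=True)
class ComputationRule:
    """A psTMB computation rule: which calls count, and at what thresholds.

    Defaults reproduce the FOCR harmonization recommendation used for the
    reference wesTMB: the six coding classes, VAF >= 5%, t_depth > 25 and
    t_alt_count > 3 (both strict).
    """

    included_classes: frozenset[str] = frozenset(FOCR_CLASSES)
    filter_hotspots: bool = False
    vaf_cutoff: float = 0.05
    min_depth: int = 25
    min_alt_count: int = 3

    def __post_init__(self) -> None:
        if not (0.0 <= self.vaf_cutoff <= 0.5):
            raise ValidationError(f"vaf_cutoff {self.vaf_cutoff} outside [0, 0.5]")
        unknown = set(self.included_classes) - set(VARIANT_CLASSES)
        if unknown:
            raise ValidationError(f"unknown variant classes in rule: {sorted(unknown)}")
        object.__setattr__(self, "included_classes", frozenset(self.included_classes))

    @classmethod
    def from_flags(
        cls,
        *,
        synonymous: bool = False,
        nonsense: bool = True,
        nonstop: bool = False,
        splice_site: bool = False,
        tss: bool = False,
        hotspot_filter: bool = False,
        vaf_cutoff: float = 0.05,
        min_depth: int = 25,
        min_alt_count: int = 3,
    ) -> "ComputationRule":
        """Build a rule from the grid's boolean inclusion flags."""
        included = set(ALWAYS_INCLUDED_CLASSES)
        flags = {
            "synonymous": synonymous,
            "nonsense": nonsense,
            "nonstop": nonstop,
            "splice_site": splice_site,
            "tss": tss,
        }
        for flag, klass in OPTIONAL_CLASS_FLAGS.items():
            if flags[flag]:
                included.add(klass)
        return cls(
            included_classes=frozenset(included),
            filter_hotspots=hotspot_filter,
            vaf_cutoff=vaf_cutoff,
            min_depth=min_depth,
            min_alt_count=min_alt_count,
        )

    def flags(self) -> dict[str, bool]:
        """The rule's boolean state, keyed by grid flag name."""
        out = {
            flag: klass in self.included_classes
            for flag, klass in OPTIONAL_CLASS_FLAGS.items()
        }
        out["hotspot_filter"] = self.filter_hotspots
        return out


@dataclass(frozen=True)
class DetectionProfile:
    """Recall/precision of somatic mutation detection."""

    recall: float
    precision: float

    def __post_init__(self) -> None:
        if not (0.0 < self.recall <= 1.0):
            raise ValidationError(f"recall {self.recall} outside (0, 1]")
        if not (0.0 < self.precision <= 1.0):
            raise ValidationError(f"precision {self.precision} outside (0, 1]")


def apply_rule(
    mutations: Sequence[MutationRecord], rule: ComputationRule
) -> list[MutationRecord]:
    """Filter calls by a computation rule, preserving input order.

    A record survives iff its class is included, vaf >= cutoff (inclusive),
    t_depth > min_depth, t_alt_count > min_alt_count, and it is not a
    hotspot when hotspot filtering is on.  Idempotent by construction.
    """
    return [
        m
        for m in mutations
        if m.variant_classification in rule.included_classes
        and m.vaf >= rule.vaf_cutoff
        and m.t_depth > rule.min_depth
        and m.t_alt_count > rule.min_alt_count
        and not (rule.filter_hotspots and m.is_hotspot)
    ]


def filter_frame(df: pd.DataFrame, rule: ComputationRule) -> pd.DataFrame:
    """Vectorised :func:`apply_rule` for a mutation DataFrame."""
    mask = (
        df["variant_classification"].isin(rule.included_classes)
        & (df["vaf"] >= rule.vaf_cutoff)
        & (df["t_depth"] > rule.min_depth)
        & (df["t_alt_count"] > rule.min_alt_count)
    )
    if rule.filter_hotspots:
        mask &= ~df["is_hotspot"].astype(bool)
    return df[mask]


def ps_tmb(mutation_count: float, panel_size_mb: float) -> float:
    """Panel-sequencing TMB: apparent mutation count per Mb of target.

    The count may be fractional (expected-count semantics of the
    detection-error model).  wesTMB is this with the exome as the panel.
    """
    if panel_size_mb <= 0:
        raise ValidationError(f"panel_size_mb must be > 0, got {panel_size_mb}")
    if mutation_count < 0:
        raise ValidationError("mutation count must be >= 0")
    return mutation_count / panel_size_mb


def rgbrp(profile: DetectionProfile) -> float:
    """Reciprocal gap between recall and precision, 1/precision - 1/recall."""
    return 1.0 / profile.precision - 1.0 / profile.recall


def apparent_count(true_count: float, profile: DetectionProfile) -> float:
    """Expected reported count under the detection-error model.

    ``true_count * (1 + 1/precision - 1/recall)``, floored at zero.  The
    result is fractional: it is the expectation of the stochastic process in
    :func:`sample_apparent_count`.
    """
    if true_count < 0:
        raise ValidationError("true_count must be >= 0")
    return max(0.0, true_count * (1.0 + rgbrp(profile)))


def sample_apparent_count(
    true_count: int,
    profile: DetectionProfile,
    rng: np.random.Generator,
) -> int:
    """One stochastic draw of the reported count.

    True calls are retained independently with probability ``recall``
    (removing FNs), then false positives are injected with a Poisson count
    whose mean tops the expectation up to ``true_count * (1 + rgbrp)``, so
    the draw is unbiased for :func:`apparent_count`.
    """
    if true_count < 0:
        raise ValidationError("true_count must be >= 0")
    if true_count == 0:
        return 0
    detected = rng.binomial(true_count, profile.recall)
    fp_mean = max(0.0, apparent_count(true_count, profile) - true_count * profile.recall)
    return int(detected + rng.poisson(fp_mean))


def rmsle(etmb: Iterable[float], rtmb: Iterable[float]) -> float:
    """Root mean squared logarithmic error between TMB vectors.

    Natural log on (value + 1); both vectors must be non-negative and of
    equal nonzero length.
    """
    e = np.asarray(list(etmb), dtype=float)
    r = np.asarray(list(rtmb), dtype=float)
    if e.shape != r.shape or e.ndim != 1 or e.size == 0:
        raise ValidationError("etmb and rtmb must be equal-length nonempty vectors")
    if (e < 0).any() or (r < 0).any():
        raise ValidationError("TMB values must be >= 0")
    d = np.log1p(e) - np.log1p(r)
    return float(np.sqrt(np.mean(d * d)))


def classify_tmb(tmb: float, cutoff: float = 10.0) -> str:
    """Binary TMB class: TMB-H iff tmb >= cutoff (tie goes high)."""
    if cutoff < 0:
        raise ValidationError("cutoff must be >= 0")
    if tmb < 0:
        raise ValidationError("tmb must be >= 0")
    return TMB_HIGH if tmb >= cutoff else TMB_NON_HIGH


_NON_HIGH_ALIASES = {"TMB-L", "TMB-M", TMB_NON_HIGH}


def _collapse(labels: Iterable[str]) -> np.ndarray:
    out = []
    for lab in labels:
        if lab == TMB_HIGH:
            out.append(True)
        elif lab in _NON_HIGH_ALIASES:
            out.append(False)
        else:
            raise ValidationError(f"unknown TMB class label {lab!r}")
    return np.asarray(out, dtype=bool)


def discrete_accuracy(predicted: Iterable[str], reference: Iterable[str]) -> float:
    """(TP + TN) / (TP + TN + FP + FN) after collapsing ternary labels.

    TMB-M and TMB-L count as non-TMB-H, so a ternary submission is scored
    on the binary TMB-H / non-TMB-H distinction only.
    """
    p = _collapse(predicted)
    r = _collapse(reference)
    if p.size != r.size:
        raise ValidationError("label vectors must have equal length")
    if p.size == 0:
        raise ValidationError("label vectors must be nonempty")
    return float(np.mean(p == r))
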