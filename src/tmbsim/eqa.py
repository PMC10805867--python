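"""External quality assessment: consensus truth sets from replicate WES
call sets, dilution propagation, and scoring of laboratory submissions.

The truth set keeps variants supported by at least ``min_support`` of the
available whole-exome call sets (exact key match after normalization) and
carries the mean VAF over supporting sets; a variant is *credible* when its
(expected) VAF is at least 9%, the empirically validated floor below which
replicate WES assays disagree.  Diluted samples inherit the truth set with
VAFs scaled by the dilution fraction and the credible flag recomputed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panels import PanelDesign, _membership_mask
from .records import TMB_HIGH, ValidationError
from .tmb import classify_tmb, discrete_accuracy, rmsle

__all__ = [
    "VariantKey",
    "CallSet",
    "TruthSet",
    "SubmittedResult",
    "normalize_variant",
    "build_truth_set",
    "propagate_truth",
    "score_variants",
    "score_tmb",
    "read_callset_vcf",
    "CREDIBLE_VAF_FLOOR",
]

#: Minimum (expected) VAF for a consensus variant to be trusted.
CREDIBLE_VAF_FLOOR = 0.09

VariantKey = tuple[str, int, str, str]


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Canonical variant key: trim shared ref/alt suffix, then prefix.

    Makes pads written differently by different callers (e.g. ``ACG>ACT``
    vs ``G>T``) compare equal.  Full left-alignment against the reference
    genome is out of scope — no FASTA is required here.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (str(chrom), int(pos), ref, alt)


@dataclass(frozen=True)
class CallSet:
    """One assay's somatic calls for one sample."""

    assay_id: str
    sample_id: str
    variants: tuple[tuple[str, int, str, str, float], ...]  # chrom,pos,ref,alt,vaf

    def keyed(self) -> dict[VariantKey, float]:
        out: dict[VariantKey, float] = {}
        for chrom, pos, ref, alt, vaf in self.variants:
            if not (0.0 < vaf <= 1.0):
                raise ValidationError(f"{self.assay_id}: vaf {vaf} outside (0, 1]")
            key = normalize_variant(chrom, pos, ref, alt)
            if key in out:
                raise ValidationError(f"{self.assay_id}: duplicate variant {key}")
            out[key] = vaf
        return out


@dataclass(frozen=True)
class TruthSet:
    """Consensus variants for one sample plus its reference wesTMB."""

    sample_id: str
    variants: pd.DataFrame  # chromosome, position, ref, alt, mean_vaf, support, credible
    ref_wes_tmb: float

    def keys(self, credible_only: bool = False) -> set[VariantKey]:
        df = self.variants[self.variants["credible"]] if credible_only else self.variants
        return {
            (r.chromosome, int(r.position), r.ref, r.alt)
            for r in df.itertuples(index=False)
        }


@dataclass(frozen=True)
class SubmittedResult:
    """One laboratory's submission for one sample."""

    lab_id: str
    method_id: str
    sample_id: str
    variants: tuple[tuple[str, int, str, str], ...] = ()
    ps_tmb: float | None = None
    e_tmb: float | None = None
    tmb_class: str | None = None  # TMB-H / TMB-M / TMB-L


def build_truth_set(
    callsets: Sequence[CallSet],
    min_support: int = 3,
    ref_wes_tmb: float = float("nan"),
    reference_assays: Iterable[str] | None = None,
    wes_tmb_by_assay: Mapping[str, float] | None = None,
) -> TruthSet:
    """Consensus truth set for one sample from replicate WES call sets.

    A variant enters the truth set when at least ``min_support`` call sets
    report it (exact normalized key match); its ``mean_vaf`` averages the
    supporting sets' VAFs and the ``credible`` flag applies the 9% floor.
    The reference wesTMB is the mean over ``wes_tmb_by_assay`` restricted to
    ``reference_assays`` (so a flagged-unreliable assay can be excluded),
    unless given directly via ``ref_wes_tmb``.
    """
    if not callsets:
        raise ValidationError("need at least one call set")
    sample_ids = {cs.sample_id for cs in callsets}
    if len(sample_ids) != 1:
        raise ValidationError(f"call sets span multiple samples: {sorted(sample_ids)}")
    if min_support > len(callsets):
        raise ValidationError(
            f"min_support {min_support} exceeds number of call sets {len(callsets)}"
        )
    support: dict[VariantKey, list[float]] = {}
    for cs in callsets:
        for key, vaf in cs.keyed().items():
            support.setdefault(key, []).append(vaf)
    rows = [
        {
            "chromosome": k[0],
            "position": k[1],
            "ref": k[2],
            "alt": k[3],
            "mean_vaf": float(np.mean(vafs)),
            "support": len(vafs),
        }
        for k, vafs in sorted(support.items())
        if len(vafs) >= min_support
    ]
    df = pd.DataFrame(
        rows, columns=["chromosome", "position", "ref", "alt", "mean_vaf", "support"]
    )
    df["credible"] = df["mean_vaf"] >= CREDIBLE_VAF_FLOOR if len(df) else pd.Series(dtype=bool)
    if math.isnan(ref_wes_tmb) and wes_tmb_by_assay:
        use = set(reference_assays) if reference_assays is not None else set(wes_tmb_by_assay)
        vals = [v for a, v in wes_tmb_by_assay.items() if a in use]
        if not vals:
            raise ValidationError("no reference assays left for wesTMB averaging")
        ref_wes_tmb = float(np.mean(vals))
    return TruthSet(sample_id=next(iter(sample_ids)), variants=df, ref_wes_tmb=ref_wes_tmb)


def propagate_truth(truth: TruthSet, dilution_fraction: float, sample_id: str | None = None) -> TruthSet:
    """Truth set for a diluted sample: VAFs scaled, credibility recomputed.

    ``dilution_fraction`` is simulated purity / original purity.  Variants
    whose expected VAF falls below the 9% floor are retained but flagged
    not credible rather than dropped.
    """
    if not (0.0 < dilution_fraction <= 1.0):
        raise ValidationError(f"dilution_fraction {dilution_fraction} outside (0, 1]")
    df = truth.variants.copy()
    df["mean_vaf"] = df["mean_vaf"] * dilution_fraction
    df["credible"] = df["mean_vaf"] >= CREDIBLE_VAF_FLOOR
    return TruthSet(
        sample_id=sample_id or truth.sample_id,
        variants=df,
        ref_wes_tmb=truth.ref_wes_tmb,
    )


def _restrict_keys(keys: set[VariantKey], panel: PanelDesign | None) -> set[VariantKey]:
    if panel is None or not keys:
        return keys
    df = pd.DataFrame(list(keys), columns=["chromosome", "position", "ref", "alt"])
    mask = _membership_mask(df, panel.intervals)
    return {k for k, m in zip(keys, mask) if m}


def score_variants(
    submitted: Iterable[tuple[str, int, str, str]],
    truth: TruthSet,
    restrict_to_panel: PanelDesign | None = None,
    credible_only: bool = True,
) -> dict[str, float | None]:
    """Recall / precision / F1 / observed rgbrp of a submitted call list.

    Truth is restricted to the submitting panel's intervals first (a lab is
    only accountable for its targets) and, by default, to credible
    variants.  Undefined ratios (zero denominators) are reported as None
    rather than 0.
    """
    truth_keys = _restrict_keys(truth.keys(credible_only=credible_only), restrict_to_panel)
    sub_keys = {normalize_variant(*v) for v in submitted}
    sub_keys = _restrict_keys(sub_keys, restrict_to_panel)
    tp = len(sub_keys & truth_keys)
    fp = len(sub_keys - truth_keys)
    fn = len(truth_keys - sub_keys)
    recall = tp / (tp + fn) if (tp + fn) else None
    precision = tp / (tp + fp) if (tp + fp) else None
    if recall is None or precision is None or (recall + precision) == 0:
        f1 = None
    else:
        f1 = 2 * recall * precision / (recall + precision)
    if recall and precision:
        rgbrp_observed: float | None = 1.0 / precision - 1.0 / recall
    else:
        rgbrp_observed = None
        warnings.warn("zero recall or precision: observed rgbrp undefined")
    return {
        "recall": recall,
        "precision": precision,
        "f1": f1,
        "rgbrp_observed": rgbrp_observed,
        "tp": tp,
        "fp": fp,
        "fn": fn,
    }


def score_tmb(
    submissions: Sequence[SubmittedResult],
    truths: Mapping[str, TruthSet],
    sample_purity: Mapping[str, float] | None = None,
    cutoff: float = 10.0,
    min_purity_for_continuous: float = 0.40,
    negative_control_ids: Iterable[str] = (),
) -> dict[str, float | int | None]:
    """Continuous (RMSLE) and discrete TMB accuracy of one lab's submissions.

    RMSLE is computed only on samples with simulated purity at or above
    ``min_purity_for_continuous`` (dilution makes continuous values
    unreliable below it); discrete accuracy uses every scored sample after
    collapsing TMB-M/TMB-L to non-TMB-H.  False-positive TMB-H calls on
    negative-control samples are counted separately, not folded into
    accuracy.
    """
    neg = set(negative_control_ids)
    e_cont, r_cont = [], []
    pred_cls, ref_cls = [], []
    negative_control_fp = 0
    for sub in submissions:
        if sub.sample_id in neg:
            if sub.tmb_class == TMB_HIGH or (
                sub.e_tmb is not None and sub.e_tmb >= cutoff
            ):
                negative_control_fp += 1
            continue
        truth = truths.get(sub.sample_id)
        if truth is None:
            warnings.warn(f"no truth set for sample {sub.sample_id!r}; skipped")
            continue
        purity = sample_purity.get(sub.sample_id, 1.0) if sample_purity else 1.0
        if sub.e_tmb is not None and purity >= min_purity_for_continuous:
            e_cont.append(max(0.0, sub.e_tmb))
            r_cont.append(truth.ref_wes_tmb)
        label = sub.tmb_class
        if label is None and sub.e_tmb is not None:
            label = classify_tmb(max(0.0, sub.e_tmb), cutoff)
        if label is not None:
            pred_cls.append(label)
            ref_cls.append(classify_tmb(truth.ref_wes_tmb, cutoff))
    if not pred_cls and not e_cont:
        raise ValidationError("no eligible samples to score")
    return {
        "rmsle": rmsle(e_cont, r_cont) if e_cont else None,
        "n_continuous": len(e_cont),
        "discrete_accuracy": discrete_accuracy(pred_cls, ref_cls) if pred_cls else None,
        "n_discrete": len(pred_cls),
        "negative_control_fp": negative_control_fp,
    }


def read_callset_vcf(
    path, assay_id: str, sample_id: str, vaf_field: str = "AF"
) -> CallSet:
    """Minimal VCF reader for a call set: CHROM/POS/REF/ALT plus a VAF.

    The VAF is looked up first in FORMAT (first sample), then INFO, under
    ``vaf_field``.  Multi-allelic records contribute one variant per ALT.
    """
    from cyvcf2 import VCF

    variants = []
    for rec in VCF(str(path)):
        vaf = None
        try:
            arr = rec.format(vaf_field)
            if arr is not None:
                vaf = float(np.ravel(arr)[0])
        except KeyError:
            pass
        if vaf is None:
            info_val = rec.INFO.get(vaf_field)
            if info_val is not None:
                vaf = float(info_val[0] if isinstance(info_val, tuple) else info_val)
        if vaf is None:
            raise ValidationError(f"{path}: no {vaf_field!r} in FORMAT or INFO at {rec.CHROM}:{rec.POS}")
        for alt in rec.ALT:
            # VCF POS is 1-based; keys are 0-based like the rest of the package
            variants.append((rec.CHROM, rec.POS - 1, rec.REF, alt, vaf))
    return CallSet(assay_id=assay_id, sample_id=sample_id, variants=tuple(variants))
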