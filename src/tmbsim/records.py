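"""Core record types shared across the pipeline.

A somatic call is a :class:`MutationRecord`; a tumor sample with its
reference whole-exome TMB is a :class:`SampleProfile`.  Cohorts are moved
around as pandas DataFrames (one row per record) because the experiment
layer is vectorised; the dataclasses define the row schema and provide the
round-trip converters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import pandas as pd

#: The MAF Variant_Classification vocabulary handled by the pipeline.
VARIANT_CLASSES = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "Silent",
    "Splice_Site",
    "Translation_Start_Site",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
)

#: The six coding classes counted by the FOCR harmonization filter.
FOCR_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "In_Frame_Del",
        "Nonsense_Mutation",
        "In_Frame_Ins",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
    }
)

TMB_HIGH = "TMB-H"
TMB_NON_HIGH = "non-TMB-H"


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call.

    Positions are 0-based half-open internally; the MAF I/O layer converts
    to/from the 1-based inclusive MAF convention.  ``vaf`` is the observed
    variant allele frequency ``t_alt_count / t_depth``.
    """

    sample_id: str
    gene_symbol: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    variant_classification: str
    vaf: float
    t_depth: int
    t_alt_count: int
    is_hotspot: bool = False

    def __post_init__(self) -> None:
        if self.variant_classification not in VARIANT_CLASSES:
            raise ValidationError(
                f"unknown variant_classification {self.variant_classification!r}"
            )
        if self.t_alt_count > self.t_depth:
            raise ValidationError(
                f"t_alt_count {self.t_alt_count} exceeds t_depth {self.t_depth}"
            )
        if not (0.0 < self.vaf <= 1.0):
            raise ValidationError(f"vaf {self.vaf} outside (0, 1]")
        if self.t_depth > 0 and abs(self.vaf - self.t_alt_count / self.t_depth) > 0.5 / self.t_depth:
            raise ValidationError("vaf inconsistent with t_alt_count/t_depth")


@dataclass(frozen=True)
class SampleProfile:
    """A tumor sample: purity, reference whole-exome TMB and its class."""

    sample_id: str
    tumor_purity: float
    ref_wes_tmb: float
    tmb_class: str

    def __post_init__(self) -> None:
        if self.ref_wes_tmb < 0:
            raise ValidationError("ref_wes_tmb must be >= 0")
        if self.tmb_class not in (TMB_HIGH, TMB_NON_HIGH):
            raise ValidationError(f"unknown tmb_class {self.tmb_class!r}")


MUTATION_COLUMNS = [f.name for f in fields(MutationRecord)]
SAMPLE_COLUMNS = [f.name for f in fields(SampleProfile)]


def mutations_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    """Tabulate mutation records, one row per call (column order fixed)."""
    rows = [
        tuple(getattr(r, name) for name in MUTATION_COLUMNS) for r in records
    ]
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def frame_to_mutations(df: pd.DataFrame) -> list[MutationRecord]:
    return [
        MutationRecord(
            sample_id=str(row.sample_id),
            gene_symbol=str(row.gene_symbol),
            chromosome=str(row.chromosome),
            position=int(row.position),
            ref_allele=str(row.ref_allele),
            alt_allele=str(row.alt_allele),
            variant_classification=str(row.variant_classification),
            vaf=float(row.vaf),
            t_depth=int(row.t_depth),
            t_alt_count=int(row.t_alt_count),
            is_hotspot=bool(row.is_hotspot),
        )
        for row in df.itertuples(index=False)
    ]


def samples_to_frame(samples: Iterable[SampleProfile]) -> pd.DataFrame:
    rows = [tuple(getattr(s, name) for name in SAMPLE_COLUMNS) for s in samples]
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def frame_to_samples(df: pd.DataFrame) -> list[SampleProfile]:
    return [
        SampleProfile(
            sample_id=str(row.sample_id),
            tumor_purity=float(row.tumor_purity),
            ref_wes_tmb=float(row.ref_wes_tmb),
            tmb_class=str(row.tmb_class),
        )
        for row in df.itertuples(index=False)
    ]
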