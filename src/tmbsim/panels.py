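"""Panel geometry: target intervals, mutation-panel intersection and the
nested synthetic panel families used for size–accuracy curves.

Intervals are 0-based half-open throughout, stored per chromosome as sorted,
merged ``(starts, ends)`` numpy arrays; membership queries are a single
``searchsorted``.  BED input follows the standard 0-based half-open
convention, with the gene symbol taken from column 4 when present.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PanelDesign",
    "PanelFamily",
    "merge_intervals",
    "read_panel_bed",
    "write_panel_bed",
    "mutations_in_panel",
    "build_panel_family",
    "strip_gene_list",
    "panel_from_genes",
]

Intervals = dict[str, tuple[np.ndarray, np.ndarray]]


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> Intervals:
    """Union of half-open intervals, per chromosome, sorted and merged."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if end <= start:
            raise ValidationError(f"empty/inverted interval [{start}, {end}) on {chrom}")
        by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
    merged: Intervals = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts: list[int] = []
        ends: list[int] = []
        for s, e in ivs:
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64))
    return merged


def _total_length(intervals: Intervals) -> int:
    return int(sum((e - s).sum() for s, e in intervals.values()))


@dataclass(frozen=True)
class PanelDesign:
    """A named target design: merged intervals, member genes, exonic size."""

    name: str
    intervals: Intervals
    genes: frozenset[str]
    exonic_size_mb: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"panel {self.name!r} has no genes")
        if not self.intervals:
            raise ValidationError(f"panel {self.name!r} has no intervals")
        object.__setattr__(self, "genes", frozenset(self.genes))
        object.__setattr__(self, "exonic_size_mb", _total_length(self.intervals) / 1e6)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class PanelFamily:
    """An ordered, nested family of panels of strictly increasing gene count."""

    panels: tuple[PanelDesign, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.panels, self.panels[1:]):
            if not prev.genes < nxt.genes:
                raise ValidationError(
                    f"family not nested: {prev.name!r} is not a strict subset of {nxt.name!r}"
                )
            if nxt.exonic_size_mb <= prev.exonic_size_mb:
                raise ValidationError("family sizes must strictly increase")

    def __len__(self) -> int:
        return len(self.panels)

    def __iter__(self):
        return iter(self.panels)


def read_panel_bed(
    path,
    gene_map: Mapping[tuple[str, int], str] | None = None,
    name: str | None = None,
) -> PanelDesign:
    """Load a panel from a BED file (0-based half-open, >= 3 columns).

    Gene symbols come from BED column 4 when present, otherwise from
    ``gene_map`` keyed by (chromosome, start).  Track/browser lines and
    columns beyond 4 are ignored.  Malformed lines raise with their line
    number.
    """
    rows: list[tuple[str, int, int]] = []
    genes: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
            if end <= start:
                raise ValidationError(f"{path}: line {lineno}: end <= start")
            rows.append((chrom, start, end))
            if len(parts) >= 4 and parts[3] and parts[3] != ".":
                genes.add(parts[3])
            elif gene_map is not None and (chrom, start) in gene_map:
                genes.add(gene_map[(chrom, start)])
    if not rows:
        raise ValidationError(f"{path}: empty BED file")
    import os

    if not genes and os.path.exists(f"{path}.genes"):
        # sidecar written by write_panel_bed (merged intervals lose gene labels)
        with open(f"{path}.genes") as fh:
            genes = {line.strip() for line in fh if line.strip()}
    if not genes:
        raise ValidationError(f"{path}: no gene symbols in column 4 and no gene_map hit")

    return PanelDesign(
        name=name or os.path.splitext(os.path.basename(str(path)))[0],
        intervals=merge_intervals(rows),
        genes=frozenset(genes),
    )


def write_panel_bed(panel: PanelDesign, path) -> None:
    """Write merged intervals as BED plus a ``<path>.genes`` sidecar.

    Merging discards per-exon gene labels, so the member gene symbols go to
    a one-symbol-per-line sidecar that :func:`read_panel_bed` picks up.
    """
    with open(path, "w") as fh:
        for chrom in sorted(panel.intervals):
            starts, ends = panel.intervals[chrom]
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t.\n")
    with open(f"{path}.genes", "w") as fh:
        for sym in sorted(panel.genes):
            fh.write(f"{sym}\n")


def _membership_mask(df: pd.DataFrame, intervals: Intervals) -> np.ndarray:
    mask = np.zeros(len(df), dtype=bool)
    chroms = df["chromosome"].to_numpy()
    pos = df["position"].to_numpy()
    seen = set(np.unique(chroms))
    if not (seen & set(intervals)):
        warnings.warn(
            "no mutation chromosome matches any panel chromosome; "
            "check naming scheme (e.g. 'chr1' vs '1')",
            stacklevel=3,
        )
    for chrom, (starts, ends) in intervals.items():
        sel = chroms == chrom
        if not sel.any():
            continue
        idx = np.searchsorted(starts, pos[sel], side="right") - 1
        inside = (idx >= 0) & (pos[sel] < ends[np.clip(idx, 0, len(ends) - 1)])
        mask[np.flatnonzero(sel)] = inside
    return mask


def mutations_in_panel(mutations: pd.DataFrame, panel: PanelDesign) -> pd.DataFrame:
    """Rows whose (chromosome, position) fall inside a panel interval.

    Order is preserved.  A chromosome-naming mismatch yields zero hits and a
    warning rather than an error.
    """
    return mutations[_membership_mask(mutations, panel.intervals)]


def panel_from_genes(
    name: str, gene_symbols: Iterable[str], genome: Sequence
) -> PanelDesign:
    """Assemble a panel covering all exons of the named genes."""
    wanted = set(gene_symbols)
    by_symbol = {g.gene_symbol: g for g in genome}
    missing = sorted(wanted - set(by_symbol))
    if missing:
        raise ValidationError(f"unknown gene symbols: {missing[:10]}")
    rows = [
        (by_symbol[sym].chromosome, s, e)
        for sym in wanted
        for s, e in by_symbol[sym].exons
    ]
    return PanelDesign(name=name, intervals=merge_intervals(rows), genes=frozenset(wanted))


def build_panel_family(
    real_gene_sets: Sequence[Iterable[str]],
    genome: Sequence,
    step: int = 1,
    seed: int = 0,
    name_prefix: str = "synthetic_panel",
) -> PanelFamily:
    """Grow nested synthetic panels by real-world gene coverage frequency.

    Genes are ranked by the number of real panel designs covering them,
    descending (ties broken by a seeded shuffle within a tier), and added
    ``step`` at a time; each added gene contributes all of its exons.  Genes
    covered by no real panel are appended as a final tier so the family can
    reach the full genome.
    """
    if step < 1:
        raise ValidationError("step must be >= 1")
    gene_symbols = [g.gene_symbol for g in genome]
    known = set(gene_symbols)
    coverage: dict[str, int] = {sym: 0 for sym in gene_symbols}
    unknown: set[str] = set()
    for gs in real_gene_sets:
        for sym in set(gs):
            if sym in coverage:
                coverage[sym] += 1
            else:
                unknown.add(sym)
    if unknown:
        raise ValidationError(f"gene sets reference unknown symbols: {sorted(unknown)[:10]}")
    rng = np.random.default_rng(seed)
    tiers: dict[int, list[str]] = {}
    for sym, cnt in coverage.items():
        tiers.setdefault(cnt, []).append(sym)
    ordered: list[str] = []
    for cnt in sorted(tiers, reverse=True):
        tier = sorted(tiers[cnt])
        rng.shuffle(tier)
        ordered.extend(tier)

    panels: list[PanelDesign] = []
    for i, upto in enumerate(range(step, len(ordered) + 1, step)):
        members = ordered[:upto]
        panels.append(panel_from_genes(f"{name_prefix}_{i:04d}", members, genome))
    if not panels or len(panels[-1].genes) < len(ordered):
        panels.append(panel_from_genes(f"{name_prefix}_{len(panels):04d}", ordered, genome))
    return PanelFamily(
        panels=tuple(panels),
        provenance=f"coverage-tier ordering over {len(real_gene_sets)} real gene sets, "
        f"step={step}, seed={seed}",
    )


def strip_gene_list(
    panel: PanelDesign, exclusion_list: Iterable[str], genome: Sequence
) -> PanelDesign:
    """Remove the listed genes (all their exons) from a panel.

    The exclusion list is a plain user-supplied set of symbols (e.g.
    hotspot/driver genes); excluding every member gene is an error because a
    panel cannot be empty.
    """
    excluded = set(exclusion_list)
    kept = panel.genes - excluded
    if not excluded & panel.genes:
        return panel
    if not kept:
        raise ValidationError("exclusion list removes every gene in the panel")
    return panel_from_genes(panel.name, kept, genome)
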