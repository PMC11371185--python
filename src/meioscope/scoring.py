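"""Scoring rules for chromosome-spread and HEI10-focus data.

Implements the configuration-based minimum-chiasma estimate (a ring
bivalent carries at least 2 chiasmata, a rod exactly 1, a univalent pair
none), the class I / class II crossover partition (unlabelled chiasmata are
booked as interference-insensitive class II crossovers), foci-per-bivalent
distributions, normalized inter-focus spacings, and immunofluorescence
intensity normalization against a reference genotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .records import (
    BivalentConfig,
    BivalentRecord,
    CellRecord,
    IntensityRecord,
    Stage,
    ValidationError,
)

#: chiasmata contributed by each configuration under the minimum rule
CONFIG_CHIASMATA = {
    BivalentConfig.RING: 2,
    BivalentConfig.ROD: 1,
    BivalentConfig.UNIVALENT_PAIR: 0,
}


@dataclass(frozen=True)
class ChiasmaEstimate:
    cell_id: str
    n_ring: int
    n_rod: int
    n_univalent_pairs: int
    min_chiasmata: int


@dataclass(frozen=True)
class COAccount:
    """Per-cell crossover bookkeeping: total = class I + class II."""

    cell_id: str
    n_class1: int
    n_class2: int
    n_total: int


@dataclass(frozen=True)
class FociDistribution:
    """Foci-per-bivalent counts over categories 0..K for one group."""

    genotype_label: str
    stage: Stage
    counts_by_category: Tuple[int, ...]
    n_bivalents: int
    proportions: Tuple[float, ...]


def score_min_chiasmata(cell: CellRecord) -> ChiasmaEstimate:
    """Minimum chiasma count of a cell from its bivalent configurations.

    Conservative by construction: a ring is scored 2 and a rod 1, so cells
    with >2 crossovers on a bivalent, or several crossovers confined to one
    arm, are undercounted.
    """
    tallies = {c: 0 for c in CONFIG_CHIASMATA}
    for biv in cell.bivalents:
        if biv.config is BivalentConfig.UNKNOWN:
            raise ValidationError(
                f"cell {cell.cell_id!r} pair {biv.pair_index} has config=unknown; "
                "cannot score chiasmata"
            )
        tallies[biv.config] += 1
    total = sum(CONFIG_CHIASMATA[c] * n for c, n in tallies.items())
    return ChiasmaEstimate(
        cell_id=cell.cell_id,
        n_ring=tallies[BivalentConfig.RING],
        n_rod=tallies[BivalentConfig.ROD],
        n_univalent_pairs=tallies[BivalentConfig.UNIVALENT_PAIR],
        min_chiasmata=total,
    )


def expected_min_chiasmata(
    p_ring: float, p_rod: float, p_univalent: float, n_pairs: int
) -> float:
    """Expected minimum chiasmata per cell from configuration proportions."""
    if abs(p_ring + p_rod + p_univalent - 1.0) > 1e-6:
        raise ValidationError(
            "configuration proportions must sum to 1 "
            f"(got {p_ring + p_rod + p_univalent})"
        )
    return n_pairs * (2.0 * p_ring + 1.0 * p_rod)


def account_crossovers(cell: CellRecord) -> COAccount:
    """Partition a diakinesis cell's chiasmata into class I and class II.

    HEI10-labelled chiasmata are class I; unlabelled chiasmata are treated
    as class II; the estimated total is their sum.
    """
    if cell.stage is not Stage.DIAKINESIS:
        raise ValidationError(
            f"crossover accounting requires diakinesis cells (got {cell.stage.value})"
        )
    n1 = n2 = 0
    for biv in cell.bivalents:
        if biv.n_chiasmata is None or biv.n_labeled_chiasmata is None:
            raise ValidationError(
                f"cell {cell.cell_id!r} pair {biv.pair_index} lacks chiasma counts"
            )
        n1 += biv.n_labeled_chiasmata
        n2 += biv.n_chiasmata - biv.n_labeled_chiasmata
    return COAccount(cell_id=cell.cell_id, n_class1=n1, n_class2=n2, n_total=n1 + n2)


def foci_distribution(
    cells: Sequence[CellRecord],
    stage: Stage,
    *,
    genotype_label: Optional[str] = None,
    count_univalents_as_zero: bool = False,
) -> FociDistribution:
    """Distribution of HEI10 foci per bivalent at the requested stage.

    Univalent pairs are excluded by default (the distribution counts
    *bivalents*); set ``count_univalents_as_zero`` to include them as
    zero-focus entries, which shifts category-0 mass.
    """
    counts: List[int] = []
    label = genotype_label
    for cell in cells:
        if cell.stage is not stage:
            continue
        if genotype_label is not None and cell.genotype_label != genotype_label:
            continue
        if label is None:
            label = cell.genotype_label
        for biv in cell.bivalents:
            if biv.config is BivalentConfig.UNIVALENT_PAIR:
                if count_univalents_as_zero:
                    counts.append(0)
                continue
            counts.append(biv.n_class1_foci)
    if not counts:
        raise ValidationError(
            f"no bivalents at stage {stage.value!r}"
            + (f" for genotype {genotype_label!r}" if genotype_label else "")
        )
    kmax = max(counts)
    tallies = np.bincount(counts, minlength=kmax + 1)
    n = int(tallies.sum())
    return FociDistribution(
        genotype_label=label or "",
        stage=stage,
        counts_by_category=tuple(int(c) for c in tallies),
        n_bivalents=n,
        proportions=tuple(float(c) / n for c in tallies),
    )


def distribution_from_counts(
    counts_by_category: Sequence[int],
    *,
    genotype_label: str = "",
    stage: Stage = Stage.DIAKINESIS,
) -> FociDistribution:
    """Build a :class:`FociDistribution` directly from category counts."""
    counts = tuple(int(c) for c in counts_by_category)
    if any(c < 0 for c in counts) or sum(counts) == 0:
        raise ValidationError("category counts must be nonnegative with positive sum")
    n = sum(counts)
    return FociDistribution(
        genotype_label=genotype_label,
        stage=stage,
        counts_by_category=counts,
        n_bivalents=n,
        proportions=tuple(c / n for c in counts),
    )


def adjacent_relative_distances(record: BivalentRecord) -> Tuple[float, ...]:
    """Consecutive differences of the sorted, length-normalized foci.

    Bivalents with fewer than two foci contribute an empty spacing set.
    """
    if record.focus_positions is None:
        raise ValidationError(
            f"cell {record.cell_id!r} pair {record.pair_index} has no recorded "
            "focus positions"
        )
    pos = record.focus_positions
    if len(pos) < 2:
        return ()
    return tuple(float(b - a) for a, b in zip(pos[:-1], pos[1:]))


def pooled_spacings(
    cells: Sequence[CellRecord],
    stage: Stage,
    *,
    genotype_label: Optional[str] = None,
) -> np.ndarray:
    """Pool adjacent relative spacings over all bivalents of a group."""
    out: List[float] = []
    for cell in cells:
        if cell.stage is not stage:
            continue
        if genotype_label is not None and cell.genotype_label != genotype_label:
            continue
        for biv in cell.bivalents:
            if biv.focus_positions is not None:
                out.extend(adjacent_relative_distances(biv))
    return np.asarray(out, dtype=float)


def normalize_intensity(
    records: Sequence[IntensityRecord], reference_genotype: str
) -> np.ndarray:
    """Background-subtracted intensities scaled by the reference-group mean.

    value_i = (raw_i - background_i) / mean_ref(raw - background), so the
    reference group has normalized mean 1 by construction and the output is
    invariant to a uniform rescaling of all raw values.
    """
    net = np.array([r.raw_intensity - r.background for r in records], dtype=float)
    ref = np.array(
        [
            r.raw_intensity - r.background
            for r in records
            if r.genotype_label == reference_genotype
        ],
        dtype=float,
    )
    if ref.size == 0:
        raise ValidationError(
            f"reference genotype {reference_genotype!r} has no records"
        )
    ref_mean = float(ref.mean())
    if ref_mean <= 0:
        raise ValidationError(
            f"reference-group mean net intensity must be > 0 (got {ref_mean})"
        )
    return net / ref_mean


@dataclass(frozen=True)
class PercentChange:
    raw: float
    rounded: int


def percent_change(mean_mutant: float, mean_reference: float) -> PercentChange:
    """Percent change of a mutant mean versus a reference mean.

    Rounded to the nearest integer, halves away from zero.
    """
    if not (mean_reference > 0):
        raise ValidationError("mean_reference must be > 0")
    raw = 100.0 * (mean_mutant - mean_reference) / mean_reference
    rounded = int(math.copysign(math.floor(abs(raw) + 0.5), raw))
    return PercentChange(raw=raw, rounded=rounded)


def univalent_fraction(mean_univalent_chromosomes: float, n_chromosomes: int) -> float:
    """Fraction of chromosome pairs occurring as univalents.

    Univalent chromosomes over total chromosomes equals the fraction of
    pairs that are univalent (both members of an achiasmate pair are
    univalents).
    """
    if not (0.0 <= mean_univalent_chromosomes <= n_chromosomes):
        raise ValidationError(
            f"mean univalents {mean_univalent_chromosomes} outside [0, {n_chromosomes}]"
        )
    return mean_univalent_chromosomes / n_chromosomes
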