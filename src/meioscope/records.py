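"""Domain types for per-meiocyte cytology data.

The unit of observation is a *bivalent*: one pair of homologous chromosomes
in one meiocyte, carrying a diakinesis/metaphase-I configuration call
(ring / rod / pair of univalents), HEI10 focus counts and positions, and
optionally chiasma counts split into HEI10-labelled and unlabelled.

Focus positions are stored as fractions of the bivalent length on the
closed unit interval [0, 1]; 0 denotes one (arbitrarily designated) end.
Raw micrometre positions are converted on ingest when ``length_um`` is
present (see :mod:`meioscope.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Tuple


class Stage(str, Enum):
    """Prophase-I / division-I substage at which a cell was scored."""

    ZYGOTENE_EARLY_PACHYTENE = "zygotene_early_pachytene"
    LATE_PACHYTENE_DIPLOTENE = "late_pachytene_diplotene"
    DIAKINESIS = "diakinesis"


class BivalentConfig(str, Enum):
    """Chromosome-pair configuration at diakinesis/metaphase I."""

    RING = "ring"
    ROD = "rod"
    UNIVALENT_PAIR = "univalent_pair"
    UNKNOWN = "unknown"


class ValidationError(ValueError):
    """A record violates one of the documented type invariants."""


def _parse_enum(cls, token: str, what: str):
    try:
        return cls(token)
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise ValidationError(
            f"unknown {what} token {token!r}; allowed tokens: {allowed}"
        ) from None


def parse_stage(token: str) -> Stage:
    return _parse_enum(Stage, token, "stage")


def parse_config(token: str) -> BivalentConfig:
    return _parse_enum(BivalentConfig, token, "config")


@dataclass(frozen=True)
class GenomeSpec:
    """Karyotype-level constants of the simulated/analysed genome.

    Brassica napus meiocytes show 19 condensed bivalents, hence the
    default ``n_pairs``.  Relative lengths and centromere positions are
    package parameters (no karyotype metrics are assumed); defaults are
    equal unit lengths with a mildly submetacentric centromere.
    """

    n_pairs: int = 19
    lengths: Tuple[float, ...] = ()
    centromere_fractions: Tuple[float, ...] = ()

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValidationError("GenomeSpec.n_pairs must be >= 1")
        lengths = tuple(self.lengths) or (1.0,) * self.n_pairs
        cents = tuple(self.centromere_fractions) or (0.45,) * self.n_pairs
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "centromere_fractions", cents)
        if len(self.lengths) != self.n_pairs:
            raise ValidationError(
                f"GenomeSpec.lengths must have exactly n_pairs={self.n_pairs} entries"
            )
        if len(self.centromere_fractions) != self.n_pairs:
            raise ValidationError(
                "GenomeSpec.centromere_fractions must have exactly "
                f"n_pairs={self.n_pairs} entries"
            )
        if any(not (l > 0 and math.isfinite(l)) for l in self.lengths):
            raise ValidationError("GenomeSpec.lengths must be strictly positive")
        if any(not (0.0 < c < 1.0) for c in self.centromere_fractions):
            raise ValidationError(
                "GenomeSpec.centromere_fractions must lie strictly inside (0, 1)"
            )


@dataclass(frozen=True)
class BivalentRecord:
    """One chromosome pair in one cell."""

    genotype_label: str
    cell_id: str
    pair_index: int
    stage: Stage
    config: BivalentConfig
    n_class1_foci: int
    focus_positions: Optional[Tuple[float, ...]] = None
    n_chiasmata: Optional[int] = None
    n_labeled_chiasmata: Optional[int] = None
    length_um: Optional[float] = None

    def __post_init__(self):
        if self.pair_index < 0:
            raise ValidationError("BivalentRecord.pair_index must be >= 0")
        if self.n_class1_foci < 0:
            raise ValidationError("BivalentRecord.n_class1_foci must be >= 0")
        if self.focus_positions is not None:
            pos = tuple(sorted(float(p) for p in self.focus_positions))
            object.__setattr__(self, "focus_positions", pos)
            if any(not (0.0 <= p <= 1.0) for p in pos):
                raise ValidationError(
                    f"focus_positions must lie in [0, 1]; got {pos}"
                )
            if len(pos) != self.n_class1_foci:
                raise ValidationError(
                    f"focus_positions has {len(pos)} entries but "
                    f"n_class1_foci={self.n_class1_foci}"
                )
        if self.n_chiasmata is not None and self.n_chiasmata < 0:
            raise ValidationError("n_chiasmata must be >= 0")
        if self.n_labeled_chiasmata is not None:
            if self.n_labeled_chiasmata < 0:
                raise ValidationError("n_labeled_chiasmata must be >= 0")
            if (
                self.n_chiasmata is not None
                and self.n_labeled_chiasmata > self.n_chiasmata
            ):
                raise ValidationError(
                    f"n_labeled_chiasmata={self.n_labeled_chiasmata} exceeds "
                    f"n_chiasmata={self.n_chiasmata}"
                )
        if self.n_chiasmata is not None:
            if self.config is BivalentConfig.RING and self.n_chiasmata < 2:
                raise ValidationError(
                    "config=ring requires n_chiasmata >= 2 "
                    f"(got {self.n_chiasmata})"
                )
            if self.config is BivalentConfig.ROD and self.n_chiasmata < 1:
                raise ValidationError(
                    "config=rod requires n_chiasmata >= 1 "
                    f"(got {self.n_chiasmata})"
                )
            if (
                self.config is BivalentConfig.UNIVALENT_PAIR
                and self.n_chiasmata != 0
            ):
                raise ValidationError(
                    "config=univalent_pair requires n_chiasmata = 0 "
                    f"(got {self.n_chiasmata})"
                )
        if self.length_um is not None and not (
            self.length_um > 0 and math.isfinite(self.length_um)
        ):
            raise ValidationError("length_um must be positive and finite")


@dataclass(frozen=True)
class CellRecord:
    """One meiocyte: a genotype label, a stage, and its bivalents."""

    genotype_label: str
    cell_id: str
    stage: Stage
    bivalents: Tuple[BivalentRecord, ...]

    def __post_init__(self):
        object.__setattr__(self, "bivalents", tuple(self.bivalents))
        for b in self.bivalents:
            if b.cell_id != self.cell_id:
                raise ValidationError(
                    f"bivalent cell_id {b.cell_id!r} != cell cell_id {self.cell_id!r}"
                )
            if b.stage is not self.stage:
                raise ValidationError(
                    f"bivalent stage {b.stage.value} != cell stage {self.stage.value}"
                )
            if b.genotype_label != self.genotype_label:
                raise ValidationError(
                    f"bivalent genotype {b.genotype_label!r} != cell genotype "
                    f"{self.genotype_label!r}"
                )

    def validate_against(self, genome: GenomeSpec) -> None:
        if len(self.bivalents) != genome.n_pairs:
            raise ValidationError(
                f"cell {self.cell_id!r} has {len(self.bivalents)} bivalents; "
                f"expected n_pairs={genome.n_pairs}"
            )
        indices = sorted(b.pair_index for b in self.bivalents)
        if indices != list(range(genome.n_pairs)):
            raise ValidationError(
                f"cell {self.cell_id!r} pair indices {indices} do not cover "
                f"0..{genome.n_pairs - 1}"
            )


@dataclass(frozen=True)
class IntensityRecord:
    """A background-paired immunofluorescence intensity measurement."""

    genotype_label: str
    cell_id: str
    stage: Stage
    raw_intensity: float
    background: float

    def __post_init__(self):
        if not (self.raw_intensity >= 0 and math.isfinite(self.raw_intensity)):
            raise ValidationError("raw_intensity must be >= 0 and finite")
        if not (self.background >= 0 and math.isfinite(self.background)):
            raise ValidationError("background must be >= 0 and finite")
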