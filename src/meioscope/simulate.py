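"""Dosage-aware synthetic meiocyte simulator.

Crossovers (COs) are placed independently on each of the 19 chromosome
pairs of a cell:

* class I (interference-sensitive) COs follow a *stationary gamma-renewal
  process*: inter-CO distances are gamma distributed with shape ``nu`` and
  mean ``1/class1_rate``.  ``nu = 1`` recovers a homogeneous Poisson process
  (no interference); larger ``nu`` spaces COs more evenly, which is the
  standard cytogenetic model of crossover interference strength.
* class II (interference-insensitive) COs form an independent homogeneous
  Poisson overlay at ``class2_rate``.

An obligate-CO mechanism may then enforce crossover assurance (every pair
obtains at least one CO), and an observation layer emits what a chromosome
spread shows: the ring/rod/univalent configuration (driven by *all* COs,
arm-wise around the centromere), the chiasma count, and the HEI10-labelled
focus count and positions (class I COs, each detected independently with
probability ``detection_prob``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Mapping, Optional, Sequence, Union

import numpy as np
import yaml
from scipy import optimize
from scipy import stats as sps

from .records import (
    BivalentConfig,
    BivalentRecord,
    CellRecord,
    GenomeSpec,
    Stage,
    ValidationError,
)

OBLIGATE_MECHANISMS = ("none", "resample_until_nonempty", "forced_extra")


@dataclass(frozen=True)
class SimulationParams:
    """Genotype-level generative parameters.

    Parameters
    ----------
    nu : float
        Gamma-renewal shape (interference strength) for class I COs;
        ``nu = 1`` means no interference.
    class1_rate, class2_rate : float
        Expected class I / class II COs per unit relative length.
    obligate_mechanism : str
        ``"none"``, ``"resample_until_nonempty"`` (redraw a pair's COs until
        at least one exists) or ``"forced_extra"`` (add one uniformly placed
        rescue CO, booked as class II, when a pair would otherwise be empty).
    detection_prob : float
        Probability that a class I CO is observed as a HEI10 focus.
        Configurations and chiasma counts use the true COs: chiasmata are
        visible in spreads independently of the immunolabel.
    asy3_dosage : float
        Annotation only (fraction of wild-type axis-protein dosage).
    seed : int
        Default RNG seed for :func:`simulate_experiment`.
    """

    nu: float = 1.0
    class1_rate: float = 1.0
    class2_rate: float = 0.0
    obligate_mechanism: str = "none"
    detection_prob: float = 1.0
    asy3_dosage: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (self.nu > 0 and math.isfinite(self.nu)):
            raise ValidationError("SimulationParams.nu must be > 0 and finite")
        if self.class1_rate < 0 or self.class2_rate < 0:
            raise ValidationError("SimulationParams rates must be >= 0")
        if not (0.0 < self.detection_prob <= 1.0):
            raise ValidationError("detection_prob must lie in (0, 1]")
        if self.obligate_mechanism not in OBLIGATE_MECHANISMS:
            raise ValidationError(
                f"unknown obligate_mechanism {self.obligate_mechanism!r}; "
                f"allowed: {OBLIGATE_MECHANISMS}"
            )
        if not (0.0 <= self.asy3_dosage <= 1.0):
            raise ValidationError("asy3_dosage must lie in [0, 1]")


@dataclass(frozen=True)
class GenotypePreset:
    label: str
    params: SimulationParams


def _equilibrium_first_arrival(rate: float, nu: float, u: float) -> float:
    """Inverse CDF of the stationary (integrated-tail) first-arrival law.

    For gamma(shape=nu, rate=beta) gaps with beta = nu*rate, the equilibrium
    CDF has the closed form  F_e(x) = F_{nu+1}(x) + (beta*x/nu) * S_nu(x),
    whose density is rate * S_nu(x) as required for stationarity.
    """
    beta = nu * rate

    def cdf(x: float) -> float:
        return (
            sps.gamma.cdf(x, nu + 1.0, scale=1.0 / beta)
            + (beta * x / nu) * sps.gamma.sf(x, nu, scale=1.0 / beta)
        )

    hi = 1.0 / rate
    while cdf(hi) < u:
        hi *= 2.0
    return optimize.brentq(lambda x: cdf(x) - u, 0.0, hi, xtol=1e-12)


def sample_stationary_gamma_process(
    length: float, rate: float, nu: float, rng: np.random.Generator
) -> np.ndarray:
    """Event positions of a stationary gamma-renewal process on [0, length].

    Gaps are gamma(shape=nu, mean=1/rate); the first event is drawn from the
    equilibrium (integrated-tail) distribution so that the expected event
    count is exactly ``rate * length`` for every ``nu``.

    For integer ``nu`` the exact thinning construction is used: a Poisson
    process at rate ``nu * rate`` is simulated and every ``nu``-th point kept,
    starting from a uniformly random phase.  Non-integer ``nu`` falls back to
    sequential sampling with the equilibrium first-interval law.
    """
    if not (
        math.isfinite(length) and math.isfinite(rate) and math.isfinite(nu)
    ):
        raise ValidationError("length, rate and nu must be finite")
    if length <= 0:
        raise ValidationError("length must be > 0")
    if rate < 0:
        raise ValidationError("rate must be >= 0")
    if nu <= 0:
        raise ValidationError("nu must be > 0")
    if rate == 0:
        return np.empty(0, dtype=float)

    m = int(round(nu))
    if m >= 1 and abs(nu - m) < 1e-12:
        n = rng.poisson(m * rate * length)
        offset = int(rng.integers(m))
        if n == 0:
            return np.empty(0, dtype=float)
        pts = np.sort(rng.uniform(0.0, length, n))
        return pts[offset::m].copy()

    out = []
    x = _equilibrium_first_arrival(rate, nu, rng.uniform())
    while x <= length:
        out.append(x)
        x += rng.gamma(nu, 1.0 / (nu * rate))
    return np.asarray(out, dtype=float)


def simulate_bivalent(
    params: SimulationParams,
    pair_length: float,
    centromere: float,
    rng: np.random.Generator,
    *,
    genotype_label: str = "sim",
    cell_id: str = "cell0000",
    pair_index: int = 0,
    stage: Stage = Stage.DIAKINESIS,
) -> BivalentRecord:
    """Simulate one chromosome pair and its cytological observation.

    The configuration is derived arm-wise from *all* COs around the
    centromere: at least one CO on each side gives a ring, COs confined to
    one side give a rod (even when more than one CO is present -- the
    configuration-based chiasma count can therefore undercount true COs),
    and an empty pair is a pair of univalents.
    """
    if not (0.0 < centromere < 1.0):
        raise ValidationError("centromere fraction must lie strictly in (0, 1)")

    def draw():
        c1 = sample_stationary_gamma_process(
            pair_length, params.class1_rate, params.nu, rng
        )
        n2 = rng.poisson(params.class2_rate * pair_length)
        c2 = np.sort(rng.uniform(0.0, pair_length, n2))
        return c1, c2

    class1, class2 = draw()
    if params.obligate_mechanism == "resample_until_nonempty":
        while len(class1) + len(class2) == 0:
            class1, class2 = draw()
    elif params.obligate_mechanism == "forced_extra":
        if len(class1) + len(class2) == 0:
            # rescue CO: interference-insensitive, hence booked as class II
            class2 = np.array([rng.uniform(0.0, pair_length)])

    all_cos = np.concatenate([class1, class2])
    cent_abs = centromere * pair_length
    if len(all_cos) == 0:
        config = BivalentConfig.UNIVALENT_PAIR
    elif (all_cos <= cent_abs).any() and (all_cos > cent_abs).any():
        config = BivalentConfig.RING
    else:
        config = BivalentConfig.ROD

    if params.detection_prob < 1.0:
        keep = rng.random(len(class1)) < params.detection_prob
        detected = class1[keep]
    else:
        detected = class1
    positions = tuple(np.sort(detected) / pair_length)

    return BivalentRecord(
        genotype_label=genotype_label,
        cell_id=cell_id,
        pair_index=pair_index,
        stage=stage,
        config=config,
        n_class1_foci=len(detected),
        focus_positions=positions,
        n_chiasmata=len(class1) + len(class2),
        n_labeled_chiasmata=len(detected),
        length_um=None,
    )


def simulate_experiment(
    preset: GenotypePreset,
    n_cells: int,
    genome: Optional[GenomeSpec] = None,
    *,
    stage: Stage = Stage.DIAKINESIS,
    rng: Optional[np.random.Generator] = None,
) -> list[CellRecord]:
    """Simulate ``n_cells`` meiocytes of one genotype.

    Reproducible: when ``rng`` is not supplied, a fresh generator is seeded
    from ``preset.params.seed``, so identical presets give identical data.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    genome = genome or GenomeSpec()
    if rng is None:
        rng = np.random.default_rng(preset.params.seed)
    cells = []
    for i in range(n_cells):
        cell_id = f"{preset.label}_cell{i:04d}"
        bivs = tuple(
            simulate_bivalent(
                preset.params,
                genome.lengths[j],
                genome.centromere_fractions[j],
                rng,
                genotype_label=preset.label,
                cell_id=cell_id,
                pair_index=j,
                stage=stage,
            )
            for j in range(genome.n_pairs)
        )
        cell = CellRecord(
            genotype_label=preset.label,
            cell_id=cell_id,
            stage=stage,
            bivalents=bivs,
        )
        cell.validate_against(genome)
        cells.append(cell)
    return cells


# Default genotype presets for the ASY3 dosage series (4 -> 0 functional
# alleles).  Class I rates are calibrated so that the expected number of
# HEI10 foci per diakinesis cell (19 * class1_rate * detection_prob) matches
# the observed genotype means; class II rates additionally absorb the
# forced-extra rescue contribution so that expected unlabelled chiasmata per
# cell match the observed class II means.  Interference is strong (nu = 8)
# in wild type and the two-functional-allele genotypes and absent (nu = 1)
# in the one- and zero-functional-allele genotypes.
GENOTYPE_LABELS = ("AACC_wt", "aaCC", "AAcc", "aaCc", "Aacc", "aacc")

_DEFAULT_PRESET_VALUES: Dict[str, Dict[str, Union[float, int, str]]] = {
    "AACC_wt": dict(
        nu=8.0, class1_rate=1.414737, class2_rate=0.323167,
        obligate_mechanism="forced_extra", detection_prob=1.0,
        asy3_dosage=1.0, seed=11,
    ),
    "aaCC": dict(
        nu=8.0, class1_rate=1.566316, class2_rate=0.333598,
        obligate_mechanism="forced_extra", detection_prob=1.0,
        asy3_dosage=0.5, seed=12,
    ),
    "AAcc": dict(
        nu=8.0, class1_rate=1.547368, class2_rate=0.332616,
        obligate_mechanism="forced_extra", detection_prob=1.0,
        asy3_dosage=0.5, seed=13,
    ),
    "aaCc": dict(
        nu=1.0, class1_rate=1.995263, class2_rate=0.205017,
        obligate_mechanism="forced_extra", detection_prob=1.0,
        asy3_dosage=0.35, seed=14,
    ),
    "Aacc": dict(
        nu=1.0, class1_rate=1.930000, class2_rate=0.226360,
        obligate_mechanism="forced_extra", detection_prob=1.0,
        asy3_dosage=0.27, seed=15,
    ),
    "aacc": dict(
        nu=1.0, class1_rate=0.288421, class2_rate=0.029474,
        obligate_mechanism="none", detection_prob=1.0,
        asy3_dosage=0.0, seed=16,
    ),
}


def genotype_presets(
    config: Optional[Union[str, Mapping[str, Mapping[str, object]]]] = None,
) -> Dict[str, GenotypePreset]:
    """Return the six default genotype presets, optionally overridden.

    ``config`` may be a mapping ``{label: {field: value, ...}}`` or the path
    of a YAML file with that layout; fields not mentioned keep their default.
    An override naming an unknown genotype label is an error.
    """
    overrides: Mapping[str, Mapping[str, object]] = {}
    if config is not None:
        if isinstance(config, (str,)):
            with open(config) as fh:
                overrides = yaml.safe_load(fh) or {}
        else:
            overrides = config
        unknown = set(overrides) - set(GENOTYPE_LABELS)
        if unknown:
            raise ValidationError(
                f"unknown genotype label(s) in preset override: {sorted(unknown)}; "
                f"allowed: {GENOTYPE_LABELS}"
            )
    presets: Dict[str, GenotypePreset] = {}
    for label in GENOTYPE_LABELS:
        values = dict(_DEFAULT_PRESET_VALUES[label])
        values.update(overrides.get(label, {}))
        presets[label] = GenotypePreset(label=label, params=SimulationParams(**values))
    return presets
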