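import numpy as np
import pytest

from meioscope import (
    BivalentConfig,
    BivalentRecord,
    CellRecord,
    GenomeSpec,
    Stage,
    genotype_presets,
)


@pytest.fixture(scope="session")
def genome():
    return GenomeSpec()


@pytest.fixture(scope="session")
def presets():
    return genotype_presets()


def make_cell(
    configs,
    *,
    genotype="AACC_wt",
    cell_id="cell0000",
    stage=Stage.DIAKINESIS,
    foci=None,
    chiasmata=None,
    labeled=None,
    positions=None,
):
    """Build a CellRecord from per-pair configuration (and optional count) lists."""
    bivs = []
    for j, cfg in enumerate(configs):
        bivs.append(
            BivalentRecord(
                genotype_label=genotype,
                cell_id=cell_id,
                pair_index=j,
                stage=stage,
                config=BivalentConfig(cfg),
                n_class1_foci=0 if foci is None else foci[j],
                focus_positions=None if positions is None else tuple(positions[j]),
                n_chiasmata=None if chiasmata is None else chiasmata[j],
                n_labeled_chiasmata=None if labeled is None else labeled[j],
            )
        )
    return CellRecord(
        genotype_label=genotype, cell_id=cell_id, stage=stage, bivalents=tuple(bivs)
    )
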