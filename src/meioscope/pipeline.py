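"""Orchestration: simulate -> score -> test -> report.

Every numeric in the rendered report comes from one serialized operation
result; the report layer only formats.  Runs are deterministic for a given
configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from . import __version__
from .io import (
    read_bivalent_table,
    write_bivalent_table,
    write_results,
)
from .records import CellRecord, GenomeSpec, Stage, ValidationError
from .scoring import (
    account_crossovers,
    foci_distribution,
    pooled_spacings,
    score_min_chiasmata,
)
from .simulate import GenotypePreset, genotype_presets, simulate_experiment
from .stats import (
    GOF_POLICIES,
    chisq_homogeneity,
    games_howell,
    poisson_gof,
    spacing_cv,
)

logger = logging.getLogger("meioscope")

REJECT = "reject Poisson"
FAIL = "fail to reject Poisson"
POLICY_SENSITIVE = "policy-sensitive"


@dataclass
class RunConfig:
    """Configuration of one simulate/analyze run."""

    genome: GenomeSpec = field(default_factory=GenomeSpec)
    presets: Optional[Dict[str, GenotypePreset]] = None
    n_cells: Union[int, Mapping[str, int]] = 50
    stage: Stage = Stage.DIAKINESIS
    gof_policy: str = "both"
    seed: int = 0
    output_dir: Union[str, Path] = "out"
    reference_genotype: str = "AACC_wt"
    alpha: float = 0.05
    count_univalents_as_zero: bool = False

    def __post_init__(self):
        if self.presets is None:
            self.presets = genotype_presets()
        if self.gof_policy not in ("both", "excel", "folded"):
            raise ValidationError("gof_policy must be 'both', 'excel' or 'folded'")

    def cells_for(self, label: str) -> int:
        if isinstance(self.n_cells, Mapping):
            return int(self.n_cells[label])
        return int(self.n_cells)

    def policies(self) -> Tuple[str, ...]:
        return {
            "both": tuple(GOF_POLICIES),
            "excel": ("excel_k_minus_1",),
            "folded": ("folded_k_minus_2",),
        }[self.gof_policy]

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        genome = GenomeSpec(
            n_pairs=int(data.get("genome", {}).get("n_pairs", 19)),
            lengths=tuple(data.get("genome", {}).get("lengths", ())),
            centromere_fractions=tuple(
                data.get("genome", {}).get("centromere_fractions", ())
            ),
        )
        presets = genotype_presets(data.get("presets"))
        if "genotypes" in data:
            presets = {g: presets[g] for g in data["genotypes"]}
        return cls(
            genome=genome,
            presets=presets,
            n_cells=data.get("n_cells", 50),
            stage=Stage(data.get("stage", "diakinesis")),
            gof_policy=data.get("gof_policy", "both"),
            seed=int(data.get("seed", 0)),
            output_dir=data.get("output_dir", "out"),
            reference_genotype=data.get("reference_genotype", "AACC_wt"),
            alpha=float(data.get("alpha", 0.05)),
            count_univalents_as_zero=bool(
                data.get("count_univalents_as_zero", False)
            ),
        )


def cmd_simulate(config: RunConfig, *, force: bool = False) -> Path:
    """Simulate all configured genotypes and write bivalents.csv + manifest.

    Per-genotype RNG streams are spawned deterministically from the run
    seed, so the output is byte-identical across reruns of one config.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    data_path = out / "bivalents.csv"
    manifest_path = out / "manifest.json"
    if (data_path.exists() or manifest_path.exists()) and not force:
        raise FileExistsError(
            f"{data_path} exists; pass force=True (--force) to overwrite"
        )
    cells: List[CellRecord] = []
    counts: Dict[str, int] = {}
    for i, (label, preset) in enumerate(sorted(config.presets.items())):
        rng = np.random.default_rng([config.seed, i])
        n = config.cells_for(label)
        batch = simulate_experiment(
            preset, n, config.genome, stage=config.stage, rng=rng
        )
        counts[label] = len(batch) * config.genome.n_pairs
        cells.extend(batch)
        logger.info("simulate %s: %d cells (%d rows)", label, n, counts[label])
    write_bivalent_table(cells, data_path)
    manifest = {
        "tool": "meioscope",
        "version": __version__,
        "seed": config.seed,
        "stage": config.stage.value,
        "n_pairs": config.genome.n_pairs,
        "rows_per_genotype": counts,
        "total_rows": sum(counts.values()),
        "params": {
            label: dataclasses.asdict(preset.params)
            for label, preset in sorted(config.presets.items())
        },
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return data_path


def _fmt_p(p: float) -> str:
    return f"{p:.2e}" if p < 0.001 else f"{p:.3f}"


def cmd_analyze(
    data: Union[str, Path, Sequence[CellRecord]],
    config: RunConfig,
) -> Dict[str, object]:
    """Score and test a dataset; write the report bundle; return it.

    Produces per-genotype summaries (mean, SD, n), foci-per-bivalent
    distribution long tables, Poisson GOF results under the configured
    policies with a cross-policy verdict, homogeneity tests versus the
    reference genotype, Games-Howell comparisons of per-cell focus counts
    and minimum chiasmata, spacing summaries, and a plain-text report.
    """
    if isinstance(data, (str, Path)):
        cells = read_bivalent_table(data, config.genome)
    else:
        cells = list(data)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    genotypes = sorted({c.genotype_label for c in cells})
    if len(genotypes) > 1 and config.reference_genotype not in genotypes:
        raise ValidationError(
            f"reference genotype {config.reference_genotype!r} absent from data "
            f"(present: {genotypes})"
        )
    by_geno: Dict[str, List[CellRecord]] = {g: [] for g in genotypes}
    for c in cells:
        by_geno[c.genotype_label].append(c)

    summary_rows: List[Dict[str, object]] = []
    dist_rows: List[Dict[str, object]] = []
    gof_results: Dict[str, Dict[str, object]] = {}
    foci_by_geno: Dict[str, List[float]] = {}
    chiasmata_by_geno: Dict[str, List[float]] = {}
    spacing_summaries: Dict[str, Dict[str, float]] = {}

    scorable = True
    for g in genotypes:
        gcells = by_geno[g]
        foci = [sum(b.n_class1_foci for b in c.bivalents) for c in gcells]
        foci_by_geno[g] = foci
        try:
            chia = [score_min_chiasmata(c).min_chiasmata for c in gcells]
            chiasmata_by_geno[g] = chia
        except ValidationError:
            scorable = False
            chia = []
        row = {
            "genotype": g,
            "n_cells": len(gcells),
            "foci_mean": float(np.mean(foci)),
            "foci_sd": float(np.std(foci, ddof=1)) if len(foci) > 1 else 0.0,
        }
        if chia:
            row["min_chiasmata_mean"] = float(np.mean(chia))
            row["min_chiasmata_sd"] = (
                float(np.std(chia, ddof=1)) if len(chia) > 1 else 0.0
            )
        have_chiasma_counts = all(
            b.n_chiasmata is not None and b.n_labeled_chiasmata is not None
            for c in gcells
            for b in c.bivalents
        )
        if have_chiasma_counts and config.stage is Stage.DIAKINESIS:
            accounts = [account_crossovers(c) for c in gcells]
            row["class2_mean"] = float(np.mean([a.n_class2 for a in accounts]))
            row["total_co_mean"] = float(np.mean([a.n_total for a in accounts]))
        summary_rows.append(row)

        dist = foci_distribution(
            gcells,
            config.stage,
            genotype_label=g,
            count_univalents_as_zero=config.count_univalents_as_zero,
        )
        for k, (cnt, prop) in enumerate(
            zip(dist.counts_by_category, dist.proportions)
        ):
            dist_rows.append(
                {
                    "genotype": g,
                    "stage": config.stage.value,
                    "category": k,
                    "count": cnt,
                    "proportion": prop,
                }
            )

        fits = {}
        verdicts = []
        for policy in config.policies():
            fit = poisson_gof(dist, policy)
            fits[policy] = fit.to_dict()
            verdicts.append(REJECT if fit.p_value < config.alpha else FAIL)
        verdict = verdicts[0] if len(set(verdicts)) == 1 else POLICY_SENSITIVE
        gof_results[g] = {"fits": fits, "verdict": verdict}

        spac = pooled_spacings(gcells, config.stage, genotype_label=g)
        if spac.size >= 2:
            spacing_summaries[g] = {
                "n": int(spac.size),
                "mean": float(spac.mean()),
                "sd": float(spac.std(ddof=1)),
                "cv": spacing_cv(spac),
            }
        logger.info("analyze %s: %d cells, verdict %s", g, len(gcells), verdict)

    homogeneity: Dict[str, Dict[str, float]] = {}
    if len(genotypes) > 1:
        ref_dist = foci_distribution(
            by_geno[config.reference_genotype],
            config.stage,
            genotype_label=config.reference_genotype,
            count_univalents_as_zero=config.count_univalents_as_zero,
        )
        for g in genotypes:
            if g == config.reference_genotype:
                continue
            dist = foci_distribution(
                by_geno[g],
                config.stage,
                genotype_label=g,
                count_univalents_as_zero=config.count_univalents_as_zero,
            )
            chi2, df, p = chisq_homogeneity(dist, ref_dist)
            homogeneity[g] = {"chi2": chi2, "df": df, "p_value": p}

    comparisons: Dict[str, List[Dict[str, object]]] = {}
    if len(genotypes) > 1:
        usable = {
            g: v
            for g, v in foci_by_geno.items()
            if len(v) >= 2 and np.var(v, ddof=1) > 0
        }
        if len(usable) > 1:
            comparisons["foci_per_cell"] = [
                dataclasses.asdict(c) for c in games_howell(usable)
            ]
        if scorable:
            usable = {
                g: v
                for g, v in chiasmata_by_geno.items()
                if len(v) >= 2 and np.var(v, ddof=1) > 0
            }
            if len(usable) > 1:
                comparisons["min_chiasmata_per_cell"] = [
                    dataclasses.asdict(c) for c in games_howell(usable)
                ]

    bundle: Dict[str, object] = {
        "seed": config.seed,
        "stage": config.stage.value,
        "reference_genotype": config.reference_genotype,
        "alpha": config.alpha,
        "summary": summary_rows,
        "distributions": dist_rows,
        "gof": gof_results,
        "homogeneity": homogeneity,
        "games_howell": comparisons,
        "spacings": spacing_summaries,
    }

    write_results(summary_rows, out / "summary")
    write_results(dist_rows, out / "distributions")
    with open(out / "gof.json", "w") as fh:
        json.dump(gof_results, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "bundle.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
        fh.write("\n")
    report = render_report(bundle)
    (out / "report.txt").write_text(report)
    (out / "report.html").write_text(
        "<html><body><pre>\n" + report + "</pre></body></html>\n"
    )
    return bundle


def render_report(bundle: Mapping[str, object]) -> str:
    """Render the analysis bundle as a deterministic plain-text report."""
    lines: List[str] = []
    lines.append("meioscope analysis report")
    lines.append("=" * 40)
    lines.append(f"stage: {bundle['stage']}   seed: {bundle['seed']}")
    lines.append("")
    lines.append("Per-genotype summaries (mean ± SD, n):")
    for row in bundle["summary"]:
        parts = [
            f"  {row['genotype']}: foci/cell {row['foci_mean']:.2f} "
            f"± {row['foci_sd']:.2f} (n={row['n_cells']})"
        ]
        if "min_chiasmata_mean" in row:
            parts.append(
                f"    min chiasmata {row['min_chiasmata_mean']:.2f} "
                f"± {row['min_chiasmata_sd']:.2f}"
            )
        if "class2_mean" in row:
            parts.append(
                f"    class II {row['class2_mean']:.2f}, "
                f"total CO {row['total_co_mean']:.2f}"
            )
        lines.extend(parts)
    lines.append("")
    lines.append("Poisson goodness of fit (foci per bivalent):")
    for g, res in sorted(bundle["gof"].items()):
        lines.append(f"  {g}: {res['verdict']}")
        for policy, fit in sorted(res["fits"].items()):
            lines.append(
                f"    {policy}: chi2={fit['chi2']:.2f}, df={fit['df']}, "
                f"p={_fmt_p(fit['p_value'])}, lambda={fit['lambda_hat']:.3f}"
            )
    if bundle["homogeneity"]:
        lines.append("")
        ref = bundle["reference_genotype"]
        lines.append(f"Distribution homogeneity vs {ref}:")
        for g, res in sorted(bundle["homogeneity"].items()):
            lines.append(
                f"  {g}: chi2={res['chi2']:.2f}, df={res['df']}, "
                f"p={_fmt_p(res['p_value'])}"
            )
    if bundle["spacings"]:
        lines.append("")
        lines.append("Relative spacing of adjacent foci:")
        for g, s in sorted(bundle["spacings"].items()):
            lines.append(
                f"  {g}: {s['mean']:.2f} ± {s['sd']:.2f} "
                f"(CV {s['cv']:.2f}, n={s['n']})"
            )
    for family, comps in sorted(bundle["games_howell"].items()):
        lines.append("")
        lines.append(f"Games-Howell comparisons ({family}):")
        for c in comps:
            lines.append(
                f"  {c['group_a']} vs {c['group_b']}: "
                f"diff={c['mean_diff']:.2f}, p={_fmt_p(c['p_adjusted'])}"
            )
    lines.append("")
    return "\n".join(lines)


def file_sha256(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
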