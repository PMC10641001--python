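"""End-to-end orchestration: simulate -> type -> compete -> phylo -> anova.

A :class:`PipelineConfig` (typically loaded from YAML) carries every stage
parameter and seed explicitly; unknown keys are rejected. ``run_pipeline``
executes the enabled stages in dependency order, writes each stage's outputs
under the configured directory, and finishes with a machine-readable manifest
(parameters, seeds, package version, SHA-256 checksums of every output), so a
rerun with the same config can be audited for bit-identity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .agrostats import pearson_correlations, percent_change, rcbd_factorial_anova
from .competition import compute_change_factors, competition_report, counts_from_assignments
from .fingerprint import assign_observations
from .io import (
    write_alignment,
    write_counts,
    write_observations,
    write_trait_table,
    write_tree,
)
from .phylogeny import (
    Alignment,
    bootstrap_support,
    collapse_low_support,
    root_with_outgroup,
)
from .simulate import (
    TRAITS,
    VARIETIES,
    CompetitionScenario,
    default_trait_effects,
    default_weights,
    gen_competition_samples,
    gen_fingerprint_observations,
    gen_strain_library,
    gen_trait_table,
)

logger = logging.getLogger("noduplex")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """All pipeline parameters; every random stage has an explicit seed."""

    out_dir: str = "noduplex-out"
    seed: int = 1
    stages: tuple[str, ...] = ("simulate", "type", "compete", "phylo", "anova")
    # simulate
    n_reference: int = 7
    n_indigenous: int = 4
    its_len: int = 461
    clade_divergence: float = 0.10
    n_colonies: int = 21
    n_nodules: int = 21
    n_experiments: int = 3
    dirichlet_concentration: float = 100.0
    band_jitter_bp: int = 3
    n_blocks: int = 3
    # typing
    method: str = "ERIC"
    tolerance_bp: float = 10.0
    min_similarity: float = 0.8
    min_margin: float = 0.05
    # competition
    pseudocount: float = 0.5
    # phylogeny
    model: str = "JC69"
    n_bootstrap: int = 1000
    support_threshold: float = 50.0
    novelty_cutoff: float = 0.05
    # anova
    traits: tuple[str, ...] = TRAITS

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for name in ("stages", "traits"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        bad = set(cfg.stages) - {"simulate", "type", "compete", "phylo", "anova"}
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cfg


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return PipelineConfig.from_dict(data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; return the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    report: dict = {"stages": list(config.stages)}

    def emit(name: str, writer, obj) -> Path:
        path = out / name
        partial = path.with_suffix(path.suffix + ".partial")
        writer(obj, partial)
        partial.replace(path)
        outputs.append(path)
        return path

    stage = "simulate"
    try:
        library = gen_strain_library(
            seed=config.seed,
            n_reference=config.n_reference,
            n_indigenous=config.n_indigenous,
            its_len=config.its_len,
            clade_divergence=config.clade_divergence,
        )
        samples = {}
        for i, variety in enumerate(VARIETIES):
            scenario = CompetitionScenario(
                variety=variety,
                weights=default_weights(variety),
                n_colonies=config.n_colonies,
                n_nodules=config.n_nodules,
                n_experiments=config.n_experiments,
                inoculum_dirichlet_concentration=config.dirichlet_concentration,
                seed=config.seed * 1000 + i,
            )
            samples[variety] = gen_competition_samples(library, scenario)
        effects = default_trait_effects()
        traits_df = gen_trait_table(
            effects,
            n_blocks=config.n_blocks,
            n_experiments=config.n_experiments,
            seed=config.seed + 17,
        )
        if "simulate" in config.stages:
            logger.info("simulate: writing library, samples and trait table")
            emit("its_alignment.fasta", write_alignment, Alignment.from_library(library))
            for variety, (inoc, nod) in samples.items():
                emit(f"inoculum_counts_{variety}.csv", write_counts, inoc)
                emit(f"nodule_counts_{variety}.csv", write_counts, nod)
            emit("trait_table.csv", write_trait_table, traits_df)

        observations = {}
        truth = {}
        for i, variety in enumerate(VARIETIES):
            inoc, nod = samples[variety]
            obs = gen_fingerprint_observations(
                library,
                nod,
                band_jitter_bp=config.band_jitter_bp,
                seed=config.seed * 7919 + i,
                source="nodule",
                variety=variety,
                treatment="MK",
            )
            truth[variety] = obs[["isolate_id", "true_tag"]]
            observations[variety] = obs.drop(columns=["true_tag"])
        if "simulate" in config.stages:
            all_obs = pd.concat(observations.values(), ignore_index=True)
            emit("nodule_observations.csv", write_observations, all_obs)
            emit(
                "nodule_observations_truth.csv",
                lambda df, p: df.to_csv(p, index=False),
                pd.concat(truth.values(), ignore_index=True),
            )

        stage = "type"
        assignments = {}
        if "type" in config.stages:
            logger.info("type: assigning isolates by %s fingerprints", config.method)
            for variety in VARIETIES:
                assigned = assign_observations(
                    observations[variety],
                    library,
                    method=config.method,
                    min_similarity=config.min_similarity,
                    min_margin=config.min_margin,
                    tolerance_bp=config.tolerance_bp,
                )
                assignments[variety] = assigned
                emit(
                    f"assignments_{variety}.csv",
                    write_observations,
                    assigned,
                )

        stage = "compete"
        if "compete" in config.stages:
            logger.info("compete: change factors and percent of mix")
            results = {}
            for variety in VARIETIES:
                inoc, _ = samples[variety]
                if variety in assignments:
                    nod_counts = counts_from_assignments(
                        assignments[variety], library.tags
                    )
                else:
                    _, nod_counts = samples[variety]
                res = compute_change_factors(
                    inoc, nod_counts, pseudocount=config.pseudocount
                )
                results[variety] = res
                per_exp = res.v.copy()
                per_exp.insert(0, "experiment", per_exp.index)
                emit(
                    f"change_factors_{variety}.csv",
                    lambda df, p: df.to_csv(p, index=False),
                    per_exp,
                )
            summary = competition_report(results)
            emit(
                "competition_summary.csv",
                lambda df, p: df.to_csv(p, index=False),
                summary,
            )
            report["competition"] = {
                v: results[v].mean_percent.round(3).to_dict() for v in results
            }

        stage = "phylo"
        if "phylo" in config.stages:
            logger.info("phylo: NJ + %d bootstrap replicates", config.n_bootstrap)
            aln = Alignment.from_library(library)
            tree, info = bootstrap_support(
                aln,
                model=config.model,
                n_replicates=config.n_bootstrap,
                seed=config.seed + 101,
            )
            tree = collapse_low_support(tree, config.support_threshold)
            rooted = root_with_outgroup(tree, library.outgroup.id)
            emit("its_nj_tree.nwk", write_tree, rooted)
            report["phylo"] = info

        stage = "anova"
        if "anova" in config.stages:
            logger.info("anova: RCBD factorial per trait")
            df = traits_df.copy()
            df["block"] = (
                "e" + df["experiment"].astype(str) + "/b" + df["block"].astype(str)
            )
            anova_rows = []
            letters_rows = []
            for trait in config.traits:
                res = rcbd_factorial_anova(df, trait)
                tab = res.table.reset_index()
                tab.insert(0, "trait", trait)
                anova_rows.append(tab)
                for (v, t), letter in res.letters.items():
                    letters_rows.append(
                        {
                            "trait": trait,
                            "variety": v,
                            "treatment": t,
                            "mean": res.cell_means.loc[v, t],
                            "letters": letter,
                            "SED": res.sed,
                            "LSD5": res.lsd5,
                            "CV_percent": res.cv_percent,
                        }
                    )
            emit(
                "anova_tables.csv",
                lambda df_, p: df_.to_csv(p, index=False),
                pd.concat(anova_rows, ignore_index=True),
            )
            emit(
                "trait_means_letters.csv",
                lambda df_, p: df_.to_csv(p, index=False),
                pd.DataFrame(letters_rows),
            )
            sdw = rcbd_factorial_anova(df, "SDW")
            pct, pct_max = percent_change(sdw.cell_means, "0K", "MK")
            report["sdw_percent_change_MK_vs_0K"] = pct.to_dict()
            report["sdw_percent_change_max"] = pct_max
            wide = (
                traits_df.groupby(["variety", "treatment", "block", "experiment", "trait"])[
                    "value"
                ]
                .mean()
                .unstack("trait")
                .reset_index()
            )
            corr_r, corr_p = pearson_correlations(wide, list(config.traits))
            emit("trait_correlations.csv", lambda df_, p: df_.to_csv(p), corr_r)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "package": "noduplex",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
        "report": report,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("wrote %d outputs to %s", len(outputs), out)
    return manifest
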