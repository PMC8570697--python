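"""End-to-end orchestration: simulate -> DE -> harmonize -> compare ->
prioritize -> timing -> persistence.

Three modes:

* ``synthetic`` — generate the four-species experiment with planted
  truth, run every stage, and score recovery against the truth;
* ``fixture`` — bypass DE and build the cross-species status tables
  directly from the packaged published gene lists, exercising the set
  logic on the exactly checkable published surface;
* ``user_data`` — read count tables, a sample sheet and an orthogroup
  table from disk and run the same stages (no truth scoring).

Every headline value in the report is computed by a stage and traceable
to a stage output; thresholds, universe sizes and the hypergeometric
population are always logged explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import crossspecies as xs
from .crossspecies import (
    CrossSpeciesTable,
    PhenotypeMap,
    default_phenotype_map,
)
from .de import DEGCall, DEResult, bh_adjust, call_degs, compute_size_factors, nb_wald_contrast
from .errors import ConfigurationError
from .fixtures import load_fixture
from .io import (
    AnalysisConfig,
    CountMatrix,
    SampleSheet,
    read_count_table,
    read_orthogroups,
    read_sample_sheet,
    write_summary,
)
from .orthology import build_universe
from .simulate import (
    RecoveryScore,
    SyntheticConfig,
    SyntheticExperiment,
    generate_experiment,
    generate_stage_profile,
    generate_timecourse,
    score_recovery,
)
from .timing import EmbryoTimecourse, assign_stage, embryo_range, flag_timing, rlog_proxy

log = logging.getLogger(__name__)

#: universe size printed for the published cross-species comparison; used as
#: the (explicit, logged) hypergeometric population in fixture mode
PUBLISHED_UNIVERSE_SIZE = 7587


@dataclass
class PipelineReport:
    """Headline values plus per-stage record counts for one run."""

    mode: str
    seed: int
    config: dict
    stage_counts: dict[str, int] = field(default_factory=dict)
    headline: dict[str, object] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_summary(self) -> dict[str, object]:
        out: dict[str, object] = {"mode": self.mode, "seed": self.seed}
        out.update({f"n_{k}": v for k, v in sorted(self.stage_counts.items())})
        out.update(dict(sorted(self.headline.items())))
        return out

    def write(self, outdir: str | Path) -> dict[str, str]:
        results: dict[str, object] = dict(self.tables)
        results.update(self.to_summary())
        return write_summary(results, outdir)


def validate_config(raw: Mapping[str, object] | None) -> AnalysisConfig:
    """Build an AnalysisConfig from a parsed mapping, rejecting unknown keys."""
    raw = dict(raw or {})
    known = AnalysisConfig.field_names()
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {unknown}")
    for key in ("fold_change_threshold", "padj_threshold", "pseudocount"):
        if key in raw and not isinstance(raw[key], (int, float)):
            raise ConfigurationError(f"{key} must be numeric, got {raw[key]!r}")
    if "seed" in raw and not isinstance(raw["seed"], int):
        raise ConfigurationError(f"seed must be an integer, got {raw['seed']!r}")
    return AnalysisConfig(**raw)


def prioritization_sets(
    phenotypes: PhenotypeMap, stress: str, species: list[str]
) -> tuple[set[str], set[str]]:
    """Include/exclude species for phenotype-paired prioritization.

    Include = species whose offspring adapt.  Exclude = species with the
    deleterious outcome when one exists (the informative contrast),
    otherwise all remaining species.
    """
    include = phenotypes.include_species(stress) & set(species)
    contrast = phenotypes.contrast_species(stress) & set(species)
    exclude = contrast if contrast else set(species) - include
    return include, exclude


def _calls_from_table(table: CrossSpeciesTable, unit: str, label: str) -> DEGCall:
    s = table.status(unit)
    return DEGCall(
        label,
        table.fold_change_threshold,
        table.padj_threshold,
        up=frozenset(s.index[s == "up"]),
        down=frozenset(s.index[s == "down"]),
    )


def _region_key(region: frozenset) -> str:
    return "+".join(sorted(region))


# ---------------------------------------------------------------------------
# fixture mode


def build_fixture_tables(species: list[str] | None = None) -> dict[str, CrossSpeciesTable]:
    """Cross-species status tables transcribing the published gene tables.

    Genes changed in all four species are marked up everywhere for the
    relevant stress; prioritized genes are marked up in the adapting
    species, with the single published inverted gene marked down in the
    contrast species.
    """
    from .fixtures import INVERTED_PATHOGEN_GENE

    species = species or ["C. elegans", "C. briggsae", "C. kamaaina", "C. tropicalis"]
    table1 = load_fixture("table1")
    table2 = load_fixture("table2")
    phenotypes = default_phenotype_map()
    genes = sorted(table1.union() | table2.union())
    idx = pd.Index(genes, name="og_id")

    def blank() -> dict[str, pd.DataFrame]:
        return {
            sp: pd.DataFrame(
                {"log2fc": 0.0, "padj": 1.0, "status": "unchanged"}, index=idx
            )
            for sp in species
        }

    def mark(frames, gene, sp, direction):
        frames[sp].loc[gene, ["log2fc", "padj", "status"]] = (
            2.0 if direction == "up" else -2.0,
            1e-6,
            direction,
        )

    tables: dict[str, CrossSpeciesTable] = {}
    for stress in ("pathogen", "osmotic"):
        frames = blank()
        core = set(table1.sections[stress]) | set(table1.sections["both"])
        for g in sorted(core):
            for sp in species:
                mark(frames, g, sp, "up")
        include, exclude = prioritization_sets(phenotypes, stress, species)
        for g in table2.sections[stress]:
            for sp in sorted(include):
                mark(frames, g, sp, "up")
            if stress == "pathogen" and g == INVERTED_PATHOGEN_GENE:
                for sp in sorted(exclude):
                    mark(frames, g, sp, "down")
        tables[stress] = CrossSpeciesTable(frames)
    return tables


def _run_fixture(config: AnalysisConfig) -> PipelineReport:
    species = list(config.species)
    tables = build_fixture_tables(species)
    phenotypes = default_phenotype_map()
    report = PipelineReport("fixture", config.seed, asdict(config))

    cores: dict[str, set[str]] = {}
    for stress, table in tables.items():
        deg_sets = {sp: table.significant(sp) for sp in species}
        cores[stress] = xs.core_conserved_set(deg_sets)
        report.headline[f"core_{stress}"] = len(cores[stress])
        venn = xs.venn_counts(table)
        report.tables[f"venn_{stress}"] = pd.DataFrame(
            {"region": [_region_key(r) for r in venn], "count": list(venn.values())}
        ).sort_values("region", ignore_index=True)
    union = xs.cross_stress_core(cores)
    both = set.intersection(*cores.values()) if cores else set()
    report.headline["core_cross_stress_union"] = len(union)
    report.headline["core_overlap_between_stresses"] = len(both)

    prioritized: dict[str, list] = {}
    for stress, table in tables.items():
        include, exclude = prioritization_sets(phenotypes, stress, species)
        pri = xs.phenotype_concordant_set(table, include, exclude)
        prioritized[stress] = pri
        report.headline[f"prioritized_{stress}"] = len(pri)
        report.tables[f"prioritized_{stress}_genes"] = pd.DataFrame(
            [{"og_id": p.og_id, "flag": p.flag} for p in pri]
        )
    inverted = [p for p in prioritized["pathogen"] if p.flag == "inverted_in_contrast"]
    report.headline["inverted_pathogen"] = len(inverted)

    known = set(load_fixture("known_pathogen_genes").union())
    drawn = {p.og_id for p in prioritized["pathogen"]}
    k = len(known & drawn)
    population = PUBLISHED_UNIVERSE_SIZE
    tail = xs.hypergeom_tail(population, len(known), len(drawn), k)
    report.headline["hypergeom_population"] = population
    report.headline["hypergeom_marked"] = len(known)
    report.headline["hypergeom_drawn"] = len(drawn)
    report.headline["hypergeom_overlap"] = k
    report.headline["hypergeom_tail_p"] = tail
    log.info(
        "fixture hypergeometric: N=%d K=%d n=%d k=%d -> P=%.4g",
        population, len(known), len(drawn), k, tail,
    )
    report.stage_counts["fixture_genes"] = len(tables["pathogen"].og_ids)
    return report


# ---------------------------------------------------------------------------
# synthetic / user-data modes


def _run_de(
    counts: dict[str, CountMatrix],
    sheet: SampleSheet,
    stresses: list[str],
    generations: tuple[str, ...] = ("F1", "F3"),
) -> dict[str, dict[str, dict[str, DEResult]]]:
    """species -> generation -> stress -> DEResult (stress vs control)."""
    out: dict[str, dict[str, dict[str, DEResult]]] = {}
    for sp, cm in counts.items():
        out[sp] = {}
        for gen in generations:
            if not sheet.samples_for(sp, gen, "control"):
                continue
            out[sp][gen] = {}
            for stress in stresses:
                if not sheet.samples_for(sp, gen, stress):
                    continue
                out[sp][gen][stress] = nb_wald_contrast(
                    cm, sheet, ("control", stress), generation=gen
                )
    return out


def _analyze(
    config: AnalysisConfig,
    counts: dict[str, CountMatrix],
    sheet: SampleSheet,
    orthogroups,
    phenotypes: PhenotypeMap,
    report: PipelineReport,
    experiment: SyntheticExperiment | None = None,
    syn_config: SyntheticConfig | None = None,
) -> PipelineReport:
    species = list(counts)
    stresses = list(config.stresses)
    fc, padj = config.fold_change_threshold, config.padj_threshold

    universe = build_universe(orthogroups, counts)
    routes = universe.route_counts()
    report.stage_counts["universe"] = len(universe)
    report.headline["universe_strict"] = routes.get("strict_single_copy", 0)
    report.headline["universe_rescued"] = routes.get("rescued", 0)
    report.tables["universe"] = universe.table.reset_index()

    de = _run_de(counts, sheet, stresses)
    for sp in species:
        for gen, per_stress in de[sp].items():
            for stress, res in per_stress.items():
                report.stage_counts[f"de_{sp}_{gen}_{stress}"] = int(
                    res.table["tested"].sum()
                )

    tables: dict[str, CrossSpeciesTable] = {}
    cores: dict[str, set[str]] = {}
    for stress in stresses:
        results = {sp: de[sp]["F1"][stress] for sp in species}
        table = xs.build_table(results, universe, fc, padj)
        tables[stress] = table
        report.tables[f"cross_species_{stress}"] = table.to_frame().reset_index()
        deg_sets = {sp: table.significant(sp) for sp in species}
        cores[stress] = xs.core_conserved_set(deg_sets)
        report.headline[f"core_{stress}"] = len(cores[stress])
        venn = xs.venn_counts(table)
        report.tables[f"venn_{stress}"] = pd.DataFrame(
            {"region": [_region_key(r) for r in venn], "count": list(venn.values())}
        ).sort_values("region", ignore_index=True)
    report.headline["core_cross_stress_union"] = len(xs.cross_stress_core(cores))
    report.headline["core_overlap_between_stresses"] = len(
        set.intersection(*cores.values()) if cores else set()
    )

    prioritized: dict[str, list] = {}
    for stress in stresses:
        include, exclude = prioritization_sets(phenotypes, stress, species)
        pri = xs.phenotype_concordant_set(tables[stress], include, exclude)
        prioritized[stress] = pri
        report.headline[f"prioritized_{stress}"] = len(pri)
        report.headline[f"inverted_{stress}"] = sum(
            p.flag == "inverted_in_contrast" for p in pri
        )
        report.tables[f"prioritized_{stress}_genes"] = pd.DataFrame(
            [
                {"og_id": p.og_id, "flag": p.flag,
                 "include_statuses": ",".join(p.include_statuses)}
                for p in pri
            ]
        )

    # persistence: F1 vs F3 per species on the universe
    for sp in species:
        if "F3" not in de[sp]:
            continue
        f1_calls, f3_calls = {}, {}
        for stress in stresses:
            t_f1 = tables[stress]
            f1_calls[stress] = _calls_from_table(t_f1, sp, f"{sp}:F1:{stress}")
            t_f3 = xs.build_table(
                {sp: de[sp]["F3"][stress]},
                None,
                fc,
                padj,
            )
            # map gene index to orthogroups via the universe representatives
            reps = universe.representatives(sp)
            gene_to_og = pd.Series(reps.index.values, index=reps.values)
            s3 = t_f3.status(sp).reindex(reps.values).fillna("not_tested")
            f3_calls[stress] = DEGCall(
                f"{sp}:F3:{stress}", fc, padj,
                up=frozenset(gene_to_og[g] for g in s3.index[s3 == "up"]),
                down=frozenset(gene_to_og[g] for g in s3.index[s3 == "down"]),
            )
        overlap = xs.persistence_overlap(f1_calls, f3_calls, set(universe.og_ids))
        for key, val in overlap.counts().items():
            report.headline[f"persistence_{sp}_{key}"] = val

    # truth-dependent scoring and the timing stage (synthetic mode only)
    if experiment is not None and syn_config is not None:
        truth = experiment.truth
        predicted = xs.classify_orthogroups(tables, phenotypes)
        recovery = score_recovery(predicted, truth)
        report.headline["recovery_macro_f1"] = round(recovery.macro_f1, 4)
        for cls, row in recovery.per_class.iterrows():
            report.headline[f"recovery_sens_{cls}"] = round(float(row["sensitivity"]), 4)
        report.tables["recovery_confusion"] = recovery.confusion.reset_index(
            names="true_class"
        )

        timecourse = generate_timecourse(syn_config, truth, seed=config.seed + 1)
        ranges = embryo_range(timecourse)
        sp = "C. elegans"
        marked = truth.classes.index[
            (truth.classes != "null")
        ]
        for stress in stresses:
            ctrl = sheet.samples_for(sp, "F1", "control")
            strs = sheet.samples_for(sp, "F1", stress)
            sub = counts[sp].subset_samples(ctrl + strs)
            sf = compute_size_factors(sub)
            rl = rlog_proxy(sub, sf)
            deg_genes = de[sp]["F1"][stress]
            call = call_degs(deg_genes, fc, padj)
            verdict = flag_timing(
                call,
                {"control": rl[ctrl], stress: rl[strs]},
                ranges,
            )
            report.headline[f"timing_fraction_not_timing_{stress}"] = (
                round(verdict.fraction_not_timing, 4)
                if len(verdict.table)
                else None
            )
            report.stage_counts[f"timing_degs_{stress}"] = len(verdict.table)

        profile = generate_stage_profile(timecourse, minutes=390.0, seed=config.seed + 2)
        _, best = assign_stage(profile, timecourse)
        report.headline["stage_best_match_minutes"] = best

        # hypergeometric check on the synthetic run: marked = planted
        # pathogen-prioritizable orthogroups, draw = the prioritized list
        stress = stresses[0]
        include, _ = prioritization_sets(phenotypes, stress, species)
        planted = {
            og
            for og in universe.og_ids
            if truth.classes[og] in ("adaptive_only", "inverted")
            and any(
                truth.effects_f1[(sp2, stress)][og] != 0 for sp2 in include
            )
        }
        drawn = {p.og_id for p in prioritized[stress]}
        k = len(planted & drawn)
        tail = xs.hypergeom_tail(len(universe), len(planted), len(drawn), k)
        report.headline["hypergeom_population"] = len(universe)
        report.headline["hypergeom_marked"] = len(planted)
        report.headline["hypergeom_drawn"] = len(drawn)
        report.headline["hypergeom_overlap"] = k
        report.headline["hypergeom_tail_p"] = tail

    return report


def run_pipeline(
    config: AnalysisConfig,
    mode: str = "synthetic",
    syn_config: SyntheticConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineReport:
    """Execute the enabled stages in dependency order; see module docstring."""
    if mode == "fixture":
        report = _run_fixture(config)
    elif mode == "synthetic":
        syn_config = syn_config or SyntheticConfig(
            species=config.species, stresses=config.stresses
        )
        experiment = generate_experiment(syn_config, seed=config.seed)
        report = PipelineReport("synthetic", config.seed, asdict(config))
        report.stage_counts["orthogroups"] = len(experiment.orthogroups)
        _analyze(
            config,
            experiment.counts,
            experiment.sheet,
            experiment.orthogroups,
            experiment.phenotypes,
            report,
            experiment=experiment,
            syn_config=syn_config,
        )
    elif mode == "user_data":
        if not config.input_dir:
            raise ConfigurationError("user_data mode requires input_dir")
        indir = Path(config.input_dir)
        sheet = read_sample_sheet(indir / "samples.tsv")
        counts = {}
        for sp in config.species:
            tag = sp.replace(" ", "_").replace(".", "")
            counts[sp] = read_count_table(indir / f"counts_{tag}.tsv", species_tag=sp)
        orthogroups = read_orthogroups(indir / "orthogroups.tsv", list(config.species))
        report = PipelineReport("user_data", config.seed, asdict(config))
        _analyze(
            config, counts, sheet, orthogroups, default_phenotype_map(), report
        )
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    if outdir is not None:
        manifest = report.write(outdir)
        log.info("wrote %d files to %s", len(manifest), outdir)
    return report
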