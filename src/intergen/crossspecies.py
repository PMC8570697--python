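"""Cross-species and cross-condition set logic on the harmonized universe.

Everything downstream of per-species differential expression lives here:
per-orthogroup status tables, shared-DEG sets, Venn region counts, core
conserved sets, phenotype-informed prioritization with inversion
detection, the exact hypergeometric overlap tail, orthogroup effect-class
calls, and F1-vs-F3 persistence.

The same operations serve two modes: units are species (cross-species
comparison on a harmonized universe) or conditions within one species
(multi-pathogen comparison); the set logic is identical.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ConfigurationError, ValidationError
from .de import DEGCall, DEResult
from .orthology import HarmonizedUniverse

STATUSES = ("up", "down", "unchanged", "not_tested")


@dataclass
class CrossSpeciesTable:
    """Per-orthogroup, per-unit (species or condition) DE status.

    ``data`` maps each unit to a frame indexed by orthogroup id with
    columns ``log2fc``, ``padj``, ``status``.
    """

    data: dict[str, pd.DataFrame]
    fold_change_threshold: float = 2.0
    padj_threshold: float = 0.01

    def __post_init__(self) -> None:
        units = list(self.data)
        if not units:
            raise ValidationError("cross-species table needs at least one unit")
        index = self.data[units[0]].index
        for u in units[1:]:
            if not self.data[u].index.equals(index):
                raise ValidationError("units disagree on the orthogroup index")
        for u, frame in self.data.items():
            bad = set(frame["status"]) - set(STATUSES)
            if bad:
                raise ValidationError(f"unit {u}: unknown statuses {bad}")

    @property
    def units(self) -> list[str]:
        return list(self.data)

    @property
    def og_ids(self) -> pd.Index:
        return self.data[self.units[0]].index

    def status(self, unit: str) -> pd.Series:
        return self.data[unit]["status"]

    def significant(self, unit: str) -> set[str]:
        s = self.status(unit)
        return set(s.index[s.isin(["up", "down"])])

    def to_frame(self) -> pd.DataFrame:
        parts = {
            (u, col): self.data[u][col]
            for u in self.units
            for col in ("log2fc", "padj", "status")
        }
        out = pd.DataFrame(parts)
        out.columns = [f"{u}::{col}" for u, col in out.columns]
        return out


@dataclass(frozen=True)
class PhenotypeMap:
    """Per stress: species -> phenotypic outcome of the parental exposure."""

    labels: dict[str, dict[str, str]]  # stress -> species -> label

    VALID = ("adaptive", "deleterious", "none")

    def __post_init__(self) -> None:
        for stress, per_species in self.labels.items():
            bad = set(per_species.values()) - set(self.VALID)
            if bad:
                raise ValidationError(f"stress {stress}: unknown phenotype labels {bad}")

    def include_species(self, stress: str) -> set[str]:
        """Species whose offspring phenotypically adapt to the stress."""
        return {sp for sp, lab in self.labels[stress].items() if lab == "adaptive"}

    def contrast_species(self, stress: str) -> set[str]:
        """Species with a deleterious intergenerational outcome."""
        return {sp for sp, lab in self.labels[stress].items() if lab == "deleterious"}


def default_phenotype_map() -> PhenotypeMap:
    """The observed phenotype pattern: parental infection protects
    C. elegans and C. kamaaina offspring, kills C. briggsae offspring and
    does nothing in C. tropicalis; parental osmotic stress protects all
    but C. tropicalis."""
    return PhenotypeMap(
        {
            "pathogen": {
                "C. elegans": "adaptive",
                "C. kamaaina": "adaptive",
                "C. briggsae": "deleterious",
                "C. tropicalis": "none",
            },
            "osmotic": {
                "C. elegans": "adaptive",
                "C. briggsae": "adaptive",
                "C. kamaaina": "adaptive",
                "C. tropicalis": "none",
            },
        }
    )


@dataclass(frozen=True)
class PrioritizedGene:
    og_id: str
    include_statuses: tuple[str, ...]
    exclude_statuses: tuple[str, ...]
    flag: str  # absent_in_contrast | inverted_in_contrast


def build_table(
    results: dict[str, DEResult],
    universe: HarmonizedUniverse | None = None,
    fold_change_threshold: float = 2.0,
    padj_threshold: float = 0.01,
) -> CrossSpeciesTable:
    """Assemble per-orthogroup statuses from per-unit DE results.

    With a universe, the representative gene's statistics are looked up
    per species; without one (within-species multi-condition mode) the
    DE result indices are used directly and must agree.
    """
    lfc_cut = math.log2(fold_change_threshold)
    data: dict[str, pd.DataFrame] = {}
    if universe is not None:
        missing = [sp for sp in universe.species if sp not in results]
        if missing:
            raise ConfigurationError(f"missing DE results for species {missing}")
        index = pd.Index(universe.og_ids, name="og_id")
        unit_iter = [(sp, results[sp], universe.representatives(sp)) for sp in universe.species]
    else:
        units = list(results)
        index = results[units[0]].table.index.rename("og_id")
        unit_iter = [(u, results[u], pd.Series(index, index=index)) for u in units]
    for unit, res, reps in unit_iter:
        t = res.table.reindex(reps.values)
        lfc = t["log2fc"].to_numpy()
        padj = t["padj"].to_numpy()
        tested = t["tested"].fillna(False).to_numpy(dtype=bool)
        sig = tested & ~np.isnan(padj) & (padj < padj_threshold)
        status = np.where(
            ~tested,
            "not_tested",
            np.where(
                sig & (lfc > lfc_cut),
                "up",
                np.where(sig & (lfc < -lfc_cut), "down", "unchanged"),
            ),
        )
        data[unit] = pd.DataFrame(
            {"log2fc": lfc, "padj": padj, "status": status}, index=index
        )
    return CrossSpeciesTable(data, fold_change_threshold, padj_threshold)


def shared_deg_sets(
    table: CrossSpeciesTable, unit_a: str, unit_b: str
) -> tuple[set[str], set[str]]:
    """Orthogroups significant in both units, and the direction-concordant subset."""
    sa, sb = table.status(unit_a), table.status(unit_b)
    sig = set(sa.index[sa.isin(["up", "down"]) & sb.isin(["up", "down"])])
    concordant = {og for og in sig if sa[og] == sb[og]}
    return sig, concordant


def venn_counts(
    sets_or_table: CrossSpeciesTable | dict[str, set[str]],
    units: list[str] | None = None,
) -> dict[frozenset, int]:
    """Exclusive Venn region counts over the units' significant sets.

    Each orthogroup significant anywhere lands in exactly one region: the
    exact subset of units in which it is significant.  Region counts sum
    to the size of the union.
    """
    if isinstance(sets_or_table, CrossSpeciesTable):
        units = units or sets_or_table.units
        sets = {u: sets_or_table.significant(u) for u in units}
    else:
        sets = sets_or_table
        units = units or list(sets)
    if len(units) < 2:
        raise ConfigurationError("venn_counts needs at least 2 units")
    counts: dict[frozenset, int] = {
        frozenset(combo): 0
        for r in range(1, len(units) + 1)
        for combo in itertools.combinations(units, r)
    }
    for og in set().union(*(sets[u] for u in units)):
        region = frozenset(u for u in units if og in sets[u])
        counts[region] += 1
    return counts


def core_conserved_set(deg_sets: dict[str, set[str]]) -> set[str]:
    """Orthogroups significant in every unit (all-species intersection)."""
    if not deg_sets:
        return set()
    sets = list(deg_sets.values())
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out


def cross_stress_core(per_stress_cores: dict[str, set[str]]) -> set[str]:
    """Union of the per-stress core conserved sets."""
    out: set[str] = set()
    for core in per_stress_cores.values():
        out |= core
    return out


def phenotype_concordant_set(
    table: CrossSpeciesTable,
    include: set[str],
    exclude: set[str],
) -> list[PrioritizedGene]:
    """Prioritize orthogroups by phenotype concordance.

    Returns orthogroups significant with one common direction in every
    ``include`` species and, in every ``exclude`` species, either not
    significant (flag ``absent_in_contrast``) or significant in the
    opposite direction (flag ``inverted_in_contrast``; set if any exclude
    species is inverted).  Ordered by orthogroup id.
    """
    include, exclude = set(include), set(exclude)
    if not include:
        raise ConfigurationError("include set must not be empty")
    if include & exclude:
        raise ConfigurationError("include and exclude sets overlap")
    for u in include | exclude:
        if u not in table.units:
            raise ConfigurationError(f"unit {u!r} absent from table")
    inc = sorted(include)
    exc = sorted(exclude)
    out: list[PrioritizedGene] = []
    status = {u: table.status(u) for u in inc + exc}
    for og in sorted(table.og_ids):
        inc_stat = tuple(status[u][og] for u in inc)
        if not all(s in ("up", "down") for s in inc_stat):
            continue
        if len(set(inc_stat)) != 1:
            continue  # discordant among include species
        sign = inc_stat[0]
        opposite = "down" if sign == "up" else "up"
        exc_stat = tuple(status[u][og] for u in exc)
        if any(s == sign for s in exc_stat):
            continue  # same-direction change in a contrast species
        flag = (
            "inverted_in_contrast"
            if any(s == opposite for s in exc_stat)
            else "absent_in_contrast"
        )
        out.append(PrioritizedGene(og, inc_stat, exc_stat, flag))
    return out


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    X counts marked items in a draw of ``n`` without replacement from a
    population of ``N`` containing ``K`` marked items.  Computed by
    log-gamma summation of the exact point masses.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if v != int(v) or v < 0:
            raise ValidationError(f"{name} must be a nonnegative integer, got {v}")
    if K > N or n > N:
        raise ValidationError("K and n must not exceed N")
    if k > min(K, n):
        raise ValidationError("k must not exceed min(K, n)")
    if k == 0:
        return 1.0
    denom = _log_choose(N, n)
    total = 0.0
    for i in range(k, min(K, n) + 1):
        if n - i > N - K:
            continue
        total += math.exp(_log_choose(K, i) + _log_choose(N - K, n - i) - denom)
    return min(total, 1.0)


def _log_choose(a: int, b: int) -> float:
    return float(gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1))


@dataclass
class PersistenceResult:
    """F1-vs-F3 overlap of differentially expressed orthogroups."""

    per_stress: dict[str, set[str]]
    f1_total: int
    f3_total: int

    @property
    def pooled(self) -> set[str]:
        out: set[str] = set()
        for s in self.per_stress.values():
            out |= s
        return out

    def counts(self) -> dict[str, int]:
        out = {f"overlap_{stress}": len(s) for stress, s in self.per_stress.items()}
        out["overlap_pooled"] = len(self.pooled)
        out["f1_total"] = self.f1_total
        out["f3_total"] = self.f3_total
        return out


def persistence_overlap(
    f1_calls: dict[str, DEGCall],
    f3_calls: dict[str, DEGCall],
    universe: set[str] | None = None,
) -> PersistenceResult:
    """Intersect F1 and F3 DEG sets per stress.

    ``f1_calls`` and ``f3_calls`` map stress label to a DEG call on a
    shared gene/orthogroup universe.  If ``universe`` is given, any gene
    outside it raises a validation error.
    """
    if set(f1_calls) != set(f3_calls):
        raise ValidationError(
            f"stress labels differ between generations: "
            f"{sorted(f1_calls)} vs {sorted(f3_calls)}"
        )
    per_stress: dict[str, set[str]] = {}
    f1_union: set[str] = set()
    f3_union: set[str] = set()
    for stress in f1_calls:
        f1 = set(f1_calls[stress].significant)
        f3 = set(f3_calls[stress].significant)
        if universe is not None:
            stray = (f1 | f3) - universe
            if stray:
                raise ValidationError(
                    f"genes outside the shared universe: {sorted(stray)[:5]}"
                )
        per_stress[stress] = f1 & f3
        f1_union |= f1
        f3_union |= f3
    return PersistenceResult(per_stress, len(f1_union), len(f3_union))


# ---------------------------------------------------------------------------
# effect-class calls (feeds parameter-recovery scoring)

EFFECT_CLASSES = (
    "null",
    "conserved_all",
    "adaptive_only",
    "inverted",
    "single_species",
    "shared_both_stresses",
)


def classify_orthogroups(
    tables: dict[str, CrossSpeciesTable],
    phenotypes: PhenotypeMap,
) -> pd.Series:
    """Call a conservation/inversion class per orthogroup.

    ``tables`` maps each stress to its cross-species status table.  For
    each orthogroup, in priority order: same-direction significance in
    all species under both stresses (``shared_both_stresses``), under one
    stress (``conserved_all``); the inversion pattern — concordant in the
    adapting species, opposite in a deleterious-phenotype species
    (``inverted``); concordant significance confined to the adapting
    species (``adaptive_only``); significance in exactly one species and
    one stress (``single_species``); otherwise ``null``.
    """
    stresses = list(tables)
    species = tables[stresses[0]].units
    index = tables[stresses[0]].og_ids
    status = {
        stress: {sp: tables[stress].status(sp) for sp in species} for stress in stresses
    }

    def per_og(og: str) -> str:
        stat = {
            stress: {sp: status[stress][sp][og] for sp in species} for stress in stresses
        }
        same_sign_all = {
            stress: len(set(stat[stress].values())) == 1
            and next(iter(stat[stress].values())) in ("up", "down")
            for stress in stresses
        }
        if all(same_sign_all.values()):
            return "shared_both_stresses"
        if any(same_sign_all.values()):
            return "conserved_all"
        for stress in stresses:
            include = phenotypes.include_species(stress)
            contrast = phenotypes.contrast_species(stress)
            if not include:
                continue
            inc_stat = {stat[stress][sp] for sp in include}
            if len(inc_stat) == 1 and inc_stat <= {"up", "down"}:
                sign = next(iter(inc_stat))
                opposite = "down" if sign == "up" else "up"
                others = {sp for sp in species if sp not in include}
                if contrast and all(stat[stress][sp] == opposite for sp in contrast):
                    rest = others - contrast
                    if all(stat[stress][sp] not in ("up", "down") for sp in rest):
                        return "inverted"
                if all(stat[stress][sp] not in ("up", "down") for sp in others):
                    return "adaptive_only"
        sig_cells = [
            (stress, sp)
            for stress in stresses
            for sp in species
            if stat[stress][sp] in ("up", "down")
        ]
        if len(sig_cells) == 1:
            return "single_species"
        if len(sig_cells) > 1 and len({sp for _, sp in sig_cells}) == 1:
            return "single_species"  # one species responding to both stresses
        return "null"

    return pd.Series([per_og(og) for og in index], index=index, name="predicted_class")
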