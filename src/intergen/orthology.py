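"""Cross-species analysis universe: single-copy orthogroups plus rescue.

The comparative analysis runs over orthogroups with exactly one usable
gene per species.  Two routes admit an orthogroup:

* ``strict_single_copy`` — exactly one member in every species;
* ``rescued`` — multi-copy in exactly one species, where every member
  but one has zero raw counts in every sample of that species; the
  uniquely expressed member becomes the representative.

"No observable expression" is read literally as raw count 0 in every
sample supplied (threshold configurable).  A member absent from its
species' count matrix is treated as zero-expressed, with a warning.  A
species with no member at all disqualifies the orthogroup from both
routes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io import CountMatrix, OrthogroupTable

log = logging.getLogger(__name__)


@dataclass
class HarmonizedUniverse:
    """One representative gene per species for each admitted orthogroup."""

    table: pd.DataFrame  # index og_id; one column per species + "route"
    species: list[str]

    def __post_init__(self) -> None:
        routes = set(self.table["route"])
        if not routes <= {"strict_single_copy", "rescued"}:
            raise ValidationError(f"unknown selection routes: {routes}")
        for sp in self.species:
            col = self.table[sp]
            if col.isna().any() or (col == "").any():
                raise ValidationError(f"missing representative for species {sp}")
            if col.duplicated().any():
                raise ValidationError(f"a {sp} gene represents more than one orthogroup")

    @property
    def og_ids(self) -> list[str]:
        return list(self.table.index)

    def representatives(self, species: str) -> pd.Series:
        return self.table[species]

    def route_counts(self) -> dict[str, int]:
        return self.table["route"].value_counts().to_dict()

    def __len__(self) -> int:
        return len(self.table)


def select_single_copy(ogs: OrthogroupTable, species: list[str]) -> set[str]:
    """Orthogroups with exactly one member in every listed species."""
    if not species:
        raise ConfigurationError("species list must not be empty")
    selected = set()
    for og_id, members in ogs.entries.items():
        if all(len(members.get(sp, [])) == 1 for sp in species):
            selected.add(og_id)
    return selected


def _zero_expressed(gene: str, counts: CountMatrix, threshold: int = 0) -> bool:
    try:
        i = counts.gene_ids.index(gene)
    except ValueError:
        log.warning(
            "gene %s (%s) absent from count matrix; treated as zero-expressed",
            gene, counts.species_tag,
        )
        return True
    return int(counts.counts[i].max(initial=0)) <= threshold


def rescue_multi_copy(
    ogs: OrthogroupTable,
    counts: dict[str, CountMatrix],
    expression_threshold: int = 0,
) -> dict[str, dict[str, str]]:
    """Expression-based rescue of orthogroups multi-copy in one species.

    Returns ``og_id -> {species: representative}`` for orthogroups that
    are single-copy in all species but exactly one, and in that species
    all members except exactly one are unexpressed.  Non-qualifying
    orthogroups are silently excluded with a logged reason.
    """
    species = ogs.species
    rescued: dict[str, dict[str, str]] = {}
    for og_id, members in ogs.entries.items():
        sizes = {sp: len(members.get(sp, [])) for sp in species}
        if any(sz == 0 for sz in sizes.values()):
            log.debug("%s: species missing entirely, excluded", og_id)
            continue
        multi = [sp for sp in species if sizes[sp] > 1]
        if len(multi) != 1:
            if multi:
                log.debug("%s: multi-copy in %d species, excluded", og_id, len(multi))
            continue
        sp = multi[0]
        cm = counts[sp]
        expressed = [
            g for g in members[sp]
            if not _zero_expressed(g, cm, expression_threshold)
        ]
        if len(expressed) != 1:
            log.debug(
                "%s: %d expressed paralogs in %s, excluded", og_id, len(expressed), sp
            )
            continue
        reps = {s: members[s][0] for s in species if s != sp}
        reps[sp] = expressed[0]
        rescued[og_id] = reps
    return rescued


def build_universe(
    ogs: OrthogroupTable,
    counts: dict[str, CountMatrix],
    expression_threshold: int = 0,
) -> HarmonizedUniverse:
    """Union of strict single-copy and rescued orthogroups."""
    species = ogs.species
    strict = select_single_copy(ogs, species)
    rescued = rescue_multi_copy(ogs, counts, expression_threshold)
    rows = {}
    for og_id in sorted(strict):
        row = {sp: ogs.entries[og_id][sp][0] for sp in species}
        row["route"] = "strict_single_copy"
        rows[og_id] = row
    for og_id in sorted(rescued):
        row = dict(rescued[og_id])
        row["route"] = "rescued"
        rows[og_id] = row
    table = pd.DataFrame.from_dict(rows, orient="index", columns=[*species, "route"])
    table.index.name = "og_id"
    universe = HarmonizedUniverse(table, list(species))
    log.info(
        "harmonized universe: %d orthogroups (%d strict single-copy, %d rescued)",
        len(universe), len(strict), len(rescued),
    )
    assert len(universe) == len(strict) + len(rescued)
    return universe
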