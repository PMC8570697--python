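"""Published gene lists packaged as fixtures.

These transcribe, symbol for symbol, the printed tables of conserved and
phenotype-prioritized intergenerationally regulated genes: genes changed
more than twofold (padj < 0.01) in F1 offspring of stressed parents in
all four Caenorhabditis species (table1), and genes changed consistently
only in the species whose offspring phenotypically adapt to the stress
(table2).  Symbols are stored exactly as printed; matching is
case-sensitive exact string equality.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

# F1 DEGs (>2-fold, padj<0.01) in all four species after parental
# P. vranovensis infection only
_TABLE1_PATHOGEN = [
    "C18A11.1", "R13A1.5", "D1053.3", "pmp-5", "C39E9.8", "nit-1",
    "lips-10", "srr-6", "Y51B9A.6", "gst-33", "ptr-8", "ZC443.1",
    "cri-2", "Y42G9A.3", "ttr-21", "F45E4.5", "C42D4.1", "asp-14",
    "cyp-32B1", "nas-10", "W01F3.2", "nhr-11", "F26G1.2", "F48E3.2",
    "hpo-26", "R05H10.1", "C08E8.4", "C11G10.1", "Y73F4A.2", "bigr-1",
    "nlp-33", "far-3",
]

# changed in all four species after BOTH parental stresses
_TABLE1_BOTH = ["C30B5.6", "hphd-1", "C42D4.3"]

# changed in all four species after parental osmotic stress only
_TABLE1_OSMOTIC = ["ttr-15", "F08F3.4"]

# consistent >2-fold change in C. elegans and C. kamaaina (which adapt to
# P. vranovensis) but absent or inverted in C. briggsae (which does not)
_TABLE2_PATHOGEN = [
    "daf-18", "gst-38", "H04M03.3", "oops-1", "F09G8.10", "glb-1",
    "F57H12.6", "elo-6", "cpr-5", "xpo-2", "cysl-1", "rhy-1",
    "cdc-25.1", "imb-1", "VZK882L.2", "cysl-2", "cyk-7",
]

# consistent change in the three osmotic-adapting species but not C. tropicalis
_TABLE2_OSMOTIC = ["T05F1.9", "grl-21", "gpdh-1", "T22B7.3"]

# genes previously shown to be required for the intergenerational
# adaptation to each stress
_KNOWN_PATHOGEN = ["rhy-1", "cysl-1", "cysl-2"]
_KNOWN_OSMOTIC = ["gpdh-1"]

# the single prioritized gene with an inverted (opposite-direction)
# response in the non-adapting species
INVERTED_PATHOGEN_GENE = "rhy-1"


@dataclass(frozen=True)
class GeneListFixture:
    """An ordered, sectioned transcription of a published gene list."""

    name: str
    sections: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for label, genes in self.sections.items():
            if len(set(genes)) != len(genes):
                raise ValidationError(f"{self.name}/{label}: duplicate gene symbols")

    def union(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sections.values():
            out.update(genes)
        return out


_FIXTURES = {
    "table1": GeneListFixture(
        "table1",
        {
            "pathogen": tuple(_TABLE1_PATHOGEN),
            "both": tuple(_TABLE1_BOTH),
            "osmotic": tuple(_TABLE1_OSMOTIC),
        },
    ),
    "table2": GeneListFixture(
        "table2",
        {
            "pathogen": tuple(_TABLE2_PATHOGEN),
            "osmotic": tuple(_TABLE2_OSMOTIC),
        },
    ),
    "known_pathogen_genes": GeneListFixture(
        "known_pathogen_genes", {"pathogen": tuple(_KNOWN_PATHOGEN)}
    ),
    "known_osmotic_genes": GeneListFixture(
        "known_osmotic_genes", {"osmotic": tuple(_KNOWN_OSMOTIC)}
    ),
}


def load_fixture(name: str) -> GeneListFixture:
    """Return a packaged gene-list fixture by name.

    Valid names: ``table1``, ``table2``, ``known_pathogen_genes``,
    ``known_osmotic_genes``.
    """
    try:
        return _FIXTURES[name]
    except KeyError:
        raise LookupError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
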